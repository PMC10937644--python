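"""Reading, validation and writing of GWAS summary-statistic tables, LD
matrices and result report tables.

The canonical summary-statistics dialect is tab-separated text with a header
row and the columns

    variant_id  chr  pos  effect_allele  other_allele  eaf  beta  se  pval  n

Positions are 1-based (GWAS convention). Missing values are written as "NA".
Rows violating basic invariants (non-positive SE, p outside (0, 1], EAF
outside (0, 1), malformed alleles) are rejected on read with counted,
logged reasons; every input row is accounted for as kept or rejected.

The LD matrix travels as a square delimited file with a leading
``variant_id`` column, plus a sidecar file of per-variant positions
(``variant_id  chr  pos``); no binary formats are used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Required columns of the canonical sumstats dialect, in canonical order.
SUMSTAT_COLUMNS = (
    "variant_id",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

_VALID_ALLELES = frozenset("ACGT")

#: Fixed column order of MR report tables (documented external interface).
MR_REPORT_COLUMNS = (
    "exposure",
    "outcome",
    "method",
    "n_snp",
    "estimate",
    "se",
    "ci_low",
    "ci_high",
    "odds_ratio",
    "or_ci_low",
    "or_ci_high",
    "pval",
    "q_stat",
    "i2",
    "egger_intercept",
    "egger_intercept_se",
    "egger_intercept_p",
    "outliers_removed",
)

#: Fixed column order of mediation report tables.
MEDIATION_REPORT_COLUMNS = (
    "exposure",
    "mediator",
    "outcome",
    "beta_exp_to_med",
    "se_exp_to_med",
    "beta_med_to_outcome_direct",
    "se_med_to_outcome_direct",
    "total_effect",
    "se_total",
    "indirect",
    "se_indirect",
    "direct",
    "proportion",
    "se_proportion",
    "ci_low_raw",
    "ci_high_raw",
    "ci_low",
    "ci_high",
    "weak_total",
)


class SumstatsError(ValueError):
    """Raised for unreadable or structurally invalid sumstats input."""


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a summary-statistics table, validating every row.

    Parameters
    ----------
    path
        Delimited text file (tab-separated by default dialect).
    column_map
        Optional mapping from canonical column name to the name used in the
        file, for ingesting external dialects. Files written by this package
        need no overrides.

    Returns
    -------
    DataFrame with the canonical columns. Rejected-row counts by reason are
    stored in ``df.attrs["rejections"]`` and the raw row count in
    ``df.attrs["n_read"]``.

    Raises
    ------
    SumstatsError
        If a required column is missing or no valid rows remain.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=True)
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in SUMSTAT_COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise SumstatsError(f"{path}: missing required column(s): {missing}")
    df = raw.rename(columns=rename)[list(SUMSTAT_COLUMNS)].copy()
    df, rejections = _validate_rows(df)
    df.attrs["rejections"] = rejections
    df.attrs["n_read"] = len(raw)
    for reason, n in rejections.items():
        logger.warning("read_sumstats(%s): rejected %d row(s): %s", path.name, n, reason)
    if len(df) == 0:
        raise SumstatsError(f"{path}: zero valid rows after validation")
    return df


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Coerce dtypes, normalize alleles and drop invalid rows.

    The first failing check (in documented precedence order) names the
    rejection reason so that n_read == n_kept + sum(rejections.values()).
    """
    df = df.copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("pos", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    reasons = pd.Series("", index=df.index, dtype=object)

    def mark(mask: pd.Series, reason: str) -> None:
        mask = mask & (reasons == "")
        reasons[mask] = reason

    numeric_cols = ["pos", "eaf", "beta", "se", "pval", "n"]
    mark(df["variant_id"].isna() | df[numeric_cols].isna().any(axis=1), "missing_value")
    mark(
        ~df["effect_allele"].isin(_VALID_ALLELES)
        | ~df["other_allele"].isin(_VALID_ALLELES),
        "invalid_allele",
    )
    mark(df["effect_allele"] == df["other_allele"], "allele_conflict")
    mark(~(df["se"] > 0), "nonpositive_se")
    mark(~((df["pval"] > 0) & (df["pval"] <= 1)), "invalid_pval")
    mark(~((df["eaf"] > 0) & (df["eaf"] < 1)), "invalid_eaf")
    mark(~(df["n"] > 0), "nonpositive_n")

    rejections = reasons[reasons != ""].value_counts().to_dict()
    kept = df[reasons == ""].copy()
    kept["pos"] = kept["pos"].astype(np.int64)
    kept["n"] = kept["n"].astype(np.int64)
    kept["chr"] = kept["chr"].astype(str)
    kept["variant_id"] = kept["variant_id"].astype(str)
    return kept.reset_index(drop=True), rejections


def write_sumstats(table: pd.DataFrame, path: str | Path) -> None:
    """Write a sumstats table in the canonical TSV dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table[list(SUMSTAT_COLUMNS)]
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


@dataclass
class LdMatrix:
    """Pairwise LD (correlation r, not r^2) between variants.

    Attributes
    ----------
    variant_ids : ordered variant identifiers, matching matrix rows/columns.
    r : symmetric correlation matrix with unit diagonal, entries in [-1, 1].
    positions : DataFrame indexed by variant_id with columns chr, pos.
    """

    variant_ids: list[str]
    r: np.ndarray
    positions: pd.DataFrame
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise ValueError(f"LD matrix shape {self.r.shape} != ({k}, {k})")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise ValueError("LD matrix diagonal must be 1")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("LD matrix must be symmetric (to 1e-12)")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("LD entries must lie in [-1, 1]")
        missing = set(self.variant_ids) - set(self.positions.index)
        if missing:
            raise ValueError(f"positions missing for {sorted(missing)[:5]} ...")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.r_between(a, b) ** 2


def write_ld_matrix(ld: LdMatrix, path: str | Path, positions_path: str | Path) -> None:
    """Write an LD matrix and its positions sidecar as TSV."""
    path, positions_path = Path(path), Path(positions_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mat = pd.DataFrame(ld.r, columns=ld.variant_ids)
    mat.insert(0, "variant_id", ld.variant_ids)
    mat.to_csv(path, sep="\t", index=False, float_format="%.10g")
    pos = ld.positions.loc[ld.variant_ids].reset_index()
    pos.columns = ["variant_id", "chr", "pos"]
    pos.to_csv(positions_path, sep="\t", index=False)


def read_ld_matrix(path: str | Path, positions_path: str | Path) -> LdMatrix:
    """Read an LD matrix written by :func:`write_ld_matrix`."""
    mat = pd.read_csv(path, sep="\t")
    variant_ids = mat["variant_id"].astype(str).tolist()
    r = mat[variant_ids].to_numpy(dtype=float)
    pos = pd.read_csv(positions_path, sep="\t", dtype={"variant_id": str, "chr": str})
    pos = pos.set_index("variant_id")[["chr", "pos"]]
    return LdMatrix(variant_ids=variant_ids, r=r, positions=pos)


def _format_or(estimate: float, scale: str) -> float | None:
    if scale == "log_odds" and estimate is not None and math.isfinite(estimate):
        return math.exp(estimate)
    return None


def write_report_table(results: Sequence, path: str | Path) -> pd.DataFrame:
    """Write a homogeneous list of MR or mediation results as a report TSV.

    MR rows gain odds-ratio columns (exp of the estimate and CI bounds) when
    the result is on the log-odds scale; per-SD results leave them as NA.
    An empty list yields a header-only MR-format file. The written frame is
    returned for convenience.
    """
    from .estimators import MRResult  # local import to avoid a cycle
    from .mediation import MediationResult

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results = list(results)
    kinds = {type(r) for r in results}
    if len(kinds) > 1:
        raise ValueError(f"mixed result types in report: {sorted(k.__name__ for k in kinds)}")

    if results and isinstance(results[0], MediationResult):
        rows = [r.to_row() for r in results]
        df = pd.DataFrame(rows, columns=list(MEDIATION_REPORT_COLUMNS))
    else:
        rows = []
        for r in results:
            if not isinstance(r, MRResult):
                raise ValueError(f"unsupported result type {type(r).__name__}")
            rows.append(
                {
                    "exposure": r.exposure,
                    "outcome": r.outcome,
                    "method": r.method,
                    "n_snp": r.n_snp,
                    "estimate": r.estimate,
                    "se": r.se,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "odds_ratio": _format_or(r.estimate, r.scale),
                    "or_ci_low": _format_or(r.ci_low, r.scale),
                    "or_ci_high": _format_or(r.ci_high, r.scale),
                    "pval": r.pval,
                    "q_stat": r.q_stat,
                    "i2": r.i2,
                    "egger_intercept": r.egger_intercept,
                    "egger_intercept_se": r.egger_intercept_se,
                    "egger_intercept_p": r.egger_intercept_p,
                    "outliers_removed": ",".join(r.outliers_removed) if r.outliers_removed else "",
                }
            )
        df = pd.DataFrame(rows, columns=list(MR_REPORT_COLUMNS))
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
    return df


def read_report_table(path: str | Path) -> pd.DataFrame:
    """Parse a report TSV back into a DataFrame (estimates to full float)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
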