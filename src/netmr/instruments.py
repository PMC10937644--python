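"""Genetic-instrument selection and harmonization.

Selection applies, in order: the significance threshold, MAF/biallelic
filters, greedy LD clumping, and the per-variant F-statistic screen
F = (beta/SE)^2 > f_min. Clumping repeatedly takes the smallest-p unclaimed
variant as an index and removes unclaimed variants on the same chromosome
within +/- window_bp whose r^2 with the index reaches the threshold; ties at
equal p break on (chr, pos) then variant_id, so the result is fully
deterministic.

Harmonization aligns outcome (and additional exposure) tables to the first
exposure table's effect allele: swapped alleles flip the beta sign and EAF;
strand flips are resolved by complementing; palindromic (A/T, C/G) pairs are
excluded as ambiguous when the minor-allele frequency exceeds the
configurable cutoff in either table, and otherwise aligned so the effect
alleles' frequencies fall on the same side of 0.5. Every excluded variant is
recorded with its reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import LdMatrix

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = ({"A", "T"}, {"C", "G"})


class EmptyInstrumentSet(ValueError):
    """Raised when a selection stage empties the instrument set."""

    def __init__(self, stage: str, detail: str = ""):
        self.stage = stage
        super().__init__(f"no instruments remain after stage {stage!r}" + (f": {detail}" if detail else ""))


@dataclass
class InstrumentConfig:
    """Instrument-selection thresholds.

    ``p_threshold`` is the genome-wide default; weakly-instrumented dietary
    traits conventionally use the relaxed 1e-5 (set per trait through
    ``p_threshold_by_trait`` in the pipeline config).
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_bp: int = 10_000_000
    f_min: float = 10.0
    palindrome_maf_max: float = 0.42
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    biallelic_only: bool = True

    def validate(self) -> None:
        if not (0 < self.clump_r2 < 1):
            raise ValueError(f"clump_r2 must be in (0, 1), got {self.clump_r2}")
        if self.clump_window_bp <= 0:
            raise ValueError("clump_window_bp must be positive")
        if self.f_min < 0:
            raise ValueError("f_min must be >= 0")
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")


@dataclass
class HarmonizedSet:
    """Variants aligned to a common effect allele across one or more
    exposures and one outcome — the matrix fed to every MR estimator."""

    variant_ids: list[str]
    beta_exposures: np.ndarray  # (n_snp, k)
    se_exposures: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    exposure_names: list[str]
    exclusions: list[tuple[str, str]] = field(default_factory=list)
    exposure_tables: list[pd.DataFrame] | None = None
    outcome_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.beta_exposures = np.atleast_2d(np.asarray(self.beta_exposures, dtype=float))
        if self.beta_exposures.shape[0] == 1 and len(self.variant_ids) > 1:
            self.beta_exposures = self.beta_exposures.T
        self.se_exposures = np.asarray(self.se_exposures, dtype=float).reshape(self.beta_exposures.shape)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float).ravel()
        self.se_outcome = np.asarray(self.se_outcome, dtype=float).ravel()
        n = len(self.variant_ids)
        if self.beta_exposures.shape[0] != n or len(self.beta_outcome) != n:
            raise ValueError("row counts of harmonized arrays disagree")
        if np.any(~np.isfinite(self.beta_exposures)) or np.any(~np.isfinite(self.beta_outcome)):
            raise ValueError("harmonized set contains missing values")
        if np.any(self.se_exposures <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("all standard errors must be positive")

    @property
    def n_snp(self) -> int:
        return len(self.variant_ids)

    @property
    def k(self) -> int:
        return self.beta_exposures.shape[1]

    def subset(self, keep: Sequence[int] | np.ndarray) -> "HarmonizedSet":
        keep = np.asarray(keep)
        return HarmonizedSet(
            variant_ids=[self.variant_ids[i] for i in keep],
            beta_exposures=self.beta_exposures[keep],
            se_exposures=self.se_exposures[keep],
            beta_outcome=self.beta_outcome[keep],
            se_outcome=self.se_outcome[keep],
            exposure_names=list(self.exposure_names),
            exclusions=list(self.exclusions),
        )


def _r2_lookup(ld: LdMatrix, a: str, b: str, same_chr: bool, within_window: bool) -> float:
    """LD between a pair, with the documented missing-pair policy: pairs the
    matrix does not cover are independent only when they could not be in the
    same clump (different chromosome or outside the window); otherwise
    assuming independence would be unsafe and we error."""
    if a in ld and b in ld:
        return ld.r2(a, b)
    if not (same_chr and within_window):
        return 0.0
    raise KeyError(
        f"LD for pair ({a}, {b}) within the clumping window is not covered by the supplied matrix"
    )


def clump(
    table: pd.DataFrame,
    ld: LdMatrix,
    r2: float = 0.001,
    window_bp: int = 10_000_000,
) -> pd.DataFrame:
    """Greedy p-ordered LD clumping; returns the retained index variants.

    Removed variants are recorded in ``result.attrs["clumped_away"]`` as a
    list of (variant_id, index_variant_id).
    """
    if len(table) == 0:
        raise EmptyInstrumentSet("clump", "empty input table")
    df = table.sort_values(
        by=["pval", "chr", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    claimed = np.zeros(len(df), dtype=bool)
    retained: list[int] = []
    removed: list[tuple[str, str]] = []
    chrs = df["chr"].to_numpy()
    poss = df["pos"].to_numpy()
    ids = df["variant_id"].to_numpy()
    for i in range(len(df)):
        if claimed[i]:
            continue
        retained.append(i)
        claimed[i] = True
        same_chr = chrs == chrs[i]
        within = np.abs(poss - poss[i]) <= window_bp
        for j in np.flatnonzero(same_chr & within & ~claimed):
            if _r2_lookup(ld, ids[i], ids[j], True, True) >= r2:
                claimed[j] = True
                removed.append((ids[j], ids[i]))
    out = df.iloc[retained].sort_values(["chr", "pos"]).reset_index(drop=True)
    out.attrs["clumped_away"] = removed
    return out


def select_instruments(
    table: pd.DataFrame,
    config: InstrumentConfig,
    ld: LdMatrix,
    p_threshold: float | None = None,
) -> pd.DataFrame:
    """Full instrument-selection cascade for one exposure table.

    Stages: significance threshold -> MAF/biallelic filters -> LD clumping
    -> F-statistic screen. An exclusion log (variant_id, stage, reason)
    accumulates in ``result.attrs["exclusions"]``; emptying the set at any
    stage raises :class:`EmptyInstrumentSet` naming that stage.
    """
    config.validate()
    p_thr = config.p_threshold if p_threshold is None else p_threshold
    exclusions: list[tuple[str, str, str]] = []

    sig = table[table["pval"] < p_thr]
    for v in table.loc[~table.index.isin(sig.index), "variant_id"]:
        exclusions.append((v, "significance", "above_p_threshold"))
    if len(sig) == 0:
        raise EmptyInstrumentSet("significance", f"no variant with p < {p_thr:g}")

    maf = np.minimum(sig["eaf"], 1 - sig["eaf"])
    ok_maf = maf > config.maf_min
    biallelic = (
        sig["effect_allele"].isin(_COMPLEMENT) & sig["other_allele"].isin(_COMPLEMENT)
        if config.biallelic_only
        else pd.Series(True, index=sig.index)
    )
    for v in sig.loc[~ok_maf, "variant_id"]:
        exclusions.append((v, "filters", "low_maf"))
    for v in sig.loc[ok_maf & ~biallelic, "variant_id"]:
        exclusions.append((v, "filters", "not_biallelic"))
    filtered = sig[ok_maf & biallelic].reset_index(drop=True)
    if len(filtered) == 0:
        raise EmptyInstrumentSet("filters")

    clumped = clump(filtered, ld, r2=config.clump_r2, window_bp=config.clump_window_bp)
    for v, index_v in clumped.attrs["clumped_away"]:
        exclusions.append((v, "clump", f"clumped_with:{index_v}"))
    f_stat = (clumped["beta"] / clumped["se"]) ** 2
    strong = f_stat >= config.f_min
    for v in clumped.loc[~strong, "variant_id"]:
        exclusions.append((v, "f_statistic", "weak_instrument"))
    result = clumped[strong].reset_index(drop=True)
    if len(result) == 0:
        raise EmptyInstrumentSet("f_statistic")
    result.attrs["exclusions"] = exclusions
    logger.info(
        "select_instruments: %d/%d retained (%d excluded)",
        len(result), len(table), len(exclusions),
    )
    return result


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in _PALINDROMIC


def _align_record(
    ref_ea: str, ref_oa: str, ref_eaf: float,
    ea: str, oa: str, eaf: float, beta: float,
    palindrome_maf_max: float,
) -> tuple[float, float] | str:
    """Align one record to the reference orientation.

    Returns (aligned beta, aligned eaf), or a rejection reason string.
    """
    if _is_palindromic(ref_ea, ref_oa):
        if not _is_palindromic(ea, oa) or {ea, oa} != {ref_ea, ref_oa}:
            return "allele_mismatch"
        if min(ref_eaf, 1 - ref_eaf) > palindrome_maf_max or min(eaf, 1 - eaf) > palindrome_maf_max:
            return "ambiguous_palindrome"
        # strand cannot be resolved from alleles; use EAF-side agreement
        if (eaf > 0.5) == (ref_eaf > 0.5):
            return beta, eaf
        return -beta, 1 - eaf
    if (ea, oa) == (ref_ea, ref_oa):
        return beta, eaf
    if (ea, oa) == (ref_oa, ref_ea):
        return -beta, 1 - eaf
    cea, coa = _COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(oa, "?")
    if (cea, coa) == (ref_ea, ref_oa):  # strand flip only
        return beta, eaf
    if (cea, coa) == (ref_oa, ref_ea):  # strand flip + swap
        return -beta, 1 - eaf
    return "allele_mismatch"


def harmonize(
    exposure_tables: pd.DataFrame | Sequence[pd.DataFrame],
    outcome_table: pd.DataFrame,
    palindrome_maf_max: float = 0.42,
    exposure_names: Sequence[str] | None = None,
    outcome_name: str | None = None,
) -> HarmonizedSet:
    """Align one or more exposure tables and an outcome table to a common
    effect allele per shared variant.

    The first exposure table defines the reference orientation. Variants
    missing from any table, with irreconcilable alleles, or palindromic with
    minor-allele frequency above ``palindrome_maf_max`` in any table are
    excluded with a recorded reason. Harmonizing an already-harmonized set
    is a no-op.
    """
    if isinstance(exposure_tables, pd.DataFrame):
        exposure_tables = [exposure_tables]
    exposure_tables = list(exposure_tables)
    if not exposure_tables:
        raise ValueError("at least one exposure table is required")
    names = list(exposure_names or [f"exposure_{i+1}" for i in range(len(exposure_tables))])

    ref = exposure_tables[0].set_index("variant_id")
    others = [t.set_index("variant_id") for t in exposure_tables[1:]]
    out = outcome_table.set_index("variant_id")

    exclusions: list[tuple[str, str]] = []
    shared: list[str] = []
    for v in ref.index:
        if v not in out.index:
            exclusions.append((v, "missing_in_outcome"))
        elif any(v not in t.index for t in others):
            exclusions.append((v, "missing_exposure_beta"))
        else:
            shared.append(v)
    if not shared:
        raise ValueError("zero shared variants between exposure and outcome tables")

    kept_ids: list[str] = []
    beta_x: list[list[float]] = []
    se_x: list[list[float]] = []
    beta_y: list[float] = []
    se_y: list[float] = []
    aligned_exp: list[list] = [[] for _ in range(len(exposure_tables))]
    aligned_out: list = []

    for v in shared:
        r = ref.loc[v]
        row_betas = [float(r["beta"])]
        row_ses = [float(r["se"])]
        reason = None
        aligned_other_rows = []
        for t in others:
            o = t.loc[v]
            res = _align_record(
                r["effect_allele"], r["other_allele"], float(r["eaf"]),
                o["effect_allele"], o["other_allele"], float(o["eaf"]), float(o["beta"]),
                palindrome_maf_max,
            )
            if isinstance(res, str):
                reason = res
                break
            b, eaf = res
            row_betas.append(b)
            row_ses.append(float(o["se"]))
            orow = o.copy()
            orow["beta"], orow["eaf"] = b, eaf
            orow["effect_allele"], orow["other_allele"] = r["effect_allele"], r["other_allele"]
            aligned_other_rows.append(orow)
        if reason is None:
            # reference palindrome ambiguity applies even with k=1 exposures
            if _is_palindromic(r["effect_allele"], r["other_allele"]) and min(
                float(r["eaf"]), 1 - float(r["eaf"])
            ) > palindrome_maf_max:
                reason = "ambiguous_palindrome"
        if reason is None:
            o = out.loc[v]
            res = _align_record(
                r["effect_allele"], r["other_allele"], float(r["eaf"]),
                o["effect_allele"], o["other_allele"], float(o["eaf"]), float(o["beta"]),
                palindrome_maf_max,
            )
            if isinstance(res, str):
                reason = res
        if reason is not None:
            exclusions.append((v, reason))
            continue
        b_out, eaf_out = res
        kept_ids.append(v)
        beta_x.append(row_betas)
        se_x.append(row_ses)
        beta_y.append(b_out)
        se_y.append(float(out.loc[v, "se"]))
        aligned_exp[0].append(ref.loc[v])
        for i, orow in enumerate(aligned_other_rows):
            aligned_exp[i + 1].append(orow)
        out_row = out.loc[v].copy()
        out_row["beta"], out_row["eaf"] = b_out, eaf_out
        out_row["effect_allele"], out_row["other_allele"] = r["effect_allele"], r["other_allele"]
        aligned_out.append(out_row)

    if not kept_ids:
        raise ValueError("harmonization excluded every shared variant")
    exp_frames = [
        pd.DataFrame(rows).rename_axis("variant_id").reset_index() for rows in aligned_exp
    ]
    out_frame = pd.DataFrame(aligned_out).rename_axis("variant_id").reset_index()
    hs = HarmonizedSet(
        variant_ids=kept_ids,
        beta_exposures=np.asarray(beta_x),
        se_exposures=np.asarray(se_x),
        beta_outcome=np.asarray(beta_y),
        se_outcome=np.asarray(se_y),
        exposure_names=names,
        exclusions=exclusions,
        exposure_tables=exp_frames,
        outcome_table=out_frame,
    )
    for v, reason in exclusions:
        logger.info("harmonize: excluded %s (%s)", v, reason)
    return hs


def mvmr_instrument_union(
    exposure_tables: Sequence[pd.DataFrame],
    config: InstrumentConfig,
    ld: LdMatrix,
    p_thresholds: Mapping[int, float] | Sequence[float] | None = None,
) -> pd.DataFrame:
    """Instrument list for multivariable MR.

    Variants passing any table's own significance threshold are merged
    *before* clumping; each union variant carries the smallest p-value of
    its association with any of the traits, and one clumping pass on that
    minimum p yields the final independent set.
    """
    if len(exposure_tables) < 2:
        raise ValueError("mvmr_instrument_union requires at least two exposure tables")
    config.validate()
    if p_thresholds is None:
        thresholds = [config.p_threshold] * len(exposure_tables)
    elif isinstance(p_thresholds, Mapping):
        thresholds = [p_thresholds.get(i, config.p_threshold) for i in range(len(exposure_tables))]
    else:
        thresholds = list(p_thresholds)

    candidates: dict[str, pd.Series] = {}
    for table, thr in zip(exposure_tables, thresholds):
        sig = table[table["pval"] < thr]
        maf = np.minimum(sig["eaf"], 1 - sig["eaf"])
        sig = sig[maf > config.maf_min]
        for _, row in sig.iterrows():
            v = row["variant_id"]
            if v not in candidates or row["pval"] < candidates[v]["pval"]:
                candidates[v] = row
    if not candidates:
        raise EmptyInstrumentSet("mvmr_union", "no variant significant for any exposure")
    union = pd.DataFrame(list(candidates.values())).reset_index(drop=True)
    return clump(union, ld, r2=config.clump_r2, window_bp=config.clump_window_bp)
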