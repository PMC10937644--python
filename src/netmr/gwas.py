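"""Per-SNP association testing on individual-level data.

The association model is ordinary least squares of the phenotype on the
allele dosage plus covariates and an intercept — a linear model even for
binary outcomes (the linear probability model), with an optional explicit
conversion of linear-scale effects to the log-odds scale,
``beta / (mu * (1 - mu))`` with ``mu`` the case fraction.

SNPs failing the minor-allele-frequency or Hardy–Weinberg filters are
dropped before testing, with counted, logged reasons. p-values come from
the t distribution with n − k residual degrees of freedom.

Implementation note: the per-SNP regressions are computed by residualizing
both the phenotype and every dosage column on the covariate design once
(Frisch–Waugh–Lovell), which is algebraically identical to fitting the full
joint OLS per SNP but runs as a handful of matrix products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import SyntheticStudy

logger = logging.getLogger(__name__)


@dataclass
class GwasConfig:
    """Filters and model options for the association scan."""

    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    covariate_names: Sequence[str] = field(
        default_factory=lambda: ("sex", "age", "pc1", "pc2", "pc3", "pc4")
    )
    outcome_is_binary: bool = False
    scale_conversion: str = "none"  # none | linear_prob_to_logodds

    def validate(self) -> None:
        if not (0 < self.maf_min < 0.5):
            raise ValueError(f"maf_min must be in (0, 0.5), got {self.maf_min}")
        if not (0 < self.hwe_p_min < 1):
            raise ValueError(f"hwe_p_min must be in (0, 1), got {self.hwe_p_min}")
        if self.scale_conversion not in ("none", "linear_prob_to_logodds"):
            raise ValueError(f"unknown scale_conversion {self.scale_conversion!r}")


def hwe_test(genotype_counts: Sequence[int]) -> float:
    """Hardy–Weinberg equilibrium p-value from genotype counts.

    Pearson 1-df chi-square of the observed (n0, n1, n2) dosage counts
    against the expectation n*(1-p)^2, 2np(1-p), np^2 at the sample allele
    frequency p. With a complete heterozygote deficit the statistic equals
    the sample size.
    """
    n0, n1, n2 = (float(c) for c in genotype_counts)
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (n1 + 2.0 * n2) / (2.0 * n)
    expected = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    observed = np.array([n0, n1, n2])
    if p in (0.0, 1.0):
        return 1.0  # monomorphic: trivially in equilibrium
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvals(genotypes: np.ndarray) -> np.ndarray:
    """Vectorized HWE chi-square p per column of an integer dosage matrix."""
    n = genotypes.shape[0]
    n2 = (genotypes == 2).sum(axis=0).astype(float)
    n1 = (genotypes == 1).sum(axis=0).astype(float)
    n0 = n - n1 - n2
    p = (n1 + 2 * n2) / (2.0 * n)
    with np.errstate(divide="ignore", invalid="ignore"):
        e0, e1, e2 = n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2
        chi2 = (n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2
    chi2 = np.where((p == 0) | (p == 1), 0.0, chi2)
    return stats.chi2.sf(chi2, df=1)


@dataclass
class IndividualData:
    """Minimal individual-level container for the association scan.

    Duck-type compatible with :class:`netmr.simulate.SyntheticStudy`:
    exposes ``genotypes``, ``variant_ids``, ``covariates`` and
    ``phenotype(trait)``. ``variants`` (variant_id/chr/pos/alleles metadata)
    is optional; placeholders are emitted when absent.
    """

    genotypes: np.ndarray
    variant_ids: Sequence[str]
    covariates: pd.DataFrame
    phenotypes: dict[str, np.ndarray]
    variants: pd.DataFrame | None = None

    def phenotype(self, trait: str) -> np.ndarray:
        return self.phenotypes[trait]


def _variant_meta(study, idx: np.ndarray) -> pd.DataFrame | None:
    variants = None
    if hasattr(study, "truth"):
        variants = study.truth.variants
    elif getattr(study, "variants", None) is not None:
        variants = study.variants
    return variants.iloc[idx] if variants is not None else None


def run_gwas(
    study: "SyntheticStudy | IndividualData",
    trait: str,
    config: GwasConfig | None = None,
) -> pd.DataFrame:
    """Association scan of one trait against every SNP in the study.

    Returns the canonical sumstats table (see :mod:`netmr.io`); for binary
    outcomes with ``scale_conversion='linear_prob_to_logodds'`` the beta/se
    columns carry the converted log-odds values and the linear-scale
    originals are kept as ``beta_linear``/``se_linear``. Filtered SNPs are
    absent from the output; exclusion counts by reason are stored in
    ``table.attrs["exclusions"]`` and logged.
    """
    config = config or GwasConfig()
    config.validate()
    y = np.asarray(study.phenotype(trait), dtype=float)
    if config.outcome_is_binary and config.scale_conversion == "linear_prob_to_logodds":
        mu = y.mean()
        if mu * (1.0 - mu) == 0:
            raise ValueError(
                f"phenotype {trait!r} has zero variance: log-odds conversion undefined"
            )
    genotypes = np.asarray(study.genotypes)
    n, m = genotypes.shape
    if len(y) != n or len(study.covariates) != n:
        raise ValueError("genotype, phenotype and covariate row counts differ")

    cov = study.covariates[list(config.covariate_names)].to_numpy(dtype=float)
    design = np.column_stack([np.ones(n), cov])
    k = design.shape[1] + 1  # + the SNP column
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("singular covariate design matrix")

    eaf = genotypes.mean(axis=0) / 2.0
    maf = np.minimum(eaf, 1 - eaf)
    hwe_p = _hwe_pvals(genotypes.astype(np.int64))
    keep = np.ones(m, dtype=bool)
    exclusions: dict[str, int] = {}
    low_maf = maf <= config.maf_min
    exclusions["low_maf"] = int(low_maf.sum())
    keep &= ~low_maf
    hwe_fail = (hwe_p <= config.hwe_p_min) & keep
    exclusions["hwe_fail"] = int(hwe_fail.sum())
    keep &= ~hwe_fail
    for reason, count in exclusions.items():
        if count:
            logger.info("run_gwas(%s): dropped %d SNP(s): %s", trait, count, reason)

    idx = np.flatnonzero(keep)
    G = genotypes[:, idx].astype(float)

    # Frisch–Waugh–Lovell: residualize y and every dosage column on covariates
    Q, _ = np.linalg.qr(design)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)

    gg = np.einsum("ij,ij->j", G_r, G_r)
    gy = G_r.T @ y_r
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
    rss = np.maximum(0.0, y_r @ y_r - beta * gy)  # clamp rounding negatives
    df = n - k
    sigma2 = rss / df
    se = np.sqrt(sigma2 / gg)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=df)
    # degenerate exact fits: se == 0 with a nonzero beta is a perfect
    # relation (p -> 0); a zero beta with zero residual is a null fit (p = 1)
    pval = np.where(se > 0, pval, np.where(beta != 0, np.nextafter(0, 1), 1.0))

    meta = _variant_meta(study, idx)
    table = pd.DataFrame(
        {
            "variant_id": np.asarray(study.variant_ids)[idx],
            "chr": meta["chr"].to_numpy() if meta is not None else "0",
            "pos": meta["pos"].to_numpy() if meta is not None else np.arange(len(idx)) + 1,
            "effect_allele": meta["effect_allele"].to_numpy() if meta is not None else "A",
            "other_allele": meta["other_allele"].to_numpy() if meta is not None else "G",
            "eaf": eaf[idx],
            "beta": beta,
            "se": se,
            "pval": np.clip(pval, np.nextafter(0, 1), 1.0),
            "n": n,
        }
    )
    if config.outcome_is_binary and config.scale_conversion == "linear_prob_to_logodds":
        mu = y.mean()
        scale = mu * (1.0 - mu)
        table["beta_linear"] = table["beta"]
        table["se_linear"] = table["se"]
        table["beta"] = table["beta"] / scale
        table["se"] = table["se"] / scale
    table.attrs["exclusions"] = exclusions
    return table
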