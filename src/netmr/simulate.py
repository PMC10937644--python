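"""Synthetic multi-trait GWAS study generator with a known causal DAG.

The generator emulates a network-MR study of one standardized exposure
(education), five lifestyle mediators (lifetime smoking index, BMI, drinks
per week, fruit and vegetable consumption) and seven low-prevalence binary
cancer groups. Every downstream stage of the package — GWAS, instrument
selection, harmonization, univariable and multivariable MR, mediation — can
be exercised against the recorded ground truth without any external data.

Structural model (per individual)::

    X      = G_x b_x + g C + e_x                    (standardized exposure)
    M_j    = a_j X + G_j b_j + g C + e_j            (standardized mediators)
    Y_k    ~ Bernoulli(sigmoid(alpha_k + d_k X + sum_j t_jk M_j
                               + g_y C + pleiotropy_k . G_x))

Quantitative traits are built to unit variance analytically (the noise
variance absorbs whatever the genetic, path and covariate terms do not use),
so the configured path coefficients *are* the true standardized effects and
the recorded proportion mediated equals the product/total closed form
exactly. Outcome intercepts ``alpha_k`` are calibrated by 1-D root finding
so the mean predicted probability hits the configured prevalence.

Genotypes are Binomial(2, MAF) dosages with LD induced by a Gaussian-copula
block structure: within blocks of ``ld_block_size`` the latent haplotype
normals share a constant correlation ``ld_rho``, giving a block-constant
latent r matrix that is supplied verbatim to clumping (the realized
dosage-scale correlation is slightly attenuated relative to the latent r;
see docs/methods.md).

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawns, one child stream per trait/purpose,
so regenerating with the same seed reproduces identical output on any
platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .io import LdMatrix, write_sumstats, write_ld_matrix

EXPOSURE = "education"
MEDIATORS = ("smoking", "bmi", "drinks_per_week", "fruit", "vegetables")
OUTCOMES = (
    "digestive",
    "female_reproductive",
    "head_neck",
    "lower_gi",
    "lower_respiratory",
    "male_reproductive",
    "upper_gi",
)
QUANT_TRAITS = (EXPOSURE,) + MEDIATORS

COVARIATE_NAMES = ("sex", "age", "pc1", "pc2", "pc3", "pc4")
# Small fixed covariate effects: on quantitative traits (per-SD units) and on
# outcome log-odds. Kept modest so the trait-variance budget stays near 1.
_COV_EFFECTS_QUANT = np.array([0.10, 0.05, 0.02, 0.02, 0.02, 0.02])
_COV_EFFECTS_BINARY = np.array([0.20, 0.10, 0.05, 0.05, 0.05, 0.05])

# Non-palindromic allele pairs cycled across variants (strand-unambiguous).
_ALLELE_PAIRS = (("A", "G"), ("T", "C"), ("C", "A"), ("G", "T"))


def _default_theta_exp_to_med() -> np.ndarray:
    # education -> (smoking, bmi, drinks/week, fruit, vegetables), SD units
    return np.array([-0.22, -0.24, 0.06, math.log(1.12), math.log(1.08)])


def _default_theta_med_to_outcome() -> np.ndarray:
    # mediator -> outcome direct effects, log-odds per SD of mediator
    t = np.zeros((len(MEDIATORS), len(OUTCOMES)))
    med, out = list(MEDIATORS), list(OUTCOMES)
    t[med.index("smoking"), out.index("lower_respiratory")] = math.log(31.4)
    t[med.index("smoking"), out.index("head_neck")] = math.log(5.96)
    t[med.index("smoking"), out.index("upper_gi")] = math.log(4.12)
    t[med.index("smoking"), out.index("digestive")] = math.log(1.67)
    t[med.index("bmi"), out.index("upper_gi")] = math.log(1.64)
    t[med.index("bmi"), out.index("lower_respiratory")] = math.log(1.65)
    t[med.index("vegetables"), out.index("lower_respiratory")] = math.log(0.32)
    return t


def _default_theta_direct() -> np.ndarray:
    """Direct education->outcome log-odds chosen so the implied total effects
    for the outcomes with clear signal sit at realistic odds-ratio scales
    (total OR ~ 0.40 lower respiratory, ~ 0.59 upper GI, ~ 0.81 digestive)."""
    a = _default_theta_exp_to_med()
    b = _default_theta_med_to_outcome()
    indirect = a @ b
    out = list(OUTCOMES)
    direct = np.zeros(len(OUTCOMES))
    totals = {
        "lower_respiratory": math.log(0.40),
        "upper_gi": math.log(0.59),
        "digestive": math.log(0.81),
    }
    for name, total in totals.items():
        k = out.index(name)
        direct[k] = total - indirect[k]
    return direct


def _default_prevalence() -> np.ndarray:
    # case fractions of the seven cancer groups (order matches OUTCOMES)
    return np.array([0.0230, 0.0200, 0.0040, 0.0195, 0.0069, 0.0568, 0.0086])


@dataclass
class DagConfig:
    """Parameters of the synthetic causal DAG and sampling scheme.

    Defaults encode the study conditions the generator is meant to emulate:
    path coefficients at the scale of the headline mediation scenario
    (education -> smoking -> lower respiratory cancer, implied proportion
    mediated ~ 0.83 under the full default DAG), seven outcome prevalences
    in the 0.4-6% range, and desk-scale sample sizes.
    """

    n_snps_per_trait: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_exposure_sd: float = 0.05
    theta_exp_to_med: np.ndarray = field(default_factory=_default_theta_exp_to_med)
    theta_med_to_outcome: np.ndarray = field(default_factory=_default_theta_med_to_outcome)
    theta_direct: np.ndarray = field(default_factory=_default_theta_direct)
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.02
    ld_block_size: int = 5
    ld_rho: float = 0.3
    prevalence: np.ndarray = field(default_factory=_default_prevalence)
    n_individuals: int = 30_000
    seed: int = 0
    #: Optional separate stream for individual-level sampling. The
    #: structural per-SNP effects always derive from ``seed``, so cohorts
    #: with different ``sample_seed`` are independent samples of the *same*
    #: study — the two-sample GWAS route relies on this.
    sample_seed: int | None = None

    def __post_init__(self) -> None:
        self.theta_exp_to_med = np.asarray(self.theta_exp_to_med, dtype=float)
        self.theta_med_to_outcome = np.asarray(self.theta_med_to_outcome, dtype=float)
        self.theta_direct = np.asarray(self.theta_direct, dtype=float)
        self.prevalence = np.asarray(self.prevalence, dtype=float)

    @property
    def n_mediators(self) -> int:
        return len(self.theta_exp_to_med)

    @property
    def n_outcomes(self) -> int:
        return len(self.prevalence)

    @property
    def mediator_names(self) -> tuple[str, ...]:
        return MEDIATORS[: self.n_mediators]

    @property
    def outcome_names(self) -> tuple[str, ...]:
        return OUTCOMES[: self.n_outcomes]

    @property
    def trait_names(self) -> tuple[str, ...]:
        return (EXPOSURE,) + self.mediator_names + self.outcome_names

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not (0 <= self.ld_rho < 1):
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if self.n_individuals <= 0:
            raise ValueError(f"n_individuals must be positive, got {self.n_individuals}")
        if self.n_snps_per_trait <= 0:
            raise ValueError("n_snps_per_trait must be positive")
        if self.ld_block_size <= 0:
            raise ValueError("ld_block_size must be positive")
        if np.any(self.prevalence <= 0) or np.any(self.prevalence >= 0.5):
            raise ValueError("prevalence entries must lie in (0, 0.5)")
        if self.theta_med_to_outcome.shape != (self.n_mediators, self.n_outcomes):
            raise ValueError(
                "theta_med_to_outcome shape "
                f"{self.theta_med_to_outcome.shape} != ({self.n_mediators}, {self.n_outcomes})"
            )
        if len(self.theta_direct) != self.n_outcomes:
            raise ValueError("theta_direct length must match prevalence length")
        if self.n_mediators > len(MEDIATORS) or self.n_outcomes > len(OUTCOMES):
            raise ValueError("more mediators/outcomes than named trait slots")
        totals = self.total_effects()
        indirect = self.theta_exp_to_med @ self.theta_med_to_outcome
        with np.errstate(divide="ignore", invalid="ignore"):
            pm = np.where(totals != 0, indirect / totals, 0.0)
        if np.any(~np.isfinite(pm[totals != 0])):
            raise ValueError("implied proportion mediated is not finite")

    def total_effects(self) -> np.ndarray:
        """True total exposure->outcome effects (log-odds per SD)."""
        return self.theta_direct + self.theta_exp_to_med @ self.theta_med_to_outcome

    def proportion_mediated(self, mediator: str, outcome: str) -> float:
        """Implied proportion mediated: (a_j * b_jk) / total_k."""
        j = self.mediator_names.index(mediator)
        k = self.outcome_names.index(outcome)
        total = self.total_effects()[k]
        if total == 0:
            raise ZeroDivisionError(f"total effect on {outcome} is zero")
        return float(self.theta_exp_to_med[j] * self.theta_med_to_outcome[j, k] / total)


def _variant_table(config: DagConfig) -> pd.DataFrame:
    """Per-variant metadata: one chromosome per genetically-instrumented
    trait, positions spaced 200 kb, LD blocks contiguous."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11E1E]))
    rows = []
    traits = (EXPOSURE,) + config.mediator_names
    for t_idx, trait in enumerate(traits):
        mafs = rng.uniform(*config.maf_range, size=config.n_snps_per_trait)
        for i in range(config.n_snps_per_trait):
            ea, oa = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
            rows.append(
                {
                    "variant_id": f"rs{t_idx + 1}_{i + 1:04d}",
                    "trait": trait,
                    "chr": str(t_idx + 1),
                    "pos": 1 + i * 200_000,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "maf": mafs[i],
                    "block": i // config.ld_block_size,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class Truth:
    """Ground-truth record: config echo plus realized per-SNP effects."""

    config: DagConfig
    variants: pd.DataFrame
    beta_trait: dict[str, np.ndarray]  # trait -> per-own-SNP structural betas
    pleiotropy: np.ndarray  # (n exposure SNPs, n outcomes) direct effects
    alpha: np.ndarray  # calibrated outcome intercepts

    def proportion_mediated(self, mediator: str, outcome: str) -> float:
        return self.config.proportion_mediated(mediator, outcome)

    def marginal_beta(self, trait: str) -> pd.Series:
        """True marginal per-allele effect of every SNP on `trait`.

        Linear path-tracing through the DAG: exposure SNPs act on mediators
        via a_j and on outcomes via the total path (plus any pleiotropic
        direct effect); mediator SNPs act on outcomes via their mediator's
        direct effect. Outcome effects are on the log-odds scale.
        """
        cfg = self.config
        out = pd.Series(0.0, index=self.variants["variant_id"].to_numpy())
        v = self.variants
        exp_ids = v.loc[v["trait"] == EXPOSURE, "variant_id"].to_numpy()
        if trait == EXPOSURE:
            out[exp_ids] = self.beta_trait[EXPOSURE]
        elif trait in cfg.mediator_names:
            j = cfg.mediator_names.index(trait)
            own = v.loc[v["trait"] == trait, "variant_id"].to_numpy()
            out[own] = self.beta_trait[trait]
            out[exp_ids] = cfg.theta_exp_to_med[j] * self.beta_trait[EXPOSURE]
        elif trait in cfg.outcome_names:
            k = cfg.outcome_names.index(trait)
            total_k = cfg.total_effects()[k]
            out[exp_ids] = self.beta_trait[EXPOSURE] * total_k + self.pleiotropy[:, k]
            for j, med in enumerate(cfg.mediator_names):
                own = v.loc[v["trait"] == med, "variant_id"].to_numpy()
                out[own] = self.beta_trait[med] * cfg.theta_med_to_outcome[j, k]
        else:
            raise KeyError(f"unknown trait {trait!r}")
        return out

    def to_dict(self) -> dict:
        d = asdict(self.config)
        for key in ("theta_exp_to_med", "theta_med_to_outcome", "theta_direct", "prevalence"):
            d[key] = np.asarray(d[key]).tolist()
        d["maf_range"] = list(d["maf_range"])
        return {
            "config": d,
            "alpha": self.alpha.tolist(),
            "beta_trait": {k: v.tolist() for k, v in self.beta_trait.items()},
            "pleiotropy": self.pleiotropy.tolist(),
            "proportion_mediated": {
                f"{m}->{o}": self.config.proportion_mediated(m, o)
                for m in self.config.mediator_names
                for o in self.config.outcome_names
                if self.config.total_effects()[self.config.outcome_names.index(o)] != 0
            },
        }


@dataclass
class SyntheticStudy:
    """Individual-level cohort with full ground truth."""

    genotypes: np.ndarray  # (n_individuals, n_snps) dosages 0/1/2
    variant_ids: list[str]
    covariates: pd.DataFrame  # columns COVARIATE_NAMES
    exposure: np.ndarray
    mediators: dict[str, np.ndarray]
    outcomes: dict[str, np.ndarray]
    truth: Truth

    def phenotype(self, trait: str) -> np.ndarray:
        if trait == EXPOSURE:
            return self.exposure
        if trait in self.mediators:
            return self.mediators[trait]
        if trait in self.outcomes:
            return self.outcomes[trait]
        raise KeyError(f"unknown trait {trait!r}")

    @property
    def is_binary(self) -> dict[str, bool]:
        d = {EXPOSURE: False}
        d.update({m: False for m in self.mediators})
        d.update({o: True for o in self.outcomes})
        return d


def _draw_genotypes(
    rng: np.random.Generator, n: int, mafs: np.ndarray, block: np.ndarray, rho: float
) -> np.ndarray:
    """Dosage matrix via a Gaussian-copula block structure on haplotypes."""
    m = len(mafs)
    thresh = norm.ppf(mafs)
    dosage = np.zeros((n, m), dtype=np.int8)
    sq_rho, sq_res = math.sqrt(rho), math.sqrt(1.0 - rho)
    for hap in range(2):
        z = rng.standard_normal((n, m))
        if rho > 0:
            for b in np.unique(block):
                cols = np.flatnonzero(block == b)
                f = rng.standard_normal(n)
                z[:, cols] = sq_rho * f[:, None] + sq_res * z[:, cols]
        dosage += (z < thresh[None, :]).astype(np.int8)
    return dosage


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance phenotype cannot be standardized")
    return (x - x.mean()) / sd


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Solve mean(sigmoid(alpha + eta)) = prevalence for alpha (tol 1e-6)."""

    def f(alpha: float) -> float:
        return float(expit(alpha + eta).mean() - prevalence)

    lo, hi = -40.0, 40.0
    try:
        return float(brentq(f, lo, hi, xtol=1e-6))
    except ValueError as err:  # pragma: no cover - unreachable for prev in (0,1)
        raise RuntimeError(
            f"prevalence {prevalence} unreachable given linear predictor range"
        ) from err


def _structural_effects(config: DagConfig) -> tuple[pd.DataFrame, dict[str, np.ndarray], np.ndarray]:
    """Draw per-SNP structural effect sizes and pleiotropy, seeded."""
    variants = _variant_table(config)
    ss = np.random.SeedSequence([config.seed, 0xBE7A])
    children = ss.spawn(len(QUANT_TRAITS) + 1)
    beta_trait: dict[str, np.ndarray] = {}
    for i, trait in enumerate((EXPOSURE,) + config.mediator_names):
        rng = np.random.default_rng(children[i])
        beta_trait[trait] = rng.normal(0.0, config.beta_exposure_sd, config.n_snps_per_trait)
    prng = np.random.default_rng(children[-1])
    n_exp = config.n_snps_per_trait
    if config.pleiotropy_mode == "none":
        pleio = np.zeros((n_exp, config.n_outcomes))
    elif config.pleiotropy_mode == "balanced":
        pleio = prng.normal(0.0, config.pleiotropy_sd, (n_exp, config.n_outcomes))
    elif config.pleiotropy_mode == "directional":
        pleio = prng.normal(config.pleiotropy_sd, config.pleiotropy_sd, (n_exp, config.n_outcomes))
    else:
        raise ValueError(f"unknown pleiotropy_mode {config.pleiotropy_mode!r}")
    return variants, beta_trait, pleio


def simulate_cohort(config: DagConfig) -> SyntheticStudy:
    """Simulate one individual-level cohort under the configured DAG.

    Raises ``ValueError`` for invalid configs (including effect sizes that
    leave a negative residual-variance budget) and ``RuntimeError`` if
    outcome intercept calibration cannot reach the target prevalence.
    """
    config.validate()
    variants, beta_trait, pleio = _structural_effects(config)
    smpl = config.seed if config.sample_seed is None else config.sample_seed
    ss = np.random.SeedSequence([smpl, 0xC040])
    geno_rng, cov_rng, noise_rng, out_rng = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    n = config.n_individuals
    mafs = variants["maf"].to_numpy()
    # blocks are unique per (trait, block) pair
    block_key = pd.factorize(variants["trait"].astype(str) + ":" + variants["block"].astype(str))[0]
    genotypes = _draw_genotypes(geno_rng, n, mafs, block_key, config.ld_rho)

    covariates = pd.DataFrame(
        {
            "sex": cov_rng.integers(0, 2, n).astype(float),
            "age": cov_rng.standard_normal(n),
            "pc1": cov_rng.standard_normal(n),
            "pc2": cov_rng.standard_normal(n),
            "pc3": cov_rng.standard_normal(n),
            "pc4": cov_rng.standard_normal(n),
        }
    )
    C = covariates.to_numpy()
    cov_var_quant = float(np.sum(_COV_EFFECTS_QUANT**2 * np.r_[0.25, np.ones(5)]))

    def genetic_score(trait: str) -> tuple[np.ndarray, float]:
        idx = variants.index[variants["trait"] == trait].to_numpy()
        beta = beta_trait[trait]
        g = genotypes[:, idx].astype(float)
        score = g @ beta
        var_g = float(np.sum(beta**2 * 2 * mafs[idx] * (1 - mafs[idx])))
        return score - score.mean(), var_g

    # exposure
    score_x, var_gx = genetic_score(EXPOSURE)
    resid_var = 1.0 - var_gx - cov_var_quant
    if resid_var <= 0:
        raise ValueError("exposure effect sizes leave a negative residual-variance budget")
    x_raw = score_x + C @ _COV_EFFECTS_QUANT + noise_rng.normal(0, math.sqrt(resid_var), n)
    exposure = _standardize(x_raw)

    mediators: dict[str, np.ndarray] = {}
    for j, med in enumerate(config.mediator_names):
        score_m, var_gm = genetic_score(med)
        a = config.theta_exp_to_med[j]
        resid_var = 1.0 - a**2 - var_gm - cov_var_quant
        if resid_var <= 0:
            raise ValueError(f"mediator {med!r} effects leave a negative residual-variance budget")
        m_raw = (
            a * exposure
            + score_m
            + C @ _COV_EFFECTS_QUANT
            + noise_rng.normal(0, math.sqrt(resid_var), n)
        )
        mediators[med] = _standardize(m_raw)

    exp_idx = variants.index[variants["trait"] == EXPOSURE].to_numpy()
    G_exp = genotypes[:, exp_idx].astype(float)
    M = np.column_stack([mediators[m] for m in config.mediator_names]) if mediators else np.zeros((n, 0))

    outcomes: dict[str, np.ndarray] = {}
    alpha = np.zeros(config.n_outcomes)
    for k, out in enumerate(config.outcome_names):
        eta = (
            config.theta_direct[k] * exposure
            + M @ config.theta_med_to_outcome[:, k]
            + C @ _COV_EFFECTS_BINARY
            + G_exp @ pleio[:, k]
        )
        alpha[k] = _calibrate_intercept(eta, config.prevalence[k])
        p = expit(alpha[k] + eta)
        outcomes[out] = (out_rng.uniform(size=n) < p).astype(np.int8)

    truth = Truth(
        config=config,
        variants=variants,
        beta_trait=beta_trait,
        pleiotropy=pleio,
        alpha=alpha,
    )
    return SyntheticStudy(
        genotypes=genotypes,
        variant_ids=variants["variant_id"].tolist(),
        covariates=covariates,
        exposure=exposure,
        mediators=mediators,
        outcomes=outcomes,
        truth=truth,
    )


def quantitative_se(maf: np.ndarray, n: int | np.ndarray) -> np.ndarray:
    """Standard error of a per-allele effect on a unit-variance trait:
    1 / sqrt(2 * MAF * (1 - MAF) * N)."""
    maf = np.asarray(maf, dtype=float)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * np.asarray(n, dtype=float))


def binary_logodds_se(maf: np.ndarray, n: int, prevalence: float) -> np.ndarray:
    """Approximate SE of a per-allele log-odds effect on a binary trait:
    the quantitative formula with effective sample size N * prev * (1 - prev)."""
    return quantitative_se(maf, n) / math.sqrt(prevalence * (1.0 - prevalence))


def _direct_sumstats(config: DagConfig, truth: Truth) -> dict[str, pd.DataFrame]:
    """Sample summary tables directly: beta_hat ~ Normal(true marginal, SE)."""
    variants = truth.variants
    mafs = variants["maf"].to_numpy()
    ss = np.random.SeedSequence([config.seed, 0xD12EC7])
    children = ss.spawn(len(config.trait_names))
    tables: dict[str, pd.DataFrame] = {}
    for child, trait in zip(children, config.trait_names):
        rng = np.random.default_rng(child)
        true_beta = truth.marginal_beta(trait).to_numpy()
        if trait in config.outcome_names:
            k = config.outcome_names.index(trait)
            se = binary_logodds_se(mafs, config.n_individuals, float(config.prevalence[k]))
        else:
            se = quantitative_se(mafs, config.n_individuals)
        beta_hat = rng.normal(true_beta, se)
        z = beta_hat / se
        pval = 2.0 * norm.sf(np.abs(z))
        tables[trait] = pd.DataFrame(
            {
                "variant_id": variants["variant_id"],
                "chr": variants["chr"].astype(str),
                "pos": variants["pos"],
                "effect_allele": variants["effect_allele"],
                "other_allele": variants["other_allele"],
                "eaf": mafs,
                "beta": beta_hat,
                "se": se,
                "pval": np.clip(pval, np.nextafter(0, 1), 1.0),
                "n": config.n_individuals,
            }
        )
    return tables


def _cohort_sumstats(config: DagConfig) -> dict[str, pd.DataFrame]:
    """Run the GWAS engine on independently simulated cohorts per trait.

    One cohort per quantitative trait, plus a single shared cohort for all
    binary outcomes (the outcome GWAS of the emulated biobank); no sample
    overlaps any other trait's sample.
    """
    from .gwas import GwasConfig, run_gwas  # deferred: gwas imports nothing from here

    ss = np.random.SeedSequence([config.seed, 0x20C0])
    cohort_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(QUANT_TRAITS) + 1)]
    tables: dict[str, pd.DataFrame] = {}
    quant_cfg = GwasConfig(outcome_is_binary=False)
    binary_cfg = GwasConfig(outcome_is_binary=True, scale_conversion="linear_prob_to_logodds")
    traits = (EXPOSURE,) + config.mediator_names
    for i, trait in enumerate(traits):
        cfg_i = DagConfig(**{**_config_kwargs(config), "sample_seed": cohort_seeds[i]})
        study = simulate_cohort(cfg_i)
        tables[trait] = run_gwas(study, trait, quant_cfg)
    cfg_out = DagConfig(**{**_config_kwargs(config), "sample_seed": cohort_seeds[-1]})
    study_out = simulate_cohort(cfg_out)
    for out in config.outcome_names:
        tables[out] = run_gwas(study_out, out, binary_cfg)
    return tables


def _config_kwargs(config: DagConfig) -> dict:
    return {
        "n_snps_per_trait": config.n_snps_per_trait,
        "maf_range": config.maf_range,
        "beta_exposure_sd": config.beta_exposure_sd,
        "theta_exp_to_med": config.theta_exp_to_med,
        "theta_med_to_outcome": config.theta_med_to_outcome,
        "theta_direct": config.theta_direct,
        "pleiotropy_mode": config.pleiotropy_mode,
        "pleiotropy_sd": config.pleiotropy_sd,
        "ld_block_size": config.ld_block_size,
        "ld_rho": config.ld_rho,
        "prevalence": config.prevalence,
        "n_individuals": config.n_individuals,
        "seed": config.seed,
        "sample_seed": config.sample_seed,
    }


def simulate_sumstats(config: DagConfig, two_sample: bool = False) -> dict[str, pd.DataFrame]:
    """Generate two-sample summary statistics for every trait in the DAG.

    ``two_sample=True`` simulates an independent cohort per trait (one shared
    cohort for the binary outcomes) and runs the GWAS engine on each — no
    sample overlap anywhere. ``two_sample=False`` samples effect estimates
    directly, ``beta_hat ~ Normal(true marginal beta, SE)`` with the
    analytic SE formula — faster, and equally overlap-free since every
    trait draws its own noise stream.
    """
    config.validate()
    if two_sample:
        return _cohort_sumstats(config)
    variants, beta_trait, pleio = _structural_effects(config)
    truth = Truth(config=config, variants=variants, beta_trait=beta_trait, pleiotropy=pleio,
                  alpha=np.zeros(config.n_outcomes))
    return _direct_sumstats(config, truth)


def study_truth(config: DagConfig) -> Truth:
    """The ground-truth record for a config without simulating individuals."""
    config.validate()
    variants, beta_trait, pleio = _structural_effects(config)
    return Truth(config=config, variants=variants, beta_trait=beta_trait,
                 pleiotropy=pleio, alpha=np.zeros(config.n_outcomes))


def ld_matrix(config: DagConfig) -> LdMatrix:
    """The latent block-constant LD matrix implied by the copula structure."""
    variants = _variant_table(config)
    m = len(variants)
    block_key = pd.factorize(variants["trait"].astype(str) + ":" + variants["block"].astype(str))[0]
    r = np.full((m, m), 0.0)
    same_block = block_key[:, None] == block_key[None, :]
    r[same_block] = config.ld_rho
    np.fill_diagonal(r, 1.0)
    positions = variants.set_index("variant_id")[["chr", "pos"]]
    positions["chr"] = positions["chr"].astype(str)
    return LdMatrix(variant_ids=variants["variant_id"].tolist(), r=r, positions=positions)


def save_sumstats(
    tables: Mapping[str, pd.DataFrame], outdir: str | Path, truth: Truth | None = None
) -> None:
    """Write per-trait sumstats TSVs (and the truth record as YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for trait, table in tables.items():
        write_sumstats(table, outdir / f"{trait}.tsv")
    if truth is not None:
        with open(outdir / "truth.yaml", "w") as fh:
            yaml.safe_dump(truth.to_dict(), fh, sort_keys=True)


def save_ld(config: DagConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_ld_matrix(ld_matrix(config), outdir / "ld.tsv", outdir / "ld_positions.tsv")
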