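"""Network-MR mediation: indirect/direct/total effects, proportion mediated
with delta-method uncertainty, Bonferroni families and the joint
significance rubric.

Notation: a = exposure->mediator effect (univariable MR, per SD),
b = mediator->outcome *direct* effect (multivariable MR, log-odds per
unit), c = total exposure->outcome effect (first-step univariable MR).
Then indirect = a*b, direct = c - a*b, proportion mediated p = a*b/c.
Standard errors propagate by the first-order delta method treating a, b, c
as independent (they come from separate regressions; see docs/methods.md
for the limits of that approximation):

    se(ab)^2 = b^2 se_a^2 + a^2 se_b^2
    se(p)^2  = (b/c)^2 se_a^2 + (a/c)^2 se_b^2 + (ab/c^2)^2 se_c^2
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .estimators import MRResult

_Z95 = float(stats.norm.ppf(0.975))


def indirect_effect(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """Product-of-coefficients indirect effect a*b with its delta-method SE."""
    est = a * b
    se = math.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
    return est, se


def bonferroni_threshold(n_tests: int, family_alpha: float = 0.05) -> float:
    """Family-wise corrected significance threshold alpha / n."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return family_alpha / n_tests


@dataclass
class SignificanceRubric:
    """Per-family Bonferroni thresholds plus the pleiotropy-intercept alpha."""

    alpha_family: dict[str, float]
    egger_intercept_alpha: float = 0.05

    @classmethod
    def from_counts(cls, n_tests: dict[str, int], family_alpha: float = 0.05,
                    egger_intercept_alpha: float = 0.05) -> "SignificanceRubric":
        return cls(
            alpha_family={k: bonferroni_threshold(n, family_alpha) for k, n in n_tests.items()},
            egger_intercept_alpha=egger_intercept_alpha,
        )


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition for one exposure-mediator-outcome
    triple, with the proportion mediated and its delta-method CI.

    The reported CI (``ci_low``/``ci_high``) is truncated to [0, 1] when the
    point estimate lies inside that range; the raw bounds are always kept.
    """

    exposure: str
    mediator: str
    outcome: str
    total_effect: float
    se_total: float
    beta_exp_to_med: float
    se_exp_to_med: float
    beta_med_to_outcome_direct: float
    se_med_to_outcome_direct: float
    indirect: float = field(init=False)
    se_indirect: float = field(init=False)
    direct: float = field(init=False)
    proportion: float = field(init=False)
    se_proportion: float = field(init=False)
    ci_low_raw: float = field(init=False)
    ci_high_raw: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    weak_total: bool = field(init=False)

    def __post_init__(self) -> None:
        a, se_a = self.beta_exp_to_med, self.se_exp_to_med
        b, se_b = self.beta_med_to_outcome_direct, self.se_med_to_outcome_direct
        c, se_c = self.total_effect, self.se_total
        if c == 0:
            raise ZeroDivisionError("total effect is zero: proportion mediated undefined")
        self.indirect, self.se_indirect = indirect_effect(a, se_a, b, se_b)
        self.direct = c - self.indirect
        self.proportion = self.indirect / c
        self.se_proportion = math.sqrt(
            (b / c) ** 2 * se_a**2 + (a / c) ** 2 * se_b**2 + (a * b / c**2) ** 2 * se_c**2
        )
        self.ci_low_raw = self.proportion - _Z95 * self.se_proportion
        self.ci_high_raw = self.proportion + _Z95 * self.se_proportion
        if 0.0 <= self.proportion <= 1.0:
            self.ci_low = max(0.0, self.ci_low_raw)
            self.ci_high = min(1.0, self.ci_high_raw)
        else:
            self.ci_low, self.ci_high = self.ci_low_raw, self.ci_high_raw
        # a total effect within 10 SEs of zero makes the ratio unstable
        self.weak_total = abs(c) < 10.0 * se_c

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "beta_exp_to_med": self.beta_exp_to_med,
            "se_exp_to_med": self.se_exp_to_med,
            "beta_med_to_outcome_direct": self.beta_med_to_outcome_direct,
            "se_med_to_outcome_direct": self.se_med_to_outcome_direct,
            "total_effect": self.total_effect,
            "se_total": self.se_total,
            "indirect": self.indirect,
            "se_indirect": self.se_indirect,
            "direct": self.direct,
            "proportion": self.proportion,
            "se_proportion": self.se_proportion,
            "ci_low_raw": self.ci_low_raw,
            "ci_high_raw": self.ci_high_raw,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "weak_total": self.weak_total,
        }


def mediation_proportion(
    total: tuple[float, float],
    a: tuple[float, float],
    b: tuple[float, float],
    exposure: str = "exposure",
    mediator: str = "mediator",
    outcome: str = "outcome",
) -> MediationResult:
    """Proportion mediated from (estimate, SE) pairs for the total effect c,
    the exposure->mediator effect a and the mediator->outcome direct
    effect b."""
    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        total_effect=total[0],
        se_total=total[1],
        beta_exp_to_med=a[0],
        se_exp_to_med=a[1],
        beta_med_to_outcome_direct=b[0],
        se_med_to_outcome_direct=b[1],
    )


@dataclass
class AssociationDecision:
    """Joint significance call for one exposure-outcome pair."""

    significant: bool
    ivw_pass: bool
    presso_pass: bool
    direction_concordant: bool
    intercept_ok: bool
    threshold: float


def classify_association(
    ivw: MRResult,
    egger: MRResult,
    wm: MRResult,
    presso: MRResult,
    threshold: float,
    egger_intercept_alpha: float = 0.05,
) -> AssociationDecision:
    """The composite significance rubric: IVW and MR-PRESSO below the
    Bonferroni threshold, Egger and weighted-median estimates in the same
    direction as IVW, and a non-significant Egger intercept."""
    for name, r in (("ivw", ivw), ("egger", egger), ("wm", wm), ("presso", presso)):
        if r is None:
            raise ValueError(f"missing {name} result")
    ivw_pass = ivw.pval < threshold
    presso_pass = presso.pval < threshold
    sgn = lambda x: math.copysign(1.0, x) if x != 0 else 0.0
    direction_concordant = sgn(egger.estimate) == sgn(wm.estimate) == sgn(ivw.estimate)
    if egger.egger_intercept_p is None:
        raise ValueError("egger result lacks an intercept p-value")
    intercept_ok = egger.egger_intercept_p > egger_intercept_alpha
    return AssociationDecision(
        significant=bool(ivw_pass and presso_pass and direction_concordant and intercept_ok),
        ivw_pass=bool(ivw_pass),
        presso_pass=bool(presso_pass),
        direction_concordant=bool(direction_concordant),
        intercept_ok=bool(intercept_ok),
        threshold=threshold,
    )
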