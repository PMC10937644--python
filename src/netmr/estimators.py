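"""Two-sample MR estimators: IVW, MR-Egger, weighted median, MR-PRESSO and
multivariable IVW, with Cochran's Q / I^2 heterogeneity.

The estimators are scikit-learn style: construct with hyper-parameters,
``fit(X, y, se_y=..., se_x=...)`` on the harmonized per-SNP association
matrices (X: exposure effects, one column per exposure; y: outcome
effects), then read trailing-underscore attributes (``estimate_``, ``se_``,
``pval_``, ``q_``, ``i2_``, ...). ``predict(X)`` returns the fitted genetic
predictions X @ estimate. Thin module-level functions (:func:`ivw`,
:func:`egger`, :func:`weighted_median`, :func:`mr_presso`,
:func:`mvmr_ivw`, :func:`cochran_q`) consume a
:class:`~netmr.instruments.HarmonizedSet` and return result records.

Conventions shared by all weighted regressions here: weights are the
inverse outcome variances 1/se_y^2; "random effects" means multiplicative
overdispersion — the model SE is inflated by sqrt(max(1, Q/df)) — and
p-values are two-sided normal. Estimates stay on the log-odds (or per-SD)
scale; exponentiation to odds ratios happens only in report tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .instruments import HarmonizedSet

logger = logging.getLogger(__name__)

_Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MRResult:
    """One MR estimate with its sensitivity statistics."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    q_stat: float | None = None
    i2: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    outliers_removed: list[str] = field(default_factory=list)
    global_p: float | None = None
    distortion: float | None = None
    exposure: str | None = None
    outcome: str | None = None
    scale: str = "log_odds"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")
        if self.i2 is not None and not (0 <= self.i2 <= 100):
            raise ValueError("I^2 must lie in [0, 100]")
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")


@dataclass
class MVMRResult:
    """Joint direct-effect estimates of k exposures on one outcome."""

    exposure_names: list[str]
    estimates: np.ndarray
    ses: np.ndarray
    ci_lows: np.ndarray
    ci_highs: np.ndarray
    pvals: np.ndarray
    n_snp: int
    q_stat: float
    conditional_f: np.ndarray | None = None
    outcome: str | None = None

    def __post_init__(self) -> None:
        k = len(self.exposure_names)
        for name in ("estimates", "ses", "ci_lows", "ci_highs", "pvals"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (k,):
                raise ValueError(f"{name} must have length {k}")
            setattr(self, name, arr)
        if self.n_snp <= k:
            raise ValueError("n_snp must exceed the number of exposures")

    def to_mr_results(self) -> list[MRResult]:
        out = []
        for i, name in enumerate(self.exposure_names):
            out.append(
                MRResult(
                    method="MVMR-IVW",
                    estimate=float(self.estimates[i]),
                    se=float(self.ses[i]),
                    ci_low=float(self.ci_lows[i]),
                    ci_high=float(self.ci_highs[i]),
                    pval=float(self.pvals[i]),
                    n_snp=self.n_snp,
                    q_stat=self.q_stat,
                    exposure=name,
                    outcome=self.outcome,
                )
            )
        return out


def _validate_xy(X, y, se_y, se_x=None):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    se_y = np.asarray(se_y, dtype=float).ravel()
    if X.shape[0] != len(y) or len(se_y) != len(y):
        raise ValueError("X, y and se_y must share their first dimension")
    if np.any(se_y <= 0):
        raise ValueError("se_y must be strictly positive")
    if se_x is not None:
        se_x = np.asarray(se_x, dtype=float)
        if se_x.ndim == 1:
            se_x = se_x[:, None]
        if se_x.shape != X.shape:
            raise ValueError("se_x must match the shape of X")
    return X, y, se_y, se_x


def _heterogeneity(q: float, df: int) -> tuple[float, float]:
    """(multiplicative SE inflation, I^2 percentage) from Cochran's Q."""
    inflation = float(np.sqrt(max(1.0, q / df))) if df > 0 else 1.0
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    return inflation, i2


class IVW(BaseEstimator):
    """Random-effects inverse-variance-weighted estimator.

    Weighted regression of outcome effects on exposure effects through the
    origin, weights 1/se_y^2; the SE is inflated by sqrt(max(1, Q/(n-1)))
    (multiplicative random effects).
    """

    def fit(self, X, y, se_y, se_x=None):
        X, y, se_y, _ = _validate_xy(X, y, se_y, se_x)
        if X.shape[1] != 1:
            raise ValueError("IVW is univariable; use MVMRIVW for k > 1")
        bx = X[:, 0]
        n = len(y)
        if np.all(bx == 0):
            raise ValueError("all exposure effects are zero: estimate unidentified")
        w = 1.0 / se_y**2
        sxx = float(np.sum(w * bx**2))
        sxy = float(np.sum(w * bx * y))
        est = sxy / sxx
        se_fixed = 1.0 / np.sqrt(sxx)
        q = float(np.sum(w * (y - est * bx) ** 2))
        inflation, i2 = _heterogeneity(q, n - 1)
        se = se_fixed * inflation
        self.estimate_ = est
        self.se_ = se
        self.q_ = q
        self.i2_ = i2
        self.n_snp_ = n
        self.pval_ = float(2 * stats.norm.sf(abs(est / se)))
        self.ci_low_ = est - _Z95 * se
        self.ci_high_ = est + _Z95 * se
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return (X[:, 0] if X.ndim == 2 else X) * self.estimate_


class MREgger(BaseEstimator):
    """MR-Egger regression: weighted fit with an intercept.

    Exposure effects are oriented positive (flipping (bx, by) jointly);
    the intercept estimates directional pleiotropy and its p-value is the
    no-pleiotropy test. Multiplicative random-effects SE inflation with
    n - 2 degrees of freedom; p-values and CIs use the t distribution with
    n - 2 df (matching the weighted-least-squares implementations commonly
    used for this regression), unlike the normal-based IVW.
    """

    def fit(self, X, y, se_y, se_x=None):
        X, y, se_y, _ = _validate_xy(X, y, se_y, se_x)
        if X.shape[1] != 1:
            raise ValueError("MREgger is univariable")
        bx, by = X[:, 0].copy(), y.copy()
        n = len(by)
        if n < 3:
            raise ValueError("MR-Egger requires at least 3 SNPs")
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        bx, by = bx * flip, by * flip
        if np.ptp(bx) == 0:
            raise ValueError("no spread in exposure effects: slope unidentified")
        w = 1.0 / se_y**2
        D = np.column_stack([np.ones(n), bx])
        WD = D * w[:, None]
        xtx = D.T @ WD
        xty = WD.T @ by
        coef = np.linalg.solve(xtx, xty)
        resid = by - D @ coef
        q = float(np.sum(w * resid**2))
        inflation, i2 = _heterogeneity(q, n - 2)
        cov = np.linalg.inv(xtx) * inflation**2
        intercept, slope = float(coef[0]), float(coef[1])
        se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        df = n - 2
        t95 = float(stats.t.ppf(0.975, df))
        self.estimate_ = slope
        self.se_ = se_slope
        self.intercept_ = intercept
        self.intercept_se_ = se_int
        self.intercept_pval_ = float(2 * stats.t.sf(abs(intercept / se_int), df))
        self.q_ = q
        self.i2_ = i2
        self.n_snp_ = n
        self.pval_ = float(2 * stats.t.sf(abs(slope / se_slope), df))
        self.ci_low_ = slope - t95 * se_slope
        self.ci_high_ = slope + t95 * se_slope
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        bx = X[:, 0] if X.ndim == 2 else X
        return self.intercept_ + bx * self.estimate_


class WeightedMedian(BaseEstimator):
    """Weighted median of the per-SNP ratio estimates.

    Ratios by/bx are ordered, inverse-variance weighted (delta
    approximation se_y^2/bx^2), and the 50% point of the standardized
    cumulative weights is linearly interpolated. The SE comes from a
    seeded parametric bootstrap.
    """

    def __init__(self, n_boot: int = 1000, random_state: int | None = None):
        self.n_boot = n_boot
        self.random_state = random_state

    @staticmethod
    def _point(bx, by, se_y):
        ratios = by / bx
        w = bx**2 / se_y**2
        # aggregate tied ratios so the estimator depends only on the weight
        # attached to each distinct ratio value (duplication-invariant)
        r, inverse = np.unique(ratios, return_inverse=True)
        w = np.bincount(inverse, weights=w)
        cum = np.cumsum(w) - 0.5 * w
        cum /= np.sum(w)
        return float(np.interp(0.5, cum, r))

    def fit(self, X, y, se_y, se_x=None):
        X, y, se_y, se_x = _validate_xy(X, y, se_y, se_x)
        if X.shape[1] != 1:
            raise ValueError("WeightedMedian is univariable")
        bx = X[:, 0]
        nonzero = bx != 0
        dropped = np.flatnonzero(~nonzero)
        if len(dropped):
            logger.info("weighted_median: dropped %d SNP(s) with zero exposure effect", len(dropped))
        bx, by, se_y = bx[nonzero], y[nonzero], se_y[nonzero]
        sx = se_x[nonzero, 0] if se_x is not None else np.zeros_like(bx)
        n = len(bx)
        if n < 3:
            raise ValueError("weighted median requires at least 3 usable SNPs")
        est = self._point(bx, by, se_y)
        rng = np.random.default_rng(self.random_state)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bx_b = rng.normal(bx, sx)
            by_b = rng.normal(by, se_y)
            bx_b[bx_b == 0] = np.finfo(float).tiny
            boots[b] = self._point(bx_b, by_b, se_y)
        se = float(boots.std(ddof=1))
        self.estimate_ = est
        self.se_ = se
        self.n_snp_ = n
        self.pval_ = float(2 * stats.norm.sf(abs(est / se))) if se > 0 else 0.0
        self.ci_low_ = est - _Z95 * se
        self.ci_high_ = est + _Z95 * se
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return (X[:, 0] if X.ndim == 2 else X) * self.estimate_


def _loo_ivw_weights(bx, by, w):
    """Leave-one-out IVW slope for each SNP, vectorized."""
    sxx = np.sum(w * bx**2)
    sxy = np.sum(w * bx * by)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


class MRPRESSO(BaseEstimator):
    """MR-PRESSO: residual-sum-of-squares outlier test with removal.

    The global test compares the observed inverse-variance-weighted RSS of
    each SNP about its leave-one-out IVW prediction against a parametric
    null (bx, by resampled from their standard errors, ``n_sim`` draws).
    Per-SNP outlier p-values come from each SNP's simulated RSS
    contribution, Bonferroni-corrected by the SNP count; flagged SNPs are
    removed and IVW refit. Distortion is the relative change in estimate.
    """

    def __init__(self, n_sim: int = 1000, outlier_p: float = 0.05, random_state: int | None = None):
        self.n_sim = n_sim
        self.outlier_p = outlier_p
        self.random_state = random_state

    def fit(self, X, y, se_y, se_x=None):
        X, y, se_y, se_x = _validate_xy(X, y, se_y, se_x)
        if X.shape[1] != 1:
            raise ValueError("MRPRESSO is univariable")
        bx = X[:, 0]
        n = len(y)
        if n < 4:
            raise ValueError("MR-PRESSO requires at least 4 SNPs")
        if self.n_sim < 1000:
            raise ValueError("n_sim must be at least 1000")
        sx = se_x[:, 0] if se_x is not None else np.zeros(n)
        w = 1.0 / se_y**2

        loo = _loo_ivw_weights(bx, y, w)
        obs_contrib = w * (y - loo * bx) ** 2
        obs_rss = float(np.sum(obs_contrib))

        rng = np.random.default_rng(self.random_state)
        bx_sim = rng.normal(bx, sx, size=(self.n_sim, n))
        by_sim = rng.normal(loo * bx, se_y, size=(self.n_sim, n))
        sxx = np.sum(w * bx_sim**2, axis=1, keepdims=True)
        sxy = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
        loo_sim = (sxy - w * bx_sim * by_sim) / (sxx - w * bx_sim**2)
        contrib_sim = w * (by_sim - loo_sim * bx_sim) ** 2
        rss_sim = contrib_sim.sum(axis=1)

        self.global_pval_ = float((np.sum(rss_sim >= obs_rss) + 1) / (self.n_sim + 1))
        outlier_raw = (np.sum(contrib_sim >= obs_contrib[None, :], axis=0) + 1) / (self.n_sim + 1)
        self.outlier_pvals_ = np.minimum(1.0, outlier_raw * n)  # Bonferroni by n_snp
        flagged = np.flatnonzero(self.outlier_pvals_ < self.outlier_p)
        self.outlier_idx_ = flagged

        raw = IVW().fit(bx, y, se_y)
        self.raw_estimate_, self.raw_se_ = raw.estimate_, raw.se_
        keep = np.setdiff1d(np.arange(n), flagged)
        if len(flagged) and len(keep) >= 2:
            corrected = IVW().fit(bx[keep], y[keep], se_y[keep])
            self.estimate_, self.se_ = corrected.estimate_, corrected.se_
            self.q_, self.i2_ = corrected.q_, corrected.i2_
            self.n_snp_ = len(keep)
            self.distortion_ = float((self.estimate_ - self.raw_estimate_) / self.raw_estimate_) \
                if self.raw_estimate_ != 0 else np.nan
            self.method_ = "PRESSO_outlier_corrected"
        else:
            self.estimate_, self.se_ = raw.estimate_, raw.se_
            self.q_, self.i2_ = raw.q_, raw.i2_
            self.n_snp_ = n
            self.distortion_ = 0.0
            self.method_ = "PRESSO_raw"
        self.pval_ = float(2 * stats.norm.sf(abs(self.estimate_ / self.se_)))
        self.ci_low_ = self.estimate_ - _Z95 * self.se_
        self.ci_high_ = self.estimate_ + _Z95 * self.se_
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return (X[:, 0] if X.ndim == 2 else X) * self.estimate_


class MVMRIVW(BaseEstimator):
    """Multivariable IVW: weighted regression of outcome effects on k
    exposure-effect columns, no intercept, weights 1/se_y^2; multiplicative
    random-effects inflation with n - k degrees of freedom. Conditional
    F-statistics (weak-instrument diagnostic, never auto-dropping) are an
    approximation ignoring cross-trait sampling covariance."""

    def fit(self, X, y, se_y, se_x=None):
        X, y, se_y, se_x = _validate_xy(X, y, se_y, se_x)
        n, k = X.shape
        if n < k + 2:
            raise ValueError(f"MVMR needs at least k+2={k+2} SNPs, got {n}")
        rank = np.linalg.matrix_rank(X)
        if rank < k:
            corr = np.corrcoef(X, rowvar=False)
            offending = [
                (i, j)
                for i in range(k)
                for j in range(i + 1, k)
                if abs(corr[i, j]) > 1 - 1e-10
            ]
            raise ValueError(
                f"exposure beta matrix is rank deficient (rank {rank} < {k}); "
                f"collinear column pairs: {offending or 'unidentified'}"
            )
        w = 1.0 / se_y**2
        WX = X * w[:, None]
        xtx = X.T @ WX
        coef = np.linalg.solve(xtx, WX.T @ y)
        resid = y - X @ coef
        q = float(np.sum(w * resid**2))
        inflation, _ = _heterogeneity(q, n - k)
        cov = np.linalg.inv(xtx) * inflation**2
        ses = np.sqrt(np.diag(cov))
        self.estimates_ = coef
        self.ses_ = ses
        self.pvals_ = 2 * stats.norm.sf(np.abs(coef / ses))
        self.ci_lows_ = coef - _Z95 * ses
        self.ci_highs_ = coef + _Z95 * ses
        self.q_ = q
        self.n_snp_ = n
        self.conditional_f_ = self._conditional_f(X, se_x)
        return self

    @staticmethod
    def _conditional_f(X: np.ndarray, se_x: np.ndarray | None) -> np.ndarray | None:
        if se_x is None:
            return None
        n, k = X.shape
        if k == 1:
            return np.array([float(np.mean((X[:, 0] / se_x[:, 0]) ** 2))])
        f = np.empty(k)
        for j in range(k):
            others = np.delete(X, j, axis=1)
            wj = 1.0 / se_x[:, j] ** 2
            WO = others * wj[:, None]
            coef = np.linalg.lstsq(others * np.sqrt(wj)[:, None], X[:, j] * np.sqrt(wj), rcond=None)[0]
            resid = X[:, j] - others @ coef
            qj = float(np.sum(wj * resid**2))
            f[j] = qj / max(1, n - k + 1)
        return f

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.estimates_


# ---------------------------------------------------------------------------
# Functional interface over HarmonizedSet


def _hs_arrays(h: HarmonizedSet):
    return h.beta_exposures, h.beta_outcome, h.se_outcome, h.se_exposures


def cochran_q(h: HarmonizedSet, estimate: float) -> tuple[float, float]:
    """Cochran's Q of the per-SNP ratio estimates about `estimate`, and I^2.

    Q = sum_i w_i (ratio_i - estimate)^2 with w_i the inverse delta-method
    ratio variances bx_i^2 / se_y_i^2; I^2 = max(0, (Q - (n-1))/Q) * 100.
    """
    if h.n_snp < 2:
        raise ValueError("heterogeneity needs at least 2 SNPs")
    bx = h.beta_exposures[:, 0]
    ratios = h.beta_outcome / bx
    w = bx**2 / h.se_outcome**2
    q = float(np.sum(w * (ratios - estimate) ** 2))
    _, i2 = _heterogeneity(q, h.n_snp - 1)
    return q, i2


def ivw(h: HarmonizedSet, exposure: str | None = None, outcome: str | None = None,
        scale: str = "log_odds") -> MRResult:
    """Random-effects IVW on a harmonized set; single-SNP sets fall back to
    the Wald ratio (labelled distinctly, never mixed into multi-SNP output)."""
    if h.k != 1:
        raise ValueError("univariable IVW requires a single-exposure harmonized set")
    bx = h.beta_exposures[:, 0]
    if h.n_snp == 1:
        b, s = float(bx[0]), float(h.se_outcome[0])
        if b == 0:
            raise ValueError("exposure effect is zero: Wald ratio undefined")
        est = float(h.beta_outcome[0]) / b
        se = s / abs(b)
        return MRResult(
            method="WaldRatio", estimate=est, se=se,
            ci_low=est - _Z95 * se, ci_high=est + _Z95 * se,
            pval=float(2 * stats.norm.sf(abs(est / se))), n_snp=1,
            exposure=exposure, outcome=outcome, scale=scale,
        )
    m = IVW().fit(bx, h.beta_outcome, h.se_outcome)
    return MRResult(
        method="IVW", estimate=m.estimate_, se=m.se_, ci_low=m.ci_low_, ci_high=m.ci_high_,
        pval=m.pval_, n_snp=m.n_snp_, q_stat=m.q_, i2=m.i2_,
        exposure=exposure, outcome=outcome, scale=scale,
    )


def egger(h: HarmonizedSet, exposure: str | None = None, outcome: str | None = None,
          scale: str = "log_odds") -> MRResult:
    m = MREgger().fit(h.beta_exposures[:, :1], h.beta_outcome, h.se_outcome)
    return MRResult(
        method="Egger", estimate=m.estimate_, se=m.se_, ci_low=m.ci_low_, ci_high=m.ci_high_,
        pval=m.pval_, n_snp=m.n_snp_, q_stat=m.q_, i2=m.i2_,
        egger_intercept=m.intercept_, egger_intercept_se=m.intercept_se_,
        egger_intercept_p=m.intercept_pval_,
        exposure=exposure, outcome=outcome, scale=scale,
    )


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None,
                    exposure: str | None = None, outcome: str | None = None,
                    scale: str = "log_odds") -> MRResult:
    m = WeightedMedian(n_boot=n_boot, random_state=seed).fit(
        h.beta_exposures[:, :1], h.beta_outcome, h.se_outcome, se_x=h.se_exposures[:, :1]
    )
    return MRResult(
        method="WeightedMedian", estimate=m.estimate_, se=m.se_,
        ci_low=m.ci_low_, ci_high=m.ci_high_, pval=m.pval_, n_snp=m.n_snp_,
        exposure=exposure, outcome=outcome, scale=scale,
    )


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, seed: int | None = None,
              outlier_p: float = 0.05, exposure: str | None = None,
              outcome: str | None = None, scale: str = "log_odds") -> MRResult:
    m = MRPRESSO(n_sim=n_sim, outlier_p=outlier_p, random_state=seed).fit(
        h.beta_exposures[:, :1], h.beta_outcome, h.se_outcome, se_x=h.se_exposures[:, :1]
    )
    outliers = [h.variant_ids[i] for i in m.outlier_idx_]
    return MRResult(
        method=m.method_, estimate=m.estimate_, se=m.se_, ci_low=m.ci_low_,
        ci_high=m.ci_high_, pval=m.pval_, n_snp=m.n_snp_, q_stat=m.q_, i2=m.i2_,
        outliers_removed=outliers, global_p=m.global_pval_, distortion=m.distortion_,
        exposure=exposure, outcome=outcome, scale=scale,
    )


def mvmr_ivw(h: HarmonizedSet, outcome: str | None = None) -> MVMRResult:
    m = MVMRIVW().fit(h.beta_exposures, h.beta_outcome, h.se_outcome, se_x=h.se_exposures)
    return MVMRResult(
        exposure_names=list(h.exposure_names),
        estimates=m.estimates_, ses=m.ses_, ci_lows=m.ci_lows_, ci_highs=m.ci_highs_,
        pvals=m.pvals_, n_snp=m.n_snp_, q_stat=m.q_, conditional_f=m.conditional_f_,
        outcome=outcome,
    )
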