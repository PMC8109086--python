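"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume per-SNP summary associations that have been
harmonized to a common effect allele: exposure effects ``x`` with
standard errors ``x_se`` and outcome effects ``y`` with standard errors
``y_se``, both on the log-odds scale.  The underlying model is

    y_j = beta * x_j + alpha_j + noise,

where ``beta`` is the causal effect of interest and ``alpha_j`` is the
direct (pleiotropic) effect of variant j on the outcome, zero for a
valid instrument.

The estimators are written as scikit-learn style classes
(``fit(X, y, x_se=..., y_se=...)``, fitted attributes with a trailing
underscore); the module-level functions below them are thin wrappers
returning the result dataclasses.

Implemented methods
-------------------
* ``IVWEstimator`` — inverse-variance weighted mean of per-SNP Wald
  ratios with first-order weights; multiplicative random-effects
  standard error floored at the fixed-effect one.
* ``EggerEstimator`` — weighted regression with an intercept; the
  intercept estimates the mean directional pleiotropic effect.
* ``MedianEstimator`` — simple or weighted median of Wald ratios,
  consistent when up to half of the weight comes from invalid
  instruments; SE by parametric bootstrap.
* ``RAPSEstimator`` — maximizer of the (optionally Huber-robustified)
  profile likelihood accounting for exposure-side sampling error, with
  an optional overdispersion parameter for systematic pleiotropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .summary_io import HarmonizedInstrument

__all__ = [
    "RatioEstimate",
    "MREstimate",
    "HeterogeneityResult",
    "EggerResult",
    "ConvergenceError",
    "IVWEstimator",
    "EggerEstimator",
    "MedianEstimator",
    "RAPSEstimator",
    "wald_ratios",
    "ivw_mre",
    "egger",
    "median_estimators",
    "raps",
    "heterogeneity",
    "as_effect_arrays",
]

Z975 = stats.norm.ppf(0.975)


class ConvergenceError(RuntimeError):
    """An iterative solver failed to converge."""


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio with its first-order standard error."""

    rsid: str
    beta_ratio: float
    se_ratio: float


@dataclass(frozen=True)
class MREstimate:
    """A named method's causal estimate on the log-odds-ratio scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    or_point: float
    ci95: tuple[float, float]

    @property
    def beta_ci(self) -> tuple[float, float]:
        lo, hi = self.ci95
        return (np.log(lo), np.log(hi))

    @classmethod
    def from_beta(cls, method: str, beta: float, se: float, n_snps: int,
                  dist: str = "normal", df: int | None = None) -> "MREstimate":
        if dist == "t":
            mult = stats.t.ppf(0.975, df)
            pval = 2.0 * stats.t.sf(abs(beta / se), df)
        else:
            mult = Z975
            pval = 2.0 * stats.norm.sf(abs(beta / se))
        pval = min(max(pval, np.nextafter(0.0, 1.0)), 1.0)
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            pval=float(pval),
            n_snps=int(n_snps),
            or_point=float(np.exp(beta)),
            ci95=(float(np.exp(beta - mult * se)), float(np.exp(beta + mult * se))),
        )


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q across Wald ratios, with df, p and the I^2 index."""

    q: float
    df: int
    pval: float
    i2: float


@dataclass(frozen=True)
class EggerResult:
    """Egger slope estimate plus its pleiotropy-intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_ci: tuple[float, float]
    intercept_pval: float


def as_effect_arrays(instruments):
    """Coerce harmonized instruments to ``(rsid, x, x_se, y, y_se)`` arrays.

    Accepts a pandas DataFrame with the harmonized-table columns, or any
    sequence of :class:`HarmonizedInstrument`.
    """
    if isinstance(instruments, pd.DataFrame):
        rsid = instruments["rsid"].to_numpy(dtype=str)
        x = instruments["beta_exp"].to_numpy(dtype=float)
        x_se = instruments["se_exp"].to_numpy(dtype=float)
        y = instruments["beta_out"].to_numpy(dtype=float)
        y_se = instruments["se_out"].to_numpy(dtype=float)
        return rsid, x, x_se, y, y_se
    items = list(instruments)
    if items and not isinstance(items[0], HarmonizedInstrument):
        raise TypeError(
            "instruments must be a DataFrame or HarmonizedInstrument sequence"
        )
    rsid = np.array([i.rsid for i in items], dtype=str)
    x = np.array([i.beta_exp for i in items], dtype=float)
    x_se = np.array([i.se_exp for i in items], dtype=float)
    y = np.array([i.beta_out for i in items], dtype=float)
    y_se = np.array([i.se_out for i in items], dtype=float)
    return rsid, x, x_se, y, y_se


def _check_arrays(X, y, x_se, y_se, min_snps, require_x_se=False):
    x = np.asarray(X, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape:
        raise ValueError("X and y must have the same length")
    if x.size < min_snps:
        raise ValueError(f"need at least {min_snps} instruments, got {x.size}")
    if y_se is None:
        raise ValueError("y_se (outcome standard errors) is required")
    y_se = np.asarray(y_se, dtype=float).reshape(-1)
    if y_se.shape != y.shape or np.any(y_se <= 0):
        raise ValueError("y_se must be positive and match y")
    if x_se is not None:
        x_se = np.asarray(x_se, dtype=float).reshape(-1)
        if x_se.shape != x.shape or np.any(x_se <= 0):
            raise ValueError("x_se must be positive and match X")
    elif require_x_se:
        raise ValueError("x_se (exposure standard errors) is required")
    if np.any(x == 0):
        bad = np.flatnonzero(x == 0)
        raise ValueError(f"zero exposure effect at instrument index {bad.tolist()}")
    return x, y, x_se, y_se


def _heterogeneity_from_ratios(r, w, beta):
    q = float(np.sum(w * (r - beta) ** 2))
    df = r.size - 1
    pval = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q)
    return HeterogeneityResult(q=q, df=df, pval=pval, i2=i2)


class IVWEstimator(BaseEstimator):
    """Inverse-variance weighted estimator with first-order weights.

    The point estimate is the precision-weighted mean of the per-SNP
    Wald ratios r_j = y_j / x_j with w_j = (x_j / y_se_j)^2, identical
    to a zero-intercept weighted regression of y on x.  With
    ``random_effects="multiplicative"`` (default) the fixed-effect SE is
    inflated by sqrt(Q / (n-1)), floored at 1, so heterogeneity can
    widen but never narrow the interval.
    """

    method = "ivw"

    def __init__(self, random_effects: str = "multiplicative"):
        self.random_effects = random_effects

    def fit(self, X, y, *, x_se=None, y_se=None):
        if self.random_effects not in ("multiplicative", "fixed"):
            raise ValueError(f"unknown random_effects: {self.random_effects!r}")
        x, y, x_se, y_se = _check_arrays(X, y, x_se, y_se, min_snps=2)
        r = y / x
        w = (x / y_se) ** 2
        beta = float(np.sum(w * r) / np.sum(w))
        fixed_se = float(np.sum(w) ** -0.5)
        het = _heterogeneity_from_ratios(r, w, beta)
        scale = max(1.0, np.sqrt(het.q / het.df)) if het.df > 0 else 1.0
        se = fixed_se * scale if self.random_effects == "multiplicative" else fixed_se

        self.n_snps_ = x.size
        self.beta_ = beta
        self.fixed_se_ = fixed_se
        self.scale_ = float(scale)
        self.se_ = float(se)
        self.pvalue_ = float(2.0 * stats.norm.sf(abs(beta / se)))
        self.heterogeneity_ = het
        return self

    def predict(self, X):
        return self.beta_ * np.asarray(X, dtype=float).reshape(-1)

    def to_estimate(self) -> MREstimate:
        return MREstimate.from_beta(self.method, self.beta_, self.se_,
                                    self.n_snps_)


class EggerEstimator(BaseEstimator):
    """Weighted regression of outcome on exposure effects with intercept.

    Instruments are first oriented so every exposure effect is positive
    (the regression is not orientation-invariant).  A nonzero intercept
    estimates the mean directional pleiotropic effect; inference uses a
    t reference with n-2 degrees of freedom and a multiplicative
    overdispersion scale floored at 1.
    """

    method = "egger"

    def __init__(self):
        pass

    def fit(self, X, y, *, x_se=None, y_se=None):
        x, y, x_se, y_se = _check_arrays(X, y, x_se, y_se, min_snps=3)
        sign = np.where(x < 0, -1.0, 1.0)
        x, y = x * sign, y * sign
        w = 1.0 / y_se**2
        res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        n = x.size
        df = n - 2
        # statsmodels' bse uses the estimated scale; re-floor it at 1 so
        # an under-dispersed fit cannot shrink the standard errors.
        unit_bse = res.bse / np.sqrt(res.scale)
        scale = max(1.0, np.sqrt(res.scale))
        se = unit_bse * scale
        tcrit = stats.t.ppf(0.975, df)

        self.n_snps_ = n
        self.df_ = df
        self.scale_ = float(scale)
        self.beta_ = float(res.params[1])
        self.se_ = float(se[1])
        self.pvalue_ = float(2.0 * stats.t.sf(abs(self.beta_ / self.se_), df))
        self.intercept_ = float(res.params[0])
        self.intercept_se_ = float(se[0])
        self.intercept_pvalue_ = float(
            2.0 * stats.t.sf(abs(self.intercept_ / self.intercept_se_), df)
        )
        self.intercept_ci_ = (
            self.intercept_ - tcrit * self.intercept_se_,
            self.intercept_ + tcrit * self.intercept_se_,
        )
        return self

    def predict(self, X):
        return self.intercept_ + self.beta_ * np.asarray(X, dtype=float).reshape(-1)

    def to_result(self) -> EggerResult:
        slope = MREstimate.from_beta(self.method, self.beta_, self.se_,
                                     self.n_snps_, dist="t", df=self.df_)
        return EggerResult(
            slope=slope,
            intercept=self.intercept_,
            intercept_se=self.intercept_se_,
            intercept_ci=self.intercept_ci_,
            intercept_pval=self.intercept_pvalue_,
        )

    def to_estimate(self) -> MREstimate:
        return self.to_result().slope


def _weighted_median_rows(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Interpolated weighted median along the last axis.

    With normalized weights w_(j) on sorted values v_(j), the breakpoint
    of v_(j) is p_j = S_j - w_(j)/2 (S_j the cumulative weight); the
    median linearly interpolates v at p = 0.5.
    """
    values = np.atleast_2d(values)
    weights = np.atleast_2d(np.broadcast_to(weights, values.shape))
    order = np.argsort(values, axis=1)
    v = np.take_along_axis(values, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(w, axis=1)
    p = s - w / 2.0
    # index of the first breakpoint >= 0.5 per row
    k = (p < 0.5).sum(axis=1)
    rows = np.arange(values.shape[0])
    out = np.empty(values.shape[0])
    low = k == 0
    high = k == values.shape[1]
    mid = ~(low | high)
    out[low] = v[low, 0]
    out[high] = v[high, -1]
    if np.any(mid):
        k_m = k[mid]
        r_m = rows[mid]
        p0, p1 = p[r_m, k_m - 1], p[r_m, k_m]
        v0, v1 = v[r_m, k_m - 1], v[r_m, k_m]
        out[mid] = v0 + (v1 - v0) * (0.5 - p0) / (p1 - p0)
    return out


class MedianEstimator(BaseEstimator):
    """Simple or weighted median of per-SNP Wald ratios.

    The weighted median interpolates the inverse-variance-weighted
    cumulative distribution of ratios at 0.5; the simple median is the
    unweighted case.  The standard error comes from a seeded parametric
    bootstrap resampling each (x_j, y_j) from normals at the observed
    values with the observed SEs.
    """

    method = "weighted-median"

    def __init__(self, weighted: bool = True, n_boot: int = 1000,
                 random_state: int | None = None):
        self.weighted = weighted
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y, *, x_se=None, y_se=None):
        x, y, x_se, y_se = _check_arrays(X, y, x_se, y_se, min_snps=3,
                                         require_x_se=True)
        r = y / x
        if self.weighted:
            w = (x / y_se) ** 2
            beta = float(_weighted_median_rows(r, w)[0])
        else:
            beta = float(np.median(r))

        rng = np.random.default_rng(self.random_state)
        n = x.size
        xb = x + x_se * rng.standard_normal((self.n_boot, n))
        yb = y + y_se * rng.standard_normal((self.n_boot, n))
        rb = yb / xb
        if self.weighted:
            wb = (xb / y_se) ** 2
            boot = _weighted_median_rows(rb, wb)
        else:
            boot = np.median(rb, axis=1)
        se = float(np.std(boot, ddof=1))

        self.n_snps_ = n
        self.beta_ = beta
        self.se_ = se
        self.pvalue_ = float(2.0 * stats.norm.sf(abs(beta / se)))
        return self

    def predict(self, X):
        return self.beta_ * np.asarray(X, dtype=float).reshape(-1)

    def to_estimate(self) -> MREstimate:
        name = "weighted-median" if self.weighted else "simple-median"
        return MREstimate.from_beta(name, self.beta_, self.se_, self.n_snps_)


def _rho(t, loss, k):
    if loss == "quadratic":
        return 0.5 * t**2
    a = np.abs(t)
    return np.where(a <= k, 0.5 * t**2, k * a - 0.5 * k**2)


def _rho_prime(t, loss, k):
    if loss == "quadratic":
        return t
    return np.clip(t, -k, k)


def _rho_delta(loss, k):
    """E[rho'(Z) * Z] for Z ~ N(0,1); centres the overdispersion score."""
    if loss == "quadratic":
        return 1.0
    return 2.0 * stats.norm.cdf(k) - 1.0


class RAPSEstimator(BaseEstimator):
    """Profile-likelihood estimator adjusting for exposure-side noise.

    Maximizes sum_j -rho(t_j) with standardized residuals

        t_j(beta, tau2) = (y_j - beta x_j) / sqrt(y_se_j^2 + beta^2 x_se_j^2 + tau2)

    where ``rho`` is quadratic or Huber (constant 1.345).  With
    ``overdispersed=True`` the pair (beta, tau2) solves the adjusted
    profile score equations, absorbing systematic pleiotropy into tau2.
    The standard error is the M-estimation sandwich at the solution.
    """

    method = "raps"

    def __init__(self, loss: str = "quadratic", overdispersed: bool = False,
                 huber_k: float = 1.345, tol: float = 1e-10,
                 max_iter: int = 100):
        self.loss = loss
        self.overdispersed = overdispersed
        self.huber_k = huber_k
        self.tol = tol
        self.max_iter = max_iter

    def _score(self, beta, tau2, x, y, x_se, y_se):
        v = y_se**2 + beta**2 * x_se**2 + tau2
        a = np.sqrt(v)
        t = (y - beta * x) / a
        dt = -x / a - t * beta * x_se**2 / v
        return np.sum(_rho_prime(t, self.loss, self.huber_k) * dt)

    def _solve_beta(self, tau2, beta0, step, x, y, x_se, y_se):
        # the objective's gradient crosses - to + through the minimum but
        # decays to zero far away, so expand outward from the initial
        # value only until the crossing is bracketed
        f = lambda b: self._score(b, tau2, x, y, x_se, y_se)
        lo, hi = beta0, beta0
        dlo = dhi = max(step, 1e-6)
        flo, fhi = f(lo), f(hi)
        tries = 0
        while flo >= 0 and tries < 200:
            lo -= dlo
            dlo *= 1.6
            flo = f(lo)
            tries += 1
        tries = 0
        while fhi <= 0 and tries < 200:
            hi += dhi
            dhi *= 1.6
            fhi = f(hi)
            tries += 1
        if not (flo < 0 < fhi):
            raise ConvergenceError(
                f"profile score has no sign change; last iterate beta={beta0:.6g}, "
                f"score norm={abs(f(beta0)):.3g}"
            )
        return optimize.brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)

    def _solve_tau2(self, beta, x, y, x_se, y_se):
        delta = _rho_delta(self.loss, self.huber_k)

        def g(tau2):
            v = y_se**2 + beta**2 * x_se**2 + tau2
            t = (y - beta * x) / np.sqrt(v)
            return np.sum((_rho_prime(t, self.loss, self.huber_k) * t - delta) / v)

        if g(0.0) <= 0:
            return 0.0
        hi = np.mean(y_se**2)
        while g(hi) > 0 and hi < 1e6:
            hi *= 4.0
        return optimize.brentq(g, 0.0, hi, xtol=1e-14)

    def fit(self, X, y, *, x_se=None, y_se=None):
        if self.loss not in ("quadratic", "huber"):
            raise ValueError(f"unknown loss: {self.loss!r}")
        x, y, x_se, y_se = _check_arrays(X, y, x_se, y_se, min_snps=3,
                                         require_x_se=True)
        init = IVWEstimator().fit(x, y, y_se=y_se)
        beta, step = init.beta_, 2.0 * init.fixed_se_
        tau2 = 0.0
        for _ in range(self.max_iter):
            beta_new = self._solve_beta(tau2, beta, step, x, y, x_se, y_se)
            tau2_new = (self._solve_tau2(beta_new, x, y, x_se, y_se)
                        if self.overdispersed else 0.0)
            done = (abs(beta_new - beta) < self.tol * (1.0 + abs(beta))
                    and abs(tau2_new - tau2) < self.tol * (1.0 + tau2))
            beta, tau2 = beta_new, tau2_new
            if done:
                break
        else:
            raise ConvergenceError(
                f"no convergence after {self.max_iter} iterations; "
                f"last iterate beta={beta:.6g}, "
                f"score norm={abs(self._score(beta, tau2, x, y, x_se, y_se)):.3g}"
            )

        # sandwich variance: A^-1 B A^-1 with per-SNP scores psi_j
        v = y_se**2 + beta**2 * x_se**2 + tau2
        a = np.sqrt(v)
        t = (y - beta * x) / a
        dt = -x / a - t * beta * x_se**2 / v
        psi = _rho_prime(t, self.loss, self.huber_k) * dt
        h = 1e-6 * (1.0 + abs(beta))
        a_info = (self._score(beta + h, tau2, x, y, x_se, y_se)
                  - self._score(beta - h, tau2, x, y, x_se, y_se)) / (2 * h)
        b_info = float(np.sum(psi**2))
        se = float(np.sqrt(b_info) / abs(a_info))

        self.n_snps_ = x.size
        self.beta_ = float(beta)
        self.tau2_ = float(tau2)
        self.se_ = se
        self.pvalue_ = float(2.0 * stats.norm.sf(abs(beta / se)))
        return self

    def predict(self, X):
        return self.beta_ * np.asarray(X, dtype=float).reshape(-1)

    def to_estimate(self) -> MREstimate:
        return MREstimate.from_beta(self.method, self.beta_, self.se_,
                                    self.n_snps_)


# ---------------------------------------------------------------------------
# functional wrappers over harmonized-instrument collections


def wald_ratios(instruments) -> list[RatioEstimate]:
    """Per-SNP Wald ratios y/x with first-order SEs y_se/|x|."""
    rsid, x, _, y, y_se = as_effect_arrays(instruments)
    zero = np.flatnonzero(x == 0)
    if zero.size:
        raise ValueError(
            f"zero exposure effect for {', '.join(rsid[zero])}"
        )
    return [
        RatioEstimate(rsid=str(s), beta_ratio=float(b / g),
                      se_ratio=float(se / abs(g)))
        for s, g, b, se in zip(rsid, x, y, y_se)
    ]


def ivw_mre(instruments) -> tuple[MREstimate, HeterogeneityResult]:
    """Multiplicative random-effects IVW estimate plus heterogeneity."""
    _, x, x_se, y, y_se = as_effect_arrays(instruments)
    est = IVWEstimator().fit(x, y, x_se=x_se, y_se=y_se)
    return est.to_estimate(), est.heterogeneity_


def egger(instruments) -> EggerResult:
    _, x, x_se, y, y_se = as_effect_arrays(instruments)
    return EggerEstimator().fit(x, y, x_se=x_se, y_se=y_se).to_result()


def median_estimators(instruments, kind: str = "weighted",
                      n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    if kind not in ("simple", "weighted"):
        raise ValueError(f"unknown median kind: {kind!r}")
    _, x, x_se, y, y_se = as_effect_arrays(instruments)
    est = MedianEstimator(weighted=(kind == "weighted"), n_boot=n_boot,
                          random_state=seed)
    return est.fit(x, y, x_se=x_se, y_se=y_se).to_estimate()


def raps(instruments, loss: str = "quadratic",
         overdispersed: bool = False) -> MREstimate:
    _, x, x_se, y, y_se = as_effect_arrays(instruments)
    est = RAPSEstimator(loss=loss, overdispersed=overdispersed)
    return est.fit(x, y, x_se=x_se, y_se=y_se).to_estimate()


def heterogeneity(instruments) -> HeterogeneityResult:
    """Cochran's Q and I^2 about the fixed-effect IVW estimate."""
    _, x, x_se, y, y_se = as_effect_arrays(instruments)
    est = IVWEstimator().fit(x, y, x_se=x_se, y_se=y_se)
    return est.heterogeneity_
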