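"""MR-PRESSO: pleiotropy residual sum and outlier test.

A simulation-based test for horizontal pleiotropy.  For each variant j
the expected outcome effect is the leave-one-out IVW prediction
``beta_{-j} * x_j``; the observed residual sum of squares is compared
with its parametric-bootstrap null distribution (global test), each
variant's squared residual with its own simulated distribution
(outlier test, Bonferroni-adjusted), and the outlier-corrected IVW
estimate with the distribution of estimates after removing random
subsets of the same size (distortion test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import (
    IVWEstimator,
    MREstimate,
    as_effect_arrays,
)

__all__ = ["PressoResult", "presso", "MRPRESSO"]


@dataclass(frozen=True, eq=False)
class PressoResult:
    rss_observed: float
    global_p: float
    outlier_pvals: "pd.Series"  # Bonferroni-adjusted empirical p per rsid
    outliers: tuple[str, ...]
    corrected: MREstimate | None
    distortion_pct: float | None
    distortion_p: float | None
    n_sim: int
    seed: int | None


def _loo_slopes(x, y, w):
    """Leave-one-out zero-intercept WLS slopes, one per observation."""
    sxy = np.sum(w * x * y)
    sxx = np.sum(w * x * x)
    return (sxy - w * x * y) / (sxx - w * x * x)


def _loo_slopes_rows(xb, yb, w):
    """Row-wise leave-one-out slopes for simulated (n_sim, n) draws."""
    sxy = (w * xb * yb).sum(axis=1, keepdims=True)
    sxx = (w * xb * xb).sum(axis=1, keepdims=True)
    return (sxy - w * xb * yb) / (sxx - w * xb * xb)


class MRPRESSO:
    """Scikit-learn style wrapper around :func:`presso`.

    Parameters mirror the reference method: ``n_sim`` parametric
    replicates, outliers called at Bonferroni-adjusted empirical
    p < ``outlier_alpha``.
    """

    def __init__(self, n_sim: int = 1000, outlier_alpha: float = 0.05,
                 random_state: int | None = None):
        self.n_sim = n_sim
        self.outlier_alpha = outlier_alpha
        self.random_state = random_state

    def get_params(self, deep: bool = True):
        return {"n_sim": self.n_sim, "outlier_alpha": self.outlier_alpha,
                "random_state": self.random_state}

    def set_params(self, **params):
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X, y, *, x_se=None, y_se=None, rsid=None):
        x = np.asarray(X, dtype=float).reshape(-1)
        if rsid is None:
            rsid = np.array([f"snp{i}" for i in range(x.size)])
        frame = pd.DataFrame({
            "rsid": rsid, "beta_exp": x, "se_exp": x_se,
            "beta_out": np.asarray(y, dtype=float).reshape(-1), "se_out": y_se,
        })
        self.result_ = presso(frame, n_sim=self.n_sim,
                              seed=self.random_state,
                              outlier_alpha=self.outlier_alpha)
        self.outliers_ = list(self.result_.outliers)
        self.global_pvalue_ = self.result_.global_p
        if self.result_.corrected is not None:
            self.beta_ = self.result_.corrected.beta
            self.se_ = self.result_.corrected.se
            self.pvalue_ = self.result_.corrected.pval
        return self


def presso(instruments, n_sim: int = 1000, seed: int | None = None,
           outlier_alpha: float = 0.05) -> PressoResult:
    """Run the global, outlier and distortion tests on harmonized data.

    The global empirical p carries the +1 continuity correction; the
    per-variant outlier p-values do not, so a residual exceeding every
    simulated draw can reach significance after Bonferroni adjustment.
    """
    rsid, x, x_se, y, y_se = as_effect_arrays(instruments)
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 instruments, got {n}")
    if n_sim < 100:
        raise ValueError(f"need at least 100 simulations, got {n_sim}")
    if x_se is None or y_se is None:
        raise ValueError("exposure and outcome SEs are required")

    rng = np.random.default_rng(seed)
    w = 1.0 / y_se**2

    slopes = _loo_slopes(x, y, w)
    resid2_obs = (y - slopes * x) ** 2
    rss_obs = float(resid2_obs.sum())

    # parametric replicates under the per-SNP expected model
    xb = x + x_se * rng.standard_normal((n_sim, n))
    yb = slopes * x + y_se * rng.standard_normal((n_sim, n))
    slopes_b = _loo_slopes_rows(xb, yb, w)
    resid2_b = (yb - slopes_b * xb) ** 2
    rss_b = resid2_b.sum(axis=1)

    global_p = float((1 + np.sum(rss_b >= rss_obs)) / (n_sim + 1))

    pvals_raw = (resid2_b >= resid2_obs).mean(axis=0)
    pvals_adj = np.minimum(1.0, pvals_raw * n)
    outlier_pvals = pd.Series(pvals_adj, index=rsid, name="presso_outlier_p")
    outlier_mask = pvals_adj < outlier_alpha
    outliers = tuple(rsid[outlier_mask])

    keep = ~outlier_mask
    if keep.sum() == 0:
        raise ValueError("no instruments remain after outlier removal")

    corrected = None
    distortion_pct = None
    distortion_p = None
    if outlier_mask.any():
        if keep.sum() >= 2:
            est = IVWEstimator().fit(x[keep], y[keep], y_se=y_se[keep])
            corrected = est.to_estimate()
            beta_all = IVWEstimator().fit(x, y, y_se=y_se).beta_
            distortion_pct = float(
                100.0 * (beta_all - est.beta_) / abs(est.beta_)
            )
            n_out = int(outlier_mask.sum())
            dist_b = np.empty(n_sim)
            for b in range(n_sim):
                drop = rng.choice(n, size=n_out, replace=False)
                mask = np.ones(n, dtype=bool)
                mask[drop] = False
                sxy = np.sum(w[mask] * x[mask] * y[mask])
                sxx = np.sum(w[mask] * x[mask] ** 2)
                beta_b = sxy / sxx
                dist_b[b] = 100.0 * (beta_all - beta_b) / abs(beta_b)
            distortion_p = float(
                (1 + np.sum(np.abs(dist_b) >= abs(distortion_pct)))
                / (n_sim + 1)
            )
    else:
        est = IVWEstimator().fit(x, y, y_se=y_se)
        corrected = est.to_estimate()

    return PressoResult(
        rss_observed=rss_obs,
        global_p=global_p,
        outlier_pvals=outlier_pvals,
        outliers=outliers,
        corrected=corrected,
        distortion_pct=distortion_pct,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )
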