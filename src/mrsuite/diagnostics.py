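"""Sensitivity diagnostics and statistical power for binary outcomes.

Leave-one-out re-estimation shows whether any single variant drives the
pooled estimate; funnel and scatter tables export the per-SNP geometry
behind the standard MR plots; the power calculation uses the
non-centrality approximation for a binary outcome,

    NCP = N * R^2 * (ln OR)^2 * K(1-K),
    power = Phi(sqrt(NCP) - z_{1-alpha/2}),

with N the sample size, R^2 the variance in exposure liability explained
by the instrument, K the case fraction and OR the true odds ratio per
unit log-odds of exposure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    EggerEstimator,
    IVWEstimator,
    MREstimate,
    as_effect_arrays,
    wald_ratios,
)

__all__ = [
    "LeaveOneOutResult",
    "PowerSpec",
    "leave_one_out",
    "funnel_data",
    "scatter_data",
    "power_binary",
    "detectable_or",
]


@dataclass(frozen=True)
class LeaveOneOutResult:
    """Per-omission IVW estimates plus the all-SNP estimate."""

    table: pd.DataFrame  # one row per omitted rsid + the "(all)" row
    full: MREstimate

    @property
    def influential(self) -> list[str]:
        """rsids whose omission moves the estimate by > 1 fixed-effect SE."""
        mask = self.table["influential"] & (self.table["omitted"] != "(all)")
        return self.table.loc[mask, "omitted"].tolist()


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to the binary-outcome power approximation."""

    n_sample: int
    r2_xz: float
    k_cases: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_sample <= 0:
            raise ValueError("n_sample must be positive")
        if not 0.0 <= self.r2_xz <= 1.0:
            raise ValueError("r2_xz must lie in [0,1]")
        if not 0.0 < self.k_cases < 1.0:
            raise ValueError("k_cases must lie in (0,1)")
        if self.or_alt <= 0:
            raise ValueError("or_alt must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0,1)")


def leave_one_out(instruments) -> LeaveOneOutResult:
    """IVW-MRE estimates with each instrument omitted in turn."""
    rsid, x, x_se, y, y_se = as_effect_arrays(instruments)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 instruments, got {n}")
    full_fit = IVWEstimator().fit(x, y, x_se=x_se, y_se=y_se)
    full = full_fit.to_estimate()
    rows = []
    for j in range(n):
        keep = np.arange(n) != j
        est = IVWEstimator().fit(x[keep], y[keep], y_se=y_se[keep]).to_estimate()
        rows.append(
            {
                "omitted": str(rsid[j]),
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "or": est.or_point,
                "ci_low": est.ci95[0],
                "ci_high": est.ci95[1],
                "influential": abs(est.beta - full.beta) > full_fit.fixed_se_,
            }
        )
    rows.append(
        {
            "omitted": "(all)",
            "beta": full.beta,
            "se": full.se,
            "pval": full.pval,
            "or": full.or_point,
            "ci_low": full.ci95[0],
            "ci_high": full.ci95[1],
            "influential": False,
        }
    )
    return LeaveOneOutResult(table=pd.DataFrame(rows), full=full)


def funnel_data(instruments) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP (ratio, precision) points plus the pooled reference lines."""
    ratios = wald_ratios(instruments)
    points = pd.DataFrame(
        {
            "rsid": [r.rsid for r in ratios],
            "beta_ratio": [r.beta_ratio for r in ratios],
            "precision": [1.0 / r.se_ratio for r in ratios],
        }
    )
    _, x, x_se, y, y_se = as_effect_arrays(instruments)
    lines = []
    if x.size >= 2:
        lines.append({"method": "ivw",
                      "beta": IVWEstimator().fit(x, y, y_se=y_se).beta_})
    if x.size >= 3:
        eg = EggerEstimator().fit(x, y, y_se=y_se)
        lines.append({"method": "egger", "beta": eg.beta_})
    return points, pd.DataFrame(lines, columns=["method", "beta"])


def scatter_data(instruments) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exposure-vs-outcome effect scatter with fitted IVW and Egger lines.

    Points are oriented so exposure effects are positive, the frame in
    which the Egger line is defined.
    """
    rsid, x, x_se, y, y_se = as_effect_arrays(instruments)
    sign = np.where(x < 0, -1.0, 1.0)
    points = pd.DataFrame(
        {
            "rsid": rsid,
            "beta_exp": x * sign,
            "se_exp": x_se if x_se is not None else np.nan,
            "beta_out": y * sign,
            "se_out": y_se,
        }
    )
    ivw_beta = IVWEstimator().fit(x, y, y_se=y_se).beta_
    lines = [{"method": "ivw", "slope": ivw_beta, "intercept": 0.0}]
    if x.size >= 3:
        eg = EggerEstimator().fit(x, y, y_se=y_se)
        lines.append({"method": "egger", "slope": eg.beta_,
                      "intercept": eg.intercept_})
    return points, pd.DataFrame(lines)


def power_binary(spec: PowerSpec) -> float:
    """Two-sided power to detect ``or_alt`` at level ``alpha``."""
    if spec.r2_xz == 0.0:
        warnings.warn("r2_xz = 0: instrument explains nothing; "
                      "power degenerates to the alpha-level baseline",
                      stacklevel=2)
    ncp = (spec.n_sample * spec.r2_xz * np.log(spec.or_alt) ** 2
           * spec.k_cases * (1.0 - spec.k_cases))
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(np.sqrt(ncp) - z))


def detectable_or(n_sample: int, r2_xz: float, k_cases: float,
                  power: float = 0.8, alpha: float = 0.05) -> float:
    """Smallest odds ratio > 1 detectable at the requested power."""
    if not 0.0 < power < 1.0:
        raise ValueError("power must lie in (0,1)")
    if r2_xz <= 0.0:
        raise ValueError("r2_xz must be positive to invert the power formula")
    z_alpha = stats.norm.ppf(1.0 - alpha / 2.0)
    z_power = stats.norm.ppf(power)
    log_or = (z_alpha + z_power) / np.sqrt(
        n_sample * r2_xz * k_cases * (1.0 - k_cases)
    )
    return float(np.exp(log_or))
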