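import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrsuite.estimators import (
    EggerEstimator,
    IVWEstimator,
    MedianEstimator,
    RAPSEstimator,
    egger,
    heterogeneity,
    ivw_mre,
    median_estimators,
    raps,
    wald_ratios,
)

from conftest import random_instrument_frame


def frame(x, sx, y, sy):
    n = len(x)
    return pd.DataFrame({"rsid": [f"rs{i}" for i in range(n)],
                         "beta_exp": x, "se_exp": sx,
                         "beta_out": y, "se_out": sy})


# ------------------------------------------------------------------ Wald ratio

@pytest.mark.parametrize("g,G,sG,ratio,se", [
    (0.1, 0.05, 0.02, 0.5, 0.2),
    (-0.1, 0.05, 0.02, -0.5, 0.2),
    (0.1, 0.0, 0.02, 0.0, 0.2),
])
def test_wald_ratio_formula(g, G, sG, ratio, se):
    (r,) = wald_ratios(frame([g], [0.01], [G], [sG]))
    assert r.beta_ratio == pytest.approx(ratio)
    assert r.se_ratio == pytest.approx(se)


def test_wald_ratio_zero_exposure_names_snp():
    with pytest.raises(ValueError, match="rs0"):
        wald_ratios(frame([0.0], [0.01], [0.1], [0.01]))


# ------------------------------------------------------------------------ IVW

def test_ivw_two_snp_closed_form():
    est, het = ivw_mre(frame([0.2, 0.1], [0.01, 0.01],
                             [0.02, 0.02], [0.01, 0.02]))
    assert est.beta == pytest.approx(45 / 425)
    assert est.se == pytest.approx(425 ** -0.5)  # Q/(n-1) < 1: floor binds
    assert het.q == pytest.approx(400 * (0.1 - 45 / 425) ** 2
                                  + 25 * (0.2 - 45 / 425) ** 2)


def test_ivw_homogeneous_ratios_give_zero_q():
    est, het = ivw_mre(frame([0.1, 0.2, 0.4], [0.01] * 3,
                             [0.05, 0.10, 0.20], [0.01, 0.01, 0.02]))
    assert est.beta == pytest.approx(0.5)
    assert het.q == pytest.approx(0.0, abs=1e-20)
    assert het.i2 == 0.0


@pytest.mark.parametrize("n", [2, 3, 4, 5])
@pytest.mark.parametrize("case_seed", [0, 1, 2])
def test_ivw_matches_closed_form_wls(n, case_seed):
    """Oracle: zero-intercept weighted least squares normal equations."""
    rng = np.random.default_rng(100 * n + case_seed)
    x = rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)
    y = rng.normal(0, 0.02, n)
    sy = rng.uniform(0.005, 0.02, n)
    w = 1.0 / sy**2
    beta_wls = np.sum(w * x * y) / np.sum(w * x * x)
    est, het = ivw_mre(frame(x, np.full(n, 0.01), y, sy))
    assert est.beta == pytest.approx(beta_wls, rel=1e-12)
    r = y / x
    wr = (x / sy) ** 2
    q = np.sum(wr * (r - beta_wls) ** 2)
    assert het.q == pytest.approx(q, rel=1e-12)
    fixed = np.sum(wr) ** -0.5
    assert est.se == pytest.approx(fixed * max(1, np.sqrt(q / (n - 1))),
                                   rel=1e-12)


def test_ivw_random_effects_floor_never_shrinks_se(rng):
    fr = random_instrument_frame(rng, n=40)
    x, y = fr.beta_exp.to_numpy(), fr.beta_out.to_numpy()
    sy = fr.se_out.to_numpy()
    mre = IVWEstimator().fit(x, y, y_se=sy)
    fe = IVWEstimator(random_effects="fixed").fit(x, y, y_se=sy)
    assert mre.se_ >= fe.se_
    assert mre.scale_ >= 1.0


def test_ivw_requires_two_instruments():
    with pytest.raises(ValueError):
        ivw_mre(frame([0.1], [0.01], [0.02], [0.01]))


# ---------------------------------------------------------------------- Egger

def test_egger_exact_linear_fit():
    g = np.array([0.1, 0.2, 0.3])
    res = egger(frame(g, [0.01] * 3, 0.01 + 0.5 * g, [0.01] * 3))
    assert res.intercept == pytest.approx(0.01)
    assert res.slope.beta == pytest.approx(0.5)


def test_egger_matches_normal_equations_oracle(rng):
    fr = random_instrument_frame(rng, n=25)
    x = np.abs(fr.beta_exp.to_numpy())
    y = fr.beta_out.to_numpy() * np.sign(fr.beta_exp.to_numpy())
    sy = fr.se_out.to_numpy()
    w = 1.0 / sy**2
    # closed-form weighted regression with intercept
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    res = egger(fr)
    assert res.slope.beta == pytest.approx(slope, rel=1e-10)
    assert res.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-12)


def test_egger_orientation_invariance(rng):
    """Negating both effects of any instrument leaves Egger unchanged."""
    fr = random_instrument_frame(rng, n=20)
    res = egger(fr)
    flip = fr.copy()
    idx = rng.choice(len(fr), 7, replace=False)
    flip.loc[idx, "beta_exp"] *= -1
    flip.loc[idx, "beta_out"] *= -1
    res2 = egger(flip)
    assert res2.slope.beta == pytest.approx(res.slope.beta)
    assert res2.intercept == pytest.approx(res.intercept)


def test_egger_recovers_planted_model_without_pleiotropy(rng):
    fr = random_instrument_frame(rng, n=200, true_beta=0.1)
    res = egger(fr)
    est, _ = ivw_mre(fr)
    assert res.intercept == pytest.approx(0.0, abs=3 * res.intercept_se)
    assert res.slope.beta == pytest.approx(est.beta, abs=3 * res.slope.se)


def test_egger_needs_three_instruments():
    with pytest.raises(ValueError):
        egger(frame([0.1, 0.2], [0.01] * 2, [0.01, 0.02], [0.01] * 2))


# --------------------------------------------------------------------- median

def test_simple_and_weighted_agree_for_symmetric_equal_weights():
    fr = frame([0.1, 0.1, 0.1], [0.01] * 3, [0.01, 0.02, 0.03], [0.01] * 3)
    simple = median_estimators(fr, kind="simple", seed=0)
    weighted = median_estimators(fr, kind="weighted", seed=0)
    assert simple.beta == pytest.approx(0.2)
    assert weighted.beta == pytest.approx(0.2)


def test_weighted_median_interpolation_formula():
    # ratios (0.1, 0.2, 0.3), normalized weights (0.25, 0.25, 0.5)
    x = np.array([1.0, 1.0, np.sqrt(2.0)])
    y = x * np.array([0.1, 0.2, 0.3])
    fr = frame(x, [0.01] * 3, y, [1.0] * 3)
    est = median_estimators(fr, kind="weighted", seed=0)
    assert est.beta == pytest.approx(0.2 + 0.1 * (0.5 - 0.375) / (0.75 - 0.375))


def _weighted_median_oracle(values, weights):
    """Independent scalar implementation: explicit breakpoint scan."""
    order = np.argsort(values)
    v, w = np.asarray(values)[order], np.asarray(weights)[order]
    w = w / w.sum()
    s = np.cumsum(w)
    p = s - w / 2
    if 0.5 <= p[0]:
        return v[0]
    for j in range(1, len(v)):
        if p[j] >= 0.5:
            return v[j - 1] + (v[j] - v[j - 1]) * (0.5 - p[j - 1]) / (p[j] - p[j - 1])
    return v[-1]


@pytest.mark.parametrize("case_seed", range(6))
def test_weighted_median_matches_independent_oracle(case_seed):
    rng = np.random.default_rng(case_seed)
    n = int(rng.integers(3, 12))
    x = rng.uniform(0.05, 0.3, n)
    y = rng.normal(0.01, 0.05, n)
    sy = rng.uniform(0.005, 0.05, n)
    est = median_estimators(frame(x, np.full(n, 0.01), y, sy),
                            kind="weighted", seed=1)
    oracle = _weighted_median_oracle(y / x, (x / sy) ** 2)
    assert est.beta == pytest.approx(oracle, rel=1e-12)


def test_median_bootstrap_is_seeded():
    fr = frame([0.1, 0.2, 0.3, 0.15], [0.01] * 4,
               [0.02, 0.05, 0.04, 0.03], [0.01] * 4)
    a = median_estimators(fr, kind="weighted", seed=7)
    b = median_estimators(fr, kind="weighted", seed=7)
    c = median_estimators(fr, kind="weighted", seed=8)
    assert a.se == b.se
    assert a.se != c.se


# ----------------------------------------------------------------------- RAPS

def test_raps_reduces_to_fixed_effect_ivw_without_exposure_noise():
    rng = np.random.default_rng(5)
    n = 50
    x = np.abs(rng.normal(0, 0.08, n)) + 0.02
    sy = np.full(n, 0.002)
    y = 0.1 * x + rng.normal(0, 0.002, n)
    fe = IVWEstimator(random_effects="fixed").fit(x, y, y_se=sy)
    est = raps(frame(x, np.full(n, 1e-8), y, sy))
    assert est.beta == pytest.approx(fe.beta_, abs=1e-8)


def test_raps_near_zero_under_null(rng):
    fr = random_instrument_frame(rng, n=80, true_beta=0.0)
    est = raps(fr)
    assert abs(est.beta) < 3 * est.se


def test_raps_overdispersed_absorbs_balanced_pleiotropy(rng):
    fr = random_instrument_frame(rng, n=120, true_beta=0.1, alpha_sd=0.004)
    plain = RAPSEstimator().fit(fr.beta_exp, fr.beta_out,
                                x_se=fr.se_exp, y_se=fr.se_out)
    over = RAPSEstimator(overdispersed=True).fit(
        fr.beta_exp, fr.beta_out, x_se=fr.se_exp, y_se=fr.se_out)
    assert over.tau2_ > 0
    assert over.tau2_ == pytest.approx(0.004**2, rel=0.6)
    assert abs(over.beta_ - 0.1) < 3 * over.se_
    assert plain.tau2_ == 0.0


def test_raps_huber_matches_quadratic_on_clean_data(rng):
    fr = random_instrument_frame(rng, n=60, true_beta=0.1)
    q = raps(fr, loss="quadratic")
    h = raps(fr, loss="huber")
    assert h.beta == pytest.approx(q.beta, abs=0.2 * q.se)


# ----------------------------------------------------- shared symmetry checks

def _all_betas(fr, seed=3):
    x, sx = fr.beta_exp.to_numpy(), fr.se_exp.to_numpy()
    y, sy = fr.beta_out.to_numpy(), fr.se_out.to_numpy()
    return {
        "ivw": IVWEstimator().fit(x, y, y_se=sy).beta_,
        "egger": EggerEstimator().fit(x, y, y_se=sy).beta_,
        "smed": MedianEstimator(weighted=False, random_state=seed)
                .fit(x, y, x_se=sx, y_se=sy).beta_,
        "wmed": MedianEstimator(weighted=True, random_state=seed)
                .fit(x, y, x_se=sx, y_se=sy).beta_,
        "raps": RAPSEstimator().fit(x, y, x_se=sx, y_se=sy).beta_,
    }


@pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
def test_scale_equivariance_of_every_estimator(rng, c):
    fr = random_instrument_frame(rng, n=30)
    base = _all_betas(fr)
    scaled = fr.copy()
    scaled["beta_exp"] *= c
    scaled["se_exp"] *= c
    got = _all_betas(scaled)
    for k in base:
        assert got[k] == pytest.approx(base[k] / c, rel=1e-7), k


def test_sign_equivariance_of_every_estimator(rng):
    fr = random_instrument_frame(rng, n=30)
    base = _all_betas(fr)
    neg = fr.copy()
    neg["beta_out"] *= -1
    got = _all_betas(neg)
    for k in base:
        assert got[k] == pytest.approx(-base[k], rel=1e-7), k


def test_heterogeneity_invariants(rng):
    fr = random_instrument_frame(rng, n=40, alpha_sd=0.003)
    het = heterogeneity(fr)
    assert het.q >= 0
    assert het.df == 39
    assert 0 <= het.i2 < 1
    assert het.pval == pytest.approx(stats.chi2.sf(het.q, het.df))
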