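"""Decay-curve fitting: noiseless exactness, AICc ranking, regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from hypothesis import given, settings, strategies as st

from neurocascade import (
    PlateauDecayModel,
    ExponentialDecayModel,
    fit_plateau_decay,
    fit_exponential_decay,
    compare_aicc,
    linear_regression,
    validate_against_curve,
    split_age_fit,
)
from neurocascade.decay import aicc


def plateau_curve(t, y0, plateau, k, anchor=2.0):
    return plateau + (y0 - plateau) * np.exp(-k * (t - anchor))


def test_noiseless_plateau_recovery_exact():
    t = np.array([2.0, 4.0, 10.0, 30.0])
    y = plateau_curve(t, 100.0, 10.0, 0.5)
    # closed form: 10 + 90 exp(-0.5 (t-2))
    assert y == pytest.approx(
        [100.0, 10 + 90 * np.exp(-1), 10 + 90 * np.exp(-4), 10 + 90 * np.exp(-14)],
        rel=1e-12,
    )
    fit = fit_plateau_decay(list(zip(t, y)))
    assert fit.Y0 == pytest.approx(100.0, rel=1e-6)
    assert fit.plateau == pytest.approx(10.0, rel=1e-6)
    assert fit.K == pytest.approx(0.5, rel=1e-6)
    assert fit.half_life == pytest.approx(np.log(2) / 0.5, rel=1e-6)
    assert fit.plateau_pct == pytest.approx(10.0, rel=1e-6)
    assert fit.R2 == pytest.approx(1.0, abs=1e-9)


def test_half_life_is_ln2_over_k():
    t = np.linspace(2, 30, 8)
    fit = fit_plateau_decay(list(zip(t, plateau_curve(t, 50, 5, np.log(2)))))
    assert fit.half_life == pytest.approx(1.0, rel=1e-9)
    assert fit.half_life * fit.K == pytest.approx(np.log(2), abs=1e-12)


def test_noiseless_exponential_recovery():
    ages_d = np.array([30.44, 60.88, 182.6, 365.3])
    k = np.log(2) / 53.0
    y = 1000.0 * np.exp(-k * ages_d)
    fit = fit_exponential_decay(list(zip(ages_d, y)))
    assert fit.K == pytest.approx(k, rel=1e-6)
    assert fit.half_life == pytest.approx(53.0, rel=1e-6)


def test_flat_data_flags_infinite_half_life():
    t = np.array([30.0, 60.0, 180.0, 365.0])
    fit = fit_exponential_decay(list(zip(t, np.full(4, 25.0))))
    assert fit.half_life_infinite
    assert fit.params["Y0"] == pytest.approx(25.0, rel=1e-4)


def test_scale_invariance_of_fits():
    t = np.array([2.0, 3.0, 4.0, 6.0, 10.0, 18.0, 30.0])
    y = plateau_curve(t, 80.0, 12.0, 0.3)
    a = fit_plateau_decay(list(zip(t, y)))
    b = fit_plateau_decay(list(zip(t, 37.5 * y)))
    assert b.half_life == pytest.approx(a.half_life, rel=1e-6)
    assert b.Y0 == pytest.approx(37.5 * a.Y0, rel=1e-6)
    assert b.plateau == pytest.approx(37.5 * a.plateau, rel=1e-6)


def test_min_points_and_anchor_preconditions():
    with pytest.raises(ValueError, match=">= 4"):
        fit_plateau_decay([(2, 10), (4, 5), (10, 2)])
    with pytest.raises(ValueError, match="anchor"):
        PlateauDecayModel([1.0, 4.0, 10.0, 30.0], [1, 1, 1, 1], anchor_t=2.0)
    with pytest.raises(ValueError, match=">= 3"):
        fit_exponential_decay([(1, 1), (2, 2)])


def test_aicc_penalty_prefers_fewer_parameters_at_equal_rss():
    # identical RSS: AICc difference is purely the parameter penalty
    n = 10
    a2 = aicc(rss=5.0, n=n, n_params=2)
    a3 = aicc(rss=5.0, n=n, n_params=3)
    assert a2 < a3
    with pytest.raises(ValueError, match="AICc undefined"):
        aicc(rss=1.0, n=4, n_params=3)  # n == K' + 1


def test_compare_aicc_ranks_true_model_first():
    t = np.repeat([2.0, 3.0, 4.0, 6.0, 10.0, 18.0, 30.0], 2)
    rng = np.random.default_rng(1)
    y = plateau_curve(t, 100.0, 30.0, 0.5) * rng.lognormal(0, 0.05, t.size)
    fits = [
        PlateauDecayModel(t, y).fit(),
        ExponentialDecayModel(t, y).fit(),
    ]
    ranked = compare_aicc(fits)
    assert ranked.iloc[0]["model"] == "plateau-decay"
    # delta is shift-invariant by construction
    assert ranked["delta_aicc"].min() == 0.0


def test_linear_regression_exact_and_degenerate():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    res = linear_regression(x, 2 * x)
    assert res.slope == pytest.approx(2.0, abs=1e-12)
    assert res.R2 == pytest.approx(1.0, abs=1e-12)
    flat = linear_regression(x, np.full(5, 3.0))
    assert flat.R2 == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="variance"):
        linear_regression(np.ones(5), x)


def test_validation_exact_curve_gives_p_one():
    t = np.array([2.0, 4.0, 10.0, 30.0])
    fit = fit_plateau_decay(list(zip(t, plateau_curve(t, 100, 10, 0.5))))
    out = validate_against_curve(fit, list(zip(t, fit.predict(t))))
    assert out["p_value"] == 1.0
    assert np.allclose(out["residuals"]["residual"], 0.0)


def test_validation_shift_detected_and_matches_t_oracle():
    # shallow curve: +50% shift gives near-constant residuals -> small p
    t = np.array([2.0, 4.0, 8.0, 15.0, 30.0])
    y = plateau_curve(t, 40.0, 30.0, 0.4)
    fit = fit_plateau_decay(list(zip(t, y)))
    shifted = list(zip(t, 1.5 * fit.predict(t)))
    out = validate_against_curve(fit, shifted)
    resid = 0.5 * fit.predict(t)
    t_stat = resid.mean() / (resid.std(ddof=1) / np.sqrt(len(resid)))
    p_oracle = 2 * stats.t.sf(abs(t_stat), df=len(resid) - 1)
    assert out["p_value"] == pytest.approx(p_oracle, rel=1e-9)
    assert out["p_value"] < 0.05
    with pytest.raises(ValueError, match=">= 3"):
        validate_against_curve(fit, [(2, 1), (4, 1)])


def test_validation_type_one_error_rate():
    t = np.array([2.0, 4.0, 8.0, 15.0, 30.0])
    y = plateau_curve(t, 100.0, 12.0, 0.4)
    fit = fit_plateau_decay(list(zip(t, y)))
    rng = np.random.default_rng(7)
    rejections = 0
    n_rep = 200
    for _ in range(n_rep):
        noisy = fit.predict(t) + rng.normal(0, 3.0, t.size)
        out = validate_against_curve(fit, list(zip(t, noisy)))
        rejections += out["p_value"] < 0.05
    # binomial(200, 0.05): 3 SD band around 10
    assert 1 <= rejections <= 20


def test_split_age_fit_recovers_piecewise_half_lives():
    young_ages = np.array([100.0, 250.0, 400.0, 600.0])
    old_ages = np.array([800.0, 2000.0, 10000.0, 30000.0])
    k_young, k_old = np.log(2) / 191.0, np.log(2) / 9131.0
    y_young = 50.0 * np.exp(-k_young * young_ages)
    anchor = 50.0 * np.exp(-k_young * 730.0) / np.exp(-k_old * 730.0)
    y_old = anchor * np.exp(-k_old * old_ages)
    pts = list(zip(young_ages, y_young)) + list(zip(old_ages, y_old))
    young_fit, old_fit = split_age_fit(pts, split_age=730.0)
    assert young_fit.half_life == pytest.approx(191.0, rel=1e-6)
    assert old_fit.half_life == pytest.approx(9131.0, rel=1e-6)
    with pytest.raises(ValueError, match="below split"):
        split_age_fit(pts, split_age=100.0)
    with pytest.raises(ValueError, match="above split"):
        split_age_fit(pts, split_age=1e6)


def test_split_grid_search_finds_planted_breakpoint():
    # brute-force RSS scan over candidate splits recovers the planted one
    rng = np.random.default_rng(3)
    ages = np.linspace(50, 1500, 16)
    split_true = 730.0
    y = np.where(
        ages < split_true,
        60 * np.exp(-np.log(2) / 191 * ages),
        6 * np.exp(-np.log(2) / 9131 * ages),
    ) * rng.lognormal(0, 0.03, ages.size)
    pts = list(zip(ages, y))
    candidates = np.linspace(350, 1200, 9)
    rss = []
    for c in candidates:
        try:
            yf, of = split_age_fit(pts, split_age=c)
            rss.append(yf.rss + of.rss)
        except ValueError:
            rss.append(np.inf)
    best = candidates[int(np.argmin(rss))]
    assert abs(best - split_true) <= 120  # nearest grid candidate


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    y0=st.floats(10, 500),
    plateau_frac=st.floats(0.05, 0.6),
    k=st.floats(0.1, 1.5),
)
def test_noiseless_recovery_property(y0, plateau_frac, k):
    t = np.array([2.0, 3.0, 4.0, 6.0, 10.0, 18.0, 30.0])
    plateau = plateau_frac * y0
    fit = fit_plateau_decay(list(zip(t, plateau_curve(t, y0, plateau, k))))
    assert fit.K == pytest.approx(k, rel=1e-5)
    assert fit.plateau == pytest.approx(plateau, rel=1e-4, abs=1e-6)
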