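"""Spline design/penalty construction and penalized quasipoisson fitting."""

import numpy as np
import pandas as pd
import pytest

from ituri.gam import (QuasiPoissonGAM, backward_delete, build_design,
                       effort_offset, fit_gam, linear, s, select_smoothing,
                       model_comparison_table)
from ituri.gam import _basis_matrix, _knots, _second_derivative_penalty


def sim_counts(n, seed, effect="sine"):
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(0, 10, n)
    x2 = rng.uniform(0, 5, n)
    off = np.log(rng.uniform(2.5, 5.0, n))
    if effect == "sine":
        eta = 0.3 + 0.9 * np.sin(x1 / 1.8) - 0.25 * x2
    elif effect == "linear":
        eta = 0.3 + 0.25 * x1 - 0.25 * x2
    else:
        eta = np.full(n, 0.3)
    y = rng.poisson(np.exp(off + eta))
    return pd.DataFrame({"x1": x1, "x2": x2}), y, off


def cox_de_boor(x, t, i, d):
    """Textbook B-spline recursion, the independent basis oracle."""
    if d == 0:
        last = np.isclose(x, t[-1]) and t[i] < t[i + 1] <= t[-1] and np.isclose(t[i + 1], t[-1])
        return 1.0 if (t[i] <= x < t[i + 1]) or last else 0.0
    left = 0.0 if t[i + d] == t[i] else (x - t[i]) / (t[i + d] - t[i]) * cox_de_boor(x, t, i, d - 1)
    right = 0.0 if t[i + d + 1] == t[i + 1] else \
        (t[i + d + 1] - x) / (t[i + d + 1] - t[i + 1]) * cox_de_boor(x, t, i + 1, d - 1)
    return left + right


def test_basis_matches_de_boor_recursion_oracle():
    rng = np.random.default_rng(0)
    x = np.sort(rng.uniform(0, 10, 60))
    k = 6
    t = _knots(x, k)
    B = _basis_matrix(x, t)
    pts = rng.uniform(x.min(), x.max() - 1e-9, 100)
    Bp = _basis_matrix(pts, t)
    for row, xv in zip(Bp, pts):
        oracle = [cox_de_boor(float(xv), t, i, 3) for i in range(k)]
        np.testing.assert_allclose(row, oracle, atol=1e-12)
    # partition of unity on the data
    np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)


def test_penalty_positive_semidefinite_with_two_dim_null_space():
    x = np.linspace(0, 1, 40)
    for k in (4, 5, 7):
        t = _knots(x, k)
        S = _second_derivative_penalty(t, k)
        np.testing.assert_allclose(S, S.T, atol=1e-12)
        eig = np.linalg.eigvalsh(S)
        assert eig[0] > -1e-8  # PSD
        # null space = functions with zero second derivative = {1, x}
        assert np.sum(np.abs(eig) < 1e-8 * max(abs(eig))) == 2


def test_smooth_blocks_are_centered_and_k_validated():
    tab, y, off = sim_counts(80, 1)
    design = build_design(tab, [s("x1", k=5)])
    block = design.X[:, 1:]
    np.testing.assert_allclose(block.sum(axis=0), 0.0, atol=1e-9)
    with pytest.raises(ValueError, match="k >= 4"):
        s("x1", k=3)
    with pytest.raises(ValueError, match="constant"):
        build_design(tab.assign(x1=1.0), [s("x1")])


def test_unpenalized_linear_fit_matches_statsmodels_glm_oracle():
    import statsmodels.api as sm

    tab, y, off = sim_counts(150, 2, effect="linear")
    design = build_design(tab, [linear("x1"), linear("x2")])
    fit = fit_gam(y, off, design, lam=[0.0, 0.0])
    Xs = sm.add_constant(np.column_stack([tab.x1 - tab.x1.mean(), tab.x2 - tab.x2.mean()]))
    oracle = sm.GLM(y, Xs, family=sm.families.Poisson(), offset=off).fit()
    np.testing.assert_allclose(fit.coef, oracle.params, atol=1e-6)
    assert fit.deviance == pytest.approx(oracle.deviance, abs=1e-6)
    assert fit.edf_total == pytest.approx(3.0, abs=1e-8)


def test_intercept_only_model_explains_zero_deviance():
    tab, y, off = sim_counts(80, 3)
    fit = fit_gam(y, off, build_design(tab, []), lam=[])
    assert fit.deviance_explained == pytest.approx(0.0, abs=1e-8)
    assert fit.edf_total == pytest.approx(1.0, abs=1e-8)


def test_huge_lambda_collapses_smooth_to_linear():
    tab, y, off = sim_counts(150, 4)
    design = build_design(tab, [s("x1", k=7)])
    fit = fit_gam(y, off, design, lam=[1e9])
    # penalty null space within the centered block is the linear function
    assert fit.edf_terms["s(x1)"] == pytest.approx(1.0, abs=0.05)
    pe = fit.partial_effect("x1", n_grid=50)
    resid = np.polyfit(pe["value"], pe["effect"], 1, full=True)[1]
    assert float(resid[0]) < 1e-6  # effect curve is a straight line


def test_offset_shift_moves_only_the_intercept():
    tab, y, off = sim_counts(120, 5)
    design = build_design(tab, [s("x1", k=5)])
    f1 = fit_gam(y, off, design, lam=[1.0])
    f2 = fit_gam(y, off + np.log(3.0), design, lam=[1.0])
    assert f2.coef[0] == pytest.approx(f1.coef[0] - np.log(3.0), abs=1e-6)
    np.testing.assert_allclose(f2.coef[1:], f1.coef[1:], atol=1e-6)
    np.testing.assert_allclose(f2.mu, f1.mu, rtol=1e-6)


def test_adding_a_term_never_increases_deviance_unpenalized():
    tab, y, off = sim_counts(120, 6)
    d_small = build_design(tab, [linear("x1")])
    d_big = build_design(tab, [linear("x1"), s("x2", k=5)])
    dev_small = fit_gam(y, off, d_small, lam=[0.0]).deviance
    dev_big = fit_gam(y, off, d_big, lam=[0.0, 0.0]).deviance
    assert dev_big <= dev_small + 1e-8


def test_gcv_selection_prefers_low_edf_for_linear_truth():
    hits = 0
    for seed in range(10):
        tab, y, off = sim_counts(250, 100 + seed, effect="linear")
        design = build_design(tab, [s("x1", k=6)])
        _, fit = select_smoothing(y, off, design)
        hits += fit.edf_terms["s(x1)"] < 2.0
    assert hits >= 7


def test_gcv_fit_beats_forced_linear_on_sinusoidal_truth():
    tab, y, off = sim_counts(400, 11, effect="sine")
    _, fit = select_smoothing(y, off, build_design(tab, [s("x1", k=8)]))
    lin = fit_gam(y, off, build_design(tab, [linear("x1")]), lam=[0.0])
    assert fit.deviance_explained >= lin.deviance_explained


def test_duplicating_rows_does_not_shrink_selected_edf():
    tab, y, off = sim_counts(150, 12, effect="sine")
    _, f1 = select_smoothing(y, off, build_design(tab, [s("x1", k=6)]))
    tab2 = pd.concat([tab, tab], ignore_index=True)
    _, f2 = select_smoothing(np.tile(y, 2), np.tile(off, 2),
                             build_design(tab2, [s("x1", k=6)]))
    assert f2.edf_terms["s(x1)"] >= f1.edf_terms["s(x1)"] - 0.2


def test_backward_delete_drops_noise_and_is_deterministic():
    drops = 0
    for seed in range(8):
        tab, y, off = sim_counts(200, 300 + seed, effect="sine")
        rng = np.random.default_rng(seed)
        tab = tab.assign(noise=rng.uniform(size=len(tab)))
        fit, trace = backward_delete([s("x1", k=5), linear("x2"), s("noise", k=5)],
                                     tab, y, off)
        drops += "s(noise)" not in fit.term_labels
    assert drops >= 6
    # determinism: identical inputs give identical traces
    tab, y, off = sim_counts(150, 42, effect="sine")
    _, tr1 = backward_delete([s("x1", k=5), linear("x2")], tab, y, off)
    _, tr2 = backward_delete([s("x1", k=5), linear("x2")], tab, y, off)
    pd.testing.assert_frame_equal(tr1, tr2)


def test_backward_delete_keeps_single_useful_term():
    tab, y, off = sim_counts(200, 13, effect="sine")
    fit, _ = backward_delete([s("x1", k=5)], tab, y, off)
    assert fit.term_labels == ["s(x1)"]


def test_table_report_ranks_by_deviance_explained():
    tab, y, off = sim_counts(250, 14, effect="sine")
    rng = np.random.default_rng(14)
    tab = tab.assign(noise=rng.uniform(size=len(tab)))
    rep = model_comparison_table(tab, y, off,
                        univariate=[s("x1", k=5), linear("x2"), s("noise", k=5)],
                        composite={"both": [s("x1", k=5), linear("x2")]})
    uni = rep[rep["kind"] == "univariate"]
    assert list(uni["deviance_explained_pct"]) == \
        sorted(uni["deviance_explained_pct"], reverse=True)
    assert uni.iloc[0]["model"] == "s(x1)"
    assert bool(uni.iloc[0]["significant"])
    comp = rep[rep["model"] == "both"].iloc[0]
    assert comp["deviance_explained_pct"] >= uni.iloc[0]["deviance_explained_pct"] - 0.5


def test_dispersion_estimated_from_overdispersed_counts():
    rng = np.random.default_rng(15)
    n = 300
    x1 = rng.uniform(0, 10, n)
    off = np.zeros(n)
    mu = np.exp(1.0 + 0.1 * x1)
    phi = 3.0
    p = 1 / phi
    y = rng.negative_binomial(mu * p / (1 - p), p)
    fit = fit_gam(y, off, build_design(pd.DataFrame({"x1": x1}), [linear("x1")]),
                  lam=[0.0])
    assert fit.phi == pytest.approx(phi, rel=0.35)


def test_effort_offset_values_and_validation():
    off = effort_offset(2.0, [2.5, 5.0])
    np.testing.assert_allclose(off, np.log([10.0, 20.0]))
    with pytest.raises(ValueError):
        effort_offset(0.0, [2.5])


def test_estimator_api():
    tab, y, off = sim_counts(150, 16, effect="sine")
    g = QuasiPoissonGAM([s("x1", k=5), linear("x2")]).fit(tab, y, offset=off)
    assert g.get_params()["select"] is True
    assert 0 < g.deviance_explained_ <= 100
    preds = g.predict(tab, offset=off)
    assert preds.shape == y.shape
    assert np.all(preds > 0)
    pe = g.partial_effect("x1")
    assert set(pe.columns) == {"value", "effect", "se"}
    assert (pe["se"] >= 0).all()
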