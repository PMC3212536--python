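"""Density arithmetic, CV decomposition, change tests and conversions.

The published two-survey summary (n=460/286 over 280 km, ESW 2.01/2.40 m,
CVs 19.07%/28.70%) serves as a deterministic fixture throughout.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ituri.density import (ConversionParams, DensityEstimate, classify_changes,
                           density_interval, dung_to_elephants, encounter_rate,
                           estimate_density, extrapolate_population,
                           ivory_to_elephants, summary_change_report,
                           ztest_change)

D1995 = DensityEstimate("1995", 460, 280.0, 51, 1.64, 18.63, 2.01, 4.07,
                        4.09, 19.07, (2.83, 5.93))
D2006 = DensityEstimate("2006", 286, 280.0, 51, 1.02, 28.08, 2.40, 5.93,
                        2.13, 28.70, (1.22, 3.70))


def test_published_table_densities_and_rates():
    assert estimate_density(460, 280.0, 2.01) == pytest.approx(4.09, abs=0.005)
    assert estimate_density(286, 280.0, 2.40) == pytest.approx(2.13, abs=0.005)
    assert 460 / 280 == pytest.approx(1.64, abs=0.005)
    assert 286 / 280 == pytest.approx(1.02, abs=0.005)
    assert estimate_density(0, 280.0, 2.01) == 0.0
    with pytest.raises(ValueError):
        estimate_density(10, 0.0, 2.0)
    with pytest.raises(ValueError):
        estimate_density(10, 280.0, -1.0)


def test_encounter_rate_matches_spreadsheet_oracle():
    """Five-location toy set against a direct evaluation of the
    effort-weighted between-unit variance formula."""
    l = np.array([3.0, 5.5, 7.0, 4.0, 6.5])
    c = np.array([4, 9, 2, 7, 11])
    pooled = pd.DataFrame({"effort_km": l, "count": c})
    rate, cv = encounter_rate(pooled)
    L, n, k = l.sum(), c.sum(), 5
    r = n / L
    var = 0.0
    for li, ci in zip(l, c):
        var += li**2 * (ci / li - r) ** 2
    var *= k / (L**2 * (k - 1))
    assert rate == pytest.approx(r)
    assert cv == pytest.approx(100 * np.sqrt(var) / r, rel=1e-12)


def test_encounter_rate_zero_cv_when_rates_identical():
    pooled = pd.DataFrame({"effort_km": [2.0, 4.0, 8.0], "count": [1, 2, 4]})
    rate, cv = encounter_rate(pooled)
    assert rate == pytest.approx(0.5)
    assert cv == pytest.approx(0.0, abs=1e-10)
    with pytest.raises(ValueError, match="sampling units"):
        encounter_rate(pooled.iloc[:1])


def test_cv_decomposition_reproduces_published_row():
    """The 1995 row's CVs imply CV(ESW) = sqrt(19.07^2 - 18.63^2) = 4.07%."""
    implied = np.sqrt(19.07**2 - 18.63**2)
    assert implied == pytest.approx(4.07, abs=0.01)
    est = DensityEstimate.from_components("1995", 460, 280.0, 51, 2.01,
                                          cv_encounter=18.63, cv_esw=implied)
    assert est.cv_density == pytest.approx(19.07, abs=0.005)
    assert est.cv_density**2 == pytest.approx(est.cv_encounter**2 + est.cv_esw**2)


def test_lognormal_interval_matches_published_ci():
    low, high = density_interval(4.09, 19.07)
    assert low == pytest.approx(2.83, abs=0.02)
    assert high == pytest.approx(5.93, abs=0.02)
    # closed-form oracle
    C = np.exp(stats.norm.ppf(0.975) * np.sqrt(np.log(1 + 0.1907**2)))
    assert (low, high) == pytest.approx((4.09 / C, 4.09 * C))
    # CV -> 0 collapses the interval
    assert density_interval(4.09, 0.0) == (4.09, 4.09)


def test_interval_coverage_near_nominal():
    """95% log-normal CI covers the true density in about 95% of simulated
    surveys (Poisson counts over 51 locations, known ESW)."""
    rng = np.random.default_rng(99)
    esw, true_d = 2.0, 4.0
    covered = 0
    n_rep = 500
    for _ in range(n_rep):
        l = rng.uniform(2.5, 5.0, size=51) * rng.integers(1, 4, size=51)
        mu = true_d * 2 * esw * l * 0.1
        c = rng.poisson(mu)
        pooled = pd.DataFrame({"effort_km": l, "count": c})
        rate, cv = encounter_rate(pooled)
        D = estimate_density(c.sum(), l.sum(), esw)
        low, high = density_interval(D, cv)
        covered += low <= true_d <= high
    assert 0.92 <= covered / n_rep <= 0.98


def test_ztest_reproduces_published_statistics():
    z, p, pct = ztest_change(D1995, D2006)
    assert z == pytest.approx(1.978, abs=5e-4)
    assert p == pytest.approx(0.024, abs=5e-4)
    assert round(pct) == 48


def test_ztest_properties():
    z, p, _ = ztest_change(D1995, D1995)
    assert z == 0.0 and p == pytest.approx(0.5)
    z12, _, _ = ztest_change(D1995, D2006)
    z21, _, _ = ztest_change(D2006, D1995)
    assert z12 == pytest.approx(-z21)
    _, p2, _ = ztest_change(D1995, D2006, two_sided=True)
    assert p2 == pytest.approx(2 * 0.02399, abs=1e-3)


def test_classify_changes_published_counts_and_chi_square():
    deltas = np.concatenate([-np.ones(28), np.zeros(10), np.ones(13)])
    counts, chi2, p = classify_changes(deltas, epsilon=0.1)
    assert counts == (28, 10, 13)
    assert chi2 == pytest.approx(10.9412, abs=5e-5)
    assert p == pytest.approx(0.004, abs=5e-4)
    # hand oracle: sum (O-E)^2 / E with E = 51/3
    assert chi2 == pytest.approx(sum((o - 17) ** 2 / 17 for o in (28, 10, 13)))
    # uniform counts give zero
    assert classify_changes(np.repeat([-1, 0, 1], 17), epsilon=0.1)[1] == 0.0
    # accepts (D1, D2) pairs too
    counts2, _, _ = classify_changes([(4.0, 2.0), (1.0, 1.05), (1.0, 3.0)], epsilon=0.1)
    assert counts2 == (1, 1, 1)
    with pytest.raises(ValueError):
        classify_changes([])


def test_classification_chi_square_type_one_error():
    """Under random uniform change the 5% chi-square test rejects ~5%."""
    rng = np.random.default_rng(7)
    counts = rng.multinomial(51, [1 / 3] * 3, size=10_000)
    chi2 = ((counts - 17.0) ** 2 / 17.0).sum(axis=1)
    rate = (stats.chi2.sf(chi2, 2) < 0.05).mean()
    assert rate == pytest.approx(0.05, abs=0.01)


def test_conversion_chain_published_numbers():
    params = ConversionParams()
    e1 = dung_to_elephants(4.09, params)
    e2 = dung_to_elephants(2.13, params)
    assert e1 == pytest.approx(0.47, abs=0.005)
    assert e2 == pytest.approx(0.24, abs=0.005)
    assert dung_to_elephants(0.0, params) == 0.0
    p1 = extrapolate_population(e1, params.area)
    p2 = extrapolate_population(e2, params.area)
    assert (p1, p2, p1 - p2) == (6439, 3288, 3151)


def test_ivory_conversion():
    assert ivory_to_elephants(6.9) == 1
    assert ivory_to_elephants(23687.0) == 3433  # direct division, 23687/6.9 = 3433.0
    assert ivory_to_elephants(117.0) == 17
    with pytest.raises(ValueError):
        ivory_to_elephants(-1.0)


def test_summary_change_report_full_chain():
    rep = summary_change_report(D1995, D2006)
    assert rep["z"] == pytest.approx(1.978, abs=5e-4)
    assert round(rep["percent_decline"]) == 48
    assert rep["population"] == (6439, 3288)
    assert rep["population_loss"] == 3151


def test_conversion_params_validation():
    with pytest.raises(ValueError):
        ConversionParams(decay_days=0.0)
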