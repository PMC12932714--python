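"""Pairwise posterior probabilities, SEAc ratios, modes, credible intervals."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from isoniche import (
    MCMCConfig,
    build_report,
    credible_intervals,
    fit_ml_ellipse,
    hdi,
    posterior_mode,
    prob_less,
    sample_posterior,
    seac_ratio,
)
from isoniche.compare import equal_tailed_interval
from isoniche.errors import ContractError
from isoniche.simulate import GroupYearSpec, derive_seed, generate_group_year


def test_prob_less_total_dominance():
    assert prob_less([1, 2, 3], [4, 5, 6]) == 1.0


def test_prob_less_ties_count_zero():
    a = np.arange(10.0)
    assert prob_less(a, a) == 0.0


def test_prob_less_unequal_lengths_rejected():
    with pytest.raises(ContractError):
        prob_less([1, 2, 3], [1, 2])
    with pytest.raises(ContractError):
        prob_less([], [])


def test_prob_less_symmetric_distributions(rng):
    a, b = rng.standard_normal((2, 10_000))
    assert prob_less(a, b) == pytest.approx(0.5, abs=0.02)


@given(st.integers(0, 2**31 - 1))
def test_prob_less_antisymmetry(seed):
    """p(a,b) = 1 − p(b,a) for continuous (tie-free) draws."""
    r = np.random.default_rng(seed)
    a, b = r.standard_normal((2, 500))
    assert prob_less(a, b) + prob_less(b, a) == pytest.approx(1.0)


def test_seac_ratio_division():
    out = seac_ratio({2014: 2.0, 2015: 3.7, 2016: 3.1}, 2014)
    assert out == pytest.approx({2014: 1.0, 2015: 1.85, 2016: 1.55})


def test_seac_ratio_reference_only():
    assert seac_ratio({2014: 2.0}, 2014) == {2014: 1.0}


def test_seac_ratio_missing_reference():
    with pytest.raises(ContractError):
        seac_ratio({2015: 1.0}, 2014)


def test_mode_of_constant_draws():
    assert posterior_mode(np.full(200, 3.25)) == 3.25


def test_mode_of_lognormal_matches_analytic(rng):
    """KDE mode of 10⁵ lognormal draws within 5% of exp(μ − σ²)."""
    mu, sigma = 1.0, 0.4
    draws = rng.lognormal(mu, sigma, 100_000)
    analytic = np.exp(mu - sigma**2)
    assert posterior_mode(draws) == pytest.approx(analytic, rel=0.05)


def test_mode_of_symmetric_draws_near_median(rng):
    draws = rng.normal(10.0, 2.0, 50_000)
    grid_step = (draws.max() - draws.min()) / 511
    assert abs(posterior_mode(draws) - np.median(draws)) < 3 * grid_step


def test_mode_requires_enough_draws():
    with pytest.raises(ContractError):
        posterior_mode(np.ones(99))


def test_hdi_uniform_length_equals_level(rng):
    draws = rng.uniform(0, 1, 1_000_000)
    lo, hi = hdi(draws, 0.95)
    assert hi - lo == pytest.approx(0.95, abs=0.01)


def test_hdi_matches_brute_force_window(rng):
    """Implementation equals an exhaustive shortest-window scan."""
    draws = rng.lognormal(0, 0.6, 2_000)
    x = np.sort(draws)
    k = int(np.ceil(0.8 * x.size))
    best = min(range(x.size - k + 1), key=lambda i: x[i + k - 1] - x[i])
    assert hdi(draws, 0.8) == (x[best], x[best + k - 1])


def test_hdi_matches_arviz(rng):
    # draw count chosen so level*n is non-integer and both window
    # conventions (ceil vs floor+1) pick the same order statistics
    arviz = pytest.importorskip("arviz")
    draws = rng.lognormal(0, 0.5, 5_001)
    lo, hi = hdi(draws, 0.9)
    ref = arviz.hdi(draws, hdi_prob=0.9)
    assert lo == pytest.approx(ref[0], rel=1e-6)
    assert hi == pytest.approx(ref[1], rel=1e-6)


def test_hdi_equals_eti_for_symmetric(rng):
    draws = rng.normal(5, 1, 400_000)
    h = hdi(draws, 0.95)
    e = equal_tailed_interval(draws, 0.95)
    np.testing.assert_allclose(h, e, atol=0.05)


def test_intervals_nested(rng):
    draws = rng.gamma(2.0, 1.0, 5_000)
    for method in ("hdi", "eti"):
        ci = credible_intervals(draws, method=method)
        assert ci[0.50][0] >= ci[0.75][0] >= ci[0.95][0]
        assert ci[0.50][1] <= ci[0.75][1] <= ci[0.95][1]


def test_interval_level_contract():
    with pytest.raises(ContractError):
        hdi(np.ones(200), 1.5)
    with pytest.raises(ContractError):
        credible_intervals(np.ones(200), method="bootstrap")


# ---- report assembly ----------------------------------------------------


def _posterior_for(area, year, n, seed, mcmc_seed):
    spec = GroupYearSpec("g", "predator", year, (0.0, 0.0), area, n=n,
                         eccentricity=1.5, angle=0.3)
    pts, _ = generate_group_year(spec, derive_seed(seed, "g", year))
    cfg = MCMCConfig(n_chains=2, n_iter=2_000, burn_in=200, thin=5, seed=mcmc_seed)
    return pts, sample_posterior(pts, cfg, "g", year)


def test_report_recovers_strong_effect():
    """True areas {1, 4, 1} at n=50: year2 clearly exceeds years 1 and 3."""
    posts, fits = {}, {}
    for year, area in zip((2014, 2015, 2016), (1.0, 4.0, 1.0)):
        pts, post = _posterior_for(area, year, 50, seed=2, mcmc_seed=year)
        posts[year], fits[year] = post, fit_ml_ellipse(pts, "g", year)
    rep = build_report(posts, fits, 2014, guild="predator")
    pw = {(r.year_a, r.year_b): r.p_a_less_b for r in rep.pairwise.itertuples()}
    assert pw[(2014, 2015)] > 0.9
    assert pw[(2015, 2016)] < 0.1
    assert rep.per_year.loc[rep.per_year.year == 2014, "seac_ratio"].item() == 1.0


def test_report_null_identical_data():
    """Same points every year: p_less ≈ 0.5 (MCMC noise only), ratios exactly 1."""
    spec = GroupYearSpec("g", "predator", 2014, (0.0, 0.0), 2.0, n=40)
    pts, _ = generate_group_year(spec, 123)
    posts, fits = {}, {}
    for year in (2014, 2015, 2016):
        cfg = MCMCConfig(n_chains=2, n_iter=4_000, burn_in=400, thin=5, seed=year)
        posts[year] = sample_posterior(pts, cfg, "g", year)
        fits[year] = fit_ml_ellipse(pts, "g", year)
    rep = build_report(posts, fits, 2014)
    assert np.allclose(rep.per_year["seac_ratio"], 1.0)
    assert np.all(np.abs(rep.pairwise["p_a_less_b"] - 0.5) < 0.1)


def test_report_nesting_and_mode_within_hdi():
    pts, post = _posterior_for(2.0, 2014, 60, seed=4, mcmc_seed=1)
    pts2, post2 = _posterior_for(2.0, 2015, 60, seed=5, mcmc_seed=2)
    rep = build_report(
        {2014: post, 2015: post2},
        {2014: fit_ml_ellipse(pts, "g", 2014), 2015: fit_ml_ellipse(pts2, "g", 2015)},
        2014,
    )
    row = rep.per_year.iloc[0]
    assert row.hdi95_lo <= row.hdi75_lo <= row.hdi50_lo
    assert row.hdi50_hi <= row.hdi75_hi <= row.hdi95_hi
    assert row.hdi95_lo <= row.seab_mode <= row.hdi95_hi


def test_report_flags_missing_year():
    pts, post = _posterior_for(2.0, 2014, 50, seed=6, mcmc_seed=1)
    pts2, post2 = _posterior_for(2.0, 2015, 50, seed=7, mcmc_seed=2)
    rep = build_report(
        {2014: post, 2015: post2},
        {2014: fit_ml_ellipse(pts, "g", 2014), 2015: fit_ml_ellipse(pts2, "g", 2015)},
        2014,
        expected_years=[2014, 2015, 2016],
    )
    assert rep.missing_years == [2016]
    assert len(rep.pairwise) == 1


def test_report_requires_two_years():
    pts, post = _posterior_for(2.0, 2014, 50, seed=8, mcmc_seed=1)
    with pytest.raises(ContractError):
        build_report({2014: post}, {2014: fit_ml_ellipse(pts, "g", 2014)}, 2014)
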