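"""Gibbs sampler for the SEAb posterior and the Gelman–Rubin diagnostic."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import invwishart

from isoniche import MCMCConfig, gelman_rubin, sample_posterior
from isoniche.bayes import _invwishart_rvs_2x2, conjugate_posterior_params
from isoniche.errors import ContractError, InsufficientSampleError

TRUE_COV = np.array([[2.0, 0.6], [0.6, 1.5]])


def _points(n, seed=7, cov=TRUE_COV):
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal([0.3, -0.2], cov, n)


def test_identical_seed_gives_bit_identical_draws(fast_mcmc):
    pts = _points(60)
    a = sample_posterior(pts, fast_mcmc)
    b = sample_posterior(pts, fast_mcmc)
    assert np.array_equal(a.mu_draws, b.mu_draws)
    assert np.array_equal(a.cov_draws, b.cov_draws)
    assert np.array_equal(a.seab_draws, b.seab_draws)


def test_different_seed_gives_different_draws(fast_mcmc):
    pts = _points(60)
    other = MCMCConfig(**{**fast_mcmc.__dict__, "seed": fast_mcmc.seed + 1})
    assert not np.array_equal(
        sample_posterior(pts, fast_mcmc).seab_draws,
        sample_posterior(pts, other).seab_draws,
    )


@given(
    n_iter=st.integers(50, 400),
    burn_in=st.integers(0, 49),
    thin=st.integers(1, 7),
    n_chains=st.integers(1, 4),
)
def test_retained_draw_accounting(n_iter, burn_in, thin, n_chains):
    """Retained draws per chain = (n_iter − burn_in) // thin for any config."""
    cfg = MCMCConfig(
        n_chains=n_chains, n_iter=n_iter, burn_in=burn_in, thin=thin, seed=1
    )
    expected = (n_iter - burn_in) // thin
    assert cfg.retained_per_chain == expected
    if expected >= 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = sample_posterior(_points(20), cfg)
        assert post.seab_draws.shape == (n_chains, expected)


def test_all_draws_positive_definite(fast_mcmc):
    post = sample_posterior(_points(40), fast_mcmc)
    dets = np.linalg.det(post.cov_draws)
    assert np.all(dets > 0)
    assert np.all(post.cov_draws[..., 0, 0] > 0)
    assert np.all(post.seab_draws > 0)
    np.testing.assert_allclose(
        post.cov_draws[..., 0, 1], post.cov_draws[..., 1, 0], atol=0
    )


def test_parameter_recovery_large_n():
    """n=200 from a normal with SEA 5.0 → posterior median within 10%
    (averaged over a fixed seed set so data noise cancels in aggregate)."""
    target = 5.0
    cov = TRUE_COV * (target / (np.pi * np.sqrt(np.linalg.det(TRUE_COV))))
    cfg = lambda s: MCMCConfig(n_chains=3, n_iter=3_000, burn_in=300, thin=5, seed=s)
    medians = [
        np.median(sample_posterior(_points(200, seed=s, cov=cov), cfg(s)).pooled_seab)
        for s in range(5)
    ]
    assert np.mean(medians) == pytest.approx(target, rel=0.10)


def test_rhat_close_to_one_when_well_mixed(fast_mcmc):
    post = sample_posterior(_points(100), fast_mcmc)
    assert all(v <= 1.1 for v in post.rhat.values())
    assert set(post.rhat) == {"log_seab", "mu1", "mu2"}


def test_direct_mode_matches_gibbs(fast_mcmc):
    pts = _points(80)
    gibbs = sample_posterior(pts, fast_mcmc, method="gibbs")
    direct = sample_posterior(pts, fast_mcmc, method="direct")
    assert np.median(direct.pooled_seab) == pytest.approx(
        np.median(gibbs.pooled_seab), rel=0.05
    )


def test_gibbs_matches_conjugate_closed_form():
    """Posterior mean of Σ from Gibbs equals Λn/(νn−3) within MC error."""
    pts = _points(100, seed=3)
    cfg = MCMCConfig(n_chains=1, n_iter=30_000, burn_in=1_000, thin=1, seed=5)
    post = sample_posterior(pts, cfg)
    _, _, nu_n, lambda_n = conjugate_posterior_params(pts, cfg)
    expected = lambda_n / (nu_n - 3)
    np.testing.assert_allclose(post.cov_draws.mean(axis=(0, 1)), expected, rtol=0.03)


def test_posterior_interquartile_range_shrinks_with_n():
    cfg = MCMCConfig(n_chains=2, n_iter=2_000, burn_in=200, thin=5, seed=9)
    iqrs = []
    for n in (200, 2_000):
        draws = sample_posterior(_points(n, seed=13), cfg).pooled_seab
        q1, q3 = np.percentile(draws, [25, 75])
        iqrs.append(q3 - q1)
    assert iqrs[1] < iqrs[0]


def test_insufficient_points_rejected(fast_mcmc):
    with pytest.raises(InsufficientSampleError):
        sample_posterior(_points(2), fast_mcmc)


def test_invalid_configs_rejected():
    with pytest.raises(ContractError):
        MCMCConfig(n_iter=100, burn_in=100)
    with pytest.raises(ContractError):
        MCMCConfig(thin=0)
    with pytest.raises(ContractError):
        sample_posterior(_points(10), MCMCConfig(), method="metropolis")


def test_invwishart_sampler_matches_scipy_moments(rng):
    """Own 2×2 Bartlett inverse-Wishart agrees with scipy's distribution."""
    df, scale = 12.0, np.array([[3.0, 0.8], [0.8, 2.0]])
    ours = np.array([_invwishart_rvs_2x2(rng, df, scale) for _ in range(20_000)])
    theirs = invwishart.rvs(df=df, scale=scale, size=20_000, random_state=1)
    np.testing.assert_allclose(ours.mean(axis=0), theirs.mean(axis=0), rtol=0.05)
    exact_mean = scale / (df - 3)  # d=2: E[Σ] = Λ/(ν−d−1)
    np.testing.assert_allclose(ours.mean(axis=0), exact_mean, rtol=0.05)


# ---- Gelman–Rubin -------------------------------------------------------


def test_gelman_rubin_converged_chains(rng):
    chains = rng.standard_normal((3, 5_000))
    assert gelman_rubin(chains) <= 1.05


def test_gelman_rubin_diverged_chains(rng):
    chains = np.stack(
        [rng.normal(0, 0.01, 500), rng.normal(100, 0.01, 500)]
    )
    assert gelman_rubin(chains) > 10


def test_gelman_rubin_unequal_lengths():
    with pytest.raises(ContractError):
        gelman_rubin([np.zeros(100), np.zeros(90)])


def test_gelman_rubin_matches_independent_formula(rng):
    """Agrees to 1e-6 with a separately written between/within computation."""
    chains = rng.normal(0, 1, (4, 800)) + rng.normal(0, 0.3, (4, 1))
    m, n = chains.shape
    means = [float(np.mean(c)) for c in chains]
    grand = sum(means) / m
    B = n / (m - 1) * sum((mu - grand) ** 2 for mu in means)
    W = sum(sum((x - mu) ** 2 for x in c) / (n - 1) for c, mu in zip(chains, means)) / m
    expected = ((((n - 1) / n) * W + B / n) / W) ** 0.5
    assert gelman_rubin(chains) == pytest.approx(expected, abs=1e-6)
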