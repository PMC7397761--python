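"""Tests of HDI/R-hat diagnostics and the hierarchical sampler."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metacov import (
    DegenerateDataError,
    GroupConfig,
    HierarchicalModelSpec,
    InvalidParameterError,
    McmcConfig,
    compute_hdi,
    compute_rhat,
    counts_by_subject_task,
    fit_hmetad_multitask,
    simulate_group,
    summarize_correlations,
    uniform_correlation,
)

from _oracles import hdi_oracle, rhat_oracle


class TestHdi:
    def test_degenerate_distribution(self):
        lo, hi = compute_hdi(np.full(20, 0.4))
        assert (lo, hi) == (0.4, 0.4)

    def test_integer_window_leftmost_tie_break(self):
        lo, hi = compute_hdi(np.arange(1, 101), mass=0.95)
        assert (lo, hi) == (1.0, 95.0)

    def test_standard_normal_matches_quantiles(self):
        rng = np.random.default_rng(0)
        lo, hi = compute_hdi(rng.standard_normal(1_000_000))
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        seed=st.integers(0, 5000),
        n=st.integers(10, 200),
        mass=st.floats(0.5, 0.99),
    )
    def test_matches_window_scan_oracle(self, seed, n, mass):
        rng = np.random.default_rng(seed)
        s = rng.gamma(2.0, 1.0, n)
        assert compute_hdi(s, mass) == pytest.approx(hdi_oracle(s, mass), abs=1e-12)

    def test_hdi_contains_median(self):
        rng = np.random.default_rng(3)
        s = rng.standard_normal(500)
        lo, hi = compute_hdi(s)
        assert lo <= np.median(s) <= hi

    def test_errors(self):
        with pytest.raises(InvalidParameterError):
            compute_hdi(np.arange(100), mass=1.5)
        with pytest.raises(DegenerateDataError):
            compute_hdi(np.arange(5))


class TestRhat:
    def test_identical_chains_hit_degenerate_limit(self):
        chain = np.random.default_rng(1).standard_normal(500)
        r = compute_rhat(np.stack([chain, chain, chain]))
        n = 500
        assert r == pytest.approx(np.sqrt((n - 1) / n), abs=1e-6)

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(2)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
        r = compute_rhat(chains)
        assert r > 1.5
        assert r == pytest.approx(rhat_oracle(chains), abs=1e-12)

    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((3, 2000))
        assert compute_rhat(chains) < 1.05

    def test_cross_check_against_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(4)
        chains = rng.standard_normal((4, 2000))
        ours = compute_rhat(chains)
        theirs = float(az.rhat(chains))
        assert ours < 1.01 and theirs < 1.01
        assert ours == pytest.approx(theirs, abs=0.01)

    def test_single_chain_rejected(self):
        with pytest.raises(InvalidParameterError):
            compute_rhat(np.arange(100)[None, :])


class _FakePosterior:
    """Minimal stand-in posterior (synthetic draws) for summary-logic tests."""

    def __init__(self, rho_draws, mu_draws=None):
        from metacov.hier import HierarchicalPosterior

        d = rho_draws.shape[0]
        self.post = HierarchicalPosterior(
            tasks=["a", "b"],
            subjects=[0],
            pairs=[(0, 1)],
            mu=np.zeros((1, d, 2)) if mu_draws is None else mu_draws[None],
            sigma=np.ones((1, d, 2)),
            rho=rho_draws.reshape(1, d, 1),
            log_mratio=np.zeros((1, d, 1, 2)),
            rhat={},
        )


class TestSummarizeCorrelations:
    def test_constant_rho_draws(self):
        post = _FakePosterior(np.full(100, 0.5)).post
        rep = summarize_correlations(post)["rho"]
        assert rep.loc[0, "mean"] == pytest.approx(0.5)
        assert rep.loc[0, "hdi_lo"] == pytest.approx(0.5)
        assert bool(rep.loc[0, "excludes_zero"]) is True

    def test_uniform_prior_draws_cover_zero(self):
        rng = np.random.default_rng(5)
        post = _FakePosterior(rng.uniform(-1, 1, 20_000)).post
        rep = summarize_correlations(post)["rho"]
        # a uniform on (-1,1) admits many equally narrow 95% windows: the
        # width is pinned at ~1.9 but the location is arbitrary in-sample
        width = rep.loc[0, "hdi_hi"] - rep.loc[0, "hdi_lo"]
        assert width == pytest.approx(1.9, abs=0.03)
        assert rep.loc[0, "hdi_lo"] < -0.85 and rep.loc[0, "hdi_hi"] > 0.85
        assert bool(rep.loc[0, "excludes_zero"]) is False

    def test_mratio_difference_on_exponentiated_scale(self):
        rng = np.random.default_rng(6)
        mu = np.stack([rng.normal(0.2, 0.01, 400), rng.normal(-0.4, 0.01, 400)], axis=-1)
        post = _FakePosterior(rng.uniform(-1, 1, 400), mu_draws=mu).post
        rep = summarize_correlations(post)["mratio_difference"]
        expected = np.exp(0.2) - np.exp(-0.4)
        assert rep.loc[0, "mean"] == pytest.approx(expected, abs=0.01)
        assert bool(rep.loc[0, "excludes_zero"]) is True


class TestHierarchicalFit:
    def test_posterior_shapes_and_bounds(self, small_posterior):
        post = small_posterior
        c, d, t = post.mu.shape
        assert (c, t) == (2, 2)
        assert post.rho.shape == (c, d, 1)
        assert np.all(post.sigma > 0)
        assert np.all(np.abs(post.rho) <= 1)
        summ = post.summary()
        assert np.all(summ["hdi_lo"] <= summ["median"] + 1e-12)
        assert np.all(summ["median"] <= summ["hdi_hi"] + 1e-12)

    def test_fit_deterministic_under_seed(self, small_group):
        cfg, trials, _ = small_group
        counts = counts_by_subject_task(trials, cfg.n_levels, collapse_to=4)
        import warnings

        mc = McmcConfig(n_chains=2, n_samples=60, n_burnin=50, seed=99)
        spec = HierarchicalModelSpec(n_tasks=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # short chains: R-hat warnings expected
            a = fit_hmetad_multitask(counts, spec, mc)
            b = fit_hmetad_multitask(counts, spec, mc)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.rho, b.rho)
        assert np.array_equal(a.log_mratio, b.log_mratio)

    def test_missing_task_rejected(self, small_group):
        cfg, trials, _ = small_group
        counts = counts_by_subject_task(trials, cfg.n_levels, collapse_to=4)
        del counts[(0, 1)]
        with pytest.raises(InvalidParameterError, match="missing"):
            fit_hmetad_multitask(counts, HierarchicalModelSpec(n_tasks=2))

    def test_prior_only_rho_marginal_is_uniform(self, small_group):
        """With the likelihood disabled the 2-task rho marginal is Uniform(-1,1)."""
        from scipy.stats import kstest

        cfg, trials, _ = small_group
        counts = counts_by_subject_task(trials, cfg.n_levels, collapse_to=4)
        post = fit_hmetad_multitask(
            counts,
            HierarchicalModelSpec(n_tasks=2),
            McmcConfig(n_chains=2, n_samples=2000, seed=13),
            prior_only=True,
        )
        draws = post.flat("rho")[:, 0]
        assert kstest(draws, "uniform", args=(-1, 2)).pvalue > 0.01

    def test_rho_posterior_means_rank_ordered(self):
        """Fits at true rho of 0, 0.3, 0.6 recover the correct ordering."""
        import warnings

        means = []
        for i, rho in enumerate((0.0, 0.3, 0.6)):
            cfg = GroupConfig(
                n_subjects=100, n_tasks=2, n_trials=400,
                rho=uniform_correlation(2, rho), seed=50 + i,
            )
            trials, _ = simulate_group(cfg)
            counts = counts_by_subject_task(trials, cfg.n_levels, collapse_to=4)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                post = fit_hmetad_multitask(
                    counts,
                    HierarchicalModelSpec(n_tasks=2),
                    McmcConfig(n_chains=2, n_samples=600, n_burnin=500, seed=60 + i),
                )
            means.append(post.flat("rho").mean())
        assert means[0] < means[1] < means[2]

    def test_hdi_shrinks_with_more_subjects(self):
        """Group-level uncertainty decreases from 50 to 200 subjects."""
        widths = {}
        for n in (50, 200):
            cfg = GroupConfig(
                n_subjects=n, n_tasks=2, n_trials=100,
                rho=uniform_correlation(2, 0.5), seed=31,
            )
            trials, _ = simulate_group(cfg)
            counts = counts_by_subject_task(trials, cfg.n_levels, collapse_to=4)
            post = fit_hmetad_multitask(
                counts,
                HierarchicalModelSpec(n_tasks=2),
                McmcConfig(n_chains=2, n_samples=500, n_burnin=400, seed=17),
            )
            lo, hi = compute_hdi(post.flat("mu")[:, 0])
            widths[n] = hi - lo
        assert widths[200] < widths[50]
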