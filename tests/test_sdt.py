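"""Tests of the counts container and type-I/type-II estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metacov import (
    CountsTable,
    DegenerateDataError,
    EstimationError,
    InvalidParameterError,
    build_counts,
    compute_auroc2,
    compute_dprime,
    fit_metad_mle,
    simulate_subject_task,
    SubjectTaskParams,
)
from metacov.sdt import type2_loglik, empirical_tau, _pad_if_needed

from _oracles import auroc2_oracle, dprime_oracle, random_counts


def _toy_trials(rows):
    import pandas as pd

    return pd.DataFrame(rows)


class TestBuildCounts:
    def test_placement_by_construction(self):
        trials = _toy_trials(
            [
                {"stimulus": "S1", "response": "S1", "confidence_level": 2},
                {"stimulus": "S2", "response": "S2", "confidence_level": 2},
            ]
        )
        c = build_counts(trials, 3)
        assert c.nR_S1[0] == 1 and c.nR_S1.sum() == 1
        assert c.nR_S2[-1] == 1 and c.nR_S2.sum() == 1

    def test_conservation_and_collapse(self):
        params = SubjectTaskParams.with_default_criteria(1.5, n_levels=11)
        trials = simulate_subject_task(params, 40, seed=8)
        full = build_counts(trials, 11)
        collapsed = build_counts(trials, 11, collapse_to=4)
        assert full.n_trials == 40
        assert collapsed.n_trials == 40
        assert collapsed.nR_S1.size == 8
        # brute-force recount of the collapsed table
        for stim, vec in (("S1", collapsed.nR_S1), ("S2", collapsed.nR_S2)):
            block = trials[trials["stimulus"] == stim]
            recount = np.zeros(8)
            for _, row in block.iterrows():
                b = min(int(row["confidence_level"]) * 4 // 11, 3)
                idx = 4 + b if row["response"] == "S2" else 3 - b
                recount[idx] += 1
            assert np.array_equal(recount, vec)

    def test_errors(self):
        with pytest.raises(DegenerateDataError):
            build_counts(_toy_trials([]), 3)
        mixed = _toy_trials(
            [
                {"subject": 1, "task": "a", "stimulus": "S1", "response": "S1", "confidence_level": 0},
                {"subject": 2, "task": "a", "stimulus": "S1", "response": "S1", "confidence_level": 0},
            ]
        )
        with pytest.raises(InvalidParameterError, match="subject"):
            build_counts(mixed, 3)


class TestDprime:
    def test_symmetric_rates_give_zero(self):
        c = CountsTable([5, 5, 5, 5], [5, 5, 5, 5], 2)
        est = compute_dprime(c, correction="none")
        assert est.dprime == pytest.approx(0.0, abs=1e-12)

    def test_unit_z_rates(self):
        # hit rate 0.8413 ~ Phi(1), fa rate 0.1587 ~ Phi(-1) -> d' ~ 2
        n = 10_000
        hits = round(0.8413 * n)
        fas = round(0.1587 * n)
        c = CountsTable([n - fas, 0, 0, fas], [n - hits, 0, 0, hits], 2)
        est = compute_dprime(c, correction="none")
        assert est.dprime == pytest.approx(2.0, abs=1e-3)

    def test_matches_rate_arithmetic_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            c, _ = random_counts(rng, n_levels=3, n_trials=60)
            est = compute_dprime(c, correction="loglinear")
            d_o, c_o = dprime_oracle(c)
            assert est.dprime == pytest.approx(d_o, abs=1e-10)
            assert est.criterion == pytest.approx(c_o, abs=1e-10)

    def test_monotone_in_hit_rate(self):
        fa = 0.2
        from scipy.special import ndtri

        prev = -np.inf
        for hr in np.linspace(0.05, 0.95, 19):
            n = 1000
            c = CountsTable(
                [round(n * (1 - fa)), 0, 0, round(n * fa)],
                [round(n * (1 - hr)), 0, 0, round(n * hr)],
                2,
            )
            d = compute_dprime(c, correction="none").dprime
            assert d > prev
            prev = d

    def test_extreme_rate_without_correction_raises(self):
        c = CountsTable([10, 0, 0, 0], [0, 0, 0, 10], 2)
        with pytest.raises(EstimationError):
            compute_dprime(c, correction="none")
        assert np.isfinite(compute_dprime(c, correction="loglinear").dprime)


class TestAuroc2:
    def test_perfect_separation(self):
        # all correct at max confidence, all errors at min confidence
        c = CountsTable([5, 0, 0, 2, 0, 0], [0, 0, 3, 0, 0, 10], 3)
        correct, incorrect = c.accuracy_histograms()
        assert np.array_equal(correct, [0, 0, 15])
        assert np.array_equal(incorrect, [5, 0, 0])
        assert compute_auroc2(c) == pytest.approx(1.0)

    def test_chance_when_confidence_uninformative(self):
        params = SubjectTaskParams.with_default_criteria(dprime=1.0, metad=0.0, n_levels=5)
        trials = simulate_subject_task(params, 40_000, seed=3)
        c = build_counts(trials, 5)
        assert compute_auroc2(c) == pytest.approx(0.5, abs=0.02)

    def test_three_level_toy_against_hand_enumeration(self):
        # correct: 1/2/7 and incorrect: 6/3/1 by ascending confidence
        c = CountsTable([0, 0, 0, 6, 3, 1], [0, 0, 0, 1, 2, 7], 3)
        correct, incorrect = c.accuracy_histograms()
        assert np.array_equal(correct, [1, 2, 7])
        assert np.array_equal(incorrect, [6, 3, 1])
        assert compute_auroc2(c) == pytest.approx(auroc2_oracle(c), abs=1e-12)

    def test_matches_trapezoid_oracle_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            c, _ = random_counts(rng, n_levels=4, n_trials=80)
            assert compute_auroc2(c) == pytest.approx(auroc2_oracle(c), abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), gaps=st.lists(st.integers(1, 3), min_size=4, max_size=4))
    def test_invariant_to_monotone_relabeling(self, seed, gaps):
        """Relabeling confidence levels with any strictly increasing map keeps AUROC2."""
        rng = np.random.default_rng(seed)
        params = SubjectTaskParams.with_default_criteria(
            dprime=1.5, metad=1.0, n_levels=5
        )
        trials = simulate_subject_task(params, 200, seed=rng)
        base = compute_auroc2(build_counts(trials, 5))
        new_levels = np.concatenate([[0], np.cumsum(gaps)])  # strictly increasing map
        relabeled = trials.copy()
        relabeled["confidence_level"] = new_levels[trials["confidence_level"].to_numpy()]
        relab = compute_auroc2(build_counts(relabeled, int(new_levels[-1]) + 1))
        assert relab == pytest.approx(base, abs=1e-12)

    def test_no_errors_raises(self):
        c = CountsTable([10, 0, 0, 0], [0, 0, 0, 10], 2)
        with pytest.raises(DegenerateDataError):
            compute_auroc2(c)


class TestMetadMle:
    def test_constant_confidence_is_degenerate_zero(self):
        # every trial rated at confidence level 1, both responses present
        c = CountsTable([0, 12, 0, 0, 8, 0], [0, 3, 0, 0, 17, 0], 3)
        fit = fit_metad_mle(c)
        assert fit.convergence_flag == "degenerate"
        assert fit.metad == 0.0

    def test_optimum_beats_random_admissible_vectors(self):
        rng = np.random.default_rng(2)
        c, _ = random_counts(rng, n_levels=3, n_trials=200)
        fit = fit_metad_mle(c)
        stacked = _pad_if_needed(c)
        cprime = fit.criterion / fit.dprime
        for _ in range(100):
            md = rng.uniform(0, 5)
            tau = rng.uniform(-3, 1.5, 4)
            ll = float(type2_loglik(stacked, md, cprime, tau, 3))
            assert fit.loglik >= ll - 1e-6

    @pytest.mark.parametrize("mratio_true", [0.5, 1.0])
    def test_median_mratio_recovery_at_400_trials(self, mratio_true):
        """Across 50 subjects x 400 trials the median MLE Mratio tracks the truth."""
        rng = np.random.default_rng(17)
        fits = []
        for _ in range(50):
            d = rng.uniform(1.0, 2.5)
            params = SubjectTaskParams.with_default_criteria(
                dprime=d, metad=mratio_true * d, n_levels=4
            )
            trials = simulate_subject_task(params, 400, seed=rng)
            fits.append(fit_metad_mle(build_counts(trials, 4)).mratio)
        assert np.median(fits) == pytest.approx(mratio_true, abs=0.1)


def test_counts_csv_round_trip(tmp_path):
    rng = np.random.default_rng(4)
    c, _ = random_counts(rng, n_levels=4, n_trials=50)
    p = tmp_path / "counts.csv"
    c.to_csv(p)
    c2 = CountsTable.from_csv(p)
    assert c2.n_levels == c.n_levels
    assert np.array_equal(c2.nR_S1, c.nR_S1)
    assert np.array_equal(c2.nR_S2, c.nR_S2)
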