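"""Resampling engine: combinatorics, metrics, reproducibility, sample sizes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conebio import (
    KD,
    MIXED,
    MORTALITY,
    CohortParams,
    OutcomeKind,
    ScenarioSpec,
    count_cone_combinations,
    empirical_reference,
    iteration_metrics,
    minimum_sample_size,
    run_scenario,
    sample_cone_selection,
    scenario_grid,
    simulate_cohort,
)
from conebio.scenarios import CohortData, ScenarioSummary


class TestCombinatorics:
    @pytest.mark.parametrize(
        "k, per_side, total",
        [(1, 4, 1024), (2, 6, 7776), (3, 4, 1024), (4, 1, 1)],
    )
    def test_counts(self, k, per_side, total):
        assert count_cone_combinations(k) == (per_side, total)

    @pytest.mark.parametrize("k", [0, 5])
    def test_out_of_range(self, k):
        with pytest.raises(ValueError):
            count_cone_combinations(k)


class TestConeSelectionSampling:
    def test_k4_always_full(self):
        rng = np.random.default_rng(0)
        sel = sample_cone_selection(4, rng)
        assert all(v == (1, 2, 3, 4) for v in sel.by_side.values())

    def test_k1_uniform_over_cones(self):
        rng = np.random.default_rng(1)
        n = 40_000
        counts = np.zeros((5, 4))
        for _ in range(n):
            sel = sample_cone_selection(1, rng)
            for s, side in enumerate(sel.by_side):
                counts[s, sel.by_side[side][0] - 1] += 1
        se = np.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(counts / n - 0.25) < 3 * se)

    def test_seeded_sequence_reproducible(self):
        a = [sample_cone_selection(2, np.random.default_rng(3)) for _ in range(5)]
        b = [sample_cone_selection(2, np.random.default_rng(3)) for _ in range(5)]
        assert a == b


class TestIterationMetrics:
    def test_direct_arithmetic(self):
        m = iteration_metrics([1, 1, 0, 0], [1, 0, 1, 0], [1, 0, 1, 0])
        assert (m.sensitivity, m.specificity, m.accuracy, m.diff_pp) == (
            0.5,
            0.5,
            0.5,
            0.0,
        )

    def test_perfect_agreement(self):
        m = iteration_metrics([1, 0, 1], [1, 0, 1], [1.0, 0.0, 1.0])
        assert m.accuracy == 1.0 and m.diff_pp == 0.0

    def test_degenerate_stratum_is_missing_not_zero(self):
        m = iteration_metrics([1, 1], [1, 1], [1.0, 1.0])
        assert m.specificity is None
        assert m.sensitivity == 1.0

    @given(
        z=st.lists(st.booleans(), min_size=2, max_size=12),
        y_seed=st.integers(0, 2**16),
    )
    def test_accuracy_is_prevalence_weighted_sens_spec(self, z, y_seed):
        rng = np.random.default_rng(y_seed)
        y = rng.random(len(z)) < 0.5
        m = iteration_metrics(z, y, y.astype(float))
        n1 = int(y.sum())
        n0 = len(z) - n1
        parts = 0.0
        if n1:
            parts += m.sensitivity * n1
        if n0:
            parts += m.specificity * n0
        assert m.accuracy == pytest.approx(parts / len(z))


@pytest.fixture(scope="module")
def small_cohort():
    nets, _ = simulate_cohort(CohortParams(n_nets=30, seed=77))
    return CohortData.from_nets(nets), nets


class TestRunScenario:
    def test_self_consistency_k4(self, small_cohort):
        """Reference forced to the 4-cone empirical classification: the k=4
        scenario must agree with it perfectly in every iteration."""
        data, nets = small_cohort
        ref = empirical_reference(nets, MIXED)
        s = run_scenario(data, ref, ScenarioSpec(MIXED, 4, 10, n_iterations=300, seed=5))
        assert s.mean_accuracy == 1.0
        assert s.mean_diff_pp == 0.0
        assert s.ci99_diff_pp == (0.0, 0.0)

    def test_exhaustive_sample_collapses_ci(self, small_cohort):
        data, nets = small_cohort
        ref = empirical_reference(nets, MORTALITY)
        s = run_scenario(
            data, ref, ScenarioSpec(MORTALITY, 4, len(nets), n_iterations=100, seed=6)
        )
        assert s.ci95_diff_pp[0] == s.ci95_diff_pp[1]

    def test_matches_iteration_metrics_on_full_sample(self, small_cohort):
        from conebio.assay import ConeSelection, classify_net

        data, nets = small_cohort
        ref = empirical_reference(nets, KD)
        s = run_scenario(
            data, ref, ScenarioSpec(KD, 4, len(nets), n_iterations=10, seed=7)
        )
        z = [classify_net(n, ConeSelection.full(), KD) for n in nets]
        m = iteration_metrics(z, ref.flags, ref.probs)
        assert s.mean_accuracy == pytest.approx(m.accuracy)
        assert s.mean_diff_pp == pytest.approx(m.diff_pp)

    def test_reproducible_summaries(self, small_cohort):
        data, nets = small_cohort
        ref = empirical_reference(nets, MORTALITY)
        spec = ScenarioSpec(MORTALITY, 2, 15, n_iterations=400, seed=11)
        assert run_scenario(data, ref, spec) == run_scenario(data, ref, spec)

    def test_oversized_sample_rejected(self, small_cohort):
        data, nets = small_cohort
        ref = empirical_reference(nets, MORTALITY)
        with pytest.raises(ValueError, match="exceeds cohort"):
            run_scenario(data, ref, ScenarioSpec(MORTALITY, 2, 31, seed=1))

    def test_reference_on_sampled_subset_with_bayes_reference(
        self, default_cohort, bayes_references
    ):
        """Full pipeline on the calibrated cohort: with 2 cones and 40 nets
        the indicator error stays a few pp on average and its 95% interval
        well bounded.  Bounds frozen from five replicate cohort/fit/engine
        runs (mean absolute error 2.2-2.9 pp, intervals within [-3.6, 8.2]);
        the error skews positive because the default cohort carries more
        mass just below the mortality cutoff than just above it."""
        nets, _ = default_cohort
        ref = bayes_references["references"][OutcomeKind.MORTALITY]
        s = run_scenario(
            CohortData.from_nets(nets),
            ref,
            ScenarioSpec(MORTALITY, 2, 40, n_iterations=1000, seed=13),
        )
        assert s.mean_abs_diff_pp < 3.5
        assert -5.0 < s.ci95_diff_pp[0] and s.ci95_diff_pp[1] < 10.0


def _summary(n, lo, hi):
    spec = ScenarioSpec(MORTALITY, 2, n, n_iterations=10, seed=0)
    return ScenarioSummary(spec, 1, 1, 1, 0, 0, (lo, hi), (lo - 1, hi + 1), 0, 0)


class TestMinimumSampleSize:
    GRID = (20, 40, 60, 80, 100, 120, 140, 160)

    def test_all_within_gives_lower_label(self):
        summaries = [_summary(n, -2, 2) for n in self.GRID]
        assert minimum_sample_size(summaries) == "<=20"

    def test_none_within_gives_upper_label(self):
        summaries = [_summary(n, -8, 8) for n in self.GRID]
        assert minimum_sample_size(summaries) == ">160"

    def test_crossing_point(self):
        half_widths = (12, 8, 4.9, 4.5, 4.0, 3.5, 3.0, 2.5)
        summaries = [
            _summary(n, -w, w) for n, w in zip(self.GRID, half_widths)
        ]
        assert minimum_sample_size(summaries) == "60"

    def test_containment_must_hold_at_all_larger_sizes(self):
        half_widths = (12, 4, 11, 4.5, 4.0, 3.5, 3.0, 2.5)  # dip then re-escape
        summaries = [
            _summary(n, -w, w) for n, w in zip(self.GRID, half_widths)
        ]
        assert minimum_sample_size(summaries) == "80"


class TestScenarioGrid:
    def test_shape_and_determinism(self, small_cohort):
        data, nets = small_cohort
        refs = {
            o.kind: empirical_reference(nets, o) for o in (MORTALITY, KD, MIXED)
        }
        kw = dict(
            outcomes=(MORTALITY, KD, MIXED),
            k_cones=(1, 2, 3, 4),
            n_grid=(10, 20, 30),
            n_iterations=50,
            seed=3,
        )
        table, mins = scenario_grid(data, refs, **kw)
        assert len(table) == 12 * 3
        assert set(mins) == {(o, k) for o in ("mortality", "kd", "mixed") for k in (1, 2, 3, 4)}
        table2, mins2 = scenario_grid(data, refs, **kw)
        assert table.equals(table2) and mins == mins2
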