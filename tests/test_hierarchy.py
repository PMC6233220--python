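"""Hierarchical reference model: shrinkage, limits, failure probabilities."""

import numpy as np
import pytest

from conebio import (
    KD,
    MIXED,
    MORTALITY,
    CohortParams,
    ModelSpec,
    OutcomeKind,
    empirical_reference,
    fit_hierarchical,
    net_failure_probabilities,
    reference_classification,
    simulate_cohort,
)
from conebio.hierarchy import HierarchicalFit, FitDiagnostics, NetPosterior

from conftest import make_net

FAST = dict(chains=2, draws=400, warmup=400)


def _toy_fit(q_draws: np.ndarray, endpoint: OutcomeKind) -> HierarchicalFit:
    """Wrap hand-written draws (draws, nets) as a single-chain fit."""
    q = q_draws[None, :, :]
    d = q.shape[1]
    diag = FitDiagnostics({}, {}, 1, d, 0, 0)
    zeros = np.zeros((1, d))
    ids = tuple(f"n{i}" for i in range(q.shape[2]))
    return HierarchicalFit(endpoint, ids, zeros, zeros, zeros, q, diag)


class TestFit:
    def test_saturated_data_gives_confident_pass(self):
        nets = [make_net(f"n{i}", dead=5, kd=5) for i in range(12)]
        fit_m = fit_hierarchical(nets, ModelSpec(OutcomeKind.MORTALITY), seed=1, **FAST)
        fit_k = fit_hierarchical(nets, ModelSpec(OutcomeKind.KD), seed=2, **FAST)
        for p in net_failure_probabilities(fit_m, fit_k):
            assert p.fail_mortality < 0.05

    def test_identical_seeds_identical_posteriors(self):
        nets, _ = simulate_cohort(CohortParams(n_nets=8, seed=5))
        f1 = fit_hierarchical(nets, ModelSpec(OutcomeKind.MORTALITY), seed=9, **FAST)
        f2 = fit_hierarchical(nets, ModelSpec(OutcomeKind.MORTALITY), seed=9, **FAST)
        np.testing.assert_array_equal(f1.q, f2.q)
        np.testing.assert_array_equal(f1.alpha, f2.alpha)

    def test_shrinkage_pulls_zero_count_net_off_zero(self):
        dead_levels = [0, 2, 3, 4, 5, 3, 4, 2, 5, 3]
        nets = [make_net(f"n{i}", dead=d, kd=d) for i, d in enumerate(dead_levels)]
        fit_m = fit_hierarchical(nets, ModelSpec(OutcomeKind.MORTALITY), seed=3, **FAST)
        fit_k = fit_hierarchical(nets, ModelSpec(OutcomeKind.KD), seed=4, **FAST)
        post = net_failure_probabilities(fit_m, fit_k)
        # net 0 observed 0/100 dead; the hierarchy keeps its posterior mean > 0
        assert post[0].q_mean > 0.0
        assert post[0].fail_mortality > 0.95

    def test_large_information_limit_matches_empirical_rates(self):
        rng = np.random.default_rng(0)
        nets = []
        for i in range(8):
            dead = rng.integers(100, 240, size=(5, 4))
            nets.append(make_net(f"n{i}", dead=dead, kd=dead, n_exposed=250))
        fit_m = fit_hierarchical(nets, ModelSpec(OutcomeKind.MORTALITY), seed=6, **FAST)
        fit_k = fit_hierarchical(nets, ModelSpec(OutcomeKind.KD), seed=7, **FAST)
        post = net_failure_probabilities(fit_m, fit_k)
        for net, p in zip(nets, post):
            emp = sum(r.n_dead_24 for r in net.cones) / sum(r.n_exposed for r in net.cones)
            assert abs(p.q_mean - emp) < 0.01

    def test_more_deaths_do_not_raise_failure_probability(self):
        nets, _ = simulate_cohort(CohortParams(n_nets=10, seed=21))
        bumped = []
        for j, net in enumerate(nets):
            if j != 0:
                bumped.append(net)
                continue
            recs = [
                r.__class__(
                    net_id=r.net_id,
                    side=r.side,
                    cone_index=r.cone_index,
                    n_exposed=r.n_exposed,
                    n_kd_60=r.n_kd_60,
                    n_dead_24=min(r.n_exposed, r.n_dead_24 + 2),
                )
                for r in net.cones
            ]
            bumped.append(net.__class__(net.net_id, net.brand, net.age_months, tuple(recs)))
        kw = dict(chains=2, draws=600, warmup=500)
        base = fit_hierarchical(nets, ModelSpec(OutcomeKind.MORTALITY), seed=8, **kw)
        more = fit_hierarchical(bumped, ModelSpec(OutcomeKind.MORTALITY), seed=8, **kw)
        fail_base = float((base.q_flat[:, 0] < 0.80).mean())
        fail_more = float((more.q_flat[:, 0] < 0.80).mean())
        assert fail_more <= fail_base + 0.05  # Monte-Carlo slack

    def test_incomplete_net_rejected_at_construction(self):
        net = make_net("n0", dead=3)
        with pytest.raises(Exception):
            net.__class__(net.net_id, net.brand, net.age_months, net.cones[:-1])


class TestFailureProbabilities:
    def test_all_draws_above_cutoff(self):
        q = np.full((20, 1), 0.9)
        post = net_failure_probabilities(
            _toy_fit(q, OutcomeKind.MORTALITY), _toy_fit(q, OutcomeKind.KD)
        )
        assert post[0].fail_mortality == 0.0

    def test_equal_weight_draws(self):
        q = np.array([[0.7], [0.9]] * 5)
        post = net_failure_probabilities(
            _toy_fit(q, OutcomeKind.MORTALITY), _toy_fit(np.full_like(q, 0.99), OutcomeKind.KD)
        )
        assert post[0].fail_mortality == 0.5

    def test_joint_failure_matches_direct_pair_count(self):
        rng = np.random.default_rng(1)
        q = rng.uniform(0.6, 1.0, size=(10, 3))
        p = rng.uniform(0.85, 1.0, size=(10, 3))
        post = net_failure_probabilities(
            _toy_fit(q, OutcomeKind.MORTALITY), _toy_fit(p, OutcomeKind.KD)
        )
        for i, np_ in enumerate(post):
            direct = sum(
                (q[d, i] < 0.80) and (p[d, i] < 0.95) for d in range(10)
            ) / 10
            assert np_.fail_mixed == pytest.approx(direct)
            assert np_.fail_mixed <= min(np_.fail_mortality, np_.fail_kd)

    def test_mismatched_net_sets_rejected(self):
        q = np.full((4, 2), 0.9)
        a = _toy_fit(q, OutcomeKind.MORTALITY)
        b = _toy_fit(q[:, :1], OutcomeKind.KD)
        with pytest.raises(ValueError, match="different net sets"):
            net_failure_probabilities(a, b)

    def test_joint_invariant_on_real_fit(self, bayes_references):
        for p in bayes_references["posteriors"]:
            assert p.fail_mixed <= min(p.fail_mortality, p.fail_kd) + 1e-12


def _post(pid, prob):
    return NetPosterior(pid, 0.5, 0.5, (0, 1), (0, 1), 1 - prob, 1 - prob, 1 - prob)


class TestReferenceClassification:
    def test_half_probability_is_valid(self):
        ref = reference_classification([_post("a", 0.5)], MORTALITY)
        assert ref.flags[0]

    def test_binary_and_expected_proportions(self):
        ref = reference_classification(
            [_post(i, p) for i, p in enumerate([1.0, 1.0, 0.0, 0.0])], MIXED
        )
        assert ref.expected_proportion == 0.5
        assert ref.binary_proportion == 0.5

    def test_divergence_between_binary_and_expected(self):
        ref = reference_classification(
            [_post(i, 0.6) for i in range(3)], KD
        )
        assert ref.binary_proportion == 1.0
        assert ref.expected_proportion == pytest.approx(0.6)


def test_empirical_reference_matches_full_classification(default_cohort):
    nets, _ = default_cohort
    ref = empirical_reference(nets[:20], MIXED)
    assert ref.probs.tolist() == [float(f) for f in ref.flags]
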