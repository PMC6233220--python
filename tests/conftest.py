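import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from conebio import (
    KD,
    MIXED,
    MORTALITY,
    CohortParams,
    ModelSpec,
    OutcomeKind,
    fit_hierarchical,
    net_failure_probabilities,
    reference_classification,
    simulate_cohort,
)
from conebio.assay import N_CONES, SIDES, ConeRecord, NetAssay

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_net(net_id="n1", dead=None, kd=None, n_exposed=5, brand="b", age=0):
    """Build a NetAssay from (5, 4) count arrays (scalars broadcast)."""
    dead = np.broadcast_to(np.asarray(dead if dead is not None else 0), (5, 4))
    kd = np.broadcast_to(np.asarray(kd if kd is not None else 0), (5, 4))
    records = [
        ConeRecord(
            net_id=net_id,
            side=SIDES[s],
            cone_index=c + 1,
            n_exposed=n_exposed,
            n_kd_60=int(kd[s, c]),
            n_dead_24=int(dead[s, c]),
        )
        for s in range(5)
        for c in range(N_CONES)
    ]
    return NetAssay(net_id, brand, age, tuple(records))


@pytest.fixture(scope="session")
def default_cohort():
    """The default calibrated 235-net synthetic cohort."""
    nets, latent = simulate_cohort(CohortParams(seed=20240917))
    return nets, latent


@pytest.fixture(scope="session")
def bayes_references(default_cohort):
    """Bayesian reference classifications of the default cohort, all rules."""
    nets, _ = default_cohort
    fit_m = fit_hierarchical(
        nets, ModelSpec(OutcomeKind.MORTALITY), chains=2, draws=750, warmup=500, seed=101
    )
    fit_k = fit_hierarchical(
        nets, ModelSpec(OutcomeKind.KD), chains=2, draws=750, warmup=500, seed=202
    )
    posteriors = net_failure_probabilities(fit_m, fit_k)
    refs = {
        o.kind: reference_classification(posteriors, o) for o in (MORTALITY, KD, MIXED)
    }
    return {"posteriors": posteriors, "references": refs, "fits": (fit_m, fit_k)}
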