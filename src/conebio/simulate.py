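"""Synthetic cone-bioassay cohorts with net- and side-level heterogeneity.

The generator draws, for each net, a bivariate-normal pair of logit-scale
random effects (mortality, knock-down) with correlation ``rho_net``, adds
independent side-within-net effects, and samples per-cone binomial counts at
the resulting side probabilities.  This is the generative counterpart of the
hierarchical reference model (see :mod:`conebio.hierarchy`), so parameter
recovery is well posed, and it emulates the kind of field cohort the analysis
is designed for: nets of several brands and ages whose mortality and
knock-down rates are broadly dispersed on both sides of the validity cutoffs
and positively correlated with each other.

The latent per-net truth is the arithmetic mean of the five side
probabilities, mirroring how the classifier averages over all cones of a
balanced design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .assay import (
    DEFAULT_N_PER_CONE,
    N_CONES,
    N_SIDES,
    SIDES,
    ConeRecord,
    NetAssay,
    OutcomeKind,
    ValidityOutcome,
)

__all__ = ["CohortParams", "simulate_cohort", "true_validity", "write_latent_truth"]

# Default offsets give older nets lower efficacy on both endpoints, spreading
# the cohort across the validity cutoffs the way a mixed-age field sample is.
DEFAULT_AGE_OFFSETS: Mapping[int, float] = {0: 0.7, 6: 0.0, 12: -0.7}
DEFAULT_BRAND_OFFSETS: Mapping[str, float] = {"brand_a": 0.0, "brand_b": 0.0, "brand_c": 0.0}


@dataclass(frozen=True)
class CohortParams:
    """Generative settings for a synthetic cohort.

    Logit-scale means and standard deviations; ``rho_net`` is the correlation
    between a net's mortality and knock-down random effects.  Defaults are
    calibrated so that a 235-net cohort shows broad mortality and knock-down
    distributions straddling the 80%/95% cutoffs, with roughly a fifth to a
    third of nets valid under each rule — the regime the method targets.
    """

    n_nets: int = 235
    mu_logit_mort: float = 0.40
    mu_logit_kd: float = 1.60
    sigma_net_mort: float = 1.5
    sigma_net_kd: float = 1.5
    sigma_side_mort: float = 0.5
    sigma_side_kd: float = 0.5
    rho_net: float = 0.8
    age_offsets: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_OFFSETS)
    )
    brand_offsets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BRAND_OFFSETS)
    )
    n_per_cone: int = DEFAULT_N_PER_CONE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nets < 1:
            raise ValueError("n_nets must be >= 1")
        for name in ("sigma_net_mort", "sigma_net_kd", "sigma_side_mort", "sigma_side_kd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1 <= self.rho_net <= 1:
            raise ValueError("rho_net must be in [-1, 1]")
        if self.n_per_cone < 1:
            raise ValueError("n_per_cone must be >= 1")
        if not self.age_offsets or not self.brand_offsets:
            raise ValueError("age_offsets and brand_offsets must be non-empty")


def simulate_cohort(params: CohortParams) -> tuple[list[NetAssay], pd.DataFrame]:
    """Draw a cohort; returns the assays and a latent-truth table.

    The latent table has one row per net with ``q_true`` (side-averaged
    mortality probability) and ``p_true`` (side-averaged knock-down
    probability), plus the assigned brand and age.  Identical params (and
    seed) give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_nets

    ages = np.asarray(sorted(params.age_offsets), dtype=int)
    brands = np.asarray(sorted(params.brand_offsets), dtype=object)
    age_of_net = rng.choice(ages, size=n)
    brand_of_net = rng.choice(brands, size=n)
    age_off = np.array([params.age_offsets[int(a)] for a in age_of_net])
    brand_off = np.array([params.brand_offsets[str(b)] for b in brand_of_net])

    # correlated net effects built from independent normals; degenerate
    # (zero-SD) components stay exactly zero
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    u = np.column_stack(
        [
            params.sigma_net_mort * z1,
            params.sigma_net_kd
            * (params.rho_net * z1 + np.sqrt(1.0 - params.rho_net**2) * z2),
        ]
    )
    v_mort = rng.normal(0.0, params.sigma_side_mort, size=(n, N_SIDES))
    v_kd = rng.normal(0.0, params.sigma_side_kd, size=(n, N_SIDES))

    eta_mort = (params.mu_logit_mort + age_off + brand_off + u[:, 0])[:, None] + v_mort
    eta_kd = (params.mu_logit_kd + age_off + brand_off + u[:, 1])[:, None] + v_kd
    q_side = expit(eta_mort)  # (n, 5) side-level mortality probabilities
    p_side = expit(eta_kd)

    dead = rng.binomial(params.n_per_cone, q_side[:, :, None], size=(n, N_SIDES, N_CONES))
    kd = rng.binomial(params.n_per_cone, p_side[:, :, None], size=(n, N_SIDES, N_CONES))

    width = len(str(n))
    nets: list[NetAssay] = []
    for i in range(n):
        net_id = f"net{i + 1:0{width}d}"
        records = [
            ConeRecord(
                net_id=net_id,
                side=SIDES[s],
                cone_index=c + 1,
                n_exposed=params.n_per_cone,
                n_kd_60=int(kd[i, s, c]),
                n_dead_24=int(dead[i, s, c]),
            )
            for s in range(N_SIDES)
            for c in range(N_CONES)
        ]
        nets.append(
            NetAssay(net_id, str(brand_of_net[i]), int(age_of_net[i]), tuple(records))
        )

    latent = pd.DataFrame(
        {
            "net_id": [net.net_id for net in nets],
            "brand": [net.brand for net in nets],
            "age_months": [net.age_months for net in nets],
            "q_true": q_side.mean(axis=1),
            "p_true": p_side.mean(axis=1),
        }
    )
    return nets, latent


def true_validity(q_true: float, p_true: float, outcome: ValidityOutcome) -> bool:
    """Ground-truth validity from latent probabilities (inclusive cutoffs)."""
    passes_mort = q_true >= outcome.mortality_cutoff
    passes_kd = p_true >= outcome.kd_cutoff
    if outcome.kind is OutcomeKind.MORTALITY:
        return bool(passes_mort)
    if outcome.kind is OutcomeKind.KD:
        return bool(passes_kd)
    return bool(passes_mort or passes_kd)


def write_latent_truth(latent: pd.DataFrame, path: str | Path) -> None:
    """Companion CSV of latent truths (test harnesses only)."""
    latent.to_csv(path, index=False)
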