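"""Hierarchical Bayesian reference model for per-net efficacy.

Each endpoint (mortality at 24 h, knock-down at 60 min) is modelled
separately as a binomial logit model with nested random effects: a net-level
effect capturing heterogeneity between nets and a side-within-net effect
capturing heterogeneity between the five netting pieces of one net.  Cone
counts within a side are treated as binomial replicates at the side's rate.

The quantity of interest per net i is the side-averaged success probability
(mortality q_i, knock-down p_i — the arithmetic mean of the five side-level
rates, matching how the bioassay classifier averages over all cones of the
balanced design).  Posterior draws of these probabilities yield each net's
failure probabilities Pr(q_i < 0.80), Pr(p_i < 0.95) and the joint
Pr(both), which is the probability the net fails the WHOPES mixed rule.

Fitting uses the package's adaptive Metropolis-within-Gibbs sampler
(:mod:`conebio._gibbs`); convergence is summarized with split-R-hat and bulk
effective sample size via arviz, and flagged as a warning rather than a
silent success.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._gibbs import sample_hierarchical_binomial
from .assay import N_CONES, N_SIDES, SIDES, NetAssay, OutcomeKind, ValidityOutcome

__all__ = [
    "ModelSpec",
    "FitDiagnostics",
    "HierarchicalFit",
    "NetPosterior",
    "Reference",
    "fit_hierarchical",
    "net_failure_probabilities",
    "reference_classification",
    "empirical_reference",
    "posteriors_to_frame",
]

RHAT_WARN = 1.05
ESS_WARN = 400.0


@dataclass(frozen=True)
class ModelSpec:
    """Model settings for one endpoint.

    ``endpoint`` selects which count is modelled; priors are weakly
    informative on the logit scale: Normal(0, 2.5^2) for the intercept and
    Half-Normal(1) for both random-effect standard deviations.
    """

    endpoint: OutcomeKind = OutcomeKind.MORTALITY
    intercept_prior_sd: float = 2.5
    sigma_prior_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.endpoint is OutcomeKind.MIXED:
            raise ValueError("fit one endpoint at a time (MORTALITY or KD)")
        if self.intercept_prior_sd <= 0 or self.sigma_prior_sd <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class FitDiagnostics:
    """Convergence summary for the top-level parameters."""

    rhat: Mapping[str, float]
    ess_bulk: Mapping[str, float]
    chains: int
    draws: int
    warmup: int
    seed: int

    @property
    def converged(self) -> bool:
        return all(r <= RHAT_WARN for r in self.rhat.values()) and all(
            e >= ESS_WARN for e in self.ess_bulk.values()
        )


@dataclass(frozen=True)
class HierarchicalFit:
    """Posterior draws from one endpoint's fit."""

    endpoint: OutcomeKind
    net_ids: tuple[str, ...]
    alpha: np.ndarray  # (chains, draws)
    sigma_net: np.ndarray
    sigma_side: np.ndarray
    q: np.ndarray  # (chains, draws, n_nets) side-averaged rates
    diagnostics: FitDiagnostics
    spec: ModelSpec = field(default_factory=ModelSpec)

    @property
    def q_flat(self) -> np.ndarray:
        """Draws pooled over chains, shape (chains*draws, n_nets)."""
        return self.q.reshape(-1, self.q.shape[-1])

    def hyper_summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in (
            ("alpha", self.alpha),
            ("sigma_net", self.sigma_net),
            ("sigma_side", self.sigma_side),
        ):
            flat = arr.ravel()
            lo, hi = np.percentile(flat, [2.5, 97.5])
            rows.append(
                {
                    "param": name,
                    "mean": float(flat.mean()),
                    "sd": float(flat.std()),
                    "ci95_low": float(lo),
                    "ci95_high": float(hi),
                    "rhat": self.diagnostics.rhat[name],
                    "ess_bulk": self.diagnostics.ess_bulk[name],
                }
            )
        return pd.DataFrame(rows)


def _side_counts(nets: Sequence[NetAssay], endpoint: OutcomeKind):
    """Side-level sufficient statistics (events, exposures), shape (n, 5)."""
    n = len(nets)
    y = np.zeros((n, N_SIDES))
    m = np.zeros((n, N_SIDES))
    for i, net in enumerate(nets):
        for s, side in enumerate(SIDES):
            for c in range(1, N_CONES + 1):
                rec = net.record(side, c)
                y[i, s] += rec.n_dead_24 if endpoint is OutcomeKind.MORTALITY else rec.n_kd_60
                m[i, s] += rec.n_exposed
    return y, m


def fit_hierarchical(
    nets: Sequence[NetAssay],
    spec: ModelSpec | None = None,
    *,
    chains: int = 4,
    draws: int = 1000,
    warmup: int = 1000,
    thin: int = 1,
    seed: int = 0,
) -> HierarchicalFit:
    """Fit the reference model to a complete cohort.

    Reproducible: identical data, spec, MCMC settings and seed give identical
    draws.  Emits a ``UserWarning`` when split-R-hat exceeds 1.05 or bulk ESS
    falls below 400 for any top-level parameter.
    """
    if not nets:
        raise ValueError("no nets supplied")
    spec = spec or ModelSpec()
    y, m = _side_counts(nets, spec.endpoint)

    post = sample_hierarchical_binomial(
        y,
        m,
        alpha_prior_sd=spec.intercept_prior_sd,
        sigma_prior_sd=spec.sigma_prior_sd,
        chains=chains,
        warmup=warmup,
        draws=draws,
        thin=thin,
        seed=seed,
    )

    import arviz as az

    idata = az.from_dict(
        posterior={k: post[k] for k in ("alpha", "sigma_net", "sigma_side")}
    )
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata, method="bulk")
    rhat = {k: float(rhat_ds[k].values) for k in ("alpha", "sigma_net", "sigma_side")}
    ess = {k: float(ess_ds[k].values) for k in ("alpha", "sigma_net", "sigma_side")}
    diag = FitDiagnostics(rhat, ess, chains, draws, warmup, seed)
    if not diag.converged:
        warnings.warn(
            f"{spec.endpoint.value} fit shows incomplete mixing: "
            f"rhat={ {k: round(v, 3) for k, v in rhat.items()} }, "
            f"ess={ {k: round(v) for k, v in ess.items()} }; "
            "increase draws/warmup before trusting the posterior",
            UserWarning,
            stacklevel=2,
        )

    return HierarchicalFit(
        endpoint=spec.endpoint,
        net_ids=tuple(net.net_id for net in nets),
        alpha=post["alpha"],
        sigma_net=post["sigma_net"],
        sigma_side=post["sigma_side"],
        q=post["q"],
        diagnostics=diag,
        spec=spec,
    )


@dataclass(frozen=True)
class NetPosterior:
    """Posterior summaries and failure probabilities for one net."""

    net_id: str
    q_mean: float  # mortality
    p_mean: float  # knock-down
    q_ci95: tuple[float, float]
    p_ci95: tuple[float, float]
    fail_mortality: float  # Pr(q_i < mortality cutoff)
    fail_kd: float  # Pr(p_i < kd cutoff)
    fail_mixed: float  # Pr(both below their cutoffs)

    def validity_probability(self, kind: OutcomeKind) -> float:
        if kind is OutcomeKind.MORTALITY:
            return 1.0 - self.fail_mortality
        if kind is OutcomeKind.KD:
            return 1.0 - self.fail_kd
        return 1.0 - self.fail_mixed


def net_failure_probabilities(
    mortality_fit: HierarchicalFit,
    kd_fit: HierarchicalFit,
    outcome: ValidityOutcome | None = None,
) -> list[NetPosterior]:
    """Per-net failure probabilities from the two endpoint fits.

    The joint (mixed-rule) failure probability pairs mortality and
    knock-down draws by index, so run both fits with identical chain/draw
    settings; each probability is the fraction of draws satisfying its
    inequality.
    """
    if mortality_fit.endpoint is not OutcomeKind.MORTALITY:
        raise ValueError("mortality_fit must be a MORTALITY fit")
    if kd_fit.endpoint is not OutcomeKind.KD:
        raise ValueError("kd_fit must be a KD fit")
    if mortality_fit.net_ids != kd_fit.net_ids:
        raise ValueError("fits cover different net sets")
    qd = mortality_fit.q_flat
    pdr = kd_fit.q_flat
    if qd.shape != pdr.shape:
        raise ValueError("fits must use identical chain/draw settings for pairing")

    outcome = outcome or ValidityOutcome(OutcomeKind.MIXED)
    below_q = qd < outcome.mortality_cutoff
    below_p = pdr < outcome.kd_cutoff
    fail_m = below_q.mean(axis=0)
    fail_k = below_p.mean(axis=0)
    fail_mx = (below_q & below_p).mean(axis=0)

    q_lo, q_hi = np.percentile(qd, [2.5, 97.5], axis=0)
    p_lo, p_hi = np.percentile(pdr, [2.5, 97.5], axis=0)
    return [
        NetPosterior(
            net_id=nid,
            q_mean=float(qd[:, i].mean()),
            p_mean=float(pdr[:, i].mean()),
            q_ci95=(float(q_lo[i]), float(q_hi[i])),
            p_ci95=(float(p_lo[i]), float(p_hi[i])),
            fail_mortality=float(fail_m[i]),
            fail_kd=float(fail_k[i]),
            fail_mixed=float(fail_mx[i]),
        )
        for i, nid in enumerate(mortality_fit.net_ids)
    ]


@dataclass(frozen=True)
class Reference:
    """Reference classification of a cohort under one validity rule.

    ``flags`` is the binary reference (validity probability >= threshold,
    inclusive); ``probs`` the per-net validity probabilities.  The cohort's
    *expected* proportion valid is the mean of the probabilities, which need
    not equal the mean of the binary flags — both are reported.
    """

    outcome: OutcomeKind
    net_ids: tuple[str, ...]
    flags: np.ndarray
    probs: np.ndarray
    probability_threshold: float = 0.5

    @property
    def expected_proportion(self) -> float:
        return float(self.probs.mean())

    @property
    def binary_proportion(self) -> float:
        return float(self.flags.mean())


def reference_classification(
    posteriors: Sequence[NetPosterior],
    outcome: ValidityOutcome | OutcomeKind,
    probability_threshold: float = 0.5,
) -> Reference:
    """Binary reference validity and expected proportion valid for a cohort."""
    kind = outcome.kind if isinstance(outcome, ValidityOutcome) else outcome
    probs = np.array([p.validity_probability(kind) for p in posteriors])
    flags = probs >= probability_threshold
    return Reference(
        outcome=kind,
        net_ids=tuple(p.net_id for p in posteriors),
        flags=flags,
        probs=probs,
        probability_threshold=probability_threshold,
    )


def empirical_reference(
    nets: Sequence[NetAssay], outcome: ValidityOutcome
) -> Reference:
    """Reference built from the full 4-cone empirical classification.

    Validity probabilities are the 0/1 flags themselves; used for
    self-consistency checks of the resampling engine, where the k=4 scenario
    must then agree with its own reference exactly.
    """
    from .assay import ConeSelection, classify_net

    full = ConeSelection.full()
    flags = np.array([classify_net(net, full, outcome) for net in nets])
    return Reference(
        outcome=outcome.kind,
        net_ids=tuple(net.net_id for net in nets),
        flags=flags,
        probs=flags.astype(float),
    )


def posteriors_to_frame(posteriors: Sequence[NetPosterior]) -> pd.DataFrame:
    """Posterior summaries as a tidy table (CSV-ready)."""
    return pd.DataFrame(
        {
            "net_id": [p.net_id for p in posteriors],
            "q_mean": [p.q_mean for p in posteriors],
            "q_ci95_low": [p.q_ci95[0] for p in posteriors],
            "q_ci95_high": [p.q_ci95[1] for p in posteriors],
            "p_mean": [p.p_mean for p in posteriors],
            "p_ci95_low": [p.p_ci95[0] for p in posteriors],
            "p_ci95_high": [p.p_ci95[1] for p in posteriors],
            "fail_mortality": [p.fail_mortality for p in posteriors],
            "fail_kd": [p.fail_kd for p in posteriors],
            "fail_mixed": [p.fail_mixed for p in posteriors],
        }
    )
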