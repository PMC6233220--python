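"""Resampling evaluation of reduced-effort cone-bioassay protocols.

A *scenario* is a validity rule (mortality, knock-down, or the WHOPES mixed
rule) combined with a number of cones read per side (1-4) and a number of
nets sampled per survey (20-160).  Each iteration draws a subsample of nets
without replacement, draws one random cone selection per net (uniform over
the C(4,k)^5 per-net combinations), classifies the nets from the selected
cones only, and scores the classification against the Bayesian reference of
the *same* sampled nets: sensitivity (probability of passing a valid net),
specificity (probability of failing an invalid net), accuracy, and the
error in the survey's headline indicator — observed proportion valid minus
the reference's expected proportion valid, in percentage points.

Aggregation over iterations yields the mean of each metric and percentile
intervals of the indicator error; the minimum sample size of a protocol is
the smallest grid size from which the 95% interval stays within +/-5 pp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import (
    N_CONES,
    N_SIDES,
    SIDES,
    ConeSelection,
    NetAssay,
    OutcomeKind,
    ValidityOutcome,
)
from .hierarchy import Reference

__all__ = [
    "ScenarioSpec",
    "IterationMetrics",
    "ScenarioSummary",
    "CohortData",
    "count_cone_combinations",
    "sample_cone_selection",
    "iteration_metrics",
    "run_scenario",
    "minimum_sample_size",
    "scenario_grid",
    "DEFAULT_N_GRID",
]

DEFAULT_N_GRID: tuple[int, ...] = tuple(range(20, 161, 20))


def count_cone_combinations(k_cones: int) -> tuple[int, int]:
    """(per-side, per-net) counts of k-of-4 cone choices across 5 sides."""
    if not 1 <= k_cones <= N_CONES:
        raise ValueError(f"k_cones must be in 1..{N_CONES}")
    per_side = math.comb(N_CONES, k_cones)
    return per_side, per_side**N_SIDES


def sample_cone_selection(k_cones: int, rng: np.random.Generator) -> ConeSelection:
    """One cone selection, uniform over the C(4,k)^5 per-net combinations."""
    if not 1 <= k_cones <= N_CONES:
        raise ValueError(f"k_cones must be in 1..{N_CONES}")
    by_side = {
        side: tuple(
            int(i) + 1
            for i in rng.choice(N_CONES, size=k_cones, replace=False)
        )
        for side in SIDES
    }
    return ConeSelection(by_side)


@dataclass(frozen=True)
class IterationMetrics:
    """Performance of one resampled survey against its reference.

    ``sensitivity``/``specificity`` are ``None`` when their stratum is empty
    (no valid, resp. no invalid, net in the sample) — degenerate, not zero.
    """

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    diff_pp: float


def iteration_metrics(
    z: Sequence[bool] | np.ndarray,
    y: Sequence[bool] | np.ndarray,
    r: Sequence[float] | np.ndarray,
) -> IterationMetrics:
    """Score empirical flags ``z`` against reference flags ``y`` and
    reference validity probabilities ``r`` for one sampled survey."""
    z = np.asarray(z, dtype=bool)
    y = np.asarray(y, dtype=bool)
    r = np.asarray(r, dtype=float)
    if not (len(z) == len(y) == len(r)) or len(z) == 0:
        raise ValueError("z, y, r must be non-empty vectors of equal length")
    n_valid = int(y.sum())
    n_invalid = len(y) - n_valid
    sens = float((z & y).sum() / n_valid) if n_valid else None
    spec = float((~z & ~y).sum() / n_invalid) if n_invalid else None
    return IterationMetrics(
        accuracy=float((z == y).mean()),
        sensitivity=sens,
        specificity=spec,
        diff_pp=float(100.0 * (z.mean() - r.mean())),
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """One evaluation scenario."""

    outcome: ValidityOutcome
    k_cones: int
    n_nets: int
    n_iterations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.k_cones <= N_CONES:
            raise ValueError(f"k_cones must be in 1..{N_CONES}")
        if self.n_nets < 1 or self.n_iterations < 1:
            raise ValueError("n_nets and n_iterations must be positive")


@dataclass(frozen=True)
class ScenarioSummary:
    """Aggregated metrics for one scenario.

    Means ignore iterations whose stratum was empty; those counts are
    reported.  Intervals are equal-tailed percentile intervals of the
    indicator error across iterations.
    """

    spec: ScenarioSpec
    mean_accuracy: float
    mean_sensitivity: float | None
    mean_specificity: float | None
    mean_diff_pp: float
    mean_abs_diff_pp: float
    ci95_diff_pp: tuple[float, float]
    ci99_diff_pp: tuple[float, float]
    n_undefined_sensitivity: int
    n_undefined_specificity: int


@dataclass(frozen=True)
class CohortData:
    """Cohort counts as dense arrays: (n_nets, 5 sides, 4 cones)."""

    net_ids: tuple[str, ...]
    dead: np.ndarray
    kd: np.ndarray
    exposed: np.ndarray

    @classmethod
    def from_nets(cls, nets: Sequence[NetAssay]) -> "CohortData":
        n = len(nets)
        dead = np.zeros((n, N_SIDES, N_CONES), dtype=np.int64)
        kd = np.zeros_like(dead)
        exposed = np.zeros_like(dead)
        for i, net in enumerate(nets):
            for s, side in enumerate(SIDES):
                for c in range(N_CONES):
                    rec = net.record(side, c + 1)
                    dead[i, s, c] = rec.n_dead_24
                    kd[i, s, c] = rec.n_kd_60
                    exposed[i, s, c] = rec.n_exposed
        return cls(tuple(net.net_id for net in nets), dead, kd, exposed)

    def __len__(self) -> int:
        return len(self.net_ids)


def _as_cohort(cohort: CohortData | Sequence[NetAssay]) -> CohortData:
    return cohort if isinstance(cohort, CohortData) else CohortData.from_nets(cohort)


def _classify_rates(mort, kd, outcome: ValidityOutcome) -> np.ndarray:
    pm = mort >= outcome.mortality_cutoff
    pk = kd >= outcome.kd_cutoff
    if outcome.kind is OutcomeKind.MORTALITY:
        return pm
    if outcome.kind is OutcomeKind.KD:
        return pk
    return pm | pk


def run_scenario(
    cohort: CohortData | Sequence[NetAssay],
    reference: Reference,
    spec: ScenarioSpec,
    *,
    chunk_size: int = 2000,
) -> ScenarioSummary:
    """Monte-Carlo evaluation of one scenario.

    Vectorized over iterations in chunks; a fixed ``spec.seed`` makes the
    whole run bit-reproducible.  Net subsets are uniform without
    replacement; cone subsets are uniform per (net, side) and independent
    across sides, one selection per net per iteration.
    """
    data = _as_cohort(cohort)
    n_cohort = len(data)
    if tuple(reference.net_ids) != data.net_ids:
        raise ValueError("reference and cohort cover different net sets")
    if spec.n_nets > n_cohort:
        raise ValueError(f"n_nets={spec.n_nets} exceeds cohort size {n_cohort}")

    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_nets, spec.k_cones
    iters = spec.n_iterations

    acc = np.empty(iters)
    sens = np.full(iters, np.nan)
    specf = np.full(iters, np.nan)
    diff = np.empty(iters)

    ref_flags = np.asarray(reference.flags, dtype=bool)
    ref_probs = np.asarray(reference.probs, dtype=float)

    done = 0
    while done < iters:
        c = min(chunk_size, iters - done)
        # uniform n-subsets of the cohort: the n smallest of c x N uniforms
        if n < n_cohort:
            u = rng.random((c, n_cohort))
            idx = np.argpartition(u, n - 1, axis=1)[:, :n]
        else:
            idx = np.broadcast_to(np.arange(n_cohort), (c, n_cohort))
        # uniform k-subsets of the 4 cones per (iteration, net, side)
        if k < N_CONES:
            w = rng.random((c, n, N_SIDES, N_CONES))
            kth = np.partition(w, k - 1, axis=-1)[..., k - 1 : k]
            sel = w <= kth
        else:
            sel = np.ones((c, n, N_SIDES, N_CONES), dtype=bool)

        dead = (data.dead[idx] * sel).sum(axis=(2, 3))
        kdc = (data.kd[idx] * sel).sum(axis=(2, 3))
        expo = (data.exposed[idx] * sel).sum(axis=(2, 3))
        mort_rate = dead / expo
        kd_rate = kdc / expo
        z = _classify_rates(mort_rate, kd_rate, spec.outcome)

        y = ref_flags[idx]
        r = ref_probs[idx]
        sl = slice(done, done + c)
        acc[sl] = (z == y).mean(axis=1)
        n1 = y.sum(axis=1)
        n0 = n - n1
        with np.errstate(invalid="ignore", divide="ignore"):
            sens[sl] = np.where(n1 > 0, (z & y).sum(axis=1) / np.maximum(n1, 1), np.nan)
            specf[sl] = np.where(
                n0 > 0, (~z & ~y).sum(axis=1) / np.maximum(n0, 1), np.nan
            )
        diff[sl] = 100.0 * (z.mean(axis=1) - r.mean(axis=1))
        done += c

    und_sens = int(np.isnan(sens).sum())
    und_spec = int(np.isnan(specf).sum())
    ci95 = tuple(float(x) for x in np.percentile(diff, [2.5, 97.5]))
    ci99 = tuple(float(x) for x in np.percentile(diff, [0.5, 99.5]))
    return ScenarioSummary(
        spec=spec,
        mean_accuracy=float(acc.mean()),
        mean_sensitivity=float(np.nanmean(sens)) if und_sens < iters else None,
        mean_specificity=float(np.nanmean(specf)) if und_spec < iters else None,
        mean_diff_pp=float(diff.mean()),
        mean_abs_diff_pp=float(np.abs(diff).mean()),
        ci95_diff_pp=ci95,  # type: ignore[arg-type]
        ci99_diff_pp=ci99,  # type: ignore[arg-type]
        n_undefined_sensitivity=und_sens,
        n_undefined_specificity=und_spec,
    )


def minimum_sample_size(
    summaries: Sequence[ScenarioSummary],
    precision_pp: float = 5.0,
) -> str:
    """Smallest grid sample size from which the 95% CI of the indicator
    error stays within +/- ``precision_pp``, at that size and all larger
    grid sizes.

    Returns ``"<=N_min"`` when the smallest grid size already qualifies and
    ``">N_max"`` when none does, mirroring how such tables are reported.
    """
    if not summaries:
        raise ValueError("no summaries supplied")
    by_n = sorted(summaries, key=lambda s: s.spec.n_nets)
    ns = [s.spec.n_nets for s in by_n]
    if len(set(ns)) != len(ns):
        raise ValueError("duplicate sample sizes in grid")
    ok = [
        s.ci95_diff_pp[0] >= -precision_pp and s.ci95_diff_pp[1] <= precision_pp
        for s in by_n
    ]
    # smallest n such that containment holds there and at every larger n
    winner: int | None = None
    for i in range(len(ns)):
        if all(ok[i:]):
            winner = ns[i]
            break
    if winner is None:
        return f">{ns[-1]}"
    if winner == ns[0]:
        return f"<={ns[0]}"
    return str(winner)


def scenario_grid(
    cohort: CohortData | Sequence[NetAssay],
    references: Mapping[OutcomeKind, Reference],
    *,
    outcomes: Sequence[ValidityOutcome],
    k_cones: Sequence[int] = (1, 2, 3, 4),
    n_grid: Sequence[int] = DEFAULT_N_GRID,
    n_iterations: int = 10_000,
    seed: int = 0,
    precision_pp: float = 5.0,
) -> tuple[pd.DataFrame, dict[tuple[str, int], str]]:
    """Run the full scenario grid; one row per (outcome, k_cones, n_nets).

    Each cell gets its own deterministic substream of ``seed``.  Returns the
    tidy results table and the minimum sample size per (outcome, k_cones).
    """
    data = _as_cohort(cohort)
    rows = []
    min_samples: dict[tuple[str, int], str] = {}
    cell = 0
    for outcome in outcomes:
        ref = references[outcome.kind]
        for k in k_cones:
            cell_summaries = []
            for n in n_grid:
                # deterministic per-cell seed derived from the master seed
                cell_seed = int(
                    np.random.SeedSequence([seed, cell]).generate_state(1)[0] % (2**31)
                )
                cell += 1
                spec = ScenarioSpec(
                    outcome=outcome,
                    k_cones=k,
                    n_nets=n,
                    n_iterations=n_iterations,
                    seed=cell_seed,
                )
                summ = run_scenario(data, ref, spec)
                cell_summaries.append(summ)
                rows.append(
                    {
                        "outcome": outcome.kind.value,
                        "k_cones": k,
                        "n_nets": n,
                        "mean_accuracy": summ.mean_accuracy,
                        "mean_sensitivity": summ.mean_sensitivity,
                        "mean_specificity": summ.mean_specificity,
                        "mean_diff_pp": summ.mean_diff_pp,
                        "mean_abs_diff_pp": summ.mean_abs_diff_pp,
                        "ci95_low_pp": summ.ci95_diff_pp[0],
                        "ci95_high_pp": summ.ci95_diff_pp[1],
                        "ci99_low_pp": summ.ci99_diff_pp[0],
                        "ci99_high_pp": summ.ci99_diff_pp[1],
                        "n_undefined_sensitivity": summ.n_undefined_sensitivity,
                        "n_undefined_specificity": summ.n_undefined_specificity,
                        "n_iterations": n_iterations,
                    }
                )
            min_samples[(outcome.kind.value, k)] = minimum_sample_size(
                cell_summaries, precision_pp
            )
    return pd.DataFrame(rows), min_samples
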