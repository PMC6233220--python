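"""End-to-end orchestration: simulate -> fit -> evaluate -> report.

A :class:`RunConfig` (loadable from YAML) drives the full analysis.  The
master seed is split into named per-stage substreams, so each stochastic
stage (cohort simulation, the two endpoint fits, the resampling grid) is
independently reproducible; rerunning an identical config reproduces every
artifact byte for byte.  A manifest records the config hash, the stage
seeds and every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .assay import (
    KD,
    MIXED,
    MORTALITY,
    ConeSelection,
    NetAssay,
    OutcomeKind,
    ValidityOutcome,
    classify_net,
    read_dataset,
    write_dataset,
)
from .danger import danger_zone_table
from .hierarchy import (
    ModelSpec,
    NetPosterior,
    Reference,
    fit_hierarchical,
    net_failure_probabilities,
    posteriors_to_frame,
    reference_classification,
)
from .scenarios import DEFAULT_N_GRID, scenario_grid
from .simulate import CohortParams, simulate_cohort, write_latent_truth

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "render_report",
    "load_posteriors_csv",
    "plot_scenario_metrics",
]

log = logging.getLogger("conebio")

_OUTCOME_BY_NAME = {"mortality": MORTALITY, "kd": KD, "mixed": MIXED}

# fixed stage indices so seed derivation is stable across versions
_STAGE_IDS = {"simulate": 0, "fit_mortality": 1, "fit_kd": 2, "scenarios": 3}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    ss = np.random.SeedSequence([master_seed, _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class RunConfig:
    """Full-run configuration.

    ``cohort_csv`` switches between analysing an existing dataset and
    simulating a synthetic cohort with ``cohort`` parameter overrides.
    """

    output_dir: str = "results"
    seed: int = 0
    cohort_csv: str | None = None
    cohort: Mapping[str, Any] = field(default_factory=dict)
    mortality_cutoff: float = 0.80
    kd_cutoff: float = 0.95
    risk_threshold: float = 0.10
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    outcomes: Sequence[str] = ("mortality", "kd", "mixed")
    k_cones: Sequence[int] = (1, 2, 3, 4)
    n_grid: Sequence[int] = DEFAULT_N_GRID
    n_iterations: int = 10_000
    precision_pp: float = 5.0
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["outcomes"] = list(self.outcomes)
        d["k_cones"] = list(self.k_cones)
        d["n_grid"] = list(self.n_grid)
        d["cohort"] = dict(self.cohort)
        return d

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("simulate")
def _stage_simulate(config: RunConfig, outdir: Path) -> list[NetAssay]:
    params = CohortParams(**{"seed": stage_seed(config.seed, "simulate"), **dict(config.cohort)})
    nets, latent = simulate_cohort(params)
    write_dataset(nets, outdir / "cohort.csv")
    write_latent_truth(latent, outdir / "latent_truth.csv")
    return nets

@_stage("load")
def _stage_load(config: RunConfig) -> list[NetAssay]:
    path = Path(config.cohort_csv)  # type: ignore[arg-type]
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    return read_dataset(path)


@_stage("danger_zone")
def _stage_danger(config: RunConfig, outdir: Path) -> pd.DataFrame:
    table = danger_zone_table(
        config.mortality_cutoff, config.kd_cutoff, config.risk_threshold
    )
    table.to_csv(outdir / "danger_zones.csv", index=False)
    return table


@_stage("fit")
def _stage_fit(config: RunConfig, nets: Sequence[NetAssay], outdir: Path):
    fits = {}
    for kind, stage in (
        (OutcomeKind.MORTALITY, "fit_mortality"),
        (OutcomeKind.KD, "fit_kd"),
    ):
        fits[kind] = fit_hierarchical(
            nets,
            ModelSpec(endpoint=kind),
            chains=config.chains,
            draws=config.draws,
            warmup=config.warmup,
            seed=stage_seed(config.seed, stage),
        )
    outcome = ValidityOutcome(
        OutcomeKind.MIXED, config.mortality_cutoff, config.kd_cutoff
    )
    posteriors = net_failure_probabilities(
        fits[OutcomeKind.MORTALITY], fits[OutcomeKind.KD], outcome
    )
    posteriors_to_frame(posteriors).to_csv(outdir / "posteriors.csv", index=False)
    meta = {
        "seed": config.seed,
        "chains": config.chains,
        "draws": config.draws,
        "warmup": config.warmup,
        "diagnostics": {
            kind.value: {
                "rhat": dict(fit.diagnostics.rhat),
                "ess_bulk": dict(fit.diagnostics.ess_bulk),
                "converged": fit.diagnostics.converged,
            }
            for kind, fit in fits.items()
        },
    }
    (outdir / "fit_meta.json").write_text(json.dumps(meta, indent=2))
    return posteriors


@_stage("evaluate")
def _stage_evaluate(
    config: RunConfig,
    nets: Sequence[NetAssay],
    posteriors: Sequence[NetPosterior],
    outdir: Path,
):
    outcomes = [_make_outcome(name, config) for name in config.outcomes]
    references = {
        o.kind: reference_classification(posteriors, o) for o in outcomes
    }
    table, min_samples = scenario_grid(
        nets,
        references,
        outcomes=outcomes,
        k_cones=tuple(config.k_cones),
        n_grid=tuple(config.n_grid),
        n_iterations=config.n_iterations,
        seed=stage_seed(config.seed, "scenarios"),
        precision_pp=config.precision_pp,
    )
    table.to_csv(outdir / "scenarios.csv", index=False)
    summary = {
        "min_sample_size": {f"{o}|{k}": v for (o, k), v in min_samples.items()},
        "reference_expected_proportion": {
            o.kind.value: references[o.kind].expected_proportion for o in outcomes
        },
        "reference_binary_proportion": {
            o.kind.value: references[o.kind].binary_proportion for o in outcomes
        },
    }
    (outdir / "scenario_summary.json").write_text(json.dumps(summary, indent=2))
    return table, min_samples, references


def _make_outcome(name: str, config: RunConfig) -> ValidityOutcome:
    base = _OUTCOME_BY_NAME[name]
    return ValidityOutcome(base.kind, config.mortality_cutoff, config.kd_cutoff)


def _observed_proportions(nets: Sequence[NetAssay], config: RunConfig) -> dict[str, float]:
    full = ConeSelection.full()
    out = {}
    for name in ("mortality", "kd", "mixed"):
        outcome = _make_outcome(name, config)
        out[name] = float(
            np.mean([classify_net(net, full, outcome) for net in nets])
        )
    return out


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis; returns a results bundle.

    Writes all artifacts under ``config.output_dir`` and a ``manifest.json``
    carrying the config hash, per-stage seeds and the file list.  A failing
    stage aborts with :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.output_dir)
    if config.cohort_csv is not None and not Path(config.cohort_csv).exists():
        raise PipelineError(f"cohort file not found: {config.cohort_csv}")
    outdir.mkdir(parents=True, exist_ok=True)

    danger = _stage_danger(config, outdir)
    if config.cohort_csv is None:
        nets = _stage_simulate(config, outdir)
    else:
        nets = _stage_load(config)
    posteriors = _stage_fit(config, nets, outdir)
    table, min_samples, references = _stage_evaluate(config, nets, posteriors, outdir)

    results: dict[str, Any] = {
        "config": config,
        "config_hash": config.config_hash,
        "danger_table": danger,
        "n_nets": len(nets),
        "observed_proportions": _observed_proportions(nets, config),
        "scenario_table": table,
        "min_samples": min_samples,
        "references": references,
    }

    report = render_report(results)
    (outdir / "report.md").write_text(report)

    if config.make_plots:
        for name in config.outcomes:
            plot_scenario_metrics(
                table, name, outdir / f"scenarios_{name}.png"
            )

    manifest = {
        "config_hash": config.config_hash,
        "config": config.to_dict(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_IDS},
        "files": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["output_dir"] = str(outdir)
    return results


def render_report(results: Mapping[str, Any]) -> str:
    """Human-readable markdown summary of whatever results are present."""
    lines: list[str] = ["# Cone-bioassay analysis report", ""]
    if "config_hash" in results:
        lines += [f"Config hash: `{results['config_hash']}`", ""]

    danger = results.get("danger_table")
    if danger is not None and len(danger):
        lines += ["## Misclassification danger zones", ""]
        lines.append('```\n' + danger.to_string(index=False) + '\n```')
        lines.append("")

    if "observed_proportions" in results:
        obs = results["observed_proportions"]
        lines += [
            "## Cohort",
            "",
            f"{results.get('n_nets', '?')} nets; observed proportion valid "
            f"(4 cones): mortality {obs['mortality']:.1%}, KD {obs['kd']:.1%}, "
            f"mixed {obs['mixed']:.1%}",
            "",
        ]

    refs = results.get("references")
    if refs:
        lines += ["## Bayesian reference", ""]
        for kind, ref in refs.items():
            lines.append(
                f"- {kind.value}: expected proportion valid "
                f"{ref.expected_proportion:.1%} (binary {ref.binary_proportion:.1%})"
            )
        lines.append("")

    table = results.get("scenario_table")
    if table is None or not len(table):
        lines += ["## Scenarios", "", "No scenarios evaluated.", ""]
    else:
        lines += ["## Scenario performance (means over the sample-size grid)", ""]
        agg = (
            table.groupby(["outcome", "k_cones"], sort=True)
            .agg(
                accuracy=("mean_accuracy", "mean"),
                sensitivity=("mean_sensitivity", "mean"),
                specificity=("mean_specificity", "mean"),
                mean_diff_pp=("mean_diff_pp", "mean"),
            )
            .reset_index()
        )
        min_samples = results.get("min_samples", {})
        agg["min_sample"] = [
            min_samples.get((o, k), "n/a")
            for o, k in zip(agg["outcome"], agg["k_cones"])
        ]
        lines.append('```\n' + agg.to_string(index=False) + '\n```')
        lines.append("")
    return "\n".join(lines)


def load_posteriors_csv(path: str | Path) -> list[NetPosterior]:
    """Rebuild :class:`NetPosterior` objects from an exported summary CSV."""
    df = pd.read_csv(path)
    return [
        NetPosterior(
            net_id=str(r.net_id),
            q_mean=float(r.q_mean),
            p_mean=float(r.p_mean),
            q_ci95=(float(r.q_ci95_low), float(r.q_ci95_high)),
            p_ci95=(float(r.p_ci95_low), float(r.p_ci95_high)),
            fail_mortality=float(r.fail_mortality),
            fail_kd=float(r.fail_kd),
            fail_mixed=float(r.fail_mixed),
        )
        for r in df.itertuples(index=False)
    ]


def plot_scenario_metrics(
    table: pd.DataFrame, outcome: str, path: str | Path
) -> None:
    """Four-panel figure: accuracy, sensitivity, specificity and the error
    interval of the proportion-valid indicator versus sample size, one line
    per cone count."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table[table["outcome"] == outcome]
    if not len(sub):
        raise ValueError(f"no rows for outcome {outcome!r}")
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    panels = [
        ("mean_accuracy", "Accuracy"),
        ("mean_sensitivity", "Sensitivity"),
        ("mean_specificity", "Specificity"),
    ]
    for ax, (col, title) in zip(axes.ravel()[:3], panels):
        for k, grp in sub.groupby("k_cones"):
            ax.plot(grp["n_nets"], grp[col], marker="o", label=f"{k} cones")
        ax.set_title(title)
        ax.set_ylim(0, 1.02)
    ax = axes[1, 1]
    for k, grp in sub.groupby("k_cones"):
        ax.plot(grp["n_nets"], grp["mean_diff_pp"], marker="o", label=f"{k} cones")
        ax.fill_between(
            grp["n_nets"], grp["ci95_low_pp"], grp["ci95_high_pp"], alpha=0.15
        )
    ax.axhline(0, color="k", lw=0.5)
    ax.set_title("Observed - reference proportion valid (pp)")
    for ax in axes[1]:
        ax.set_xlabel("nets sampled")
    axes[0, 0].legend(fontsize=8)
    fig.suptitle(f"Scenario performance - {outcome}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
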