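"""End-to-end pipeline: prep -> dfnc -> states -> metrics -> stats.

A run directory accumulates one subdirectory per stage plus a machine-readable
``run_log.json`` (stage timings, seeds, window counts, exclusion counts).
Re-running with ``resume=True`` regenerates only stages whose outputs are
missing.  All randomness flows from the single config seed; stage-local seeds
are derived by fixed offsets.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as dio
from .clustering import fit_states
from .inference import DEFAULT_COVARIATES, run_group_analysis, subject_state_connectivity
from .metrics import compute_temporal_metrics
from .prep import PrepConfig, prep_cohort
from .synthetic import CohortConfig, simulate_cohort
from .windows import SparsityConfig, TaperSpec, compute_dfnc

STAGES = ("prep", "dfnc", "states", "metrics", "stats")
_SEED_STATES = 700_000


@dataclass
class RunConfig:
    input_dir: str = "cohort"
    output_dir: str = "run"
    seed: int = 0
    taper: TaperSpec = field(default_factory=TaperSpec)
    sparsity: SparsityConfig = field(default_factory=SparsityConfig)
    prep: PrepConfig = field(default_factory=PrepConfig)
    k: int | None = 2
    k_range: tuple[int, int] | None = None  # inclusive (lo, hi)
    q: float = 0.05
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    aggregation: str = "mean"
    discard_initial: int = 0

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, typ in (("taper", TaperSpec), ("sparsity", SparsityConfig), ("prep", PrepConfig)):
            if key in raw and isinstance(raw[key], dict):
                if key == "sparsity" and "grid" in raw[key]:
                    raw[key]["grid"] = tuple(raw[key]["grid"])
                raw[key] = typ(**raw[key])
        for key in ("covariates", "k_range"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: RunConfig, resume: bool = False) -> Path:
    """Execute all stages, writing artifacts and a run log; returns run dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": {}}
    log_path = out / "run_log.json"
    if resume and log_path.exists():
        log = json.loads(log_path.read_text())

    dirty = not resume

    def stage_done(name: str) -> bool:
        return (not dirty) and (out / name).exists() and name in log["stages"]

    def record(name: str, t0: float, **info):
        log["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}
        log_path.write_text(json.dumps(log, indent=1))

    current_stage = "read"
    try:
        cohort = dio.read_cohort(config.input_dir)

        # prep
        current_stage = "prep"
        t0 = time.time()
        if stage_done("prep"):
            prepped = dio.read_cohort(out / "prep")
        else:
            dirty = True
            prepped = prep_cohort(cohort, config.prep)
            dio.write_cohort(prepped, out / "prep")
            record("prep", t0, n_subjects=prepped.n_subjects)

        # dfnc
        current_stage = "dfnc"
        t0 = time.time()
        if stage_done("dfnc"):
            fnc = dio.read_fnc(out / "dfnc", cohort.partition)
        else:
            dirty = True
            fnc = compute_dfnc(
                prepped, config.taper, config.sparsity,
                discard_initial=config.discard_initial,
            )
            dio.write_fnc(fnc, out / "dfnc")
            record("dfnc", t0, n_windows=int(fnc.n_windows), n_pairs=int(fnc.n_pairs),
                   n_nonconverged=fnc.meta.get("n_nonconverged", 0))

        # states
        current_stage = "states"
        t0 = time.time()
        if stage_done("states"):
            model = dio.read_state_model(out / "states")
        else:
            dirty = True
            k_range = (
                range(config.k_range[0], config.k_range[1] + 1)
                if config.k_range is not None
                else None
            )
            model = fit_states(
                fnc, k=config.k, seed=config.seed + _SEED_STATES, k_range=k_range
            )
            dio.write_state_model(model, out / "states", fnc.pair_ids)
            record("states", t0, k=model.k, objective=model.objective)

        # metrics
        current_stage = "metrics"
        t0 = time.time()
        metrics = compute_temporal_metrics(
            model.labels, model.k, fnc.subject_ids, tr_seconds=cohort.tr_seconds
        )
        metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
        record("metrics", t0)

        # stats
        current_stage = "stats"
        t0 = time.time()
        profiles = subject_state_connectivity(fnc, model, config.aggregation)
        result = run_group_analysis(
            metrics, profiles, cohort.manifest, q=config.q,
            covariates=config.covariates, pair_ids=fnc.pair_ids,
        )
        stats_dir = out / "stats"
        stats_dir.mkdir(exist_ok=True)
        result.temporal.to_csv(stats_dir / "temporal.tsv", sep="\t", index=False)
        for k, tab in result.connectivity.items():
            tab.to_csv(stats_dir / f"connectivity_state{k}.tsv", sep="\t", index=False)
        result.clinical.to_csv(stats_dir / "clinical.tsv", sep="\t", index=False)
        summary = {
            "q": result.q,
            "exclusions": result.exclusions,
            "warnings": result.warnings_,
            "n_temporal_rejected": int(result.temporal["reject"].sum()),
            "n_connectivity_rejected": {
                k: int(tab["reject"].sum()) for k, tab in result.connectivity.items()
            },
        }
        (stats_dir / "summary.json").write_text(json.dumps(summary, indent=1))
        record("stats", t0, **{"exclusions": result.exclusions})
    except Exception as err:  # annotate the failing stage for the caller
        raise RuntimeError(f"pipeline failed at stage '{current_stage}': {err}") from err

    config.to_yaml(out / "config.yaml")
    return out


def simulate_to_dir(out_dir: Path, config: CohortConfig | None = None, seed: int = 0) -> Path:
    """Generate a synthetic cohort and write it in the cohort directory format."""
    cohort, truth = simulate_cohort(config, seed=seed)
    return dio.write_cohort(cohort, Path(out_dir), truth)


def report_text(run_dir: Path) -> str:
    """Plain-text summary of group statistics from a completed run."""
    run_dir = Path(run_dir)
    import pandas as pd

    lines = ["dFNC state analysis report", "=" * 30]
    tpath = run_dir / "stats" / "temporal.tsv"
    if tpath.exists():
        t = pd.read_csv(tpath, sep="\t")
        lines.append("\nTemporal dynamics (one-way ANOVA, BH-FDR):")
        for _, r in t.iterrows():
            lines.append(
                f"  {r['outcome']:<14} F({int(r['df1'])},{int(r['df2'])}) = "
                f"{r['F']:.3f}, p = {r['p']:.4f}, p_fdr = {r['p_fdr']:.4f}"
                f"{'  *' if r['reject'] else ''}"
            )
    for st in (1, 2, 3, 4):
        cpath = run_dir / "stats" / f"connectivity_state{st}.tsv"
        if cpath.exists():
            c = pd.read_csv(cpath, sep="\t")
            lines.append(
                f"\nState {st} connectivity: {int(c['reject'].sum())} of "
                f"{len(c)} pairs differ between groups (BH-FDR)"
            )
    cpath = run_dir / "stats" / "clinical.tsv"
    if cpath.exists():
        c = pd.read_csv(cpath, sep="\t")
        lines.append("\nClinical partial correlations (patient group):")
        for _, r in c.iterrows():
            lines.append(
                f"  {r['metric']:<14} x {r['scale']:<12} r = {r['r']:+.3f}, "
                f"p = {r['p']:.4f}, p_fdr = {r['p_fdr']:.4f}"
                f"{'  *' if r['reject'] else ''}"
            )
    return "\n".join(lines)
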