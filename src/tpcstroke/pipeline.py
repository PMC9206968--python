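"""End-to-end orchestration: simulate (or load) -> TPC -> GNN stratification.

A :class:`RunConfig` fully determines a run: a master seed fans out
deterministically (CRC32 of ``"<stage>:<master_seed>"``, modulo 2**31) to the
simulation, clustering and stratification stages, so a saved config
re-executes to identical outputs.  Every run directory contains the subtype
labels, one affected-fraction CSV per reportable subtype, the per-timepoint
accuracy table, and a JSON manifest recording every tunable plus the key
outputs (number of subtypes L, modularity, sizes, accuracies).
"""

from __future__ import annotations

import dataclasses
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortTensor, load_cohort, write_cohort
from .clustering import (
    DEFAULT_KAPPA,
    DEFAULT_RESTARTS,
    MIN_REPORT_SIZE,
    SubtypePartition,
    run_tpc,
)
from .gnn import StratifyConfig, stratification_analysis
from .simulate import SimConfig, generate_cohort

__all__ = ["RunConfig", "stage_seed", "run_full_pipeline", "render_profile_report"]


def stage_seed(stage: str, master_seed: int) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return zlib.crc32(f"{stage}:{master_seed}".encode()) % (2**31)


@dataclass
class RunConfig:
    """Serializable configuration for one full pipeline run."""

    master_seed: int = 42
    # input: either paths to an existing cohort, or simulation parameters
    scores_path: str | None = None
    meta_path: str | None = None
    n_patients: int = 300
    treatment_fraction: float = 0.5
    treatment_recovery_boost: float = 0.05
    noise_sd: float = 0.05
    # clustering
    kappa: float = DEFAULT_KAPPA
    threshold_mode: str = "fraction"
    n_restarts: int = DEFAULT_RESTARTS
    min_report_size: int = MIN_REPORT_SIZE
    # stratification
    epochs: int = 100
    hidden_units: int = 64
    learning_rate: float = 0.01
    split_fraction: float = 0.7
    replicates: int = 10
    feature_mode: str = "onehot"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name, fn, log, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise PipelineError(name, exc) from exc
    log.append({"stage": name, "wall_time_s": round(time.perf_counter() - t0, 3)})
    return result


def render_profile_report(
    partition: SubtypePartition,
    outdir: Path,
    item_ids: list[str],
    arm: np.ndarray | None = None,
) -> Path:
    """Write each reportable subtype profile as an item x timepoint CSV.

    Also writes ``subtype_summary.txt`` listing each reportable community's
    size and, when arm labels exist, its treated fraction.  Non-reportable
    communities appear in the labels file only.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = []
    for c in range(partition.n_communities):
        if not partition.reportable[c]:
            continue
        prof = partition.subtype_profiles[c]
        df = pd.DataFrame(
            prof, index=item_ids, columns=[f"t{t}" for t in range(prof.shape[1])]
        )
        df.index.name = "item"
        df.to_csv(outdir / f"subtype_{c}_profile.csv")
        line = f"subtype {c}: n={partition.sizes[c]}"
        if arm is not None:
            members = partition.labels == c
            line += f", treated_fraction={arm[members].mean():.3f}"
        lines.append(line)
    hidden = int((~partition.reportable).sum())
    if hidden:
        lines.append(
            f"{hidden} community(ies) below min_report_size="
            f"{partition.min_report_size} omitted from the report"
        )
    summary = outdir / "subtype_summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    return summary


def run_full_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the full pipeline and write all outputs to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    true_labels = None
    if config.scores_path is not None:
        if not Path(config.scores_path).exists():
            raise FileNotFoundError(f"cohort file not found: {config.scores_path}")
        cohort = _stage(
            "load", load_cohort, log, config.scores_path, config.meta_path
        )
    else:
        sim = SimConfig(
            n_patients=config.n_patients,
            treatment_fraction=config.treatment_fraction,
            treatment_recovery_boost=config.treatment_recovery_boost,
            noise_sd=config.noise_sd,
            seed=stage_seed("simulate", config.master_seed),
        )
        cohort, true_labels = _stage("simulate", generate_cohort, log, sim)
        write_cohort(cohort, outdir / "cohort.csv", outdir / "items.csv")
        pd.DataFrame(
            {"patient": cohort.patients, "archetype": true_labels}
        ).to_csv(outdir / "truth.csv", index=False)

    partition = _stage(
        "tpc",
        run_tpc,
        log,
        cohort,
        kappa=config.kappa,
        seed=stage_seed("tpc", config.master_seed),
        n_restarts=config.n_restarts,
        min_report_size=config.min_report_size,
        threshold_mode=config.threshold_mode,
    )
    pd.DataFrame(
        {
            "patient": cohort.patients,
            "community": partition.labels,
            "reportable": partition.reportable[partition.labels],
        }
    ).to_csv(outdir / "labels.csv", index=False)
    render_profile_report(
        partition, outdir, [it.item_id for it in cohort.items], cohort.arm
    )

    strat_cfg = StratifyConfig(
        split_fraction=config.split_fraction,
        epochs=config.epochs,
        hidden_units=config.hidden_units,
        learning_rate=config.learning_rate,
        replicates=config.replicates,
        seed=stage_seed("stratify", config.master_seed),
        feature_mode=config.feature_mode,
        kappa=config.kappa,
    )
    curve = _stage("stratify", stratification_analysis, log, cohort, partition, strat_cfg)
    pd.DataFrame(curve.to_rows()).to_csv(outdir / "accuracy.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {
            s: stage_seed(s, config.master_seed) for s in ("simulate", "tpc", "stratify")
        },
        "n_patients": cohort.n_patients,
        "n_items": cohort.n_items,
        "n_timepoints": cohort.n_timepoints,
        "n_communities": partition.n_communities,
        "n_reportable": partition.n_reportable,
        "modularity": partition.modularity,
        "community_sizes": partition.sizes.tolist(),
        "accuracy": {k: v.tolist() for k, v in curve.accuracy.items()},
        "stderr": {k: v.tolist() for k, v in curve.stderr.items()},
        "log": log,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir
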