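"""End-to-end orchestration: simulate → render → trace → classify → fit.

One :class:`PipelineConfig` (YAML-loadable, unknown keys rejected) reaches
every stage parameter. A single root seed fans out into named substreams for
the simulator, the renderer and the fit multistarts, so each stage is
independently reproducible and two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import yaml

from . import classification, kinetics, tracing
from .afm_synth import render_field
from .kinetic_model import (
    PopulationSnapshot,
    molecule_category,
    simulate_population,
    summarize,
)
from .params import ImageConfig, KineticParams

__all__ = [
    "PipelineConfig",
    "run_end_to_end",
    "track_cluster_movie",
    "stage_seed",
    "REPORT_VERSION",
]

REPORT_VERSION = 1

_STAGES = ("simulate", "synthesize", "trace", "fit")


def stage_seed(root_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage substream seed derived from the root seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([root_seed, _STAGES.index(stage), index])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    kinetic: KineticParams = field(default_factory=KineticParams)
    image: ImageConfig = field(default_factory=ImageConfig)
    n_molecules: int = 1000
    timepoints_s: List[float] = field(
        default_factory=lambda: [300.0, 600.0, 1200.0, 1800.0, 3600.0]
    )
    molecules_per_field: int = 12
    low_threshold_nm: float = 0.3
    min_area_px: int = 30
    filament_threshold_nm: Optional[float] = None
    tolerance_bp: float = 30.0
    linkage_cutoff_nm: float = 100.0
    fit_with_offset: bool = False
    seed: int = 7
    condition_label: str = "37C"
    render: bool = True   # False: classify simulator truth only (fast path)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "kinetic" in raw:
            raw["kinetic"] = KineticParams(**raw["kinetic"])
        if "image" in raw:
            raw["image"] = ImageConfig(**raw["image"])
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _chunk(seq: Sequence, size: int) -> List[Sequence]:
    return [seq[i: i + size] for i in range(0, len(seq), size)]


def track_cluster_movie(
    frames: np.ndarray,
    frame_times_s: Sequence[float],
    image_config: ImageConfig,
    linkage_cutoff_nm: float = 400.0,
    seed: int = 0,
):
    """Detect filament blobs in each movie frame, track the cluster, and fit
    its dispersion time constant.

    The default linkage cutoff (400 nm) is sized for a ~dozen-filament
    cluster followed over a few e-foldings: it must stay above the growing
    inter-filament spacing for the whole tracked window, otherwise the
    largest fragment's radius measures the cutoff instead of the dispersal.
    Blob pixel areas weight the radius of gyration so that filaments crowded
    into one blob keep their mass. Returns ``(ClusterSeries, DecayFit)``.
    """
    detections = [
        tracing.blob_centroids(f, image_config, return_weights=True)
        for f in frames
    ]
    series = kinetics.cluster_series(
        [d[0] for d in detections],
        frame_times_s,
        linkage_cutoff_nm=linkage_cutoff_nm,
        frame_weights=[d[1] for d in detections],
    )
    fit = kinetics.fit_cluster_decay(series, seed=seed)
    return series, fit


def _measure_snapshot(
    snapshot: PopulationSnapshot,
    cfg: PipelineConfig,
    seed: int,
) -> classification.StateCounts:
    """Render the snapshot as fields, trace them, and classify what was seen."""
    categories: List[str] = []
    joint_counts: List[int] = []
    n_imaged = 0
    chunks = _chunk(snapshot.molecules, cfg.molecules_per_field)
    for k, molecules in enumerate(chunks):
        sub = PopulationSnapshot(
            time_s=snapshot.time_s,
            molecules=list(molecules),
            free_filament_fraction=snapshot.free_filament_fraction,
            rng_seed=snapshot.rng_seed,
        )
        image, _truth = render_field(
            sub, cfg.image, seed=stage_seed(seed, "synthesize", k),
            params=cfg.kinetic,
        )
        traced = tracing.trace_field(
            image, cfg.image, cfg.low_threshold_nm, cfg.min_area_px,
            cfg.filament_threshold_nm,
            nominal_length_bp=cfg.kinetic.dsdna_length_bp,
        )
        n_imaged += len(traced)
        for t in traced:
            if not t.included:
                continue
            categories.append(
                classification.classify(t, cfg.kinetic, cfg.tolerance_bp)
            )
            joint_counts.append(t.n_filaments)
    return classification.count_states(
        categories, joint_counts, cfg.kinetic, snapshot.time_s,
        n_total_imaged=n_imaged, condition_label=cfg.condition_label,
    )


def run_end_to_end(
    config: PipelineConfig,
    outdir: Optional[Union[str, Path]] = None,
) -> Dict:
    """Full pipeline; returns (and optionally writes) a versioned report.

    Stages: kinetic simulation at the configured timepoints; optional
    rendering of every snapshot into synthetic fields followed by tracing and
    classification of what the measurement sees; time-course construction;
    exponential decay fit of the any-joint fraction from its peak onward.
    Any stage failure raises with the stage name attached.
    """
    report: Dict = {"report_version": REPORT_VERSION, "stages": {}}
    cfg = config

    def _run(stage: str, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        report["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
        return out

    sim_seed = stage_seed(cfg.seed, "simulate")
    snapshots = _run(
        "simulate",
        lambda: simulate_population(
            cfg.kinetic, cfg.n_molecules, cfg.timepoints_s, sim_seed
        ),
    )
    truth_counts = [summarize(s, cfg.kinetic, cfg.condition_label)
                    for s in snapshots]

    measured_counts = None
    if cfg.render:
        measured_counts = _run(
            "measure",
            lambda: [_measure_snapshot(s, cfg, cfg.seed) for s in snapshots],
        )

    counts = measured_counts if measured_counts is not None else truth_counts
    tc = kinetics.timecourse(counts)
    report["timepoints"] = [
        {
            "time_s": sc.timepoint_s,
            "n_included": sc.n_total_included,
            "n_any_joint": sc.n_with_synaptic + sc.n_post_singular,
            "n_post_singular": sc.n_post_singular,
            "n_bare": sc.n_bare,
            "frac_any_joint": round(sc.frac_any_joint, 6),
            "frac_post_singular": round(sc.frac_post_singular, 6),
            "mean_joints_per_engaged": round(sc.mean_joints_per_engaged, 4),
            "occupancy_fraction_mean": round(sc.occupancy_fraction_mean, 6),
        }
        for sc in counts
    ]
    if measured_counts is not None:
        report["simulator_truth"] = [
            {
                "time_s": sc.timepoint_s,
                "frac_any_joint": round(sc.frac_any_joint, 6),
                "frac_post_singular": round(sc.frac_post_singular, 6),
            }
            for sc in truth_counts
        ]

    # decay of the any-joint fraction from its peak (the resolution phase)
    t_arr, y_arr = tc.series("any_joint")
    peak = int(np.argmax(y_arr))
    fit_info = None
    if len(t_arr) - peak >= 3:
        fit = _run(
            "fit",
            lambda: kinetics.fit_decay(
                t_arr[peak:], y_arr[peak:],
                with_offset=cfg.fit_with_offset,
                seed=stage_seed(cfg.seed, "fit"),
            ),
        )
        fit_info = {
            "tau_s": round(fit.tau_s, 3),
            "amplitude": round(fit.amplitude, 6),
            "offset": round(fit.offset, 6),
            "residual_rms": round(fit.residual_rms, 6),
            "n_points": fit.n_points,
            "from_time_s": float(t_arr[peak]),
        }
    report["any_joint_decay_fit"] = fit_info
    report["seeds"] = {
        "root": cfg.seed,
        "simulate": sim_seed,
        "fit": stage_seed(cfg.seed, "fit"),
    }
    report["condition_label"] = cfg.condition_label
    report["n_molecules"] = cfg.n_molecules

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import write_state_counts_csv, write_timecourse_csv

        write_state_counts_csv(counts, outdir / "state_counts.csv")
        write_timecourse_csv(tc, outdir / "timecourse.csv")
        (outdir / "report.yaml").write_text(
            yaml.safe_dump(report, sort_keys=True)
        )
    return report
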