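"""Round-trip file I/O: TSV/CSV tables, float TIFF height maps, YAML reports.

Images are single-channel float32 TIFFs in nm; movies are multi-page TIFFs.
Tables go through pandas. Every writer here has a matching reader that
recovers the written fields losslessly.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .classification import StateCounts
from .kinetic_model import BoundFilament, PopulationSnapshot, POST, SYN
from .kinetics import DecayFit, TimeCourse
from .tracing import TracedMolecule

__all__ = [
    "write_snapshots_tsv",
    "read_snapshots_tsv",
    "write_molecule_table",
    "read_molecule_table",
    "write_state_counts_csv",
    "read_state_counts_csv",
    "write_timecourse_csv",
    "write_decay_yaml",
    "read_decay_yaml",
    "save_height_map",
    "load_height_map",
    "save_movie",
    "load_movie",
]

PathLike = Union[str, Path]

_STATE_CODE = {SYN: "syn", POST: "post"}
_CODE_STATE = {v: k for k, v in _STATE_CODE.items()}


def _encode_joints(joints: Sequence[BoundFilament]) -> str:
    return ";".join(
        f"{j.position_bp}:{_STATE_CODE[j.state]}:{j.bound_since_s!r}"
        for j in joints
    )


def _decode_joints(s: str) -> List[BoundFilament]:
    if not s or s != s:  # empty or NaN
        return []
    out = []
    for item in str(s).split(";"):
        pos, code, since = item.split(":")
        out.append(BoundFilament(int(pos), _CODE_STATE[code], float(since)))
    return out


def write_snapshots_tsv(snapshots: Sequence[PopulationSnapshot],
                        path: PathLike) -> None:
    rows = []
    for snap in snapshots:
        for mid, joints in enumerate(snap.molecules):
            rows.append(
                {
                    "molecule_id": mid,
                    "time_s": snap.time_s,
                    "n_synaptic": sum(j.state == SYN for j in joints),
                    "n_post": sum(j.state == POST for j in joints),
                    "positions_bp": _encode_joints(joints),
                    "free_filament_fraction": snap.free_filament_fraction,
                    "rng_seed": snap.rng_seed,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_snapshots_tsv(path: PathLike) -> List[PopulationSnapshot]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    snapshots = []
    for t, grp in df.groupby("time_s", sort=True):
        grp = grp.sort_values("molecule_id")
        molecules = [_decode_joints(s) for s in grp["positions_bp"]]
        snapshots.append(
            PopulationSnapshot(
                time_s=float(t),
                molecules=molecules,
                free_filament_fraction=float(grp["free_filament_fraction"].iloc[0]),
                rng_seed=int(grp["rng_seed"].iloc[0]),
            )
        )
    return snapshots


def _encode_segments(segs) -> str:
    return ";".join(f"{s}:{e}:{h:.6g}" for s, e, h in segs)


def write_molecule_table(molecules: Sequence[TracedMolecule],
                         path: PathLike) -> None:
    rows = [
        {
            "molecule_id": m.label,
            "included": m.included,
            "exclusion_reason": m.exclusion_reason,
            "contour_nm": round(m.contour_length_nm, 3),
            "n_filaments": m.n_filaments,
            "segments": _encode_segments(m.filament_segments),
        }
        for m in molecules
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_molecule_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)

    def decode(s):
        if not s:
            return []
        return [
            (int(a), int(b), float(h))
            for a, b, h in (item.split(":") for item in str(s).split(";"))
        ]

    df["segments"] = df["segments"].map(decode)
    return df


_COUNT_COLS = [
    "timepoint_s", "n_total_included", "n_bare", "n_with_synaptic",
    "n_post_singular", "mean_joints_per_engaged", "mean_joints_per_molecule",
    "occupancy_fraction_mean", "n_total_imaged", "condition_label",
]


def write_state_counts_csv(counts: Sequence[StateCounts],
                           path: PathLike) -> None:
    pd.DataFrame(
        [{c: getattr(sc, c) for c in _COUNT_COLS} for sc in counts]
    ).to_csv(path, index=False)


def read_state_counts_csv(path: PathLike) -> List[StateCounts]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        kw = {c: row[c] for c in _COUNT_COLS}
        kw["n_total_imaged"] = (
            int(float(kw["n_total_imaged"]))
            if str(kw["n_total_imaged"]) != "" else None
        )
        for c in ("timepoint_s", "mean_joints_per_engaged",
                  "mean_joints_per_molecule", "occupancy_fraction_mean"):
            kw[c] = float(kw[c])
        for c in ("n_total_included", "n_bare", "n_with_synaptic",
                  "n_post_singular"):
            kw[c] = int(kw[c])
        kw["condition_label"] = str(kw["condition_label"])
        out.append(StateCounts(**kw))
    return out


def write_timecourse_csv(tc: TimeCourse, path: PathLike) -> None:
    pd.DataFrame([vars(p) for p in tc.points]).to_csv(path, index=False)


def write_decay_yaml(fit: DecayFit, path: PathLike, label: str = "") -> None:
    payload = {
        "label": label,
        "amplitude": float(fit.amplitude),
        "tau_s": float(fit.tau_s),
        "offset": float(fit.offset),
        "residual_rms": float(fit.residual_rms),
        "n_points": int(fit.n_points),
        "covariance": (
            np.asarray(fit.covariance).tolist()
            if fit.covariance is not None
            else None
        ),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_decay_yaml(path: PathLike) -> DecayFit:
    d = yaml.safe_load(Path(path).read_text())
    return DecayFit(
        amplitude=d["amplitude"],
        tau_s=d["tau_s"],
        offset=d["offset"],
        residual_rms=d["residual_rms"],
        covariance=(
            np.array(d["covariance"]) if d["covariance"] is not None else None
        ),
        n_points=d["n_points"],
    )


def save_height_map(image: np.ndarray, path: PathLike) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def load_height_map(path: PathLike) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.float32)


def save_movie(frames: np.ndarray, path: PathLike) -> None:
    tifffile.imwrite(
        str(path), np.asarray(frames, dtype=np.float32), photometric="minisblack"
    )


def load_movie(path: PathLike) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.float32)
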