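"""Synthetic AFM height-map generator with exact ground truth.

Two modes mirror the two kinds of raw data the measurement stack consumes:

* **field** — a snapshot of deposited 890 bp dsDNA molecules (2D worm-like
  chains) carrying bound filaments, rendered as a single height map. A
  configurable fraction of molecules is deliberately placed straddling the
  frame edge or crossing another molecule, to exercise the inclusion filters.
* **movie** — HS-AFM-style frames of a filament cluster dispersing around a
  static long dsDNA backbone; the cluster spread grows exponentially,
  ``sigma(t) = sigma0 * exp(t / tau_cluster)``, so the normalised inverse
  cluster radius decays with the ground-truth time constant.

Rendering model: every feature is stamped at its physical radius plus the tip
radius (``tip_sigma_nm``, the dilation a finite tip produces), the composite
is smoothed with a Gaussian of the same sigma and overlaid with additive
Gaussian noise. Heights are nm, stored as 32-bit floats on a 0-based,
row-major pixel grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .kinetic_model import PopulationSnapshot
from .params import ImageConfig, KineticParams

__all__ = [
    "FilamentRecord",
    "MoleculeTruth",
    "FieldGroundTruth",
    "MovieGroundTruth",
    "generate_wlc",
    "render_field",
    "generate_movie",
]


@dataclass(frozen=True)
class FilamentRecord:
    position_bp: int
    state: str


@dataclass
class MoleculeTruth:
    """Exact geometry behind one rendered molecule."""

    molecule_id: int
    vertices_nm: np.ndarray              # (N, 2) frame coordinates, nm
    filaments: List[FilamentRecord]
    clipped: bool
    overlapped: bool

    @property
    def included_expected(self) -> bool:
        return not (self.clipped or self.overlapped)

    @property
    def contour_length_nm(self) -> float:
        return float(
            np.sum(np.hypot(*np.diff(self.vertices_nm, axis=0).T))
        )


@dataclass
class FieldGroundTruth:
    molecules: List[MoleculeTruth]
    config: ImageConfig


@dataclass
class MovieGroundTruth:
    cluster_centroid_nm: np.ndarray       # (2,)
    frame_centroids_nm: List[np.ndarray]  # per frame, (n_filaments, 2)
    frame_times_s: List[float]
    tau_cluster_true: float
    sigma0_nm: float
    config: ImageConfig


def generate_wlc(
    length_bp: int,
    config: ImageConfig,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Discrete 2D worm-like chain, returned as an (N, 2) polyline in nm.

    Tangent angles take independent Gaussian steps of variance
    ``segment / persistence_length`` (the 2D convention, under which the
    tangent correlation decays as ``exp(-s / 2P)``), so the ensemble
    mean-squared end-to-end distance follows the 2D closed form
    ``<R^2> = 4PL [1 - (2P/L)(1 - exp(-L/2P))]``. The segment length divides
    the contour exactly, making the polyline arc length exact. Infinite
    persistence length yields a straight rod. Self-intersection is allowed
    (deposited molecules do cross themselves).
    """
    if length_bp < 2:
        raise ValueError("length_bp must be >= 2")
    rng = rng if rng is not None else np.random.default_rng(seed)
    contour_nm = length_bp * config.rise_nm_per_bp
    n_seg = max(1, round(contour_nm / config.wlc_segment_nm))
    seg = contour_nm / n_seg
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    if math.isinf(config.persistence_length_nm):
        theta = np.full(n_seg, theta0)
    else:
        steps = rng.normal(
            0.0,
            math.sqrt(seg / config.persistence_length_nm),
            size=n_seg - 1,
        )
        theta = theta0 + np.concatenate([[0.0], np.cumsum(steps)])
    xy = np.zeros((n_seg + 1, 2))
    xy[1:, 0] = np.cumsum(seg * np.cos(theta))
    xy[1:, 1] = np.cumsum(seg * np.sin(theta))
    return xy


# ---------------------------------------------------------------------------
# Rasterisation helpers
# ---------------------------------------------------------------------------

def _dense_points(vertices_nm: np.ndarray, step_nm: float) -> np.ndarray:
    """Resample a polyline at ~step_nm spacing (includes both ends)."""
    d = np.hypot(*np.diff(vertices_nm, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(d)])
    total = arc[-1]
    n = max(2, int(math.ceil(total / step_nm)) + 1)
    s = np.linspace(0.0, total, n)
    x = np.interp(s, arc, vertices_nm[:, 0])
    y = np.interp(s, arc, vertices_nm[:, 1])
    return np.column_stack([x, y])


def _arc_slice(vertices_nm: np.ndarray, arc_lo: float, arc_hi: float,
               step_nm: float) -> np.ndarray:
    """Points along the polyline between two arc-length coordinates (nm)."""
    d = np.hypot(*np.diff(vertices_nm, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(d)])
    total = arc[-1]
    lo = min(max(arc_lo, 0.0), total)
    hi = min(max(arc_hi, 0.0), total)
    n = max(2, int(math.ceil((hi - lo) / step_nm)) + 1)
    s = np.linspace(lo, hi, n)
    x = np.interp(s, arc, vertices_nm[:, 0])
    y = np.interp(s, arc, vertices_nm[:, 1])
    return np.column_stack([x, y])


def _mark(mask: np.ndarray, points_nm: np.ndarray, pixel_nm: float) -> None:
    """Set mask pixels under the given nm coordinates (row=y, col=x)."""
    ij = np.round(points_nm[:, ::-1] / pixel_nm).astype(int)
    keep = (
        (ij[:, 0] >= 0) & (ij[:, 0] < mask.shape[0])
        & (ij[:, 1] >= 0) & (ij[:, 1] < mask.shape[1])
    )
    ij = ij[keep]
    mask[ij[:, 0], ij[:, 1]] = True


def _disk(radius_px: int) -> np.ndarray:
    if radius_px <= 0:
        return np.ones((1, 1), dtype=bool)
    r = radius_px
    yy, xx = np.mgrid[-r: r + 1, -r: r + 1]
    return (yy * yy + xx * xx) <= r * r


def _compose(
    dna_mask: np.ndarray,
    fil_mask: np.ndarray,
    config: ImageConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    px = config.pixel_nm
    dna = ndimage.binary_dilation(
        dna_mask, _disk(round((config.dna_radius_nm + config.tip_sigma_nm) / px))
    )
    fil = ndimage.binary_dilation(
        fil_mask,
        _disk(round((config.filament_radius_nm + config.tip_sigma_nm) / px)),
    )
    height = np.maximum(
        config.dna_height_nm * dna.astype(np.float32),
        config.filament_height_nm * fil.astype(np.float32),
    )
    height = ndimage.gaussian_filter(height, sigma=config.tip_sigma_nm / px)
    if config.noise_sd_nm > 0:
        height = height + rng.normal(
            0.0, config.noise_sd_nm, size=height.shape
        ).astype(np.float32)
    return height.astype(np.float32)


# ---------------------------------------------------------------------------
# Field rendering
# ---------------------------------------------------------------------------

def _place_molecule(
    rng: np.random.Generator,
    poly: np.ndarray,
    config: ImageConfig,
    clearance: np.ndarray,
    core: np.ndarray,
    mode: str,
    max_tries: int = 200,
) -> Optional[np.ndarray]:
    """Rigidly translate a centred polyline into the frame.

    mode "interior": entirely inside with a margin, clear of other molecules
    (tested against the dilated ``clearance`` mask so that tip broadening
    cannot merge neighbours). mode "clip": crosses a frame edge. mode
    "overlap": crosses an already placed molecule (tested against the raw
    ``core`` mask). Returns placed vertices or None if placement failed.
    """
    frame = config.frame_nm
    px = config.pixel_nm
    margin = config.filament_radius_nm + 4.0 * config.tip_sigma_nm
    centred = poly - poly.mean(axis=0)
    half_w = centred[:, 0].max() - centred[:, 0].min()
    half_h = centred[:, 1].max() - centred[:, 1].min()
    if mode == "interior" and (half_w > frame - 2 * margin
                               or half_h > frame - 2 * margin):
        raise ValueError("frame too small for molecule")
    for _ in range(max_tries):
        centre = rng.uniform(0.0, frame, size=2)
        cand = centred + centre
        inside = (
            (cand >= margin).all() and (cand <= frame - margin).all()
        )
        idx = np.round(cand[:, ::-1] / px).astype(int)
        ok_idx = (
            (idx[:, 0] >= 0) & (idx[:, 0] < clearance.shape[0])
            & (idx[:, 1] >= 0) & (idx[:, 1] < clearance.shape[1])
        )
        near = clearance[idx[ok_idx, 0], idx[ok_idx, 1]].any()
        crosses_other = core[idx[ok_idx, 0], idx[ok_idx, 1]].any()
        crosses_edge = (
            ((cand < 0).any(axis=1) | (cand > frame).any(axis=1)).any()
            and ok_idx.any()
        )
        if mode == "interior" and inside and not near:
            return cand
        if mode == "clip" and crosses_edge and not near:
            return cand
        if mode == "overlap" and crosses_other and (cand >= margin).all() \
                and (cand <= frame - margin).all():
            return cand
    return None


def render_field(
    snapshot: PopulationSnapshot,
    config: ImageConfig,
    seed: int,
    params: Optional[KineticParams] = None,
) -> Tuple[np.ndarray, FieldGroundTruth]:
    """Render one snapshot as a height map plus exact ground truth.

    Each molecule is drawn as a worm-like chain carrying its bound filaments
    at their footprint arc positions (bp 0 at the polyline's first vertex;
    the rod follows the local contour over the 60 bp window). Fractions
    ``clip_fraction`` / ``overlap_fraction`` of molecules are deliberately
    placed across the frame edge or across a previously placed molecule.
    """
    params = params or KineticParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = snapshot.n_molecules
    shape = (config.frame_px, config.frame_px)

    n_clip = int(round(config.clip_fraction * n))
    n_over = int(round(config.overlap_fraction * n))
    order = rng.permutation(n)
    clip_ids = set(order[:n_clip].tolist())
    over_ids = set(order[n_clip: n_clip + n_over].tolist())

    dna_mask = np.zeros(shape, dtype=bool)
    fil_mask = np.zeros(shape, dtype=bool)
    core = np.zeros(shape, dtype=bool)       # raw molecule pixels
    clearance = np.zeros(shape, dtype=bool)  # dilated keep-out zone
    clear_disk = _disk(
        max(1, round((2 * config.filament_radius_nm
                      + 4 * config.tip_sigma_nm) / config.pixel_nm))
    )
    step = config.pixel_nm / 2.0
    truths: List[MoleculeTruth] = []
    rise = config.rise_nm_per_bp
    fl = config.filament_length_nm

    # overlap-designated molecules placed last so there is something to cross
    render_order = (
        [i for i in range(n) if i not in over_ids]
        + [i for i in range(n) if i in over_ids]
    )
    for mid in render_order:
        joints = snapshot.molecules[mid]
        mode = ("clip" if mid in clip_ids
                else "overlap" if mid in over_ids else "interior")
        placed = None
        for _ in range(20):  # fresh conformation if placement keeps failing
            poly = generate_wlc(params.dsdna_length_bp, config, rng=rng)
            placed = _place_molecule(rng, poly, config, clearance, core, mode)
            if placed is not None:
                break
        if placed is None:
            if mode == "overlap":  # nothing to overlap yet: fall back
                placed = _place_molecule(
                    rng, poly, config, clearance, core, "interior"
                )
            if placed is None:
                raise ValueError(
                    f"could not place molecule {mid} (mode={mode}); "
                    "frame too small or too crowded"
                )
        pts = _dense_points(placed, step)
        _mark(dna_mask, pts, config.pixel_nm)
        mol_mask = np.zeros(shape, dtype=bool)
        _mark(mol_mask, pts, config.pixel_nm)
        core |= mol_mask
        clearance |= ndimage.binary_dilation(mol_mask, clear_disk)
        # inset the stamped arc by the stamp radius so the rendered footprint
        # has the filament's physical extent (disks add the radius back)
        inset = min(config.filament_radius_nm + config.tip_sigma_nm,
                    fl / 2.0 - step)
        for j in joints:
            mid_arc = (j.position_bp + params.filament_length_nt / 2.0) * rise
            seg_pts = _arc_slice(placed, mid_arc - fl / 2.0 + inset,
                                 mid_arc + fl / 2.0 - inset, step)
            _mark(fil_mask, seg_pts, config.pixel_nm)
        truths.append(
            MoleculeTruth(
                molecule_id=mid,
                vertices_nm=placed,
                filaments=[FilamentRecord(j.position_bp, j.state) for j in joints],
                clipped=mid in clip_ids,
                overlapped=mid in over_ids,
            )
        )
    truths.sort(key=lambda m: m.molecule_id)
    image = _compose(dna_mask, fil_mask, config, rng)
    return image, FieldGroundTruth(molecules=truths, config=config)


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------

def generate_movie(
    n_filaments: int,
    tau_cluster: float,
    frame_times: Sequence[float],
    config: ImageConfig,
    seed: int,
    backbone_length_bp: int = 3500,
    jitter_nm: float = 5.0,
) -> Tuple[np.ndarray, MovieGroundTruth]:
    """HS-AFM-style frames of a dispersing filament cluster.

    Filament centroids at time t are distributed as an isotropic Gaussian of
    spread ``sigma0 * exp(t / tau_cluster)`` about a fixed centroid, so the
    normalised inverse radius of gyration of the cluster decays exponentially
    with the ground-truth constant. The frames track *the same* filaments
    through the dispersal (as a movie does): each filament keeps its unit
    offset drawn at t=0 and scales outward with sigma(t), plus a small
    per-frame diffusive jitter (``jitter_nm``) and a fresh orientation. A
    static dsDNA backbone is present in every frame; filaments are rendered
    as randomly oriented rigid rods. Returns a (T, H, W) float32 stack and
    the ground truth.
    """
    if n_filaments < 3:
        raise ValueError("n_filaments must be >= 3")
    times = [float(t) for t in frame_times]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("frame_times must be ascending")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shape = (config.frame_px, config.frame_px)
    frame = config.frame_nm
    centre = np.array([frame / 2.0, frame / 2.0])
    step = config.pixel_nm / 2.0

    backbone = generate_wlc(backbone_length_bp, config, rng=rng)
    backbone = backbone - backbone.mean(axis=0) + centre
    dna_mask = np.zeros(shape, dtype=bool)
    _mark(dna_mask, _dense_points(backbone, step), config.pixel_nm)

    frames = np.empty((len(times), *shape), dtype=np.float32)
    per_frame_centroids: List[np.ndarray] = []
    half = max(
        step,
        config.filament_length_nm / 2.0
        - (config.filament_radius_nm + config.tip_sigma_nm),
    )
    unit_offsets = rng.normal(0.0, 1.0, size=(n_filaments, 2))
    for k, t in enumerate(times):
        sigma = (
            config.cluster_sigma0_nm
            if math.isinf(tau_cluster)
            else config.cluster_sigma0_nm * math.exp(t / tau_cluster)
        )
        centroids = (
            centre
            + sigma * unit_offsets
            + rng.normal(0.0, jitter_nm, size=(n_filaments, 2))
        )
        per_frame_centroids.append(centroids)
        fil_mask = np.zeros(shape, dtype=bool)
        angles = rng.uniform(0.0, math.pi, size=n_filaments)
        for c, a in zip(centroids, angles):
            u = np.array([math.cos(a), math.sin(a)])
            rod = np.array([c - half * u, c + half * u])
            _mark(fil_mask, _dense_points(rod, step), config.pixel_nm)
        frames[k] = _compose(dna_mask, fil_mask, config, rng)
    truth = MovieGroundTruth(
        cluster_centroid_nm=centre,
        frame_centroids_nm=per_frame_centroids,
        frame_times_s=times,
        tau_cluster_true=tau_cluster,
        sigma0_nm=config.cluster_sigma0_nm,
        config=config,
    )
    return frames, truth
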