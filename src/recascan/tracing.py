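"""Contour tracing of dsDNA molecules and filament detection in height maps.

The measurement stack mirrors manual AFM analysis: threshold the height map,
keep connected components of plausible size, skeletonise each component, and
accept a molecule only when its skeleton is a clean open path — exactly two
endpoints, no branch points (branch points mean crossing/overlapping
molecules), and no contact with the frame border. Accepted molecules yield an
ordered contour polyline with per-vertex heights; maximal runs of
above-threshold height along the contour are recorded as bound-filament
segments in base-pair coordinates.

Base-pair coordinates are 0-based from an arbitrary trace endpoint: AFM
cannot distinguish the 5' from the 3' terminus, so all downstream position
logic must be (and is) symmetric under end reversal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .params import ImageConfig

__all__ = [
    "TracedMolecule",
    "segment",
    "trace_contour",
    "detect_filaments",
    "trace_field",
    "blob_centroids",
]

_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class TracedMolecule:
    """One traced molecule: ordered contour, heights, flags, filament segments."""

    label: int
    vertices_nm: np.ndarray          # (N, 2) ordered (x, y), nm
    heights_nm: np.ndarray           # (N,)
    contour_length_nm: float
    termini_resolved: bool
    touches_edge: bool
    overlaps_other: bool
    filament_segments: List[Tuple[int, int, float]] = field(default_factory=list)

    @property
    def included(self) -> bool:
        return (
            self.termini_resolved
            and not self.touches_edge
            and not self.overlaps_other
        )

    @property
    def exclusion_reason(self) -> str:
        if self.touches_edge:
            return "touches_edge"
        if self.overlaps_other:
            return "overlaps_other"
        if not self.termini_resolved:
            return "termini_unresolved"
        return ""

    @property
    def n_filaments(self) -> int:
        return len(self.filament_segments)

    @property
    def arc_nm(self) -> np.ndarray:
        d = np.hypot(*np.diff(self.vertices_nm, axis=0).T)
        return np.concatenate([[0.0], np.cumsum(d)])

    def reversed(self) -> "TracedMolecule":
        """The same trace measured from the other terminus."""
        total = self.contour_length_nm
        segs = sorted(
            (round(total_bp(total, self._rise) - e),
             round(total_bp(total, self._rise) - s), h)
            for s, e, h in self.filament_segments
        )
        rev = TracedMolecule(
            label=self.label,
            vertices_nm=self.vertices_nm[::-1].copy(),
            heights_nm=self.heights_nm[::-1].copy(),
            contour_length_nm=total,
            termini_resolved=self.termini_resolved,
            touches_edge=self.touches_edge,
            overlaps_other=self.overlaps_other,
            filament_segments=[(int(s), int(e), float(h)) for s, e, h in segs],
        )
        rev._rise = self._rise
        return rev

    _rise: float = 0.34  # recorded at detection time for end reversal


def total_bp(arc_nm: float, rise_nm_per_bp: float) -> float:
    return arc_nm / rise_nm_per_bp


def denoise(image: np.ndarray, sigma_px: float = 1.0) -> np.ndarray:
    """Light Gaussian denoise; per-pixel noise would fray the threshold mask."""
    if sigma_px <= 0:
        return np.asarray(image, dtype=np.float32)
    return ndimage.gaussian_filter(
        np.asarray(image, dtype=np.float32), sigma=sigma_px
    )


def segment(
    image: np.ndarray,
    low_threshold_nm: float = 0.3,
    min_area_px: int = 30,
    denoise_sigma_px: float = 1.0,
) -> np.ndarray:
    """Connected components above a height threshold, small specks removed.

    The image is lightly smoothed first (see :func:`denoise`). Returns a
    labelled integer array (0 = background).
    """
    if image.size == 0:
        raise ValueError("empty image")
    mask = denoise(image, denoise_sigma_px) > low_threshold_nm
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area_px)
    if len(small):
        mask &= ~np.isin(labels, small)
        labels = measure.label(mask, connectivity=2)
    return labels


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pix = set(zip(rows.tolist(), cols.tolist()))
    for p in pix:
        g.add_node(p)
    for (r, c) in pix:
        for dr, dc in _NBRS:
            q = (r + dr, c + dc)
            if q in pix and not g.has_edge((r, c), q):
                g.add_edge((r, c), q, weight=math.hypot(dr, dc))
    return g


def _prune_spurs(g: nx.Graph, max_len_px: float) -> nx.Graph:
    """Iteratively remove endpoint branches shorter than max_len_px."""
    g = g.copy()
    changed = True
    while changed:
        changed = False
        for ep in [n for n in g.nodes if g.degree(n) == 1]:
            path = [ep]
            length = 0.0
            cur, prev = ep, None
            while True:
                nbrs = [n for n in g.neighbors(cur) if n != prev]
                if g.degree(cur) >= 3 or not nbrs:
                    break
                nxt = nbrs[0]
                length += g[cur][nxt]["weight"]
                prev, cur = cur, nxt
                if g.degree(cur) >= 3:
                    break
                path.append(cur)
                if length > max_len_px:
                    break
            # prune only if the walk hit a junction within the length budget
            if g.degree(cur) >= 3 and length <= max_len_px:
                g.remove_nodes_from(path)
                changed = True
    return g


def _ordered_path(g: nx.Graph) -> Optional[List[Tuple[int, int]]]:
    ends = [n for n in g.nodes if g.degree(n) == 1]
    if len(ends) != 2 or any(g.degree(n) > 2 for n in g.nodes):
        return None
    # deterministic orientation: start from the lexicographically smaller end
    start = min(ends)
    path = [start]
    prev = None
    cur = start
    while True:
        nbrs = [n for n in g.neighbors(cur) if n != prev]
        if not nbrs:
            break
        prev, cur = cur, nbrs[0]
        path.append(cur)
    if len(path) != g.number_of_nodes():
        return None  # disconnected leftovers
    return path


def _smooth_path_nm(path: List[Tuple[int, int]], pixel_nm: float,
                    window: int = 3) -> np.ndarray:
    """Pixel path -> nm polyline, boxcar-smoothed to suppress staircase bias."""
    xy = np.array([(c * pixel_nm, r * pixel_nm) for r, c in path], dtype=float)
    if len(xy) > window:
        kernel = np.ones(window) / window
        sm = xy.copy()
        half = window // 2
        for k in range(2):
            sm[half:-half, k] = np.convolve(xy[:, k], kernel, mode="valid")
        xy = sm
    return xy


def trace_contour(
    component_mask: np.ndarray,
    image: np.ndarray,
    config: ImageConfig,
    label: int = 0,
) -> TracedMolecule:
    """Skeletonise one component and order its contour endpoint-to-endpoint.

    A clean trace has exactly two skeleton endpoints and no branch points
    after pruning spurs up to the mask half-width (filament radius plus twice
    the tip sigma — thinning a band of that width leaves spurs of up to that
    length at curvature maxima and blob shoulders); any remaining
    branch point marks the molecule as overlapping. Components with more
    than two endpoints and a single branch point get one extra, more
    aggressive pruning pass before being given up on. Touching the frame
    border sets ``touches_edge``.
    """
    if component_mask.sum() < 3:
        raise ValueError("component smaller than 3 pixels")
    px = config.pixel_nm
    touches_edge = bool(
        component_mask[0, :].any()
        or component_mask[-1, :].any()
        or component_mask[:, 0].any()
        or component_mask[:, -1].any()
    )
    skel = morphology.skeletonize(component_mask)
    if skel.sum() < 3:
        raise ValueError("component smaller than 3 skeleton pixels")
    g = _skeleton_graph(skel)
    if g.number_of_nodes() and not nx.is_connected(g):
        g = g.subgraph(
            max(nx.connected_components(g), key=len)
        ).copy()
    prune_px = (config.filament_radius_nm + 2.0 * config.tip_sigma_nm) / px
    g = _prune_spurs(g, prune_px)
    branch = [n for n in g.nodes if g.degree(n) >= 3]
    ends = [n for n in g.nodes if g.degree(n) == 1]
    if len(ends) > 2 and len(branch) == 1:
        g = _prune_spurs(g, 2.0 * prune_px)  # one retry, deeper prune
        branch = [n for n in g.nodes if g.degree(n) >= 3]
        ends = [n for n in g.nodes if g.degree(n) == 1]
    overlaps = bool(branch)
    path = None if overlaps else _ordered_path(g)
    if path is None:
        # keep raw skeleton pixels for bookkeeping; molecule is excluded
        nodes = sorted(g.nodes)
        xy = np.array([(c * px, r * px) for r, c in nodes], dtype=float)
        heights = np.array([image[r, c] for r, c in nodes], dtype=float)
        traced = TracedMolecule(
            label=label,
            vertices_nm=xy,
            heights_nm=heights,
            contour_length_nm=0.0,
            termini_resolved=False,
            touches_edge=touches_edge,
            overlaps_other=overlaps,
        )
        traced._rise = config.rise_nm_per_bp
        return traced
    xy = _smooth_path_nm(path, px)
    heights = np.array([image[r, c] for r, c in path], dtype=float)
    arc = np.concatenate(
        [[0.0], np.cumsum(np.hypot(*np.diff(xy, axis=0).T))]
    )
    traced = TracedMolecule(
        label=label,
        vertices_nm=xy,
        heights_nm=heights,
        contour_length_nm=float(arc[-1]),
        termini_resolved=True,
        touches_edge=touches_edge,
        overlaps_other=False,
    )
    traced._rise = config.rise_nm_per_bp
    return traced


def detect_filaments(
    traced: TracedMolecule,
    config: ImageConfig,
    filament_threshold_nm: Optional[float] = None,
    min_run_nm: float = 10.0,
    merged_spacing_nm: float = 25.0,
    nominal_length_bp: Optional[int] = None,
) -> TracedMolecule:
    """Record above-threshold height runs along the contour as filaments (bp).

    The default threshold sits midway between the rendered dsDNA and filament
    heights. Joints bound closer than roughly their own length blur into one
    continuous run, so a run much longer than a single filament is split into
    ``1 + round((extent - single) / merged_spacing_nm)`` filaments placed
    evenly along it — ``merged_spacing_nm`` is the typical centre-to-centre
    spacing of joints close enough to merge (between the 60 bp hard-core
    minimum, ~20 nm, and the ~38 nm beyond which blobs separate). A run
    touching a contour end is positioned from its interior edge, because the
    blob's outer edge extends past the DNA end and is not a reliable
    landmark.

    Arc positions convert to base pairs at the B-DNA rise; when
    ``nominal_length_bp`` is given (the template length is known in a
    designed reaction) and the traced contour is within 15% of it, positions
    are mapped fractionally instead, which cancels the few-percent contour
    shortening that skeletonising a tip-broadened image inevitably causes.
    """
    if not traced.termini_resolved:
        raise ValueError("trace its contour first (termini unresolved)")
    thr = (
        filament_threshold_nm
        if filament_threshold_nm is not None
        else 0.5 * (config.dna_height_nm + config.filament_height_nm)
    )
    if thr <= config.dna_height_nm:
        raise ValueError(
            "filament threshold at or below the DNA height would mark the "
            "whole molecule as filament"
        )
    arc = traced.arc_nm
    total = arc[-1]
    above = traced.heights_nm >= thr
    rise = config.rise_nm_per_bp
    if (
        nominal_length_bp
        and abs(total / rise - nominal_length_bp) <= 0.15 * nominal_length_bp
    ):
        rise = total / nominal_length_bp  # fractional-position mapping
    # apparent extent of one filament between halfway-threshold crossings:
    # the crossings sit ~0.85 tip-sigma inside the physical footprint end
    single = max(
        2.0 * config.pixel_nm,
        config.filament_length_nm - 1.7 * config.tip_sigma_nm,
    )
    half_bp = 0.5 * config.filament_length_nm / rise

    segments: List[Tuple[int, int, float]] = []

    def add(center_nm: float, height: float) -> None:
        c_bp = center_nm / rise
        segments.append(
            (int(round(c_bp - half_bp)), int(round(c_bp + half_bp)), height)
        )

    i = 0
    n = len(above)
    end_eps = 2.0 * config.pixel_nm
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        lo, hi = float(arc[i]), float(arc[j])
        extent = hi - lo
        height = float(traced.heights_nm[i: j + 1].max())
        if extent >= min_run_nm:
            at_start = lo <= end_eps
            at_end = hi >= total - end_eps
            n_fil = max(1, 1 + round(max(0.0, extent - single)
                                     / merged_spacing_nm))
            if n_fil == 1:
                if at_start and not at_end:
                    add(hi - single / 2.0, height)
                elif at_end and not at_start:
                    add(lo + single / 2.0, height)
                else:
                    add((lo + hi) / 2.0, height)
            else:
                first, last = lo + single / 2.0, hi - single / 2.0
                if at_start and not at_end:
                    first = hi - single / 2.0 - (n_fil - 1) * merged_spacing_nm
                    last = hi - single / 2.0
                elif at_end and not at_start:
                    first = lo + single / 2.0
                    last = lo + single / 2.0 + (n_fil - 1) * merged_spacing_nm
                for c in np.linspace(first, last, n_fil):
                    add(float(c), height)
        i = j + 1
    traced.filament_segments = sorted(segments)
    traced._rise = rise
    return traced


def trace_field(
    image: np.ndarray,
    config: ImageConfig,
    low_threshold_nm: float = 0.3,
    min_area_px: int = 30,
    filament_threshold_nm: Optional[float] = None,
    denoise_sigma_px: float = 1.0,
    nominal_length_bp: Optional[int] = None,
) -> List[TracedMolecule]:
    """Segment a height map and trace every component; detect filaments on
    the clean traces. Returns one TracedMolecule per component."""
    smoothed = denoise(image, denoise_sigma_px)
    labels = segment(smoothed, low_threshold_nm, min_area_px,
                     denoise_sigma_px=0.0)
    out: List[TracedMolecule] = []
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        if mask.sum() < 3:
            continue
        try:
            t = trace_contour(mask, smoothed, config, label=lab)
        except ValueError:
            continue
        if t.termini_resolved:
            t = detect_filaments(
                t, config, filament_threshold_nm,
                nominal_length_bp=nominal_length_bp,
            )
        out.append(t)
    return out


def blob_centroids(
    image: np.ndarray,
    config: ImageConfig,
    threshold_nm: Optional[float] = None,
    min_area_px: int = 12,
    return_weights: bool = False,
):
    """Centroids (nm) of filament-height blobs in one frame.

    Used on movie frames: anything above the filament threshold (default
    midway between DNA and filament heights, so the dsDNA backbone is
    ignored) and larger than ``min_area_px`` counts as one filament blob.
    With ``return_weights=True`` also returns each blob's pixel area, which
    serves as its mass when filaments crowd into one blob.
    """
    thr = (
        threshold_nm
        if threshold_nm is not None
        else 0.5 * (config.dna_height_nm + config.filament_height_nm)
    )
    labels = segment(image, thr, min_area_px)
    if labels.max() == 0:
        empty = np.empty((0, 2))
        return (empty, np.empty(0)) if return_weights else empty
    props = measure.regionprops(labels)
    cent = np.array([[p.centroid[1], p.centroid[0]] for p in props])
    cent = cent * config.pixel_nm
    if return_weights:
        return cent, np.array([p.area for p in props], dtype=float)
    return cent
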