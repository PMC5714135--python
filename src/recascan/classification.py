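"""Interaction-state categories of dsDNA molecules and occupancy statistics.

Every included molecule falls in exactly one of three categories:

* ``bare`` — no bound filament;
* ``synaptic`` — one or more joints, in any mixture that is not a single
  post-synaptic complex (a molecule carrying a post-synaptic joint plus any
  other filament has *not* resolved);
* ``post_synaptic_singular`` — exactly one filament, located at the
  homologous window (or its end-reversed mirror: AFM cannot tell the 5' end
  from the 3' end, so positions are only defined up to end reversal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

from .params import KineticParams

__all__ = [
    "BARE",
    "SYNAPTIC",
    "POST_SYNAPTIC_SINGULAR",
    "StateCounts",
    "homology_window",
    "classify",
    "classify_positions",
    "occupancy",
    "count_states",
]

BARE = "bare"
SYNAPTIC = "synaptic"
POST_SYNAPTIC_SINGULAR = "post_synaptic_singular"


@dataclass
class StateCounts:
    """Per-timepoint category counts for one molecule population."""

    timepoint_s: float
    n_total_included: int
    n_bare: int
    n_with_synaptic: int
    n_post_singular: int
    mean_joints_per_engaged: float = 0.0
    mean_joints_per_molecule: float = 0.0
    occupancy_fraction_mean: float = 0.0
    n_total_imaged: Optional[int] = None  # denominator before inclusion filters
    condition_label: str = ""

    def __post_init__(self) -> None:
        if self.n_bare + self.n_with_synaptic + self.n_post_singular \
                != self.n_total_included:
            raise ValueError("category counts must sum to n_total_included")

    @property
    def frac_any_joint(self) -> float:
        return 1.0 - self.n_bare / self.n_total_included

    @property
    def frac_post_singular(self) -> float:
        return self.n_post_singular / self.n_total_included


def homology_window(params: KineticParams) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Half-open homologous window ``[start, end)`` and its end-reversed mirror.

    For the 890 bp / 60 bp / start-360 design this is ``(360, 420)`` and
    ``(470, 530)``; the window start sits 85 bp from the molecule centre,
    which is what makes the homologous site distinguishable from its mirror
    image in an end-symmetric measurement. A centred window would coincide
    with its own mirror and lose positional discrimination — flagged.
    """
    start = params.homology_start_bp
    end = start + params.filament_length_nt
    mirror = (params.dsdna_length_bp - end, params.dsdna_length_bp - start)
    if (start, end) == mirror:
        import warnings

        warnings.warn(
            "homology window is centred: it coincides with its mirror and "
            "post-synaptic complexes cannot be distinguished positionally",
            stacklevel=2,
        )
    return (start, end), mirror


def _near_window(mid_bp: float, window: Tuple[int, int], tol: float) -> bool:
    lo, hi = window
    return lo - tol <= mid_bp <= (hi - 1) + tol


def classify_positions(
    midpoints_bp: Sequence[float],
    params: KineticParams,
    tolerance_bp: float = 30.0,
) -> str:
    """Category of a molecule given its filament-segment midpoints (bp).

    Exactly one filament whose midpoint lies within ``tolerance_bp`` of the
    homologous window or its mirror resolves the molecule
    (``post_synaptic_singular``) — unless that filament sits within
    ``tolerance_bp`` of a terminus, in which case it is treated as an
    end-bound synaptic joint. Everything else with >= 1 filament is
    ``synaptic``. Symmetric under end reversal by construction.
    """
    mids = list(midpoints_bp)
    if not mids:
        return BARE
    if len(mids) == 1:
        m = mids[0]
        win, mirror = homology_window(params)
        near_end = m <= tolerance_bp or m >= params.dsdna_length_bp - tolerance_bp
        if not near_end and (
            _near_window(m, win, tolerance_bp) or _near_window(m, mirror, tolerance_bp)
        ):
            return POST_SYNAPTIC_SINGULAR
    return SYNAPTIC


def classify(traced, params: KineticParams, tolerance_bp: float = 30.0) -> str:
    """Category of a traced molecule (see :func:`classify_positions`).

    The molecule must have passed the inclusion filters (termini resolved,
    fully in frame, not overlapping another molecule).
    """
    if not traced.included:
        raise ValueError(
            "molecule failed inclusion filters "
            f"({traced.exclusion_reason}); filter upstream"
        )
    mids = [0.5 * (s + e) for (s, e, _h) in traced.filament_segments]
    return classify_positions(mids, params, tolerance_bp)


def occupancy(n_filaments: int, params: KineticParams) -> float:
    """Fraction of the dsDNA concurrently covered by bound filaments.

    Three concurrent 60-nt joints on an 890 bp molecule cover 180/890 ≈ 20%.
    Capped at 1 (the packing bound caps it near 840/890 in practice).
    """
    if n_filaments < 0:
        raise ValueError("n_filaments must be >= 0")
    return min(
        1.0, n_filaments * params.filament_length_nt / params.dsdna_length_bp
    )


def count_states(
    categories: Sequence[str],
    joint_counts: Sequence[int],
    params: KineticParams,
    timepoint_s: float,
    n_total_imaged: Optional[int] = None,
    condition_label: str = "",
) -> StateCounts:
    """Aggregate per-molecule categories into a :class:`StateCounts` row."""
    if len(categories) != len(joint_counts):
        raise ValueError("categories and joint_counts must align")
    n = len(categories)
    if n == 0:
        raise ValueError("no molecules to count")
    n_bare = sum(c == BARE for c in categories)
    n_post = sum(c == POST_SYNAPTIC_SINGULAR for c in categories)
    n_syn = n - n_bare - n_post
    engaged = [k for k in joint_counts if k > 0]
    return StateCounts(
        timepoint_s=timepoint_s,
        n_total_included=n,
        n_bare=n_bare,
        n_with_synaptic=n_syn,
        n_post_singular=n_post,
        mean_joints_per_engaged=(sum(engaged) / len(engaged)) if engaged else 0.0,
        mean_joints_per_molecule=sum(joint_counts) / n,
        occupancy_fraction_mean=sum(
            occupancy(k, params) for k in joint_counts
        ) / n,
        n_total_imaged=n_total_imaged,
        condition_label=condition_label,
    )
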