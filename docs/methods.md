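# Methods

## The kinetic model

Each dsDNA molecule evolves independently given one global clock. Filaments
dock onto a molecule as a non-homogeneous Poisson process with per-molecule
hazard

    a(t) = k_assoc0 · exp(−t / tau_cluster),

the minimal form that ties the shut-off of association to the dispersal of
the locally enhanced filament concentration around each molecule: both the
engaged-fraction decline and the cluster radius follow single exponentials,
so one clock serves for both. Footprint start positions are uniform over the
admissible set with hard-core exclusion (no two 60 bp footprints overlap;
at most ⌊890/60⌋ = 14 joints fit). Each synaptic joint survives an
exponential lifetime `tau_dissoc`; at its terminal event, a joint whose
footprint overlaps the homologous window `[360, 420)` by at least
`min_capture_overlap_bp` (30 bp) converts with probability `p_capture` into
a post-synaptic complex instead of dissociating — at most one per molecule,
irreversible on the experimental timescale (ATPγS chemistry). Association
onto molecules already carrying a post-synaptic complex remains allowed;
the resolved category demands singularity at observation time, not a frozen
molecule.

The simulator is exact: per molecule, the next association time is drawn by
analytic inversion of the cumulative hazard `k0·τc·(e^(−t0/τc) − e^(−t/τc))`
and competes with the first of the joints' exponential clocks; requested
timepoints are read off as instantaneous states (quench-and-image sampling).
Every molecule consumes its own substream spawned deterministically from
the root seed, so identical inputs give bit-identical snapshot lists.

`k_hydrolysis` (0.01 min⁻¹, the slow ATPγS turnover that eventually
disassembles filaments) is bookkeeping for the *free* filament supply. It is
not an extra loss channel on bound joints: `tau_dissoc` is defined as the
total observed joint lifetime, which already contains every microscopic
contribution. Over a one-hour reaction at 3:1 filament:dsDNA stoichiometry
the supply stays ample — even 40% of molecules each sequestering one
filament consumes only 0.4/3 ≈ 13% of it — so free-pool depletion is
reported (`free_filament_fraction`) but feeds back on nothing.

### Mean-field surrogate

For calibration the package carries a deterministic approximation: joints
per molecule are Poisson with mean

    mu(t) = k0 · (e^(−t/τd) − e^(−t/τc)) / (1/τc − 1/τd),

cumulative births `B(t) = k0·τc·(1 − e^(−t/τc))`, deaths `D = B − mu`, and
the first capture is a thinning of deaths with probability `p·q` where
`q` is the fraction of placements that can capture (61/831 for the default
geometry). It ignores hard-core exclusion and treats capture as Poisson
thinning; at the calibrated parameters it tracks the simulator to a few
tenths of a percentage point at 600 s and ~2 points at 3600 s (the
exponential-thinning approximation undercounts capture when `p` is large),
which is why the shipped presets come from a simulator-level refinement.

### The operational category definition

AFM reads positions, not binding chemistry. A molecule is classified

* **bare** — no bound filament;
* **synaptic** — any other mixture (including a post-synaptic complex with
  extra company: such a molecule has not resolved);
* **singular post-synaptic** — exactly one filament whose footprint
  midpoint lies in the homologous window *or its end-reversed mirror*
  `[470, 530)`, regardless of the joint's latent state: a lone synaptic
  joint parked on the window is indistinguishable from a genuine
  post-synaptic complex in a height map, and end-symmetry makes the mirror
  site indistinguishable from the true site.

The simulator's `summarize` applies the same operational rule to its exact
coordinates (`operational=False` recovers latent-state counting for model
introspection). This choice is not cosmetic: under latent-state counting no
parameter set reproduces all four printed 37 °C fractions closer than
~1.5 percentage points, while the operational definition — the one the
measurement actually implements — admits an essentially exact joint fit.

### Calibration and presets

`calibrate(printed_points, params0, seed, free=..., method=...)` minimises
the squared deviation of model category fractions from printed time-course
values: `method="meanfield"` by differential evolution on the surrogate,
`method="simulate"` by Nelder–Mead on the stochastic simulator with common
random numbers. Bounds keep rates physical; in particular
`tau_dissoc ≥ 60 s` (transient joints live seconds to minutes). A set is
declared calibrated when every residual is within 0.02.

The shipped **37 °C** preset (`k_assoc0 = 0.011189 s⁻¹`,
`tau_cluster = 654.5 s`, `tau_dissoc = 487.6 s`, `p_capture = 0.848`) is the
simulator-level least-squares fit to the four printed fractions
{92%, 4.4% at 600 s; 43%, 36% at 3600 s}; at an independent seed and
n = 20000 it reproduces them within one percentage point. The **22 °C**
preset refits `k_assoc0`, `tau_cluster` and `p_capture` to the printed 55%
saturation with the saturation plateau near 20 minutes (`tau_cluster` frees
up because a colder, slower-dispersing cluster is the natural reading of
the delayed saturation); `tau_dissoc` is shared. The **heterologous** preset
has association and capture off and realises the fitted 580 s joint
lifetime directly; combined with one seeded joint per molecule it isolates
the dissociation channel. **4C** is a near-zero-rate quench control.

Known discrepancy: at 22 °C the operational singular fraction has a floor
of ~5% (lone synaptic joints transiting the window region,
`mu·q_region ≈ 0.72·0.144` at 1200 s), above the printed 3.6 ± 0.6%. The
mean joints per engaged molecule at the 37 °C peak is ~2.6–2.8 against the
reported "about three"; it is pinned by the printed 8% bare fraction under
near-Poisson occupancy, and both statistics (per molecule and per engaged
molecule) are reported.

## The synthetic data generator

**What it emulates.** 890 bp molecules deposited in 2D as discrete
worm-like chains (segment 2 nm, persistence length 50 nm, rise 0.34 nm/bp;
tangent-angle variance `ds/P`, the 2D convention under which
`⟨R²⟩ = 4PL[1 − (2P/L)(1 − e^(−L/2P))]`); bound filaments as 5-nm-high,
30-nm-long rods laid along the local contour over their footprint (dsDNA
ridge height 0.7 nm); tip broadening as stamping at the physical feature
radius plus the tip sigma followed by Gaussian smoothing of the same sigma
(so a bare molecule's rendered peak stays within ~20% of its nominal
height, as tip dilation — a maximum filter — would give); additive white
noise of 0.1 nm; configurable fractions of molecules deliberately straddling
the frame edge or crossing a neighbour, with everything recorded in an
exact ground-truth object. Interior molecules are placed with a dilated
keep-out zone so that tip broadening cannot merge unrelated neighbours.

Movies render a static 3.5 kbp backbone plus n filaments whose centroids
are `centre + σ(t)·Z_i + jitter`, with `Z_i` standard-normal offsets drawn
once per movie, `σ(t) = σ₀·e^(t/τ_cluster)` (σ₀ = 50 nm) and a 5 nm
per-frame diffusive jitter. The marginal at every t is the isotropic
Gaussian of spread σ(t); drawing offsets once makes consecutive frames
track the *same* dispersing cluster, as a movie does — with independent
per-frame draws the radius series carries ~30% sampling noise per frame and
no estimator recovers the time constant. Cluster dispersal is
phenomenological exponential spread, not free diffusion: √t growth cannot
produce the exponential the downstream fit assumes, and the generator must
realise the model being fitted.

**What it does not emulate** (hence what passing tests do not show about
real data): tip-shape artifacts beyond isotropic Gaussian broadening,
scan-line noise and drift, molecule–surface equilibration kinetics, RecA's
1.5× extension of the underlying duplex (a ≤ ~30 bp positional error,
absorbed by the classification tolerance), filament flexibility, and any
sequence-level energetics. Category-recovery rates measured on these fields
bound the pipeline's algorithmic errors, not an instrument's.

## The measurement stack

Images are lightly denoised (1 px Gaussian — raw per-pixel noise frays the
threshold mask into loops no pruning can repair), thresholded at 0.3 nm,
and labelled; specks under 30 px are dropped. Each component is
skeletonised; the skeleton graph (8-connected, √2 diagonal weights) is
pruned of endpoint spurs shorter than `filament_radius + 2·tip_sigma`
(≈ 11 nm — the spur length that thinning a band of that half-width
produces at curvature maxima; components with > 2 endpoints and a single
branch point get one deeper pruning pass). A clean trace has exactly two
endpoints and no branch points; remaining branch points flag overlap
(including genuine self-crossings, which an analyst would likewise
discard), border contact flags clipping, and only clean, fully-interior
molecules are included — mirroring the study's inclusion rules.

Vertices are boxcar-smoothed (window 3) before arc-length measurement,
which brings the digital-length bias on rods at random orientations under
2%. Skeletonising a tip-broadened image irreducibly loses ~4% of a
worm-like chain's contour (wiggle below the apparent width is absent from
the image), so base-pair coordinates are mapped fractionally along the
measured contour whenever the designed template length is supplied and the
trace is within 15% of it; the raw `arc/0.34` mapping is the fallback.

Filament segments are maximal runs of contour height above the midpoint of
the DNA and filament rendered heights, at least 10 nm long. A single
filament's run extends between threshold crossings that sit ~0.85 tip-sigma
inside its physical footprint (~25 nm at defaults); runs much longer than
that are unavoidable merges of joints closer than ~40 nm and are split into
`1 + round((extent − single)/25 nm)` filaments spaced evenly — 25 nm is the
midpoint of the mergeable spacing range (the 60 bp hard core, ~20 nm, up to
the ~38 nm separation limit). Runs touching a contour end are positioned
from their interior edge (the outer edge overhangs the DNA terminus). On
validation fields at default noise: 98% correct categories and 100% correct
filament counts among included molecules, positional error 26 bp at the
95th percentile, and every deliberately clipped or overlapped molecule
excluded.

A singular filament within the 30 bp classification tolerance of a
*terminus* is always synaptic (end-binding is a recognised docking mode and
cannot be homologous here). Note that with the default geometry the
window-plus-tolerance acceptance bands `[330, 450)` and `[440, 560)` meet
at the molecule centre: tolerance 30 bp is the tracing error budget, and
shrinking it below ~20 bp would orphan genuine post-synaptic complexes.

## Time-courses, decay fits, cluster tracking

Fractions carry Wilson score intervals at the 68% level (the ±1-point style
of n ≈ 1000 single-molecule counts; 95% intervals are also emitted).
`fit_decay` fits `A·e^(−t/τ) (+ C)` by bounded nonlinear least squares from
six starts (the canonical `τ₀ = span/2` plus five log-spaced, seeded-jitter
guesses); lowest residual wins, ties to the smaller τ. Times are fitted
relative to the first point and the amplitude is transformed back, making
the offset-free fit exactly shift- and scale-equivariant. The
resolution-phase fit uses timepoints from the peak of the any-joint series
onward; the heterologous recovery uses the offset-free variant (the decay
runs to bare molecules), while an offset variant is available where a
resolved plateau remains.

Cluster tracking detects blobs above the filament threshold in each frame,
takes their centroids *weighted by blob pixel area* (a merged blob carries
the mass of its members — unweighted centroids overweight stragglers and
inflate the early radius ~30%), selects the largest single-linkage cluster
at the cutoff, and measures its mass-weighted radius of gyration
(`max_pairwise/2` available behind a flag). Tracking ends at the first
frame where the cluster stops being one object at the cutoff — fewer than
3 points, or the largest cluster holding under 90% of that frame's
detections — because past fragmentation the largest fragment's radius
measures the cutoff, not the dispersal. The normalised inverse radius
`r(0)/r(t)`, with t = 0 at the first frame, is fitted offset-free.
`cluster_series` defaults to the 100 nm cutoff appropriate for dense
fields; the movie-tracking entry point (`track_cluster_movie`, the CLI
default) uses 400 nm, sized so a ~dozen-filament cluster spanning a few
hundred nm mid-track keeps its identity over ≥ 2 e-foldings. Recovery of
the dispersion constant through the full pipeline is typically within a few
percent, with occasional adverse seeds near the 15% band edge.

## Problem sizes and numerics

The packaged experiments use the study's sampling depth, n = 1000 molecules
per quenched population (the calibration-consistency tests use n = 4000 so
that binomial noise stays well inside the two-point comparison band), 12
filaments and 16 movie frames over 300 s, and fields of 12 molecules per
1024² frame at 2 nm/pixel. Calibration used n = 6000 with common random
numbers. All randomness descends from explicit integer seeds via
`SeedSequence` substreams (per molecule, per stage); reports are
byte-identical across reruns with the same config. Degenerate inputs are
rejected loudly: empty timepoint lists, unsorted times, centred homology
windows (which coincide with their mirror and lose positional
discrimination) warn, thresholds at or below the DNA height raise, and a
cluster series with fewer than three intact frames raises rather than fit.

## Known limitations

* One global cluster clock: no per-molecule cluster size, no coupling
  between cluster density and the number of joints formed per encounter.
* No 1D sliding or intersegmental transfer; no filament length dependence;
  temperatures are independent parameter sets with no Arrhenius structure.
* The operational category definition overpredicts the 22 °C singular
  fraction (~5% vs the printed 3.6%), and the calibrated 37 °C set sits at
  ~2.7 joints per engaged molecule against the reported "about three".
* The renderer's apparent widths come from stamping plus Gaussian
  smoothing, a serviceable but simplified stand-in for true tip–sample
  dilation; height-based RecA monomer counting is out of scope.
* Cluster-dispersion recovery assumes the cluster is the only
  filament-height object in frame apart from the backbone.
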