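# recascan

Stochastic kinetics and synthetic-AFM quantification of the RecA-facilitated
homology search on dsDNA.

## The problem

RecA polymerises on single-stranded DNA into a nucleoprotein filament that
must locate its complementary sequence somewhere on a double-stranded
genome. Atomic force microscopy (AFM) of a designed reaction — 60-nt
filaments searching an 890 bp dsDNA template that carries a single 60 bp
homologous window starting at base pair 360 (85 bp off-centre, so the
homologous site is distinguishable from its mirror image in an
end-symmetric measurement) — reveals a cooperative, two-phase landscape:

* **Association phase.** Filaments arrive in locally dense clusters, and
  several dock simultaneously onto each dsDNA as transient *synaptic
  joints*: the engaged fraction of molecules peaks above 90% within
  10 minutes, with on the order of three concurrent joints per engaged
  molecule, i.e. over 20% of the sequence space probed in parallel.
* **Resolution phase.** Association shuts off as the clusters disperse;
  heterologous joints dissociate, and only molecules whose filament found
  the homologous window retain a singular, irreversible *post-synaptic
  complex* (under the non-hydrolysable ATP analogue ATPγS these persist
  for hours).

`recascan` implements that picture end to end as a reusable pipeline:

1. **`kinetic_model`** — an exact event-driven (Gillespie-type) simulator of
   the mechanism. Per dsDNA, filaments associate at rate
   `k_assoc0 · exp(−t/τ_cluster)` (a single global clock for the dispersal
   of the local filament cloud), land uniformly over admissible footprint
   start positions with hard-core exclusion (≤ ⌊890/60⌋ = 14 joints), live
   `Exp(τ_dissoc)`, and at their terminal event convert with probability
   `p_capture` into a permanent post-synaptic complex if their footprint
   overlaps the homologous window by ≥ 30 bp. A least-squares calibration
   routine fits the free rates to printed time-course values; calibrated
   37 °C / 22 °C / heterologous presets ship with the package.
2. **`afm_synth`** — a synthetic AFM height-map generator with exact ground
   truth: 2D worm-like-chain dsDNA (persistence length 50 nm, rise
   0.34 nm/bp), bound filaments as 5-nm-high rods, Gaussian tip broadening,
   additive noise, deliberate frame-edge clipping and molecule overlap to
   exercise the inclusion filters, and HS-AFM-style movies of a filament
   cluster whose spread grows exponentially in time.
3. **`tracing`** — segmentation, skeleton-based contour tracing with the
   study's inclusion rules (both termini resolved, fully in frame, no
   overlap), and filament detection along the contour in base-pair
   coordinates.
4. **`classification`** — the three interaction categories: bare; one or
   more synaptic joints; singular filament at the homologous window (or its
   end-reversed mirror).
5. **`kinetics`** — time-courses with Wilson binomial intervals,
   offset-optional exponential decay fitting with seeded multistart, and
   cluster-dispersion analysis (single-linkage tracking, mass-weighted
   radius of gyration, decay of the normalised inverse radius).
6. **`pipeline` / `cli`** — one-config orchestration
   (`simulate → synthesize → trace → classify → fit`) and a `recascan`
   command-line tool with `simulate`, `synthesize`, `analyze`, `classify`,
   `fit-decay`, `cluster-track` and `run-all` subcommands.

## Worked example

Simulate the calibrated 37 °C reaction at n = 1000 molecules and summarise
the population at five quench timepoints:

```python
import recascan as rs

params = rs.preset("37C")
times = [300.0, 600.0, 1200.0, 1800.0, 3600.0]
snaps = rs.simulate_population(params, n_molecules=1000, timepoints=times, seed=7)
tc = rs.timecourse([rs.summarize(s, params) for s in snaps])
for p in tc.points:
    if p.category == "any_joint":
        print(f"t={p.time_s:6.0f} s  any-joint {100*p.fraction:5.1f}%  "
              f"(68% CI {100*p.ci_low:.1f}-{100*p.ci_high:.1f})")
```

```
t=   300 s  any-joint  88.3%  (68% CI 87.3-89.3)
t=   600 s  any-joint  92.2%  (68% CI 91.3-93.0)
t=  1200 s  any-joint  85.6%  (68% CI 84.5-86.7)
t=  1800 s  any-joint  71.1%  (68% CI 69.7-72.5)
t=  3600 s  any-joint  44.9%  (68% CI 43.3-46.5)
```

The engaged fraction peaks at 92% ten minutes in and falls to ~45% after an
hour, while the singular-at-homology fraction rises steadily (3.6% at
600 s → 37.6% at 3600 s in this run): the biphasic association/resolution
signature. The heterologous control isolates the joint-lifetime decay, and
a synthetic HS-AFM movie exercises the cluster-dispersion estimator:

```python
het = rs.preset("heterologous")          # association off, joints seeded
snaps = rs.simulate_population(het, 1000, [300, 600, 1200, 1800, 2700, 3600],
                               seed=7, initial_joints_per_molecule=1)
occ = [sum(1 for js in s.molecules if js) / s.n_molecules for s in snaps]
fit = rs.fit_decay([300, 600, 1200, 1800, 2700, 3600], occ, seed=7)

cfg = rs.ImageConfig()
frame_times = [float(t) for t in range(0, 301, 20)]
frames, truth = rs.generate_movie(12, 94.0, frame_times, cfg, seed=7)
series, cfit = rs.track_cluster_movie(frames, frame_times, cfg, seed=7)
print(fit.tau_s, cfit.tau_s, rs.dispersion_ratio(fit, cfit))
```

```
heterologous joint decay: tau = 581 s (rms 0.0104)
cluster dispersion:       tau = 102 s over 9 frames
ratio = 5.70
```

The joint population decays with a ~580 s time constant; the filament
cluster disperses about six times faster (~100 s) — the dispersal of the
locally enhanced filament concentration is what switches the association
phase off. The same computations are available from the shell:

```bash
recascan simulate --preset 37C --n 1000 --times 300,600,1200,1800,3600 \
         --seed 7 --out out/sim
recascan synthesize --mode movie --tau-cluster 94 \
         --frame-times 0,20,40,60,80,100,120,140,160,180,200 \
         --seed 7 --out out/movie
recascan cluster-track --movie out/movie/movie.tif \
         --frame-times 0,20,40,60,80,100,120,140,160,180,200 \
         --seed 7 --out out/cluster_fit.yaml
```

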