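# Methods

`cellagg` models the formation of cell aggregates on soft hydrogels at
two levels: a spaceless Smoluchowski (perikinetic) description of the
aggregate-count kinetics, and an off-lattice agent-based model (ABM)
that additionally captures aggregate morphology, compaction and
proliferation.  A measurement layer converts simulated configurations
into the two observables recorded in time-lapse experiments — the
normalized number of aggregates and their mean projected area — so that
simulations and experiments are quantified identically.

## The agent-based model

Cells are disks of fixed diameter `d` on a 2D square with periodic
boundary conditions.  The observed field in the experiments this model
targets is a 1280 × 1080 px camera frame at 0.658 µm/px; the simulation
box side equals the frame width, 842.24 µm.  Periodic boundaries are
essential: the field of view is a small window on a much larger
substrate, and walls would distort aggregation.  One iteration
represents one minute.

Per iteration, in order:

1. **Aggregate identification.** Aggregates are connected components of
   the contact graph (two cells are in contact when their minimal-image
   center distance is at most `d`; tolerance 1e-6 µm).  Membership is
   frozen for the iteration.
2. **Collective motion.** Each aggregate of `N >= 2` cells performs one
   rigid translation of length `a0/N` — a cluster of N cells diffuses N
   times slower than a single cell — in a random direction (restricted
   to the flux half-plane when the flux bias applies to aggregates).
   The translation is truncated at first contact with any non-member
   cell, using the earliest ray–circle intersection over all
   member–outsider pairs.
3. **Individual motion.** Cells are visited in a fresh random
   permutation.  A cell with `n` current neighbors steps `a0/(1+n^2)`
   (adhesion slows motion inside aggregates) in a direction drawn:
   uniformly for an unbiased individual cell; in the half-plane around
   the flux direction for an individual cell under flux; in the sector
   of half-width `90(1+e^(-N/40))` degrees centered on the direction to
   the aggregate's center of mass for an aggregate member when the
   compaction rule is on (the sector shrinks from the full circle for
   tiny clusters to a half-plane for massive ones).  The step is
   truncated at the first position where some center pair would reach
   the minimum distance `dmin = d(1-alpha_max)` (adhesion on contact;
   optionally the whole step is cancelled instead).  A move that would
   leave the cell with fewer contacts than before is cancelled — cells
   do not detach.
4. **Proliferation.** After moving, each cell divides with probability
   `kappa` per iteration; a single candidate daughter position is drawn
   at distance `d` and uniform angle, and the division is aborted if it
   violates `dmin` against any cell.  Daughters do not move or divide in
   their birth iteration (a negligible shift of the effective rate).

The superimposition coefficient `alpha_max` in [0, 1) is a 2D effective
stand-in for cell deformability and 3D stacking: it allows centers to
approach down to `d(1-alpha_max)`.  The hard-core constraint (no pair
below `dmin - 1e-9` µm) is an invariant checked in tests at every
sampled state.

### Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| `n_initial` | seeded cells | count | required (figure presets: 100–900) |
| `cell_diameter` | disk diameter | µm | 13.2 (F98); 21.1 (U87) |
| `step_length` | free-cell step per minute | µm | 3.948 (= 6 px) |
| `alpha_max` | max pairwise overlap fraction | — | 0.7 (F98); 0.2 (U87) |
| `proliferation_rate` | division probability/min | 1/min | 7e-4 (F98); 3e-4 (U87) |
| `compaction_enabled` | center-of-mass motion bias | flag | on (F98); off (U87) |
| `flux` | half-plane drift bias | spec | off; on for non-adhesive gels |
| `box.side_length` | periodic box side | µm | 842.24 |

The flux scope defaults to individuals and all aggregates; a variant
restricted to individuals plus aggregates of at most `small_threshold`
cells (default 10, not quantified in the source experiments) is
selectable.

### Design choices where the rules leave freedom

* **Neighbor metric.** "Neighbor" is defined as center distance <= `d`
  (touching disks) — the only scale-free choice consistent with
  adhesion-on-contact.
* **Order of the two motion components.** The rigid aggregate move is
  applied before individual updates, with membership frozen; this keeps
  the hard-core constraint satisfiable and the trajectory reproducible.
* **Neighbor counts** for the step length and the no-detach rule are
  recomputed from current positions as cells move sequentially.
* **Compaction vs flux for aggregate members:** the compaction sector
  wins; flux acts on the collective move and on individual cells.
* **Center of mass under periodicity** uses the per-axis circular mean
  (map each coordinate to an angle, average unit vectors, map back).
  For clusters of extent much smaller than the box — always the case
  here — it agrees with the minimal-image arithmetic mean to
  O((extent/L)^2 · extent); the residual (~1e-3 µm for a 10-µm cluster
  in a 100-µm box) only perturbs the direction of an already-random
  bias.
* **Initialization** places cells i.i.d. uniformly and resamples any
  cell violating `dmin` (up to 1e6 draws, then an error reporting the
  achievable density).  Randomly placed cells may legitimately start in
  contact, so the aggregate count at t = 0 can be slightly below
  `n_initial`.
* **Determinism.** One seeded NumPy generator drives placement, the
  per-iteration permutation, all direction draws and division in a fixed
  order; identical config + seed gives bit-identical trajectories and
  byte-identical CSV output (9 significant digits).
* **Numerical safety.** Truncated travels are backed off by 1e-9 µm so
  roundoff cannot push a pair below `dmin`; contact tests use a +1e-6 µm
  tolerance so exactly-touching pairs register as neighbors.

## Measurement

Simulated positions are rasterized exactly like the experimental frames:
a pixel is foreground when its center lies within one cell radius of a
cell center (through periodic images).  The viewport is the frame's
1280 × 1080 px rectangle: the full box width and the first 1080 rows
(the crop used when analyzing simulations like experiments is not
specified beyond the frame size; anchoring at the box origin is the
convention chosen here).  Components are labeled with 8-connectivity
(the particle-analyzer default; 4-connectivity is switchable), with an
optional minimum-area filter (default: none, consistent with the
normalized count starting at 1 for separated cells).  Per frame the
aggregate count (singletons included), the count normalized by
`n_initial`, and the mean component area (px² and µm²) are reported.
Counts from the raster can merge clusters whose disks do not touch but
whose pixel masks do; the graph-theoretic and raster counts agree
whenever inter-cluster gaps exceed ~2 px.

The diffusion coefficient of isolated cells is estimated from tracks
unwrapped by accumulating minimal-image displacements: MSD(t) is fitted
through the origin over the first half of available lags and D =
slope/4.  For the model's fixed-step random walk, MSD(t) = a0²·t, so
D = a0²/4 per minute.

## The spaceless model

The size spectrum `N_k` obeys the coagulation equation
`dN_k/dt = 1/2 Σ_{i+j=k} K_ij N_i N_j − Σ_i K_ik N_i N_k`.  Two kernels
are implemented:

* **Constant kernel.** The rate `K` is defined by the total-count
  equation `dN/dt = −K N²`, i.e. `N(t) = N0/(1+K N0 t)`; in the
  size-resolved equation this corresponds to entries `K_ij = 2K`
  (summing the general equation over k with entries `K` gives
  `−K N²/2`).  The two conventions coexist in the literature; defining
  `K` on the closed form makes the fitted rate directly comparable to
  published values.
* **Monomer-only kernel.** `K_1j = K_j1 = K1`, zero otherwise: only
  individual cells move and react.  The k-resolved system is
  `dN1/dt = −K1 N1 N`, `dN2/dt = K1(N1²/2 − N1 N2)`,
  `dNk/dt = K1 N1 (N_{k−1} − N_k)` for k >= 3.  The dimer source sign
  and the `N1` in the monomer equation are fixed by requiring the sum
  over k to telescope exactly to `dN/dt = K1 N1 (N1/2 − N)` (verified
  numerically to 1e-10 at random states) and by agreement with an exact
  Gillespie stochastic oracle.

Integration uses LSODA at rtol 1e-8 on a spectrum truncated at `kmax`
(default 256); flux into sizes beyond `kmax` is dropped, the lost mass
is monitored, and `kmax` doubles automatically when it exceeds 1% over
the integration horizon.  Rates are carried per count per minute and
converted to area units by multiplying by the observed-field area
842.24 × 710.64 µm² (1 µm²/min = 1e-12/60 m²/s); the area normalization
convention is configurable since published rates are reported in
m²/s without stating it.

Kernel fitting minimizes the unweighted SSE on counts over the single
rate (log-spaced bracket, then bounded scalar minimization); model
selection fits both kernels and returns the lower SSE, ties going to the
constant kernel.

## Calibration workflow

The fitting procedure mirrors how the published parameters were set: the
step length is driven by the decay of the aggregate count, the
proliferation rate by the late-time mean area, and the flux switch by
whether the count keeps decreasing late.  Visual matching is formalized
as `w_n Σ Δn_norm² + w_a Σ (Δarea/area_scale)²` with `area_scale` the
reference's initial mean area, evaluated on an exhaustive grid with R
replicate simulations per point (replicates seeded `base_seed + i`).
`alpha_max` is not fitted — it is set per cell line from images of
two-cell overlaps — and ties break toward smaller step, then smaller
rate.

Synthetic references are generated by the same pipeline from known
parameters (>= 3 replicates, mimicking the triplicate experiments),
with optional multiplicative Gaussian noise, and carry their generating
parameters as provenance.  `recovery_report` closes the loop: on such
references the grid search recovers the step length to within one grid
step and the proliferation rate to within a factor two (checked in the
test suite).

## What the synthetic data does and does not emulate

Synthetic references reproduce the statistical structure of the
experimental curves (time grid, replicate mean and dispersion, the two
observables) but come from the same model family being fitted, so
recovery tests demonstrate identifiability of the procedure — not the
adequacy of the disk-cell model for real cells.  Real micrograph
segmentation (thresholding DIC images) is out of scope; the measurement
stage starts from simulated rasters.  The published experimentally
fitted values (kernel rates 2.6e-13 / 6.4e-14 m²/s; per-experiment step
lengths) derive from experimental curves available only as figures and
are used here as preset configurations, not as recovery targets.

## Problem sizes used in the test suite

Full-scale runs (e.g. 784 cells, 720 iterations, 20 replicates) take
tens of seconds each; the suite uses density-preserving reductions —
box side and cell number scaled together (64 cells in a 240.64 µm box,
196/121 cells in a 421.12 µm box for the substrate contrast, 300 cells
in a 326.2 µm box at the elevated compaction density) with 4–8
replicates — chosen because the properties under test (hard-core
invariance, merging monotonicity, the substrate and compaction
contrasts, parameter recovery) are controlled by density and dynamics,
not by absolute system size.

## Known limitations

* Cells are non-deformable disks; polarization, shape and chemotaxis
  are absent by design, and 3D stacking is collapsed into `alpha_max`.
* No fragmentation: detachment is neglected, so the model cannot
  represent unstable aggregates.
* Aggregate identity is not tracked across frames (no merge lineage).
* The spaceless model describes only the aggregate count; it cannot fit
  the mean-area curve.
* Very high densities (area fraction near close packing) make
  rejection-sampling initialization fail; the error reports the
  achievable density.
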