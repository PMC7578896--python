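# Methods

## The model

`chromoswitch` studies how a chromosome's 3D organization rearranges when a
cell changes state (e.g. a stem cell differentiating into a somatic cell,
or the reverse reprogramming), using only the two states' Hi-C contact
maps as input.  The approach has three layers:

1. **Maximum-entropy restrained polymer.**  Each cell state's binned
   contact-probability map `f_ij` is imposed on a generic coarse-grained
   polymer (one bead per genomic bin) as the minimal-bias restraint
   `V = V_polymer + Σ_ij α_ij w(r_ij)`, where `w` is a smoothed contact
   step and the couplings `α_ij` are iterated until the simulated contact
   probability `P_ij = ⟨w(r_ij)⟩` matches `f_ij`.  The fitted potential is
   an effective energy landscape for that cell state.
2. **Landscape switching.**  A non-equilibrium cell-state transition is
   idealized as an instantaneous replacement of one fitted landscape by
   the other (velocities retained), followed by relaxation under the new
   landscape.  The excitation models the energy input (e.g. ATP-driven
   remodeling) that breaks detailed balance in the real process.
3. **Analysis stack.**  Relaxation trajectories are summarized by
   contact-map differences and stage clustering, P(s) scaling exponents,
   A/B compartment profiles (O/E → ICE → correlation → PCA), Crane
   insulation-score TAD boundaries, gyration-tensor shape descriptors,
   fractions of native contacts, radial density profiles, MSD exponents,
   and k-means kinetic classes with exponential relaxation times.

## Polymer and reduced units

Beads have unit mass; energies are in units of the reduced temperature
T = 1, lengths in units of the bond length b = 1.  The force field is

* harmonic bonds, `½ k (r − b)²` with `k = 100`;
* a soft-core repulsion `u(r) = E_cap (1 − (r/σ)²)²` for `r < σ`
  (`σ = 1.1`, `E_cap = 4T`), finite at overlap so strands can cross —
  an effective, always-on topoisomerase activity;
* optional restraints `α_ij w(r)` with `w(r) = ½(1 + tanh(η(r_c − r)))`,
  `r_c = 1.5 b`, `η = 5/b`, on pairs `|i − j| > 1` (adjacent pairs are
  held by bonds; their contact probability is 1 by convention).

No angle or confinement terms: all large-scale shape comes from the
fitted restraints.  Dynamics are BAOAB Langevin with `dt = 0.01` and
friction `γ = 0.1` (defaults; every parameter is config-exposed).  The
trajectory time unit is `τ = 1000` integration steps.  The tanh tail is
truncated where `η(r − r_c) > 12` (`w < 4e−11`), far below every
tolerance used.  Mapping reduced units to nanometers/seconds is out of
scope; all kinetics are reported in multiples of τ.

The integrator was validated against equipartition (kinetic energy per
degree of freedom within 1% of T/2), the T = 0 gradient-descent limit
(total energy non-increasing), free diffusion (MSD exponent 1), ideal
random-walk chain statistics, and a central-difference check that forces
are the exact negative gradient to better than 1e−6 relative.

## Maximum-entropy fit

The update rule is the standard first-order proportional scheme:
`α_ij ← α_ij + lr (P_ij − f_ij)` on non-excluded pairs, clipped to
`|α| ≤ 10 T`.  A positive α penalizes an over-formed contact.

Convergence at desk scale needs care.  The long-range entries of `f` are
tiny (≈`s^a` at separation s), so their gradients are tiny, while the
ensemble estimate `P` carries sampling noise; and the chain's structural
relaxation time (tens of τ for a 200-bead globule) exceeds any affordable
per-iteration window, so naive short-window iteration calibrates the
couplings against a lagging transient ensemble — the resulting field
over-collapses the chain once it is allowed to equilibrate.  Two choices
address this, both pure sampling/optimization choices that leave the
model unchanged:

* **Annealed schedule.**  Default `((25 iters, 1 τ window, lr 8),
  (15 iters, 2 τ window, lr 3))`, with measurement frames taken only from
  the second half of each window.  Early rounds shape the couplings
  quickly; late rounds measure closer to equilibrium with a damped rate.
  The rate is halved whenever the deviation jumps >25% in one iteration
  (overshoot), and the fit aborts if the deviation grows five iterations
  running to twice its best value.
* **Fit-time friction 0.05.**  Equilibrium averages do not depend on the
  Langevin friction; halving it halves the chain relaxation time per
  integration step, so each window samples closer to equilibrium.
  Kinetic analyses (switching, MSD) use the model's own friction.

Sixteen persistent replicas are advanced with warm restarts each
iteration; the returned production ensemble is sampled at stride τ after
the last update.  Validation: fitting a 200-bin power-law target with
decay exponent −1.5 reaches Pearson ≈ 0.98 between `P` and `f`, the
production-ensemble P(s) slope reproduces the generating exponent within
a few hundredths, and the slope is stationary (within sampling noise)
over a further 30 τ of simulation under the frozen field — i.e. the
field's equilibrium, not a transient, matches the target.  The
convergence tolerance (mean |P − f| ≤ 0.005) sits below the desk-scale
sampling noise floor (~0.01 with ~160 frames per iteration), so desk
fits terminate on the schedule; the `converged` flag is therefore
conservative.

## Switching protocol

Initial structures are selected by average-linkage hierarchical
clustering of equilibrium conformations by contact-map distance
(mean |w_a − w_b|); clusters with population > 0.3% contribute two
members each (the full-scale defaults are 2400 sampled conformations and
hundreds of trajectories; tests and the demo pipeline scale these down
proportionally).  Each trajectory equilibrates ~10 τ under the source
landscape, the potential is replaced in a single step with velocities
retained, and the chain relaxes under the destination landscape with
frames recorded on a log-spaced schedule (default 20/decade) whose
origin is the switch instant.

## Synthetic data: what it emulates and what it does not

The generator composes the three signatures the analyses key on — a
power-law P(s) backbone with a state-specific exponent (−1.5
stem-cell-like vs −1.0 differentiated-like), shared block TADs, and a
plaid compartment pattern — multiplicatively:
`f_ij = min(1, c·s^a · m_comp · m_tad)` with
`m_comp = 1 ± plaid_strength` (same/different compartment label),
`m_tad = 1 + tad_strength` (same TAD), and `c` set so the backbone is
0.5 at s = 2.  Compartment labels form alternating A/B runs with
geometric block lengths (mean 20 bins); TAD sizes are uniform in
9 × (1 ± 0.25) bins, i.e. 7–11 bins at the emulated 100-kb resolution —
TAD-scale blocks that a 500-kb insulation window can resolve (a 5-bin
window provably merges domains closer than ~7 bins).  Between the two
states of a pair, whole compartment blocks are flipped in random order
until the requested fraction of switched bins is reached, mirroring
switching in TAD-sized units; TAD boundaries are shared.

Not emulated: read-level noise, coverage/mappability bias, replicate
structure, inter-chromosomal contacts, and real gene-density phasing of
compartments (the PC1 sign is fixed against ground-truth labels instead).
Passing the recovery suite therefore shows the pipeline is correct on
maps with the assumed statistical structure, not that it is robust to
experimental artifacts.

## Analysis conventions

* **Bin convention.**  Inclusive fence-post: `[start, end]` at bin size w
  has `(end − start)/w + 1` bins (so chr14:20.5–106.1 Mb at 100 kb is
  857 bins).  Emitted BED/bedGraph are standard 0-based half-open.
* **Map normalization.**  Raw maps are divided by the mean of the first
  off-diagonal, clipped at 1; the diagonal and first off-diagonal are set
  to 1 (adjacent loci always in contact).
* **ΔP matrices.**  `Δ^{I,J} = Σ|P^I − P^J| / Σ P^I` over a
  genomic-distance filter (total, local < 2 Mb, non-local > 2 Mb).  The
  normalization makes Δ asymmetric; a symmetrized mean is used for
  clustering and a min–max rescaled copy for display only.
* **Stages.**  Average-linkage trees of the local and non-local
  symmetrized Δ are cut (independently) at the smallest cluster counts
  whose joint membership changes partition the time axis into exactly the
  requested number of contiguous runs; if no cut pair achieves it, the
  error names the nearest feasible count.  Default 7 stages,
  parameterized.
* **Compartments.**  O/E enhancement (observed over the mean at the same
  separation), ICE balancing (row sums equalized to the stated tolerance;
  all-zero rows dropped with a warning and re-inserted as missing),
  Pearson correlation matrix, covariance-based PCA without column
  standardization; A is PC1 > 0 after flipping the sign to correlate
  positively with a reference profile (ground-truth labels for synthetic
  data).  Compartment calling runs at 10× coarsened resolution (1 Mb for
  100-kb maps).  A map with no enhancement structure (relative spread
  < 1e−9 after balancing, e.g. a pure power law) yields an identically
  zero profile rather than amplified floating-point noise.
* **Insulation/TADs.**  Per bin, the mean contact level in the
  window×window square strictly off-diagonal (default 5 bins = 500 kb),
  log2-normalized by its chromosome-wide mean; edge bins inside the
  window get no score.  The delta vector is the left-minus-right flanking
  mean of the score; boundaries are downward zero crossings whose nearest
  left delta maximum minus right delta minimum exceeds 0.1.  Boundary
  matching allows ±1 bin.  Finite chains carry a real insulation gradient
  within roughly three windows of each end (terminal segments are less
  crowded than interior ones), which can produce boundary-like crossings
  there even for a featureless chain; on chromosome-sized chains this end
  region is a negligible fraction, and validation checks that exclude it
  say so explicitly.
* **Shape.**  Mass-uniform gyration tensor; asphericity
  `Δ = [(λ1−λ2)² + (λ2−λ3)² + (λ3−λ1)²] / [2(λ1+λ2+λ3)²]`; principal-axis
  extensions are max-minus-min projections on the eigenvectors.  (For
  equal masses the inertia and gyration tensors share eigenvectors, and
  this Δ is the standard shape measure.)
* **Q.**  Fraction of category pairs (by genomic separation, excluding
  |i−j| ≤ 1) with `r_ij < 1.2 ×` the reference ensemble's mean pairwise
  distance; 1.2 is the usual native-contact tolerance from the folding
  literature, config-exposed.
* **Radial density.**  Histogram of |r_i − r_cm| pooled over frames, each
  group normalized to unit integral; by default radii are divided by the
  frame's Rg so differently compacted states are comparable (an
  unnormalized variant is available).
* **MSD / β.**  MSD is averaged over trajectories, time origins, and
  interior beads (5% of the chain excluded at each end), with
  displacements measured in the chain's center-of-mass frame: a nucleus
  cages a chromosome's center of mass, so the caged frame — not the
  freely diffusing one of an isolated simulated chain — is what
  locus-tracking experiments observe (COM removal is switchable).  β is
  the log-log slope over an intermediate lag window, default 1–30 τ.
  The window choice matters: below ~1/γ the dynamics are inertial, and
  beyond the chain relaxation time finite-size saturation sets in.  MSD
  production runs therefore use γ = 1 so the default window is fully
  overdamped; the window and friction are config-exposed and every fit
  reports its window.
* **Exponential fits.**  `y(t) = y_∞ + (y0 − y_∞) e^{−t/τ_r}` by
  nonlinear least squares with `y_∞` free; constant series are flagged
  degenerate rather than fitted.  k-means (k = 4 default, k-means++ with
  50 restarts, seeded) clusters per-locus compartment time courses before
  fitting per-cluster means.

## Problem sizes

Desk-scale defaults were chosen so the full validation suite and the
reproduction script each run on one CPU in well under half an hour:
fits use n = 200 bins (the headline scaling/kinetics numbers) or n = 60
(switching ensembles), 16 replicas, and the schedule above; switching
ensembles use 12 trajectories per direction over ~30 τ; MSD runs use
5–6 trajectories of 80–100 τ.  The full-scale parameters (857 beads,
2400 sampled conformations, 354/226 trajectories, 10³–10⁴ τ) are the
package defaults where they appear in `switching` and are documented in
the config; they require cluster-scale compute.

## Known limitations

* The maximum-entropy solution is not proven unique; the fit reports
  deviation and correlation trajectories so stalled or oscillating fits
  are visible.
* Desk-scale ensembles leave ~1% absolute sampling noise in P; long-range
  couplings are accurate only in aggregate (P(s), compartments), not
  pairwise.
* The instantaneous switch is an idealization; finite-rate excitation and
  multi-landscape cascades (intermediate cell states) are out of scope.
* Stage boundaries from hierarchical clustering are sensitive to the
  recording schedule's density near the switch.
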