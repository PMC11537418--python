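# Methods

This note documents the models and procedures implemented in `ca1forge`,
the defaults they ship with, and the boundaries of what the synthetic
test-bed can and cannot show.

## Parametric atlas coordinates

A voxelized region mask is annotated with three coordinates in [0, 1]:
longitudinal `l`, transverse `t`, radial `r`.  The construction follows
the anatomy of curved laminar structures:

1. **Smoothing.** The raw mask is Gaussian-filtered (σ in µm,
   re-thresholded at 0.5) and morphologically closed.  The result is
   unioned with the morphologically opened input so that denoising cannot
   erode genuine structure (a sharp convex corner survives unchanged);
   only the largest connected component is kept.  σ and the closing
   radius are configuration, defaulting to one voxel each — small enough
   to preserve a clean input exactly, large enough to remove
   salt-and-pepper voxel noise.
2. **Centerline.** Dijkstra's algorithm on the 26-connected voxel graph
   with edge weight step / (d + ½voxel)², where d is the Euclidean
   distance transform, pulls the path onto the interior ridge between two
   user-supplied seed points.  The quantized path is subsampled and fitted
   with a smoothing cubic spline (residual budget of ~1 voxel per control
   point); the spline is reparameterized by arc length.
3. **Coordinates.** One cross-section plane per voxel of arc length is
   erected perpendicular to the centerline; each voxel joins the plane
   with the smallest out-of-plane offset among its nearest candidate
   planes (this is robust to residual centerline wiggle, which defeats
   pure nearest-anchor assignment).  Within a plane, the two boundary
   shells are resampled into matched polylines parameterized by u ∈ [0, 1]
   (ordering along the leading principal component of each shell
   separately — the union's principal component would be dominated by the
   radial separation).  A voxel takes `t` from the nearest lower-to-upper
   connecting segment and `r` as its relative position along it; `r` = 0
   on the lower (stratum-oriens) shell.  The transverse sign is fixed by
   requiring (tangent, transverse, radial) to be right-handed, which makes
   the whole construction covariant under rigid rotation — verified by
   rebuilding after a 90° grid rotation.
4. **Shells as input.** Separating the boundary into upper and lower
   shells is taken as an input rather than automated: on strongly curved
   ridges automatic separation is unreliable, and the fixtures generate
   shells analytically.
5. **Direction vectors** are the normalized gradient of `r` (Gaussian
   pre-smoothing of 1.5 voxels suppresses voxelization staircase;
   zero-gradient voxels inherit their nearest neighbor).  The coordinate
   build additionally stores the exact connecting-segment directions.
6. **Layers.** Cumulative fractions of `r` (defaults from mean laminar
   thicknesses SO 168, SP 59, SR 279, SLM 146 µm → 0.258 / 0.090 /
   0.42791 / 0.224) label each voxel SO/SP/SR/SLM from the lower shell
   upward.  Printed, rounded proportions are renormalized if they miss
   1.0 by ≤ 10⁻³.

Tolerances met on analytic fixtures: slab `r` exact to < 0.02, quarter
annulus (inner 40, outer 60 voxels) `r` within 0.05 and directions within
5° of the cylindrical radial field.  The annulus fixture is 24 voxels
tall so that the mid-radius ridge, not the axial faces, dominates the
distance transform.

## Morphology library

Morphologies are rooted typed trees (SWC).  Curation recenters the soma,
removes zero-length segments, corrects shrinkage (default +25 % z,
+10 % x/y) and flags axon-less cells.  Cloning applies isotropic scaling
(|s| ≤ 0.15) about the soma plus seeded per-branch jitter — rotations
~N(0, 0.1 rad) about the parent direction and length factors
~N(1, 0.05); the exact jitter law is a modeling choice, exposed as
configuration.  Cloned pyramidal axons are re-aligned by rotating the
axon point cloud's first principal component onto +x (caudal side to
positive x); clones whose axonal z-range exceeds 3.3× the original are
rejected.

Validation uses two instruments:

* **MVS score** |median(A) − median(B)| / OVS(A, B), with scores < 0.3
  read as good agreement.  OVS ("overall visible spread") is implemented
  as the width of the union of the two populations' boxplot whisker
  intervals [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; the function is pluggable since
  "visible spread" admits several formalizations, and the score's
  sample-size dependence enters exactly through it.
* **Topological persistence** of each neurite under the radial filtration
  (Euclidean distance from the soma surface, radius subtracted, floored
  at 0).  Components are born at tips and merge by the elder rule — the
  farther-reaching branch survives — so each leaf yields one
  (start, end) bar and the surviving stem component dies at the soma.
  Persistence images are normalized Gaussian-kernel densities of the
  bars; population images subtract on a shared grid.

## Composition and placement

The pyramidal count is density × SP volume (264 × 10³ /mm³ × 1.5789 mm³ →
416,830 cells at full scale; the toy circuits use desk-scale counts).
Interneuron relative abundances are rescaled so inhibitory cells are 11 %
of the population (E:I = 89:11).  Somata are placed per m-type with
multinomial voxel allocation (weights ∝ density × voxel volume, total
conserved exactly); axo-axonic-restricted types keep their default
sub-bands (SCA mid-SR ± 5 %, PPA lower 2–10 % of SLM).

Orientation aligns each cell's local y-axis with the radial direction;
interneurons get a seeded uniform spin about it, pyramidal cells point
their PCA-aligned axon along the local transverse direction toward the
distal end (negative t-gradient).

Morphology choice scores every candidate against placement rules.  Each
rule compares the morphology's annotated interval (shifted by the soma
position) with a target interval along the local radial axis:
I = max(overlap / wider interval, 0).  Optional rules aggregate as a
harmonic mean (zero if any optional score < 0.001): low scores are
punished harder than by an arithmetic mean, yet one weak rule can be
rescued by strong ones.  Strict rules aggregate as a minimum; the total
is the product.  Candidates are sampled with probability ∝ score
(argmax with seeded tie-break available); positions whose candidates all
score zero are dropped and counted, with a warning above 5 % dropped.

## Connectome synthesis

Appositions are near-contacts between presynaptic axon segments and
postsynaptic neurites at maximum touch distances of 1.0 µm onto
pyramidal cells and 6.0 µm onto interneurons, measured to the
postsynaptic *surface* (the soma counts with its radius; dendritic radii
are negligible at these thresholds).  Admissibility: axo-axonic cells
contact only the pyramidal axon initial segment (first 60 µm of axon
path, configurable); PC→PC contacts avoid somata; SCA/Ivy/bistratified
cells avoid PC somata; everything else may target dendrites and somata.
Candidate pairs come from axis-aligned bounding-box overlap; distances
use the exact closed-form segment-segment minimum, and the test suite
keeps an independent brute-force oracle.

Expected synapses/connection are predicted from appositions/connection by
the two linear fits 0.1096·x (inhibitory→inhibitory) and 1.1690·x
(all other pathways).  Pruning is two-stage and only removes synapses:
(1) within-connection binomial thinning at p = target/current mean (one
correction pass for the truncation of emptied connections); (2) per-axon
bouton-density targets drawn from a gamma distribution with the
prescribed mean and CV (default 0.50), using 1.15 synapses per bouton to
convert counts — realized synapse counts are divided by 1.15 before
density comparison.  Infeasible targets keep everything and flag the
pathway.  The exact functional forms of the original pruning algorithm
are not public; this minimal structure satisfies the two published
constraint families and is the package's own design.

## Afferent (Schaffer-collateral) projections

Presynaptic CA3 cells are virtual fibers.  Convergence targets are
midpoints of the reported ranges (pyramidal 20,878, interneuron 12,714
synapses at full scale; toy circuits use scaled-down targets).  Total
synapses per postsynaptic class are split across layers by the laminar
distribution (SO 24.7 %, SP 7.1 %, SR 67.9 %, SLM 0.3 %) with
largest-remainder integer rounding; quota for layers the (small) circuit
does not reach is redistributed proportionally.  Target segments are
drawn with replacement, weighted by segment length, with uniform offsets;
somata are excluded.  Fibers are assigned uniformly at random, so most
connections carry a single synapse when fibers are plentiful.  The
workflow runs separately for pyramidal and interneuron targets.

## Synapse physiology

Release follows the stochastic Tsodyks–Markram model with a vesicle pool:
utilization u obeys u_k = U + u_{k−1}(1 − U)·exp(−Δt/τ_facil) (u = U at
the first spike); each of the N_RRP vesicles, if recovered, releases
independently with probability u_k and re-enters recovery with an
exponential τ_rec clock.  Because u is deterministic given the spike
train and vesicles are independent, the expectation obeys the classic
deterministic recursion in u·x exactly — that recursion is the oracle for
the Monte-Carlo tests (3σ at 10⁴ trials).  Released quanta drive
difference-of-exponential conductances normalized to peak g_max per
vesicle.

Modulation scales U_SE multiplicatively:

* **Calcium**: Hill function of extracellular Ca²⁺ normalized to 1 at
  2 mM, exponents 4/3/2 for steep/intermediate/shallow profiles with
  half-concentration 2.3 mM.  These three exponents and the Kd are
  stand-in defaults exposed as configuration — the published coefficients
  are not in the public text.
* **Acetylcholine**: the factor 1 / (1 + (ACh/4.541)^0.576) (→ 1 at zero
  concentration, 0.5 at 4.541 µM), applied to every pathway including
  afferents; in network simulations ACh additionally injects
  0.567·ACh^0.436/(100^0.436 + ACh^0.436) nA of somatic current into
  every cell.  The saturation (0.567 nA) and half-effect points are the
  package's checkable constants.

Afferent parameters not available from paired recordings are fitted by an
alternating two-step grid search: step 1 scans (g_max, N_RRP) against
amplitude/CV targets, step 2 scans AMPA (τ_rise, τ_decay) against
kinetics targets, iterating until both optima are stable; the cost is the
sum of relative errors Σ|x_mod − x_exp|/x_exp.  PSP features (amplitude,
10–90 % rise, half-width, decay τ from an exponential fit of the falling
phase) feed the targets; traces without a deflection ≥ 5 baseline SDs are
flagged rather than fitted.

## Stimuli

Poisson trains use exponential gaps (homogeneous) or Lewis–Shedler
thinning (inhomogeneous; exact for bounded rates).  The sinusoidal rate
is m·(1 + sin 2πft) — offset equals amplitude so the rate touches zero;
an independent-amplitude variant exists because the source description is
ambiguous on clamping.  Phase-histogram rates circularly smooth a
discharge-probability histogram, map phase to time at the requested
frequency and normalize to a requested mean.  Septal disinhibition is
I(t) = −A + A·sin(2πft) (mean = −amplitude, never depolarizing, default
8 Hz); tonic depolarization is a percentage of each cell's rheobase.

## Surrogate network

The simulator is explicitly a stand-in: adaptive exponential
integrate-and-fire point neurons per e-type replace multicompartment
models, so all network-level statements are property-level (directions of
effects, orderings, curve shapes), never quantitative matches to detailed
tissue models.  With Δ_T = 0 the model is leaky integrate-and-fire, whose
closed-form rheobase g_L(V_th − E_L) anchors the bisection test; rheobase
search halves a bracket to 10⁻³ nA and returns the upper bound, so the
cell is guaranteed to spike at the reported value.  Integration is
fixed-step Euler (0.1 ms default); synaptic state updates are vectorized
with per-step binomial vesicle recovery (the discretization of the
exponential clock).  The extracellular proxy sums per-cell net synaptic
currents with 1/(4πσd) weights (σ = 0.3 S/m, d floored at 10 µm) — a
point-source approximation that preserves dipole-vs-monopole decay but
not the true current-source geometry of extended dendrites.

Toy circuits add per-cell threshold jitter (±2.5 mV uniform) because a
population of identical neurons produces an unrealistically step-like
input–output curve.  Afferent unit conductances are desk-scaled (weak per
contact, since the toy carries ~500× fewer afferent synapses per cell
than tissue); the slice input–output protocol calibrates a global
afferent gain so that activating 100 % of the fiber pool discharges all
sampled neurons, defining the 100 %-input/100 %-output point.  Under this
calibration, feedforward inhibition linearizes the input–output curve
(higher Pearson correlation with input fraction in control than with
GABAergic synapses disabled), and disabling inhibition raises excitatory
spike counts in paired-seed volley experiments.

## Analysis

All filters are zero-phase forward-backward 6th-order Butterworth so
phase analysis downstream sees no group delay.  The 2 kHz extracellular
signal splits at 400 Hz into LFP and high-frequency parts; the LFP is
detrended, downsampled to 400 Hz (polyphase), and band-filtered into
delta 1–3, theta 4–12, gamma 30–120 Hz.  PSDs are multitaper (DPSS, NW
from the 1.5 Hz resolution, K = 2NW − 1 tapers; Parseval holds within
5 %).  Spectrograms use complex Morlet wavelets, n_cycles = 7, 1–150 Hz
in 0.25 Hz steps, in dB with a −300 dB floor.  CSD is a regularized
second spatial derivative (Savitzky–Golay across ≥ 5 channels; direct
differences otherwise); positive values mark sources.  Full kernel-based
CSD is intentionally out of scope — the regularized derivative satisfies
the defining checks (constant for quadratic profiles, zero for linear,
dipole localization within one channel).

Spike phases come from the analytic-signal angle of the theta band with
the trough at 0°; per cell the resultant vector gives preferred phase and
locking strength and the Rayleigh test (z = nR² with the standard series
correction, cross-checked against an independent implementation) decides
significance; cells under 10 spikes are excluded.  The waveform asymmetry
index is log(t_rise/t_decay) per cycle on the 1–80 Hz signal with
peaks/troughs by z-score threshold (default |z| > 1; the source threshold
is unstated).  Pure sines score 0 ± 0.05; a 1:3 sawtooth scores
log(1/3) ± 0.1 — the residual bias comes from band-limiting the
discontinuity, which is why the reference test uses a low fundamental.
STTC uses the published tiling definition with 10 ms windows; the ADF
stationarity check (α = 0.05) runs on detrended single channels.  The
first 1,000 ms of any simulation are discarded as settling transient.

## Synthetic test-bed: what it shows and what it does not

The fixtures provide analytic volumes (slab, bent slab, quarter annulus)
with closed-form coordinates, random binary-branching morphologies, and
end-to-end toy circuits (tens of cells, tens of fibers).  Passing tests
demonstrate that each operator implements its definition and that the
pipeline composes: they do not show that the surrogate reproduces tissue
oscillation magnitudes, phase-locking angles, or full-scale convergence
statistics, all of which depend on detailed neuron models and full-size
circuits that are outside this package's scope.  Known limitations:
single-compartment neurons (no dendritic filtering, so the LFP proxy has
no laminar dipole structure), no gap junctions, no long-term plasticity,
no GABA_B, morphology fixtures much sparser than real arbors (touch
statistics are qualitatively, not quantitatively, realistic).
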