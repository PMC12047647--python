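# Methods

`nibsim` implements a desk-scale version of a personalized non-invasive
brain stimulation (NIBS) modeling chain: volume-conductor field simulation,
temporal-interference (tTIS) exposure planning, whole-brain neural-mass
simulation with field coupling, virtual EEG, and dynamic functional
connectivity (DFC) analysis. This note records the models, the parameter
choices that matter, the numerical decisions, and what the synthetic inputs
do and do not represent.

## Synthetic head phantom and derived geometry

All inputs are generated, not measured. The volume conductor is a nested
concentric-shell sphere (scalp / skull / CSF / grey matter / white matter)
on a voxel grid in RAS millimeter coordinates (`world = origin + index *
spacing`, voxel centers, grid centered on the origin so the phantom is
exactly mirror-symmetric). The reference shell radii are 92 / 86 / 80 / 78 /
70 mm with low-frequency conductivities 0.4 / 0.01 / 1.8 / 0.3 / 0.15 S/m —
literature-typical values shipped as data, not results. Each shell must be
at least one voxel thick; the pipeline default therefore uses slightly
redistributed radii (92 / 84 / 78 / 74 / 62 mm) at 4 mm spacing so that the
CSF shell survives voxelization while the electrode-solve workload stays
small.

Electrodes are placed by the landmark-based 10-10 construction: the scalp
isosurface is extracted (marching cubes on a one-voxel-smoothed head mask),
geodesics are computed as shortest paths on the surface edge graph, the
vertex electrode Cz is iterated to be the common midpoint of the
nasion–inion and pre-auricular geodesics, and the midline, coronal,
circumferential and transverse chains are subdivided at 10% (5% on the
ring) arc-length fractions. Graph geodesics overestimate true geodesic
length slightly, but positions are defined through arc-length *fractions*
along the same paths, which cancels the systematic part; on the sphere the
construction reproduces Cz at the pole and left/right mirror pairs to well
under a voxel. Pads are circular, 3 cm² by default.

The cortex is an icosphere at the mid-grey-matter radius with radial
outward normals. Vertices are grouped into `n_regions` equal-solid-angle
sectors, two hemispheric blocks of `n_regions/2`; the synthetic connectome
places its region centroids at the same sector centers, so surface nodes
aggregate consistently to connectome regions. The connectome itself is
bi-hemispheric and distance-dependent: `w_ij = exp(-d_ij / decay) *
s_inter^[cross-hemisphere] * jitter`, symmetric log-normal jitter, zero
diagonal, tract lengths equal to Euclidean centroid distances. Weights are
globally rescaled to unit mean row sum so that the global coupling constant
G acts on a defined scale (defaults: 84 regions, decay 40 mm,
inter-hemispheric attenuation 0.5, jitter sigma 0.5).

What the phantom does **not** emulate: gyrification and sulcal geometry,
realistic skull inhomogeneity (spongy bone), subcortical structures,
tractography-derived connection topology, and inter-subject variability.
Passing tests therefore demonstrate correctness of the algorithms and the
qualitative physics (shunting, selectivity trade-offs, rhythm entrainment),
not quantitative predictions for any real head.

## Conductivity mapping

White-matter anisotropy is modeled by mapping a diffusion tensor field to a
conductivity tensor field sharing its eigenvectors. Two magnitude modes are
provided: linear eigenvalue scaling `sigma_i = k d_i` (k configurable,
default 700 S·s/(m·mm²), surfaced in logs — no value is hard-coded as
truth), and database axial/radial assignment (default 1.1 / 0.13 S/m to the
principal / transverse axes). The DTI-derived (linear) magnitudes are
post-processed by the two-step clamp: (i) eigenvalues above 2 S/m are
clamped to 2 S/m; (ii) any eigenvalue still above c = 3 times the smallest
is clamped to that threshold, in a single pass using the post-step-(i)
minimum. Clamping to exactly `c * min` satisfies the ratio test, so the rule
is idempotent; single-pass semantics (not re-evaluating the minimum after
each clamp) are the documented reading of the two-step wording. Database
axial/radial magnitudes are assigned after the clamping stage and are
trusted as-is (their physiological ratio ~8.5 intentionally exceeds c).
A synthetic DTI generator provides radially oriented prolate WM tensors
(axial 1.4e-3, radial 0.35e-3 mm²/s, seeded log-normal jitter) for tests
and the anisotropic pipeline mode.

## Electroquasistatic solver

At tES frequencies (1–10 kHz) tissue currents are Ohmic, so the potential
obeys `div(sigma grad phi) = 0` with electrode boundary conditions and
zero-flux elsewhere, and `E = -grad phi`. Discretization is cell-centered
finite volumes: the axis-aligned flux uses the 7-point stencil with
harmonic-mean face conductivities (exact for layered media, hence the 1%
slab oracles); tensor off-diagonal terms enter through a symmetric
cell-centered cross-gradient correction (`A += Ga' D Gb + Gb' D Ga`), which
is exact for homogeneous anisotropic media in the interior and keeps the
matrix symmetric. The linear systems are solved with Jacobi-preconditioned
conjugate gradients (relative tolerance 1e-8 by default, deterministic).

Driven pads are Dirichlet equipotential patches of scalp-surface voxels
(±0.5 V), rescaled post hoc to 1 mA using the injected current summed from
discrete face fluxes; charge conservation between the pads holds to solver
tolerance by construction. Every *non-driven* montage pad is kept in the
model as a floating perfect conductor — an equipotential super-node with
zero net current, implemented by merging the pad's unknowns through a
sparse projection. This matters: it is what makes the per-electrode E-field
basis exactly superposable (any pair's field equals a basis difference to
solver tolerance), because each solution is then fully determined by the
net currents injected at the pad super-nodes. With a Dirichlet-only
reference and no other pads present, the same identity fails at the
several-percent level on a small head.

The EEG lead field is obtained by reciprocity: entry (electrode e, vertex
l) is `-E_e(r_l)·n_l / I_e` (trilinear interpolation, normal-constrained
dipoles, V per A·m). The sign convention makes a dipole pointing toward an
electrode raise its potential, so `V = LF @ m` directly. The independent
verification path is a direct dipole forward solve: the dipole is realized
as three axis-aligned monopole pairs centered on the nearest voxel (exact
oblique moment), all pads float, and each pad's super-node potential is
read out — the physical measurement model of an equipotential electrode.
At dipole positions (voxel centers) the two routes agree to solver
tolerance; evaluating the lead field half a voxel away from the dipole adds
a few percent of pure sampling mismatch that reflects neither method's
error. Within one voxel of strong conductivity jumps the interpolated
normal field component is low-accuracy (the physical normal-E
discontinuity); lead-field quality is best for sources at least one stencil
width inside their tissue, which the mid-GM mesh respects when the GM shell
is ≥ 3 voxels thick.

Known limitations: no capacitive effects (quasistatic), no adaptive
meshing, O(h) accuracy at curved tissue boundaries (the grid-refinement
check on a uniform sphere with point-like pads bounds the interior error at
~2% RMS between 2 mm and 1 mm grids; thin-shell geometry voxelized at 4 mm
carries larger, geometry-dominated error).

## Temporal-interference planning

Two sinusoidal channels at nearby kHz frequencies produce
`E(t,r) = sin(w1 t) E1(r) + sin(w2 t) E2(r)`; the neurally effective
quantity is the beat-envelope modulation. Per direction n the two-tone
amplitude swings between `||p1|-|p2||` and `|p1|+|p2|` (`p_i = E_i·n`), so
the modulation is `2 min(|p1|,|p2|)`; the modulation envelope magnitude
(MEM) maximizes it over directions. The closed form (with `|e1| >= |e2|`
after relabeling and e2 flipped when the angle is obtuse) is `2|e2|` when
`|e2| <= |e1| cos(alpha)`, else `2 |e2 x (e1-e2)| / |e1-e2|`. The
verification oracle samples Fibonacci-sphere directions, evaluates the
envelope by sampling the two-tone amplitude over a beat period, and
polishes the best few well-separated directions with Nelder–Mead (the
direction objective has multiple ridges); closed form and oracle agree to
1e-3 relative on 1000 seeded random pairs (observed: ~1e-7).

Configurations are scored by three objectives: M1, the p-th percentile
(default p = 50, linear-interpolation percentile) of the quantity of
interest in the target; M2, target mean over non-target brain mean
("off-target" is read as all non-target brain voxels, consistent with M3's
wording); M3, the fraction of non-target brain above a threshold, where the
"auto" threshold is the configuration's own M1 (a fixed global threshold
mode exists as well). For single-channel tACS the field magnitude |E|
replaces MEM under the same metrics. The Pareto front (maximize M1, M2;
minimize M3; ties all kept) is checked against an O(n²) dominance scan;
weighted ranking min-max-normalizes the objectives and always places front
members before dominated ones, with stable ties. Current steering varies
the split of a fixed total current over the ratio grid (always including
0.5), so the winner is never below the even split by construction; for
mirror-image channel pairs and a centered target the score is symmetric in
the split and the optimum sits at 0.5. Time-multiplexing across
configurations is supported only as sequential exposure-map averaging.

## Jansen-Rit network model

Each node is the three-population Jansen-Rit neural mass with second-order
synaptic kinetics and sigmoid `S(v) = 2 e0 / (1 + exp(r (v0 - v)))`;
parameters default to A = 3.25 mV, B = 22 mV, a = 100 /s, b = 50 /s,
C1 = 135, C2 = 0.8 C1, C3 = C4 = 0.25 C1, v0 = 5.52 mV, e0 = 2.5 /s,
r = 0.56 /mV. The pyramidal potential `v_p = y1 - y2` is the
EEG-generating signal. Long-range coupling transmits the delayed firing
rate: node input includes `G * sum_j w_ij S(v_p,j(t - tau_ij))` with
G = 7, `tau = length / speed` (conduction speed 3 mm/ms, not dictated by
the source material — configurable), rounded to integer steps at region
granularity. Surface mode adds an undelayed Gaussian local kernel
(width 10 mm, amplitude 1, cutoff 20 mm, geodesic distances, no
self-coupling). Integration is stochastic Heun (predictor–corrector
trapezoidal) at dt = 0.5 ms with additive noise `sqrt(2 * nsig * dt) *
N(0,1)` on the excitatory rate state, nsig = 1e-7 honored as a plain
number; the first second is discarded as burn-in. Halving dt changes the
1–40 Hz average log-PSD by well under 5% RMS, the convergence criterion
behind the 0.5 ms default.

**Background input.** The equations require a mean pyramidal input rate p
(pulse density, 1/s), which the source conventions inherit from TVB without
restating; it is exposed as `mean_input`. A linear-stability and attractor
scan of this implementation (v0 = 5.52 variant) shows: a stable rest state
below p ≈ 90 /s; a large-amplitude ~3 Hz spike cycle for p ≈ 114–140 /s;
and an alpha-band (~10–11.5 Hz) limit cycle above, up to p ≈ 320 /s. The
default is p = 260 /s — upper-middle of the model's physiological 120–320
pulse range — where both a single noisy node and the G = 7 coupled network
peak at 9.8–10.7 Hz. Consequences used by the tests: the noise-free
fixed-point check runs at p = 0 (where the stable equilibrium exists and is
reached; the root is verified by an independent scalar root-finder over all
equilibria with Jacobian-based stability selection); the regime contrast
runs at p = 90, where the default time constants decay to rest but the
fluid regime a = 60 /s, b = 30 /s has a single strongly unstable focus and
sustains a limit cycle.

**Stimulation coupling.** The lambda·E model: the field component along the
cortical normal times the effective membrane space constant perturbs the
pyramidal membrane potential, `s_i = lambda * (E(r_i)·n_i)` in mV
(1 V/m × 1 mm = 1 mV), added inside every sigmoid argument that takes
v_p — both the local feedback sigmoid and the transmitted rate. Interneuron
coupling is omitted (their field sensitivity is much weaker); an
input-current entry mode exists behind a flag for sensitivity checks.
`lambda_mm` defaults to 1 mm as an order-of-magnitude placeholder:
quantitative predictions require tuning it against measured data. The tACS
demonstration uses an adjusted value of 10 mm, chosen so the
drive-frequency spectral line is clearly visible against the endogenous
alpha rhythm without overdriving it (at ~2x that value the stimulated
run's alpha-band power fluctuations can exceed a 15 Hz drive line).

## Virtual EEG and spectra

Sensor voltages are `V(t) = LF @ (scale * v_pyr(t))`; region-mode sources
broadcast each region's trace to its member vertices before projection.
The default reference is the average reference (the source convention is
unstated; configurable). The dipole-moment scale is a single global
constant — amplitudes are in arbitrary units, and only spectral content
and spatial patterns are interpreted. Spectra use Welch estimates with 2 s
Hann windows at 50% overlap (estimator settings are this package's
defaults, all configurable); spectrograms use the same windows stepped at
0.5 s; band power integrates the PSD over a band per channel for
topographic rendering.

## DFC analysis

Sliding-window FC uses Pearson correlation of raw pyramidal output
(default 10 s windows, 50% overlap, no band-pass); a zero-variance node in
any window is an error. States are k-means clusters of the vectorized
upper triangles (seeded, multi-restart, k user-chosen; a silhouette helper
exists but no automatic selection is claimed); PCA components reshape back
to symmetric matrices for display. Fluidity is not given a formula by the
source; it is reported as the state-transition rate per second of
window-center time, with the variance of pairwise window-FC correlations
as a secondary measure. The fluid-regime demonstration (a = 60, b = 30,
G = 7, noise 1e-7, region mode) yields multiple occupied states whose
leading principal components load preferentially on cross-hemisphere
blocks; this is asserted with a permutation test (mean absolute
cross-hemisphere loading minus within-hemisphere, hemisphere labels
permuted, p < 0.05). The clean circular PC-space manifold reported for a
specific template connectome is *not* asserted — it is tied to that
external dataset, and subject-specific connectomes are reported to give
noisier dynamics; only the block-structure property is claimed for the
synthetic connectome.

## Orchestration and reproducibility

One validated configuration (unknown keys rejected) drives the stage chain
phantom → conductivity → basis → lead field → (optional tTIS planning) →
simulation → EEG → DFC. Per-stage seeds derive from the master seed by a
counter scheme, every artifact is content-hashed into a run manifest, and
reruns with the same configuration are bit-identical (floating-point
summaries are rounded at the 1e-10 level before hashing, below which
parallel BLAS reductions are run-to-run dependent).

## Problem sizes

Chosen once as the package's desk-scale defaults: phantom 49³ voxels at
4 mm (93³ at the 2 mm reference resolution); 61-electrode full montage,
with a 21-channel subset (the 10-20 positions plus AF7/AF8) for lead-field
work; cortex meshes of 162–642 vertices; 84 regions. Baseline rhythm runs
are 31 s (1 s burn-in discarded); the tACS demonstration runs 91 s with
stimulation during the central 30 s (reduced-surface tests use 61 s); the
fluid-regime DFC demonstration defaults to 10 min (tests use ~3 min). The
solver validation phantom is 33³ voxels with a deliberately thick GM shell
so that mid-GM field-sampling stencils stay inside grey matter.
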