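# Methods

`pvcloc` is a self-contained, desk-scale model of a physics + learning
pipeline for localizing focal ventricular ectopic sources (premature
ventricular contractions / focal VT) from body-surface ECGs and from the
electrograms (EGMs) an implanted device records. Every input is synthetic
and generated by the package itself; this note states the models, the
defaults and their rationale, and what the synthetic testbed does and does
not establish.

## Geometry

The left ventricle is a truncated-ellipsoid shell: endocardial and
epicardial ellipsoids of revolution with a common centre on the long axis,
cut by a flat base plane. Defaults: apex-to-base length 90 mm, equatorial
epicardial radius 30 mm, wall thickness 10 mm — physiological LV scale, so
millimetre localization errors are directly interpretable. The mesh is a
structured transmural × longitudinal × circumferential lattice of
tetrahedra with a target edge length of 2.5 mm (a config knob; the
construction is deterministic, and surface nodes lie exactly on their
bounding surfaces). At the default resolution this yields ≈ 16 k nodes and
≈ 75 k tetrahedra with a mean edge of ≈ 3 mm.

**Ventricular coordinates.** Each node carries (z, ρ, φ): z is the
normalized two-sided geodesic (graph) distance between the apex axis (z=0)
and the base plane (z=1); ρ the same between endocardium (0) and
epicardium (1); φ the azimuth about the long axis in (−π, π], with φ=0
fixed at the +x ("septal") reference direction — the published coordinate
constructions leave this convention open, so we fix and document one. Any
monotone surface-anchored construction satisfies the same invariants; the
two-sided graph distance is exact on the anchoring surfaces by
construction.

**AHA segments.** Seventeen segments from the standard z/φ boundaries
(basal z ∈ [2/3, 1]: six 60° sectors; mid z ∈ [1/3, 2/3): six sectors;
apical z ∈ [z_cap, 1/3): four 90° sectors; apex cap z < z_cap = 0.1,
configurable — the cap boundary is not standardized). The 68-segment model
quarters each segment by halving its z and φ ranges (the cap splits into
four φ quadrants), so parent = ceil(child/4). Segment centres of gravity
are plain means of each segment's endocardial or epicardial surface nodes;
segment adjacency comes from mesh edges joining differently labelled
nodes.

**Fibers.** A linear transmural helix: angle +60° at the endocardium to
−60° at the epicardium, rotated in the local frame built from the discrete
gradients of ρ (wall normal) and z (longitudinal). This replaces
rule-based fiber atlases; only the anisotropy of conduction matters
downstream, not fine fiber architecture.

**Electrodes.** Nine ECG electrodes (V1–V6 on an anterior arc at 120 mm
torso radius, RA/LA/LL at torso extremes) and nine device sensing points:
RV tip/ring and RV coil just outside the anterolateral epicardium, an SVC
coil above the base, the device can at the LA position (the common
modelling approximation CAN = LA), and four collinear LV lead tips along
the lateral epicardium spaced 7.5 mm. All sensing elements are points by
default; a finite 2-mm "tip cloud" (quasi-uniform Fibonacci points in a
sphere, averaged) is the stated sensitivity variant. Placement scenarios
(±50 mm axis shifts of the ECG set, LV-tip re-spacing, a septal RV-coil
variant) are exact re-parameterizations, so applying a displacement and
its inverse restores coordinates bit-for-bit.

## Activation model

Activation times are shortest arrival times on the mesh edge graph: an
edge of direction d (unit) and length L costs L / v(d) with the elliptical
speed profile v(d) = sqrt(cv_l² (d·f)² + cv_t² (1 − (d·f)²)), f the local
fiber (normalized mean of the fibers of elements incident to the edge).
Default conduction velocities are 0.5455 m/s along and 0.1802 m/s across
the fiber. The discrete graph formulation was chosen over a PDE
fast-marching solver because it is exactly testable: the solver must agree
bit-for-bit with an independent binary-heap shortest-path oracle on the
same weighted graph. Its known artefacts: the graph metric overestimates
continuum travel times (decreasing with refinement), and on paths oblique
to the fiber the L/v(d) cost can admit zig-zag shortcuts relative to a
Riemannian metric — both are discretization properties shared by the
family of edge-graph eikonal surrogates.

Membrane dynamics are reduced to an action-potential template shifted by
the local activation time: resting −85 mV, a 1 ms linear upstroke to
+25 mV, a flat plateau (APD 300 ms, repolarization linear over 50 ms),
sampled at dt = 0.5 ms. Only the QRS window is consumed downstream, so
repolarization shape is irrelevant by construction. Each simulation is a
single paced beat; the 400 ms basic cycle length is carried as metadata
only.

## Forward signals

Electrode potentials use an infinite homogeneous volume conductor: kernel
Z_e(x) = 1/(4π σ_b |x − x_e|) at element centroids (σ_b = 0.2 S/m), and
the source integral φ_e(t) = Σ_el σ_i ∇Vm·∇Z_e vol with per-tetrahedron
gradients and σ_i = 0.1845 S/m (the along-fiber intracellular conductivity
used isotropically). The sign convention follows the formula as written;
amplitude-normalized learning is indifferent to it. Because the integral
is linear in nodal Vm it collapses to a transfer matrix M (electrodes ×
nodes); and because the template upstroke is a linear ramp, a whole beat's
traces have a closed form via prefix sums over activation-sorted nodes,
which the batch simulator uses (verified identical to M·Vm(t) to ~1e−13).
A homogeneous medium cannot reproduce torso-specific conductivity
scenarios; a surrogate per-electrode lead-field scaling hook is provided
and labelled as such in logs and reports.

Sixteen channels per modality: the 12 standard leads (precordials against
the Wilson central terminal) plus the four auxiliary combinations
LL−RA−LA, LA−RA−LL, RA−LA−LL and (RA+LA+LL)/2, read as literal electrode
arithmetic (the inherited lead set does not define it further); and
sixteen device vectors (CAN−SVC, CAN−RVcoil, SVC−RVcoil, RVtip−RVring,
four LVtip−RVtip, four CAN−LVtip, four SVC−LVtip). The QRS window is
[0, max activation + upstroke + 2 ms]; simulated data needs no QRS
detector. Each channel is linearly resampled to 16 points (endpoints
inclusive) and the 16 channels stacked into a 16×16 matrix.

**Noise and normalization.** White Gaussian noise is added per channel at
a prescribed SNR (variance = channel mean-square power / 10^(SNR/10)), on
the raw scale, *before* per-matrix max-abs normalization. Normalization is
required here: homogeneous-medium amplitudes differ from torso amplitudes,
so the learning stage must be scale-invariant. Training sets are augmented
by replacing each training beat with 10 independently noised copies at
25 dB; augmented copies inherit their parent's labels and split (noisy
replicas of one beat never straddle the train/test boundary, and grouped
cross-validation folds respect the same grouping).

## Networks

Four small CNNs share one architecture on the 16×16 matrices: conv 16@3×3
→ maxpool 2×2 → conv 32@3×3 → maxpool 2×2 → FC 128 → linear head (layer
widths are our choice, config-overridable). Heads: softmax over 17 (or 68)
AHA segments; softmax over endo/epi (trained on surface beats only);
two linear outputs (z, ρ) with mean-absolute-error loss; softmax over 68
rotational wedges of width 2π/68 ≈ 0.09 rad covering [−π, π] (φ is
classified rather than regressed because of its cyclic topology). Training
uses minibatch 23, learning rate 0.001, 10 epochs for classification and
15 for regression, cross-entropy for the classifiers — and stochastic
gradient descent with classical momentum 0.9. Plain SGD (momentum = 0,
available in config) does not converge within this short epoch budget on
this problem: at full training size it leaves the wedge classifier near
chance and the UVC scheme several millimetres worse; momentum is the
minimal standard remedy and is our own design choice. The implementation
is pure numpy (im2col convolutions) exposed as scikit-learn estimators;
fixed seeds give bit-reproducible weights on a fixed platform.

## Localization

*Cartesian probability-based*: restrict the segment probabilities to the
most probable segment and its adjacent segments, renormalize over that
subset, and form Σᵢ Pseg,i (P_endo CoG_i,endo + P_epi CoG_i,epi). The
restriction follows the scheme's description; the renormalization is our
choice — it makes the output an exact convex combination of the
participating centres of gravity, hence always inside their hull.

*UVC-based*: clip the regressed (z, ρ) to [0, 1], convert the most
probable wedge to its central φ, and return the mesh node minimizing
d² = w_z Δz² + w_ρ Δρ² + w_φ wrap(Δφ)², with weights converting each
coordinate to approximate millimetres: w_z = (apex-base length)²,
w_ρ = (wall thickness)², w_φ = (mean mid-wall cylindrical radius)². The
inversion is exact on mesh nodes and errs by at most a local edge length
elsewhere. Scores: Euclidean error in mm; classifier accuracy = percent of
beats in the correct segment; per-segment precision = correct predictions
of a segment over all predictions of it (reported as missing when a
segment is never predicted). Bull's-eye display maps z piecewise-linearly
to the radius across apical/mid/basal rings at r = 1/3, 2/3, 1, θ = φ,
with ρ colour-coded.

## Experiment protocol and problem sizes

The reference run samples 3767 pacing sites stratified ~32 % endocardial /
36 % mid-wall / 32 % epicardial (volume-weighted within each class for
approximately uniform spatial coverage), splits 2767 train / 1000 test,
augments ×10 at 25 dB, trains per modality (ECG and EGM separately), and
evaluates the frozen networks on the test beats noised once at 25 dB. The
acceptance script reruns exactly this. Sensitivity sweeps never retrain:
the noise sweep re-noises the retained test matrices at SNR 5–30 dB; the
electrode sweep recomputes the lead field per scenario, re-renders the
same test beats (activation maps are electrode-independent and reused),
and evaluates the frozen models, so the identity scenario reproduces the
reference numbers exactly. The test suite exercises the same protocol at
2000/500 beats and a coarser 5-mm mesh for unit-level checks; these sizes
are our choice of desk-scale operating points, and the stratified split,
seeds and thresholds are fixed in the configs.

Every random stream (site sampling, splitting, augmentation noise, test
noise, weight initialization, shuffling) derives a named child seed from
the single experiment seed, so any reported row is regenerable from
(config hash, seed) recorded beside it.

## What the synthetic testbed shows — and does not

The testbed preserves the pipeline topology of the torso-scale original
(precomputed per-electrode lead fields × fast activation models → matrix
encoding → CNNs → probability/coordinate decoding) while remaining exactly
oracle-testable. It does not contain: a heterogeneous torso (absolute
amplitudes and inter-lead amplitude ratios differ from FEM lead fields —
hence the normalization), an RV or atria, real fiber architecture, ionic
membrane dynamics, QRS detection on noisy clinical recordings, or
inter-patient anatomical variability. Passing tests therefore establish
internal correctness and the behaviour of the method under its own forward
model, not clinical performance. Known numerical choices: graph-metric
eikonal overestimation (monotone under refinement), point-kernel lead
fields evaluated at element centroids (electrodes must keep > 0.5 mm
clearance; tip-cloud points violating it are excluded with a warning), φ
seam fixed at ±π with wedge 1 starting at −π and φ = π assigned to wedge
68, ties in nearest-node searches broken by lowest node index.
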