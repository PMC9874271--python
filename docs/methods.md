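# Methods

This note documents the models behind `bipedsim`, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter.

## Frames, units, sign conventions

Right-handed world frame: x craniocaudal (positive cranial), y vertical
(positive up), z mediolateral (positive right). All interfaces take
angles in degrees (radians internally), lengths in metres, forces in
newtons, moments in N m. GRF magnitudes are expressed in body weights
(BW = whole-body mass × g, g = 9.81 m s⁻²). Pitch is the moment about
z: positive nose-up, negative nose-down; roll is about x.

## Mass properties

Segment shapes are closed, consistently wound triangle meshes. Mass,
COM and inertia are the exact polyhedral integrals (computed by
trimesh's divergence-theorem implementation); validation checks closure
(every edge shared by exactly two faces), winding consistency, and
normalises a globally inverted mesh by flipping all faces. Air spaces
(lung, trachea, cranial sinus) are separate contained meshes handled by
negative-mass superposition at the surrounding tissue density — exact
for fully contained cavities and simpler than boolean subtraction. Body
tissue density defaults to 1000 kg m⁻³ and is configurable; a
`mass_override` per segment rescales mesh-derived mass (and inertia)
while keeping the shape-derived COM, so a target body mass can be
imposed exactly.

Whole-body properties compose posed segments: mass-weighted COM and
parallel-axis transport of each inertia tensor to the composite COM.

## Posing

The model document's articulated pose is the reference (zero) pose; for
the synthetic model it is a crouched early-stance hindlimb
configuration. Body angle (BA) and tail angle (TA), both measured from
horizontal, are applied after the joint coordinates as rigid rotations
about the mediolateral axis: the trunk–neck–head group about the trunk
joint, the tail segments about the proximal tail joint. Positive BA
raises the head; positive TA raises the tail tip.

## Static optimization

Moment arms use the tendon-excursion definition, r = −∂L/∂q, by central
finite differences with a 1 × 10⁻⁴ rad step (configurable; the paths
are piecewise straight so the length function is smooth away from
degenerate geometries). Maximal isometric force is
F_max = σ · m/(ρ l_o) · cos(pennation) with specific tension
σ = 3 × 10⁵ Pa and muscle density ρ = 1060 kg m⁻³ (standard literature
values); pennation defaults to 0° where a table omits it. Architecture
rows scale to the target body mass by geometric similarity (muscle mass
∝ M, fibre length ∝ M^⅓, hence F_max ∝ M^⅔).

Equality constraints are written only for the actuated degrees of
freedom (hip 3, knee, ankle, MTP, 2 × 2 tail = 10 in the default
model). The six pelvis-to-ground d.f. carry no actuators and are
excluded: a single-instant static analysis with a prescribed multi-BW
GRF cannot close the whole-body equations without accelerations. A
consequence worth knowing: limb-muscle demands depend only on the GRF
and on gravity of segments distal to each joint, so body angle
influences the statics only through actuators that couple into the
axial chain (here the caudofemoralis longus, whose origin rides on the
tail) and through the tail's own gravity moments.

The required moment at d.f. k with world axis â_k through p_k is

M_k = −[ â_k · ((COP − p_k) × F_grf)   (if the stance foot is distal to k)
       + Σ_{s distal} â_k · ((com_s − p_k) × m_s g) ],

verified in the tests against an independent virtual-work evaluation.

The QP (minimise Σa², subject to Aa = b and box bounds) is solved by an
LP feasibility probe (HiGHS), SLSQP from two deterministic starts, and
an exact minimum-norm polish on the detected active set
(pseudo-inverse); the best bounded candidate meeting the scaled 10⁻⁶
equality tolerance is returned. Infeasibility is decided by the LP, so
ramp searches are fast: the moment matrix is pose-only and the
right-hand side is affine in GRF magnitude, so each ramp step costs one
small LP. The ramp starts at one step (0.1 BW) and reports 0 BW if that
already fails; a configurable cap (20 BW) flags cap-limited results.

Reserve actuators are bidirectional (a_q ∈ [−1, 1], moment a_q T_q) at
the MTP and at both tail joints' pitch and yaw d.f. (Q = 5). T_q is
auto-sized to twice the largest required-moment magnitude over the
posture set — large enough that reserves are never near full
activation (a warning fires at |a_q| ≥ 0.95), small enough not to
condition the QP badly. The exact value is immaterial by design.

Group-mean activations average muscles within ten functional groups
(hip abductors/adductors/flexors/extensors, knee extensors/flexors,
ankle plantar-/dorsiflexors, digital plantar-/dorsiflexors); IT3 is
grouped as a knee flexor, not an extensor, because its lateral routing
makes it a knee abductor/flexor. Empty groups report NaN, never 0.

## COM moments

τ = (COP − COM) × F at a fixed 2 BW, independent of the per-pose
maximum sustainable GRF. The implementation computes the moment twice —
as the cross product and by the skew-line geometric construction
(signed shortest distance between the GRF line and each COM axis,
scaled by the in-plane force component) — and asserts agreement to
1 × 10⁻¹⁰ relative on every call, turning the geometric identity into a
runtime invariant.

The 4 × 4 BA × TA grid is interpolated to 1° by tensor-product cubic
splines with not-a-knot end conditions (MATLAB `spline`'s default; with
four knots this reproduces any cubic polynomial exactly, which natural
end conditions would not). Zero crossings along fixed TA are located by
a 1° scan plus Brent bracketing, reported at 0.5° precision.

Hull sensitivity rebuilds the grid for: uniform segment-mass scaling
(0.8×, 1.2×) and per-segment COM pushed to the cranial/caudal extremes
of its local bounding box ("implausible extremes"). The 2 BW load is
re-expressed in newtons from each variant's own body weight, so uniform
mass scaling scales τ exactly proportionally (the ×1.2 variant differs
by exactly 20%). Each variant reports mean|Δτ| / mean|τ_ref| × 100
(robust near sign changes) and whether any cell's sign flips; the COM
bounding-box extremes are deliberately drastic perturbations and
dominate the overall mean.

## Ancestral-state reconstruction

Mk models with k = 2 (quadrupedal, bipedal) or k = 3 (quadrupedal,
facultatively bipedal, bipedal); rate structures ER (1 rate), ARD
(k(k−1) rates) and ordered (k = 3 with q₀₂ = q₂₀ ≡ 0). Likelihood by
Felsenstein pruning with per-branch matrix exponentials
(eigendecomposition, vectorised over branches, with scipy `expm` as the
fallback for ill-conditioned eigenbases); partials are max-scaled to
avoid underflow. The root prior is flat (1/k), switchable to
stationary. Ambiguous taxa enter as flat tip weight vectors — the
likelihood-weights device equivalent to flat tip priors. Zero or
missing branch lengths (dating artefacts) are floored at 0.1 Myr and
counted.

Rates are fitted in log space by L-BFGS-B with five seeded starts: one
heuristic (about one expected change over the whole tree) and the rest
spread with jitter across the log-rate box [e⁻⁸, e⁴] per Myr. The
spread matters: starts clustered at one corner can strand the optimiser
on the saturation plateau (all transition probabilities → 1/k), which
is flat to numerical gradients.

Model choice: AIC = 2p − 2 lnL, ascending; within a ΔAIC < 2 band of
the best model the fewer-parameter model is ranked first (ties are
flagged). Under this rule, data simulated under ER (0.01 changes/Myr,
200 tips, root drawn from the flat prior) select ER in ~94% of
replicates; a strict lowest-AIC rule would select ER only at the
asymptotic P(χ²₁ < 2) ≈ 84% rate, which is a property of AIC itself,
not of the implementation. Node states are marginal probabilities from
an inside/outside recursion valid for non-reversible rate matrices,
checked against exhaustive enumeration on small trees.

## The synthetic model generator

The generator emulates the *structure* of a small-bodied, long-tailed,
bipedal-candidate archosauriform and the study conditions around it; it
does not attempt to reproduce any real specimen's geometry numerically.
Specifics and rationale:

- **Body mass 8 kg**, hip height 0.20 m, snout–tail length ≈ 1.2 m;
  segment mass fractions (trunk 0.53, head+neck 0.12, tail 0.14, pelvis
  0.09, limb 0.12) put the COM cranial to the foot's centre of pressure
  at low body angles — the nose-down regime of interest — and caudal to
  it at high body angles, so the pitch sign change falls inside the
  grid (~29–39° BA depending on TA).
- **Capsule hulls** (and a lung capsule inside the trunk) instead of
  bone-accurate hulls: watertight by construction and closed-form
  checkable; the mass-property mathematics is identical for arbitrary
  hulls.
- **36 muscles** with anatomically motivated via-point routes; the
  routing was chosen so every actuated d.f. has torque capacity of the
  sign the early-stance GRF demands (the ankle plantarflexors are the
  weakest link, as in crouched-limb mechanics generally). A reduced
  10-muscle set keeps one representative per functional group, carrying
  the group's summed mass, so statics tests run in well under a second;
  its hip-extensor representative is ISTR because a tail-origin
  representative would leave hip long-axis rotation unbalanceable.
- **Architecture tables** at a 10 kg extant-analog source mass:
  log-normal mass jitter (σ = 0.08) around ranked template means
  (proximal > distal), fibre lengths correlated with segment length.
- **Volumetric (method 4) parameters** from capsule bellies sized to
  about twice the architecture-scaled muscle volume (log-normal
  σ = 0.10), emulating the empirical pattern that volumetric
  reconstructions recover whole-belly masses exceeding literature
  scaling; method-4 maximum sustainable GRFs come out ~60–80% above
  methods 1–3.
- **Methods 1–3** differ only in how attachment-patch centroids are
  computed (2-D alpha shape on the best-fit plane with alpha = 2 ×
  median nearest-neighbour spacing; convex-hull area centroid;
  arithmetic mean), applied to seeded quasi-planar scatter patches
  around each origin/insertion — millimetre-scale endpoint shifts, as
  in the real estimation problem.
- **COP** is the centroid of the full plantar contact (ankle ground
  projection to toe tip): the crouched reference pose puts the whole
  foot on the ground in early stance.
- **Trees** are birth–death simulations (0.05/0.02 per Myr) with a
  seeded fraction of tips shortened into fossils (non-ultrametric) and
  characters simulated by the exact Mk transition kernels; a
  configurable fraction of tips is recorded as ambiguous.

What passing tests on synthetic data do **not** show: that any real
taxon's printed moments, activations or AICs are reproduced — those
depend on the deposited specimen geometry and architecture tables,
which can be dropped into the same interfaces (model directory, CSV
tables, Newick + states CSV) when available.

## Numerical choices and degenerate inputs

- QP equality tolerance 10⁻⁶ (scaled by |b|∞); LP decides feasibility.
- Moment-arm finite-difference step 10⁻⁴ rad.
- Spline interpolation refuses extrapolation outside [0°, 75°].
- Attachment patches that are rank-deficient (a point, a line) fall
  back to the arithmetic mean under every centroid method; an alpha
  shape that retains no triangle falls back to the convex hull.
- Open meshes raise errors naming the offending edges; inverted
  windings are normalised only when globally consistent.
- Transition-probability rows sum to 1 to 10⁻¹²; degenerate rate
  matrices route through scaling-and-squaring `expm`.
- Every stochastic element takes an explicit seed; identical seeds give
  byte-identical model directories and bit-identical experiment CSVs
  (digests recorded in the run manifest).

## Problem sizes

Default experiment: 4 methods × 16 postures = 64 ramp simulations
(~10 s total); pitch surface 76 × 76; sensitivity 4 variants × 16-knot
grids; ASR demonstration tree 60 tips. The statistical test suites use
500-tip trees (rate recovery, 20 replicates) and 200-tip trees (model
selection, 50 replicates).

## Known limitations

- No dynamics: no accelerations, angular momentum, or stride-resolved
  GRF integration; the early-skewed GRF profile generator exists for
  documentation and plotting only, and the static analyses consume its
  peak.
- No muscle wrapping surfaces, tendon compliance, or force–length–
  velocity effects.
- The pelvis free-body equations are intentionally outside the
  equality constraints (see above); whole-body balance is addressed by
  the COM pitch-moment analysis, not by the QP.
- Marginal (not joint) ancestral reconstruction; no Bayesian ASR, no
  tree dating — dated trees are inputs.
- The alpha-shape parameter and the per-method fibre-length derivations
  are documented defaults, not values asserted against any source.
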