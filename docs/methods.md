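# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `gaitload`. Everything stated here is computed by the code;
no empirical claim below goes beyond what the test suite and
`scripts/acceptance.py` verify.

## Coordinate conventions and template model

The laboratory frame is right-handed with x anterior (walking direction),
y to the subject's left, z up; neutral segment frames are aligned with it,
and the right leg lies at y < 0. All internal units are SI; TRC marker
files and STL meshes use millimeters at the I/O boundary only.

The template is a reduced lower-limb cadaver model: a pelvis segment with
the head–arms–trunk mass lumped in (60.3% of body mass), and bilateral
thigh (14.16%), shank (4.33%) and foot (1.37%) segments — Dempster-style
fractions. Reference anthropometry: 75 kg, 176 cm, segment lengths 0.18 m
(inter-hip pelvis width), 0.42 m thigh, 0.43 m shank, 0.23 m heel-to-toe
foot, 76 mm tibial plateau width. Hips are spherical, knees and ankles are
hinges about the medio-lateral axis. Sign conventions: hip/knee flexion
positive, hip adduction positive toward the midline on both sides, hip
axial rotation positive internal, ankle dorsiflexion positive.

Fourteen muscle-tendon units per leg represent *functional groups*, not
individual muscles: iliopsoas, gluteus maximus, gluteus medius (abductor
group), adductor group, internal and external deep-rotator groups,
hamstrings, rectus femoris, a three-way vasti split (which exercises the
volume-normalization weights: v = 1/3 per head, summing to 1),
gastrocnemius, soleus and tibialis anterior. Paths are straight lines
through via points (no wrapping surfaces); the quadriceps route through a
suprapatellar via point whose offset produces an effective extensor moment
arm of ≈3–4 cm, standing in for the patellar mechanism rather than a
patella segment. Group strengths are set so that each unit carries its
whole synergist group's capacity with headroom for altered-gait postures
(peak utilization stays below ~0.7 across the synthetic study); because
the recruitment cost depends only on utilizations fᵢ/Nᵢ, a uniform
rescaling of all strengths leaves the force-sharing solution unchanged —
only feasibility margins move.

Template bone surfaces are parametric meshes (tapered tubes, spheres,
subdivided boxes) with named landmarks, labelled vertex regions (femoral
head, condylar cylinder, distal tibia) for analytical joint fitting, and
enough shaft/surface correspondence points for landmark-driven morphing.
The 32-marker protocol is a conventional bilateral lower-body set: four
pelvis markers (ASIS/PSIS), femoral epicondyles, malleoli, heel and toe
markers, and four-marker rigid clusters on each thigh and shank.

## Synthetic gait laboratory

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

**Subjects.** The default cohort is five patients with the published
demographics (74/156 R, 112/184 L, 90/163 R, 89/165.5 R, 71.2/167.5 L;
mass kg / height cm / tested leg). Per-bone geometry is the template
deformed by a *recorded* map: an anisotropic scale (long-bone axis from
height with 2% per-segment jitter; transverse from the mass–height ratio),
plus a smooth non-affine bump field — three Gaussian bumps, amplitude
2.5 mm SD and width σ = 90 mm — expressed in a rigidly displaced scan
frame (±7° rotation, ±2 cm translation). The bump field is corrected to
have no net affine component over the bone surface and to vanish exactly
at the joint anchor points, so (i) the affine/rigid/non-affine split of
the deformation is well defined and (ii) joint-to-joint distances equal
the scaled template lengths to machine precision. Feet deform affinely
only, matching their affine-only morph protocol. The recorded map is the
ground truth that morphing recovery is tested against.

**Motion.** Joint-angle ground truth follows parametric gait-cycle
templates (sinusoids and periodic Gaussian humps: hip flexion 28° at heel
strike to −12° in late stance; knee flexion with a 22° loading-response
hump and 61° swing peak; ankle plantarflexion burst at push-off; small
pelvis translations/rotations with lateral sway toward the stance leg).
Stride time 1.1 s, stance 62% of the cycle, speed 1.2 m/s; per-trial
variability perturbs amplitude, stride time and speed by ~3% (seeded).
Markers are the forward kinematics of these poses plus cluster-level
soft-tissue artifact (a common 3 mm sinusoidal displacement per
thigh/shank cluster — this is what gives the linear-scaling optimizer
something genuine to optimize) and 1 mm white noise.

**Ground reactions.** The vertical force is the classic double hump,
1.18·BW·(sin πu + 0.3 sin 3πu) over stance fraction u, with a braking/
propulsion fore–aft component (±0.18 BW) and a small medial component.
The center of pressure travels heel to toe under the foot. Each plate
records a single contact: the symptomatic leg strikes plate 2, the
contralateral leg plate 1 half a stride later. Condition effects:

| condition | mechanism | default |
|---|---|---|
| insoles 0/5/10° | CoP shifts laterally 2 mm/deg; ground reaction tilts medially 0.4% of Fz per degree | both configurable |
| toe-in / toe-out | ∓10° foot progression via hip axial rotation | configurable |
| wide | 0.03 m lateral foot placement via hip abduction | configurable |

The wedge coefficients are chosen so the insole effect on the knee
adduction moment is the *net* of two opposing mechanisms (lateral CoP
shift lowers it, medial force tilt raises it), which yields the small
insole effects typical of wedge studies while keeping the direction-only
property testable: increasing the CoP-shift coefficient alone lowers peak
KAM monotonically. The magnitudes of the taught modifications (toe angle,
step width) are design choices, not claims about any particular study.

**What the generator does not emulate.** Kinematics and ground reactions
are not dynamically consistent (no contact model closes the loop); marker
gaps/occlusions, force-plate noise and drift, double-support force
sharing on one plate, and trunk/arm motion are absent. Passing tests
therefore demonstrate correctness of the estimation machinery on data of
known structure, not robustness to every artifact of a real laboratory.

## Personalization

**Linear scaling.** Unknowns: four segment-type scale factors (applied
isotropically to each segment's local geometry), the 16 standing-pose
coordinates, and implicitly the local positions of the 16 cluster markers
(free parameters: they are excluded from the residual and re-estimated in
the fitted pose, so all scale information comes from the 16 bony-landmark
markers — 48 residuals for 20 parameters). Levenberg–Marquardt on the
frame-averaged standing trial; deterministic from unit scales and a pose
initialized under the pelvis markers. The report carries per-marker
residuals, the Jacobian condition number and a rank-deficiency flag (no
silent regularization). Knee lever arms for this route are
regression-style: d = 0.24 × plateau width per side (configurable
coefficients), with the plateau width estimated from the shank scale.

**Geometry morphing.** Per bone: (1) least-squares affine over the full
matched vertex set (morphed surfaces share point numbering with the
template, so dense correspondence is available — the stand-in for
registration-based morphing tools); (2) exact tri-harmonic RBF
(φ(r) = r³, first-order polynomial augmentation, no smoothing) over the
named landmarks plus ~70 subsampled vertex correspondences; (3) reverse
rigid = the inverse of the rigid polar factor of the fitted affine, which
removes the scan pose and re-expresses the morphed geometry in the
template segment frame. The polar-factor choice (rather than a Procrustes
fit of morphed onto template landmarks) is deliberate: when the subject
genuinely differs in size, Procrustes-to-template would fold part of the
size difference into the rigid step; the polar factor removes exactly the
rotation the affine stage absorbed, so a recorded deformation is recovered
point-for-point (≤ 1 mm at attachment sites in the acceptance check).
Feet use the affine stage only, over their 36-point landmark protocol.
Segment lengths come from morphed joint-to-joint distances; hip centers
and knee/ankle axes are refit with the analytical sphere/cylinder fits
(principal-axis initialization, Levenberg–Marquardt refinement); knee
lever arms are measured on the morphed tibia (origin at the mid-point of
the tibial edges, arms = ML-distance to each plateau center).

**Strength scaling.** N_i = N⁰_i · (m_seg/m_ref) / (l_seg/l_ref) ·
(1−F)/(1−F_ref), per the muscle's insertion segment. The fat fraction F
maps linearly from BMI (slope 0.01 per BMI unit, anchored at F = 0.25 for
the template's BMI of 24.2, clipped to [0.05, 0.60]); the exact law and
its coefficients are configurable since published formulations live in
cited references with several variants.

## Kinematics

Per frame, q minimizes Σ w‖m_measured − m_model(q)‖² by damped
Gauss–Newton (finite-difference Jacobians, per-frame Levenberg damping
that only ever accepts non-increasing steps, gradient tolerance 1e-10),
batched over frames and warm-started in blocks of 16. Optional zero-lag
2nd-order Butterworth filtering of q (default 6 Hz) precedes
central-difference velocity/acceleration. Missing-marker handling is not
implemented (synthetic output has no gaps). Analyses solve a window of
stance ± 15 frames, which keeps filter and differentiation edge effects
away from the analyzed interval.

## Dynamics and recruitment

Each frame assembles 24 Newton–Euler equations (4 segments × 6) with
unknowns: 14 muscle tensions, hip force (3), knee and ankle force +
two hinge-orthogonal constraint moments each (5 + 5), and six pelvis
residual actuators — 33 columns. Muscle columns apply unit-tension path
forces at origin, via and insertion points; gravity, inertial terms
(segment accelerations and angular terms differentiated numerically from
the solved poses) and the measured ground reaction (force at CoP + free
moment) are on the right-hand side. The knee constraint force is the
total tibiofemoral contact force; the hinge's constraint-moment component
about the tibial AP axis is the ab/adduction moment.

Recruitment minimizes G = Σ vᵢ(fᵢ/Nᵢ)³ plus a quadratic residual penalty
(weight 1000 on (r/BW)², configurable) subject to Cf = d and bounds. The
solver works in scaled variables (muscle utilizations, reactions in
body-weight units, row-normalized equations), warm-starts by projecting
the previous frame's solution onto the new equality manifold, falls back
to a phase-1 linear program for a feasible start, and verifies the
constraint violation (< 1e-6 scaled) before accepting; infeasibility is
reported with the worst-violated row, never absorbed. The cubic cost is
convex for f ≥ 0, so the muscle solution is unique. A torque-actuator
mode (all joints transmit full moments, no muscles) yields classic
inverse-dynamics net moments as a square linear solve; it is cross-checked
against an independent recursive Newton–Euler oracle in the tests.

The pelvis residuals absorb the (deliberate) dynamic inconsistency of the
synthetic inputs — chiefly the unmodeled trunk and contralateral-leg
dynamics — and peak around 0.6–0.9 BW in the synthetic cohort. They are
reported per trial so this inconsistency stays visible. This is a
documented deviation from measured-data pipelines, which have no explicit
residual actuators.

## Knee load decomposition

MCF = (TCF·d_lat + M_add)/(d_med + d_lat), LCF = TCF − MCF, with
conservation MCF + LCF = TCF exact by construction. Adduction moment is
signed positive when it loads the medial compartment *for both legs*
(the left/right mirror is handled in the tibial frame construction, which
keeps the AP axis anterior and flips the ML axis label). Lever arms are
constant over knee flexion. Negative compartment forces (condylar
lift-off) are clamped to zero by default with the complement carrying the
full compression; clamped frames are flagged.

## Outcomes, statistics, and problem sizes

Stance is detected on the vertical force at a 20 N threshold with a 10%
hysteresis band; curves are linearly resampled to 101 points; impulses
integrate over real stance seconds (units %BW·s and %BW·BH·s); peaks are
maxima of the normalized curves. Aggregation is mean ± SD with the n−1
denominator (3 trials per patient, 5 patients per group). Best-alteration
selection takes the arg-min of the per-patient (or group) mean over the
six alterations, returns "none" when nothing beats shod, and breaks exact
ties toward the canonical condition order with a flag.

The statistical battery is four one-way repeated-measures ANOVAs
(peak MCF and MCF impulse × two model routes) — one-way with subjects as
blocks, F = MS_condition/MS_error, df (k−1), (k−1)(n−1) — with paired-t
post-hoc contrasts of shod against each alteration and against each
patient's individually selected alteration, Bonferroni-adjusted over the
m = 7 contrasts actually tested (configurable), with simultaneous
confidence intervals at the adjusted level, and Shapiro–Wilk normality
checks of each paired-difference set. The "individual best" contrast is a
plain paired comparison of shod against the selected condition's values;
selecting the minimum and then testing it is optimistic
(selection-conditional inference is not corrected for), which is a known
caveat of this design. Null-simulation calibration (5,000 ANOVA
replicates at n = 5, k = 7; 10,000 Shapiro–Wilk replicates at n = 5)
verifies type-I rates of 5% ± 1%.

The full synthetic study — 5 subjects × 7 conditions × 3 trials × 2
personalization routes — runs in about four minutes on one CPU; these
problem sizes (101-point stance curves, ~80 recruitment frames per trial,
1.6 s trials at 120 Hz) were chosen to keep the complete analysis and its
verification fast enough to run routinely.

## Known limitations

* Straight-line muscle paths without wrapping; an effective extensor via
  point instead of a patella segment.
* Constant knee lever arms over flexion; regression-arm coefficients for
  the LS route are configured defaults, not a claim about any published
  regression.
* Single-leg dynamics with penalized pelvis residuals rather than
  whole-body dynamics.
* Only the compressive (proximal–distal) component defines the
  medial/lateral split; shear components are reported but not decomposed.
* Synthetic-cohort load magnitudes are internally consistent but are not
  expected to reproduce any specific patient cohort's values; condition
  effect magnitudes follow the generator's documented coefficients.
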