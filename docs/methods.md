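# Methods

## The measurement model

A jump is observed as four digitized points per frame (head, abdomen tip,
femorotibial joint, tarsus) in a lateral view at 2000 Hz, SI units, y up.
The body is idealized as a rigid uniform rod spanning head to abdomen tip:
the rod midpoint proxies the center of mass and the abdomen→head direction
defines the body angle θ (counter-clockwise from +x; positive rotation
carries the head over the back). Angles are unwrapped across frames, so
consecutive differences always lie in (−π, π) and multi-turn rotations
accumulate correctly.

Events:

- **stationary** — the frame before the centroid first moves more than
  `motion_threshold` (default 0.3 mm, a few times the tracking-noise
  scale) from its initial position;
- **take-off** — the first frame at which the tarsus exceeds
  `substrate_y + clearance` (default 0.5 mm) *and stays above it for the
  rest of the trajectory*; the persistence requirement makes single-frame
  noise spikes harmless;
- **contact** — the first frame at which the head reaches
  `target_y − tolerance` (default 1 mm). The criterion is one-sided
  because the head approaches the target from below.

Estimators:

- **secant velocities** (the whole-jump averages the study's formulas
  define): centroid displacement, or unwrapped θ change, between take-off
  and contact divided by the elapsed frame time. The formula's
  "divided by the number of frames" is implemented as divided by elapsed
  *time*; dividing by a frame count would carry units of m·frame⁻¹.
- **local velocities**: least-squares slope of the centroid coordinates
  and of θ over a short window (default 5 frames). In `analyze_jump` the
  take-off local estimate uses a flight-side window starting at the
  take-off frame, so stance acceleration does not leak in.
- **FTJ angle**: interior angle at the ftj vertex between the rays to the
  abdomen tip (proximal stand-in for the femur's body end — the femur's
  proximal landmark is not among the tracked points) and to the tarsus.
  Rotation- and translation-invariant by construction.

Known estimator biases, all bounded and small relative to the study's
standard errors: the stationary frame can land a few frames into stance,
where the FTJ has opened by at most `motion_threshold / stance_rise` of
its total excursion (≤ ~0.7° at defaults); contact detection can fire up
to a few frames early on slow, near-apex approaches, perturbing the
secant velocity by ≲ 0.01 m/s; frame quantization of events contributes
g/(2·frame_rate) ≈ 0.0025 m/s to the secant linear velocity.

## Energy budget and the calibrated body length

`I = mL²/12`, `E_trans = ½mv²`, `E_rot = ½Iω²`; the rotation fraction
`100·E_rot/(E_rot+E_trans)` is mass-free. The study animals' body length
is not published, so a single calibration length is derived by inverting
the fraction equation at the 50 mm condition (v = 1.40 m·s⁻¹,
ω = 47.36 rad·s⁻¹, fraction 2%), giving L = 14.63 mm — anatomically
plausible for the genus. The 75 and 100 mm fractions computed with this
length are genuine cross-checks (they round to 1% and 0.6%). Per-jump
fractions use each animal's own sampled body length; the pipeline both
averages per-jump fractions and evaluates the fraction of the per-height
mean velocities, since the two aggregations differ and either could have
been used upstream.

## Beam null model

Force F at moment arm l from the center of a rod (m, L):
`ÿ = F/m`, `θ̈ = 12·F·l/(mL²)`, so `ÿ/θ̈ = lv/av = L²/(12l)` under fixed
posture. `posture_arm` inverts this per jump into an effective (fitted,
never measured) arm; `null_hypothesis_test` checks the sign prediction
with a Spearman correlation and a seeded label-permutation p-value
(add-one rule). This deliberately replaces mixed-model machinery: the
prediction at stake is a sign, and the rank/permutation test makes no
distributional assumptions.

## Flight model

After take-off: gravity only (no drag — flights last ≲ 50 ms over
≲ 10 cm, where aerodynamic corrections are secondary for a ~75 mg body),
and constant angular velocity (no in-air torque; consistent with the
50 mm observation that take-off and whole-jump spin agree). All paths are
evaluated from the closed-form parabola — the sampler discretizes, never
integrates — and an independent Euler integrator at dt = 10 µs agrees to
< 0.1 mm in the tests. An inverted landing means the body angle at
contact is within `success_tolerance` (default 0.35 rad ≈ 20°, the
package's operationalization of "landed and held on") of a half turn from
take-off, in either spin direction. g defaults to 9.81 m·s⁻².

## Synthetic-study generator

The generator emulates the study design: 7 animals (5 M / 2 F), masses
uniform on 0.0678–0.0822 g, body lengths ~N(14.6 mm, 1 mm) truncated
positive, hind-leg length exactly 1.37 body lengths (split evenly femur /
tibia); 151 jumps assigned 47/53/51 to the 0.050/0.075/0.100 m targets,
round-robin over animals (per-animal counts are not published; round-robin
is an assumption); 2000 Hz sampling.

Responses (lv, av, FTJ rest, FTJ take-off) follow a random-intercept
model per height: value = height mean + animal intercept + residual.
Height means and SEs default to the reported values; between-jump SD is
recovered as SE·√n_height. The intercept takes `animal_sd_fraction`
(default 0.5 — the study reports no variance components; this is an
assumption) of that SD, the residual the complementary √(1−f²) share.
The FTJ take-off mean at 75 mm (136.5°, SE 3.5) interpolates the reported
129°→144° range; the resting FTJ level (100°, SE 3) is unreported and
chosen as a plausible crouched value, consistent with "no height effect
at rest".

Physical floors truncate the draws (av > 0; lv above ~0.6 of the
ballistic minimum √(2g·(h−y0)), below which no take-off speed can realize
the jump). Naive resampling above a floor would inflate the mean, so the
pre-truncation location is shifted so the post-truncation *conditional*
mean (given the animal intercept) equals the intended one — the marginal
per-height mean then equals the configured mean, which is what the
recovery tests check. Under heavy truncation the realized spread is
slightly sub-nominal; means are exact.

The sampled linear velocity is the **whole-jump secant** velocity — the
quantity the study's formula defines — and the generator numerically
solves for the take-off speed whose ballistic flight (including the
rotating head's contact geometry) realizes that secant. Each trajectory
then has three phases: ≥ 10 resting frames (body level, tarsus planted);
a constant-acceleration stance carrying the centroid from `rest_height`
(8 mm) to the take-off height `y0` while the body spins up to the
take-off rotation and the FTJ opens linearly with displacement; and
closed-form ballistic flight with constant rotation until the head
reaches the target. `y0` defaults to 24 mm: this is a reconciliation
device, not a reported value — it makes default air times (~16/29/43 ms)
bracket the reported 20–44 ms, which the reported take-off speeds cannot
do from a floor-level start. A corollary the package does not hide: at
those air times a 47 rad/s spin rotates ~0.9 rad, not the π of an
inverted landing — the reported air times, spins and the 180° rotation
are not simultaneously satisfiable in any ballistic model, so generated
study jumps match the printed velocities and air times, and the π
rotation lives in the flight simulator where the spin is chosen to land.

Leg points are placed to *encode the FTJ angle*, not anatomical segment
lengths: tarsus planted on the substrate through stance (folding against
the body in flight after a 3 ms hold, so the take-off frame still shows
the take-off angle), with the ftj vertex on the isoceles locus realizing
the target interior angle. With y0 = 24 mm and ~20 mm legs, a planted
tarsus with true segment lengths is geometrically impossible at take-off;
since the angle estimator is length-free, the encoding sacrifices nothing
the pipeline measures. I.i.d. Gaussian noise (default SD 0.1 mm) is added
to every coordinate last. Ground truth for every estimated quantity is
stored beside the data and never read by the analysis.

What the generator does **not** emulate: digitization artifacts beyond
i.i.d. noise (no autocorrelated tracking drift, no occlusions), in-air
spin changes (the 100 mm take-off vs whole-jump spin discrepancy reported
in the source), limb-counterweight dynamics, non-vertical take-off
directions (supported but defaulted off), or any within-jump coupling
between lv and av — within a height they are independent draws, so the
pooled per-jump lv–av correlation is attenuated toward zero and the
anti-ordering lives in the height structure (the analysis drivers center
within animal before correlating across height cells). Passing recovery
tests therefore demonstrate estimator correctness under this noise model,
not robustness to real digitization pathologies.

## Inference

Per-height summaries report mean and SE = SD/√n. The height-effect test
is a stratified permutation test: values are centered within animal, the
statistic is the variance across heights of the per-height means, and the
null permutes height labels within each animal (the exchangeability that
holds when height is irrelevant for every animal). P-values use the
add-one rule, so min p = 1/(m+1); animals seen at a single height are
excluded with a warning. Pairwise contrasts are the same test on height
pairs with Holm correction. Type-I error is verified at ~5% over 200 null
replicates in the acceptance suite. Mixed-effects models with
Satterthwaite ANOVA are intentionally out of scope.

## Determinism and problem sizes

Every random quantity derives from a single integer seed through
`numpy.random.SeedSequence` spawning (roster, animal effects, one child
per jump), so studies re-generate byte-identically and stages can be
re-run in isolation. Default problem sizes — one 151-jump study for
recovery checks, 200 replicates for the type-I calibration, 999–9999
permutations for reported p-values — were chosen so the full suite and
the acceptance script each run in well under a minute on one core.

## Known limitations

- The analysis consumes digitized coordinates; video processing is out of
  scope, as are 3-D effects (yaw/roll, out-of-plane motion).
- The effective moment arm is a fitted descriptive parameter of the beam
  abstraction, not a measurement of leg geometry.
- The stationary-frame FTJ bias and early-contact bias above are inherent
  to threshold-based event detection; both are quantified and small at
  the study's noise level but grow with tracking noise.
- With 7 animals and a 0.5 intercept share, per-height sample means carry
  roster-level sampling variability ~1.6× the nominal SE; single-study
  recoveries should be judged against that, as the tests do.
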