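# Methods

This note documents the models behind the package, the defaults and why
they were chosen, and what the synthetic components do and do not emulate.

## Light field

The scene illumination is a three-part directional field in a right-handed,
z-up world frame (azimuth clockwise from +y):

* **Diffuse sky.** The CIE general-sky two-factor form: relative radiance is
  a *gradation* `phi(Z) = 1 + a exp(b / cos Z)` of the element's zenith
  angle times a scattering *indicatrix*
  `f(chi) = 1 + c (exp(d chi) - exp(d pi/2)) + e cos^2 chi` of its angular
  distance from the sun, normalized so that the zenith leaves radiance
  `zenith_radiance`. The default coefficient set is the standard clear
  ("sunny") sky, low turbidity (a = -1, b = -0.32, c = 10, d = -3,
  e = 0.45); a standard overcast set (a = 4, b = -0.7, c = 0) and an
  isotropic set are provided, and any coefficients can be supplied. Which
  clear-sky variant and sun/diffuse balance the original rendering system
  used is not recoverable, so both remain configurable.
* **Direct sun.** A delta beam at azimuth 270°, altitude 45° by default
  (the experiments' arrangement: above and behind a viewer facing azimuth
  90°). Its strength defaults to 5x the diffuse horizontal irradiance — a
  typical clear-day ratio. All radiometry is single-band and in arbitrary
  linear units; every downstream quantity is a ratio, and normalized
  results are invariant to a global rescale of the light field (tested).
* **Ground.** A constant-radiance plane reflecting `ground_albedo`
  (default 0.25, typical vegetated ground) of the horizontal sun + sky
  irradiance. One bounce only: ground light reaches only downward-facing
  patches, and the next-order term is below albedo² of the diffuse term.

**Irradiance integration.** The irradiance of a unit normal is
`E = E_sun max(0, n·s) + ∫ L(ω) max(0, n·ω) dω`. The diffuse-sky part is
integrated on a fixed world-frame product rule — Gauss–Legendre in the
cosine of the zenith angle times uniform azimuth, 64 x 32 nodes by default
(minimum accepted 16 x 8) — with the incidence cosine clipped at the
patch's own horizon; the ground contributes its exact tilted-patch view
factor `pi L_g (1 - n_z)/2`. Placing the quadrature in the world frame
keeps the sky/ground discontinuity out of the integration domain (only a
derivative kink from the clipped cosine remains), makes the sampled sky
radiances reusable across all face normals, and converges to ~0.05%
relative at the default resolution (doubling the rule changes results by
< 0.1%; agreement with a 10^6-sample cosine-weighted Monte-Carlo oracle is
within 0.5%). No occlusion is modelled anywhere: the experimental
arrangement was chosen to avoid cast shadows, and the bodies are convex.

## Bodies and poses

The target is a (60, 20, 20) mm ellipsoid (120 mm long), meshed by
icosphere subdivision (20·4^k faces; k = 3, 1280 faces, by default). Leaf
distractors start from the same ellipsoid, flatten the vertical short axis
by 0.1 (the flattening amount is unstated in the source experiments; 0.1
makes leaves effectively laminar at 4 mm thickness), then fold about the
long axis: each vertex rotates by an angle proportional to its signed
lateral offset so the tangent planes at the lateral extremes meet at the
fold angle (smooth curvature; a rigid two-half crease mode is available
since the original parametrization is not recoverable). The lateral extent
is then rescaled so the leaf's projected outline matches the unfolded
ellipse — distractors and target share a 2D outline, leaving shading as
the only identity cue. The rescale slightly re-tilts normals; geometric
tests of the fold itself can disable it.

Poses are pitch (long axis out of horizontal, ±90°), roll (spin about the
long axis, ±180°) and yaw (about the world vertical, ±180°), applied about
the body centroid in the intrinsic order roll → pitch → yaw (each about
the body's current axes, yaw about world z). Every experiment varies one
angle at a time, so the composition order does not affect any reported
condition. Leaf pitches drawn outside ±90° are folded into the canonical
range through the Euler equivalence (pitch → 180° − pitch with roll and
yaw flipped by 180°).

**Reference pose.** In the scenes the viewer looks toward azimuth 90°, so
at the reference orientation the body lies broadside — long axis along
world y, dorsal side up (`scene_pose`). With the sun at azimuth 270° this
reproduces the experimental geometry: sun perpendicular to the body axis,
45° up, in the vertical plane through the viewing axis. Countershading
optimisation and all departure sweeps start from this pose.

## Optimal countershading and apparent shading

For a Lambertian body the reflectance `refl(x) = pi rad_hor_leaf / irr(x)`
makes every face leave the radiance of a horizontal upward-facing leaf
patch (default leaf albedo 0.5), so at the reference orientation the body
renders flat and matches the foliage. The formula can demand albedo > 1 on
faces turned away from the light (under the default 5:1 sun the map spans
~0.35-3.7); maps are **unclamped by default**, which keeps the flatness
identity exact — with map and rendering on the same quadrature the
reference radiance is constant to machine precision, and to ≲0.5% across
quadratures. A clamp-at-1 mode (what a physical or renderer-constrained
stimulus would use) is provided and logged; it breaks flatness only on the
darkest faces.

*Apparent shading* is max − min outgoing radiance over the body, by
default over viewer-visible faces (back-face test against the +x viewing
direction); whether the original figure used visible or all faces is
unstated, so both modes exist, and both are monotone in departure. The
statistic is computed on face radiances, not pixels, making it independent
of image resolution. Sweeping pitch, roll and yaw over
{0, 15, 30, 45, 90}° and dividing all fifteen values by their joint
maximum gives the shading curves; the global maximum is exactly 1 by
construction (it lands on yaw 90° under the default geometry, where the
pattern is fully misaligned with the illumination gradient).

A caveat on comparisons with a uniform body: at the reference orientation
the countershaded body's shading is ~0 and the uniform body's is large,
but beyond ~15° the rotated pattern *modulates* radiance on top of the
illumination gradient and its max − min range can exceed the uniform
body's. The behavioural advantage of countershading at all orientations is
a claim about detectability, not about this physical statistic; no theory
links the two, and the package does not assert dominance beyond the
reference orientation.

## Scenes, rendering and designs

A stimulus holds one target plus 20 or 40 leaves on a fronto-parallel
plane. Centres are drawn i.i.d. uniformly and the **whole scene** is
rejected until every pairwise distance is ≥ 1.3 leaf lengths (156 mm), so
accepted scenes follow the uniform distribution conditioned on the
separation rule; per-item resampling would bias positions toward the
borders. The default plane side is 27.5 leaf lengths (3300 mm): with 41
items the acceptance probability of a whole-scene draw is ~3·10⁻³, safely
inside the 10⁴-attempt budget, whereas at the display's nominal
item-to-field ratio (~8.3 leaf lengths) the required packing density is
beyond the jamming limit of random placement and no admissible scene can
be drawn. The plane side is a parameter; the on-screen angular metadata
(10.58° field) is carried separately.

Leaf poses randomize about horizontal-upward: roll ~ N(0°, 50°),
yaw ~ N(0°, 10°), pitch ~ U(−180°, 180°], fold angles ~ N(20°, 20°)
truncated to [0°, 90°) (the untruncated distribution has mass at
meaningless negative folds).

Rendering is flat-shaded rasterization with a depth buffer under an
orthographic camera along +x (items lie on one plane; perspective at ~1°
item sizes is negligible). Per-face radiance is albedo·irradiance/π;
backdrop and implied ground plane render at the horizontal-leaf radiance;
scene rendering defaults to a 32 x 16 quadrature and subdivision-2 leaf
meshes (the statistics of interest are face-level, not pixel-level).
Tone mapping divides by the 99th-percentile pixel and clips to [0, 1]. In
these synthetic scenes the constant backdrop is itself near that
percentile, so display images show items against a near-white field;
linear rasters (32-bit float TIFF) are the quantitative output, 16-bit PNG
the display output.

Designs are 200 trials with the five departure levels represented 40 times
each and the two set sizes balanced within level (20 per cell), shuffled
by seed; per-trial scene seeds are drawn from the same generator.

## Synthetic observers

The generator produces the data-generating process the analysis assumes —
its purpose is to make the statistics testable end-to-end, not to model
search mechanisms (no saliency, eye movements or diffusion):

    u_j ~ N(0, sigma_u²),  v_j ~ N(0, sigma_v²)          (participant j)
    P(correct) = g + (1-g) logistic(beta0 + beta1 s + u_j)
    rt ~ Gamma(k, mean mu),
    log mu = alpha0 + alpha1 s + alpha2 exp(-e s) log(n) + v_j

with s the normalized apparent shading of the trial's departure level and
n the set size. Defaults: beta0 = 0, beta1 = 3 (accuracy ~0.5 at the
reference, ~0.95 at full shading), sigma_u = 0.8; alpha0 = 1.18,
alpha1 = −1.5 (mean RT ~8 s at reference with 20 items, ~1.5 s at full
shading), alpha2 = 0.3 log-s per log-item, efficiency decay e = 3 (the
set-size slope at s = 1 is 5% of its s = 0 value: search becomes
efficient when the target is conspicuous), k = 4 (RT CV = 0.5),
sigma_v = 0.3. These reproduce the qualitative behavioural pattern —
accuracy rising, RT falling, set-size cost vanishing at 90° — and are
deliberately not calibrated to any published figure; passing tests
demonstrate the machinery recovers whatever structure of this form is
present, not that real observers have these parameter values. The guess
floor g models the forced-choice identification stage (1/(n_items + 1));
the mixed-model analysis ignores it, so g = 0 is the default for
recovery studies.

## Mixed models

Accuracy is analysed with a binomial-logit GLMM and reaction times with a
Gamma GLMM, both with a per-participant random intercept and the departure
level as a 5-level treatment-coded factor. No installed Python package
fits these by maximum likelihood, so the marginal likelihood is
implemented directly: per participant, the random intercept is integrated
out by **adaptive Gauss–Hermite quadrature** — an inner Newton search
centres each participant's integrand at its mode and rescales by its
curvature before applying the Hermite rule (25 nodes by default; 1 node is
the Laplace approximation; 25 vs 50 nodes changes the log-likelihood by
< 1e-4 on the test fixtures). The fit matches lme4's `glmer` at equal
node counts to ~1e-4 in log-likelihood and estimates (tested), and
collapses onto the ordinary GLM when the random-effect variance hits zero.

The Gamma link is log by default — the source analysis does not state its
link, and log is the numerically safe standard for reaction times — with
the inverse link available; the link is recorded in the fit. RT models
use correct trials only by default (configurable: whether the original
analysis filtered errors is unstated). The Gamma shape is estimated
jointly by ML. Quasi-separation (an all-correct design cell) triggers a
warning and a weak Gaussian penalty (sd 5) on the fixed effects.

Reported chi-square statistics are likelihood-ratio tests of the 5-level
factor against the intercept-only model (df = 4), using 2(llf_full −
llf_null) against chi-square. Pairwise level comparisons use the
single-step ("Tukey") adjustment: each contrast's adjusted p is
1 − P(max_j |Z_j| ≤ |z_i|) under the joint normal distribution of the ten
contrast z-statistics, whose correlation comes from the observed-
information covariance. The joint probability is evaluated by scrambled-
Sobol quasi-Monte-Carlo in the contrasts' rank-4 principal subspace
(2^17 points, fixed seed): reproducible, accurate to ~1e-4 against the
Genz algorithm, and fast enough for error-rate simulations. Standard
errors come from a central-difference Hessian of the negative
log-likelihood at the optimum.

Search efficiency is summarized per level as (mean RT at 40 − mean RT at
20)/20 items over correct trials, with seeded bootstrap SEs (1000
resamples).

## Problem sizes and numerical choices

Tests and the acceptance script run at the study's own scales: 1280-face
target meshes, 64 x 32 irradiance quadrature, 200-trial designs, 10
participants per experiment, 500 null replicates for the type-I-error
check and 200 for family-wise error, 100 scenes for the separation check.
Optimizer: L-BFGS-B on (beta, log sigma_u[, log shape]) with a
derivative-free polish when the finite-difference line search stalls at
the optimum; log-scale parameterization keeps variance and shape positive,
with sigma_u bounded below at e^-8 (a boundary fit reports sigma_u ≈ 0).

## Known limitations

* Radiometry is single-band; no colour, no display calibration.
* No cast shadows or inter-reflections (faithful to the experimental
  arrangement but not to general scenes), and the ground bounce is
  single-pass.
* The flat synthetic backdrop makes the 99th-percentile tone map clip the
  background itself; real rendered backdrops had spatial variation.
* The observer model is a generative stand-in with monotone links; it
  contains no mechanism of search and cannot predict absolute
  detectability.
* The whole-scene sampler needs a sparser plane than the display's nominal
  item-to-field ratio; item density on the rendered stimulus is therefore
  lower than on the original display.
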