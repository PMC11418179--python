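# Methods

This note documents the models, numerical choices and validation logic of
`strikescape`, in the package's own terms.

## Landmark ingestion

Pose-estimation exports store a coordinate array plus a node-name list,
but the axis order differs between tools and versions. Axes are resolved
by shape: the length-2 axis is the coordinate pair, the axis matching the
node-name list length is the node axis, and for 4-D arrays the smaller
remaining axis is the track axis. When two length-2 axes are both
plausible (a two-track file), the trailing axis is taken as coordinates —
the common `(…, nodes, 2)` convention. Genuinely unresolvable layouts are
an error, never a guess, as are node labels missing from the editable
alias table.

Missing detections are NaN and define the missing mask. Gap filling
linearly interpolates missing runs of at most `max_gap_frames` (default
3, ≈ 2.7 ms at 1100 fps — short enough not to fabricate kinematic
events) and never extrapolates leading/trailing gaps, so observed
coordinates are never altered and clip edges cannot acquire invented
events. No confidence thresholding or temporal smoothing is applied by
default; a 3-frame median filter is available behind a flag.

## Kinematic variables

All geometry is metric (distances and angles), so the image-coordinate
convention is irrelevant and the five variables are invariant to rigid
motion of the camera frame — a property the test suite asserts on random
rotations/translations.

The 20 %-of-peak-gape event uses the *last* upward crossing of
0.2 × peak before the peak frame, linearly interpolated between the
bracketing observed frames; scanning backward makes the event robust to
pre-strike mouth flutter. TTPG is (peak frame − crossing) × frame
interval; at 1100 fps the interval is 0.909 ms to the printed precision.
Ram speed is the Euclidean displacement of the pupil between its
(interpolated) positions at the crossing and at peak gape, divided by
TTPG; the paper-style alternative of a horizontal-only displacement is a
config choice, not a default, since "distance traveled" does not specify
a projection. The minimum lower jaw angle is taken at the jaw-joint
vertex between the rays to the lower jaw tip and to the opercle landmark
(the ventral reference available in the five-landmark set; data with a
dedicated preopercle point can remap it via the alias table), restricted
to frames in [⌈t20⌉, peak-gape frame].

The peak search spans the whole clip by default because gel-contact
frames are not annotated; a frame window is accepted where users have
one. Strikes whose gape never drops below the threshold before the peak
(baseline too open) are flagged with TTPG undefined rather than given a
fabricated crossing; strikes with > 20 % missing frames inside the TTPG
window are flagged `low_quality` but still reported.

## Mixed models

For repeated strikes by the same fish, each response is modeled as
y = Xβ + Zb + e with a single random intercept per individual,
b ~ N(0, σ²_b), e ~ N(0, σ²_e). REML estimation profiles the variance
ratio γ = σ²_b/σ²_e: for fixed γ the fixed effects are GLS and σ²_e has
a closed form, so the criterion is a 1-D function of log γ, minimized by
bounded scalar search over three log-scale brackets with the boundary
γ = 0 always evaluated explicitly. (I + γZZᵀ)⁻¹ is block diagonal with
closed-form Woodbury blocks, so no dense n × n algebra occurs. On
balanced one-way layouts the estimates coincide with the classical ANOVA
estimators MSW and (MSB − MSW)/m to 1e-6, and on general designs with
statsmodels' MixedLM — both checked in tests. With a true zero variance
component the estimate lands exactly on the boundary in roughly half of
replicates, the expected behaviour.

Satterthwaite denominator degrees of freedom are computed from the
observed information of (σ²_b, σ²_e) on the unprofiled REML surface
(central finite differences, relative step 1e-5; one-sided in σ²_b at
the boundary). Multi-df type II F tests decompose the contrast
covariance into eigencontrasts, compute a Satterthwaite ν per
eigencontrast, and combine them as ddf = 2E/(E − q) with
E = Σ νᵢ/(νᵢ − 2). Because the default model has no interactions, the
Wald test of a factor's coefficients adjusting for the other factors is
the type II test. Pairwise contrasts of estimated marginal means (which
reduce to coefficient differences under treatment coding in an additive
model) use the studentized range for Tukey adjustment, with per-contrast
Satterthwaite df. The empirical size of the species test under a null
simulation is asserted to lie in [0.03, 0.07] at α = 0.05. Alternative
fixed-effect structures are compared by ML-based AIC (REML likelihoods
are not comparable across fixed-effect structures). A quantile–quantile
residual table is emitted for normality checking; no automatic
transformation is applied.

## Linear discriminant analysis

Axes solve the generalized eigenproblem S_b v = λ S_w v of between- vs
within-class scatter (at most min(groups − 1, variables) axes, ordered
by λ, the per-axis between/within variance ratio). Classification uses
the Gaussian rule with pooled covariance and empirical priors (an
equal-prior flag exists). A singular S_w receives a 1e-8 × trace/p
diagonal ridge only when needed. Because the field's reported
classification rates rarely state the scheme, both resubstitution and
leave-one-out rates are always computed; resubstitution on no-signal
data carries a small optimistic bias (~+1 % at n = 10⁴ with 5
variables), so chance-level calibration is measured on an independent
draw.

## Performance-landscape GAM

The response (bite length, volume = L × W × D, width or depth) is
modeled as parametric terms (species, strike type, linear kinematic
covariates) plus thin-plate smooths. A smooth of d covariates uses the
radial basis η(r) = r² log r (d = 2) or |r|³ (d = 1) about k knots
chosen by deterministic farthest-point thinning of the observed
covariate points (k = 30 for 2-D, 10 for 1-D — generous relative to
n ≈ 130 while keeping the penalized problem small). The conditional
positive-definiteness constraint is absorbed by a null-space basis of
the knot polynomial, giving a penalty that is PSD with null-space
dimension d + 1; within a model each smooth is centered (sum-to-zero
over the training data) so its constant aliases into the intercept,
leaving the linear trend in the smooth's own null space.

For fixed smoothing parameters, β̂ = (XᵀX + Σλᵢ Sᵢ)⁻¹Xᵀy by Cholesky.
λ is chosen by minimizing the exact Gaussian REML score
(n − M_p)(log 2πσ̂² + 1) + log|XᵀX + S_λ| − log|S_λ|₊ with σ̂² profiled
out, using bounded scalar search (one smooth) or Nelder–Mead (several)
from multi-starts λ ∈ {1e-3, 1, 1e3}; a derivative-free simplex was
chosen over Newton steps because the criterion is nearly flat on the
large-λ plateau where finite-difference curvature is unreliable, and
the optimizer is validated against brute-force dense solves (1e-8) and
an independent thin-plate interpolation oracle at λ = 0. Effective
degrees of freedom are traces of the influence matrix
(XᵀX + S_λ)⁻¹XᵀX, per-smooth via its coefficient block; edf is
monotone non-increasing in λ and the penalized RSS monotone
non-decreasing, both asserted over a λ ladder. An R mgcv fit of the
same data serves as a validation-grade external cross-check of the
REML-selected predictions in one test.

Shrinkage smooths add a light penalty on the smooth's null space
(scaled to one tenth of the mean positive penalty eigenvalue by
default) so that an irrelevant covariate's entire term — including its
linear part — can shrink toward zero edf during selection; setting the
null penalty to zero reproduces the plain fit exactly.

AIC is conditional: n log(RSS/n) + n log 2π + n + 2(edf_total + 1),
with total edf plus one scale parameter as the effective parameter
count. This flavor is internally consistent for the package's own model
comparisons; it need not be bit-identical to other software's marginal
or corrected variants, which is why edf-style comparisons against
published values are validation-grade (±15 %) rather than exact. Models
within ΔAIC < 2 are flagged statistically equivalent.

## Surface prediction and peak detection

Surfaces are predicted over a rectangular grid spanning the observed
(gape, protrusion) range with other covariates at reference levels
(most frequent factor level, numeric means). A support mask keeps grid
points within distance d of at least one observation, d defaulting to
the 95th percentile of nearest-neighbor distances among observations —
peaks are never reported from extrapolated regions. Peak candidates
must exceed all 8 grid neighbors with the whole neighborhood supported
(so monotone ramps yield no boundary "peaks"); candidates closer than
two grid steps merge, keeping the higher. Each candidate's topographic
prominence — its height above the highest saddle connecting it to any
higher peak, computed by a descending union-find sweep over supported
cells — must exceed 5 % of the supported surface range; replicate
simulations showed spurious noise maxima with prominence ≤ 1 % of range
versus ≥ 30 % for true optima, so the threshold separates the two
regimes by more than an order of magnitude rather than sitting near
either. Saddle heights between surviving peaks are reported as the
valley diagnostic. A peak within half a neighborhood of the mask edge
cannot be detected; that is the accepted cost of refusing boundary
artifacts.

## Synthetic studies and what recovery does (and does not) show

The generator emulates the structure the analysis assumes: four groups
(scale eaters with roughly twice the generalist gape and far greater
protrusion), 37 individuals, 227 strikes with 1–10 strikes per
individual, 130 strikes with bite dimensions, 1100 fps filming, 0.05 mm
isotropic landmark noise, per-individual random intercepts on every
kinematic variable, and a bite-length performance function that is a
sum of Gaussian peaks over (gape, protrusion) — by default one optimum
at the generalist-typical kinematics (2.5, 2.0) and a higher one at the
scale-eater-typical kinematics (5.0, 6.5), amplitudes 4.0 and 6.5 mm,
residual SD 0.8 mm — so both optima lie inside the sampled kinematic
range, as in the study design being emulated. Bite width tracks the
individual's typical gape (a morphology proxy) and is nearly flat in
strike kinematics; depth is a fraction of length (much shallower for
scrapes); misses (probability 0.1) have all dimensions zero. Dimensions
are redrawn, not clipped, into [0, 15] mm so the cube bound creates no
boundary atom.

Gape and protrusion open along a raised cosine and close symmetrically.
The 20 % crossing is placed exactly on an integer frame by solving the
profile for the baseline gape given the crossing frame; the discrete
extractor is then exactly invertible at zero noise, which is what makes
1e-6-level recovery a meaningful oracle for a sampled signal (with an
arbitrary profile the crossing falls between frames and linear
interpolation alone caps agreement near 1e-3). TTPG targets are snapped
to the frame grid and must span ≥ 3 frames; the jaw angle follows the
gape profile so its minimum lands exactly at peak gape, inside the
extraction window; the head translates rigidly at the target ram speed.

What passing recovery tests shows: the extraction, modeling and peak
detection code inverts data generated under the stated assumptions, at
study-realistic sizes and noise. What it does not show: robustness to
violations the generator does not produce — non-rigid head deformation,
tracking identity swaps, heteroscedastic or autocorrelated landmark
error, strike-type-dependent kinematics, or performance functions
outside the Gaussian-mixture family. Results on real exports inherit
those caveats.

## Problem sizes and determinism

Simulation-based checks use the study-scale defaults above: 100
replicates for landscape recovery, 50 seeds for noisy kinematic
recovery, 1000 null studies for type-I calibration in the test suite
(400 in the faster acceptance script), 10⁴ draws for chance-level
classification. All randomness flows through seeded NumPy generators;
the full-study checksum is reproducible bit for bit under a fixed seed.
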