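# Methods

This note documents the models, simulators, and statistical procedures in
`facesim`, the defaults they run with, and the choices made where the design
was genuinely open.

## Face-space geometry

Faces are points in a D-dimensional latent space (default D = 398, the
first half labeled "shape", the second "texture"); units are SDs of the
generating population and the origin is the average face. A pair's relation
to the origin is (r₁, r₂, θ). Canonical form stores r₁ ≤ r₂ and sets θ = 0
whenever a radius is zero (the direction of a zero vector, hence the angle,
is undefined). Design enumeration crosses all unordered pairs of nonzero
grid radii with all grid angles and, when the grid contains zero, adds one
origin pair per radius value; with k nonzero radii and m angles the count
is m·k(k+1)/2 (+ k + 1 when zero is on the grid). The default 8 × 8 grid
(radii 0–40, angles 0–180°) gives 232 pairs.

Pair construction is exact rather than approximate: a uniformly random
orthonormal 2-frame (e₁, e₂) is drawn by Gram–Schmidt on two independent
standard-normal vectors (redrawing when the residual norm falls below
1e-12), and v₁ = r₁e₁, v₂ = r₂(cos θ·e₁ + sin θ·e₂). Norms and the mutual
angle are exact to floating point, and the orientation is uniform on the
sphere. Angles are degrees at the API surface and radians internally.

## Candidate models

Each model maps a pair to one predicted dissimilarity. Latent models apply
an optional projection (coordinate subset, leading-k subset, or the span of
four unit-normalized "person-attribute" directions) before a Euclidean or
cosine metric. Cosine distance is undefined when a projected vector is
zero; affected pairs are flagged NaN and excluded pairwise downstream
rather than silently imputed.

Feature models run through the synthetic generative map (below): raw mesh
and raw pixel Euclidean distances; an Eigenface space (mean-centered PCA of
a training image set, all nonzero-variance components kept — via the Gram
matrix when dimensionality exceeds the sample count); and configural
models on N = 30 keypoints — order 0 the 3N coordinates, order 1 the
N(N−1)/2 pairwise distances, order 2 those distances divided by their
geometric mean. The order-2 definition is one choice among several ways to
form "ratios of distances": the full set of pairwise ratios grows
quadratically in the distance count, while dividing by the geometric mean
is scale-free, keeps the feature length at N(N−1)/2, and preserves all
ratio information up to a common factor.

## Synthetic data generator

The generator defines the simulated study conditions; its defaults are not
tuning knobs.

**Rendering map.** Affine maps from latents to a 150-vertex mesh (the
first 30 vertices are the configural landmarks, so mesh and configural-0
are distinct predictors) and to a 32 × 32 pixel image. Column j of each
linear map is scaled by 1/(1+j), so low-index latent dimensions matter most,
as in a PCA-ordered face model; the image map's columns are orthonormal
before scaling, making its singular values exactly the decay profile. The
zero latent maps to the base (average) face.

**Observer model.** Perceived dissimilarity of a pair with generating-model
distance d is the 4-parameter logistic f(d) = lo + (hi−lo)/(1+e^(−k(d−x0))),
defaults lo = 0.05, hi = 0.90, x0 = 25, k = 0.10 — a curve that is near
floor for identical faces, saturates around 50–60 SD of distance, and puts
maximal sensitivity at moderately distant faces. Each participant adds a
stable per-pair offset (SD `participant_sd`) and each session adds fresh
placement noise (SD `noise_sd`); the sum is clipped to the [0, 1] screen.
Noise acts on the placement scale after the sigmoid because the measurement
is a screen coordinate. Each trial (a random disjoint partition of the
pairs, 8 per trial → 29 trials for the 232-pair design) carries an identity
line at τ = 0.55 plus placement noise (SD 0.02); the binary same/different
label is re-derived from the placed line, so labels and continuous
judgments can never disagree.

**Noise calibration.** With signal variance s² = Var(f(d)) across pairs,
participant-offset variance u and session variance v, the between-session
correlation is (s²+u)/(s²+u+v) and the between-participant correlation of
m-session-averaged judgments is s²/(s²+u+v/m). Solving at the target
reliabilities 0.85 / 0.80 for the default design gives the defaults
participant_sd = 0.095, noise_sd = 0.111; simulated reliabilities land
within ~0.01 of the targets (screen censoring shrinks signal and noise
together).

**What the generator does not emulate.** Real faces, familiarity effects,
caricature percepts, view/lighting variation, drag-and-drop kinematics,
trial-order or anchoring drift. Passing tests therefore certify the
*analysis machinery* — that each statistic recovers known ground truth
under its own assumptions — not any claim about human vision.

**Censoring and the psychometric estimand.** Because placements are
censored at the screen edges, the measurable mean response is
E[clip₀₁(f(d)+ε)], not f(d): the lower asymptote is pulled up a few
hundredths and the apparent slope steepens by ~10% at calibrated noise.
Parameter-recovery checks therefore compare fits against the logistic
description of that censored curve; noiseless recovery is checked against
the raw parameters.

## Evaluation

**Cross-validation.** 10 repeats by default; participants split 50/50 and
stimuli 80/20 into train/test, independently per repeat; at least 10 test
stimuli are required. With the sigmoid transform, the 4PL is fitted on
(model distance → mean training-participant judgment) over training stimuli
only, then applied to test-stimulus predictions. Performance is the Pearson
r against each held-out participant's session-averaged judgments over
held-out stimuli, averaged over participants and repeats. Raw mode uses
distances directly (Pearson r is affine-invariant).

**Sigmoid fit.** Bounded least squares (0 ≤ lo, hi ≤ 1, k > 0, x0 within
one data range of the observations) with five starts placing x0 at the
20/35/50/65/80th distance percentiles and a secant-based initial slope;
best-loss solution wins. Goodness of fit is the coefficient of
determination. A bounded logistic only approximately nests a straight line
(R² gap ≈ 0.013 on noiseless linear data over these designs), so
linear-vs-sigmoid comparisons are read with that in mind.

**Noise ceiling.** Standard RSA convention: upper bound = mean correlation
of each participant with the include-self group mean; lower bound = the
same with the leave-one-out mean.

**Inference.** Percentile bootstrap over stimuli (2,000 resamples, 95%)
for CIs; two-sided Wilcoxon signed-rank tests over participants for model
pairs, multiplied by the number of pairs (Bonferroni) and capped at 1;
zero differences dropped, with p = 1 when all differences vanish (SciPy
uses the exact null for n ≤ 25 without ties, a normal approximation above).

**NNLS combination and unique variance.** The combined model is fitted per
repeat by nonnegative least squares of training-participant mean judgments
on the model-distance matrix plus an intercept column (the intercept is
thereby constrained nonnegative — innocuous for judgments in [0, 1]) and
evaluated exactly as a single model. Unique variance of model m for one
participant is R²(full NNLS GLM) − R²(GLM without m), nonnegative by
construction since the reduced feasible set is nested; one-sided Wilcoxon
tests assess it across participants.

## Identity analyses

The identity line is averaged over trials within participant, then
summarized (mean, SEM) across participants. Each geometric predictor
(Euclidean distance, θ, |r₁−r₂|) feeds a univariate maximum-likelihood
logistic regression (L2 ridge 1e-6, which also caps coefficients under
perfect separation; separable data are flagged); the ROC is traced over 101
probability thresholds in [0, 1] (score ≥ threshold ⇒ "same") and AUC is the
trapezoidal area, which converges to the tie-aware rank statistic
P(s⁺ > s⁻) + ½P(s⁺ = s⁻) as the grid densifies. Judgments are pooled across
participants by default; a per-participant variant averages AUCs.

## Isotropy and uniformity

Isotropy: per shared participant, correlations r(A1,A2), r(A1,B), r(A2,B)
between per-pair judgments of the two same-set sessions and the
different-set session; one-tailed paired t and Wilcoxon tests of
within-set > mean between-set. Both tests are reported. Isotropy
simulations run at a reduced latent dimension (16) where the
direction-dependent component of an anisotropic metric is visible at desk
scale — at D = 398 a 3:1 axis weighting perturbs distances by ~1%, far
below session noise.

Uniformity: pairs are split into five equal-count Euclidean-distance bins
(≥ 40 pairs per bin on the default design; bins reduce automatically if a
bin would fall under 10 pairs). Within each bin, mean dissimilarity is
regressed on θ *with the residual within-bin distance as a covariate*:
distance and angle are positively correlated inside a distance bin by
construction of the radius × angle design, so a plain θ slope would flag a
purely distance-driven observer. The partial-slope p-values are combined
across bins by Fisher's method. Degenerate bins (constant judgments or
constant angle) contribute slope 0, p = 1.

## Numerical and reproducibility choices

- Seeds: one master seed; stage i draws `SeedSequence([master, i])` with a
  fixed stage order, so stages rerun independently and identically.
- CSV floats are written at 17 significant digits and parsed in
  round-trip mode; artifacts carry seed and config-hash headers.
- The Eigenface fit keeps components with variance above 1e-10 of the
  leading variance; n mean-centered samples yield n−1 such components.
- Model-zoo cosine models report NaN (flagged, excluded pairwise) for
  zero-radius pairs rather than raising, since the default design contains
  the origin.
- Simulation sizes in the validation suites (e.g., 26 participants ×
  2 sessions, 50–100 simulated experiments, 5-repeat cross-validation in
  the ranking suite) were chosen to keep each suite to a few minutes while
  leaving decisive margins; the ranking suite compares against the
  main model set and omits the shape-only/texture-only/leading-k subspace
  variants, which are near-duplicates of the full-space generating model
  (predicted-distance correlation ≈ 0.99 under isotropic latent sampling)
  and thus uninformative as ranking competitors.

## Known limitations

- The generative rendering map is linear; real rendering is highly
  nonlinear, so feature-model performances here say nothing about their
  merits on real images.
- Participant idiosyncrasy is modeled as additive per-pair offsets; real
  observers differ in their psychometric curves as well.
- Anchor pairs are assumed to calibrate all participants identically; no
  per-trial renormalization is simulated, and judgments are summarized by
  absolute vertical position.
- The uniformity statistic tests a linear within-bin angle effect;
  nonmonotone angle effects at matched distance would need a different
  alternative.
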