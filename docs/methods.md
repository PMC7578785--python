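# Methods

## Behavioural model

Choices over 50/50 mixed gambles are modelled as a logistic regression of
the binary accept/reject decision on the gamble's gain and loss magnitudes
(losses stored as positive magnitudes; their sign lives in the
coefficient). Subjective value is the intercept-free linear predictor;
decision entropy is the binary Shannon entropy (base 2) of the model's
acceptance probability, and iDE its negative. The probability of being
correct is max(p_accept, 1 − p_accept), computed from the fitted model
rather than observed accuracy. Entropy is evaluated on min(p, 1 − p) so
that DE(p) = DE(1 − p) holds *exactly* in floating point — rank-based
validation statistics depend on that tie structure.

### Estimation

Coefficients are maximised by Newton/IRLS on a ridge-penalised Bernoulli
likelihood. The stake coefficients carry a fixed weakly-informative
Gaussian prior (λ = 0.75, i.e. prior SD ≈ 1.15 logit units per currency
unit); the intercept is unpenalised. The penalty does not grow with the
number of trials, so the estimator is asymptotically the MLE, while small
or nearly separable samples — where the unpenalised likelihood is flat and
estimates are heavy-tailed — stay on scale. A near-unpenalised probe fit
detects separation (monotone likelihood classifies the data perfectly or
runs away); separable data are flagged, and only when the main fit itself
runs away (|coefficient| > 10 or non-convergence) is it refit with λ = 2 on
all coefficients, which also keeps one-class response data finite. The
tests cross-check the estimator against an exact-likelihood grid search and
against statsmodels' unpenalised Logit on well-identified data.

On all-positive stake designs the intercept is the weakly identified
direction (its sampling SD is ≈ 0.37 at 256 trials for coefficients up to
±2); recovery bounds are therefore stated for the two stake coefficients.
The recovery suite uses a 16×16 crossing of stakes on linspace(0.25, 6)
currency units, chosen by a design-time Fisher-information scan so that
coefficients anywhere in ±2 yield non-degenerate choice probabilities.

### Exclusions and validation

Participants are excluded when a gain or loss coefficient lies more than
2.3 group SDs from the group mean (two-sided, SD over all participants
including the candidate, ddof = 1) or when mean framewise displacement
exceeds the group mean + 2.3 SD (one-sided; only high movers are excluded).
Zero group SD disables the corresponding rule. The validation report
computes per-participant Spearman correlations SV↔p_accept and
iDE↔p(correct) (exactly 1 whenever SV, respectively |p − 0.5|, is
tie-free), their group mean/SD and one-sample t, and a Welch t comparing
mean iDE for weak vs strong responses built from per-participant,
per-response-type means (two observations per participant on each side,
matching a four-level response scale; the non-integer degrees of freedom
come from Welch–Satterthwaite).

## Synthetic cohort

The generator is the study-design mirror of the analysis, with ground truth
known everywhere.

- **Task.** Gains and losses are crossed orthogonally. Equal-indifference
  condition (default): gains 10–40 in steps of 2, losses 5–20 in steps of
  1, so the loss range is half the gain range; equal-range condition: both
  5–20. The default 64 trials/run × 4 runs exactly exhausts the 256-cell
  crossing, making the gain–loss sample correlation identically zero.
  Trials last 4 s with a uniform 2–6 s inter-trial interval; TR = 1 s.
- **Choices.** accept ~ Bernoulli(p_accept) under generating coefficients
  drawn as β_gains ~ U(0.08, 0.25), loss-aversion ratio ~ N(2, 0.3)
  truncated to [1.2, 3], intercept ~ N(0, 0.5) — acceptance probabilities
  span the unit interval on the default grids without saturating. The
  four-level response splits each choice at θ = 0.75 on p(correct)
  (configurable; the threshold is a modelling convenience — the underlying
  model is fit only to the binary distinction).
- **Ground-truth maps.** 20³ voxel grid, 3 mm voxels. "Aligned" mode
  builds SV and iDE weights around one smooth field: a linear gradient from
  +1 to −1 along one axis plus Gaussian-smoothed noise (smoothness 1.5
  voxels, periodic boundaries; see below), with small independent
  perturbations per map, so the two weight maps share sign almost
  everywhere by construction. "Independent" samples two unrelated smooth
  fields; "opposed" flips one sign. Default amplitudes: intercept 4,
  SV 0.25 signal units per logit unit, iDE 8 per bit — the two modulators
  have very different natural ranges (SV spans ~±10 logit units, centred
  iDE ~±0.5 bits), so per-modulator amplitudes put both effects at
  comparable, detectable SNR.
- **BOLD.** Voxel time series = baseline 100 + intercept/SV/iDE weights
  times the HRF-convolved trial regressors + low-order random drift +
  optional motion-coupled nuisance + stationary AR(1) noise (σ = 1,
  ρ = 0.3). The generator calls the same convolution code as the
  first-level design builder, which is what makes the noise-free
  end-to-end identity exact; the convolution itself is validated against an
  independent fine-grid quadrature in the tests, so the shared code path is
  oracle-checked, not self-confirming. Motion parameters are smoothed
  random walks; framewise displacement sums absolute parameter changes with
  rotations on a 50 mm sphere.

What the generator does **not** emulate: physiological noise and spikes,
susceptibility distortion, spatial non-stationarity of noise, between-run
coefficient drift, and real anatomical structure. Passing tests therefore
demonstrate the *statistical machinery* under its stated assumptions, not
performance on real scanner data.

## First-level GLM

Double-gamma HRF (delays 6/16 s, dispersions 1, undershoot ratio 6),
normalised to unit peak independently of the sampling grid. Boxcars are
built at 0.1 s microtime, convolved, and sampled at volume times; SV and
iDE amplitudes are mean-centred across the run's trials *before*
convolution, so a constant shift of all SV values leaves the design
unchanged. Each convolved task column contributes a temporal derivative
(post-convolution central differences); seven motion confounds enter
unconvolved; no orthogonalisation is applied between regressors — with
correlated modulators the joint model remains identifiable, which the
noise-free identity test exercises directly.

High-pass filtering projects out a discrete-cosine basis (periods above the
100 s cutoff) augmented with an explicit linear term, applied identically
to data and regressors; the projection is idempotent and annihilates exact
linear trends. Spatial smoothing is a per-volume Gaussian with FWHM 5 mm
converted through the voxel size.

Serial correlation: per-voxel AR(1) Cochrane–Orcutt prewhitening. The
AR coefficient is estimated from OLS residuals, clipped to [0, 0.95] and
quantised to 0.01 so that voxels sharing a coefficient are solved in one
batched least squares. Known limitation: smooth nuisance regressors
(motion walks, derivatives) absorb part of the low-frequency noise and
attenuate the residual-based AR estimate, leaving a small anticonservative
remainder (type-I ≈ 0.10 at nominal 0.05 under ρ = 0.5 with the full
design; nominal with task-only designs) — the same qualitative behaviour
as tool-default autocorrelation estimators. Runs are pooled within subject
by inverse-variance weighting; noise-free simulations have zero run
variance, which pooling treats as an error (inspect run betas directly in
that regime).

## Group level and inference

The group model is a voxelwise one-sample random-effects test
(method-of-moments between-subject variance), with an optional single round
of Huber deweighting (c = 1.345 on standardised residuals) whose weighted
mean and effective-n t statistic shrink outlying subjects. t maps convert
to Z by matching tail mass.

Cluster-level FWE uses a sign-flip permutation null of the maximum
supra-threshold cluster extent (cluster-forming Z = 2.3, 26-connectivity,
corrected p = (1 + #{null ≥ size})/(n_perm + 1)); negative tails negate the
maps. Permutation maps are plain one-sample t maps even when the observed
map was deweighted — a deliberate simplification recorded in the run
report's deviations list. Measured FWE on null cohorts: 0.03 at nominal
0.05 (400 repetitions). Conjunctions take the voxelwise minimum statistic,
with the joint (paired) sign-flip null requiring both permuted maps to
cross the threshold.

The SV-vs-iDE comparison is a paired sign-flip permutation test on subject
differences of Z maps, both directions computed from one permutation pass
(so swapping the inputs exactly swaps the outputs). One-sided permutation
p values convert to Z via the normal quantile — attainable Z saturates at
Φ⁻¹(n_perm/(n_perm + 1)), which is why peak statistics in such analyses
have low variance. Each direction is conjoined with its main effect and
masked by voxels whose absolute group Z favours the tested variable;
cluster-corrected p values come from the same permutations with a
parametric t quantile as the null cluster-forming threshold.

## Joint-coding statistics

Voxels significant for both variables (corrected clusters by default, an
uncorrected |Z| threshold as a config alternative), restricted to the
task-active mask (|intercept Z| ≥ 2.3), are classified by sign pair. The
2×2 table is reported with observed and expected (product-of-marginals)
percentages and the classical χ² (df = 1, no continuity correction).
Because neighbouring voxels are not independent samples, the χ² tail
probability is anticonservative on smooth maps; significance is therefore
also computed by a torus-translation permutation — randomly
circular-shifting one variable's sign structure relative to the other,
which preserves each map's spatial autocorrelation under the independence
null. This is the reason the generator smooths with periodic boundaries:
it keeps the synthetic fields stationary on the grid torus, where the
translation null is exact. Calibration on independent smooth maps: 0.050
rejection at nominal 0.05 (1000 draws); on white maps 0.052–0.058.

ROI overlap reports the percentage of jointly significant ROI voxels with
matching signs (undefined, not zero, when no ROI voxel qualifies).
Map correlations are Pearson r between the two group maps over a mask or
ROI; probabilistic ROI masks are nearest-neighbour resampled and binarised
at 50%. The gradient map z-scores each group map across the mask and sums
them: near zero where effects cancel, large where they agree. The
loss-aversion link counts negative vs positive supra-threshold voxels in
each participant's subject-level SV Z map and rank-correlates the ratio
with behavioural |β_losses/β_gains|.

## Pipeline, problem sizes and reproducibility

A single YAML-serialisable config fixes all parameters; seeds are spawned
per stage from one root seed, so identical configs give identical outputs
(tested). The default cohort — 24 subjects, 4 runs × 64 trials, 20³ grid,
σ = 1 — runs in about a minute on one CPU. The validation suite scales
some studies down to keep iteration fast while preserving the property
under test: FWE calibration uses 12-subject null cohorts on a 16³ grid
with 250 permutations × 400 repetitions; contingency calibration uses 16³
independent maps × 1000 draws with 199 translations; the independent-mode
joint-coding check uses three 12-subject cohorts (map correlation and
contingency need only group maps, not cluster permutations). The run
report names every stand-in for the original tooling (AR(1) prewhitening,
DCT high-pass, method-of-moments mixed effects, permutation cluster
correction) in a `deviations` list, embeds a config hash, and the written
dataset manifest carries seeds and true coefficients so a cohort can be
regenerated bit-for-bit.
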