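# Methods

## The measurement model

A two-channel epitranscriptomic array hybridizes the immunoprecipitated
(IP, m⁶A-containing) and supernatant (Sup, unmodified) fractions of each
RNA sample. Writing T_g for the abundance of transcript g and f_g for its
modified fraction, the ideal linear intensities are IP ∝ T_g·f_g and
Sup ∝ T_g·(1−f_g), each multiplied by a sample/channel scale factor. The
spike-in normalization removes the scale factor by centering each channel's
log₂ intensities on the mean log₂ spike-in intensity of that channel; it is
exact when both channels share the scale factor, and it preserves within-
channel rank order by construction. The m⁶A modification level
100·IP/(IP+Sup) then estimates 100·f_g; by construction
level(ip, sup) + level(sup, ip) = 100, and the level is invariant to any
common rescaling of both channels. The m⁶A quantity (the normalized IP
intensity alone) is retained as a separate reported measure of modification
amount.

Differential methylation between an exposed and a control group is a fold
change of group-mean levels on the linear scale, gated at > 2 or < 0.5
(strict inequalities), combined with a two-sided unpaired t-test on
log₂-transformed levels at p < 0.01 (strict). The test is Student by
default with a Welch option; at n = 5 per group either is defensible, and
the choice is exposed as a flag. Degenerate inputs are defined rather than
undefined: zero within-group variance with equal means gives p = 1, with
unequal means p = 0 plus a warning. Raw p-values drive the calls (matching
the screen's design); a Benjamini–Hochberg FDR column is emitted for
information only.

## The two-stage screen

Stage I uses a high-dose exposure profiled at five timepoints. Genes with
at least one differential call are partitioned into Hyper (hyper calls
only), Hypo (hypo only) and Inconsistent (both; removed). Within a
category, per-gene temporal log₂FC profiles are z-standardized and soft-
clustered with fuzzy c-means (two clusters, fuzzifier 2 by default; both
are configuration). Standardization makes clustering sensitive to profile
*shape*, not amplitude — the known cost is that an exactly constant profile
standardizes to pure noise, so "consistent" membership is never decided on
the standardized space: a sub-cluster is consistent when its mean
*unstandardized* log₂FC profile keeps the category's sign at every
timepoint. Hard assignments take the maximum membership, ties to the
lowest cluster index. Stage II contributes single-timepoint hyper sets
from an independent lower-dose exposure, and the candidate set is the exact
intersection of the stage-I consistent sub-cluster with every stage-II set;
the subset property (candidates ⊆ every contributing set) is checked on
every run.

The fuzzy c-means implementation is the standard Bezdek alternating
scheme (membership update u_ij ∝ d_ij^(−2/(m−1)), center update as the
u^m-weighted mean), run from several random initializations with the best
final objective kept; the objective is non-increasing across iterations.
Points at zero distance from one or more centers split membership equally
among those centers, so a fully degenerate geometry (all profiles
identical) yields the uniform 1/c membership.

## qPCR quantification

All amount arithmetic assumes amount ∝ eff^(−Ct) with amplification
efficiency eff = 2.0 by default (perfect doubling; configurable in (1, 2]).
MeRIP enrichment rescales the IP and input amounts to a common RNA mass
before taking their ratio — enrichment = eff^(Ct_input − Ct_IP) ·
m_input/m_IP with default masses 2000 ng (IP) and 500 ng (input) — so
scaling both masses together changes nothing. Per-group relative m⁶A
levels are group-mean enrichments normalized to the unirradiated control
group, with a delta-method standard error. Primer feasibility gates on the
IP/IgG enrichment ratio (≥ 4 by default); IgG background is reported and
gated, never subtracted. Relative expression uses the ΔΔCt method against
a reference gene.

SELECT (an elongation/ligation-based, antibody-free single-base assay, in
which m⁶A at the interrogated base suppresses product formation) is
calibrated by a linear standard curve of relative product against known
m⁶A fraction. The default normalization defines the relative product as
the 2^Ct value normalized to the 2^Ct value of the 100% m⁶A standard,
r = 2^(Ct − Ct₁₀₀); the alternative reading of the product as template
abundance, r = 2^(Ct₁₀₀ − Ct), is available behind a flag — both give a
linear calibration with opposite slope signs, and the inverse estimator
(fraction = (r − intercept)/slope, clamped to [0, 1] with an out-of-range
flag) works identically under either convention.

Group testing is one-way ANOVA followed by Dunnett's many-to-one
comparison against the control. The Dunnett adjustment is Monte-Carlo:
under the common-variance null with the study's exact group sizes, group
means are drawn N(0, 1/n_i) together with a pooled χ²_df/df variance, the
max over comparisons of |t| is formed, and the adjusted p-value is the tail
probability of that maximum at the observed |t_i|. This is exact for
unbalanced designs up to Monte-Carlo error and is checked against both the
two-group t-test degeneracy and an independent multivariate-t
implementation in the tests. The analytic inequality adjusted ≥ raw is
enforced by clipping, because a finite Monte-Carlo sample can undershoot
it by sampling noise in the two-group case.

## Dose reconstruction

Calibration is inverse regression — absorbed dose (Gy) regressed on the
observed m⁶A level — matching how the models are used at triage time:
measure m⁶A, read off dose. Two model families are provided as
scikit-learn estimators: a per-timepoint quadratic in the level, and an
integrated bivariate cubic in (level, time post irradiation) over all ten
monomials mⁱtʲ with i + j ≤ 3 (the standard reading of a bivariate cubic;
the 16-term tensor basis of degree ≤ 3 per variable is a configuration
option). Both are ordinary least squares via `numpy.linalg.lstsq`; a
rank-deficient design (for example, every observation at a single
timepoint, which needs at least four distinct timepoints for the cubic
time terms) raises an error naming the dependent monomials. Training R²
is reported with each fit, together with 95% confidence bands from the
least-squares coefficient covariance. Negative dose estimates are
reported as-is with a flag by default (transparency for calibration
audits); a clamp-at-zero flag exists for triage-style reporting.

Classification at a dose cutoff c labels a point positive when its actual
dose ≥ c (so at the lowest administered dose the sham group is the sole
negative class) and scores it by the model-predicted dose; AUC is
rank-based (Mann–Whitney, ties credited ½). Cross-validated performance
uses k = 5 folds repeated 100 times: folds are stratified by (dose,
timepoint) group so every fold spans the dose range (stratification by
subject, or none, is available; when any stratum is thinner than k the
splitter degrades to a plain shuffled k-fold with a warning). Held-out
predictions are pooled within each repetition, an AUC is computed per
repetition, and the mean and SD over repetitions are reported. Repetition
r draws its fold seed from SeedSequence(seed, spawn_key=(r,)), so
extending the number of repetitions preserves the per-repetition AUC
prefix.

## The synthetic-data generator

The generator emulates the structure of an irradiated-mouse study: doses
{0, 0.2, 0.5, 1, 2, 4, 6.5} Gy (an optional 10 Gy arm restricted to days 1
and 3), days {1, 3, 7, 14, 28}, five subjects per group. The dose–time
response surface for a relative m⁶A level is

    baseline + A · dᵸ/(dᵸ + Kᵸ) · exp(−ln²(t/t_peak)/(2w²)),

a Hill function in dose (saturating, zero response at dose 0) times a
log-normal kernel in time (unimodal on a log-spaced day grid). The
persistent-marker preset uses A = 3 (≈ 4-fold maximal elevation), K = 3 Gy,
h = 1.5, peak at day 14 with width 1.5 log-days; early-marker presets peak
at day 1. Measurement noise is multiplicative log-normal with mean exactly
1 and coefficient of variation 0.1 by default — m⁶A fold values are
strictly positive ratios, so a multiplicative error model is the natural
choice, and placing it on the response keeps least-squares calibration
unbiased. Array noise is additive Gaussian on log₂ intensities (sd 0.15
by default) and qPCR noise is additive Gaussian on Ct, the standard error
models for those platforms. Planted array effects multiply (hyper) or
divide (hypo) the baseline modified fraction, either at every exposed
timepoint (consistent), or at one designated timepoint (transient);
effects that would push a fraction outside (0, 1) are rejected. Ct tables
are generated by inverting the quantification formulas, so the zero-noise
round trip through the corresponding estimator is exact to machine
precision — this inverse property anchors most of the test suite.

Reproducibility: every simulator is a pure function of its arguments and a
seed, and one global seed expands into fixed, named sub-streams
(SeedSequence spawn keys), so any component of a study can be regenerated
independently.

What the generator does *not* model: probe cross-hybridization and image-
level array artifacts, read-level sequencing data, primer thermodynamics,
absolute copy numbers, between-subject biological variance components
(the study's variance components are not public, so the default noise
magnitudes are chosen for test power, not fidelity), or any dependence of
dose response on sex, age, immune status or radiation quality. Passing
tests therefore demonstrate correctness and calibration of the analysis
machinery under the stated error models, not performance on real assay
data.

## Problem sizes and numerical choices

The default pipeline simulates 2,000 genes (32 planted) and completes in
seconds; calibration experiments in the test suite use 10,000 genes for
the null call-rate check, 200 simulations for coefficient-recovery bias,
1,000–2,000 replicate studies for Monte-Carlo calibration of fraction
recovery and the Dunnett test — sizes at which binomial/Monte-Carlo
standard errors are small enough to make the assertions meaningful while
the whole suite stays fast. Fuzzy c-means runs five random starts with
tolerance 1e−9 on memberships; ties in hard assignment go to the lowest
cluster index. Tables are plain TSV with `%.12g` float formatting so
reruns are byte-identical; model files and the run manifest are sorted-key
JSON containing the seed, every threshold actually used, and a SHA-256
configuration hash.

## Known limitations

- With the default saturating Hill response (K = 3 Gy, h = 1.5), the mean
  separation between the 4 and 6.5 Gy arms is comparable to the cv-0.1
  measurement noise, so the cross-validated AUC at the top-dose cutoff
  plateaus near 0.93 rather than approaching 1; discrimination at the
  highest cutoffs is limited by the assumed saturation, not by the fitting
  machinery.
- The integrated cubic is a smooth approximation to the true (Hill ×
  log-time) surface; its training R² (~0.82 on the default study) reflects
  both noise and approximation bias, and per-timepoint quadratics fit
  better near the response peak (R² ≈ 0.93–0.98) than at day 1 where the
  dose signal is weakest.
- The t-test calibration under the array error model is slightly
  conservative (empirical p < 0.01 rate ≈ 0.008–0.009 at n = 5), because
  log₂ of a ratio of noisy channels is only approximately normal.
- Fuzzy sub-clustering cannot separate exactly-flat profiles from noise
  after z-standardization; the screen's consistency decision deliberately
  bypasses this by using raw cluster-mean profiles, and the stage-II
  intersection provides the specificity.
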