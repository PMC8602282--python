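# Methods

`mbtemporal` implements a longitudinal quantitative microbiome analysis for
dense (near-daily) genus-level 16S time series with matched flow-cytometry
cell counts. This note documents the models, the statistical procedures, the
synthetic-cohort generator used to exercise them, and the numerical and
design choices that were genuinely open.

## Profiles

**RMP (relative microbiome profile).** Each sample's read counts are
rarefied (multivariate hypergeometric subsampling, i.e. without
replacement) to a fixed depth, 10,000 reads by default; samples below the
depth are excluded.

**QMP (quantitative microbiome profile).** Counts are first corrected for
16S rRNA gene copy number: the corrected depth of a sample is
`sum_g count_g / cn_g` with `cn_g >= 1` from an rrnDB-style map (genera
missing from the map receive the map mean). The per-sample *sampling depth*
is `d_s = corrected_depth_s / load_s`, corrected reads per cell, where
`load_s` is the microbial load in cells per gram. A common target depth `D`
is chosen from the observed `d_s` values (any other candidate is dominated
by an observed one) to maximize the number of retained samples subject to
two constraints: `d_s >= D` (no upsampling) and `round(D * load_s) >= 500`
corrected reads (minimum information per sample; at the cohort's average
copy number of ~3.9 this corresponds to roughly 2,000 raw reads). Ties are
broken toward larger `D`, i.e. more reads per retained sample. Each
retained sample is then subsampled to `round(D * load_s)` corrected reads —
because corrected reads are fractional, this is realized as a multinomial
draw with probabilities proportional to `count_g / cn_g` — converted to
relative abundance, and multiplied by `load_s` to give cells/g. Exclusion
reasons are recorded per sample (`no_load`, `low_reads`,
`below_min_after_rarefaction`).

**Alpha diversity.** Observed richness `S`, Shannon `H = -sum p ln p`
(natural log), Pielou `J = H / ln S` (null for `S <= 1`), so `J` is exactly
the evenness normalization of `H`.

**Filters.** Genus-level analyses use an abundance threshold of 0.5%
(maximum within-cohort relative abundance), motivated by the inconsistent
detection of very-low-abundance genera in technical replicates; the
variability analyses additionally require detection in more than 5
participants with more than 3 positive samples each. Inequalities are
strict.

## Temporal-variability statistics

**ICC.** One-way ANOVA variance components with participants as groups:
`var_within = MSW`, `var_among = (MSB - MSW)/k0`, where
`k0 = (N - sum n_i^2 / N)/(k - 1)` is the unbalanced-design average group
size; `ICC = var_among / (var_among + var_within)`. Negative estimates
(MSB < MSW) are reported raw, never truncated, so the estimator stays
unbiased around zero.

**CV.** Per genus and participant, `sd/mean` over the detected (positive)
observations; the cohort summary is taken over per-genus medians across
participants.

**Fold changes.** Per genus and participant: the maximum ratio
larger/smaller over all pairs of positive observations (overall) and over
adjacent collected samples (consecutive). Zeros are skipped rather than
pseudocounted — the definition concerns detected abundances; a pseudocount
mode (half the minimum positive value) is available for sensitivity
analysis. Rank coverage is the dense-rank span (max − min + 1) of the
genus across a participant's samples, ranking genera within each sample by
descending abundance; the count of distinct attained ranks is available as
an option.

**Stationarity.** Augmented Dickey–Fuller test with drift and no trend,
since the hypothesis of interest is fluctuation around an equilibrium
level rather than around a deterministic trend. Rejection of the unit root
is reported as *stationary*. The augmentation order is selected by AIC up
to `floor((n-1)^(1/3))` lags: forcing the maximal order at n≈35 destroys
most of the test's power (measured 0.55 versus 0.94 with AIC selection for
an AR(1) with coefficient 0.2 at n=40, while the size on a random walk
stays below 0.1). Genera present in at most 60% of a participant's samples
are skipped and recorded.

**Taylor's law.** Per genus, OLS of `log10(variance)` on `log10(mean)`
with intercept over per-participant temporal (mean, variance) pairs;
series with fewer than three detections are dropped and at least five
participants must contribute. Slope 2 corresponds to a constant temporal
CV across hosts. Log base 10 is fixed so intercepts are reportable; the
slope is base-invariant and invariant under global rescaling of
abundances. The high- vs. low-ranked contrast is a Welch two-sample t of
slopes, top-n by cohort-wide mean abundance against the rest.

**Error on the median.** For each participant's top-100 genera, `n`
distinct timepoints are drawn uniformly (default 10,000 repetitions; the
bundled runs use fewer, stated with each result) and the SD of the
subsample medians, averaged over genera and participants, is reported per
`n` together with the curve's elbow (maximum distance to the chord).

## Core membership

On the 0.5%-filtered QMP matrix, with presence = abundance > 0 and
"consecutive" meaning adjacent in collection order (the only complete
ordering when days are missed): temporal core (> 95% of a person's
samples), persistent (> 20% presence, >= 90% consecutive), transient
(> 60% presence, < 75% consecutive), cross-sectional core (present in
every participant), person-specific (present in exactly one participant,
excluding genera seen in negative controls). The predicates are not
mutually exclusive; every satisfied class is reported and overlaps are
flagged. Core-size accumulation resamples `n` samples without replacement
and reports the expected temporal-core size per `n` plus the smallest `n`
from which the estimate stays within 10% of the full-series value.

## Community structure

Bray–Curtis dissimilarity (`sum|x-y| / sum(x+y)`); principal coordinates
by Gower double-centering and eigendecomposition with negative eigenvalues
retained. The dispersion test follows the betadisper convention: distances
to group centroids combine real and imaginary axes as
`sqrt(max(0, d_real^2 - d_imag^2))`, followed by a one-way ANOVA across
groups; singleton groups are excluded. Within- versus between-individual
comparisons use each participant's full series against one sample per
participant (the earliest study day by default, standing in for the sample
closest to the first day of menses), with Benjamini–Hochberg adjustment
across participants.

Similarity decay interpolates each participant's QMP series linearly to
daily resolution across gaps of at most 3 days (longer gaps stay missing —
linear interpolation over long gaps would fabricate stability), forms all
within-participant day pairs at elapsed times 1..36, subsamples every
elapsed-day bin to the smallest bin size (seeded), and regresses
`log(1 - BC)` on elapsed days.

## Enterotyping

A K-component Dirichlet-multinomial mixture is fit by EM on integer count
compositions (relative matrices are rescaled to a common depth). The
E-step computes responsibilities from the component Polya log-likelihoods;
the M-step updates weights by mean responsibility and each component's
alpha vector by the responsibility-weighted fixed-point
(minorize–maximize) iteration, which keeps the EM objective monotone —
monotonicity is asserted on every iteration. Initialization is seeded
k-means on relative abundances followed by method-of-moments Dirichlet
estimates, avoiding degenerate starts.

Model evidence per K is approximated two ways: a Laplace penalty (half
log-determinant of the diagonal observed information of the component
alphas at the optimum, in alpha space, where vanishing parameters are
properly penalized) and BIC. BIC is the default decision rule for the
number of components: the block-diagonal Laplace penalty grows too slowly
with K once samples are split among components (its curvature scales with
the per-component sample count), which admits spurious components on
homogeneous data, whereas BIC recovers the generating K in both the
homogeneous and the well-separated regime.

Longitudinal samples are assigned iteratively against a cross-sectional
background so that no two samples of one individual are clustered at once:
each iteration adds one not-yet-assigned time point per participant (in
seeded random order) to the background and refits; component identity
across iterations is resolved by majority overlap of the background-sample
assignments, with alpha-vector cosine similarity breaking ties. A cheaper
fixed-background assignment mode is available.

The mislabeling screen tests, for every sample and every other
participant, whether the Bray–Curtis dissimilarities to that participant's
samples are stochastically smaller than to the sample's own participant
(one-sided rank-sum test, BH-adjusted over all sample × participant
tests); swap candidates are reciprocal participant pairs matched
sample-to-sample by strongest evidence. Optionally, a DMM clustering into
one cluster per participant adds cluster-vs-modal evidence per sample.
Community-state excursions are a genuine confounder here: a sample taken
mid-excursion legitimately resembles individuals whose home state matches,
so flags exceed confirmed swaps on cohorts with state switching (as they
do on real data); the null-specificity guarantees hold for cohorts of
well-separated individuals.

## State transitions

The transition null compares observed consecutive-sample state switches
(direction-collapsed to 10 unordered categories for four states) with
expectations from pooled prevalence: `P({A,B}) = n_A n_B / C(N,2)` for
A != B and `C(n_A,2)/C(N,2)` for A = B. A chi-square goodness-of-fit test
and standardized residuals `(O - E)/sqrt(E(1 - p_i))` quantify departures;
a Pearson-residual mode is available. Constellation dissimilarity reports
the median BC per state pair over all applicable sample pairs, plus
per-participant within-subject medians grouped by the participant's
majority state. The consecutive-shift test subsamples same- and
different-state consecutive pairs to equal size and applies a two-sided
rank-sum test.

The CTMC observes states as snapshots at collection times, with elapsed
days between observations. All directed transitions are allowed;
intensities are log-parameterized with proportional covariate effects,
`q_rs(z) = q0_rs exp(beta_rs . z)`, covariates taken at the interval
start. The likelihood multiplies entries of `P(t; z) = expm(Q(z) t)`
computed by batched eigendecomposition (with a scaling-and-squaring
fallback verified against `scipy.linalg.expm` to 1e-10); maximization is
L-BFGS-B on the log scale from crude observed-rate starts, standard errors
come from the numerical Hessian, and risk ratios are `exp(beta)` with Wald
95% CIs (significant when the CI excludes 1). Covariate contributions are
tested by likelihood ratio against the nested model without the covariate.

## Host covariates

Energy intake uses Atwater factors (9/4/4 kcal/g for fat/protein/carb);
P/C is protein %EI over carbohydrate %EI. The dietary lag starts from the
1-day average transit time and is adjusted per participant from Pearson
cross-correlations of P/C with stool moisture at lags 0..5 days (diet
leading), computed on pairwise-complete observations (missing diet days
are excluded, not interpolated); significance threshold `|r| > 1.96/sqrt(n)`.
A significant, stronger correlation at lags 2–5 moves the lag; a stronger
same-day correlation moves it to 0 only when most samples were collected
in the late afternoon or evening. Note the assignment rule is deliberately
conservative: with a true effect of r = 0.5 over 36 days the significance
gate alone caps rule-based recovery near 85%, while the cross-correlation
argmax identifies the generating lag in >= 90% of replicates — recovery
statements therefore refer to the identified (`best_ccf_lag`) lag.

Hormone profiles align a 28-day standard curve to each reported cycle
length, modifying only the variable follicular phase at the start: shorter
cycles drop days from the start; longer cycles insert
`level(28+x) = level(day1) + (level(day1) - level(day28)) e^{-x}` for each
additional day x (converging to the day-1 level), with the inserted days
placed at the cycle start in increasing x; the 14-day luteal tail is
always preserved. The difference is taken as day1 − day28; the sign is an
acknowledged ambiguity of the extrapolation and is trivially flipped by
supplying a transformed curve. The bundled 28-day standard curve is
synthetic (two log-normal-shaped peaks aligned to a day-14 LH reference,
arbitrary units) because the underlying reference measurements are not
redistributable; users supply their own curve file for real analyses.

## Synthetic cohort generator

The generator emulates the study design: 20 participants, 36 days,
near-daily sampling (3.5% missed days, ~694 samples), 150 genera with a
heavy-tailed (lognormal, sigma 1.5) cohort profile, loads around
6–22 × 10^10 cells/g, moisture within 52–93%.

Latent per-genus log10 cell abundances follow a stationary AR(1) (default
coefficient 0.3) around per-participant equilibria; per-genus temporal CVs
are drawn log-uniformly (default 0.5–2.0) and rank-matched so abundant
genera fluctuate least, keeping the summed load in a realistic band;
per-participant CVs scale as `mean^((b-2)/2)` so that temporal variance
follows `mean^b` across hosts (Taylor control, default b = 2). Independent
participant effects (sd 0.25 log10) set the latent intraclass correlation
`sigma_b^2/(sigma_b^2 + sigma_w^2)` per genus — with these defaults most
genus ICCs fall below 0.5 and the Shannon-diversity ICC lands near 0.68,
matching the within-dominated variance structure the analyses target.
Community states are four Dirichlet templates built by boosting disjoint
driver-genus blocks (the two most abundant genera stay state-neutral);
each participant orbits a home state with 5%/day excursion and 60%/day
return probabilities. Loads are the sum of genus cells; moisture couples
negatively to log load and positively to the P/C ratio at the configured
lag; reads are drawn multinomially from copy-number-distorted relative
cell abundances (lognormal rrnDB-like copy numbers, mean 3.88) at
lognormal depths around 30,000 — exactly the forward model the QMP
construction inverts. Genera below a detection fraction (2e-5 of load) are
truncated to zero so core/transient classification sees realistic
absences.

What the generator does **not** emulate: taxonomic identity and
phylogeny, compositional interactions between genera (each genus
fluctuates independently given the state), sequencing batch effects,
primer/extraction bias beyond a static copy-number factor, diet
autocorrelation, and perturbations such as infections or antibiotics.
Passing recovery tests therefore demonstrates the estimators' correctness
under the stated stochastic model, not robustness to every artifact of
real amplicon data.

## Problem sizes of the bundled runs

The test suite and the acceptance script run the full method stack at the
study design (20 × ~35 samples) where the quantity under test depends on
it, and at reduced sizes (fewer genera, fewer Monte-Carlo repetitions,
e.g. 300 instead of 10,000 median-error repetitions) where only numerical
correctness is at stake; every reported number states its `n`. These sizes
are the package's choices for routine verification and are configurable.

## Known limitations

- The DMM evidence uses a block-diagonal information approximation; the
  full mixture Hessian (including weight cross-terms) is not assembled.
- CTMC standard errors are Wald-type from a numerical Hessian; profile
  likelihood CIs are not implemented.
- The QMP depth optimizer searches observed sampling depths only (provably
  sufficient for the retention objective).
- The dispersion test inherits betadisper's behavior of comparing
  centroid distances, not spatial medians.
- No direct support for ASV-level input; tables are genus-level.
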