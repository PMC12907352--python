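# Methods

This note documents the statistical machinery, the synthetic-data model
behind the test suite, and the numerical and design choices a user should
know before trusting (or extending) the package.

## Coded behavior streams

The unit of observation is a behavior event: a category from a fixed
alphabet with onset/offset in seconds from session start, half-open
`[onset, offset)`. The default 6-category alphabet (nonverbal initiation,
responsive behavior, emotional sharing, joint attention, speech
initiation, avoidance) matches the labels of the group-level transition
matrix; a 7-category preset adds stereotyped actions, needed for the
avoidance→stereotypy chain analyses. Each category carries a minimum
credible duration (1, 0.5, 2, 1.5, 1, 3, 2.5 s respectively) used by
preprocessing.

**Preprocessing** (`segment_events`) merges consecutive same-category
events separated by less than 0.5 s (configurable) and then drops events
shorter than their category minimum. Merging precedes filtering so a long
behavior fragmented by a coding glitch survives; a merge may bridge over
an intervening event only when that event is itself below its own minimum
duration (in which case it is dropped as part of the merge). This makes
the operation idempotent while preserving the no-overlap invariant. Time
convention: decimal seconds from session start; events sorted by (onset,
offset). The ordinal 0–2 quality scores from the coding manual are carried
as optional event metadata but consumed by no computation.

**Reliability.** Cohen's κ for categorical agreement (κ defined as 1 when
both coders are constant and identical, where the formula is 0/0) and the
two-way random, absolute-agreement, single-measure ICC — ICC(A,1) — for
continuous ratings. The κ edge case and the ICC variant are the only
non-obvious choices; the ICC penalizes systematic rater shifts, which is
the behavior wanted for duration codings.

## Temporal analysis

Lag-1 transition counts never cross child/session boundaries. Rows with
no outgoing transitions are undefined (NaN) under raw normalization and
excluded from aggregates; optional pseudo-count smoothing
`(N(i→j)+α)/(N(i)+αK)` makes all rows proper. The multi-step operator is
the Chapman–Kolmogorov power λᵀ·Pᵀ: the printed multi-step formula in the
source material is not a coherent T-step law (a product of identical
conditional probabilities), so the matrix power — which coincides with the
lag-1 usage at T = 1, the stated primary case — is implemented instead.

**Entropy support.** Behavioral entropy defaults to the lag-1 *bigram*
distribution (at most K² = 36 cells). The reported TD group mean of
3.08 bits exceeds log₂ 6 ≈ 2.585, so unigram entropy over six categories
cannot be the published quantity; the bigram reading makes both group
means feasible (max log₂ 36 ≈ 5.17). Unigram support remains available.

**Episodes.** Average sequence length partitions a session into episodes
wherever the inter-event gap exceeds 5 s (configurable; the source
material does not define the delimiter). Chain mining pools category
n-grams over children and reports each chain's conditional probability
given its first state, with support = fraction of children exhibiting it.

**Group statistics.** The two-sample t test defaults to Welch (the
printed t values match neither the pooled nor the Welch recomputation
from the printed summaries, so the recomputed value is what the package
reports; both variants are exposed). The chi-square test is the plain
Pearson statistic with (r−1)(c−1) df and per-cell adjusted residuals.

## Physiological coupling

Signals are consumed as already-derived series (deriving HRV from raw ECG
is out of scope). Smoothing is a causal moving average with
partial-window normalization at the start, so output length equals input
length and no padding values are invented. Cross-correlation is the
Pearson correlation of `HRV_t` with `B_{t+τ}` recomputed on the
overlapping region per lag — the fixed-N textbook form is undefined at
series edges — which guarantees |CC| ≤ 1 at every lag. Sign convention:
positive τ means the behavior follows the HRV sample, so a physiological
response lagging behavior onset by L samples peaks at τ = −L.

## Latent class analysis

The Bernoulli-mixture EM uses log-sum-exp responsibilities, closed-form
M-steps, θ floored at 1e-6, convergence at a log-likelihood gain below
1e-6, and 20 random restarts by default (initialized near the indicator
means with class-specific jitter); K = 1 uses the exact closed form. Fit
indices: BIC = −2LL + q ln n and AIC = −2LL + 2q with q = K·I + (K−1);
relative classification entropy 1 − EN/(n ln K) (1 for K = 1).

The Lo–Mendell–Rubin test is implemented as the standard adjusted-LRT
approximation: LR/(1 + 1/(Δq·ln n)) referred to χ²(Δq). Near the mixture
boundary this approximation is anti-conservative (its null rejection rate
exceeds the nominal level), which is why a parametric-bootstrap LRT is
provided as the robust alternative and used for calibration checks.
Selection scans k = 2…5: minimum BIC wins, stepped down one class only
when the LMR test fails at the BIC winner while supporting the class
count below it.

**Indicators.** The published likelihood is Bernoulli, while the inputs
are described as Z-scored frequencies; the package resolves this by
dichotomizing frequencies (median split by default, ties low; mean-split
and explicit thresholds available, with the rule recorded in the matrix
provenance). A Gaussian-mixture variant is deliberately out of scope.

## Clinical association

Response = (baseline − post)/baseline ≥ 0.20, inclusive at the boundary
(a 1e-12 slack absorbs float rounding). Rates are integer percentages
under round-half-up, which reproduces all three published per-class rates
from their printed counts. The logistic model dummy-codes class against
the low-interaction reference; complete or quasi-complete separation
raises an error rather than being silently penalized. ANCOVA-style
adjusted differences come from OLS with the group coefficient as the
contrast. Mediation is the product of coefficients: a from a linear
mediator-on-class fit, b from a class-adjusted logistic outcome fit, with
a percentile bootstrap interval. No multiple-testing correction is
applied anywhere (matching the source analyses); interpret families of
tests accordingly.

## The synthetic cohort generator

The generator is the package's test bed: it emulates the *statistical
structure* of a structured-play cohort so that every pipeline stage has a
known truth to recover. What it plants:

- **Classes.** Three ASD latent classes (high 0.35 / medium 0.40 /
  low 0.25) plus a TD group. Class indicator profiles θ are anchored at
  the published class-conditional probabilities (high: initiation 0.78,
  responsiveness 0.65, joint attention 0.52, avoidance 0.19; medium:
  initiation 0.41, maintenance 0.34, rigid actions 0.62; low: avoidance
  0.78, joint attention 0.12) over the seven coded behaviors; unanchored
  entries are set so the classes are well separated, consistent with the
  published classification entropy (~0.85) and the BIC minimum at three
  classes, which a weakly separated mixture cannot produce at any
  realistic sample size. Where the two source passages disagree on which
  class carries rigid actions 0.62, the results-section attribution
  (medium class) is used and the low class's stereotypy indicator is
  treated as free.
- **Dynamics.** The low-interaction class follows the empirical ASD
  transition matrix row-normalized (only its first row is row-stochastic
  as published; its verbatim nonverbal-initiation row carries the planted
  0.62 avoidance entry). The high class follows a constructed TD-like
  kernel whose modal path is nonverbal initiation → joint attention at
  0.56; the medium class is the midpoint blend. The 7-category ASD kernel
  plants P(stereotypy | avoidance) = 0.42 as the largest conditional
  probability in the matrix. Per-child Dirichlet jitter (concentration
  200) around the class kernel models between-child variation; it is
  invented structure, disclosed here.
- **Timing.** Episode lengths are geometric with class means chosen so
  the ASD mixture mean is 4.2 events/episode and TD 6.8; the final
  episode is completed rather than truncated so per-child episode means
  are unbiased. Within-episode gaps are uniform on [0.6, 2.0] s;
  between-episode gaps exceed the 5 s threshold by an exponential excess;
  durations are the category minimum plus an exponential excess — so
  generated logs pass preprocessing unchanged by construction. The
  category sequence is a single Markov chain per session: episode gaps
  are timing structure only and do not reset the chain, keeping lag-1
  structure, chain probabilities and entropy calibration exact.
- **Physiology.** HRV is baseline + white noise + an additive deflection
  of fixed latency and duration after each coupled behavior onset, at a
  10 Hz derived-series rate. This is the simplest ground truth the
  cross-correlation can detect — a stand-in, not a physiological model;
  real HRV has autocorrelated noise, variable latencies and non-additive
  responses, so passing recovery tests here says nothing about those.
- **Outcomes.** Responder flags are Bernoulli with class rates
  0.68/0.42/0.19; ADOS-2 post scores are placed safely on either side of
  the 20% boundary (floor(0.75·baseline) vs ceil(0.90·baseline)).
  Covariates (age, IQ, SRS-2 with class-graded means) follow simple
  parametric models adequate for exercising the adjustment machinery.

All draws flow from one seed through per-stage `SeedSequence` spawning;
identical config + seed reproduce the cohort exactly.

**Entropy calibration.** `calibrate_entropy_kernel` finds a kernel on the
convex path between a 2-state cycle (bigram entropy 1 bit) and the
iid-uniform kernel (2·log₂ K bits) by bisection, with a monotonicity
check along the path. By default it targets the stationary bigram
entropy. Because the plug-in entropy estimator is biased low at realistic
session lengths (about 0.06–0.11 bit at 200 events over 36 cells), the
generator offers a finite-length mode that instead targets the *expected
measured* entropy of sequences of a given length, estimated from 2000
simulated sequences with a fixed internal seed (common random numbers
across bisection steps). Experiments that compare simulated cohort means
against published measured entropies use the finite-length mode; the
published values are themselves finite-sample measurements.

**What the generator does not emulate.** The empirical ASD matrix implies
a bigram entropy far above the published ASD group mean (the published
numbers are not mutually consistent), so the default cohort reproduces
the transition structure, chains, episode lengths and responder gradient,
while entropy-level emulation is done through explicitly calibrated
kernels. It also does not simulate raw physiological waveforms, item-level
clinical scores, longitudinal waves, or coder disagreement.

## Sizes, tolerances, and experiment protocols

Recovery experiments use n = 300 indicator vectors with *stratified*
class assignment (exact counts round(n·π)): a recovery study controls its
design factor, so measured error reflects estimation rather than the
multinomial draw of membership. Reported proportion estimates average a
small number of seeded replicates (5 for estimates, 20 for the selection
majority) to make them stable estimates of the experiment's expectation.
Entropy-cohort experiments simulate 60 (ASD) and 40 (TD) children at 200
events per child and average three replicate cohorts of that size. The
chain-mining experiment uses 60 children × 200 events with min support
0.5. Bootstrap defaults: 1000 resamples for mediation intervals (100+ in
tests for runtime), ≥ 39 refits for bootstrap LRT smoke checks.

Numerical details worth knowing: θ is clipped to [1e-6, 1−1e-6]; modal
class assignment breaks posterior ties toward the lower class index;
label matching is exhaustive over K! permutations and refuses K > 8;
stationary distributions come from the left Perron eigenvector;
percentage rates round half-up; the responder boundary is inclusive with
1e-12 slack.

## Known limitations

- The LMR approximation is anti-conservative near the boundary; use the
  bootstrap variant for calibrated p-values.
- With parameters anchored at the published class profiles, per-replicate
  worst-case θ̂ cell error at n = 300 is binomially bounded below ~0.06
  (√(θ(1−θ)/(n·πₖ)) for the smallest class), so parameter-level recovery
  claims are stated in mean absolute error.
- The pipeline's default LCA indicators are the first four alphabet
  categories' frequencies (median split); a study with different core
  indicators should configure `indicator_categories`.
- Cross-correlation p-values are not provided: behavior indicators are
  strongly autocorrelated, and naive significance would be misleading.
  Peak lags and magnitudes are descriptive.
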