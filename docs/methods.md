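# Methods

## Model

The unit of analysis is the ordered gene pair (a, b). Within sample *i* the
pair contributes the binary feature `s(i) = 1{x_a(i) > x_b(i)}`; ties score 0
(the "otherwise" branch). Strictness matters: on continuous microarray or
TPM data ties are essentially absent, but rank-transformed or heavily
rounded data can tie, and then (a, b) and (b, a) are *not* complementary —
both score 0. The tie rule is therefore applied identically at discovery and
scoring time.

A signature is a set of K pairs with Cox log-hazard coefficients; the risk
score is the linear predictor `r_i = Σ β_k s_k(i)`, modeled as
proportional hazards: `h_i(t) = h_0(t) exp(r_i)`. Because every `s_k` is
invariant to strictly increasing per-sample transforms, so is `r_i` —
exactly, not approximately — which is the property that lets one signature
score RNA-seq and microarray cohorts without normalization.

## Discovery pipeline

1. **Gene universe.** Optional intersection with a user gene list (an
   immune-gene list in the melanoma application). The bundled list slot
   ships the 39 genes of the packaged signature; larger curated lists are
   supplied by the user.
2. **Variance filter.** Genes with median absolute deviation ≤ 0.5 are
   dropped. The MAD is *unscaled* (median of |x − median(x)|, no 1.4826
   consistency constant): the threshold is a bare data-spread cut, not a
   robust SD estimate. A `scaled=True` flag exposes the consistency-scaled
   variant. When a testing cohort is supplied, a gene must pass the filter
   in both halves.
3. **Pair enumeration.** All n(n−1)/2 unordered pairs, emitted in canonical
   lexicographic order. Orientation is a labeling choice: flipping a pair
   complements its indicator (tie-free data) and flips its eventual
   coefficient sign.
4. **Prevalence filter.** Pairs whose indicator mean lies outside
   [0.20, 0.80] in the training *or* testing half are removed. Near-constant
   indicators carry no stratification information and make log-rank groups
   degenerate. (An alternative reading of the selection rule — *keeping*
   pairs constant in >80% of samples — is statistically vacuous and is not
   implemented.)
5. **Log-rank screen with FDR control.** Each pair's indicator splits the
   cohort in two; the standard two-group log-rank statistic
   (O−E)²/V with hypergeometric variance and aggregate handling of tied
   event times is referred to χ²₁. The screen is computed by vectorized
   risk-set counting over blocks of pairs (~2·10⁵ pairs × hundreds of
   samples run in seconds); per-pair library calls are used only as test
   oracles. Benjamini–Hochberg q-values control the FDR; the default
   retention threshold is q < 0.001. Pairs that put every sample in one
   group (precluded by the prevalence filter, but guarded anyway) get
   statistic 0, p = 1, and a warning.
6. **LASSO Cox.** The surviving pairs enter an L1-penalized Cox model. The
   penalty path is solved by coxnet (scikit-survival); the penalty is chosen
   by repeated K-fold cross-validation of the Verweij–van Houwelingen
   partial-likelihood deviance, `-2·[pl(all; β_fold) − pl(train; β_fold)]`,
   with fold assignments redrawn each repetition from the seeded generator
   and the deviance curves averaged before applying the selection rule. The
   default rule is minimum deviance; a 1-SE rule is available. Defaults are
   10 folds and 1000 repetitions (mirroring common repeated-CV practice with
   the reference survival-lasso tooling); tests and the bundled examples use
   2–5 repetitions, which changes the selected penalty negligibly on the
   simulated cohorts while keeping runtimes interactive. Breslow's
   approximation handles ties inside the penalized fit (the coxnet
   formulation); the unpenalized Cox models of the evaluation layer use
   Efron's approximation, which has lower bias under ties.

The orchestrator records a provenance funnel (genes kept, pairs enumerated,
pairs after prevalence, pairs after FDR, final pairs) and propagates the
failing stage's name on error.

## Scoring and evaluation

* **Cutoffs.** `median` (sample median of scores), `roc_youden`
  (threshold maximizing sensitivity + specificity − 1 on the time-dependent
  ROC at a horizon, 5 years by default), or a fixed value carried by the
  signature (the bundled melanoma signature carries −0.674; its OBS variant
  −1.433). "High risk" means score **strictly greater** than the cutoff.
* **KM / log-rank.** Product-limit estimates and the two-group (or
  multi-group) log-rank test, via lifelines.
* **Harrell's C.** A pair of subjects is usable iff the shorter observed
  time ended in an event and the times differ; concordant when the
  shorter-lived subject has the higher score; score ties count 0.5. The 95%
  CI uses the asymptotic U-statistic (per-subject projection) standard
  error: with per-subject concordance and usability projections
  `pc_i, pw_i`, `Var(C) ≈ 4·Var(pc_i − C·pw_i) / (n·E[pw]²)`.
* **Time-dependent AUC.** Cumulative-case/dynamic-control ROC at horizon t.
  Censoring before t is handled by redistributing each censored subject into
  case/control pseudo-membership through the whole-cohort Kaplan–Meier
  curve: censored at c ≤ t counts as a case with probability
  1 − S(t)/S(c). The AUC is the trapezoidal integral of the ROC polyline
  (one vertex per distinct score, so score ties contribute ½). With no
  censoring before t this estimator equals the Mann–Whitney AUC of the
  binary dead-by-t outcome exactly, which the tests assert.
  Incident/dynamic variants are out of scope.
* **Cox models.** lifelines `CoxPHFitter` with Efron ties and a tightened
  Newton stopping rule (1e−9) so small-sample coefficients agree with a
  direct partial-likelihood maximizer to 1e−4. Sex is encoded binary
  (male = 1), tumor stage ordinal 1–4 (so one coefficient per stage step),
  age stays continuous. Univariate mode fits each covariate alone. Rows with
  missing covariates are dropped with a logged count.
* **Stratified analyses.** Risk-group log-rank comparisons inside
  age (≤65 vs >65), stage (I–II vs III–IV) and sex strata; levels with
  fewer than two subjects per risk group are skipped with a warning.
* **Horizons.** Time is days throughout; the 1/3/5-year horizons are
  365/1095/1825 days.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes —
nothing more. Per gene g, a latent log-mean `m_g ~ N(2, 1)`; sample values
`exp(N(m_g, 1))` (log-normal expression). K gene-disjoint signal pairs are
planted; the two genes of a signal pair share one log-mean so the pair
indicator has prevalence near 0.5 (a pair of genes with well-separated
means has a near-constant indicator and would be removed by the prevalence
filter — and carries no information anyway). Hazard is
`h_i = h0·exp(Σ β_k s_k(i))` with `h0 = 1e−3`/day (median baseline survival
≈ 693 days), exponential event times, exponential random censoring
(5.3e−4/day) plus administrative censoring at 10 years — together censoring
≈ 30% of subjects at the default configuration. Default β alternate ±1
across 5 pairs in a 150-gene, 400-sample cohort.

Signal pairs are gene-disjoint so recovery is unambiguous (a real signature
may reuse genes — the bundled one uses GBP2 in three pairs); disjointness is
purely a scoring convenience for simulations. Multi-platform replicates
apply strictly monotone within-sample distortions (log1p, random power,
per-sample positive affine, within-sample rank with average ranks on ties);
indicator matrices across replicates are identical by construction, and
tests assert exact equality.

Draws come from a single `numpy` Generator per call in a documented fixed
order (signal genes, gene log-means, expression, event times, censoring
times), so equal seeds give bitwise-identical cohorts; reusing a cohort's
truth object resamples new patients from the same planted signal.

What the generator does **not** emulate: read-count/overdispersion
structure, gene–gene correlation beyond the planted pairs, batch effects
other than monotone distortion, non-proportional hazards, informative
censoring, or any tumor biology. Passing tests therefore demonstrate the
pipeline's statistical correctness under its own assumptions, not clinical
performance on real cohorts.

## Numerical choices and edge cases

* Pair screening blocks are sized to keep intermediates ≈ tens of MB, so
  620-gene universes (~192k pairs) fit comfortably in memory.
* Log-rank variance terms with a single subject at risk are zeroed (n−1
  guard); zero-variance pairs get p = 1 rather than NaN.
* The Youden cutoff is the observed score maximizing J; with multiple
  maximizers the highest such threshold is returned (first along the
  descending threshold grid).
* Duplicate gene rows / sample columns collapse by arithmetic mean at load;
  symbols are uppercased and whitespace-stripped. No alias mapping is
  attempted: symbol-level matching is what keeps the signature portable
  across platforms, and alias resolution would drag in an annotation
  dependency.
* Signature files serialize coefficients with `repr`, so read(write(S)) is
  exact. Unicode minus signs in hand-edited files are tolerated on read.
* The OBS published-signature entry ships cutoff and endpoint metadata only
  (its pair list was never published); scoring with it raises until entries
  are supplied.
* The pipeline derives per-stage seeds from the global seed by fixed
  offsets, and writes reports with sorted keys, so identical configurations
  give byte-identical outputs.

## Known limitations

* The discovery screen is univariate; pairs correlated with a planted pair
  can enter the penalized model in its place when the penalty is weak.
* The C-index CI assumes asymptotic normality of the U-statistic; very
  small or heavily censored cohorts should bootstrap instead.
* The time-dependent ROC estimator redistributes censored mass marginally
  (whole-cohort KM), ignoring score-dependent censoring.
* Cross-cohort funnel counts (how many genes/pairs survive each filter)
  depend strongly on cohort composition and are not portable claims.
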