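# Methods

`invascreen` implements the statistics of a pooled CRISPRi loss-of-function
invasion screen and its downstream analyses, exercisable end to end on
seeded synthetic data.  This note describes each model, its assumptions,
the defaults and why they were chosen, and what the synthetic generators do
and do not emulate.

## Screen phenotypes and gene scores

**Model.** A pooled screen perturbs each cell with one sgRNA (~10 per
targeted lncRNA plus a few hundred non-targeting controls, NTCs) and reads
out sgRNA abundance by sequencing the starting population (T0) and the
non-invading cells harvested from the top of a Matrigel chamber at the
endpoint.  Per sgRNA and replicate the invasion phenotype is

    phenotype = log2((endpoint_rpm + c) / (T0_rpm + c)) - median over NTCs,

with reads-per-million (rpm) computed per sample and pseudocount `c = 1`
added after rpm scaling.  The NTC-median centering makes the NTC phenotype
median identically zero per replicate and absorbs population-wide drift;
rpm scaling makes the statistic invariant to sequencing depth.  The sign
convention is that a **positive** phenotype means the sgRNA was enriched
among non-invading cells, i.e. the knockdown decreased invasion.  No
growth normalization is applied: over a 24-hour invasion window, with
proliferation verified unchanged by MTT, the raw enrichment is the
phenotype of interest.

Replicates are averaged at the phenotype level and scored once; a
per-replicate scoring path exists as a diagnostic.

**Gene score.** Per gene: a two-sided Mann-Whitney test of all the gene's
sgRNA phenotypes against all NTC phenotypes, and the signed mean of the
top-3 sgRNAs by |phenotype| (ties broken lexicographically by sgRNA id).

    screen_score = avg_top3_phenotype * (-log10 p).

"Top" is defined by absolute magnitude so that suppressors and promoters
of invasion are ranked symmetrically, matching a two-sided volcano layout.
Hits require `p <= 0.05` and `|avg_top3| >= log2(4/3) ~ 0.415` (about a
25% abundance change); both thresholds are parameters.

**Mann-Whitney implementation.** Exact p-values come from the permutation
distribution of U, computed by a dynamic programme over tie groups (integer
2U arithmetic, ties contribute 1/2); the exact path is used when
`min(n) <= 8` and `n1*n2 <= 10,000`.  Beyond that a normal approximation
with tie correction and a 0.5 continuity correction is used; at the
screen's 10-vs-247 comparison its error is far below the resolution of any
downstream decision.  The exact path is verified against full enumeration
in the test suite.

**Empirical FDR.** Pseudo-genes are assembled by sampling `sgrnas_per_pseudo`
(default 10, the modal sgRNAs/gene) NTC phenotypes without replacement and
scoring them exactly like genes.  The sampled sgRNAs are excluded from the
NTC comparison set for that pseudo-gene: a real gene's sgRNAs are never in
the control pool, and leaving them in biases pseudo-gene p-values
conservative (null rate ~0.038 instead of 0.05 at 10-of-247 sampling).
`empirical FDR = (pseudo pass rate) / (real pass rate)`, clipped to [0, 1],
and reported as unavailable (never zero) when no real gene passes.

## Expression stage

CPM is normalized to the read total of a reference gene subset (e.g. all
chromosome-10 genes) rather than the whole library, which protects the
unit against global composition shifts; RPKM uses gene length in kb and
assigned-read totals in millions.  Patient stratification takes the upper
and lower 25% by linear-interpolation quantiles, with boundary ties going
to the middle group so the split is deterministic.

Differential expression is one Welch t stage on `log2(x + 0.5)` values
with Benjamini-Hochberg adjustment (statsmodels).  This replaces the
negative-binomial / linear-model machinery of dedicated DE packages with a
transparent test that behaves well at the moderate fold changes and sample
sizes exercised here; its null calibration and power are covered by the
acceptance suite.  The offset 0.5 stabilises zeros; it also means a
noise-free k-fold gene shows log2FC exactly log2 k only in the large-count
limit (the offset is a parameter and can be set to 0).  Genes with zero
variance in both groups get p = 1 when the means agree and p = 0 otherwise.
The DEG filter is `|log2FC| > 1`, adjusted `p < 0.05`, and group-mean
RPKM >= 1 in either group, optionally restricted to coding biotypes.

The correlation screen computes Pearson r of every gene against the target
gene with a two-sided t test on n-2 degrees of freedom; zero-variance
genes are flagged and reported non-significant.  Gene symbols are
upper-cased before DEG-set intersections because mixed-case symbols for
the same gene are common in practice.

## Survival stage

Kaplan-Meier estimation and the log-rank test are delegated to lifelines.
The Cox model is fit by Newton maximisation of the partial likelihood,
written here to support both Efron (default, more accurate under ties) and
Breslow tie handling and to expose the score test at beta = 0 (which, for
a single group indicator with Breslow ties, *is* the log-rank statistic —
an identity the tests verify).  Convergence requires gradient norm < 1e-8
or a Newton decrement below 1e-12 relative to |log L| (the absolute
gradient criterion is unreachable in double precision on cohorts of tens
of thousands); non-convergence, singular information and monotone
likelihood (detected as a partial likelihood at its supremum or |beta| >
50) raise errors.  Wald standard errors come from the inverse observed
information; AIC = -2 log L + 2k with k the number of regression
coefficients (the baseline hazard is nonparametric and not counted).

The expression covariate enters as a two-segment linear spline,
`(min(x, knot), max(x - knot, 0))`, whose coefficients are per-CPM log
hazard ratios below and above the knot.  The knot is chosen by the lowest
AIC over a grid (default 2.0-3.0 CPM by 0.1, ties to the smaller knot).
Martingale residuals (event minus fitted cumulative hazard, Breslow
baseline) check linearity; they sum to zero by construction.  Risk groups
split at 2.5 CPM with high strictly above the cutoff.

Optional categorical covariates (IDH status, MGMT methylation, 1p/19q
codeletion, grade) are validated against fixed vocabularies; the primary
analyses use expression alone to avoid over-adjustment.

## Assay statistics

qPCR knockdown uses the delta-delta-Ct method with per-well
dCt = target Ct - housekeeping Ct (RPLP0 plays the housekeeping role in
the motivating experiments); relative expression is `2^(-ddCt)` and the
p-value a Welch t on per-well dCt.  Boyden-chamber invasion counts are
averaged within experiment first; the experiment (not the field) is the
inference unit, matching a mean ± SEM over three experiments of nine
fields each; a field-level test exists for sensitivity analysis.  MTT
viability is OD570 minus OD650 with "no change" operationalised as
p >= 0.05.  Spheroid invasion compares absolute invaded areas.  Welch's
unequal-variance t is used everywhere a two-group comparison is needed; a
flag switches to Student's t.  Identical constant groups give p = 1.

## Synthetic data

All generators are pure functions of (configuration, seed).

* **Screen**: library of 2,307 genes x 10 sgRNAs + 247 NTCs at 1000x
  coverage, two replicates.  T0 abundances are log-normal (sigma 0.5);
  endpoint means multiply by `2^(effect x efficacy)` with per-sgRNA
  efficacy ~ Beta(5, 2) (mean ~0.71, modelling the partial knockdown seen
  in validation, configurable or disabled); counts are Gamma-Poisson with
  dispersion 0.01.  The Gamma draws precede the Poisson step so that runs
  differing only in planted effects share their overdispersion noise.
* **Expression**: log2 abundances Normal(mu_g, sigma) with baselines
  uniform on [3, 8] and sigma 0.5; planted correlations use a Gaussian
  copula with the target on the log scale; fold changes add to the log2
  values of the treated cohort.
* **Survival**: exponential event times with hazard
  `r0 * exp(b1 min(x, knot) + b2 (x - knot)+)`; expression is log-normal
  matched to a glioma cohort (median 1.65 CPM, IQR 0.72-3.09); independent
  exponential censoring with its rate solved (Brent) so the expected
  censored fraction equals the request; baseline rate 1/400 per day.
* **qPCR**: housekeeping Ct ~ Normal(18, sd), target Ct adds a baseline
  dCt of 6 cycles minus log2(fold change), noise on both wells.

What the generators do **not** emulate: sgRNA-specific cloning or
sequence-context effects, PCR amplification bias, index hopping, batch
effects or normalization artefacts in expression data, informative
censoring, or competing risks.  Passing tests therefore demonstrate the
statistical machinery is correct and well calibrated under the stated
models, not that real screens or cohorts satisfy those models.

## Numerical choices and known limitations

* Exact Mann-Whitney enumeration is limited to `min(n) <= 8`,
  `n1*n2 <= 10,000`; above that the corrected normal approximation is used.
* The Newton Cox fitter starts at beta = 0 with step halving; Efron and
  Breslow agree to 1e-10 on tie-free data (tested).
* Wald CIs for the above-knot spline coefficient undercover slightly
  (~93-94% instead of 95% at n=600) because `(x - 2.5)+` is heavy-tailed
  under the log-normal expression model; the below-knot coefficient is
  essentially nominal.
* AIC knot localisation is intrinsically coarse at moderate cohort sizes:
  with n=600, 30% censoring and a flat hazard above the knot, the selected
  knot falls within ±0.1 CPM of the truth in only ~44% of replicates
  (within ±0.2 in ~70%); the selection is consistent — at n=20,000 it
  recovers the true knot essentially always.  Quantities derived from the
  knot should be read with this resolution in mind.
* Problem sizes in the test and acceptance suites (e.g. 600-patient
  cohorts, 200-600 replicate seeds, 1,000-5,000-gene matrices) were chosen
  to keep Monte-Carlo error well below the widths of the asserted bands.
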