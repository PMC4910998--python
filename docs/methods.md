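# Methods

## Data model

A biallelic imputed genotype is a posterior distribution over the three
genotype classes. Internally a triple is ordered `(p0, p1, p2)` where the
index counts copies of the *counted* allele — by default the B/ALT allele
of the source file (matching `.gen` column order and VCF `DS` semantics);
a flag flips the convention. Triples whose components sum to 1 within
`1e-3` are renormalized to sum exactly to 1 (text formats truncate
decimals); larger deviations are treated as data errors with the offending
line reported. Derived quantities:

* **dosage** `= 2 p2 + p1`, the expected counted-allele count in [0, 2];
* **best guess** = the argmax class, reported missing when the maximum is
  below a call threshold (default 1/3). Ties are broken toward the lower
  allele count — an arbitrary but documented and tested rule;
* **discordance** between a dosage `d` and a true count `g` is
  `|g − d| / 2`, a fraction of the 0–2 allele-count scale.

Per-variant imputation quality is taken from the producer when available
(VCF `INFO/R2`); otherwise it is computed. Two standard metrics are
implemented: the IMPUTE2-style info score
`1 − Σ_j (f_j − e_j²) / (2 N θ(1−θ))` with `e_j = 2 p2 + p1`,
`f_j = p1 + 4 p2` and `θ` the estimated counted-allele frequency (clamped
to [0, 1]), and the minimac-style r², the empirical dosage variance over
the Hardy–Weinberg binomial variance `2θ(1−θ)` (unclamped — values above 1
flag overdispersed dosages). Both are undefined for monomorphic columns
and raise accordingly. The post-imputation quality filter removes variants
with quality below 0.4 (boundary retained), the conventional threshold.

Missingness policy: no per-genotype filtering is applied anywhere in the
scan path — deleting uncertain genotypes would reintroduce exactly the
informative-missingness bias that imputation is meant to remove. The
best-guess comparator scan is the one deliberate exception, since
thresholded calling *is* the method being emulated.

## Multiple imputation

`mi_scan` draws `d` complete datasets (default `d = 10`, a draw count past
the point where the combined estimates stabilize in the convergence sweep,
see below), regresses the phenotype on each drawn genotype with OLS
(intercept and optional covariates), and combines per variant:

    β_MI  = mean(β_i)
    s_W²  = mean(s_i²)
    s_B²  = var(β_i)              # sample variance, d−1 denominator
    s_MI² = s_W² + (1 + 1/d) s_B²
    t     = β_MI / s_MI,  df = (d−1)(1 + d s_W² / ((d+1) s_B²))²

with a two-sided p from the T distribution. One printed source of this
combination gives the within-draw term as a mean of standard *errors*
rather than squared errors; that reading would make `s_MI²` dimensionally
inconsistent, so the standard mean-of-`s_i²` within-variance is used. When
`s_B² = 0` (below `1e-12` — e.g. perfect-confidence data) the reference
distribution is normal (infinite df), and when every draw agrees exactly
the combined estimate is the common value itself, so degenerate
probability data reproduce the hard-call scan bit for bit. A variant whose
drawn genotype is constant in any draw is flagged untestable rather than
erroring the scan.

The OLS core uses the Frisch–Waugh–Lovell projection: the phenotype and
each genotype column are residualized against the nuisance design once per
draw, giving per-variant slopes and standard errors identical to a full
multiple regression at a fraction of the cost. Agreement with an
independent OLS implementation is enforced in the tests at 1e-8 relative.

Reproducibility: every random draw comes from a counter-based Philox
substream keyed by the root seed and offset by the variant index, so
results are bit-reproducible and independent of the order in which
variants are processed or parallelized.

### Draw-count diagnostics

`draw_count_sweep` evaluates nested draw subsets (the run at `d' > d`
reuses the first `d` draws) and reports, per draw count, the Pearson
correlation of `β_MI` with estimates from the true genotypes and the
distribution of `|Δ s_B²|` against the previous draw count. On calibrated
simulations the correlation saturates and `|Δ s_B²|` concentrates near
zero well before `d = 10`; outliers are dominated by low-quality variants.

## Nested-model meta-analysis

For M cohorts contributing `(β_MI,i, s_W,i², s_B,i², d_i)`:

    β̂    = mean(β_MI,i)        ŝ_W² = mean(s_W,i²)     ŝ_B² = mean(s_B,i²)
    ŝ_meta² = var(β_MI,i)       # sample variance, M−1 denominator
    ŝ²   = ŝ_W² + (1 + 1/d) ŝ_B² + (1 − 1/M) ŝ_meta²

Unbalanced draw counts use the conservative `d = min(d_i)` (a strict mode
refuses imbalance instead). The degrees of freedom are implemented as

    df = [ (1/(M(d−1))) ((1 − 1/d) ŝ_W²/ŝ²)²
         + (1/(M−1))    ((1 + 1/M) ŝ_meta²/ŝ²)² ]⁻¹

The printed source for this expression reads as a bare sum of squared
variance fractions, which in standard Satterthwaite constructions is the
*reciprocal* of a df; the reciprocal reading is adopted here and the raw
components are exposed on the result object so an alternative reading can
be applied downstream. With `M = 1` the meta term vanishes and the
single-cohort Rubin df is used.

Two properties of this combination worth knowing: the component means are
unweighted across cohorts (no sample-size weighting), and the total
variance has no 1/M precision gain — it is a variance *decomposition* of a
single-study-scale uncertainty, not an inverse-variance pooled variance.
Both follow the combination as printed in its source; the point estimate
still equals the equal-weight fixed-effect combination.

The `s_B²` heterogeneity statistic quantifies cross-cohort dispersion of
imputation uncertainty: `Q_B = Σ (s_B,i² − mean)² / (mean²/M)` and
`stat = max(0, 1 − (M−1)/Q_B)`, an I²-style normalization (0 =
homogeneous). The underlying test was proposed without a formula; this
construction is the package's own and is labeled as such.

## Calibration diagnostics

Both diagnostics consume `(probabilities, truth)` pairs from any source;
imputation itself is out of scope, so the masked-truth protocol is split
into a `select_mask` utility (hold out a random 10% of variants for
external re-imputation) and the diagnostics proper. Truth matrices are
reconciled to the probability data by variant ID and allele pair, allowing
swapped alleles (counts flipped) and excluding strand-ambiguous A/T and
C/G variants.

* **Discordance strata**: mean dosage discordance (or best-guess mismatch
  fraction) per true genotype class × MAF bin × quality bin, classes
  oriented by the minor allele. Defaults: ten 0.05-wide MAF bins over
  (0, 0.5]; quality bins (0.8, 0.9] and (0.9, 1]. CIs are the normal
  approximation `1.96 sd/√n`.
* **Consistency curves**: for each class and 0.02-wide probability bin,
  the signed mean of `P(class) − 1{truth = class}` (positive = the stated
  probability overstates the empirical one), stratified by quality or by
  MAF. The per-entry indicator definition is used; it coincides in
  expectation with the per-bin class-frequency reading.
* **Frequency baseline**: the no-LD reference predictor is the constant
  dosage `2q`, so a true class with count `g` has baseline discordance
  `|g − 2q| / 2`. A haplotype-independence baseline admits more than one
  construction; this frequency-only reading is the one implemented and is
  labeled as such in output.

For CI-coverage checks, "populated" bins are those with at least ~30
entries, the usual validity range of the normal approximation; sparser
bins are reported but not held to nominal coverage.

## Enrichment evaluation

Scans are ranked by p-value into percentiles `100 (1 − (rank − 0.5)/M)`
(100 = most significant, average ranks on ties — MI's discrete df can
produce exact ties). ROC curves treat a supplied positive-control list as
positives and all other scanned variants as negatives; AUCs are compared
with the paired DeLong test (midrank structural components), one-tailed
for the alternative that one method's AUC exceeds another's.

The matched-null adjustment draws, for each positive, 1000 variants
matched on quality ±0.01 and frequency ±0.01, and scores the positive by
its empirical percentile within the matched null ranks; the ROC is then
re-run with positives' percentiles replaced by their adjusted values.
Sparse pools are handled by sampling with replacement (with a warning)
and, for empty pools, doubling the tolerances up to 4× before excluding
the positive — the matching protocol's source does not address sparse
pools, so this policy is the package's own.

The quality-binned null analysis reports `|mean percentile − 50|` per
quality bin plus two trends: the correlation of per-variant percentile on
quality (positive when low-quality variants are downranked, under the
100-=-top convention) and the correlation of the per-bin deviation
`|mean − 50|` on bin quality, which is the deviation-plot reading (large
deviations at low quality give a negative slope). Both are reported
because the two sign conventions coexist in the literature.

## Synthetic data generator

The generator emulates the marginal statistical structure of imputed GWAS
data; LD is deliberately absent because every analysis in the package is
single-variant and draws need only per-variant marginals.

Per variant: a minor allele frequency is drawn (default uniform on
[0.01, 0.5]); truth genotypes are Hardy–Weinberg at that frequency; each
truth genotype passes through a symmetric allele-flip channel (each of the
two alleles misread independently with probability ε), and the emitted
triple is the exact posterior `P(g | observation)` under the HWE prior —
so the probabilities are calibrated by construction. The channel error ε
is solved by bisection (tolerance 1e-4) so the column's *expected*
IMPUTE2-info equals a target quality drawn from a spectrum shaped like
real post-imputation quality distributions: 40% of variants above 0.9, 18%
in (0.8, 0.9], and the remaining 42% uniform down to the 0.4 filter
threshold. Expected info decreases monotonically from 1 (ε = 0) to 0
(ε = 0.5), so every target is attainable; realized column info lands
within ±0.02 of target for n ≥ 2000.

Controlled miscalibration: `shrink_lambda` mixes each emitted triple
toward its HWE prior (under-confident tails, over-stated low
probabilities — deviation `λ/(1−λ)(π_c − p')` at stated probability `p'`,
used as the analytic oracle in tests); `class_bias_delta` moves mass
between the heterozygote and the homozygote classes, emulating the
complementary het-vs-hom miscalibration pattern of real imputers.

Phenotypes are `Σ β_j g_j + N(0, σ²)` over the causal set, computed from
the *true* genotypes (the imputation channel never sees the phenotype,
as in real pipelines). The generator exports the closed-form expected
discordance per variant and true class, which the diagnostic tests use as
an independent oracle.

What the generator does not emulate: LD between variants, population
structure and relatedness, genotyping batch effects, and the
window/phasing artifacts that give real imputers their program-specific
bias signatures. Tests passing on this generator therefore validate the
statistical machinery, not the behavior of any particular imputer.

## Known statistical limitations

Two properties of phenotype-agnostic MI draws are worth stating plainly,
because the test suite measures both:

* **Attenuation.** Regressing on a genotype drawn from `P(g | imputation
  data)` is an errors-in-variables regression: the slope is attenuated by
  approximately the info metric (`E[β_MI] ≈ r² β`). The dosage predictor,
  being the conditional expectation `E[g | data]`, is *not* attenuated.
  At quality 0.95 the residual MI bias is ≈ 5% of the effect — visible
  with enough replicates, negligible for single-study inference at
  realistic standard errors, and absent entirely at quality 1.
* **Conservatism at low quality.** Under the null, Rubin's total variance
  `s_W² + (1+1/d) s_B²` exceeds the true sampling variance of `β_MI` by
  roughly `[1 + (1+1/d)(1−r²)] / [r² + (1−r²)/d]`, so the MI test is
  increasingly conservative as quality falls (empirically: rejection at
  the 0.05 level is ≈ 0.04 at r² ≈ 0.95 but ≈ 0.004 at r² ≈ 0.6, and
  ≈ 0.02 pooled over the realistic quality spectrum). This is the
  mechanism behind the method's signature behavior: low-quality variants
  are selectively pushed down the ranking while well-imputed variants are
  essentially unaffected. It is a deliberate property of the
  variance model, not a bug — but users should know that MI p-values for
  poorly imputed variants are conservative rather than uniformly
  calibrated, exactly balanced against a much stronger quality–rank
  deviation than dosage or best-guess scans exhibit.

Would-be exact calibration would require drawing genotypes from
`P(g | data, y)` — conditioning the imputation on the phenotype — which
the upstream imputation software does not do and which is out of scope
here.

## Numerical choices

* Triple sum tolerance 1e-3 at parse time; renormalized exactly afterward.
* `s_B²` below 1e-12 treated as exactly 0 (normal reference).
* OLS flags: constant predictor (untestable), residual sum of squares
  below 1e-12 of the phenotype scale (exact fit, `s² = 0`), fewer than
  covariates + 3 complete samples (insufficient).
* DS-only VCF records are completed to the minimum-KL (maximum-entropy
  relative to the HWE prior) triple with the observed dosage as mean,
  solved by bisection on the exponential tilt.
* MI-summary files round-trip at full float precision (`repr` /
  round-trip parsing).
* Default MAF/quality bin edges as above; bins are left-open, right-closed.
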