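# miscan

Multiple-imputation association analysis for probabilistic genotype data.

## The problem

Genotype imputation fills in unassayed variants of a GWAS cohort from
external reference haplotypes, but what it produces is not a genotype call:
it is a posterior probability triple `(P(aa), P(Aa), P(AA))` per sample per
variant. Standard association methods expect integer allele counts, so in
practice the triple is collapsed — either to the most probable class
("best guess") or to the expected allele count, the **allelic dosage**
`2 P(AA) + P(Aa)`. Both projections discard the uncertainty structure of
the posterior, and that loss is not benign: the probabilities produced by
imputation software are themselves inconsistently calibrated across
genotype classes, allele frequency, and reported quality, and association
statistics computed from collapsed genotypes rank poorly imputed variants
as if they were well measured.

`miscan` implements the alternative: **Multiple Imputation (MI)**. For each
variant, `d` complete genotype datasets are drawn from the posterior
triples (default `d = 10`), each draw is analyzed with an ordinary
regression, and the `d` results `{β_i, s_i²}` are combined with Rubin's
rules:

    β_MI  = (1/d) Σ β_i
    s_W²  = (1/d) Σ s_i²                    (within-draw variance)
    s_B²  = 1/(d-1) Σ (β_i - β_MI)²         (between-draw variance)
    s_MI² = s_W² + (1 + 1/d) s_B²
    t     = β_MI / s_MI ~ T with df = (d-1) (1 + d s_W² / ((d+1) s_B²))²

Uncertain genotypes inflate `s_B²` and shrink the test statistic, so
unreliable variants are downweighted in the ranking instead of competing
on equal terms with well-imputed ones. For multi-cohort studies, the
nested-model meta-analysis combines per-cohort `(β_MI, s_W², s_B², d)`
summaries with an additional between-site variance component — per-draw
results never need to be shared.

The package is aimed at statistical geneticists running association scans
on imputed data (IMPUTE2 `.gen`/`.sample` or VCF `GP`/`DS` dialects) and at
methodologists studying how imputation uncertainty propagates into
association statistics.

## What is included

| module | contents |
| --- | --- |
| `miscan.gp_core` | probability triples, dosage, best-guess, genotype draws, IMPUTE2-info / minimac-r² quality metrics, quality filtering |
| `miscan.gp_io` | `.gen`/`.sample` and VCF GP/DS readers, phenotype tables, MI-summary interchange files |
| `miscan.mi_engine` | MI scan, dosage and best-guess comparator scans, Rubin combination, draw-count convergence diagnostics |
| `miscan.mi_meta` | nested-model MI meta-analysis, between-draw-variance heterogeneity statistic |
| `miscan.calibration_diag` | masked-truth dosage/best-guess discordance strata, probability-consistency curves |
| `miscan.enrichment_eval` | rank percentiles, ROC/AUC, paired one-tailed DeLong tests, matched-null adjustment, quality-binned null analysis |
| `miscan.simdata` | synthetic cohort generator with controllable imputation quality and miscalibration |
| `miscan.cli` | `miscan` command-line tool (`simulate`, `mi-scan`, `dosage-scan`, `bestguess-scan`, `meta`, `calibrate`, `enrich`, `sweep-draws`) |

## Worked example

Simulate a cohort of 1000 samples and 500 variants with one causal variant
(index 7, effect 0.4 trait units per allele) under a realistic imputation
quality spectrum, run the MI scan, and look at the top of the ranking:

```python
import pandas as pd
from miscan import simdata, mi_scan

cfg = simdata.SimConfig(n_samples=1000, n_variants=500,
                        causal_effects={7: 0.4}, seed=42)
sim = simdata.simulate(cfg)
scan = mi_scan(sim.pm, sim.phenotypes, d=10, seed=1)
cols = ["variant_id", "maf", "quality", "beta", "sw2", "sb2", "df", "p"]
print(scan.sort_values("p")[cols].head(3)
      .to_string(index=False, float_format=lambda x: f"{x:.4g}"))
```

```
variant_id     maf  quality   beta      sw2       sb2        df         p
 var000007  0.2868   0.8609 0.3425 0.002494 0.0001926      1468 6.319e-11
 var000312 0.05582   0.6497 0.2697   0.0103  0.001079     843.2   0.01207
 var000113 0.02694   0.9978 0.3567   0.0214 3.125e-05 3.501e+06     0.01483
```

The causal variant tops the list. Its effect estimate (0.34) sits a little
below the simulated 0.4 because genotype draws from an imperfect posterior
(quality 0.86) attenuate the slope, and its between-draw variance `sb2` is
an order of magnitude above that of the well-imputed runner-up — the MI
variance components make the reliability of each variant explicit. The two
runners-up are null variants: note how the poorly imputed one
(quality 0.65) carries a large `sb2` and a reduced df, which is exactly
the penalty that pushes unreliable variants down the ranking.

Combining two cohorts from their MI summaries:

```python
from miscan import nested_meta, StudyMISummary
res = nested_meta([StudyMISummary("cohortA", 1.0, 1.0, 0.5, 10),
                   StudyMISummary("cohortB", 2.0, 1.0, 0.5, 10)])
print(res.beta, res.s2)   # 1.5 1.8
```

The total variance 1.8 decomposes as `1.0` (within-draw) `+ 1.1 × 0.5`
(between-draw) `+ 0.5 × 0.5` (between-site).

The same pipeline is available from the shell:

```sh
miscan simulate --n-samples 1000 --n-variants 500 --seed 42 --out sim/
miscan mi-scan --gen sim/probs.gen --sample sim/probs.sample \
    --phenotypes sim/phenotypes.tsv --trait trait --draws 10 --seed 1 \
    --out scan/
```

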