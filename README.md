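# hyposig

Tools for deriving a hypoxia gene signature from paired
normoxic/hypoxic expression profiles of tumor cell lines and for
evaluating its prognostic value on a tumor cohort. The package targets
the neuroblastoma setting — where hypoxia of the tumor
microenvironment is linked to aggressiveness independently of *MYCN*
amplification — but every stage is generic bulk-transcriptomics
machinery: it is aimed at computational biologists who want a tested,
reproducible implementation of this "biology-driven" signature workflow
rather than a signature learned directly from patient outcomes.

## The method

**Stage 1 — signature derivation (cell lines).** Probeset-level signals
are normalized (per-array scaling to mean 500, division by the array
median, per-probeset division by the probeset median). Two independent
branches then run on hypoxic (+1) vs normoxic (−1) samples:

1. *l1-l2 selection with double optimization.* Minimize
   (1/n)‖y − Xβ‖² + τ‖β‖₁ + μ‖β‖₂² by damped iterative
   soft-thresholding; refit the selected support by least squares for
   prediction. The l2 weight μ = ε·μ₀ controls how much correlation the
   selection tolerates (ε = 100 by default: inclusive,
   correlation-aware lists). τ is chosen by inner leave-one-out error
   inside an outer leave-one-out loop; each of the L = n loops yields a
   probeset list, aggregated by a frequency score, and the l1-l2 list
   is the set of probesets selected in ≥ 50% of loops.
2. *Differential expression.* Per-line hypoxic/normoxic fold changes;
   keep probesets with mean |log2 FC| ≥ 1, then a one-sample t-test of
   the log2 ratios with Benjamini–Hochberg correction, adjusted
   p < 0.05.

The hypoxia signature is the intersection of the two lists.

**Stage 2 — prognostic evaluation (tumors).** Patients are stratified
by k-means (k = 2, euclidean, 100 restarts) on the z-scored log2
signature expression; the high-expression cluster is labeled poor
prognosis. Stability is tested against 300 random same-size probeset
sets via the misclassification distance to the reference split,
compared with its exact hypergeometric chance expectation by a t-test.
Prognosis is quantified by Kaplan–Meier curves, the log-rank test, and
multivariate Cox regression (cluster, INSS stage 4, *MYCN*
amplification, age ≥ 1 year; HR with Wald 95% CI, Efron ties), plus a
*MYCN*-normal subgroup rerun.

Kaplan–Meier, log-rank and Cox are implemented from their defining
formulas and cross-checked against lifelines in the test suite. A
seeded synthetic-data module generates both datasets with known ground
truth (planted responsive probesets; a latent hypoxia status with a
specified hazard ratio), so the whole pipeline is testable offline.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```sh
python analysis/01_simulate_cell_lines.py
python analysis/02_derive_signature.py
python analysis/03_simulate_cohort.py
python analysis/04_stratify_tumors.py
python analysis/05_survival_analysis.py
```

Output of a run (seeds fixed in the scripts):

```
l1-l2 list: 1905 probesets (LOO error 0.0%)
DE list: 49 probesets
intersection (the hypoxia signature): 49 probesets
planted-truth recovery: 98.0%, false discoveries: 0
...
clusters: {1: 22, 2: 66} (poor = cluster 1)
poor cluster recovers 100% of latently hypoxic tumors
stability: mean distance 0.047 vs chance 0.390, t-test p = 0.00e+00
...
OS: 5-y survival 63.8% (good) vs 11.4% (poor), log-rank p = 8.06e-07
multivariate Cox (full cohort):
                 HR  ci_lower  ci_upper      p
cluster_poor  4.197     2.324     7.579  0.000
stage4        1.490     0.870     2.551  0.147
mycn          1.110     0.427     2.886  0.831
age_ge1       1.128     0.650     1.956  0.669
```

Reading: of the 50 planted hypoxia-responsive probesets, the
intersection recovers 49 with no false discoveries — the inclusive
l1-l2 branch contributes recall, the fold-change/BH branch contributes
specificity. On the cohort, the 22/66 k-means split recovers the latent
hypoxia status exactly; random probeset sets reproduce the split far
better than chance (distance 0.047 vs 0.390), so the structure is
pervasive and the stratification stable. The poor-prognosis cluster
carries a Cox hazard ratio of 4.2 (true simulated value 4) and remains
the dominant predictor while the null covariates stay non-significant.

A command-line interface mirrors the scripts
(`hyposig simulate | derive-signature | stratify | survival | run-all`).

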