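# Methods

`hyposig` implements a two-stage, biology-driven pipeline: a hypoxia
gene signature is derived from paired normoxic/hypoxic expression
profiles of tumor cell lines, and the signature's prognostic value is
then evaluated on a tumor cohort. This note records the models, the
defaults and why they were chosen, and what the synthetic data do and
do not establish.

## Normalization

Input matrices are summarized array signals (probesets × samples,
strictly positive, linear scale). The chain applies, in order:
(1) global scaling of each array to a mean intensity of 500 (the
MAS5-style convention, with "average" read as the arithmetic mean);
(2) per-array division by the array's 50th percentile; (3) per-probeset
division by the probeset's median across arrays. After step 3 every
probeset has median 1 (asserted to 1e-12 in tests). Steps 1–2 compose
to a single per-array rescaling, so the chain is reported as printed
rather than algebraically reduced. Missing values are rejected at load;
no imputation rule is defined. With a single array, step 3 is degenerate
and the step-2 output is returned with a warning. Each dataset
(cell lines, tumors) is normalized on its own.

## Signature derivation

### l1-l2 selection with double optimization

For hypoxic (+1) vs normoxic (−1) samples the selection stage minimizes

    (1/n) ||y − Xβ||² + τ||β||₁ + μ||β||₂²

by damped iterative soft-thresholding,

    β ← (1 + μ/σ)⁻¹ · soft(β + Xᵀ(y − Xβ)/(nσ), τ/(2σ)),

a proximal-gradient step with step size 1/(2σ), σ the largest
eigenvalue of XᵀX/n. The objective is monotonically non-increasing
(asserted per iteration in tests) and the iteration stops when the
largest coefficient change falls below `tol` (default 1e-5, budget
3000 iterations; exhausting the budget raises with the last iterate
attached). Features are standardized to mean 0 and unit l2 norm
*inside each training fold only*, so no held-out sample influences
scaling, τ selection or fitting (a poisoning test perturbs a held-out
sample and asserts the fold's selected list is unchanged).

The l2 weight is μ = ε·μ₀ with μ₀ = 10⁻³·σ. ε is therefore a
dimensionless multiplier of a data-driven baseline: ε ≤ 1 behaves like
the lasso and yields minimal lists; ε = 100 (the default) makes the
selection correlation-aware and inclusive — with a heavy l2 term the
active-set condition approximately decouples into per-feature screening
on the residual correlation, so groups of correlated discriminant
probesets enter together. Tests assert the qualitative property that
mean list size is non-decreasing in ε.

The "double optimization" refits the selected support by (ridge)
least squares — minimum-norm OLS at the default `ridge_lambda = 0` —
and classifies by sign(x·β + ȳ). The refit is used for prediction
only; it never changes the support.

τ is chosen on a 30-point log-spaced grid from τ_max = 2‖Xᵀy‖∞/n down
to 10⁻³ τ_max by inner leave-one-out classification error. Plateaus of
the minimum are resolved by the `tie_break` setting. The default is
`"dense"`: the smallest τ attaining the minimal error, i.e. the most
inclusive model that cross-validates best. This is a deliberate design
choice matching the purpose of a large ε — the selection stage is meant
to capture *every* probeset concurring in the discrimination, while
specificity is delegated to the intersection with the differential-
expression list (below). On strongly separable data the inner error
curve has a wide plateau at zero and a sparsest-model tie-break would
collapse each loop's list to a handful of probesets; the inclusive rule
keeps the frequency score informative. `tie_break="sparse"` restores
the sparsest-model behavior, and a completely flat error curve falls
back to the most regularized end of the grid under that setting.

The outer loop is leave-one-out over the n samples: each loop selects τ
on its training fold, fits, records the selected list and the held-out
prediction. Aggregation is a per-feature frequency score (count of
loops selecting the feature, out of L = n) plus the leave-one-out
error. The l1-l2 list is the set of features selected in at least a
fraction `frequency_threshold` (default 0.5) of loops. The numeric
mapping of ε to μ and the frequency threshold are exposed as
configuration because only their qualitative roles are identifiable.

### Differential expression

Per cell line, the fold change of each probeset is the linear ratio
hypoxic/normoxic. A probeset passes the fold filter when its mean
|log2 FC| across lines is ≥ log2(2) (the `all-lines` rule — every line
modulated 2-fold in the same direction — is available). The test is a
two-sided one-sample t-test of the per-line log2 ratios against 0
(equivalent to a paired t-test on log2 values; log ratios stabilize
variance and make up-/down-regulation symmetric), with
Benjamini–Hochberg correction applied within the fold-filtered set and
a significance cut of adjusted p < 0.05. α and the filter-then-test
order follow the printed procedure; both are configurable. Zero-variance
log ratios get p = 1.

### Intersection

The signature is the set intersection of the l1-l2 and DE lists,
ordered by the l1-l2 list's frequency order. In the planted simulations
the two branches have complementary failure modes — the inclusive
selection has near-perfect recall with many hitchhikers, the DE filter
has near-zero false positives — so the intersection inherits recall
≈ the DE branch's and a false-discovery proportion near zero.

## Tumor-stage evaluation

### Stratification

Patients are clustered by k-means (k = 2, euclidean) on the signature
probesets of the normalized, log2-transformed, per-probeset z-scored
tumor matrix (the same scaling used for heatmap display; z-scoring can
be disabled). "100 iterations" is implemented as 100 random restarts of
Lloyd's algorithm, each run to convergence, keeping the best
within-cluster sum of squares; restarts initialize centroids at a
random pair of distinct data points and are seeded. Tests assert the
restart scheme attains the exhaustive-partition optimum on small
instances and that WCSS never increases within a Lloyd run. The cluster
with the higher mean signature expression is labeled poor prognosis.

### Stability permutation test

The reference split is compared with splits obtained from `n_perm`
(default 300) random probeset sets of the signature's size, drawn
uniformly without replacement from all probesets (the signature's own
probesets are not excluded). Distance between two 2-labelings is the
misclassification distance: the minimal disagreement fraction over
cluster-label permutations, in [0, 0.5]. Each permutation distance is
compared with its exact chance expectation — the hypergeometric
expectation of the distance between two independent labelings with the
realized cluster sizes of the reference and of that permutation — and a
one-sample two-sided t-test of (distance − expectation) summarizes the
result. This null is exact under a structureless matrix by sample
exchangeability, which is what the type-I calibration test verifies
(rejection rate ≈ 5%). A significantly *smaller* mean distance means
random probeset sets reproduce the reference split better than chance,
i.e. the cohort structure the signature detects is pervasive rather
than an artifact of one gene set.

### Survival analysis

Kaplan–Meier product-limit curves per arm; arm survival rates are the
KM estimate at the largest observed time by default, or at a fixed
horizon (the analysis drivers use 5 years) — which of the two a
printed "survival rate" means is a reporting convention, so it is
configurable. Two-group log-rank test with hypergeometric variance.
Multivariate Cox proportional hazards by Newton–Raphson with
step-halving (log partial likelihood non-decreasing), Efron tie
handling by default (Breslow available; survival times are rounded to
3 decimals in the simulator precisely to exercise ties), standard
errors from the inverse observed information, HR = exp(β) with Wald
95% CIs. Covariates are coded so HR > 1 is adverse: poor cluster,
INSS stage 4, MYCN amplified, age ≥ 1 year. The MYCN-normal subgroup
analysis refits without the MYCN covariate. All three estimators match
lifelines to numerical precision in the cross-check tests, and the Cox
fit matches a brute-force 1-D partial-likelihood maximization on a tiny
fixture.

## Synthetic data

The generators are first-class, tested code; they define the study
conditions for every downstream property.

**Cell lines.** Log-normal baselines (log2 mean 7, sd 1.5), 11 lines ×
2 paired conditions × 2000 probesets by default. Planted probesets
(default 50) shift by sign·1.5 + N(0, 0.3²) log2 units per line under
hypoxia (signs 50/50 up/down; an `up_only` switch reflects that in
vitro hypoxia programs are dominated by inductions), residual log2
noise sd 0.5 everywhere. All values are exponentiated so the
normalization and fold-change code paths see realistic positive data.

**Tumor cohort.** A latent hypoxia indicator H ~ Bernoulli(0.24)
(matching a ~1:3 poor/good split in an 88-patient cohort) raises
signature probesets by 1.5 log2 units and leaves a weaker genome-wide
footprint on the remaining probesets (per-probeset signed shifts with
sd 0.5). The footprint reflects the fact that hypoxic, aggressive
tumors differ broadly in expression, not only in the signature genes;
it is also what gives the stability test its power, since with strictly
signature-confined effects random probeset sets would be independent of
the reference split by exchangeability and no stability statistic could
detect anything. Survival is exponential with hazard
0.10·4^H·exp(βᵀx) per year and independent exponential censoring at
rate 0.05/year, i.e. a median ~7-year survival in the good group and
roughly two-thirds of patients with observed events; binary covariates
(MYCN 18.2%, stage 4 45.5%, age ≥ 1 y 71.6%) default to null hazard
effects so specificity can be tested. Times are rounded to 3 decimals.

**What passing tests do not show.** The generators use independent
Gaussian log2 noise — no probe-level artifacts, batch effects, array
outliers, or gene–gene correlation beyond the single latent hypoxia
axis. Recovery and power results therefore certify the machinery under
the stated model, not performance on real arrays; in particular the
clean separability of the planted cell-line classes makes the inner CV
error curves plateau at zero, a regime real data rarely reaches.

## Problem sizes used by the test suite

Chosen once, from power analysis, to keep the default suite and the
acceptance script self-contained: the planted derivation runs at the
full reference conditions (11 × 2000 × 50, 10 seeds); the zero-effect
null control keeps 11 lines (the fold-filter null rate scales with
lines, and fewer lines would make spurious DE hits common) but uses 200
probesets and a 12-point τ grid over 100 seeds; stability runs use 60
permutations, 15 restarts, and a 1500-probeset pool for the
structureless type-I check (a small pool makes random draws overlap the
reference signature often enough to bias the null); Cox recovery and
coverage use n = 500 with 20 and 200 replicates.

## Known limitations

* The ε ↦ μ mapping is a modeling convention; only the ordering of ε
  values is meaningful across datasets.
* The stability t-test treats permutation distances as independent;
  draws from a small probeset pool violate this mildly.
* Cox inference is Wald-based; no proportionality diagnostics,
  stratified baselines, or time-varying covariates.
* The misclassification distance and the stability baseline are
  specific to k = 2.
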