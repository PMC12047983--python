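# Methods

## The problem

Gene-level burden tests aggregate rare variant dosages within a gene and
regress a trait on the aggregate. Which variants to aggregate is decided by a
*mask* — a boolean filter over bioinformatic annotations (predicted
consequence, loss-of-function confidence, pathogenicity-predictor calls and
scores) and allele-frequency ceilings. Published studies use wildly
heterogeneous masks, and a set of masks analyzed jointly (a *masking
strategy*) pays a Bonferroni price that grows with its size. This package
implements the machinery for (i) defining, harmonizing, and evaluating masks;
(ii) running calibrated burden scans across masks, traits, and MAF sub-bins;
(iii) counting strategy-level significant associations under the
size-dependent threshold α₀/m; and (iv) choosing strategies — by clustering
redundant masks and picking representatives, or by greedy maximum-coverage
optimization — together with a synthetic-cohort generator that provides
ground truth for recovery tests.

## Mask grammar and harmonization

Masks are infix boolean expressions (`&` over `|`, parentheses) whose leaves
are annotation atoms and MAF tokens (`maf1` ≡ MAF < 1%, `maf0_1` ≡ MAF <
0.1%, `maf_gt_X` ≡ MAF > X%). Score-threshold atoms use ≥ on the native
scale (`REVEL_score_0_55` reads "REVEL at least 0.55"). Harmonization
rewrites applied before canonicalization: `MAF ≤ t` → `MAF < t`;
`nonsynonymous` → `missense`; a bare `splice` token → splice donor or
acceptor; unversioned PolyPhen2 → both the HDIV and HVAR models;
reference-panel MAF atoms → cohort MAF. The canonical form is a flattened,
lexicographically sorted n-ary AND/OR with duplicate leaves removed — no
full boolean minimization. That is deterministic, cheap, and sufficient for
deduplicating published definitions, which differ by commutation, grouping,
and vocabulary rather than by distributivity; logical equivalence beyond the
canonical form is checked in the test suite by exhaustive truth-table
enumeration (≤ 20 atoms).

A score or categorical atom evaluated on a variant missing that predictor's
value is false: an unscored variant cannot satisfy a score threshold. This
is the conservative filter semantics annotation-based masking implies.

Masks are categorized on two axes: the maxMAF class from the tightest
`maf<` token (none → common, <1% → low-frequency, <0.1% → rare, <0.01% →
ultra-rare) and the annotation class from the leaf composition of the
MAF-stripped predicate (pLoF, damMis, pLoFdamMis, pLoFmis, misIndels,
coding, resolved in that precedence order).

## Composite damaging scores

From a variants × algorithms matrix of rank scores (each algorithm's raw
scores rank-transformed to (0, 1], average ranks for ties), three composite
scores are built. Missing rank scores are first imputed with scikit-learn's
iterative round-robin conditional-regression imputer, then clipped back to
(0, 1]; observed values are never altered.

* **og** — the fraction of algorithms whose rank score exceeds the vote cut.
* **pc / ic** — the same vote over principal / independent components.
  Component scores are rank-transformed; a component whose rank score
  correlates significantly *positively* with MAF (Pearson, P < 0.01) is
  inverted (`1 − rank + 1/N`), because damaging variation is held at low
  frequency by selection and every well-behaved predictor correlates
  negatively with MAF. Votes are weighted by explained-variance ratio (PCA)
  or, for ICA — which has no variance decomposition — by normalized mixing-
  column L2 norms, the closest analogue. All components are retained.

The vote cut defaults to 0.67, matching the calibration that categorical
predictors call roughly a third of missense variants damaging. Composite
masks take the form `(LoF_HC | (missense & combo_<m><cut>)) [& mafX]` over
cuts {25, 50, 75, 90}% and MAF tokens {none, 1%, 0.1%}: 36 masks.
Membership is nested across cuts by construction.

## Burden scan

For each (mask, gene, MAF bin ∈ {0.5, 0.01, 0.001}) the qualifying dosages
are summed per sample (missing dosages contribute 0 — callers wanting
imputation should pre-impute) and the trait is regressed on
[intercept, burden, covariates] by OLS; the burden test is the two-sided
t-test on the burden coefficient. The scan uses a Frisch–Waugh
residualization so one QR factorization serves every gene sharing the
covariate design; it is numerically identical to the single-test routine.
Traits are rank-inverse-normal transformed with the Blom offset (k = 3/8).

Calibration gates, defaults as printed in the field's practice: tests with
cMAC ≤ 10 removed; masks matching zero variants removed; masks with mean
genomic inflation λ > 1.2 across traits removed, where
λ = median(χ²₁-quantile(1 − p)) / 0.455 per (mask, trait, bin) and the
widest bin decides exclusion. One numerical guard is added at desk scale:
a mask is eligible for λ-exclusion only if its λ rests on ≥ 50 tests per
trait on average (`lambda_min_tests`). A median-based λ over a handful of
genes has a standard deviation near 0.25 under the null, so without the
guard the gate fires on sampling noise rather than miscalibration; the
threshold 1.2 itself is unchanged.

Conditional analysis: common index variants are chosen by greedy LD
clumping (sort by p; take the best with p < 1e-4; remove neighbours within
250 kb with dosage r² ≥ 0.5) and appended to the covariates, dropping
collinear columns. A burden that merely tags a common variant deflates.

## Strategy counting and selection

An association is a (gene, trait) pair, counted once per strategy however
many member masks detect it, at threshold α₀/m with α₀ = 2.5 × 10⁻⁶.
Frequency-stratified counting keys on the bin-specific p-value (0.5 /
0.01 / 0.001 for total / low-frequency / rare).

*Clustering route*: PCA on binary variant membership keeps the fewest
components explaining ≥ 90% of variance (deterministic sign convention:
largest-magnitude loading positive); k-means (10 restarts, fixed seed) with
k chosen where the cost drop to k+1 falls below 5% of the total cost at
k = 1 — normalizing by the total cost rather than the local cost makes the
elbow rule terminate. Each round-1 cluster is re-clustered on MAF-valued
features (variant MAF where included, else 0), separating masks that share
membership but admit different frequency ranges. Round-2 silhouette is
averaged per subcluster. Each (sub)cluster contributes its member with the
largest significant count (ties: lexicographically smallest id).

*Greedy covering route*: for each size m, all members share threshold α₀/m;
iteratively pick the mask adding the most uncovered associations (ties
lexicographic), re-sorting after every pick, until m masks are chosen; when
useful masks run out, remaining slots are filled with unused masks in id
order at zero gain so the strategy has exactly m members and the α₀/m
threshold is honest. The best strategy across all m wins (ties: smaller m,
then lexicographic). Coverage sets per m are prefix queries on one sorted
p-list per mask. Greedy maximum coverage carries the (1 − 1/e) guarantee
versus the optimal same-size subset at fixed threshold; because the
threshold tightens with m, the optimal m is finite, and it is smaller for
common-variant signal (captured by few masks, so extra masks only raise the
Bonferroni price) than for rare signal. Leave-one-trait-out validation
optimizes on the other traits and scores the held-out trait's coverage
against its trait-specific optimum.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
any particular dataset. Defaults (one choice, applied throughout): 3,000
samples; 100 genes with Poisson(30) coding variants; 90% of MAFs from
Beta(0.15, 40) floored at 1/(2n), 10% Uniform(0.01, 0.5); a latent damaging
indicator with 30% marginal prevalence whose logit falls one unit per
standard deviation of log-MAF; 39 predictor rank scores sharing one latent
factor plus unit-scale independent noise, 5% missing at random; pLoF
consequences drawn only for damaging variants and LOFTEE-HC with
probability 0.8; 8% of genes causal, each active per trait with probability
0.8, with per-allele effects of ±1 trait s.d. applied to truly damaging
alleles below 1% MAF (the allelic-series architecture burden tests target —
unrestricted common-variant effects of that size would dominate trait
variance); sex, array, and five PC-like covariates with 0.15-s.d. effects;
Hardy–Weinberg genotypes; traits inverse-normalized. A synthetic
clinical-style call (`ClinVar_pred` = P exactly for damaging variants)
backs a planted *oracle mask* — the truly damaging rare variants — so
recovery can be scored.

What the generator does not emulate: linkage disequilibrium (beyond an
explicit correlated-pair fixture for clumping tests), relatedness,
population structure beyond synthetic PCs, polygenic background,
winner's-curse ascertainment, and genome-scale gene counts. Passing
recovery tests therefore show the machinery is correct under its stated
model, not that any particular real-data yield would be reproduced.

## Problem sizes in the test and acceptance runs

Suites run at desk scale by design: the greedy-versus-exhaustive comparison
uses instances with ≤ 12 masks (exhaustive enumeration is C(12,4) subsets);
null calibration uses 10,000 vectorized gene tests at n = 300; parameter
recovery uses 300–500 genes at n = 2,000 with cMAC ≥ 100; the end-to-end
recovery experiment uses cohorts of 3,000 samples and 200 genes with ~60
variants per gene, 10 predictor algorithms, and a 4% causal-gene fraction.
The larger gene size keeps the oracle mask's per-gene rare cMAC comfortably
above the cMAC > 10 gate, and the sparser causal architecture keeps the
λ > 1.2 gate meaningful: that gate presumes a mostly-null scan (at biobank
scale causal genes are a negligible share of ~18k tested), and a cohort
where 8% of 100 genes carry 1-s.d. effects inflates median-based λ with
true signal rather than miscalibration. Thresholds (α₀, λ cutoff, cMAC
gate, vote cut) are never altered.

Ultra-rare-only masks show genuinely elevated λ (≈1.2–1.4) even on the
synonymous negative control when traits carry large rare-allele effects:
burdens with cMAC in the tens concentrate leverage in a handful of carriers
and the residual trait distribution is heavy-tailed, which is precisely the
miscalibration the λ gate exists to catch. At desk scale this occasionally
excludes the planted oracle mask itself — a faithful reproduction of the
gate's behaviour, not a defect.

## Numerical choices and degenerate inputs

* Burdens constant after covariate projection raise a degenerate-test
  signal; the scan omits and logs them.
* Collinear conditional covariates are pruned by a greedy rank check.
* λ requires at least one p-value; empty masks are flagged, not scored.
* k-means k is capped at the number of distinct score rows; silhouette is
  reported only when 1 < k < n.
* ICA (FastICA) is stochastic; its seed is a configuration field.
* The identical-mask catalog degenerates to one cluster and one subcluster.
* All randomness flows from explicit seeds; pipeline outputs embed the
  configuration hash and a manifest of SHA-256 digests, and identical
  config + seed reproduces byte-identical files.

## Known limitations

Only quantitative traits and plain covariate-adjusted OLS are supported —
no binary traits, SKAT/ACAT-style tests, saddlepoint/Firth corrections, or
relatedness modeling (a whole-genome ridge step would be needed at biobank
scale). LD clumping operates on dosage correlations within a window, not
haplotype phase. The canonical form does not minimize boolean expressions.
Published-literature curation (which masks exist and their provenance) is
an input, not something this package derives.
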