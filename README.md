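# maskopt

Rare-variant association studies collapse the qualifying variants of a gene
into a per-sample burden and regress traits on it. Which variants qualify is
decided by a *mask* — a boolean filter over bioinformatic annotations and
allele-frequency ceilings, e.g.

```
(stop_gained | stop_lost | frameshift | essential_splice |
 (missense & REVEL_score_0_55)) & maf0_1
```

Published studies use hundreds of heterogeneous masks, and testing several
masks jointly (a *masking strategy* of size m) tightens the significance
threshold to α₀/m (α₀ = 2.5 × 10⁻⁶, exome-wide). `maskopt` is a toolkit for
choosing masking strategies that maximize the number of Bonferroni-surviving
gene–trait associations. It provides:

* a **mask grammar** — parsing, harmonization of heterogeneous published
  definitions into one vocabulary, canonical-form deduplication,
  categorization (6 annotation classes × 4 maxMAF classes), and vectorized
  evaluation against annotation tables;
* **composite damaging scores** — ensemble votes of pathogenicity predictors
  over the raw algorithms (`og`) or their principal / independent components
  (`pc` / `ic`), with components oriented against allele frequency and a new
  family of 36 composite masks;
* a **burden engine** — covariate-adjusted OLS burden tests per
  (mask, gene, trait) at nested MAF bins (50% / 1% / 0.1%), cMAC and
  genomic-inflation (λ) calibration gates, LD clumping, and conditional
  analysis on common index variants;
* **strategy selection** — Bonferroni-aware counting of unique associations,
  two-round clustering of redundant masks (variant membership, then variant
  MAF) with representative picks, and a **greedy maximum-coverage
  optimizer** that searches over all strategy sizes m, with
  leave-one-trait-out validation;
* a **synthetic-cohort generator** with a recorded ground truth (latent
  per-variant pathogenicity tracked noisily by predictor rank scores and
  anti-correlated with frequency, Hardy–Weinberg genotypes, planted per-gene
  burden effects) so every stage can be tested against a known answer,
  including a planted *oracle mask* that selects exactly the truly damaging
  rare variants.

The intended audience is statistical geneticists who want to prototype or
stress-test mask/strategy designs without access to restricted biobank data.

## Worked example

```python
import maskopt as mo
from maskopt.greedy import CoverageInstance

sim = mo.SimulationConfig(n_genes=200, causal_fraction=0.04,
                          mean_variants_per_gene=60, n_algorithms=10, seed=7)
cohort = mo.simulate_cohort(sim)
variants = mo.attach_composite_scores(cohort.variants, cohort.rank_scores, seed=7)
catalog = mo.dedupe_catalog(cohort.catalog)
results, calibration = mo.run_mask_scan(catalog, cohort.genotypes, variants,
                                        cohort.phenotypes, cohort.covariates)
print("masks:", len(cohort.catalog), "->", len(catalog), "unique;",
      "tests:", len(results), "; inflated:", calibration.inflated_masks)
for freq in ("total", "low-frequency", "rare"):
    inst = CoverageInstance.from_results(results, freq)
    trace = mo.optimal_strategy_search(inst, m_max=10)
    print(f"{freq:>14}: optimal m={trace.strategy.m} "
          f"masks={list(trace.strategy.mask_ids)} count={trace.count}")
```

prints

```
masks: 29 -> 26 unique; tests: 49190 ; inflated: []
         total: optimal m=2 masks=['cat_pLoFdamMis.low-frequency', 'cat_pLoF.common'] count=30
 low-frequency: optimal m=2 masks=['cat_pLoFdamMis.common', 'cat_pLoF.common'] count=30
          rare: optimal m=1 masks=['oracle_damaging_rare'] count=12
```

Reading this: the simulated catalog of 29 masks deduplicates to 26 (planted
textual duplicates collapse after harmonization); 49,190 burden tests run
across 26 masks × 5 traits × 3 MAF bins; no mask is excluded for inflation.
The greedy optimizer then finds that total and low-frequency associations
are best covered by a 2-mask strategy mixing a pLoF-plus-damaging-missense
mask with a plain pLoF mask (30 unique gene–trait associations at threshold
α₀/2), while rare associations are maximized by the single planted oracle
mask — exactly the damaging rare variants — because any second mask would
halve the threshold for no extra coverage. That is the Bonferroni trade-off
the optimizer is built around, and the oracle recovery is the expected
answer given the simulation's ground truth.

A shell interface mirrors the stages
(`maskopt simulate | masks | scan | strategies | cluster | optimize |
export-groups | report | run`):

```bash
maskopt simulate --out cohort/ --seed 7
maskopt run --in cohort/ --out run/ --seed 7
maskopt report --run-dir run/
```

Group files for external burden-testing engines (variant set list,
annotation, mask definition; headerless TSV) are written by
`maskopt export-groups`.

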