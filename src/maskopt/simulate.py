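"""Synthetic cohorts with the statistical structure burden testing assumes.

The generator emulates the inputs of an exome-wide rare-variant association
study: a rare-skewed site-frequency spectrum, a latent per-variant damaging
indicator whose probability falls with allele frequency (selection keeps
damaging variation rare), an ensemble of pathogenicity predictors that track
the latent state through a shared single factor plus independent noise,
Hardy-Weinberg genotypes, and quantitative traits built from planted per-gene
burden effects acting on the truly damaging variants, plus covariates.

Ground truth (causal genes, effect sizes, the damaging indicator) is recorded
so recovery can be scored.  All draws flow from one seed; identical
configurations reproduce identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .burden import GenotypeMatrix, inverse_normal_transform
from .masks import MaskCatalog, parse_mask, normalize_mask
from .composite import rank_transform

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedCohort",
    "simulate_variants",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_mask_catalog",
    "simulate_cohort",
    "simulate_correlated_pair",
    "ORACLE_MASK_ID",
]

ORACLE_MASK_ID = "oracle_damaging_rare"

_DAMAGING_CONSEQUENCES = ["stop_gained", "frameshift", "splice_donor",
                          "splice_acceptor", "missense", "inframe_indel"]
_DAMAGING_WEIGHTS = [0.18, 0.18, 0.05, 0.05, 0.47, 0.07]
_BENIGN_CONSEQUENCES = ["missense", "synonymous", "splice_region", "other"]
_BENIGN_WEIGHTS = [0.35, 0.40, 0.10, 0.15]

_IMPACT = {"stop_gained": "HIGH", "stop_lost": "HIGH", "frameshift": "HIGH",
           "splice_donor": "HIGH", "splice_acceptor": "HIGH",
           "missense": "MODERATE", "inframe_indel": "MODERATE",
           "splice_region": "LOW", "synonymous": "LOW", "other": "MODIFIER"}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a desk-scale exome cohort: 3,000 samples, 100 genes
    with ~30 coding variants each, 90% of variants drawn from a rare-skewed
    Beta(0.15, 40) frequency spectrum (floored at 1/(2n)) and 10% common,
    a 30% damaging prevalence falling with log-MAF, 39 rank-scored predictor
    algorithms sharing one latent factor with unit-scale independent noise
    and 5% missing scores, 8% of genes causal with per-allele effects of one
    trait s.d. acting on the truly damaging alleles below 1% MAF (the
    allelic-series architecture burden tests target), and sex/array/5-PC
    covariates.
    """

    n_samples: int = 3000
    n_genes: int = 100
    n_traits: int = 5
    mean_variants_per_gene: float = 30.0
    p_common: float = 0.10
    rare_beta: tuple[float, float] = (0.15, 40.0)
    damaging_prevalence: float = 0.30
    maf_pathogenicity_slope: float = -1.0   # logit slope in standardized log-MAF
    n_algorithms: int = 39
    score_noise: float = 1.0
    missing_rate: float = 0.05
    causal_fraction: float = 0.08
    effect_size: float = 1.0                # per damaging allele, trait s.d.
    effect_maf_max: float = 0.01            # effects act on rare damaging alleles
    trait_gene_prob: float = 0.8            # causal gene active per trait
    covariate_sd: float = 0.15              # effect scale of each covariate
    noise_sd: float = 1.0
    inverse_normalize: bool = True
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimulationTruth:
    damaging: np.ndarray                    # per-variant latent indicator
    causal_genes: list[str]
    trait_betas: dict[str, dict[str, float]]  # trait -> gene -> beta
    latent: np.ndarray = field(default=None)  # per-variant latent factor


def _draw_maf(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    a, b = config.rare_beta
    rare = rng.beta(a, b, size=n)
    common = rng.uniform(0.01, 0.5, size=n)
    is_common = rng.random(n) < config.p_common
    maf = np.where(is_common, common, rare)
    floor = 1.0 / (2 * config.n_samples)
    return np.clip(maf, floor, 0.5)


def simulate_variants(config: SimulationConfig,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Annotation table, rank-score matrix, and ground truth.

    Returns ``(variants, rank_scores, truth)``; ``rank_scores`` rows align
    with ``variants`` rows.
    """
    if config.damaging_prevalence <= 0 or config.damaging_prevalence >= 1:
        raise ValueError("damaging_prevalence must be in (0, 1)")
    if config.mean_variants_per_gene <= 0:
        raise ValueError("mean_variants_per_gene must be positive")
    rng = rng or config.rng()

    counts = np.maximum(1, rng.poisson(config.mean_variants_per_gene,
                                       size=config.n_genes))
    genes = np.repeat([f"GENE{g:04d}" for g in range(config.n_genes)], counts)
    n = genes.size
    maf = _draw_maf(rng, n, config)

    # damaging probability decreases with log-MAF; intercept holds the
    # marginal prevalence near its configured value
    z = stats.zscore(np.log10(maf))
    logits = np.log(config.damaging_prevalence
                    / (1 - config.damaging_prevalence)) \
        + config.maf_pathogenicity_slope * z
    damaging = rng.random(n) < 1.0 / (1.0 + np.exp(-logits))

    consequence = np.empty(n, dtype=object)
    n_dam = int(damaging.sum())
    consequence[damaging] = rng.choice(_DAMAGING_CONSEQUENCES, size=n_dam,
                                       p=_DAMAGING_WEIGHTS)
    consequence[~damaging] = rng.choice(_BENIGN_CONSEQUENCES, size=n - n_dam,
                                        p=_BENIGN_WEIGHTS)
    is_plof = np.isin(consequence, ["stop_gained", "frameshift",
                                    "splice_donor", "splice_acceptor"])
    lof_conf = np.where(is_plof & (rng.random(n) < 0.8), "HC",
                        np.where(is_plof, "LC", "none"))
    is_indel = np.isin(consequence, ["frameshift", "inframe_indel"])

    # single latent factor links the damaging state to every predictor
    latent = damaging.astype(float) + rng.normal(0, 0.3, size=n)
    raw = latent[:, None] + config.score_noise * rng.normal(
        0, 1, size=(n, config.n_algorithms))
    ranks = np.column_stack([rank_transform(raw[:, j])
                             for j in range(config.n_algorithms)])
    rank_scores = pd.DataFrame(
        ranks, columns=[f"alg{j:02d}" for j in range(config.n_algorithms)])
    if config.missing_rate > 0:
        miss = rng.random(rank_scores.shape) < config.missing_rate
        # keep every row >= 1 observed and every column >= 2 observed
        full_rows = miss.all(axis=1)
        miss[full_rows, 0] = False
        for j in range(miss.shape[1]):
            if (~miss[:, j]).sum() < 2:
                miss[:2, j] = False
        rank_scores = rank_scores.mask(miss)

    variants = pd.DataFrame({
        "variant_id": [f"v{i:05d}" for i in range(n)],
        "chrom": "1",
        "pos": np.arange(1, n + 1) * 5000,
        "ref": "A",
        "alt": np.where(is_indel, "AT", "G"),
        "gene": genes,
        "consequence": consequence,
        "is_indel": is_indel,
        "lof_confidence": lof_conf,
        "impact": [_IMPACT[c] for c in consequence],
        "maf": maf,
        "mac": np.round(2 * config.n_samples * maf).astype(int),
    })
    # predictor columns the mask vocabulary addresses
    variants["REVEL_score"] = rank_transform(latent + config.score_noise
                                             * rng.normal(0, 1, n))
    variants["CADD_phred"] = 10 + 30 * variants["REVEL_score"]
    for alg in ("SIFT", "Polyphen2_HDIV", "Polyphen2_HVAR"):
        noisy = rank_transform(latent + config.score_noise
                               * rng.normal(0, 1, n))
        variants[f"{alg}_pred"] = np.where(noisy > 0.67, "D", "B")
    # near-ground-truth clinical call backing the planted oracle mask
    variants["ClinVar_pred"] = np.where(damaging, "P", "B")

    pool = sorted(rng.choice(config.n_genes,
                             size=max(1, round(config.causal_fraction
                                               * config.n_genes)),
                             replace=False))
    causal_genes = [f"GENE{g:04d}" for g in pool]
    trait_betas: dict[str, dict[str, float]] = {}
    for t in range(config.n_traits):
        betas = {}
        for g in causal_genes:
            if rng.random() < config.trait_gene_prob:
                betas[g] = config.effect_size * rng.choice([-1.0, 1.0])
        trait_betas[f"trait{t}"] = betas

    truth = SimulationTruth(damaging=damaging, causal_genes=causal_genes,
                            trait_betas=trait_betas, latent=latent)
    return variants, rank_scores, truth


def simulate_genotypes(variants: pd.DataFrame, n_samples: int,
                       rng: np.random.Generator | int = 0,
                       ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Hardy-Weinberg dosages, Binomial(2, MAF) per sample; realized MAF and
    MAC are written back onto the returned annotation table."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    maf = variants["maf"].to_numpy(dtype=float)
    dosages = rng.binomial(2, maf, size=(n_samples, maf.size)).astype(float)
    genotypes = GenotypeMatrix(dosages, [f"s{i:05d}" for i in range(n_samples)],
                               list(variants["variant_id"]))
    realized = variants.copy()
    realized["mac"] = genotypes.mac().astype(int)
    realized["maf"] = genotypes.maf()
    return genotypes, realized


def simulate_phenotypes(genotypes: GenotypeMatrix, variants: pd.DataFrame,
                        truth: SimulationTruth, config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Traits from planted burden effects plus covariates plus noise.

    Effects act on each causal gene's *truly damaging* dosage sum.  Traits
    are rank-inverse-normalized (Blom) unless the configuration disables it.
    Returns ``(phenotypes, covariates)``; covariates are sex, array, and
    5 PC-like standard-normal columns.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n = genotypes.n_samples
    covariates = np.column_stack([
        rng.integers(0, 2, n).astype(float),   # sex
        rng.integers(0, 2, n).astype(float),   # genotyping array
        rng.normal(0, 1, size=(n, 5)),          # ancestry PCs
    ])
    genes = variants["gene"].to_numpy()
    phen = {}
    for trait, betas in truth.trait_betas.items():
        y = rng.normal(0, config.noise_sd, n)
        gamma = rng.normal(0, config.covariate_sd, covariates.shape[1])
        y = y + covariates @ gamma
        maf = variants["maf"].to_numpy(dtype=float)
        for gene, beta in betas.items():
            cols = np.flatnonzero((genes == gene) & truth.damaging
                                  & (maf < config.effect_maf_max))
            if cols.size:
                y = y + beta * np.nansum(genotypes.dosages[:, cols], axis=1)
        phen[trait] = inverse_normal_transform(y) if config.inverse_normalize \
            else y
    table = pd.DataFrame(phen, index=genotypes.sample_ids)
    return table, covariates


# --------------------------------------------------------------------------
# Mask catalog
# --------------------------------------------------------------------------

_CLASS_EXPRESSIONS = {
    "pLoF": "stop_gained | stop_lost | frameshift | essential_splice",
    "damMis": "missense & Polyphen2_HDIV_pred_D",
    "pLoFdamMis": "LoF_HC | (missense & REVEL_score_0_5)",
    "pLoFmis": "LoF_HC | missense",
    "misIndels": "missense | inframe_indel",
    "coding": "missense | synonymous | inframe_indel | splice_region | other",
}
_MAF_TOKENS = {"common": None, "low-frequency": "maf1", "rare": "maf0_1",
               "ultra-rare": "maf0_01"}


def simulate_mask_catalog(include_oracle: bool = True,
                          include_duplicates: bool = True) -> MaskCatalog:
    """A compact catalog spanning all 24 (annotation x maxMAF) categories,
    with planted near-duplicates for dedup and a planted oracle mask
    (the truly damaging rare variants, via the synthetic clinical call)."""
    masks = []
    for cls, expr in _CLASS_EXPRESSIONS.items():
        for maf_cls, token in _MAF_TOKENS.items():
            full = expr if token is None else f"({expr}) & {token}"
            mask_id = f"cat_{cls}.{maf_cls}"
            masks.append(normalize_mask(parse_mask(full, mask_id=mask_id,
                                                   source="simulated")))
    if include_duplicates:
        # textual variants that collapse onto catalog members after
        # harmonization and canonicalization
        dups = [
            ("dup_pLoF_reordered",
             "essential_splice | frameshift | stop_lost | stop_gained"),
            ("dup_pLoFmis_nonsyn", "nonsynonymous | LoF_HC"),
            ("dup_damMis_le", "(Polyphen2_HDIV_pred_D & missense)"),
        ]
        for mask_id, expr in dups:
            masks.append(parse_mask(expr, mask_id=mask_id, source="simulated"))
    masks.append(parse_mask("synonymous & maf0_1",
                            mask_id="negative_control.rare",
                            source="simulated"))
    if include_oracle:
        masks.append(parse_mask("ClinVar_pred_P & maf0_1",
                                mask_id=ORACLE_MASK_ID, source="simulated"))
    return MaskCatalog(masks)


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    variants: pd.DataFrame
    rank_scores: pd.DataFrame
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    covariates: np.ndarray
    truth: SimulationTruth
    catalog: MaskCatalog


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full reproducible cohort: variants, genotypes, phenotypes, catalog."""
    rng = config.rng()
    variants, rank_scores, truth = simulate_variants(config, rng)
    genotypes, variants = simulate_genotypes(variants, config.n_samples, rng)
    phenotypes, covariates = simulate_phenotypes(genotypes, variants, truth,
                                                 config, rng)
    return SimulatedCohort(config=config, variants=variants,
                           rank_scores=rank_scores, genotypes=genotypes,
                           phenotypes=phenotypes, covariates=covariates,
                           truth=truth, catalog=simulate_mask_catalog())


def simulate_correlated_pair(rng: np.random.Generator, n_samples: int,
                             maf_a: float = 0.2, maf_b: float = 0.2,
                             r: float = 0.7) -> tuple[np.ndarray, np.ndarray]:
    """Two dosage vectors with approximate correlation ``r`` (a minimal LD
    fixture for clumping and conditional-analysis tests)."""
    za = rng.normal(size=(n_samples, 2))
    zb = r * za + np.sqrt(1 - r**2) * rng.normal(size=(n_samples, 2))
    a = (za < stats.norm.ppf(maf_a)).sum(axis=1).astype(float)
    b = (zb < stats.norm.ppf(maf_b)).sum(axis=1).astype(float)
    return a, b
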