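"""Gene-level burden testing with calibration filters and conditional analysis.

For each (mask, gene, MAF bin) the qualifying variant dosages are summed into
a per-sample burden and regressed on each quantitative trait with covariates
(ordinary least squares; the two-sided t-test on the burden coefficient is the
burden test).  Burdens are recomputed at nested MAF sub-bins (0.5 / 0.01 /
0.001) so an association can be attributed to common, low-frequency, or rare
variation.  Calibration: tests with cumulative minor-allele count (cMAC) <= 10
are dropped, masks matching no variants are dropped, and masks whose mean
genomic inflation lambda across traits exceeds 1.2 are excluded.

Significant burdens can be re-tested conditional on nearby common index
variants (greedy LD clumping), which deflates associations merely tagging a
common-variant signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse, stats

from .config import FREQ_CLASS_BIN, PipelineConfig
from .masks import MaskCatalog

__all__ = [
    "GenotypeMatrix",
    "BurdenCollapse",
    "BurdenTestResult",
    "CalibrationReport",
    "DegenerateBurdenError",
    "inverse_normal_transform",
    "collapse_burden",
    "fit_burden_test",
    "genomic_lambda",
    "run_mask_scan",
    "classify_association_frequency",
    "ld_clump",
    "conditional_burden_test",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, df=1)  # 0.45494...

RESULT_COLUMNS = ["gene", "trait", "mask_id", "maf_bin", "n_variants",
                  "cmac", "beta", "se", "p"]


class DegenerateBurdenError(ValueError):
    """Burden has no variance after covariate projection; test undefined."""


@dataclass
class GenotypeMatrix:
    """samples x variants dosage matrix; missing dosages are NaN."""

    dosages: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError("dosage matrix shape does not match id lists")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def mac(self) -> np.ndarray:
        return np.nansum(self.dosages, axis=0)

    def maf(self) -> np.ndarray:
        called = 2 * np.sum(~np.isnan(self.dosages), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = self.mac() / called
        return np.minimum(np.nan_to_num(af), 1 - np.nan_to_num(af))


def inverse_normal_transform(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset (k = 3/8)."""
    values = np.asarray(values, dtype=float)
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - offset) / (values.size - 2 * offset + 1))


# --------------------------------------------------------------------------
# Collapsing
# --------------------------------------------------------------------------


@dataclass
class BurdenCollapse:
    burden: np.ndarray
    cmac: float
    n_variants: int


def collapse_burden(genotypes: GenotypeMatrix, membership: np.ndarray,
                    maf: np.ndarray, maf_bin: float,
                    mac: np.ndarray | None = None) -> BurdenCollapse:
    """Sum qualifying dosages per sample.

    A variant qualifies if it is in the mask and its MAF is below the bin.
    Missing dosages contribute 0.  cMAC is the summed minor-allele count of
    the qualifying variants.
    """
    membership = np.asarray(membership, dtype=bool)
    if membership.shape[0] != len(genotypes.variant_ids):
        raise ValueError(
            f"membership length {membership.shape[0]} does not match "
            f"{len(genotypes.variant_ids)} genotype columns")
    maf = np.asarray(maf, dtype=float)
    keep = membership & (maf < maf_bin)
    if not keep.any():
        return BurdenCollapse(np.zeros(genotypes.n_samples), 0.0, 0)
    sub = genotypes.dosages[:, keep]
    burden = np.nansum(sub, axis=1)
    if mac is None:
        cmac = float(np.nansum(sub))
    else:
        cmac = float(np.asarray(mac, dtype=float)[keep].sum())
    return BurdenCollapse(burden, cmac, int(keep.sum()))


# --------------------------------------------------------------------------
# Testing
# --------------------------------------------------------------------------


@dataclass
class BurdenTestResult:
    beta: float
    se: float
    p: float


def _design(burden: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(burden), burden]
    if covariates is not None and covariates.size:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != burden.shape[0]:
            covariates = covariates.T
        cols.append(covariates)
    return np.column_stack(cols)


def fit_burden_test(burden: np.ndarray, trait: np.ndarray,
                    covariates: np.ndarray | None = None) -> BurdenTestResult:
    """OLS of trait on [intercept, burden, covariates]; two-sided t-test on
    the burden coefficient."""
    burden = np.asarray(burden, dtype=float)
    trait = np.asarray(trait, dtype=float)
    x = _design(burden, covariates)
    # burden must retain variance once covariates are projected out
    q, _ = np.linalg.qr(np.delete(x, 1, axis=1))
    resid_b = burden - q @ (q.T @ burden)
    if np.sum(resid_b**2) <= 1e-12 * max(1.0, np.sum(burden**2)):
        raise DegenerateBurdenError("burden is constant given covariates")
    fit = sm.OLS(trait, x).fit()
    return BurdenTestResult(beta=float(fit.params[1]), se=float(fit.bse[1]),
                            p=float(fit.pvalues[1]))


def _scan_ols(burdens: np.ndarray, trait: np.ndarray,
              covariates: np.ndarray | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized burden tests for many genes sharing one covariate design.

    Frisch-Waugh: residualize trait and every burden column on
    [intercept, covariates]; the burden coefficient, its standard error, and
    the t-test follow from the residualized simple regressions with the full
    model's degrees of freedom.  Agrees with :func:`fit_burden_test`.
    """
    n = trait.shape[0]
    if covariates is None or not np.size(covariates):
        base = np.ones((n, 1))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        base = np.column_stack([np.ones(n), cov])
    q, _ = np.linalg.qr(base)
    ry = trait - q @ (q.T @ trait)
    rb = burdens - q @ (q.T @ burdens)
    ss_b = np.sum(rb**2, axis=0)
    ok = ss_b > 1e-12 * np.maximum(1.0, np.sum(burdens**2, axis=0))
    df = n - base.shape[1] - 1
    beta = np.full(burdens.shape[1], np.nan)
    se = np.full(burdens.shape[1], np.nan)
    pval = np.full(burdens.shape[1], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta[ok] = (rb[:, ok].T @ ry) / ss_b[ok]
        resid = ry[:, None] - rb[:, ok] * beta[ok]
        sigma2 = np.sum(resid**2, axis=0) / df
        se[ok] = np.sqrt(sigma2 / ss_b[ok])
        t = beta[ok] / se[ok]
        pval[ok] = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, pval


def genomic_lambda(pvalues: np.ndarray) -> float:
    """Genomic inflation factor: median observed chi-square (1 df, from the
    p-values) over the null median 0.455."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        raise ValueError("no p-values for genomic lambda")
    chi2 = stats.chi2.isf(pvalues, df=1)
    return float(np.median(chi2) / _CHI2_MEDIAN_1DF)


# --------------------------------------------------------------------------
# Scan
# --------------------------------------------------------------------------


@dataclass
class CalibrationReport:
    """Per-(mask, trait, bin) genomic inflation, mean lambda per mask, and
    the masks excluded as empty or inflated."""

    lambdas: pd.DataFrame
    mask_mean_lambda: pd.Series
    empty_masks: list[str] = field(default_factory=list)
    inflated_masks: list[str] = field(default_factory=list)

    @property
    def excluded_masks(self) -> list[str]:
        return sorted(set(self.empty_masks) | set(self.inflated_masks))


def run_mask_scan(catalog: MaskCatalog, genotypes: GenotypeMatrix,
                  variants: pd.DataFrame, phenotypes: pd.DataFrame,
                  covariates: np.ndarray | None = None,
                  config: PipelineConfig | None = None,
                  ) -> tuple[pd.DataFrame, CalibrationReport]:
    """Burden-test every (mask, trait, gene, MAF bin) and calibrate.

    ``variants`` must be aligned with ``genotypes.variant_ids`` and carry
    ``gene``, ``maf``, ``mac``.  ``phenotypes`` holds one column per trait
    (already inverse-normalized).  Returns the results table (tests with
    cMAC <= cmac_min removed; masks empty of variants or with mean
    lambda > lambda_max excluded) and the calibration report.
    """
    config = config or PipelineConfig()
    variants = variants.set_index("variant_id").loc[genotypes.variant_ids].reset_index()
    maf = variants["maf"].to_numpy(dtype=float)
    mac = variants["mac"].to_numpy(dtype=float)
    genes = variants["gene"].to_numpy()
    gene_order = sorted(pd.unique(genes))
    gene_index = {g: i for i, g in enumerate(gene_order)}
    gene_idx = np.array([gene_index[g] for g in genes])
    n_genes = len(gene_order)
    dosages = np.nan_to_num(genotypes.dosages)  # missing dosages count 0
    dosages_t = np.ascontiguousarray(dosages.T)  # variants x samples

    membership = catalog.membership(variants)

    rows: list[tuple] = []
    empty_masks: list[str] = []
    for mask in catalog:
        member = membership.loc[mask.mask_id].to_numpy(dtype=bool)
        if not member.any():
            empty_masks.append(mask.mask_id)
            logger.info("mask %s matches no variants; excluded", mask.mask_id)
            continue
        for maf_bin in config.aaf_bins:
            keep = member & (maf < maf_bin)
            if not keep.any():
                continue
            cmac_per_gene = np.bincount(gene_idx[keep], weights=mac[keep],
                                        minlength=n_genes)
            nvar_per_gene = np.bincount(gene_idx[keep], minlength=n_genes)
            tested = np.flatnonzero(cmac_per_gene > config.cmac_min)
            if tested.size == 0:
                continue
            gene_stats = [(gene_order[gi], float(cmac_per_gene[gi]),
                           int(nvar_per_gene[gi])) for gi in tested]
            # burdens for all tested genes in one sparse product
            kept_cols = np.flatnonzero(keep)
            local = {gi: j for j, gi in enumerate(tested)}
            sel = np.array([local.get(gi, -1) for gi in gene_idx[kept_cols]])
            use = sel >= 0
            indicator = sparse.csr_matrix(
                (np.ones(use.sum()), (sel[use], kept_cols[use])),
                shape=(tested.size, len(genotypes.variant_ids)))
            burdens = (indicator @ dosages_t).T
            for trait in phenotypes.columns:
                y = phenotypes[trait].to_numpy(dtype=float)
                beta, se, p = _scan_ols(burdens, y, covariates)
                for (g, cmac, nvar), b, s, pv in zip(gene_stats, beta, se, p):
                    if np.isnan(pv):
                        logger.info("degenerate burden: mask=%s gene=%s "
                                    "trait=%s bin=%g", mask.mask_id, g, trait,
                                    maf_bin)
                        continue
                    rows.append((g, trait, mask.mask_id, maf_bin, nvar,
                                 cmac, b, s, pv))

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    results = results.sort_values(["mask_id", "trait", "maf_bin", "gene"],
                                  ascending=[True, True, False, True],
                                  ignore_index=True)

    # lambda per (mask, trait, bin); exclusion decided on the widest bin
    lam_rows = []
    for (mask_id, trait, maf_bin), grp in results.groupby(
            ["mask_id", "trait", "maf_bin"], sort=True):
        lam_rows.append((mask_id, trait, maf_bin,
                         genomic_lambda(grp["p"].to_numpy())))
    lambdas = pd.DataFrame(lam_rows,
                           columns=["mask_id", "trait", "maf_bin", "lambda"])
    widest = max(config.aaf_bins)
    at_widest = lambdas[lambdas["maf_bin"] == widest]
    mask_mean = at_widest.groupby("mask_id")["lambda"].mean()
    # a median-based lambda from a handful of genes is noise, not evidence of
    # miscalibration: only masks with enough tests per trait can be excluded
    n_tests = (results[results["maf_bin"] == widest]
               .groupby(["mask_id", "trait"]).size()
               .groupby("mask_id").mean())
    eligible = n_tests[n_tests >= config.lambda_min_tests].index
    inflated = sorted(mask_mean[(mask_mean > config.lambda_max)
                                & mask_mean.index.isin(eligible)].index)
    if inflated:
        logger.info("excluding %d inflated masks (mean lambda > %.2f): %s",
                    len(inflated), config.lambda_max, inflated)
        results = results[~results["mask_id"].isin(inflated)].reset_index(drop=True)

    report = CalibrationReport(lambdas=lambdas, mask_mean_lambda=mask_mean,
                               empty_masks=sorted(empty_masks),
                               inflated_masks=inflated)
    return results, report


def classify_association_frequency(results: pd.DataFrame,
                                   threshold: float = 2.5e-6) -> dict[str, bool]:
    """Frequency-class flags for one (gene, trait, mask) across MAF bins.

    ``total`` if the widest (0.5) bin is significant; ``low-frequency`` if the
    0.01 bin is; ``rare`` if the 0.001 bin is.  Rare variants are a subset of
    low-frequency variants, so rare signal also surfaces in the 0.01 bin.
    """
    flags = {}
    for cls, maf_bin in FREQ_CLASS_BIN.items():
        sub = results[results["maf_bin"] == maf_bin]
        flags[cls] = bool(len(sub) and (sub["p"].to_numpy() < threshold).any())
    return flags


# --------------------------------------------------------------------------
# Conditional analysis
# --------------------------------------------------------------------------


def ld_clump(pvalues: np.ndarray, genotypes: np.ndarray,
             positions: np.ndarray, chrom: np.ndarray | None = None,
             p1: float = 1e-4, r2: float = 0.5,
             window_kb: int = 250) -> list[int]:
    """Greedy LD clumping; returns indices of index variants.

    Sort by p ascending; take the best remaining variant with p < p1 as an
    index; remove remaining variants within the window whose squared dosage
    correlation with the index is >= r2; repeat.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    positions = np.asarray(positions)
    n_var = pvalues.size
    if chrom is None:
        chrom = np.zeros(n_var)
    chrom = np.asarray(chrom)
    order = np.lexsort((np.arange(n_var), pvalues))
    removed = np.zeros(n_var, dtype=bool)
    indices: list[int] = []
    window = window_kb * 1000
    for i in order:
        if removed[i] or pvalues[i] >= p1:
            continue
        indices.append(int(i))
        removed[i] = True
        near = np.flatnonzero((chrom == chrom[i])
                              & (np.abs(positions - positions[i]) <= window)
                              & ~removed)
        if near.size == 0:
            continue
        gi = genotypes[:, i]
        for j in near:
            gj = genotypes[:, j]
            si, sj = np.std(gi), np.std(gj)
            r2_ij = 1.0 if (si == 0 and sj == 0) else (
                0.0 if (si == 0 or sj == 0)
                else np.corrcoef(gi, gj)[0, 1] ** 2)
            if r2_ij >= r2:
                removed[j] = True
    return indices


def conditional_burden_test(burden: np.ndarray, trait: np.ndarray,
                            covariates: np.ndarray | None,
                            index_genotypes: np.ndarray | None) -> BurdenTestResult:
    """Burden test with common index-variant dosages added as covariates.

    Collinear index columns (with the covariates or each other) are dropped.
    """
    if index_genotypes is None or not np.size(index_genotypes):
        return fit_burden_test(burden, trait, covariates)
    idx = np.atleast_2d(np.asarray(index_genotypes, dtype=float))
    if idx.shape[0] != np.asarray(burden).shape[0]:
        idx = idx.T
    base = covariates
    if base is None or not np.size(base):
        combined = idx
    else:
        base = np.atleast_2d(np.asarray(base, dtype=float))
        if base.shape[0] != np.asarray(burden).shape[0]:
            base = base.T
        combined = np.column_stack([base, idx])
    # prune collinear columns by greedy QR rank check
    n = combined.shape[0]
    kept: list[int] = []
    current = np.ones((n, 1))
    for j in range(combined.shape[1]):
        cand = np.column_stack([current, combined[:, j]])
        if np.linalg.matrix_rank(cand) > current.shape[1]:
            kept.append(j)
            current = cand
        else:
            logger.info("dropping collinear conditional covariate column %d", j)
    return fit_burden_test(burden, trait, combined[:, kept])
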