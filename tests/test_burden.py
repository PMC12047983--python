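"""Burden collapsing, OLS testing, calibration, clumping, conditioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from maskopt.burden import (DegenerateBurdenError, GenotypeMatrix,
                            classify_association_frequency, collapse_burden,
                            conditional_burden_test, fit_burden_test,
                            genomic_lambda, inverse_normal_transform,
                            ld_clump, run_mask_scan)
from maskopt.config import PipelineConfig
from maskopt.masks import MaskCatalog, normalize_mask, parse_mask
from maskopt.simulate import simulate_correlated_pair

from conftest import make_variant, variant_frame


# --------------------------------------------------------------------------
# Independent oracle: explicit normal equations + t distribution
# --------------------------------------------------------------------------

def ols_oracle(burden, trait, covariates=None):
    x = [np.ones(len(burden)), np.asarray(burden, dtype=float)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(burden):
            cov = cov.T
        for j in range(cov.shape[1]):
            x.append(cov[:, j])
    x = np.column_stack(x)
    y = np.asarray(trait, dtype=float)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta_hat = xtx_inv @ x.T @ y
    resid = y - x @ beta_hat
    df = len(y) - x.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    t = beta_hat[1] / se
    p = 2 * stats.t.sf(abs(t), df)
    return beta_hat[1], se, p


# --------------------------------------------------------------------------
# Collapsing
# --------------------------------------------------------------------------

def _geno(dosages):
    d = np.asarray(dosages, dtype=float)
    return GenotypeMatrix(d, [f"s{i}" for i in range(d.shape[0])],
                          [f"v{i}" for i in range(d.shape[1])])


def test_collapse_empty_membership_gives_zero_burden():
    g = _geno([[1, 0], [0, 2], [1, 1]])
    out = collapse_burden(g, [False, False], [0.1, 0.1], 0.5)
    assert out.burden.tolist() == [0, 0, 0]
    assert out.cmac == 0 and out.n_variants == 0


def test_collapse_sum_arithmetic():
    g = _geno([[1, 0], [0, 2], [1, 1]])
    out = collapse_burden(g, [True, True], [0.01, 0.01], 0.5)
    assert out.burden.tolist() == [1, 2, 2]
    assert out.cmac == 5 and out.n_variants == 2


def test_collapse_missing_dosage_contributes_zero():
    g = _geno([[1, np.nan], [0, 2]])
    out = collapse_burden(g, [True, True], [0.01, 0.01], 0.5)
    assert out.burden.tolist() == [1, 2]


def test_collapse_misaligned_membership_errors():
    g = _geno([[1, 0]])
    with pytest.raises(ValueError, match="match"):
        collapse_burden(g, [True], [0.1], 0.5)


def test_collapse_bins_are_nested(rng):
    n_var = 40
    maf = rng.uniform(0, 0.05, n_var)
    dosages = rng.binomial(2, maf, size=(50, n_var)).astype(float)
    g = _geno(dosages)
    member = rng.random(n_var) < 0.7
    prev_burden = None
    for maf_bin in (0.5, 0.01, 0.001):
        out = collapse_burden(g, member, maf, maf_bin)
        if prev_burden is not None:
            assert (out.burden <= prev_burden + 1e-12).all()
        prev_burden = out.burden


# --------------------------------------------------------------------------
# Testing
# --------------------------------------------------------------------------

def test_perfect_fit_recovers_slope():
    burden = np.arange(30, dtype=float)
    res = fit_burden_test(burden, 0.5 * burden)
    assert res.beta == pytest.approx(0.5)
    assert res.p < 1e-100


def test_fit_matches_normal_equations_oracle(rng):
    """beta/se/p agree with the explicit linear-algebra oracle to 1e-10."""
    for _ in range(20):
        n = 50
        burden = rng.poisson(1.0, n).astype(float)
        cov = rng.normal(size=(n, 3))
        trait = 0.2 * burden + cov @ rng.normal(size=3) + rng.normal(size=n)
        if np.var(burden) == 0:
            continue
        res = fit_burden_test(burden, trait, cov)
        b, s, p = ols_oracle(burden, trait, cov)
        assert res.beta == pytest.approx(b, rel=1e-10)
        assert res.se == pytest.approx(s, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10, abs=1e-300)


def test_constant_burden_raises_degenerate():
    with pytest.raises(DegenerateBurdenError):
        fit_burden_test(np.ones(20), np.random.default_rng(0).normal(size=20))


def test_null_type_one_error_is_calibrated(rng):
    n, reps = 200, 2000
    hits = 0
    for _ in range(reps):
        burden = rng.poisson(0.5, n).astype(float)
        if burden.var() == 0:
            continue
        trait = rng.normal(size=n)
        if fit_burden_test(burden, trait).p < 0.05:
            hits += 1
    lo, hi = stats.binom.interval(0.999, reps, 0.05)
    assert lo <= hits <= hi


# --------------------------------------------------------------------------
# Genomic inflation
# --------------------------------------------------------------------------

def test_lambda_of_all_median_pvalues_is_one():
    assert genomic_lambda(np.full(99, 0.5)) == pytest.approx(1.0)


def test_lambda_closed_form_at_p_005():
    expected = stats.chi2.ppf(0.95, 1) / stats.chi2.ppf(0.5, 1)
    assert genomic_lambda(np.full(11, 0.05)) == pytest.approx(expected)
    assert expected == pytest.approx(8.44, abs=0.01)


def test_lambda_uniform_pvalues_near_one(rng):
    p = rng.uniform(size=10_000)
    assert genomic_lambda(p) == pytest.approx(1.0, abs=0.03)


def test_lambda_empty_errors():
    with pytest.raises(ValueError):
        genomic_lambda(np.array([]))


def test_inverse_normal_transform_standardizes(rng):
    y = rng.exponential(size=2000)
    z = inverse_normal_transform(y)
    assert abs(z.mean()) < 0.05
    assert 0.9 < z.var() < 1.1


# --------------------------------------------------------------------------
# Scan
# --------------------------------------------------------------------------

def _scan_fixture(rng, causal_beta=0.0):
    n_samples, n_genes, per_gene = 600, 20, 8
    rows, dosage_cols = [], []
    for g in range(n_genes):
        for v in range(per_gene):
            maf = float(rng.uniform(0.004, 0.009))
            rows.append(make_variant(
                f"g{g}v{v}", gene=f"G{g:03d}",
                consequence="missense" if v % 2 else "synonymous",
                maf=maf, mac=0))
            dosage_cols.append(rng.binomial(2, maf, n_samples).astype(float))
    variants = variant_frame(rows)
    dosages = np.column_stack(dosage_cols)
    variants["mac"] = dosages.sum(axis=0).astype(int)
    variants["maf"] = dosages.sum(axis=0) / (2 * n_samples)
    g = GenotypeMatrix(dosages, [f"s{i}" for i in range(n_samples)],
                       list(variants["variant_id"]))
    trait = rng.normal(size=n_samples)
    if causal_beta:
        causal_cols = [i for i, r in enumerate(rows)
                       if r["gene"] == "G000" and r["consequence"] == "missense"]
        trait = trait + causal_beta * dosages[:, causal_cols].sum(axis=1)
    phen = pd.DataFrame({"t0": inverse_normal_transform(trait)},
                        index=g.sample_ids)
    return variants, g, phen


def test_scan_negative_control_produces_no_significant_hits(rng):
    variants, g, phen = _scan_fixture(rng)
    catalog = MaskCatalog([normalize_mask(parse_mask("synonymous & maf1",
                                                     mask_id="syn"))])
    results, report = run_mask_scan(catalog, g, variants, phen)
    assert (results["p"] >= 2.5e-6).all()
    assert not report.excluded_masks


def test_scan_detects_planted_effect(rng):
    variants, g, phen = _scan_fixture(rng, causal_beta=2.0)
    catalog = MaskCatalog([normalize_mask(parse_mask("missense & maf1",
                                                     mask_id="mis"))])
    results, _ = run_mask_scan(catalog, g, variants, phen)
    hit = results[(results["gene"] == "G000") & (results["maf_bin"] == 0.5)]
    assert (hit["p"] < 2.5e-6).all() and len(hit) == 1


def test_scan_excludes_and_flags_empty_mask(rng):
    variants, g, phen = _scan_fixture(rng)
    catalog = MaskCatalog([
        normalize_mask(parse_mask("missense", mask_id="mis")),
        normalize_mask(parse_mask("stop_gained", mask_id="none_match")),
    ])
    results, report = run_mask_scan(catalog, g, variants, phen)
    assert "none_match" in report.empty_masks
    assert "none_match" not in set(results["mask_id"])


def test_scan_cmac_gate_removes_thin_tests(rng):
    variants, g, phen = _scan_fixture(rng)
    catalog = MaskCatalog([normalize_mask(parse_mask("missense & maf1",
                                                     mask_id="mis"))])
    results, _ = run_mask_scan(catalog, g, variants, phen)
    assert (results["cmac"] > 10).all()


def test_scan_agrees_with_single_fit(rng):
    variants, g, phen = _scan_fixture(rng, causal_beta=0.5)
    catalog = MaskCatalog([normalize_mask(parse_mask("missense & maf1",
                                                     mask_id="mis"))])
    results, _ = run_mask_scan(catalog, g, variants, phen)
    member = np.array(["missense" == c for c in variants["consequence"]])
    row = results[(results["gene"] == "G003")
                  & (results["maf_bin"] == 0.5)].iloc[0]
    cols = np.flatnonzero(member & (variants["gene"] == "G003").to_numpy()
                          & (variants["maf"].to_numpy() < 0.01))
    burden = np.nansum(g.dosages[:, cols], axis=1)
    ref = fit_burden_test(burden, phen["t0"].to_numpy())
    assert row["beta"] == pytest.approx(ref.beta, rel=1e-9)
    assert row["se"] == pytest.approx(ref.se, rel=1e-9)
    assert row["p"] == pytest.approx(ref.p, rel=1e-9)


# --------------------------------------------------------------------------
# Frequency classification
# --------------------------------------------------------------------------

def _bin_results(p_total, p_low, p_rare):
    return pd.DataFrame({
        "maf_bin": [0.5, 0.01, 0.001],
        "p": [p_total, p_low, p_rare],
    })


def test_classification_total_only():
    flags = classify_association_frequency(_bin_results(1e-7, 0.3, 0.4))
    assert flags == {"total": True, "low-frequency": False, "rare": False}


def test_classification_all_classes():
    flags = classify_association_frequency(_bin_results(1e-7, 1e-7, 1e-7))
    assert all(flags.values())


def test_rare_causal_fixture_sets_rare_with_total(rng):
    """When every causal variant is ultra-rare, significance in the widest
    bin comes with significance in the rare bin."""
    n = 2000
    dosages, rows = [], []
    for v in range(30):
        maf = 8e-4
        rows.append(make_variant(f"v{v}", gene="G0", consequence="missense",
                                 maf=maf))
        dosages.append(rng.binomial(2, maf, n).astype(float))
    dosages = np.column_stack(dosages)
    burden = dosages.sum(axis=1)
    trait = 1.2 * burden + rng.normal(size=n)
    res = []
    for maf_bin in (0.5, 0.01, 0.001):
        r = fit_burden_test(burden, trait)
        res.append({"maf_bin": maf_bin, "p": r.p})
    flags = classify_association_frequency(pd.DataFrame(res))
    assert flags["total"] == flags["rare"] == True  # noqa: E712


# --------------------------------------------------------------------------
# Clumping + conditional analysis
# --------------------------------------------------------------------------

def test_uncorrelated_distant_variants_all_become_indices(rng):
    geno = rng.binomial(2, 0.3, size=(500, 3)).astype(float)
    idx = ld_clump(np.array([1e-6, 1e-6, 1e-6]), geno,
                   positions=np.array([0, 10_000_000, 20_000_000]))
    assert sorted(idx) == [0, 1, 2]


def test_duplicated_column_keeps_one_index(rng):
    col = rng.binomial(2, 0.3, 500).astype(float)
    geno = np.column_stack([col, col])
    idx = ld_clump(np.array([1e-6, 1e-5]), geno,
                   positions=np.array([100, 200]))
    assert idx == [0]


def test_nonsignificant_variants_are_not_indices(rng):
    geno = rng.binomial(2, 0.3, size=(200, 2)).astype(float)
    idx = ld_clump(np.array([0.5, 1e-6]), geno, positions=np.array([0, 1000]))
    assert idx == [1]


def test_clump_matches_reference_greedy_trace(rng):
    """Block-structured fixture: result equals an independently coded greedy
    reference."""
    n, blocks, per_block = 400, 10, 5
    cols, positions = [], []
    for b in range(blocks):
        base = rng.binomial(2, 0.25, n).astype(float)
        for v in range(per_block):
            flip = rng.random(n) < 0.1
            col = base.copy()
            col[flip] = rng.binomial(2, 0.25, flip.sum())
            cols.append(col)
            positions.append(b * 1_000_000 + v * 1000)
    geno = np.column_stack(cols)
    pvals = rng.uniform(1e-8, 1e-3, blocks * per_block)
    positions = np.array(positions)

    got = ld_clump(pvals, geno, positions, p1=1e-4, r2=0.5, window_kb=250)

    # reference implementation: same contract, written independently
    alive = set(range(len(pvals)))
    expect = []
    for i in sorted(range(len(pvals)), key=lambda i: (pvals[i], i)):
        if i not in alive or pvals[i] >= 1e-4:
            continue
        expect.append(i)
        alive.discard(i)
        for j in list(alive):
            if abs(positions[j] - positions[i]) <= 250_000:
                r = np.corrcoef(geno[:, i], geno[:, j])[0, 1]
                if r * r >= 0.5:
                    alive.discard(j)
    assert got == expect


def test_conditional_without_indices_equals_unconditional(rng):
    burden = rng.poisson(1.0, 300).astype(float)
    trait = 0.3 * burden + rng.normal(size=300)
    a = fit_burden_test(burden, trait)
    b = conditional_burden_test(burden, trait, None, None)
    assert (a.beta, a.se, a.p) == (b.beta, b.se, b.p)


def test_perfect_confounding_nullifies_burden(rng):
    """A burden that merely tags the index variant loses its signal once the
    index dosage is conditioned on."""
    n = 800
    dosage = rng.binomial(2, 0.3, n).astype(float)
    # burden tracks the index variant almost exactly
    burden = dosage + 0.01 * rng.normal(size=n)
    trait = 0.5 * dosage + rng.normal(size=n)
    uncond = fit_burden_test(burden, trait)
    cond = conditional_burden_test(burden, trait, None, dosage[:, None])
    assert uncond.p < 1e-10
    assert cond.p > 0.01


def test_ld_attenuates_conditional_association(rng):
    n = 2000
    common, rare_like = simulate_correlated_pair(rng, n, 0.3, 0.05, r=0.7)
    trait = 0.4 * common + rng.normal(size=n)
    uncond = fit_burden_test(rare_like, trait)
    cond = conditional_burden_test(rare_like, trait, None, common[:, None])
    assert cond.p > uncond.p


def test_collinear_index_columns_are_dropped(rng):
    burden = rng.poisson(1.0, 300).astype(float)
    trait = 0.3 * burden + rng.normal(size=300)
    idx = rng.binomial(2, 0.2, 300).astype(float)
    doubled = np.column_stack([idx, idx])  # second column collinear
    res = conditional_burden_test(burden, trait, None, doubled)
    ref = conditional_burden_test(burden, trait, None, idx[:, None])
    assert res.beta == pytest.approx(ref.beta, rel=1e-10)
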