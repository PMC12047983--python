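"""End-to-end orchestration: simulate -> masks -> scan -> strategies ->
cluster -> optimize -> report.

Every stage writes tab-separated outputs whose first line carries the
configuration hash, plus a run manifest with SHA-256 digests of each output,
so a run is traceable to its configuration and reruns are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .burden import run_mask_scan
from .composite import attach_composite_scores, build_composite_masks
from .config import FREQ_CLASS_BIN, PipelineConfig
from .greedy import CoverageInstance, optimal_strategy_search
from .io import (read_annotation_table, read_genotype_matrix,
                 read_mask_catalog, read_phenotype_table, write_group_files)
from .masks import MaskCatalog, dedupe_catalog
from .reduction import cluster_and_subcluster, select_representatives
from .simulate import SimulationConfig, simulate_cohort
from .strategies import mask_association_pvalues

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "simulate_to_directory", "PipelineConfig"]


def _write_tsv(frame: pd.DataFrame, path: Path, config_hash: str,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# maskopt config_hash={config_hash}\n")
        frame.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_to_directory(sim_config: SimulationConfig, out_dir: str | Path,
                          config: PipelineConfig | None = None) -> Path:
    """Generate a cohort and write the pipeline's input files."""
    config = config or PipelineConfig(seed=sim_config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(sim_config)
    h = config.config_hash()

    _write_tsv(cohort.variants, out / "annotation.tsv", h)
    _write_tsv(cohort.rank_scores, out / "rank_scores.tsv", h)
    geno = pd.DataFrame(cohort.genotypes.dosages,
                        index=pd.Index(cohort.genotypes.sample_ids,
                                       name="sample_id"),
                        columns=cohort.genotypes.variant_ids)
    _write_tsv(geno, out / "genotypes.tsv", h, index=True)
    phen = cohort.phenotypes.copy()
    phen.index.name = "sample_id"
    _write_tsv(phen, out / "phenotypes.tsv", h, index=True)
    cov = pd.DataFrame(cohort.covariates,
                       columns=["sex", "array"] + [f"PC{i+1}" for i in range(5)],
                       index=pd.Index(cohort.genotypes.sample_ids,
                                      name="sample_id"))
    _write_tsv(cov, out / "covariates.tsv", h, index=True)
    cat = pd.DataFrame({"mask_id": [m.mask_id for m in cohort.catalog],
                        "expression": [m.expression for m in cohort.catalog],
                        "source": [m.source for m in cohort.catalog]})
    _write_tsv(cat, out / "mask_catalog.tsv", h)
    truth = {
        "causal_genes": cohort.truth.causal_genes,
        "trait_betas": cohort.truth.trait_betas,
        "damaging": [int(x) for x in cohort.truth.damaging],
        "seed": sim_config.seed,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    (out / "sim_config.json").write_text(
        json.dumps(asdict(sim_config), indent=1, sort_keys=True))
    return out


def run_pipeline(config: PipelineConfig, in_dir: str | Path,
                 out_dir: str | Path) -> dict:
    """Run every stage on the files in ``in_dir``; returns the report dict.

    Missing inputs fail fast with the offending path.
    """
    in_dir, out = Path(in_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    for name in ("annotation.tsv", "rank_scores.tsv", "genotypes.tsv",
                 "phenotypes.tsv", "covariates.tsv", "mask_catalog.tsv"):
        if not (in_dir / name).exists():
            raise FileNotFoundError(f"missing pipeline input: {in_dir / name}")

    variants = read_annotation_table(in_dir / "annotation.tsv")
    rank_scores = pd.read_csv(in_dir / "rank_scores.tsv", sep="\t", comment="#")
    genotypes = read_genotype_matrix(in_dir / "genotypes.tsv")
    phenotypes = read_phenotype_table(in_dir / "phenotypes.tsv")
    covariates = pd.read_csv(in_dir / "covariates.tsv", sep="\t", comment="#",
                             index_col="sample_id").to_numpy(dtype=float)
    catalog = read_mask_catalog(in_dir / "mask_catalog.tsv")

    # ---- masks: harmonize, dedupe, composite scores, composite masks
    n_raw = len(catalog)
    catalog = dedupe_catalog(catalog)
    logger.info("masks: %d raw -> %d unique", n_raw, len(catalog))
    variants = attach_composite_scores(variants, rank_scores, seed=config.seed,
                                       threshold=config.composite_threshold)
    composites = build_composite_masks()
    catalog = MaskCatalog(list(catalog) + composites)
    _write_tsv(pd.DataFrame({
        "mask_id": [m.mask_id for m in catalog],
        "expression": [m.expression for m in catalog],
        "annotation_class": [m.category[0] for m in catalog],
        "maxmaf_class": [m.category[1] for m in catalog],
        "source": [m.source for m in catalog]}),
        out / "masks.tsv", h)

    # ---- scan + calibration
    results, calibration = run_mask_scan(catalog, genotypes, variants,
                                         phenotypes, covariates, config)
    _write_tsv(results, out / "results.tsv", h)
    _write_tsv(calibration.lambdas, out / "calibration.tsv", h)
    logger.info("scan: %d results; %d empty masks, %d inflated masks",
                len(results), len(calibration.empty_masks),
                len(calibration.inflated_masks))

    scanned = [m for m in catalog.mask_ids
               if m not in calibration.excluded_masks]

    # ---- per-mask significant counts (the strategy building block)
    count_rows = []
    for freq_class in FREQ_CLASS_BIN:
        pvals = mask_association_pvalues(results, freq_class)
        sig = pvals[pvals["p"] < config.alpha0]
        counts = sig.groupby("mask_id").size()
        for mid in scanned:
            count_rows.append((mid, freq_class, int(counts.get(mid, 0))))
    mask_counts = pd.DataFrame(count_rows,
                               columns=["mask_id", "freq_class", "count"])
    _write_tsv(mask_counts, out / "mask_counts.tsv", h)

    # ---- clustering on variant membership, then variant MAF
    membership = catalog.membership(variants).loc[scanned]
    maf_features = membership.to_numpy(dtype=float) \
        * variants["maf"].to_numpy(dtype=float)[None, :]
    clustering = cluster_and_subcluster(scanned, membership.to_numpy(),
                                        maf_features, config)
    _write_tsv(pd.DataFrame({
        "mask_id": scanned,
        "cluster": clustering.labels.to_numpy(),
        "subcluster": clustering.subcluster_labels.to_numpy(),
        "silhouette": clustering.silhouette_contributions.to_numpy()}),
        out / "clusters.tsv", h)

    strategies_report = {}
    optimizer_rows: list[tuple] = []
    for freq_class in FREQ_CLASS_BIN:
        counts = (mask_counts[mask_counts["freq_class"] == freq_class]
                  .set_index("mask_id")["count"])
        rep_cluster = select_representatives(
            clustering.labels, counts, f"cluster_reps_{freq_class}")
        rep_sub = select_representatives(
            clustering.subcluster_labels, counts, f"subcluster_reps_{freq_class}")

        instance = CoverageInstance.from_results(results, freq_class,
                                                 config.alpha0)
        trace = optimal_strategy_search(instance, config.m_max)
        trace_rows = []
        cumulative = 0
        for order, (mask_id, gain) in enumerate(
                zip(trace.strategy.mask_ids, trace.marginal_gains), 1):
            cumulative += gain
            trace_rows.append((freq_class, order, mask_id, gain, cumulative))
        optimizer_rows.extend(trace_rows)
        strategies_report[freq_class] = {
            "cluster_representatives": list(rep_cluster.mask_ids),
            "subcluster_representatives": list(rep_sub.mask_ids),
            "optimal_m": trace.strategy.m,
            "optimal_masks": list(trace.strategy.mask_ids),
            "optimal_count": trace.count,
            "greedy_marginal_gains": trace.marginal_gains,
        }
    (out / "strategies.json").write_text(
        json.dumps(strategies_report, indent=1, sort_keys=True))
    _write_tsv(pd.DataFrame(optimizer_rows,
                            columns=["freq_class", "pick_order", "mask_id",
                                     "marginal_gain", "cumulative_count"]),
               out / "optimizer_trace.tsv", h)

    # ---- group-file export
    group_paths = write_group_files(variants, catalog, out, prefix="groups")

    report = {
        "config_hash": h,
        "config": config.to_dict(),
        "n_masks_raw": n_raw,
        "n_masks_unique": len(catalog),
        "n_masks_scanned": len(scanned),
        "empty_masks": calibration.empty_masks,
        "inflated_masks": calibration.inflated_masks,
        "n_results": int(len(results)),
        "clustering": {
            "k": clustering.k,
            "n_components": clustering.n_components,
            "explained_variance": clustering.explained_variance,
            "silhouette": None if np.isnan(clustering.silhouette)
            else clustering.silhouette,
            "n_subclusters": clustering.n_subclusters,
        },
        "strategies": strategies_report,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1,
                                                sort_keys=True))
    manifest = {p.name: _digest(p) for p in sorted(out.iterdir())
                if p.name != "manifest.json"}
    manifest["config_hash"] = h
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    _ = group_paths
    return report
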