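"""File interfaces: annotation/genotype/phenotype TSVs, mask and strategy
catalogs, results tables, and REGENIE-dialect group files.

All tabular interchange is tab-separated with a header, except the three
group files (variant set list, variant annotation, mask definition), which
follow the headerless tab-separated dialect burden-testing engines consume.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .burden import GenotypeMatrix
from .masks import MaskCatalog, parse_mask
from .strategies import Strategy

__all__ = [
    "read_mask_catalog", "write_mask_catalog",
    "read_annotation_table", "write_annotation_table",
    "read_genotype_matrix", "write_genotype_matrix",
    "read_phenotype_table", "write_phenotype_table",
    "read_strategies", "write_strategies",
    "write_group_files", "read_group_files",
]


def read_mask_catalog(path: str | Path) -> MaskCatalog:
    """Mask catalog TSV: columns mask_id, expression, source."""
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    masks = [parse_mask(row.expression, mask_id=row.mask_id,
                        source=row.source)
             for row in table.itertuples()]
    return MaskCatalog(masks)


def write_mask_catalog(catalog: MaskCatalog, path: str | Path) -> None:
    pd.DataFrame(
        {"mask_id": [m.mask_id for m in catalog],
         "expression": [m.expression for m in catalog],
         "source": [m.source for m in catalog]},
    ).to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"variant_id": str, "chrom": str, "gene": str})


def write_annotation_table(variants: pd.DataFrame, path: str | Path) -> None:
    variants.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_genotype_matrix(genotypes: GenotypeMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(genotypes.dosages, index=genotypes.sample_ids,
                         columns=genotypes.variant_ids)
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t", float_format="%g")


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    return GenotypeMatrix(frame.to_numpy(dtype=float),
                          [str(s) for s in frame.index],
                          [str(v) for v in frame.columns])


def write_phenotype_table(phenotypes: pd.DataFrame, path: str | Path) -> None:
    out = phenotypes.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")


def read_strategies(path: str | Path) -> list[Strategy]:
    """Strategy catalog TSV: strategy_id, source, comma-joined mask_ids."""
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    return [Strategy(row.strategy_id, tuple(row.mask_ids.split(",")))
            for row in table.itertuples()]


def write_strategies(strategies: list[Strategy], path: str | Path,
                     sources: dict[str, str] | None = None) -> None:
    sources = sources or {}
    pd.DataFrame(
        {"strategy_id": [s.strategy_id for s in strategies],
         "source": [sources.get(s.strategy_id, "") for s in strategies],
         "mask_ids": [",".join(s.mask_ids) for s in strategies]},
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Group files (REGENIE dialect: tab-separated, headerless)
# --------------------------------------------------------------------------


def write_group_files(variants: pd.DataFrame, catalog: MaskCatalog,
                      out_dir: str | Path, prefix: str = "groups") -> dict[str, Path]:
    """Set-list, annotation, and mask-definition files.

    * set list: gene, chrom, first position, comma-joined variant ids;
    * annotation: variant id, gene, label (one label per variant: the ids of
      the masks including it are used as a composite label);
    * mask definition: mask id, comma-joined labels it accepts.

    A variant's label is the sorted comma-free join (``+``) of the masks that
    include it, so membership is reconstructable exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    member = catalog.membership(variants).astype(bool)

    labels = {}
    for vid in variants["variant_id"]:
        masks_in = [mid for mid in catalog.mask_ids if member.loc[mid, vid]]
        labels[vid] = "+".join(masks_in) if masks_in else "none"

    setlist = out_dir / f"{prefix}.setlist.tsv"
    with open(setlist, "w") as fh:
        for gene, grp in variants.groupby("gene", sort=True):
            grp = grp.sort_values("pos")
            fh.write("\t".join([gene, str(grp["chrom"].iloc[0]),
                                str(int(grp["pos"].iloc[0])),
                                ",".join(grp["variant_id"])]) + "\n")

    annot = out_dir / f"{prefix}.annotations.tsv"
    with open(annot, "w") as fh:
        for row in variants.itertuples():
            fh.write(f"{row.variant_id}\t{row.gene}\t{labels[row.variant_id]}\n")

    maskdef = out_dir / f"{prefix}.masks.tsv"
    all_labels = sorted(set(labels.values()))
    with open(maskdef, "w") as fh:
        for mid in catalog.mask_ids:
            accepted = [lab for lab in all_labels
                        if mid in lab.split("+")]
            fh.write(f"{mid}\t{','.join(accepted) if accepted else 'none'}\n")

    return {"setlist": setlist, "annotations": annot, "maskdef": maskdef}


def read_group_files(setlist: str | Path, annotations: str | Path,
                     maskdef: str | Path) -> pd.DataFrame:
    """Reconstruct the masks x variants membership matrix from group files."""
    annot = pd.read_csv(annotations, sep="\t", header=None,
                        names=["variant_id", "gene", "label"], dtype=str)
    masks = pd.read_csv(maskdef, sep="\t", header=None,
                        names=["mask_id", "labels"], dtype=str)
    variant_ids = list(annot["variant_id"])
    data = {}
    for row in masks.itertuples():
        accepted = set(row.labels.split(",")) if row.labels != "none" else set()
        data[row.mask_id] = annot["label"].isin(accepted).astype(int).to_numpy()
    return pd.DataFrame(data, index=variant_ids).T
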