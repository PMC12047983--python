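import numpy as np
import pandas as pd
import pytest

from maskopt.simulate import SimulationConfig, simulate_cohort


def make_variant(variant_id="v1", consequence="missense", maf=5e-4,
                 gene="GENE0001", lof_confidence="none", impact="MODERATE",
                 is_indel=False, mac=3, **scores):
    """One annotation-table row with arbitrary predictor columns."""
    row = {
        "variant_id": variant_id, "chrom": "1", "pos": 1000, "ref": "A",
        "alt": "AT" if is_indel else "G", "gene": gene,
        "consequence": consequence, "is_indel": is_indel,
        "lof_confidence": lof_confidence, "impact": impact,
        "maf": maf, "mac": mac,
    }
    row.update(scores)
    return row


def variant_frame(rows):
    frame = pd.DataFrame(rows)
    # ensure score columns exist even if only some rows set them
    for col in ("REVEL_score", "CADD_phred", "combo_og", "combo_pc",
                "combo_ic"):
        if col not in frame.columns:
            frame[col] = np.nan
    for col in ("SIFT_pred", "Polyphen2_HDIV_pred", "Polyphen2_HVAR_pred",
                "ClinVar_pred"):
        if col not in frame.columns:
            frame[col] = None
    return frame


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(
        n_samples=600, n_genes=30, n_traits=3, mean_variants_per_gene=20,
        n_algorithms=8, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
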