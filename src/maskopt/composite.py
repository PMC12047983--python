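"""Composite damaging scores from ensembles of pathogenicity predictors.

Pathogenicity predictors agree strongly with one another, so instead of picking
one algorithm a mask can use an ensemble vote.  Three composite scores are
built from the variants x algorithms matrix of rank scores (each algorithm's
raw scores rank-transformed to (0, 1], higher = more damaging):

``og``
    the fraction of algorithms whose rank score exceeds a cut (default 0.67,
    chosen so roughly a third of missense variants are called damaging, the
    average fraction categorical predictors call damaging);
``pc`` / ``ic``
    the same vote taken over principal / independent components of the rank
    scores, weighted by explained-variance ratio (PCA) or mixing-vector norm
    (ICA).  Component scores are rank-transformed and oriented so that higher
    means rarer: a component whose rank score correlates significantly
    positively with MAF (Pearson, P < 0.01) is inverted, because damaging
    variation is held at low frequency by selection.

Missing rank scores are imputed first with scikit-learn's iterative
round-robin conditional-regression imputer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA, FastICA
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .masks import MaskDefinition, parse_mask

__all__ = [
    "CompositeModel",
    "rank_transform",
    "impute_rank_scores",
    "derive_components",
    "composite_score",
    "original_ensemble_score",
    "attach_composite_scores",
    "build_composite_masks",
    "DEFAULT_THRESHOLD",
    "COMPOSITE_CUTS",
    "COMPOSITE_MAF_TOKENS",
]

DEFAULT_THRESHOLD = 0.67
COMPOSITE_CUTS = (0.25, 0.50, 0.75, 0.90)
COMPOSITE_MAF_TOKENS = (None, "maf1", "maf0_1")


def rank_transform(values: np.ndarray) -> np.ndarray:
    """Rank scores in (0, 1]: average ranks for ties, scaled by N."""
    values = np.asarray(values, dtype=float)
    return stats.rankdata(values, method="average") / values.size


def impute_rank_scores(matrix: pd.DataFrame, max_iter: int = 10,
                       tol: float = 1e-3, seed: int = 0) -> pd.DataFrame:
    """Fill missing rank scores by iterative conditional regression.

    Columns are initialized at their means and each column with missing values
    is regressed on the others until convergence.  Observed entries are
    returned unchanged; imputed entries are clipped to (0, 1].

    Raises ``ValueError`` naming the algorithm if a column is all-missing.
    """
    all_missing = matrix.columns[matrix.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(
            f"rank-score column(s) entirely missing: {list(all_missing)}")
    if not matrix.isna().any().any():
        return matrix.copy()
    imputer = IterativeImputer(max_iter=max_iter, tol=tol, random_state=seed,
                               sample_posterior=False, keep_empty_features=False)
    filled = imputer.fit_transform(matrix.to_numpy(dtype=float))
    out = pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)
    eps = 1.0 / max(len(matrix), 2)
    out = out.clip(lower=eps, upper=1.0)
    observed = ~matrix.isna()
    out[observed] = matrix[observed]
    return out


@dataclass
class CompositeModel:
    """Fitted component model for the ``pc``/``ic`` composite scores.

    ``components`` holds the loading matrix (components x algorithms);
    ``weights`` are non-negative and sum to one; ``orientation`` is +-1 per
    component, chosen from the component rank score's MAF correlation.
    """

    method: str  # "pc" | "ic"
    components: np.ndarray
    weights: np.ndarray
    orientation: np.ndarray
    mean_: np.ndarray
    threshold: float = DEFAULT_THRESHOLD

    def transform(self, matrix: pd.DataFrame) -> np.ndarray:
        """Per-variant oriented component rank scores (variants x components)."""
        x = matrix.to_numpy(dtype=float) - self.mean_
        raw = x @ self.components.T
        n = raw.shape[0]
        ranks = np.column_stack([rank_transform(raw[:, j])
                                 for j in range(raw.shape[1])])
        flipped = 1.0 - ranks + 1.0 / n
        return np.where(self.orientation > 0, ranks, flipped)


def _orient(ranks: np.ndarray, maf: np.ndarray, alpha: float = 0.01) -> int:
    """-1 (invert) iff the rank score correlates significantly positively
    with MAF; otherwise keep."""
    if np.std(ranks) == 0 or np.std(maf) == 0:
        return 1
    r, p = stats.pearsonr(ranks, maf)
    return -1 if (r > 0 and p < alpha) else 1


def derive_components(matrix: pd.DataFrame, maf: np.ndarray,
                      method: str = "pc", seed: int = 0,
                      threshold: float = DEFAULT_THRESHOLD) -> CompositeModel:
    """Fit the PCA (``pc``) or ICA (``ic``) component model on a complete
    rank-score matrix and orient every component against MAF."""
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("rank-score matrix must be complete (impute first)")
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need more variants than algorithms")
    if np.allclose(np.var(x, axis=0), 0):
        raise ValueError("zero-variance rank-score matrix")
    maf = np.asarray(maf, dtype=float)

    n_comp = x.shape[1]
    if method == "pc":
        fit = PCA(n_components=n_comp, random_state=seed).fit(x)
        components = fit.components_
        raw_weights = fit.explained_variance_ratio_.copy()
        mean_ = fit.mean_
    elif method == "ic":
        fit = FastICA(n_components=n_comp, random_state=seed,
                      whiten="unit-variance", max_iter=1000, tol=1e-3).fit(x)
        # unmixing rows project data onto sources; mixing-column norms play
        # the role explained variance plays for PCA
        components = fit.components_
        raw_weights = np.linalg.norm(fit.mixing_, axis=0)
        mean_ = fit.mean_
    else:
        raise ValueError(f"unknown method {method!r} (expected 'pc' or 'ic')")

    weights = raw_weights / raw_weights.sum()
    model = CompositeModel(method=method, components=components,
                           weights=weights, orientation=np.ones(n_comp),
                           mean_=mean_, threshold=threshold)
    raw = (x - mean_) @ components.T
    orientation = np.array(
        [_orient(rank_transform(raw[:, j]), maf) for j in range(n_comp)])
    model.orientation = orientation
    return model


def composite_score(model: CompositeModel, matrix: pd.DataFrame) -> np.ndarray:
    """Weighted vote of per-component damaging calls, in [0, 1]."""
    if matrix.shape[1] != model.components.shape[1]:
        raise ValueError(
            f"matrix has {matrix.shape[1]} algorithms, model expects "
            f"{model.components.shape[1]}")
    oriented = model.transform(matrix)
    calls = oriented > model.threshold
    return calls @ model.weights


def original_ensemble_score(matrix: pd.DataFrame,
                            threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """``og`` score: fraction of algorithms calling the variant damaging."""
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("rank-score matrix must be complete (impute first)")
    return (x > threshold).mean(axis=1)


def attach_composite_scores(variants: pd.DataFrame, matrix: pd.DataFrame,
                            seed: int = 0,
                            threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Compute ``combo_og``/``combo_pc``/``combo_ic`` columns on the
    annotation table (rows aligned with the rank-score matrix)."""
    complete = impute_rank_scores(matrix, seed=seed)
    maf = variants["maf"].to_numpy(dtype=float)
    out = variants.copy()
    out["combo_og"] = original_ensemble_score(complete, threshold)
    for method in ("pc", "ic"):
        model = derive_components(complete, maf, method=method, seed=seed,
                                  threshold=threshold)
        out[f"combo_{method}"] = composite_score(model, complete)
    return out


def build_composite_masks(methods=("og", "pc", "ic"),
                          cuts=COMPOSITE_CUTS,
                          maf_tokens=COMPOSITE_MAF_TOKENS,
                          source: str = "composite") -> list[MaskDefinition]:
    """Masks combining high-confidence pLoF with composite-damaging missense
    at each vote cut and MAF token: 3 methods x 4 cuts x 3 tokens = 36."""
    masks = []
    for method in methods:
        for cut in cuts:
            atom = f"combo_{method}{int(round(cut * 100))}"
            core = f"(LoF_HC | (missense & {atom}))"
            # id suffix encodes the MAF ceiling as a fraction: maf1 -> 0_01
            suffixes = {None: "all", "maf1": "0_01", "maf0_1": "0_001"}
            for token in maf_tokens:
                expr = core if token is None else f"{core} & {token}"
                suffix = suffixes.get(token, token)
                mask_id = f"new_damaging_{method}{int(round(cut * 100))}.{suffix}"
                masks.append(parse_mask(expr, mask_id=mask_id, source=source))
    return masks
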