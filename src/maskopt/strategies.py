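"""Masking strategies: Bonferroni-aware counting of significant associations.

A *masking strategy* is an ordered set of m masks tested jointly; the
significance threshold for every member is alpha0 / m, so adding a mask both
widens the search and tightens the bar.  An association — a (gene, trait)
pair, optionally restricted to a frequency class — is counted once per
strategy no matter how many member masks detect it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FREQ_CLASS_BIN

__all__ = [
    "Strategy",
    "StrategySummary",
    "mask_association_pvalues",
    "significant_set",
    "count_strategy_significant",
    "summarize_catalog_strategies",
    "jaccard_similarity",
]

ALPHA0 = 2.5e-6


@dataclass(frozen=True)
class Strategy:
    strategy_id: str
    mask_ids: tuple[str, ...]
    alpha0: float = ALPHA0

    def __post_init__(self) -> None:
        if len(self.mask_ids) < 1:
            raise ValueError("strategy needs at least one mask")
        if len(set(self.mask_ids)) != len(self.mask_ids):
            raise ValueError("mask_ids repeated within a strategy")

    @property
    def m(self) -> int:
        return len(self.mask_ids)

    @property
    def threshold(self) -> float:
        return self.alpha0 / self.m


def mask_association_pvalues(results: pd.DataFrame,
                             freq_class: str = "total") -> pd.DataFrame:
    """Per-(mask, gene, trait) best p-value at the class-matching MAF bin.

    Returns a frame with columns mask_id, gene, trait, p.
    """
    maf_bin = FREQ_CLASS_BIN[freq_class]
    sub = results[results["maf_bin"] == maf_bin]
    return (sub.groupby(["mask_id", "gene", "trait"], as_index=False)["p"]
            .min())


def significant_set(pvals: pd.DataFrame, mask_id: str,
                    threshold: float) -> set[tuple[str, str]]:
    sub = pvals[(pvals["mask_id"] == mask_id) & (pvals["p"] < threshold)]
    return set(zip(sub["gene"], sub["trait"]))


def count_strategy_significant(strategy: Strategy, results: pd.DataFrame,
                               freq_class: str = "total",
                               ) -> tuple[set[tuple[str, str]], int]:
    """Union over member masks of associations with p < alpha0/m at the
    class-matching bin; the count is the union's size."""
    pvals = mask_association_pvalues(results, freq_class)
    known = set(pvals["mask_id"])
    missing = [m for m in strategy.mask_ids if m not in known]
    if missing:
        raise KeyError(f"strategy {strategy.strategy_id!r} references masks "
                       f"absent from results: {missing}")
    covered: set[tuple[str, str]] = set()
    for mask_id in strategy.mask_ids:
        covered |= significant_set(pvals, mask_id, strategy.threshold)
    return covered, len(covered)


@dataclass
class StrategySummary:
    counts: pd.DataFrame          # strategy_id, m, count
    average: float
    best: Strategy
    best_count: int


def summarize_catalog_strategies(strategies: list[Strategy],
                                 results: pd.DataFrame,
                                 freq_class: str = "total") -> StrategySummary:
    """Counts for every previously employed strategy, their mean ("average"
    strategy yield), and the argmax ("best" strategy; ties broken by
    lexicographic strategy id)."""
    if not strategies:
        raise ValueError("no strategies to summarize")
    rows = []
    for strat in sorted(strategies, key=lambda s: s.strategy_id):
        _, count = count_strategy_significant(strat, results, freq_class)
        rows.append((strat.strategy_id, strat.m, count))
    counts = pd.DataFrame(rows, columns=["strategy_id", "m", "count"])
    average = float(counts["count"].mean())
    best_row = counts.sort_values(["count", "strategy_id"],
                                  ascending=[False, True]).iloc[0]
    best = next(s for s in strategies
                if s.strategy_id == best_row["strategy_id"])
    return StrategySummary(counts=counts, average=average, best=best,
                           best_count=int(best_row["count"]))


def jaccard_similarity(a: Strategy, b: Strategy) -> float:
    """|A n B| / |A u B| over mask-id sets; two empty sets give 0."""
    sa, sb = set(a.mask_ids), set(b.mask_ids)
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)
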