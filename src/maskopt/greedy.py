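"""Greedy covering optimizer for masking strategies.

Exhaustively comparing all 2^M subsets of M candidate masks is infeasible, so
strategies are searched greedily within each size m (all members of an m-mask
strategy share the Bonferroni threshold alpha0/m):

1. for each mask, collect the associations with p < alpha0/m;
2. pick the mask covering the most;
3. remove the covered associations from every remaining mask;
4. repeat until m masks are picked.

The best strategy over all m is the overall pick.  Greedy maximum coverage
carries the classic (1 - 1/e) guarantee relative to the optimal same-size
subset at a fixed threshold.  Because the threshold tightens with m, adding
masks can *lose* associations — borderline hits fail the stricter bar — which
is why the optimal m is finite and differs between common and rare signal.

Robustness is assessed by leave-one-trait-out validation: optimize on all
traits but one, then score the held-out trait's coverage against its own
trait-specific optimum.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strategies import ALPHA0, Strategy, mask_association_pvalues

__all__ = [
    "CoverageInstance",
    "GreedyTrace",
    "greedy_cover_fixed_m",
    "optimal_strategy_search",
    "leave_one_trait_out",
    "truncate_strategy",
]

AssociationKey = tuple


@dataclass
class CoverageInstance:
    """Per-mask p-value lists, sorted so the significant set at any threshold
    is a prefix.  Built once; queried for every candidate m."""

    mask_pvalues: dict[str, tuple[np.ndarray, list[AssociationKey]]]
    alpha0: float = ALPHA0

    @classmethod
    def from_results(cls, results: pd.DataFrame, freq_class: str = "total",
                     alpha0: float = ALPHA0,
                     mask_ids: list[str] | None = None) -> "CoverageInstance":
        pvals = mask_association_pvalues(results, freq_class)
        if mask_ids is None:
            # masks with any tested gene at the widest bin are candidates
            mask_ids = sorted(results["mask_id"].unique())
        return cls.from_pvalue_table(pvals, alpha0, mask_ids)

    @classmethod
    def from_pvalue_table(cls, pvals: pd.DataFrame, alpha0: float = ALPHA0,
                          mask_ids: list[str] | None = None,
                          ) -> "CoverageInstance":
        """``pvals``: columns mask_id, gene, trait, p (one row per mask x
        association).  ``mask_ids`` forces candidates with no tested
        associations to appear with empty sets."""
        table: dict[str, tuple[np.ndarray, list[AssociationKey]]] = {}
        for mask_id, grp in pvals.groupby("mask_id", sort=True):
            grp = grp.sort_values(["p", "gene", "trait"])
            keys = list(zip(grp["gene"], grp["trait"]))
            table[mask_id] = (grp["p"].to_numpy(dtype=float), keys)
        for mask_id in mask_ids or []:
            table.setdefault(mask_id, (np.array([]), []))
        return cls(mask_pvalues=table, alpha0=alpha0)

    @property
    def mask_ids(self) -> list[str]:
        return sorted(self.mask_pvalues)

    @property
    def n_masks(self) -> int:
        return len(self.mask_pvalues)

    def significant_set(self, mask_id: str, threshold: float) -> set:
        ps, keys = self.mask_pvalues[mask_id]
        cut = bisect.bisect_left(ps, threshold)
        return set(keys[:cut])

    def restrict_traits(self, traits: set, keep: bool = True) -> "CoverageInstance":
        """Instance limited to (or excluding) the given traits."""
        table = {}
        for mask_id, (ps, keys) in self.mask_pvalues.items():
            sel = [(p, k) for p, k in zip(ps, keys)
                   if (k[1] in traits) == keep]
            table[mask_id] = (np.array([p for p, _ in sel]),
                              [k for _, k in sel])
        return CoverageInstance(table, self.alpha0)


@dataclass
class GreedyTrace:
    strategy: Strategy
    covered: set
    marginal_gains: list[int]

    @property
    def count(self) -> int:
        return len(self.covered)


def greedy_cover_fixed_m(instance: CoverageInstance, m: int,
                         strategy_id: str | None = None) -> GreedyTrace:
    """Greedy maximum coverage at the fixed threshold alpha0/m.

    Each step picks the mask adding the most uncovered associations (ties by
    lexicographic mask id).  When no remaining mask adds coverage, the
    remaining slots are filled with unused masks in id order at zero gain so
    the strategy has exactly m members and the alpha0/m threshold is honest.
    """
    if not 1 <= m <= instance.n_masks:
        raise ValueError(f"m={m} out of range [1, {instance.n_masks}]")
    threshold = instance.alpha0 / m
    sets = {mid: instance.significant_set(mid, threshold)
            for mid in instance.mask_ids}
    covered: set = set()
    picks: list[str] = []
    gains: list[int] = []
    remaining = list(instance.mask_ids)
    for _ in range(m):
        best_id, best_gain = None, -1
        for mid in remaining:  # id order -> lexicographic tie-break
            gain = len(sets[mid] - covered)
            if gain > best_gain:
                best_id, best_gain = mid, gain
        picks.append(best_id)
        gains.append(best_gain)
        covered |= sets[best_id]
        remaining.remove(best_id)
    sid = strategy_id or f"greedy_m{m}"
    return GreedyTrace(Strategy(sid, tuple(picks), alpha0=instance.alpha0),
                       covered, gains)


def optimal_strategy_search(instance: CoverageInstance,
                            m_max: int | None = None) -> GreedyTrace:
    """Best greedy strategy over all sizes m in [1, m_max]; ties favour the
    smaller m (fewer tests), then the lexicographically smaller strategy."""
    if instance.n_masks == 0:
        raise ValueError("empty coverage instance")
    m_max = instance.n_masks if m_max is None else min(m_max, instance.n_masks)
    best: GreedyTrace | None = None
    for m in range(1, m_max + 1):
        trace = greedy_cover_fixed_m(instance, m)
        if best is None or trace.count > best.count or (
                trace.count == best.count
                and (trace.strategy.m, trace.strategy.mask_ids)
                < (best.strategy.m, best.strategy.mask_ids)):
            best = trace
    return best


def truncate_strategy(trace: GreedyTrace, size: int,
                      instance: CoverageInstance) -> GreedyTrace:
    """First ``size`` greedy picks, re-thresholded at alpha0/size and
    recounted."""
    if size > trace.strategy.m:
        raise ValueError("cannot truncate to a larger size")
    picks = trace.strategy.mask_ids[:size]
    threshold = instance.alpha0 / size
    covered: set = set()
    gains = []
    for mid in picks:
        s = instance.significant_set(mid, threshold)
        gains.append(len(s - covered))
        covered |= s
    return GreedyTrace(Strategy(f"{trace.strategy.strategy_id}_trunc{size}",
                                picks, alpha0=instance.alpha0),
                       covered, gains)


def _strategy_coverage(instance: CoverageInstance, strategy: Strategy) -> set:
    covered: set = set()
    for mid in strategy.mask_ids:
        if mid in instance.mask_pvalues:
            covered |= instance.significant_set(mid, strategy.threshold)
    return covered


def leave_one_trait_out(instance: CoverageInstance,
                        m_max: int | None = None) -> pd.DataFrame:
    """Cross-validation of the optimizer across traits.

    For each trait: optimize on the other traits, evaluate the resulting
    strategy's coverage of the held-out trait, and divide by the trait's own
    trait-specific optimum.  Traits with a zero optimum report NaN.
    Returns a frame with columns trait, heldout_count, trait_optimum,
    fraction.
    """
    traits = sorted({k[1] for ps, keys in instance.mask_pvalues.values()
                     for k in keys})
    if len(traits) < 2:
        raise ValueError("leave-one-trait-out needs at least two traits")
    rows = []
    for trait in traits:
        train = instance.restrict_traits({trait}, keep=False)
        test = instance.restrict_traits({trait}, keep=True)
        cross = optimal_strategy_search(train, m_max)
        heldout = len(_strategy_coverage(test, cross.strategy))
        own = optimal_strategy_search(test, m_max).count
        frac = heldout / own if own > 0 else float("nan")
        rows.append((trait, heldout, own, frac))
    return pd.DataFrame(rows, columns=["trait", "heldout_count",
                                       "trait_optimum", "fraction"])
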