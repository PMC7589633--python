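"""Rank-shift concordance between a perturbation signature and cancer DE lists.

Genes are ranked by descending log2 fold change in the perturbation
(rank 1 = most upregulated).  For each cancer, its up- and downregulated
DE genes are tested with one-sided Wilcoxon rank-sum (Mann-Whitney)
tests for concentration at the top or the bottom of the ranking, giving
four one-sided p-values per cancer: up-top, up-bottom, down-top,
down-bottom.  Significant up-top and/or down-bottom (p <= alpha, default
0.1) classify the cancer as *consistent* with the perturbation;
significant up-bottom and/or down-top as *reverse*.  Both labels can
co-occur (a conflicting trend).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PATTERNS = ("up-top", "up-bottom", "down-top", "down-bottom")


class RankTestError(ValueError):
    """Degenerate rank-shift test input."""


@dataclass
class RankedSignature:
    """Genes ordered by descending log2FC; rank 1 = most upregulated."""

    genes: list[str]
    ranks: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise RankTestError("duplicate gene ids in signature")
        if not self.ranks:
            self.ranks = {g: i + 1 for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)


def rank_signature(de_table: pd.DataFrame) -> RankedSignature:
    """Order a DE table (indexed by gene, with ``log2FC``) into a signature.

    Ties in log2FC are broken by gene id (lexicographic) so the ranking
    is deterministic.
    """
    if de_table.index.duplicated().any():
        raise RankTestError("duplicate gene ids in DE table")
    order = pd.DataFrame(
        {"log2FC": de_table["log2FC"].to_numpy(float), "gene": de_table.index.astype(str)}
    ).sort_values(["log2FC", "gene"], ascending=[False, True])
    return RankedSignature(genes=order["gene"].tolist())


def rank_shift_test(
    signature: RankedSignature,
    de_set: set[str],
    side: str = "top",
    exact_max: int = 25,
) -> float:
    """One-sided Wilcoxon rank-sum p for a DE set sitting at one end of the ranking.

    ``side='top'`` tests whether the DE genes have systematically smaller
    ranks than the remaining genes; ``side='bottom'`` tests larger.  The
    exact null distribution is used when the smaller group has at most
    ``exact_max`` members (signature ranks are tie-free); otherwise the
    normal approximation with continuity correction.  DE genes absent
    from the signature universe are dropped with a logged count.
    """
    if side not in ("top", "bottom"):
        raise RankTestError(f"side must be 'top' or 'bottom', got {side!r}")
    in_universe = de_set & set(signature.genes)
    dropped = len(de_set) - len(in_universe)
    if dropped:
        logger.info("rank_shift_test: dropped %d DE genes absent from the signature", dropped)
    if not in_universe:
        raise RankTestError("DE set does not intersect the signature universe")
    if len(in_universe) == len(signature):
        raise RankTestError("DE set covers the entire universe; no reference group")
    de_ranks = np.array(sorted(signature.ranks[g] for g in in_universe), dtype=float)
    rest = np.array(
        sorted(set(range(1, len(signature) + 1)) - set(int(r) for r in de_ranks)), dtype=float
    )
    alternative = "less" if side == "top" else "greater"
    method = "exact" if min(len(de_ranks), len(rest)) <= exact_max else "asymptotic"
    res = stats.mannwhitneyu(de_ranks, rest, alternative=alternative, method=method)
    return float(res.pvalue)


def rank_shift_exact_bruteforce(n_universe: int, de_ranks: set[int], side: str = "top") -> float:
    """Oracle: exhaustive enumeration over all equally-likely rank subsets.

    Counts subsets of the same size whose rank sum is as small (top) or
    as large (bottom) as the observed one.  Only for tiny universes.
    """
    k = len(de_ranks)
    observed = sum(de_ranks)
    total = 0
    extreme = 0
    for subset in combinations(range(1, n_universe + 1), k):
        total += 1
        s = sum(subset)
        if (side == "top" and s <= observed) or (side == "bottom" and s >= observed):
            extreme += 1
    return extreme / total


@dataclass
class PatternResult:
    """Four one-sided rank-shift p-values and their classification."""

    cancer: str
    p_values: dict[str, float]
    significant_patterns: set[str]
    consistent: bool
    reverse: bool


def classify_patterns(p_values: dict[str, float], alpha: float = 0.1, cancer: str = "") -> PatternResult:
    """Label a cancer from its four one-sided pattern p-values.

    consistent <= significant up-top or down-bottom; reverse <=
    significant up-bottom or down-top.  Both may hold simultaneously.
    """
    if not 0.0 < alpha < 1.0:
        raise RankTestError("alpha must be in (0,1)")
    unknown = set(p_values) - set(PATTERNS)
    if unknown:
        raise RankTestError(f"unknown patterns: {sorted(unknown)}")
    sig = {p for p in PATTERNS if p in p_values and p_values[p] <= alpha}
    return PatternResult(
        cancer=cancer,
        p_values=dict(p_values),
        significant_patterns=sig,
        consistent=bool(sig & {"up-top", "down-bottom"}),
        reverse=bool(sig & {"up-bottom", "down-top"}),
    )


def evaluate_cancer(
    signature: RankedSignature,
    cancer_de: dict[str, set[str]],
    alpha: float = 0.1,
    cancer: str = "",
) -> PatternResult:
    """Run all four pattern tests for one cancer's up/down DE sets.

    Sides with an empty (or universe-disjoint) DE set report p = 1.
    """
    p: dict[str, float] = {}
    for direction in ("up", "down"):
        genes = cancer_de.get(direction, set())
        usable = genes & set(signature.genes)
        for side in ("top", "bottom"):
            key = f"{direction}-{side}"
            if not usable or len(usable) == len(signature):
                p[key] = 1.0
            else:
                p[key] = rank_shift_test(signature, genes, side=side)
    return classify_patterns(p, alpha=alpha, cancer=cancer)


def same_direction_overlap(
    pert_de: dict[str, set[str]], cancer_de: dict[str, set[str]]
) -> set[str]:
    """Genes DE in both signatures with matching direction."""
    for name, sets in (("perturbation", pert_de), ("cancer", cancer_de)):
        if sets.get("up", set()) & sets.get("down", set()):
            raise RankTestError(f"{name} up and down sets overlap")
    return (pert_de.get("up", set()) & cancer_de.get("up", set())) | (
        pert_de.get("down", set()) & cancer_de.get("down", set())
    )


def read_cancer_de(path) -> dict[str, set[str]]:
    """Read a cancer DE list TSV (gene, log2FC, FDR, direction) into up/down sets."""
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "direction"}
    if not required <= set(table.columns):
        raise RankTestError(f"cancer DE table needs columns {sorted(required)}")
    bad = set(table["direction"]) - {"up", "down"}
    if bad:
        raise RankTestError(f"unknown directions: {sorted(bad)}")
    return {
        "up": set(table.loc[table["direction"] == "up", "gene"].astype(str)),
        "down": set(table.loc[table["direction"] == "down", "gene"].astype(str)),
    }


def pattern_table(results: list[PatternResult]) -> pd.DataFrame:
    """Tabulate per-cancer p-values, significant patterns and labels."""
    rows = []
    for r in results:
        labels = []
        if r.consistent:
            labels.append("consistent")
        if r.reverse:
            labels.append("reverse")
        rows.append(
            {
                "cancer": r.cancer,
                **{f"p_{p.replace('-', '_')}": r.p_values.get(p, np.nan) for p in PATTERNS},
                "significant_patterns": ";".join(sorted(r.significant_patterns)),
                "labels": ";".join(labels),
            }
        )
    return pd.DataFrame(rows)
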