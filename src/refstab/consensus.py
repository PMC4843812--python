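"""Geometric-mean aggregation of per-algorithm stability rankings.

Each stability program (geNorm, NormFinder, BestKeeper, or an external
ranking such as an RNA-seq CV ordering) contributes an ordinal ranking of
the same candidate genes; the comprehensive ranking orders genes by the
geometric mean of their per-program ranks.  Ranks use the competition
convention ("1, 1, 3" for a two-way tie at the top) — in particular
geNorm's unrankable final pair enters with both genes at rank 1.

Ties in the geometric mean are broken by the worst single-program rank
(the gene with the less damaging worst case wins), then by the canonical
input gene order.  This tie policy is exercised against transcribed
published rankings in the test suite and reproduces them exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

__all__ = ["StabilityRanking", "ConsensusResult", "ranks_from_scores", "consensus_rank"]


@dataclass
class StabilityRanking:
    """One algorithm's ordinal ranking (ties allowed) with optional scores.

    ``ranks`` maps every gene to a rank >= 1; with competition ranking the
    ranks need not be consecutive (a two-way tie at 1 is followed by 3).
    """

    algorithm: str
    ranks: Dict[str, int]
    statistic: Optional[Dict[str, float]] = None

    def __post_init__(self):
        for g, r in self.ranks.items():
            if not (isinstance(r, (int, float)) and math.isfinite(r) and r >= 1):
                raise ValueError(f"invalid rank {r!r} for gene {g!r}")

    @property
    def genes(self) -> List[str]:
        return list(self.ranks)

    def order(self) -> List[str]:
        """Genes best-first (ties in rank keep insertion order)."""
        return sorted(self.ranks, key=lambda g: (self.ranks[g],
                                                 list(self.ranks).index(g)))


def ranks_from_scores(
    scores: Dict[str, float], ascending: bool = True, algorithm: str = "scores"
) -> StabilityRanking:
    """Competition-rank genes by a stability statistic.

    ``ascending=True`` means a lower score is better (geNorm M, NormFinder
    SV, BestKeeper sd).  Tied scores share the best position; the next
    distinct score resumes at 1 + number of better-or-equal genes
    ("1, 1, 3").  All scores must be finite.
    """
    for g, v in scores.items():
        if not math.isfinite(v):
            raise ValueError(f"non-finite score for gene {g!r}: {v!r}")
    genes = list(scores)
    key = (lambda g: scores[g]) if ascending else (lambda g: -scores[g])
    ordered = sorted(genes, key=key)
    ranks: Dict[str, int] = {}
    for pos, g in enumerate(ordered, start=1):
        if pos > 1 and key(g) == key(ordered[pos - 2]):
            ranks[g] = ranks[ordered[pos - 2]]
        else:
            ranks[g] = pos
    return StabilityRanking(algorithm=algorithm, ranks={g: ranks[g] for g in genes},
                            statistic=dict(scores))


@dataclass
class ConsensusResult:
    """Comprehensive ranking: geometric-mean rank per gene and the order.

    ``order`` lists genes best-first; ``ranks`` gives the 1-based position
    of each gene in that order.
    """

    geomean: Dict[str, float]
    order: List[str]
    inputs: List[StabilityRanking] = field(default_factory=list)

    @property
    def ranks(self) -> Dict[str, int]:
        return {g: i + 1 for i, g in enumerate(self.order)}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.order:
            row = {"gene": g, "geomean_rank": self.geomean[g], "consensus_rank": self.ranks[g]}
            for ranking in self.inputs:
                row[f"rank_{ranking.algorithm}"] = ranking.ranks[g]
            rows.append(row)
        return pd.DataFrame(rows).set_index("gene")


def consensus_rank(
    rankings: Sequence[StabilityRanking],
    gene_order: Optional[Sequence[str]] = None,
) -> ConsensusResult:
    """Aggregate >= 2 rankings over the identical gene set.

    The geometric mean of each gene's per-algorithm ranks orders the
    consensus (ascending).  Exact ties — compared on the integer product
    of ranks, so no floating-point fuzz — are broken by the worst single
    ranking, then by ``gene_order`` (defaults to the first ranking's gene
    listing).
    """
    if len(rankings) < 2:
        raise ValueError("consensus needs >= 2 rankings")
    gene_set = set(rankings[0].ranks)
    for r in rankings[1:]:
        if set(r.ranks) != gene_set:
            raise ValueError(
                f"gene-set mismatch between {rankings[0].algorithm!r} and {r.algorithm!r}"
            )
    if gene_order is None:
        gene_order = rankings[0].genes
    else:
        gene_order = list(gene_order)
        if set(gene_order) != gene_set:
            raise ValueError("gene_order must cover exactly the ranked genes")
    position = {g: i for i, g in enumerate(gene_order)}

    n = len(rankings)
    product = {g: 1 for g in gene_order}
    worst = {g: 0 for g in gene_order}
    for r in rankings:
        for g in gene_order:
            product[g] *= r.ranks[g]
            worst[g] = max(worst[g], r.ranks[g])
    order = sorted(gene_order, key=lambda g: (product[g], worst[g], position[g]))
    geomean = {g: product[g] ** (1.0 / n) for g in gene_order}
    return ConsensusResult(geomean=geomean, order=order, inputs=list(rankings))
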