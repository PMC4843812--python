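"""geNorm expression-stability analysis.

A gene's stability measure M is the arithmetic mean of the pairwise
variations V between that gene and every other candidate, where V for a
gene pair is the sample standard deviation (n-1 denominator) of the
log2-ratio of their relative quantities across samples.  Genes that covary
(constant ratio) get V = 0; lower M means more stable.  The ranking is
produced by stepwise elimination: repeatedly drop the gene with the highest
M and recompute on the survivors until two genes remain.  The final pair
cannot be ranked against each other (their mutual V is all that is left)
and is reported tied at rank 1.

The optimal number of reference genes comes from the pairwise variation
V(n/n+1): the sample SD of log2(NF_n / NF_{n+1}) across samples, where NF_n
is the per-sample geometric mean of the top-n genes' quantities.  The
smallest n with V(n/n+1) below the 0.15 cutoff is recommended; when no V
falls below the cutoff no recommendation is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .relquant import RelQuantTable

__all__ = [
    "GeNormResult",
    "pairwise_v",
    "stability_m",
    "genorm_rank",
    "normalization_factor",
    "pairwise_variation_series",
]

#: Default V(n/n+1) cutoff: an additional reference gene below this adds
#: no significant contribution to the normalization factor.
V_CUTOFF = 0.15

#: Default M threshold above which a gene is flagged as unstable.
M_THRESHOLD = 1.5


def pairwise_v(q_j: Sequence[float], q_k: Sequence[float]) -> float:
    """Pairwise variation between two genes: SD of their log2 ratios.

    Symmetric in its arguments; zero iff the two quantity vectors are
    proportional.  Values must be positive and of equal length >= 2.
    """
    a = np.asarray(q_j, dtype=float)
    b = np.asarray(q_k, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("quantity vectors must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("pairwise variation needs >= 2 samples")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("quantities must be positive")
    return float(np.std(np.log2(a / b), ddof=1))


def _log2q(table: RelQuantTable, gene_set: Optional[Sequence[str]]) -> Tuple[List[str], np.ndarray]:
    genes = list(table.genes) if gene_set is None else list(gene_set)
    lookup = {g: i for i, g in enumerate(table.genes)}
    idx = [lookup[g] for g in genes]
    return genes, np.log2(table.q[idx, :])


def _m_values(y: np.ndarray) -> np.ndarray:
    """Mean pairwise log-ratio SD for each row of a log2-quantity matrix."""
    k = y.shape[0]
    m = np.zeros(k)
    for i in range(k):
        vs = [np.std(y[i] - y[j], ddof=1) for j in range(k) if j != i]
        m[i] = float(np.mean(vs))
    return m


def stability_m(table: RelQuantTable, gene_set: Optional[Sequence[str]] = None) -> pd.Series:
    """geNorm stability value M for each gene of ``gene_set``.

    M_j is the arithmetic mean of ``pairwise_v(j, k)`` over all other genes
    k in the set.  Lower M = more stable.  Needs at least two genes.
    """
    genes, y = _log2q(table, gene_set)
    if len(genes) < 2:
        raise ValueError("M is undefined for fewer than 2 genes")
    return pd.Series(_m_values(y), index=pd.Index(genes, name="gene"), name="M")


@dataclass
class GeNormResult:
    """Outcome of the stepwise geNorm ranking.

    ``ranking`` lists genes best-first (the unrankable final pair first, in
    input order); ``ranks`` assigns both final-pair genes ordinal rank 1 and
    the next gene rank 3 (competition ranking), the convention needed for
    geometric-mean rank aggregation.  ``m_trajectory`` holds the surviving
    set's M values at each elimination round.
    """

    elimination_order: List[str]
    final_pair: Tuple[str, str]
    m_trajectory: List[pd.Series]
    ranking: List[str]
    flagged_unstable: List[str] = field(default_factory=list)
    v_series: Optional[pd.Series] = None
    recommended_n: Optional[int] = None

    @property
    def ranks(self) -> Dict[str, int]:
        out = {self.final_pair[0]: 1, self.final_pair[1]: 1}
        for pos, gene in enumerate(self.ranking[2:], start=3):
            out[gene] = pos
        return out

    def to_ranking(self):
        from .consensus import StabilityRanking

        m_final = {}
        for series in self.m_trajectory:
            for g, v in series.items():
                m_final[g] = float(v)  # last round each gene survived
        return StabilityRanking(algorithm="genorm", ranks=self.ranks, statistic=m_final)


def genorm_rank(
    table: RelQuantTable,
    *,
    m_threshold: float = M_THRESHOLD,
    v_cutoff: float = V_CUTOFF,
) -> GeNormResult:
    """Rank genes by stepwise elimination of the least stable gene.

    At each round the gene with the highest M is removed and M is
    recomputed on the survivors, until two genes remain.  Ties at the
    maximal M are broken by removing the later-listed gene, so the
    procedure is deterministic in the input gene order.  Genes whose M in
    the full candidate set exceeds ``m_threshold`` (default 1.5) are
    flagged as unstable.  The V(n/n+1) series and recommended reference
    count are computed from the resulting ranking.
    """
    genes, y = _log2q(table, None)
    if len(genes) < 3:
        raise ValueError("stepwise ranking requires >= 3 genes")
    if y.shape[1] < 2:
        raise ValueError("stepwise ranking requires >= 2 samples")

    surviving = list(range(len(genes)))
    elimination: List[str] = []
    trajectory: List[pd.Series] = []
    first_m = None
    while len(surviving) > 2:
        m = _m_values(y[surviving, :])
        trajectory.append(
            pd.Series(m, index=pd.Index([genes[i] for i in surviving], name="gene"), name="M")
        )
        if first_m is None:
            first_m = trajectory[0]
        # remove the later-listed gene among those tied at the max M
        worst_local = int(np.flatnonzero(m == m.max())[-1])
        elimination.append(genes[surviving[worst_local]])
        del surviving[worst_local]
    # M of the final pair: their mutual pairwise variation
    pair_m = np.std(y[surviving[0]] - y[surviving[1]], ddof=1)
    trajectory.append(
        pd.Series(
            [pair_m, pair_m],
            index=pd.Index([genes[i] for i in surviving], name="gene"),
            name="M",
        )
    )
    if first_m is None:  # pragma: no cover - k >= 3 guarantees a round
        first_m = trajectory[0]

    final_pair = (genes[surviving[0]], genes[surviving[1]])
    ranking = list(final_pair) + elimination[::-1]
    flagged = [g for g, v in first_m.items() if v > m_threshold]

    result = GeNormResult(
        elimination_order=elimination,
        final_pair=final_pair,
        m_trajectory=trajectory,
        ranking=ranking,
        flagged_unstable=flagged,
    )
    v_series, recommended = pairwise_variation_series(table, ranking, cutoff=v_cutoff)
    result.v_series = v_series
    result.recommended_n = recommended
    return result


def normalization_factor(
    table: RelQuantTable, ranked_genes: Sequence[str], n: int
) -> pd.Series:
    """Per-sample normalization factor NF_n.

    The geometric mean of the top-``n`` ranked genes' relative quantities
    in each sample.  ``n`` must satisfy ``2 <= n <= k``.
    """
    ranked = list(ranked_genes)
    if not (2 <= n <= len(ranked)):
        raise ValueError(f"n must lie in [2, {len(ranked)}]; got {n}")
    sub = table.select_genes(ranked[:n])
    nf = np.exp(np.mean(np.log(sub.q), axis=0))
    return pd.Series(nf, index=pd.Index(table.sample_ids, name="sample"), name=f"NF{n}")


def pairwise_variation_series(
    table: RelQuantTable,
    ranked_genes: Sequence[str],
    cutoff: float = V_CUTOFF,
) -> Tuple[pd.Series, Optional[int]]:
    """V(n/n+1) for n = 2..k-1 and the recommended reference count.

    V(n/n+1) is the sample SD across samples of log2(NF_n / NF_{n+1});
    the recommendation is the smallest n whose V falls below ``cutoff``,
    or None when every V is at or above it (more references, or a more
    homogeneous candidate panel, would be needed).
    """
    ranked = list(ranked_genes)
    k = len(ranked)
    if k < 3:
        raise ValueError("V series requires >= 3 ranked genes")
    values = {}
    nf = normalization_factor(table, ranked, 2).to_numpy()
    for n in range(2, k):
        nf_next = normalization_factor(table, ranked, n + 1).to_numpy()
        values[n] = float(np.std(np.log2(nf / nf_next), ddof=1))
        nf = nf_next
    series = pd.Series(values, name="V")
    series.index.name = "n"
    below = [n for n, v in values.items() if v < cutoff]
    return series, (min(below) if below else None)
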