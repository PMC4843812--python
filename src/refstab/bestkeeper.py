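"""BestKeeper-style descriptive stability statistics on raw Ct values.

Unlike geNorm and NormFinder, BestKeeper works on the raw Ct scale.  Each
gene gets descriptive statistics across the subset's samples; its "SD" is
the mean absolute deviation about the arithmetic mean Ct (the BestKeeper
convention — NOT the n-1 sample SD; a flag switches conventions for
sensitivity analysis), and CV is that deviation as a percentage of the
mean Ct.  Genes with SD above 1 cycle are flagged as unacceptable
references but remain in the ranking (subsets may have no gene under the
threshold).  The BestKeeper index is the per-sample geometric mean Ct over
the included genes, and each gene is Pearson-correlated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import CtTable

__all__ = [
    "BestKeeperResult",
    "bestkeeper_stats",
    "bestkeeper_index",
    "bestkeeper_rank",
    "bestkeeper_analysis",
]

#: Genes whose Ct dispersion exceeds this many cycles are flagged.
SD_THRESHOLD = 1.0


def _dispersion(ct: np.ndarray, convention: str) -> np.ndarray:
    """Row-wise Ct dispersion under the chosen convention."""
    if convention == "mad":
        mean = ct.mean(axis=1, keepdims=True)
        return np.abs(ct - mean).mean(axis=1)
    if convention == "sample_sd":
        return ct.std(axis=1, ddof=1)
    raise ValueError(f"unknown SD convention {convention!r}")


@dataclass
class BestKeeperResult:
    """Descriptive statistics, exclusion flags, index and correlations.

    ``stats`` has one row per gene: n, geometric/arithmetic mean Ct,
    min, max, sd (cycles), cv (%), excluded flag, and (once the index is
    computed) Pearson r and two-sided p against the index.
    """

    stats: pd.DataFrame
    sd_threshold: float = SD_THRESHOLD
    convention: str = "mad"
    index: Optional[pd.Series] = None
    gene_order: List[str] = field(default_factory=list)

    @property
    def excluded(self) -> List[str]:
        return list(self.stats.index[self.stats["excluded"]])

    def to_ranking(self):
        from .consensus import StabilityRanking

        order = bestkeeper_rank(self)
        ranks = {g: i + 1 for i, g in enumerate(order)}
        return StabilityRanking(
            algorithm="bestkeeper", ranks=ranks, statistic=self.stats["sd"].to_dict()
        )


def bestkeeper_stats(
    table: CtTable,
    subset: Optional[Sequence[str]] = None,
    *,
    sd_threshold: float = SD_THRESHOLD,
    convention: str = "mad",
) -> BestKeeperResult:
    """Per-gene BestKeeper descriptive statistics on raw Ct.

    ``convention="mad"`` (default) uses the mean absolute deviation about
    the arithmetic mean; ``"sample_sd"`` uses the n-1 sample SD instead.
    ``cv = 100 * sd / mean Ct``.  Genes with sd > ``sd_threshold`` are
    flagged excluded (they stay listed and ranked).
    """
    sub = table if subset is None else table.select_samples(list(subset))
    if sub.n_samples < 2:
        raise ValueError("BestKeeper statistics require >= 2 samples")
    ct = sub.ct
    am = ct.mean(axis=1)
    sd = _dispersion(ct, convention)
    stats = pd.DataFrame(
        {
            "n": sub.n_samples,
            "geo_mean": np.exp(np.mean(np.log(ct), axis=1)),
            "arith_mean": am,
            "min": ct.min(axis=1),
            "max": ct.max(axis=1),
            "sd": sd,
            "cv": 100.0 * sd / am,
            "excluded": sd > sd_threshold,
        },
        index=pd.Index(sub.genes, name="gene"),
    )
    return BestKeeperResult(
        stats=stats,
        sd_threshold=sd_threshold,
        convention=convention,
        gene_order=list(sub.genes),
    )


def bestkeeper_index(
    table: CtTable,
    included_genes: Sequence[str],
    subset: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """BestKeeper index and per-gene correlations against it.

    The index is the per-sample geometric mean Ct over ``included_genes``
    (>= 2 required).  Returns a DataFrame with each gene's Pearson r and
    two-sided p-value against the index; the index itself is attached as
    ``result.attrs["index"]``.
    """
    included = list(included_genes)
    if len(included) < 2:
        raise ValueError("the BestKeeper index requires >= 2 included genes")
    sub = table if subset is None else table.select_samples(list(subset))
    block = sub.select_genes(included).ct
    index = np.exp(np.mean(np.log(block), axis=0))
    rows = {}
    for i, gene in enumerate(sub.genes):
        x = sub.ct[i, :]
        if np.std(x) == 0 or np.std(index) == 0:
            rows[gene] = (np.nan, np.nan)
        else:
            r, p = sps.pearsonr(x, index)
            rows[gene] = (float(r), float(p))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["r", "p"])
    out.index.name = "gene"
    out.attrs["index"] = pd.Series(index, index=pd.Index(sub.sample_ids, name="sample"), name="bk_index")
    return out


def bestkeeper_rank(result: BestKeeperResult) -> List[str]:
    """Total stability ordering: sd ascending, then cv, then input order.

    Excluded genes (sd over threshold) sort after all non-excluded genes
    but are still ranked — a subset may leave no gene under the threshold.
    """
    stats = result.stats
    order_index = {g: i for i, g in enumerate(result.gene_order or list(stats.index))}
    return sorted(
        stats.index,
        key=lambda g: (
            bool(stats.at[g, "excluded"]),
            float(stats.at[g, "sd"]),
            float(stats.at[g, "cv"]),
            order_index[g],
        ),
    )


def bestkeeper_analysis(
    table: CtTable,
    subset: Optional[Sequence[str]] = None,
    *,
    sd_threshold: float = SD_THRESHOLD,
    convention: str = "mad",
) -> BestKeeperResult:
    """Full BestKeeper pass: statistics, index over included genes (all
    genes when fewer than two pass the SD filter), and correlations."""
    result = bestkeeper_stats(
        table, subset, sd_threshold=sd_threshold, convention=convention
    )
    included = [g for g in result.stats.index if not result.stats.at[g, "excluded"]]
    if len(included) < 2:
        included = list(result.stats.index)
    corr = bestkeeper_index(table, included, subset)
    result.stats = result.stats.join(corr)
    result.index = corr.attrs["index"]
    return result
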