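"""FPKM-based candidate screening and qPCR/RNA-seq ranking comparison.

Candidate reference genes are screened from an RNA-seq expression matrix
by three per-unigene indices: the mean FPKM (MV), its sample standard
deviation (SD), and the coefficient of variation CV = SD / MV.  A good
candidate has an adequate expression level (MV above a floor), a low CV
across conditions, and — optionally — membership in an annotated set.
The unigene with the lowest CV is regarded as the most stable.

The screen's CV ordering can also be compared with a qPCR-derived
stability ranking via Pearson correlation of the two rank vectors
(equivalently, Spearman correlation of the underlying scores).
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .consensus import StabilityRanking
from .data_io import FPKMTable

__all__ = ["fpkm_stats", "screen_candidates", "cv_ranking", "ranking_correlation"]


def fpkm_stats(table: FPKMTable) -> pd.DataFrame:
    """Per-unigene MV, SD (n-1) and CV = SD / MV.

    Requires >= 2 conditions.  Rows with zero mean get CV = NaN and a True
    ``cv_undefined`` flag; they are kept, not dropped.
    """
    if len(table.conditions) < 2:
        raise ValueError("FPKM statistics require >= 2 conditions")
    mv = table.fpkm.mean(axis=1)
    sd = table.fpkm.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mv > 0, sd / np.where(mv > 0, mv, 1.0), np.nan)
    return pd.DataFrame(
        {"mv": mv, "sd": sd, "cv": cv, "cv_undefined": mv == 0},
        index=pd.Index(table.unigenes, name="unigene"),
    )


def screen_candidates(
    stats: pd.DataFrame,
    min_mv: float = 1.0,
    max_cv: float = 0.5,
    annotated: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Filter and order candidate reference unigenes.

    Keeps unigenes with ``mv >= min_mv``, defined ``cv <= max_cv`` and,
    when ``annotated`` is given, membership in that set; the survivors are
    sorted by CV ascending (most stable first).  The ``min_mv`` floor
    realizes the "appropriate expression level" requirement; its default
    of 1 FPKM is an arbitrary but conventional detectability cutoff.
    """
    if min_mv <= 0 or max_cv <= 0:
        raise ValueError("screening thresholds must be > 0")
    mask = (stats["mv"] >= min_mv) & (~stats["cv_undefined"]) & (stats["cv"] <= max_cv)
    if annotated is not None:
        allowed = {str(a) for a in annotated}
        mask &= stats.index.to_series().isin(allowed)
    out = stats.loc[mask].sort_values("cv", kind="stable").copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def cv_ranking(stats: pd.DataFrame, algorithm: str = "rnaseq_cv") -> StabilityRanking:
    """Competition ranking of unigenes by CV ascending (lowest CV = rank 1)."""
    from .consensus import ranks_from_scores

    usable = stats.loc[~stats["cv_undefined"], "cv"]
    return ranks_from_scores(usable.to_dict(), ascending=True, algorithm=algorithm)


def ranking_correlation(
    rank_a: StabilityRanking,
    rank_b: StabilityRanking,
    method: str = "pearson",
) -> float:
    """Correlation between two stability rankings over the same genes.

    ``method="pearson"`` correlates the rank vectors directly (the usual
    way two published orderings are compared); ``"kendall"`` computes
    Kendall's tau as a robustness check.  Returns NaN when either rank
    vector has zero variance (all genes tied).
    """
    genes = set(rank_a.ranks)
    if genes != set(rank_b.ranks):
        raise ValueError("rankings cover different gene sets")
    order = rank_a.genes
    a = np.array([rank_a.ranks[g] for g in order], dtype=float)
    b = np.array([rank_b.ranks[g] for g in order], dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    if method == "pearson":
        return float(sps.pearsonr(a, b)[0])
    if method == "kendall":
        return float(sps.kendalltau(a, b)[0])
    raise ValueError(f"unknown method {method!r}")
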