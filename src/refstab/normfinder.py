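"""Model-based stability values in the NormFinder style.

The model treats the log2 relative quantity of gene i in sample j as

    y_ij = alpha_i + beta_j + eps_ij,

an additive gene effect, a shared per-sample effect (loading, RT yield),
and a gene-specific fluctuation eps_ij with variance sigma_i^2.  The
shared effect is removed by centering each sample over genes; a gene's
stability is then the estimated SD of its own fluctuation term.

Because the per-sample centering mixes every gene's noise into every
residual, the naive residual variance v_i is biased:

    E[v_i] = ((k-2)/k) * sigma_i^2 + sum_i' sigma_i'^2 / (k (k-1)),

for k genes, so the package uses the bias-corrected estimator

    sigma_i^2 = max(0, (k/(k-2)) * (v_i - sum_i' v_i' / (k (k-1)))),

which is unbiased under the model (see docs/methods.md for the
derivation; unbiasedness is verified by simulation in the test suite).
The ungrouped stability value is SV_i = sqrt(sigma_i^2).

In grouped mode the same decomposition runs within each sample group
(treatment, tissue class, ...), and a gene additionally carries an
intergroup deviation d_ig (its group mean departing from its grand mean).
The true intergroup variance gamma^2 is estimated across all genes and
groups, each observed d_ig is shrunk toward zero by the ratio
gamma^2 / (gamma^2 + sigma_ig^2 / n_g), and the stability value combines
the shrunk intergroup deviation with the sampling error of the group
mean, averaged over groups.  Low SV = stable within groups *and* not
systematically shifted between groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .relquant import RelQuantTable

__all__ = ["NormFinderResult", "normfinder_sv"]


@dataclass
class NormFinderResult:
    """Per-gene stability values plus the variance components behind them.

    ``sv`` maps gene -> stability value (log2 units; lower = more stable).
    ``intragroup_var`` maps (gene, group) -> estimated sigma^2;
    ``intergroup_dev`` maps (gene, group) -> shrunk deviation (grouped mode
    only, summing to ~0 over groups for each gene).
    """

    sv: pd.Series
    mode: str
    intragroup_var: Dict[Tuple[str, str], float]
    intergroup_dev: Dict[Tuple[str, str], float]
    gamma_sq: float = 0.0

    def to_ranking(self):
        from .consensus import StabilityRanking, ranks_from_scores

        ranking = ranks_from_scores(self.sv.to_dict(), ascending=True)
        return StabilityRanking(
            algorithm="normfinder", ranks=ranking.ranks, statistic=self.sv.to_dict()
        )


def _corrected_sigma_sq(z_block: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Bias-corrected per-gene variances from a sample-centered log block.

    Returns (sigma_sq, group_means): the clamped variance estimates and the
    per-gene mean of the centered values over the block's samples.
    """
    k = z_block.shape[0]
    if z_block.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    v = np.var(z_block, axis=1, ddof=1)
    sigma_sq = (k / (k - 2.0)) * (v - v.sum() / (k * (k - 1.0)))
    return np.maximum(sigma_sq, 0.0), z_block.mean(axis=1)


def normfinder_sv(
    table: RelQuantTable,
    groups: Optional[Mapping[str, str]] = None,
) -> NormFinderResult:
    """Compute NormFinder-style stability values for all genes.

    Parameters
    ----------
    table:
        Complete matrix of relative quantities with >= 3 genes (the
        variance estimator divides by k - 2).
    groups:
        Optional mapping sample_id -> group label.  With one distinct
        label (or None) the ungrouped estimator is used; otherwise each
        group needs >= 2 samples and every sample a label.
    """
    genes = list(table.genes)
    k = len(genes)
    if k < 3:
        raise ValueError("NormFinder requires >= 3 genes")
    y = np.log2(table.q)
    z = y - y.mean(axis=0, keepdims=True)  # remove the shared sample effect

    sample_ids = table.sample_ids
    if groups is not None:
        missing = [s for s in sample_ids if s not in groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        labels = [str(groups[s]) for s in sample_ids]
        group_names = list(dict.fromkeys(labels))
    else:
        group_names = ["all"]
        labels = ["all"] * len(sample_ids)

    if len(group_names) == 1:
        # ungrouped: the intergroup terms vanish
        sigma_sq, _ = _corrected_sigma_sq(z)
        sv = pd.Series(np.sqrt(sigma_sq), index=pd.Index(genes, name="gene"), name="SV")
        return NormFinderResult(
            sv=sv,
            mode="ungrouped",
            intragroup_var={(g, group_names[0]): float(s) for g, s in zip(genes, sigma_sq)},
            intergroup_dev={},
        )

    cols = {g: [j for j, lab in enumerate(labels) if lab == g] for g in group_names}
    n_g = {g: len(cols[g]) for g in group_names}
    small = [g for g in group_names if n_g[g] < 2]
    if small:
        raise ValueError(f"groups with < 2 samples: {small}")

    G = len(group_names)
    sigma_sq = np.zeros((k, G))
    a = np.zeros((k, G))
    for gi, g in enumerate(group_names):
        sigma_sq[:, gi], a[:, gi] = _corrected_sigma_sq(z[:, cols[g]])

    d = a - a.mean(axis=1, keepdims=True)  # intergroup deviations, sum 0 per gene
    n_vec = np.array([n_g[g] for g in group_names], dtype=float)
    sampling_var = sigma_sq / n_vec[None, :]  # variance of each group mean
    gamma_sq = max(
        0.0,
        float(np.sum(d**2) / ((k - 1.0) * (G - 1.0)) - np.mean(sampling_var)),
    )
    denom = gamma_sq + sampling_var
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(denom > 0, gamma_sq / np.where(denom > 0, denom, 1.0), 0.0)
    d_shrunk = d * shrink
    sv_values = np.mean(np.abs(d_shrunk) + np.sqrt(sampling_var * shrink), axis=1)

    sv = pd.Series(sv_values, index=pd.Index(genes, name="gene"), name="SV")
    return NormFinderResult(
        sv=sv,
        mode="grouped",
        intragroup_var={
            (genes[i], g): float(sigma_sq[i, gi]) for i in range(k) for gi, g in enumerate(group_names)
        },
        intergroup_dev={
            (genes[i], g): float(d_shrunk[i, gi]) for i in range(k) for gi, g in enumerate(group_names)
        },
        gamma_sq=gamma_sq,
    )
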