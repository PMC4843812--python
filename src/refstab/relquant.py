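"""Relative quantification of Ct values via the 2^-dCt transform.

For each gene, Ct values within an analysis subset are referenced to that
gene's minimum Ct (its most abundant sample), and converted to relative
quantities ``q = base^-(Ct - min Ct)``.  With the default base of 2 this is
the classic 2^-dCt transform: every gene's quantities lie in (0, 1] with the
maximum exactly 1.  The per-gene minimum is taken *within* the subset so
that each subset's analysis is self-contained; geNorm and NormFinder
statistics are invariant to this per-gene scaling in any case.

A per-gene amplification efficiency (per-cycle factor in (1, 2]) may be
supplied instead of the uniform base; this is off by default because the
standard workflow uses base 2 even when measured efficiencies are lower.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .data_io import CtTable, SampleAnnotation
from .exceptions import SubsetError, TableFormatError

__all__ = ["RelQuantTable", "delta_ct_transform"]


@dataclass
class RelQuantTable:
    """Genes x samples matrix of relative quantities in (0, 1].

    For every gene the maximum over the table's samples equals 1 exactly
    (the sample at the gene's minimum Ct).
    """

    genes: list
    samples: list
    q: np.ndarray

    def __post_init__(self):
        self.genes = [str(g) for g in self.genes]
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.genes), len(self.samples)):
            raise TableFormatError("q matrix shape mismatch")
        if np.any(~np.isfinite(self.q)) or np.any(self.q <= 0) or np.any(self.q > 1 + 1e-12):
            raise ValueError("relative quantities must lie in (0, 1]")

    @property
    def sample_ids(self) -> list:
        return [s.sample_id if isinstance(s, SampleAnnotation) else str(s) for s in self.samples]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.q, index=self.genes, columns=self.sample_ids)

    def select_genes(self, genes: Sequence[str]) -> "RelQuantTable":
        lookup = {g: k for k, g in enumerate(self.genes)}
        idx = [lookup[g] for g in genes]
        # note: sub-selection does not re-reference to the new minimum;
        # rows keep their original (0, 1] scaling, which downstream
        # statistics are invariant to.
        return RelQuantTable(
            genes=[self.genes[k] for k in idx],
            samples=list(self.samples),
            q=self.q[idx, :].copy(),
        )


def delta_ct_transform(
    table: CtTable,
    subset: Optional[Sequence[str]] = None,
    base: Union[float, Mapping[str, float]] = 2.0,
) -> RelQuantTable:
    """Transform Ct to relative quantities ``base^-(Ct - min Ct)`` per gene.

    Parameters
    ----------
    table:
        Complete Ct table (no missing cells).
    subset:
        Optional sequence of sample ids restricting the analysis; the
        per-gene minimum Ct is taken within this subset.  Must select at
        least 2 samples.
    base:
        Uniform amplification base (default 2) or a mapping
        gene -> per-cycle efficiency; every base must lie in (1, 2].

    Returns
    -------
    RelQuantTable
        Quantities in (0, 1] with each gene's maximum exactly 1.
    """
    sub = table if subset is None else table.select_samples(list(subset))
    if sub.n_samples < 2:
        raise SubsetError("delta-Ct transform requires a subset of >= 2 samples")
    if isinstance(base, Mapping):
        bases = np.array([float(base[g]) for g in sub.genes])
    else:
        bases = np.full(sub.n_genes, float(base))
    if np.any(bases <= 1.0) or np.any(bases > 2.0):
        raise ValueError("amplification base must lie in (1, 2]")
    dct = sub.ct - sub.ct.min(axis=1, keepdims=True)
    q = bases[:, None] ** (-dct)
    # the minimum-Ct sample has dCt == 0 -> q == 1 exactly
    return RelQuantTable(genes=list(sub.genes), samples=list(sub.samples), q=q)
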