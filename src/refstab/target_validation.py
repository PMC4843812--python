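"""Target-gene normalization against chosen references and fold changes.

Once reference genes are chosen for a subset, a target gene's relative
quantity in each sample is divided by the geometric mean of the reference
quantities (a single reference is the degenerate geometric mean), and
per-condition fold changes are reported relative to the control condition
(typically the 0 h time point).  Fold changes are computed from
per-condition means of the biological replicates, so the control
condition's fold change is exactly 1.

Because the references absorb the shared per-sample loading effect, fold
changes are invariant to it — which is the entire premise of
reference-gene normalization.  Normalizing the same target against a
stable and an unstable reference set and taking the per-condition ratio
of the two fold-change series quantifies the distortion an unstable
reference introduces (apparent over-/under-estimation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .data_io import CtTable
from .relquant import delta_ct_transform

__all__ = ["FoldChangeSeries", "normalized_expression", "reference_choice_distortion"]


@dataclass
class FoldChangeSeries:
    """Normalized target expression across a condition series.

    ``normalized`` holds the per-sample normalized quantity (target over
    geometric mean of references); ``fold_change`` maps each condition to
    the ratio of its replicate-mean normalized quantity to the control's.
    The control condition maps to exactly 1.
    """

    target: str
    references: List[str]
    control: object
    normalized: pd.Series
    conditions: List[object]
    fold_change: Dict[object, float]
    n_replicates: Dict[object, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "condition": c,
                "fold_change": self.fold_change[c],
                "n_replicates": self.n_replicates[c],
            }
            for c in self.conditions
        ]
        return pd.DataFrame(rows).set_index("condition")


def _condition_of(sample) -> object:
    # the condition axis of a time course is the sampling time
    return sample.time_point if sample.time_point is not None else sample.group


def normalized_expression(
    table: CtTable,
    target: str,
    references: Sequence[str],
    subset: Optional[Sequence[str]] = None,
    control: object = 0.0,
    base: Union[float, dict] = 2.0,
) -> FoldChangeSeries:
    """Normalize a target gene and express it as per-condition fold change.

    Parameters
    ----------
    table:
        Ct table carrying condition annotations (time points or groups).
    target:
        Target gene symbol (must not appear among the references).
    references:
        One or more reference genes; normalization divides by the
        geometric mean of their relative quantities per sample.
    subset:
        Optional sample-id selection (a treatment time course).
    control:
        Condition value serving as the fold-change baseline; must select
        at least one sample.
    base:
        Amplification base passed to the delta-Ct transform.
    """
    refs = [str(r) for r in references]
    if not refs:
        raise ValueError("at least one reference gene is required")
    if str(target) in refs:
        raise ValueError("the target gene cannot be its own reference")
    rq = delta_ct_transform(table, subset=subset, base=base)
    lookup = {g: i for i, g in enumerate(rq.genes)}
    for g in [target, *refs]:
        if g not in lookup:
            raise ValueError(f"gene {g!r} not present in the table")
    q_target = rq.q[lookup[target], :]
    q_refs = rq.q[[lookup[r] for r in refs], :]
    nf = np.exp(np.mean(np.log(q_refs), axis=0))
    normalized = q_target / nf

    conditions_per_sample = [_condition_of(s) for s in rq.samples]
    conditions = list(dict.fromkeys(conditions_per_sample))
    if control not in conditions:
        raise ValueError(f"control condition {control!r} selects no sample")
    means = {}
    counts = {}
    for c in conditions:
        idx = [j for j, cc in enumerate(conditions_per_sample) if cc == c]
        means[c] = float(np.mean(normalized[idx]))
        counts[c] = len(idx)
    fold = {c: means[c] / means[control] for c in conditions}
    return FoldChangeSeries(
        target=str(target),
        references=refs,
        control=control,
        normalized=pd.Series(normalized, index=pd.Index(rq.sample_ids, name="sample")),
        conditions=conditions,
        fold_change=fold,
        n_replicates=counts,
    )


def reference_choice_distortion(
    series_stable: FoldChangeSeries, series_unstable: FoldChangeSeries
) -> pd.Series:
    """Per-condition ratio of two fold-change series for the same target.

    Values above 1 mean the second (unstable-reference) series
    *under*-reports relative to the stable one at that condition; below 1,
    it over-reports.  Identical reference sets give all-1 ratios.
    """
    if series_stable.target != series_unstable.target:
        raise ValueError("series describe different target genes")
    if list(series_stable.conditions) != list(series_unstable.conditions):
        raise ValueError("condition mismatch between the two series")
    ratios = {
        c: series_stable.fold_change[c] / series_unstable.fold_change[c]
        for c in series_stable.conditions
    }
    out = pd.Series(ratios, name="fold_change_ratio")
    out.index.name = "condition"
    return out
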