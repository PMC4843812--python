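"""Bundled fixture datasets.

Two small CSV fixtures transcribed from a published qRT-PCR
reference-gene study of *Lycoris aurea* (14 candidate reference genes plus
the validation target *CYP72A1*, assayed across seven stress/hormone time
courses, a nine-tissue panel, and the pooled sample set):

``primer_panel.csv``
    The assay panel: gene identity, amplicon length, per-cycle
    amplification efficiency and calibration R^2.  The source layout
    prints each forward/reverse primer pair as a single undelimited
    nucleotide string; it is kept verbatim in the ``primer_pair`` column
    (the split point is not recoverable), so the per-record
    forward/reverse fields stay unset.

``stability_rankings.csv``
    The per-program stability orderings (geNorm, NormFinder, BestKeeper)
    and the published geometric-mean comprehensive ranking for each of the
    nine analysis subsets (panels A-I).  geNorm's unrankable final pair is
    encoded as two rank-1 rows.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List

import pandas as pd

from ..consensus import StabilityRanking
from ..data_io import PrimerRecord

__all__ = [
    "load_primer_panel",
    "load_stability_rankings",
    "candidate_gene_order",
    "PANEL_SUBSETS",
]

#: Panel letter -> analysis subset name.
PANEL_SUBSETS = {
    "A": "all",
    "B": "NaCl",
    "C": "PEG",
    "D": "cold",
    "E": "heat",
    "F": "ABA",
    "G": "MeJA",
    "H": "SNP",
    "I": "tissue",
}

#: The three stability programs aggregated into the comprehensive ranking.
ALGORITHMS = ("genorm", "normfinder", "bestkeeper")


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_primer_panel(as_frame: bool = False):
    """The bundled assay panel: 14 candidate references + 1 target gene.

    Returns a list of :class:`~refstab.data_io.PrimerRecord` (file order),
    or the raw DataFrame when ``as_frame`` is true (which also carries the
    undelimited ``primer_pair`` sequences).
    """
    df = _read("primer_panel.csv")
    if as_frame:
        return df
    return [
        PrimerRecord(
            gene_symbol=row.gene_symbol,
            gene_id=row.gene_id,
            arabidopsis_locus=row.arabidopsis_locus,
            amplicon_length=int(row.amplicon_bp),
            efficiency=float(row.efficiency),
            r_squared=float(row.r_squared),
            is_candidate_reference=bool(row.is_candidate_reference),
        )
        for row in df.itertuples()
    ]


def candidate_gene_order() -> List[str]:
    """The 14 candidate gene symbols in canonical (assay-panel) order.

    This order is the documented last-resort tie-break of the consensus
    ranking."""
    df = _read("primer_panel.csv")
    return list(df.loc[df.is_candidate_reference, "gene_symbol"])


def load_stability_rankings() -> Dict[str, dict]:
    """The transcribed per-program orderings and comprehensive rankings.

    Returns a mapping panel letter -> ``{"subset": name, "rankings":
    {algorithm: StabilityRanking}, "comprehensive": [genes best-first]}``.
    The geNorm rankings carry the final pair tied at rank 1.
    """
    df = _read("stability_rankings.csv")
    out: Dict[str, dict] = {}
    for panel, block in df.groupby("panel", sort=True):
        entry = {"subset": block["subset"].iloc[0], "rankings": {}, "comprehensive": None}
        for algorithm, rows in block.groupby("algorithm", sort=False):
            rows = rows.sort_index()  # file order = printed order
            if algorithm == "comprehensive":
                entry["comprehensive"] = list(rows["gene"])
            else:
                ranks = {g: int(r) for g, r in zip(rows["gene"], rows["rank"])}
                entry["rankings"][algorithm] = StabilityRanking(
                    algorithm=algorithm, ranks=ranks
                )
        out[panel] = entry
    return out
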