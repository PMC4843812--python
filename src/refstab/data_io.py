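"""Domain types and table I/O for qRT-PCR reference-gene studies.

The central container is :class:`CtTable`, a genes x samples matrix of
quantification-cycle (Ct) values with per-sample annotations (subset,
treatment group, time point, replicate indices).  Tables are exchanged as
plain CSV/TSV in either a *wide* layout (genes as rows, samples as columns)
or a *long* layout (one record per gene/sample pair, carrying annotation
columns).  Companion types hold primer metadata (:class:`PrimerRecord`),
the study design (:class:`StudyDesign`) and RNA-seq expression matrices
(:class:`FPKMTable`).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    AmpliconLengthWarning,
    CompletenessError,
    NearFloorCtWarning,
    ReplicateDispersionWarning,
    SubsetError,
    TableFormatError,
)

__all__ = [
    "SampleAnnotation",
    "CtTable",
    "PrimerRecord",
    "SubsetDef",
    "StudyDesign",
    "FPKMTable",
    "read_ct_table",
    "write_ct_table",
    "collapse_technical_replicates",
    "summarize_ct",
    "read_primer_table",
    "read_fpkm_table",
    "write_fpkm_table",
]

#: Ct values above this are flagged as near the detection floor of a
#: standard 40-cycle protocol (kept as data; flagging is non-fatal).
NEAR_FLOOR_CT = 40.0

#: Hard validity window for Ct values, in cycles.
CT_MAX = 45.0

#: Recommended amplicon size window for SYBR-green assays, in bp.
AMPLICON_RANGE = (100, 250)

_ANNOTATION_COLUMNS = ("subset", "group", "time_point", "bio_replicate", "tech_replicate")


@dataclass(frozen=True)
class SampleAnnotation:
    """Metadata for one qPCR sample (one cDNA well after technical collapsing).

    Parameters
    ----------
    sample_id:
        Unique identifier within a table (after technical-replicate collapsing).
    subset:
        Name of the analysis subset the sample belongs to (e.g. a stress
        time course, the tissue panel, or ``"all"``).
    group:
        Optional treatment/tissue group label, used by grouped NormFinder.
    time_point:
        Optional sampling time in hours.
    bio_replicate, tech_replicate:
        1-based replicate indices.
    """

    sample_id: str
    subset: str = "all"
    group: Optional[str] = None
    time_point: Optional[float] = None
    bio_replicate: int = 1
    tech_replicate: int = 1

    def __post_init__(self):
        if self.bio_replicate < 1 or self.tech_replicate < 1:
            raise ValueError("replicate indices are 1-based and must be >= 1")


def _as_annotation(obj) -> SampleAnnotation:
    if isinstance(obj, SampleAnnotation):
        return obj
    return SampleAnnotation(sample_id=str(obj))


@dataclass
class CtTable:
    """Genes x samples matrix of quantification-cycle values.

    Invariants enforced at construction: unique gene symbols, unique sample
    ids, all Ct finite and in ``(0, 45]`` (missing cells raise
    :class:`~refstab.exceptions.CompletenessError` unless ``allow_missing``).
    Ct values above 40 cycles trigger a non-fatal near-floor warning.
    """

    genes: list
    samples: list
    ct: np.ndarray
    allow_missing: bool = False

    def __post_init__(self):
        self.genes = [str(g) for g in self.genes]
        self.samples = [_as_annotation(s) for s in self.samples]
        self.ct = np.asarray(self.ct, dtype=float)
        if self.ct.shape != (len(self.genes), len(self.samples)):
            raise TableFormatError(
                f"ct matrix shape {self.ct.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = {g for g in self.genes if self.genes.count(g) > 1}
            raise TableFormatError(f"duplicate gene symbols: {sorted(dupes)}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise TableFormatError(f"duplicate sample ids: {sorted(dupes)}")
        missing = np.argwhere(~np.isfinite(self.ct))
        if missing.size and not self.allow_missing:
            raise CompletenessError(
                (self.genes[i], ids[j]) for i, j in missing
            )
        finite = self.ct[np.isfinite(self.ct)]
        if finite.size and (np.any(finite <= 0) or np.any(finite > CT_MAX)):
            i, j = np.argwhere(
                np.isfinite(self.ct) & ((self.ct <= 0) | (self.ct > CT_MAX))
            )[0]
            raise ValueError(
                f"Ct out of range (0, {CT_MAX}] at gene {self.genes[i]!r}, "
                f"sample {ids[j]!r}: {self.ct[i, j]}"
            )
        if finite.size and np.any(finite > NEAR_FLOOR_CT):
            n = int(np.sum(finite > NEAR_FLOOR_CT))
            warnings.warn(
                f"{n} Ct value(s) above {NEAR_FLOOR_CT} cycles: near the "
                "detection floor", NearFloorCtWarning, stacklevel=2,
            )

    # -- convenience ------------------------------------------------------

    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.samples]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: genes as index, sample ids as columns."""
        return pd.DataFrame(self.ct, index=self.genes, columns=self.sample_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "CtTable":
        """Column subset preserving the requested order."""
        lookup = {s.sample_id: k for k, s in enumerate(self.samples)}
        try:
            idx = [lookup[i] for i in sample_ids]
        except KeyError as exc:
            raise SubsetError(f"unknown sample id {exc.args[0]!r}") from None
        return CtTable(
            genes=list(self.genes),
            samples=[self.samples[k] for k in idx],
            ct=self.ct[:, idx].copy(),
            allow_missing=self.allow_missing,
        )

    def select_genes(self, genes: Sequence[str]) -> "CtTable":
        lookup = {g: k for k, g in enumerate(self.genes)}
        try:
            idx = [lookup[g] for g in genes]
        except KeyError as exc:
            raise TableFormatError(f"unknown gene {exc.args[0]!r}") from None
        return CtTable(
            genes=[self.genes[k] for k in idx],
            samples=list(self.samples),
            ct=self.ct[idx, :].copy(),
            allow_missing=self.allow_missing,
        )

    def drop_incomplete_samples(self) -> "CtTable":
        """Restrict to samples with a complete Ct column (used with the
        allow-missing flag; the exclusion is reported via a warning)."""
        keep = np.all(np.isfinite(self.ct), axis=0)
        dropped = [s.sample_id for s, k in zip(self.samples, keep) if not k]
        if dropped:
            warnings.warn(
                f"excluding {len(dropped)} sample(s) with missing Ct: {dropped}",
                UserWarning, stacklevel=2,
            )
        return CtTable(
            genes=list(self.genes),
            samples=[s for s, k in zip(self.samples, keep) if k],
            ct=self.ct[:, keep].copy(),
            allow_missing=False,
        )


# ---------------------------------------------------------------------------
# CSV / TSV readers and writers
# ---------------------------------------------------------------------------

def _delimiter_for(path, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    suffix = Path(path).suffix.lower()
    return "\t" if suffix in {".tsv", ".tab", ".txt"} else ","


def _validate_numeric(df: pd.DataFrame, what: str) -> np.ndarray:
    values = np.full(df.shape, np.nan)
    for i, gene in enumerate(df.index):
        for j, col in enumerate(df.columns):
            cell = df.iat[i, j]
            if pd.isna(cell) or (isinstance(cell, str) and cell.strip() in {"", "NA", "NaN", "nan"}):
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric {what} at gene {gene!r}, sample {col!r}: {cell!r}"
                ) from None
    return values


def read_ct_table(
    path,
    layout: str = "wide",
    *,
    delimiter: Optional[str] = None,
    allow_missing: bool = False,
    annotations: Optional[Mapping[str, SampleAnnotation]] = None,
) -> CtTable:
    """Read a Ct table from CSV/TSV.

    ``layout="wide"``: genes as rows (first column holds the gene symbol),
    samples as columns, header row of sample ids.  ``layout="long"``: one
    record per (gene, sample) with columns ``gene``, ``sample_id``, ``ct``
    and optional annotation columns (``subset``, ``group``, ``time_point``,
    ``bio_replicate``, ``tech_replicate``).

    The decimal separator is ".", encoding UTF-8, delimiter inferred from
    the file extension (.tsv/.tab/.txt = tab, otherwise comma) unless given.
    """
    sep = _delimiter_for(path, delimiter)
    if layout == "wide":
        df = pd.read_csv(path, sep=sep, dtype=str)
        if df.shape[1] < 2:
            raise TableFormatError("wide Ct table needs a gene column plus >= 1 sample")
        gene_col = df.columns[0]
        genes = df[gene_col].astype(str).tolist()
        if len(set(genes)) != len(genes):
            raise TableFormatError("duplicate gene symbol in first column")
        body = df.set_index(gene_col)
        ct = _validate_numeric(body, "Ct")
        sample_ids = [str(c) for c in body.columns]
        if annotations:
            samples = [annotations.get(i, SampleAnnotation(i)) for i in sample_ids]
        else:
            samples = [SampleAnnotation(i) for i in sample_ids]
        return CtTable(genes=genes, samples=samples, ct=ct, allow_missing=allow_missing)

    if layout == "long":
        df = pd.read_csv(path, sep=sep)
        required = {"gene", "sample_id", "ct"}
        if not required.issubset(df.columns):
            raise TableFormatError(
                f"long Ct table requires columns {sorted(required)}; got {list(df.columns)}"
            )
        sample_ids: list = []
        ann: dict = {}
        for _, row in df.iterrows():
            sid = str(row["sample_id"])
            if sid not in ann:
                sample_ids.append(sid)
                kwargs = {"sample_id": sid}
                for col in _ANNOTATION_COLUMNS:
                    if col in df.columns and not pd.isna(row[col]):
                        value = row[col]
                        if col in ("bio_replicate", "tech_replicate"):
                            value = int(value)
                        elif col == "time_point":
                            value = float(value)
                        else:
                            value = str(value)
                        kwargs[col] = value
                ann[sid] = SampleAnnotation(**kwargs)
        genes = list(dict.fromkeys(str(g) for g in df["gene"]))
        wide = df.pivot_table(index="gene", columns="sample_id", values="ct", aggfunc="first")
        wide = wide.reindex(index=genes, columns=sample_ids)
        ct = _validate_numeric(wide, "Ct")
        return CtTable(
            genes=genes,
            samples=[ann[i] for i in sample_ids],
            ct=ct,
            allow_missing=allow_missing,
        )

    raise ValueError(f"unknown layout {layout!r}; expected 'wide' or 'long'")


def write_ct_table(table: CtTable, path, layout: str = "wide", *, delimiter=None) -> None:
    """Write a Ct table as CSV/TSV; inverse of :func:`read_ct_table`."""
    sep = _delimiter_for(path, delimiter)
    if layout == "wide":
        df = table.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep=sep)
        return
    if layout == "long":
        records = []
        for i, gene in enumerate(table.genes):
            for j, s in enumerate(table.samples):
                records.append(
                    {
                        "gene": gene,
                        "sample_id": s.sample_id,
                        "ct": table.ct[i, j],
                        "subset": s.subset,
                        "group": s.group,
                        "time_point": s.time_point,
                        "bio_replicate": s.bio_replicate,
                        "tech_replicate": s.tech_replicate,
                    }
                )
        pd.DataFrame.from_records(records).to_csv(path, sep=sep, index=False)
        return
    raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# Replicate collapsing and descriptive summaries
# ---------------------------------------------------------------------------

_TECH_SUFFIX = re.compile(r"[._\-]?(?:t|tech|rep)?(\d+)$")


def collapse_technical_replicates(
    table: CtTable, *, dispersion_warn: float = 0.5
) -> CtTable:
    """Average technical replicates into one column per biological sample.

    Replicate groups are defined by identical (subset, group, time_point,
    bio_replicate) annotations; the collapsed Ct is the arithmetic mean of
    the group's technical replicates.  Biological replicates stay separate
    samples — stability statistics need the biological variation.  A group
    whose Ct values span more than ``dispersion_warn`` cycles (default 0.5)
    triggers a :class:`~refstab.exceptions.ReplicateDispersionWarning`.
    """
    groups: dict = {}
    order: list = []
    for j, s in enumerate(table.samples):
        key = (s.subset, s.group, s.time_point, s.bio_replicate)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(j)

    new_samples = []
    columns = []
    for key in order:
        idx = groups[key]
        if not idx:  # pragma: no cover - defensive, dict construction forbids it
            raise ValueError("empty replicate group")
        first = table.samples[idx[0]]
        if len(idx) == 1:
            new_id = first.sample_id
        else:
            new_id = _TECH_SUFFIX.sub("", first.sample_id) or first.sample_id
        block = table.ct[:, idx]
        span = np.nanmax(block, axis=1) - np.nanmin(block, axis=1)
        bad = np.where(span > dispersion_warn)[0]
        for i in bad:
            warnings.warn(
                f"technical replicates of gene {table.genes[i]!r}, sample "
                f"{new_id!r} span {span[i]:.2f} cycles (> {dispersion_warn})",
                ReplicateDispersionWarning, stacklevel=2,
            )
        columns.append(block.mean(axis=1))
        new_samples.append(replace(first, sample_id=new_id, tech_replicate=1))
    return CtTable(
        genes=list(table.genes),
        samples=new_samples,
        ct=np.column_stack(columns),
        allow_missing=table.allow_missing,
    )


def summarize_ct(table: CtTable) -> pd.DataFrame:
    """Per-gene descriptive summary of Ct values (box-plot statistics).

    Returns one row per gene with ``mean``, ``sd`` (n-1 denominator),
    ``min``, ``q25``, ``median``, ``q75`` and ``max``.  Requires >= 2
    samples so the sample SD is defined.
    """
    if table.n_samples < 2:
        raise ValueError("summary requires >= 2 samples")
    ct = table.ct
    data = {
        "mean": ct.mean(axis=1),
        "sd": ct.std(axis=1, ddof=1),
        "min": ct.min(axis=1),
        "q25": np.percentile(ct, 25, axis=1),
        "median": np.median(ct, axis=1),
        "q75": np.percentile(ct, 75, axis=1),
        "max": ct.max(axis=1),
    }
    return pd.DataFrame(data, index=pd.Index(table.genes, name="gene"))


# ---------------------------------------------------------------------------
# Primer metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimerRecord:
    """One qPCR assay: gene identity, primer pair and calibration metrics.

    ``efficiency`` is the per-cycle amplification factor (2 = perfect
    doubling); values outside ``(1, 2]`` are rejected.  Amplicon lengths
    outside 100-250 bp are accepted with a warning (the usual SYBR-green
    design window).
    """

    gene_symbol: str
    gene_id: str = ""
    arabidopsis_locus: Optional[str] = None
    forward_primer: Optional[str] = None
    reverse_primer: Optional[str] = None
    amplicon_length: int = 0
    efficiency: float = 2.0
    r_squared: float = 1.0
    is_candidate_reference: bool = True

    def __post_init__(self):
        if self.amplicon_length <= 0:
            raise ValueError(f"{self.gene_symbol}: amplicon_length must be > 0")
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError(
                f"{self.gene_symbol}: efficiency {self.efficiency} outside (1, 2]"
            )
        if not (0.0 < self.r_squared <= 1.0):
            raise ValueError(f"{self.gene_symbol}: r_squared outside (0, 1]")
        lo, hi = AMPLICON_RANGE
        if not (lo <= self.amplicon_length <= hi):
            warnings.warn(
                f"{self.gene_symbol}: amplicon {self.amplicon_length} bp outside "
                f"the {lo}-{hi} bp design window",
                AmpliconLengthWarning, stacklevel=3,
            )


_PRIMER_ALIASES = {
    "gene_symbol": ("gene_symbol", "symbol", "gene"),
    "gene_id": ("gene_id", "id", "unigene"),
    "arabidopsis_locus": ("arabidopsis_locus", "locus", "homolog_locus"),
    "forward_primer": ("forward_primer", "forward"),
    "reverse_primer": ("reverse_primer", "reverse"),
    "amplicon_length": ("amplicon_length", "amplicon_bp", "size", "size_bp", "length"),
    "efficiency": ("efficiency", "e"),
    "r_squared": ("r_squared", "r2"),
}


def read_primer_table(
    path,
    *,
    delimiter: Optional[str] = None,
    target_genes: Iterable[str] = (),
) -> list:
    """Read primer/assay metadata into a list of :class:`PrimerRecord`.

    Candidate-reference status is taken from an ``is_candidate_reference``
    column when present, otherwise inferred: genes listed in
    ``target_genes`` are validation targets, everything else a candidate.
    Column names are matched case-insensitively against common aliases.
    """
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep)
    colmap = {}
    lowered = {c.lower().strip(): c for c in df.columns}
    for field_name, aliases in _PRIMER_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                colmap[field_name] = lowered[alias]
                break
    for required in ("gene_symbol", "amplicon_length", "efficiency", "r_squared"):
        if required not in colmap:
            raise TableFormatError(f"primer table lacks a {required!r} column")
    targets = {str(t) for t in target_genes}
    records = []
    seen = set()
    for _, row in df.iterrows():
        symbol = str(row[colmap["gene_symbol"]])
        if symbol in seen:
            raise TableFormatError(f"duplicate gene symbol {symbol!r} in primer table")
        seen.add(symbol)
        if "is_candidate_reference" in lowered:
            raw = row[lowered["is_candidate_reference"]]
            is_candidate = str(raw).strip().lower() in {"1", "true", "yes", "y"}
        else:
            is_candidate = symbol not in targets
        kwargs = {"gene_symbol": symbol, "is_candidate_reference": is_candidate}
        for field_name in ("gene_id", "arabidopsis_locus", "forward_primer", "reverse_primer"):
            if field_name in colmap and not pd.isna(row[colmap[field_name]]):
                kwargs[field_name] = str(row[colmap[field_name]])
        kwargs["amplicon_length"] = int(row[colmap["amplicon_length"]])
        kwargs["efficiency"] = float(row[colmap["efficiency"]])
        kwargs["r_squared"] = float(row[colmap["r_squared"]])
        records.append(PrimerRecord(**kwargs))
    return records


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

@dataclass
class SubsetDef:
    """One analysis slice: either the samples annotated with this subset
    name, an explicit sample-id list, or a union of other subsets."""

    name: str
    sample_ids: Optional[list] = None
    union_of: Optional[list] = None
    group_by: Optional[str] = None  # annotation field for grouped NormFinder


@dataclass
class StudyDesign:
    """Declares the analysis subsets and the algorithm parameters.

    ``v_cutoff`` is the pairwise-variation threshold below which adding a
    reference gene no longer improves normalization; ``m_threshold`` flags
    geNorm-unstable genes; ``sd_threshold`` is BestKeeper's exclusion rule
    on the Ct mean absolute deviation.
    """

    subsets: list = field(default_factory=list)
    v_cutoff: float = 0.15
    m_threshold: float = 1.5
    sd_threshold: float = 1.0

    def __post_init__(self):
        names = [s.name for s in self.subsets]
        if len(set(names)) != len(names):
            raise ValueError("subset names must be unique")

    @property
    def subset_names(self) -> list:
        return [s.name for s in self.subsets]

    def select(self, table: CtTable, subset_name: str) -> list:
        """Sample ids belonging to a subset, in table order."""
        defs = {s.name: s for s in self.subsets}
        if subset_name not in defs:
            raise SubsetError(f"unknown subset {subset_name!r}")
        d = defs[subset_name]
        if d.sample_ids is not None:
            return list(d.sample_ids)
        if d.union_of is not None:
            members: set = set()
            for other in d.union_of:
                members.update(self.select(table, other))
            return [s.sample_id for s in table.samples if s.sample_id in members]
        return [s.sample_id for s in table.samples if s.subset == subset_name]

    def groups(self, table: CtTable, subset_name: str) -> Optional[dict]:
        """Sample -> group mapping for grouped NormFinder, or None."""
        defs = {s.name: s for s in self.subsets}
        d = defs[subset_name]
        if d.group_by is None:
            return None
        ids = set(self.select(table, subset_name))
        out = {}
        for s in table.samples:
            if s.sample_id in ids:
                out[s.sample_id] = str(getattr(s, d.group_by))
        return out

    def validate_samples(self, table: CtTable) -> None:
        """Every sample must map to at least one subset."""
        covered: set = set()
        for name in self.subset_names:
            covered.update(self.select(table, name))
        orphans = [s.sample_id for s in table.samples if s.sample_id not in covered]
        if orphans:
            raise SubsetError(f"samples outside every subset: {orphans}")

    @classmethod
    def from_dict(cls, spec: Mapping) -> "StudyDesign":
        subsets = []
        for item in spec.get("subsets", []):
            if isinstance(item, str):
                subsets.append(SubsetDef(name=item))
            else:
                subsets.append(
                    SubsetDef(
                        name=item["name"],
                        sample_ids=item.get("sample_ids"),
                        union_of=item.get("union_of"),
                        group_by=item.get("group_by"),
                    )
                )
        return cls(
            subsets=subsets,
            v_cutoff=float(spec.get("v_cutoff", 0.15)),
            m_threshold=float(spec.get("m_threshold", 1.5)),
            sd_threshold=float(spec.get("sd_threshold", 1.0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# FPKM tables
# ---------------------------------------------------------------------------

@dataclass
class FPKMTable:
    """Unigene x condition matrix of FPKM values (all >= 0)."""

    unigenes: list
    conditions: list
    fpkm: np.ndarray

    def __post_init__(self):
        self.unigenes = [str(u) for u in self.unigenes]
        self.conditions = [str(c) for c in self.conditions]
        self.fpkm = np.asarray(self.fpkm, dtype=float)
        if self.fpkm.shape != (len(self.unigenes), len(self.conditions)):
            raise TableFormatError("fpkm matrix shape mismatch")
        if len(set(self.unigenes)) != len(self.unigenes):
            raise TableFormatError("duplicate unigene ids")
        if not np.all(np.isfinite(self.fpkm)):
            raise ValueError("FPKM values must be finite")
        if np.any(self.fpkm < 0):
            raise ValueError("FPKM values must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fpkm, index=self.unigenes, columns=self.conditions)


def read_fpkm_table(path, *, delimiter: Optional[str] = None) -> FPKMTable:
    """Read a wide FPKM matrix (unigenes as rows, conditions as columns)."""
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise TableFormatError("FPKM table needs an id column plus >= 1 condition")
    body = df.set_index(df.columns[0])
    values = _validate_numeric(body, "FPKM")
    if np.any(~np.isfinite(values)):
        raise ValueError("FPKM table contains missing values")
    return FPKMTable(
        unigenes=[str(i) for i in body.index],
        conditions=[str(c) for c in body.columns],
        fpkm=values,
    )


def write_fpkm_table(table: FPKMTable, path, *, delimiter: Optional[str] = None) -> None:
    sep = _delimiter_for(path, delimiter)
    df = table.to_frame()
    df.index.name = "unigene"
    df.to_csv(path, sep=sep)
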