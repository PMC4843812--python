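"""Synthetic Ct and FPKM generators with known ground truth.

The Ct generator follows the standard additive qPCR error model on the
cycle scale (equivalently, multiplicative on transcript abundance):

    Ct[i, (c, b, r)] = baseline_i + loading_(c,b) + effect_i(c) + eps + tech,

with a per-gene baseline Ct (drawn uniformly from 13-25 cycles unless
given, matching the span typical of moderately-to-highly expressed
housekeeping candidates), a shared per-sample loading effect (template
input, RT yield) common to ALL genes of a sample, an optional
gene-by-condition destabilization shift, per-gene Gaussian biological
noise, and a small independent technical-replicate jitter.

The generator's hidden parameters imply a true stability score per gene,

    sqrt(noise_sd_i^2 + population variance of its condition shifts),

so every downstream test can compare estimated rankings against truth.
Everything is reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .data_io import CtTable, FPKMTable, SampleAnnotation, StudyDesign, SubsetDef

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_ct",
    "simulate_fpkm",
    "default_scenario",
    "simulate_study",
    "TREATMENT_SUBSETS",
    "TISSUE_CONDITIONS",
]

#: Stress/hormone time-course subsets of the reference study design.
TREATMENT_SUBSETS = ("NaCl", "PEG", "cold", "heat", "ABA", "MeJA", "SNP")

#: Tissue panel of the reference study design.
TISSUE_CONDITIONS = (
    "root", "bulb", "leaf", "filament", "anther", "column", "petal", "ovary", "stem",
)

#: Sampling times (hours) of each treatment time course.
DEFAULT_TIME_POINTS = (0.0, 1.0, 6.0, 24.0)


@dataclass
class SyntheticConfig:
    """Parameters of one simulated subset (a condition series).

    ``conditions`` may be numbers (time points in hours, annotated as
    ``time_point``) or strings (e.g. tissue names, annotated as ``group``).
    ``effects`` maps a gene name to one Ct shift (cycles) per condition —
    the mechanism that makes a gene *unstable* across conditions.
    ``noise_sd`` is the per-gene biological noise SD in cycles (scalar or
    one value per gene); ``loading_sd`` the SD of the shared per-sample
    effect; ``tech_sd`` the technical-replicate jitter.
    """

    n_genes: int = 14
    conditions: Sequence = DEFAULT_TIME_POINTS
    n_bio_replicates: int = 3
    n_tech_replicates: int = 1
    baseline_ct: Optional[Sequence[float]] = None
    baseline_range: Tuple[float, float] = (13.0, 25.0)
    loading_sd: float = 0.5
    effects: Mapping[str, Sequence[float]] = field(default_factory=dict)
    noise_sd: Union[float, Sequence[float]] = 0.2
    tech_sd: float = 0.05
    subset: str = "treatment"
    gene_names: Optional[Sequence[str]] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_genes < 1 or self.n_bio_replicates < 1 or self.n_tech_replicates < 1:
            raise ValueError("counts must be >= 1")
        if self.loading_sd < 0 or self.tech_sd < 0:
            raise ValueError("SDs must be >= 0")
        noise = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        if np.any(noise < 0):
            raise ValueError("noise_sd must be >= 0")
        if noise.size not in (1, self.n_genes):
            raise ValueError("noise_sd must be scalar or one value per gene")
        for g, shifts in self.effects.items():
            if len(shifts) != len(self.conditions):
                raise ValueError(
                    f"effect for {g!r} must give one shift per condition"
                )

    def resolved_gene_names(self) -> List[str]:
        if self.gene_names is not None:
            names = [str(g) for g in self.gene_names]
            if len(names) != self.n_genes:
                raise ValueError("gene_names length must equal n_genes")
            return names
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def resolved_noise(self) -> np.ndarray:
        noise = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        return np.full(self.n_genes, noise[0]) if noise.size == 1 else noise.copy()


@dataclass
class SyntheticTruth:
    """Realized generator parameters and the implied true stability order."""

    gene_names: List[str]
    baseline_ct: np.ndarray
    noise_sd: np.ndarray
    effects: Dict[str, np.ndarray]
    loading_sd: float
    true_stability: pd.Series
    true_order: List[str]

    @property
    def designed_stable(self) -> List[str]:
        """The two genes with the lowest true stability score."""
        return self.true_order[:2]

    @property
    def designed_unstable(self) -> List[str]:
        """The two genes with the highest true stability score."""
        return self.true_order[-2:]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "baseline_ct": self.baseline_ct,
                "noise_sd": self.noise_sd,
                "true_stability": self.true_stability.to_numpy(),
                "true_rank": [self.true_order.index(g) + 1 for g in self.gene_names],
            },
            index=pd.Index(self.gene_names, name="gene"),
        )


def _true_stability(config: SyntheticConfig, genes: List[str]) -> pd.Series:
    noise = config.resolved_noise()
    scores = []
    for i, g in enumerate(genes):
        shifts = np.asarray(config.effects.get(g, np.zeros(len(config.conditions))), dtype=float)
        scores.append(np.sqrt(noise[i] ** 2 + np.var(shifts)))  # population variance
    return pd.Series(scores, index=pd.Index(genes, name="gene"), name="true_stability")


def simulate_ct(
    config: SyntheticConfig, seed: Optional[int] = None
) -> Tuple[CtTable, SyntheticTruth]:
    """Draw one Ct table (and its ground truth) from the generator.

    ``seed`` overrides ``config.seed``; the same seed yields an identical
    table.  Samples are laid out condition-major, then biological
    replicate, then technical replicate.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = config.resolved_gene_names()
    noise = config.resolved_noise()
    if config.baseline_ct is not None:
        baseline = np.asarray(config.baseline_ct, dtype=float)
        if baseline.shape != (config.n_genes,):
            raise ValueError("baseline_ct must give one value per gene")
    else:
        lo, hi = config.baseline_range
        baseline = rng.uniform(lo, hi, size=config.n_genes)

    shift = np.zeros((config.n_genes, len(config.conditions)))
    for i, g in enumerate(genes):
        if g in config.effects:
            shift[i, :] = np.asarray(config.effects[g], dtype=float)

    samples: List[SampleAnnotation] = []
    columns: List[np.ndarray] = []
    numeric = all(isinstance(c, (int, float)) for c in config.conditions)
    for ci, cond in enumerate(config.conditions):
        for b in range(1, config.n_bio_replicates + 1):
            loading = rng.normal(0.0, config.loading_sd) if config.loading_sd > 0 else 0.0
            eps = rng.normal(0.0, 1.0, size=config.n_genes) * noise
            bio_ct = baseline + loading + shift[:, ci] + eps
            label = f"{cond:g}h" if numeric else str(cond)
            for r in range(1, config.n_tech_replicates + 1):
                tech = (
                    rng.normal(0.0, config.tech_sd, size=config.n_genes)
                    if config.tech_sd > 0 and config.n_tech_replicates > 1
                    else np.zeros(config.n_genes)
                )
                sid = f"{config.subset}_{label}_b{b}"
                if config.n_tech_replicates > 1:
                    sid += f"_t{r}"
                samples.append(
                    SampleAnnotation(
                        sample_id=sid,
                        subset=config.subset,
                        group=None if numeric else str(cond),
                        time_point=float(cond) if numeric else None,
                        bio_replicate=b,
                        tech_replicate=r,
                    )
                )
                columns.append(bio_ct + tech)

    table = CtTable(genes=genes, samples=samples, ct=np.column_stack(columns))
    stability = _true_stability(config, genes)
    order = sorted(genes, key=lambda g: (stability[g], genes.index(g)))
    truth = SyntheticTruth(
        gene_names=genes,
        baseline_ct=baseline,
        noise_sd=noise,
        effects={g: np.asarray(v, dtype=float) for g, v in config.effects.items()},
        loading_sd=config.loading_sd,
        true_stability=stability,
        true_order=order,
    )
    return table, truth


def default_scenario(
    subset: str = "treatment",
    n_bio_replicates: int = 3,
    n_tech_replicates: int = 1,
    seed: Optional[int] = None,
) -> SyntheticConfig:
    """The package's reference simulation scenario: a 14-gene panel over a
    0/1/6/24 h time course.

    Two designed-stable genes (G01, G02; biological noise 0.1 cycles, the
    reproducibility of an excellent reference assay), ten ordinary
    candidates with noise graded from 0.3 to 0.5 cycles (real panels show
    a spread of stabilities, not a single common noise level), one
    treatment-responsive gene (G13) monotonically induced 0/+1/+2/+3
    cycles along the time course (an 8-fold expression change by 24 h,
    noise 0.3), and one erratic gene (G14; noise 1.5 cycles).  Shared
    per-sample loading SD 0.5 cycles.
    """
    noise = np.concatenate([[0.1, 0.1], np.linspace(0.3, 0.5, 10), [0.3, 1.5]])
    return SyntheticConfig(
        n_genes=14,
        conditions=DEFAULT_TIME_POINTS,
        n_bio_replicates=n_bio_replicates,
        n_tech_replicates=n_tech_replicates,
        loading_sd=0.5,
        effects={"G13": (0.0, 1.0, 2.0, 3.0)},
        noise_sd=noise,
        subset=subset,
        seed=seed,
    )


def simulate_study(
    seed: Optional[int] = None,
    *,
    scenario: Optional[SyntheticConfig] = None,
    include_tissues: bool = True,
) -> Tuple[CtTable, StudyDesign, Dict[str, SyntheticTruth]]:
    """Simulate a full multi-subset study sharing one gene panel.

    Seven treatment time courses plus (optionally) a nine-tissue panel are
    drawn with shared per-gene baselines, and an ``all``-samples subset
    unions them.  Returns the pooled Ct table, the matching
    :class:`~refstab.data_io.StudyDesign`, and one truth object per subset.
    """
    rng = np.random.default_rng(seed)
    base = scenario if scenario is not None else default_scenario()
    genes = base.resolved_gene_names()
    lo, hi = base.baseline_range
    baseline = (
        np.asarray(base.baseline_ct, dtype=float)
        if base.baseline_ct is not None
        else rng.uniform(lo, hi, size=base.n_genes)
    )

    tables: List[CtTable] = []
    truths: Dict[str, SyntheticTruth] = {}
    subset_names: List[str] = []
    for name in TREATMENT_SUBSETS:
        cfg = replace(base, subset=name, baseline_ct=baseline, seed=None)
        tbl, truth = simulate_ct(cfg, seed=int(rng.integers(0, 2**31 - 1)))
        tables.append(tbl)
        truths[name] = truth
        subset_names.append(name)
    if include_tissues:
        cfg = replace(
            base,
            subset="tissue",
            conditions=TISSUE_CONDITIONS,
            effects={g: np.zeros(len(TISSUE_CONDITIONS)) for g in base.effects},
            baseline_ct=baseline,
            seed=None,
        )
        tbl, truth = simulate_ct(cfg, seed=int(rng.integers(0, 2**31 - 1)))
        tables.append(tbl)
        truths["tissue"] = truth
        subset_names.append("tissue")

    merged = CtTable(
        genes=genes,
        samples=[s for t in tables for s in t.samples],
        ct=np.concatenate([t.ct for t in tables], axis=1),
    )
    design = StudyDesign(
        subsets=[SubsetDef(name=n) for n in subset_names]
        + [SubsetDef(name="all", union_of=list(subset_names))]
    )
    return merged, design, truths


def simulate_fpkm(
    means: Sequence[float],
    cvs: Sequence[float],
    n_conditions: int,
    seed: Optional[int] = None,
    unigene_ids: Optional[Sequence[str]] = None,
) -> Tuple[FPKMTable, pd.DataFrame]:
    """Draw a moment-matched log-normal FPKM matrix.

    Each unigene's draws have the requested mean and coefficient of
    variation exactly in expectation (``sigma^2 = ln(1 + cv^2)``,
    ``mu = ln(mean) - sigma^2 / 2``); ``cv = 0`` gives a constant row.
    Returns the table plus a truth frame with the requested moments.
    """
    mu_req = np.asarray(means, dtype=float)
    cv_req = np.asarray(cvs, dtype=float)
    if mu_req.shape != cv_req.shape or mu_req.ndim != 1:
        raise ValueError("means and cvs must be 1-D and of equal length")
    if np.any(mu_req <= 0) or np.any(cv_req < 0):
        raise ValueError("means must be > 0 and cvs >= 0")
    if n_conditions < 1:
        raise ValueError("n_conditions must be >= 1")
    rng = np.random.default_rng(seed)
    n = mu_req.size
    ids = (
        [str(u) for u in unigene_ids]
        if unigene_ids is not None
        else [f"U{i + 1:04d}" for i in range(n)]
    )
    sigma_sq = np.log1p(cv_req**2)
    mu = np.log(mu_req) - sigma_sq / 2.0
    draws = np.exp(mu[:, None] + np.sqrt(sigma_sq)[:, None] * rng.normal(size=(n, n_conditions)))
    table = FPKMTable(
        unigenes=ids,
        conditions=[f"cond{j + 1}" for j in range(n_conditions)],
        fpkm=draws,
    )
    truth = pd.DataFrame(
        {"mean": mu_req, "cv": cv_req}, index=pd.Index(ids, name="unigene")
    )
    return table, truth
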