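"""Pipeline runner: all stability analyses for every subset of a study.

``run_pipeline`` drives the full workflow from a single YAML/JSON config:
read (or simulate) a Ct table, collapse technical replicates, and for each
subset of the study design run geNorm, NormFinder and BestKeeper, the
V(n/n+1) series, the geometric-mean consensus, and the per-gene Ct
summary.  Every output is tidy CSV with a stable column contract, and a
JSON run manifest records config/input digests, package version, seed and
output paths so each reported number is traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .bestkeeper import bestkeeper_analysis, bestkeeper_rank
from .consensus import consensus_rank
from .data_io import (
    CtTable,
    StudyDesign,
    collapse_technical_replicates,
    read_ct_table,
    summarize_ct,
    write_ct_table,
)
from .genorm import genorm_rank
from .normfinder import normfinder_sv
from .relquant import delta_ct_transform
from .synthetic import simulate_study

__all__ = ["run_pipeline", "render_report"]

log = logging.getLogger("refstab")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_config(config_path) -> dict:
    path = Path(config_path)
    with path.open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg["_config_path"] = str(path)
    return cfg


def _tidy_ranking(subset: str, algorithm: str, ranks: dict, statistic: dict) -> pd.DataFrame:
    rows = [
        {
            "subset": subset,
            "gene": g,
            "statistic": algorithm,
            "value": (statistic or {}).get(g),
            "rank": r,
        }
        for g, r in ranks.items()
    ]
    return pd.DataFrame(rows)


def run_pipeline(config_path, *, seed: Optional[int] = None, out_dir=None) -> dict:
    """Run every configured subset analysis; returns the run manifest.

    The config file provides: ``ct_table`` (path to a Ct CSV; omit to
    simulate the default synthetic study), ``layout`` (wide|long),
    ``design`` (subset definitions and algorithm parameters, see
    :meth:`~refstab.data_io.StudyDesign.from_dict`), ``seed`` and
    ``output_dir`` (both overridable by the keyword arguments).
    """
    cfg = _load_config(config_path)
    out = Path(out_dir if out_dir is not None else cfg.get("output_dir", "refstab_out"))
    out.mkdir(parents=True, exist_ok=True)
    run_seed = seed if seed is not None else cfg.get("seed")

    manifest: dict = {
        "package_version": __version__,
        "seed": run_seed,
        "config_digest": _digest(Path(cfg["_config_path"])),
        "inputs": {},
        "subsets": {},
        "warnings": [],
        "failed_at": None,
    }

    try:
        if cfg.get("ct_table"):
            ct_path = Path(cfg["ct_table"])
            table = read_ct_table(
                ct_path,
                layout=cfg.get("layout", "wide"),
                allow_missing=bool(cfg.get("allow_missing", False)),
            )
            manifest["inputs"]["ct_table"] = {"path": str(ct_path), "sha256": _digest(ct_path)}
            design = StudyDesign.from_dict(cfg.get("design", {"subsets": ["all"]}))
        else:
            table, design, _ = simulate_study(run_seed)
            if "design" in cfg:
                design = StudyDesign.from_dict(cfg["design"])
            sim_path = out / "simulated_ct.csv"
            write_ct_table(table, sim_path, layout="long")
            manifest["inputs"]["ct_table"] = {"path": str(sim_path), "simulated": True}

        # validate before any computation so a bad subset name fails fast
        design.validate_samples(table)
        table = collapse_technical_replicates(table)
        base = float(cfg.get("base", 2.0))

        for subset_name in design.subset_names:
            sample_ids = design.select(table, subset_name)
            sub = table.select_samples(sample_ids)
            if sub.n_samples < 2:
                raise ValueError(f"subset {subset_name!r} has < 2 samples")
            rq = delta_ct_transform(sub, base=base)

            gn = genorm_rank(rq, m_threshold=design.m_threshold, v_cutoff=design.v_cutoff)
            nf = normfinder_sv(rq, groups=design.groups(table, subset_name))
            bk = bestkeeper_analysis(sub, sd_threshold=design.sd_threshold)
            rankings = [gn.to_ranking(), nf.to_ranking(), bk.to_ranking()]
            cons = consensus_rank(rankings, gene_order=table.genes)

            paths = {}
            frames = {
                "ct_summary": summarize_ct(sub).reset_index().assign(subset=subset_name),
                "genorm_m": pd.concat(
                    [
                        s.rename("M").reset_index().assign(round=i + 1, subset=subset_name)
                        for i, s in enumerate(gn.m_trajectory)
                    ]
                ),
                "v_series": gn.v_series.rename("value")
                .reset_index()
                .assign(
                    subset=subset_name,
                    below_cutoff=lambda d: d["value"] < design.v_cutoff,
                ),
                "bestkeeper": bk.stats.reset_index().assign(subset=subset_name),
                "consensus": cons.to_frame().reset_index().assign(subset=subset_name),
            }
            for alg, ranking in zip(("genorm", "normfinder", "bestkeeper"), rankings):
                frames[f"rank_{alg}"] = _tidy_ranking(
                    subset_name, alg, ranking.ranks, ranking.statistic
                )
            for name, frame in frames.items():
                path = out / f"{subset_name}_{name}.csv"
                frame.to_csv(path, index=False)
                paths[name] = str(path)

            manifest["subsets"][subset_name] = {
                "n_samples": sub.n_samples,
                "outputs": paths,
                "genorm_final_pair": list(gn.final_pair),
                "genorm_flagged_unstable": gn.flagged_unstable,
                "recommended_n": gn.recommended_n,
                "bestkeeper_excluded": bk.excluded,
                "consensus_order": cons.order,
            }
            log.info("subset %s: consensus top2 %s, recommended n=%s",
                     subset_name, cons.order[:2], gn.recommended_n)
    except Exception as exc:
        manifest["failed_at"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def render_report(manifest) -> str:
    """Human-readable summary of a completed run manifest.

    Accepts the manifest dict or a path to ``manifest.json``.  Idempotent:
    rendering the same manifest twice gives identical text.
    """
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    if manifest.get("failed_at"):
        raise ValueError(f"manifest records a failed run: {manifest['failed_at']}")
    if not manifest.get("subsets"):
        raise ValueError("manifest lists no completed subset outputs")
    lines = [
        f"refstab {manifest['package_version']} run "
        f"(seed={manifest.get('seed')}, config {manifest['config_digest']})",
        "",
    ]
    for name, info in manifest["subsets"].items():
        rec = info.get("recommended_n")
        rec_text = (
            f"optimal reference count n={rec}"
            if rec is not None
            else "no V(n/n+1) below the cutoff - no reference count recommended"
        )
        lines.append(f"[{name}] n_samples={info['n_samples']}")
        lines.append(f"  consensus ranking: {', '.join(info['consensus_order'])}")
        lines.append(
            f"  geNorm final pair: {' & '.join(info['genorm_final_pair'])}; {rec_text}"
        )
        if info.get("genorm_flagged_unstable"):
            lines.append(
                f"  geNorm M > threshold: {', '.join(info['genorm_flagged_unstable'])}"
            )
        if info.get("bestkeeper_excluded"):
            lines.append(
                f"  BestKeeper SD > threshold: {', '.join(info['bestkeeper_excluded'])}"
            )
        lines.append("")
    return "\n".join(lines)
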