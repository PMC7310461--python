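"""End-to-end orchestration: normalize -> fit -> contrast -> merge -> export.

``run_study`` is the in-memory pipeline used from Python (and by the tests);
``run_pipeline`` wraps it with file I/O driven by a YAML configuration and
writes every export (contrast/final TSVs, count and extrema summaries,
GraphML per pathway, a JSON run log recording the design decisions in
force: removed cycle edges, skipped genes, dropped collinear parents,
mixture weights).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .difftest import (
    ParameterContrast,
    apply_fdr,
    contrast_networks,
    contrasts_to_frame,
    count_significant,
)
from .estimate import FittedNetwork, fit_network, network_to_frame
from .manifest import StudyManifest, load_manifest
from .merge import (
    FinalParameter,
    PlatformWeights,
    extrema_table,
    finals_to_frame,
    finals_to_graph,
    merge_contrasts,
    platform_weights,
    rank_parameters,
)
from .normalize import (
    ExpressionDataset,
    MergedPlatformDataset,
    QCReport,
    combat_adjust,
    merge_platform,
    qc_summary,
    quantile_normalize,
)
from .pathway import PathwayGraph, break_cycles, parse_sif

__all__ = ["StudyResult", "run_study", "run_pipeline", "load_config"]


@dataclass
class StudyResult:
    """Everything the pipeline computes, keyed for export and inspection."""

    merged: dict[str, MergedPlatformDataset]
    qc_before: dict[str, QCReport]
    qc_after: dict[str, QCReport]
    networks: dict[tuple[str, str, str], FittedNetwork]  # (pathway, platform, group)
    contrasts: list[ParameterContrast]
    untestable: dict[tuple[str, str], list] = field(default_factory=dict)
    finals: dict[str, list[FinalParameter]] = field(default_factory=dict)
    weights: PlatformWeights | None = None
    alpha: float = 0.05
    pathways: dict[str, PathwayGraph] = field(default_factory=dict)

    def summary_counts(self) -> pd.DataFrame:
        return count_significant(self.contrasts, self.alpha)

    def summary_extrema(self) -> pd.DataFrame:
        frames = []
        for pid in sorted(self.finals):
            t = extrema_table(self.finals[pid])
            t.insert(0, "pathway_id", pid)
            frames.append(t)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def top_parameters(self, k: int = 3) -> pd.DataFrame:
        rows = []
        for pid in sorted(self.finals):
            ranked = rank_parameters(self.finals[pid], k=k)
            for table, items in sorted(ranked.items()):
                for rank, f in enumerate(items, start=1):
                    rows.append(
                        {
                            "pathway_id": pid,
                            "table": table,
                            "rank": rank,
                            "parameter": str(f.key),
                            "mu_star": f.mu_star,
                            "sign_class": f.sign_class,
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=["pathway_id", "table", "rank", "parameter", "mu_star", "sign_class"],
        )


def run_study(
    pathways: dict[str, PathwayGraph],
    datasets: list[ExpressionDataset],
    manifest: StudyManifest | dict[str, int] | None = None,
    alpha: float = 0.05,
    combat: bool = True,
    preserve_group: bool = True,
) -> StudyResult:
    """Run the full analysis in memory.

    Platform mixture weights come from the manifest when given (subject
    counts per platform), otherwise from the observed per-platform sample
    counts.  Cyclic pathways are reduced deterministically before fitting.
    """
    by_platform: dict[str, list[ExpressionDataset]] = {}
    for d in datasets:
        by_platform.setdefault(d.platform_id, []).append(d)

    merged: dict[str, MergedPlatformDataset] = {}
    qc_before: dict[str, QCReport] = {}
    qc_after: dict[str, QCReport] = {}
    for plat in sorted(by_platform):
        ds = [quantile_normalize(d) for d in sorted(by_platform[plat], key=lambda d: d.dataset_id)]
        m = merge_platform(ds)
        qc_before[plat] = qc_summary(m)
        if combat and len(m.batches) >= 2:
            m = combat_adjust(m, preserve_group=preserve_group)
        qc_after[plat] = qc_summary(m)
        merged[plat] = m

    if manifest is None:
        counts = {p: m.matrix.shape[1] for p, m in merged.items()}
    elif isinstance(manifest, StudyManifest):
        counts = manifest.platform_subjects()
    else:
        counts = dict(manifest)
    weights = platform_weights(counts)

    result = StudyResult(
        merged=merged,
        qc_before=qc_before,
        qc_after=qc_after,
        networks={},
        contrasts=[],
        weights=weights,
        alpha=alpha,
    )
    for pid in sorted(pathways):
        pg = pathways[pid]
        if not pg.is_acyclic():
            pg = break_cycles(pg)
        result.pathways[pid] = pg
        pathway_contrasts: list[ParameterContrast] = []
        for plat in sorted(merged):
            case = fit_network(pg, merged[plat], "case")
            control = fit_network(pg, merged[plat], "control")
            result.networks[(pid, plat, "case")] = case
            result.networks[(pid, plat, "control")] = control
            contrasts, untestable = contrast_networks(case, control)
            apply_fdr(contrasts, alpha)  # family = (pathway, platform)
            result.untestable[(pid, plat)] = untestable
            pathway_contrasts.extend(contrasts)
        result.finals[pid] = merge_contrasts(pathway_contrasts, weights)
        result.contrasts.extend(pathway_contrasts)
    return result


# -- file-driven pipeline -------------------------------------------------

def load_config(source) -> dict:
    """Read the YAML pipeline configuration (path or text)."""
    if isinstance(source, dict):
        return source
    p = Path(source)
    text = p.read_text() if p.exists() else str(source)
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    return cfg


def _load_datasets(cfg: dict, base: Path) -> list[ExpressionDataset]:
    meta_path = base / cfg["expression"]["metadata"]
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    required = {"group", "dataset_id", "platform_id"}
    if not required <= set(meta.columns):
        raise ValueError(f"sample metadata needs columns {sorted(required)}")
    data_dir = base / cfg["expression"].get("directory", ".")
    datasets = []
    for dsid in sorted(meta["dataset_id"].unique()):
        sub = meta[meta["dataset_id"] == dsid]
        mat = pd.read_csv(data_dir / f"{dsid}.tsv", sep="\t", index_col="gene_id")
        mat = mat[sub.index.tolist()]
        platform = sub["platform_id"].iloc[0]
        datasets.append(
            ExpressionDataset(
                dataset_id=str(dsid),
                platform_id=str(platform),
                matrix=mat,
                sample_meta=sub[["group"]].copy(),
            )
        )
    return datasets


def run_pipeline(config, out_dir) -> StudyResult:
    """Execute the configured study and write all exports under ``out_dir``.

    Any stage failure aborts with the stage name; artifacts of completed
    stages are left in place.
    """
    cfg = load_config(config)
    base = Path(cfg.get("base_dir", "."))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": [], "config": {k: v for k, v in cfg.items() if k != "base_dir"}}

    def stage(name):
        log["stages"].append({"name": name, "started": time.time()})
        return name

    try:
        stage("load_pathways")
        pathways = {
            pid: parse_sif(Path(base / path).read_text(), pathway_id=pid)
            for pid, path in sorted(cfg["pathways"].items())
        }
        stage("load_expression")
        datasets = _load_datasets(cfg, base)
        manifest = None
        if cfg.get("manifest"):
            manifest = load_manifest(base / cfg["manifest"])
        stage("run_study")
        result = run_study(
            pathways,
            datasets,
            manifest=manifest,
            alpha=float(cfg.get("alpha", 0.05)),
            combat=bool(cfg.get("combat", {}).get("enabled", True)),
            preserve_group=bool(cfg.get("combat", {}).get("preserve_group", True)),
        )
    except Exception as exc:
        failed = log["stages"][-1]["name"] if log["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    stage("export")
    contrasts_to_frame(result.contrasts).to_csv(
        out / "contrasts.tsv", sep="\t", index=False, float_format="%.8g"
    )
    frames = [finals_to_frame(result.finals[pid]) for pid in sorted(result.finals)]
    finals_frame = (
        pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    )
    finals_frame.to_csv(out / "finals.tsv", sep="\t", index=False, float_format="%.8g")
    result.summary_counts().to_csv(
        out / "summary_counts.tsv", sep="\t", index=False
    )
    result.summary_extrema().to_csv(
        out / "summary_extrema.tsv", sep="\t", index=False, float_format="%.8g"
    )
    result.top_parameters().to_csv(
        out / "top_parameters.tsv", sep="\t", index=False, float_format="%.8g"
    )
    fitted = [network_to_frame(n) for n in result.networks.values()]
    pd.concat(fitted, ignore_index=True).to_csv(
        out / "fitted_parameters.tsv", sep="\t", index=False, float_format="%.8g"
    )
    for pid, pg in result.pathways.items():
        nx.write_graphml(
            finals_to_graph(pg, result.finals[pid]), out / f"{pid}.graphml"
        )
    qc = {
        "before": {p: r.to_dict() for p, r in result.qc_before.items()},
        "after": {p: r.to_dict() for p, r in result.qc_after.items()},
    }
    (out / "qc.json").write_text(json.dumps(qc, indent=2, sort_keys=True))

    log["alpha"] = result.alpha
    log["mixture_weights"] = result.weights.weights if result.weights else {}
    log["removed_cycle_edges"] = {
        pid: pg.removed_edges for pid, pg in result.pathways.items()
    }
    log["skipped_genes"] = {
        f"{pid}/{plat}/{grp}": net.skipped
        for (pid, plat, grp), net in result.networks.items()
        if net.skipped
    }
    log["dropped_collinear_parents"] = {
        f"{pid}/{plat}/{grp}": {
            g: list(nm.dropped_parents)
            for g, nm in net.node_models.items()
            if nm.dropped_parents
        }
        for (pid, plat, grp), net in result.networks.items()
        if any(nm.dropped_parents for nm in net.node_models.values())
    }
    log["lost_gene_report"] = {
        p: m.lost_gene_report.reset_index().to_dict(orient="records")
        for p, m in result.merged.items()
    }
    for s in log["stages"]:
        s["elapsed"] = time.time() - s["started"]
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True, default=str))
    return result
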