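"""End-to-end pipeline: config in, report bundle out.

The YAML config names the inputs (expression matrix, sample sheet, probe
annotation, GMT collections, PPI edge list — or ``synthetic`` to generate
them), the screening parameters and a top-level seed.  Outputs are written in
stage order to the output directory, and a run manifest records every
effective parameter so any stage can be re-run reproducibly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cascade import MEVALONATE_GENES, NFY_SUBUNITS
from .empirical_null import NullConfig
from .enrichment import GeneSetCollection
from .expr_io import (
    map_probes,
    read_probe_annotation,
    read_sample_sheet,
    read_series_matrix,
    write_sample_sheet,
    write_series_matrix,
)
from .model import CorrelationCascadeModel
from .ppi import read_edge_list, write_edge_list
from .synthetic import (
    SyntheticConfig,
    generate_annotation,
    generate_expression,
    generate_ppi,
)

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_pipeline", "PipelineError"]

DEFAULT_CONFIG: dict[str, Any] = {
    "expression": "synthetic",
    "sample_sheet": None,
    "probe_annotation": None,
    "collapse_rule": "max_mean",
    "gene_sets": None,          # GMT path; "synthetic" fixtures write their own
    "ppi": None,                # edge-list path
    "anchors": list(MEVALONATE_GENES),
    "subunits": list(NFY_SUBUNITS),
    "screen_anchors": ["EGFR", "MET"],
    "tumor_label": "tumor",
    "normal_label": "normal",
    "normalize": True,
    "n_pairs": 100000,
    "lower_pct": 2.5,
    "upper_pct": 97.5,
    "min_anchor_count": 3,
    "count_percentile": 97.5,
    "alpha": 0.025,
    "seed": 0,
    "synthetic": {},            # SyntheticConfig overrides
    "output_dir": "corrcascade_run",
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(path: str | Path | None, overrides: dict | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config must be a YAML mapping")
        unknown = set(loaded) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(loaded)
    for k, v in (overrides or {}).items():
        if v is not None:
            cfg[k] = v
    return cfg


def _stage_seed(seed: int, stage: int) -> int:
    # derive independent per-stage streams from the top-level seed
    return int(np.random.SeedSequence(seed).spawn(stage + 1)[stage]
               .generate_state(1)[0] % (2**31))


def run_pipeline(config: str | Path | dict | None, outdir: str | Path | None = None) -> dict:
    """Run every stage in order; returns the manifest dict."""
    cfg = config if isinstance(config, dict) else load_config(config)
    out = Path(outdir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict[str, Any] = {"version": __version__, "config": _tidy(cfg),
                                "outputs": {}}

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = path.name  # relative to the run directory

    stage = "inputs"
    try:
        truth = None
        if cfg["expression"] == "synthetic":
            syn = SyntheticConfig(**{**cfg.get("synthetic", {}),
                                     "seed": _stage_seed(seed, 0)})
            expr, groups, truth = generate_expression(syn)
            collection = generate_annotation(truth, seed=_stage_seed(seed, 1))
            graph, planted = generate_ppi(truth, seed=_stage_seed(seed, 2))
            write_series_matrix(expr, out / "expression.txt", groups)
            write_sample_sheet(groups, out / "samples.tsv")
            collection.to_gmt(out / "gene_sets.gmt")
            write_edge_list(graph, out / "ppi_edges.tsv")
            (out / "truth.json").write_text(
                json.dumps({**truth.to_json_dict(), "ppi": planted}, indent=2))
            for n in ("expression.txt", "samples.tsv", "gene_sets.gmt",
                      "ppi_edges.tsv", "truth.json"):
                emit(n.split(".")[0], out / n)
        else:
            expr, groups = read_series_matrix(cfg["expression"])
            if cfg["sample_sheet"]:
                groups = read_sample_sheet(cfg["sample_sheet"])
            if groups.empty:
                raise ValueError("no sample labels; provide sample_sheet")
            if cfg["probe_annotation"]:
                ann = read_probe_annotation(cfg["probe_annotation"])
                expr = map_probes(expr, ann, cfg["collapse_rule"])
            collection = (GeneSetCollection.from_gmt(cfg["gene_sets"])
                          if cfg["gene_sets"] else None)
            graph = read_edge_list(cfg["ppi"]) if cfg["ppi"] else None

        stage = "fit"
        null_cfg = NullConfig(int(cfg["n_pairs"]), float(cfg["lower_pct"]),
                              float(cfg["upper_pct"]), _stage_seed(seed, 3),
                              cfg["tumor_label"])
        model = CorrelationCascadeModel(
            expr, groups,
            anchors=cfg["anchors"], subunits=cfg["subunits"],
            tumor_label=cfg["tumor_label"], normal_label=cfg["normal_label"],
            null_config=null_cfg, normalize=bool(cfg["normalize"]),
            min_anchor_count=int(cfg["min_anchor_count"]),
            count_percentile=float(cfg["count_percentile"]),
        )
        res = model.fit()

        stage = "normalize"
        write_series_matrix(res.normalized, out / "normalized.txt", groups)
        emit("normalized", out / "normalized.txt")

        stage = "null"
        res.thresholds.to_json(out / "null_thresholds.json")
        emit("null_thresholds", out / "null_thresholds.json")

        stage = "screen"
        screens = []
        for anchor in cfg["screen_anchors"]:
            if anchor not in res.tumor.index:
                logger.warning("screen anchor %s absent; skipped", anchor)
                continue
            t = res.screen(anchor).table
            t.insert(0, "anchor", anchor)
            screens.append(t)
        if screens:
            pd.concat(screens).to_csv(out / "anchor_screen.tsv", sep="\t",
                                      index=False)
            emit("anchor_screen", out / "anchor_screen.tsv")

        stage = "count"
        res.anchor_count_table().to_csv(out / "anchor_counts.tsv", sep="\t",
                                        index=False)
        emit("anchor_counts", out / "anchor_counts.tsv")
        assoc = pd.DataFrame({
            "gene": sorted(res.associated_positive | res.associated_negative)})
        assoc["positive"] = assoc["gene"].isin(res.associated_positive)
        assoc["negative"] = assoc["gene"].isin(res.associated_negative)
        assoc.to_csv(out / "associated_sets.tsv", sep="\t", index=False)
        emit("associated_sets", out / "associated_sets.tsv")

        stage = "enrich"
        if collection is not None and res.cascade is not None and res.cascade.final:
            enr = res.enrich(collection, alpha=float(cfg["alpha"]))
            enr.to_csv(out / "enrichment_final_set.tsv", sep="\t", index=False)
            emit("enrichment", out / "enrichment_final_set.tsv")

        stage = "cascade"
        cascade_payload = {
            "per_subunit_sizes": (res.cascade.per_subunit_sizes
                                  if res.cascade else {}),
            "union_size": len(res.cascade.union) if res.cascade else 0,
            "count_threshold": res.count_threshold.value,
            "final_set": sorted(res.cascade.final) if res.cascade else [],
        }
        (out / "cascade.json").write_text(json.dumps(cascade_payload, indent=2))
        emit("cascade", out / "cascade.json")

        stage = "net"
        if graph is not None and res.cascade is not None and res.cascade.final:
            report = res.hub_analysis(graph)
            write_edge_list(report.subnetwork, out / "subnetwork_edges.tsv")
            report.node_roles(cfg["subunits"], sorted(res.cascade.final)).to_csv(
                out / "subnetwork_nodes.tsv", sep="\t", index=False)
            emit("subnetwork_edges", out / "subnetwork_edges.tsv")
            emit("subnetwork_nodes", out / "subnetwork_nodes.tsv")
    except PipelineError:
        raise
    except Exception as exc:  # partial outputs stay on disk for debugging
        raise PipelineError(stage, str(exc)) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _tidy(cfg: dict) -> dict:
    return {k: (str(v) if isinstance(v, Path) else v) for k, v in cfg.items()}
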