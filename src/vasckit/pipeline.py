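"""Stage orchestration: run the analysis stages as a reproducible pipeline.

A :class:`RunConfig` selects stages and carries every stage's parameters;
outputs land in ``out_dir`` together with ``run_meta.json`` echoing the full
configuration, its hash, the seed and the package version, so identical
config + seed reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .correction import CollapseConfig, SmoothingConfig, detect_collapsed, multiscale_smooth
from .graph import find_root, validate_graph
from .io import read_spatial_graph, write_spatial_graph
from .morphometry import (
    branching_angles,
    cumulative_volume_by_order,
    grouped_summary,
    intervessel_midpoint_distance,
    segment_metrics,
)
from .ordering import compute_ordering, order_counts
from .scaling import OutlierConfig, extract_bifurcations, fit_branching_ratio, murray_regression
from .synthetic import TreeSpec, generate_tree

logger = logging.getLogger("vasckit")

STAGES = ("simulate", "ingest", "order", "correct", "metrics", "stats")

# per stage: list of requirement groups; each group is satisfied by any member
_REQUIRES: dict[str, list[tuple[str, ...]]] = {
    "order": [("simulate", "ingest")],
    "correct": [("order",)],
    "metrics": [("simulate", "ingest")],
    "stats": [("order",), ("metrics",)],
}


@dataclass
class RunConfig:
    stages: list[str] = field(default_factory=lambda: ["simulate", "order", "metrics", "stats"])
    out_dir: str = "vasckit_run"
    seed: int = 0
    input_graph: str | None = None  # required by the ingest stage
    tree: dict = field(default_factory=dict)  # TreeSpec overrides for simulate
    smoothing: dict = field(default_factory=dict)
    collapse: dict = field(default_factory=dict)
    outliers: dict = field(default_factory=dict)
    murray_unit_scale: float = 1e-6  # μm -> m for the Murray regression
    root_strategy: str = "max_radius_terminal"
    root_node: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def preflight(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        have: set[str] = set()
        for stage in self.stages:
            for group in _REQUIRES.get(stage, []):
                if not set(group) & have:
                    raise ValueError(
                        f"stage {stage!r} requires {' or '.join(group)} to run first"
                    )
            have.add(stage)
        if "ingest" in self.stages and not self.input_graph:
            raise ValueError("ingest stage needs input_graph")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages; returns a summary of produced artifacts."""
    config.preflight()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    graph = None
    ordering = None
    metrics = None

    for stage in config.stages:
        logger.info("stage %s", stage)
        if stage == "simulate":
            spec = TreeSpec(**{"seed": config.seed, **config.tree})
            graph = generate_tree(spec)
            write_spatial_graph(graph, out / "graph.sg.tsv")
            artifacts["graph"] = str(out / "graph.sg.tsv")
        elif stage == "ingest":
            graph = read_spatial_graph(config.input_graph)
            artifacts["graph"] = config.input_graph
        elif stage == "order":
            root = find_root(graph, strategy=config.root_strategy, node_id=config.root_node)
            ordering = compute_ordering(graph, root)
            table = pd.DataFrame({
                "strahler": pd.Series(ordering.strahler),
                "generation": pd.Series(ordering.generation),
            }).sort_index()
            table.to_csv(out / "ordering.tsv", sep="\t", index_label="segment_id")
            artifacts["ordering"] = str(out / "ordering.tsv")
        elif stage == "correct":
            graph = multiscale_smooth(graph, ordering, SmoothingConfig(**config.smoothing))
            pre_metrics = segment_metrics(graph)
            candidates = detect_collapsed(pre_metrics, ordering, CollapseConfig(**config.collapse))
            candidates.to_csv(out / "collapse_candidates.tsv", sep="\t", index=False)
            write_spatial_graph(graph, out / "graph_corrected.sg.tsv")
            # re-order after correction
            ordering = compute_ordering(graph, ordering.root)
            artifacts["collapse_candidates"] = str(out / "collapse_candidates.tsv")
        elif stage == "metrics":
            metrics = segment_metrics(graph)
            metrics.to_csv(out / "metrics.tsv", sep="\t")
            artifacts["metrics"] = str(out / "metrics.tsv")
        elif stage == "stats":
            counts = order_counts(ordering)
            br = fit_branching_ratio(counts)
            angles = branching_angles(graph, ordering.root)
            ivd = intervessel_midpoint_distance(graph) if graph.n_segments >= 2 else None
            summary = grouped_summary(metrics, ordering, angles, ivd)
            summary.to_csv(out / "order_summary.tsv", sep="\t", index_label="order")
            cumvol = cumulative_volume_by_order(metrics, ordering)
            records = extract_bifurcations(graph, metrics, ordering)
            stats_payload = {
                "order_counts": {str(k): v for k, v in sorted(counts.items())},
                "branching_ratio": br.gamma,
                "branching_fit_r2": br.r2,
                "cumulative_volume_fraction": {str(k): float(v) for k, v in cumvol.items()},
            }
            if len(records) >= 3:
                mf = murray_regression(records, unit_scale=config.murray_unit_scale,
                                       outliers=OutlierConfig(**config.outliers)
                                       if config.outliers else None)
                stats_payload["murray"] = asdict(mf)
            (out / "stats.json").write_text(json.dumps(stats_payload, indent=2))
            artifacts["stats"] = str(out / "stats.json")

    report = validate_graph(graph) if graph is not None else None
    meta = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "artifacts": artifacts,
        "graph_ok": bool(report.ok) if report else None,
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    artifacts["run_meta"] = str(out / "run_meta.json")
    return meta
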