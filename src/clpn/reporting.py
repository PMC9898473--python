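"""End-to-end pipeline, run configuration, layout export and reports.

``run_pipeline`` wires the stages together — rescale, structure search +
non-regularized refit, case bootstrap, three-part triage, effect-size
conversion and RVE contrasts — and writes every artefact (model JSON, edge
CSV, accuracy/stability summary, layout JSON, run log) so each printed
number can be recomputed from the archived files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from . import __version__
from .data import PanelDataset, read_panel, read_node_specs, rescale_to_likert
from .cohort import CohortScenario, simulate
from .effects import effect_records_from_edges, rve_contrast
from .model import PanelGVAR, structure_search
from .stability import (
    bootstrap,
    summarize_edges,
    ci_accuracy_report,
    stability_report,
    edges_to_frame,
)

__all__ = ["RunConfig", "count_possible_edges", "fr_layout", "run_pipeline"]

log = logging.getLogger("clpn")


def count_possible_edges(p_nodes: int, kind: str) -> int:
    """Structural edge count for ``p_nodes`` nodes.

    ``directed_lag1`` counts every ordered pair including autoregressive
    self-loops (p^2); ``undirected`` counts unordered distinct pairs
    (p(p-1)/2).  These are the denominators of stability percentages.
    """
    if p_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if kind == "directed_lag1":
        return p_nodes * p_nodes
    if kind == "undirected":
        return p_nodes * (p_nodes - 1) // 2
    raise ValueError(f"kind must be 'directed_lag1' or 'undirected', got {kind!r}")


def fr_layout(
    weights: np.ndarray, seed: int = 0, node_names: list[str] | None = None
) -> dict[str, tuple[float, float]]:
    """Fruchterman-Reingold coordinates for one network.

    Edge attraction is proportional to |weight|; coordinates are rescaled to
    the unit square and are deterministic given the seed.
    """
    W = np.abs(np.asarray(weights, dtype=float))
    p = W.shape[0]
    if p < 2:
        raise ValueError("need at least 2 nodes")
    names = node_names or [f"x{j + 1}" for j in range(p)]
    G = nx.Graph()
    G.add_nodes_from(names)
    for i in range(p):
        for j in range(i + 1, p):
            w = max(W[i, j], W[j, i])
            if w > 0:
                G.add_edge(names[i], names[j], weight=float(w))
    pos = nx.spring_layout(G, weight="weight", seed=seed)
    xy = np.array([pos[n] for n in names], dtype=float)
    span = xy.max(axis=0) - xy.min(axis=0)
    span[span == 0] = 1.0
    xy = (xy - xy.min(axis=0)) / span
    return {n: (float(x), float(y)) for n, (x, y) in zip(names, xy)}


@dataclass
class RunConfig:
    """Everything one reproducible run needs, loadable from YAML/JSON.

    All randomness flows from ``seed``; triage thresholds default to the
    (p < .001, inclusion >= 50%, |d| >= 0.100) rule.
    """

    panel_path: str | None = None
    nodes_path: str | None = None
    scenario_path: str | None = None
    output_dir: str = "clpn_run"
    seed: int = 0
    n_reps: int = 1000
    n_models: int = 100
    gamma: float = 0.5
    rescale: bool = True
    fit_method: str = "auto"
    bootstrap_refit: str = "moment"
    pvalue_method: str = "auto"
    p_threshold: float = 0.001
    inclusion_threshold: float = 0.5
    d_threshold: float = 0.100
    run_search: bool = True
    rve_designs: list[str] = field(
        default_factory=lambda: ["vulnerability_vs_scar", "somatic_by_proinflammatory"]
    )

    def __post_init__(self):
        if min(self.p_threshold, self.inclusion_threshold, self.d_threshold) <= 0:
            raise ValueError("triage thresholds must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, completed: dict, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.completed_artifacts = completed


def _load_input(config: RunConfig) -> PanelDataset:
    if config.panel_path:
        nodes = read_node_specs(config.nodes_path) if config.nodes_path else None
        return read_panel(config.panel_path, layout="long", node_specs=nodes)
    if config.scenario_path:
        scenario = CohortScenario.load(config.scenario_path)
        return simulate(scenario)
    raise ValueError("config needs either panel_path or scenario_path")


def run_pipeline(config: RunConfig, data: PanelDataset | None = None) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict with the fitted results, edge estimates, reports, RVE
    contrasts and the paths of all written artefacts.  Any stage error
    aborts with the stage name and the artefacts completed so far.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    t0 = time.time()
    stage = "load"
    try:
        if data is None:
            data = _load_input(config)
        stage = "rescale"
        if config.rescale:
            data = rescale_to_likert(data)

        stage = "fit"
        if config.run_search:
            masks, res = structure_search(
                data,
                n_models=config.n_models,
                gamma=config.gamma,
                method=config.fit_method,
            )
        else:
            masks = None
            res = PanelGVAR(data).fit(method=config.fit_method)
        model_json = {
            "mu": res.params.mu.tolist(),
            "B": res.params.B.tolist(),
            "K_zeta": res.params.K_zeta.tolist(),
            "K_B": res.params.K_B.tolist(),
            "networks": {
                "temporal": res.networks.temporal.tolist(),
                "contemporaneous": res.networks.contemporaneous.tolist(),
                "between": res.networks.between.tolist(),
            },
            "fit_indices": asdict(res.fit_indices),
            "masks": None
            if masks is None
            else {
                "b_mask": masks.b_mask.tolist(),
                "kzeta_mask": masks.kzeta_mask.tolist(),
                "kb_mask": masks.kb_mask.tolist(),
            },
            "solver": {
                "method": res.method,
                "converged": res.converged,
                "n_iter": res.n_iter,
                "log_likelihood": res.log_likelihood,
            },
            "nodes": data.node_names,
        }
        path = out / "model.json"
        path.write_text(json.dumps(model_json, indent=2))
        artifacts["model"] = str(path)

        stage = "bootstrap"
        archive = bootstrap(
            data,
            n_reps=config.n_reps,
            seed=config.seed,
            refit=config.bootstrap_refit,
            n_models=min(config.n_models, 30),
            gamma=config.gamma,
        )

        stage = "triage"
        edges = summarize_edges(
            archive,
            res,
            p_threshold=config.p_threshold,
            inclusion_threshold=config.inclusion_threshold,
            d_threshold=config.d_threshold,
            pvalue_method=config.pvalue_method,
        )
        frame = edges_to_frame(edges)
        path = out / "edges.csv"
        frame.to_csv(path, index=False, float_format="%.10g")
        artifacts["edges"] = str(path)

        stage = "reports"
        accuracy = ci_accuracy_report(edges)
        stability = stability_report(edges)
        summary = {
            "accuracy_ci_excludes_zero": {
                k: {"count": c, "total": t, "percent": pct}
                for k, (c, t, pct) in accuracy.items()
            },
            "stability_inclusion_ge_50": {
                k: {"count": c, "total": t, "percent": pct}
                for k, (c, t, pct) in stability.items()
            },
            "n_significant": {
                which: int(sum(e.significant for e in edges if e.network == which))
                for which in ("temporal", "contemporaneous", "between")
            },
            "bootstrap": {
                "n_reps": archive.n_reps,
                "n_failed": archive.n_failed,
                "seed": archive.seed,
            },
        }

        stage = "effects"
        contrasts = {}
        for design in config.rve_designs:
            nets = ("temporal",) if design == "vulnerability_vs_scar" else (
                "temporal",
                "contemporaneous",
                "between",
            )
            records = effect_records_from_edges(edges, data.nodes, networks=nets)
            try:
                results = rve_contrast(records, design)
                contrasts[design] = [asdict(r) for r in results]
            except ValueError as exc:
                contrasts[design] = {"skipped": str(exc)}
        summary["rve_contrasts"] = contrasts
        path = out / "summary.json"
        path.write_text(json.dumps(summary, indent=2))
        artifacts["summary"] = str(path)

        stage = "layout"
        layouts = {
            which: fr_layout(
                res.networks.matrix(which), seed=config.seed, node_names=data.node_names
            )
            for which in ("temporal", "contemporaneous", "between")
        }
        path = out / "layout.json"
        path.write_text(json.dumps(layouts, indent=2))
        artifacts["layout"] = str(path)

        stage = "log"
        logpath = out / "run.log"
        logpath.write_text(
            "\n".join(
                [
                    f"clpn version: {__version__}",
                    f"seed: {config.seed}",
                    f"n_persons: {data.n_persons}  n_waves: {data.n_waves}  "
                    f"n_nodes: {data.n_nodes}",
                    f"bootstrap reps: {config.n_reps} (failed: {archive.n_failed})",
                    f"elapsed seconds: {time.time() - t0:.1f}",
                ]
            )
            + "\n"
        )
        artifacts["log"] = str(logpath)
    except Exception as exc:  # noqa: BLE001 - stage context matters here
        raise PipelineError(stage, artifacts, exc) from exc

    return {
        "results": res,
        "edges": edges,
        "archive": archive,
        "summary": summary,
        "contrasts": contrasts,
        "artifacts": artifacts,
    }
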