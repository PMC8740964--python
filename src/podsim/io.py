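"""Result serialization, experiment manifests, the full experiment grid,
and small deterministic test fixtures."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig
from .contagion import preset
from .core import BeliefSpace, Institution
from .engine import BatchResult, BeliefTimeseries, RunResult, run_batch
from .networks import GraphSpec, SocialGraph, wire_subscribers, write_edgelist_csv

logger = logging.getLogger(__name__)

GRID_METHODS = ("simple", "proportional", "dcc")
GRID_SCHEDULES = ("single", "split", "gradual")
GRID_FAMILIES = ("ER", "WS", "BA", "MAG")


@dataclass
class ExperimentManifest:
    """Written before any simulation output; enough to re-run bit-identically."""

    name: str
    config: dict
    seeds: list
    outputs: list = field(default_factory=list)
    version: str = __version__

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def read(cls, path) -> "ExperimentManifest":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# result export / import


def batch_to_frame(batch: BatchResult) -> pd.DataFrame:
    return pd.concat(
        [r.timeseries.to_frame(replicate=i) for i, r in enumerate(batch.results)],
        ignore_index=True,
    )


def export_run(result, path, format: str = "csv") -> None:
    """Tidy export: columns replicate,t,belief_level,count,fraction."""
    if isinstance(result, RunResult):
        df = result.timeseries.to_frame(replicate=0)
    elif isinstance(result, BatchResult):
        df = batch_to_frame(result)
    else:
        raise TypeError(f"cannot export {type(result).__name__}")
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        df.to_json(path, orient="records")
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_timeseries(path) -> dict:
    """Inverse of :func:`export_run`: replicate -> BeliefTimeseries."""
    df = pd.read_csv(path)
    out = {}
    for rep, grp in df.groupby("replicate"):
        counts = (
            grp.pivot(index="t", columns="belief_level", values="count")
            .sort_index()
            .to_numpy()
            .astype(np.int64)
        )
        out[int(rep)] = BeliefTimeseries(counts)
    return out


def import_mean_counts(path) -> np.ndarray:
    """Replicate-mean count table from an exported CSV."""
    series = import_timeseries(path)
    return np.mean([ts.counts for ts in series.values()], axis=0)


# ---------------------------------------------------------------------------
# the full experiment grid


def grid_cell_config(
    method: str,
    schedule: str,
    family: str,
    n_agents: int = 500,
    horizon: int = 100,
    replicates: int = 10,
) -> SimulationConfig:
    return SimulationConfig(
        n_agents=n_agents,
        horizon=horizon,
        replicates=replicates,
        graph_spec=GraphSpec(family=family),
        contagion_spec=preset(method),
        schedule_name=schedule,
    )


def run_paper_experiments(
    out_dir,
    seed: int = 0,
    n_agents: int = 500,
    horizon: int = 100,
    replicates: int = 10,
) -> ExperimentManifest:
    """The full 3 (method) x 3 (message set) x 4 (topology) grid.

    Writes one tidy timeseries CSV per cell plus a summary of final belief
    histograms; a failed cell is reported without discarding completed ones.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cells = [
        (m, s, f) for m in GRID_METHODS for s in GRID_SCHEDULES for f in GRID_FAMILIES
    ]
    manifest = ExperimentManifest(
        name="contagion-grid",
        config={"n_agents": n_agents, "horizon": horizon, "replicates": replicates},
        seeds=[seed + i * replicates for i in range(len(cells))],
    )
    manifest.write(out_dir / "manifest.json")

    summary_rows = []
    failures = []
    for i, (method, schedule, family) in enumerate(cells):
        cell = f"{method}_{schedule}_{family}"
        try:
            cfg = grid_cell_config(method, schedule, family, n_agents, horizon, replicates)
            batch = run_batch(cfg, base_seed=manifest.seeds[i])
            path = out_dir / f"{cell}.csv"
            export_run(batch, path)
            manifest.outputs.append(str(path))
            final = batch.mean_counts[-1]
            for level, count in enumerate(final):
                summary_rows.append(
                    {"method": method, "schedule": schedule, "family": family,
                     "belief_level": level, "mean_final_count": count}
                )
            logger.info("grid cell %s done", cell)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append((cell, repr(exc)))
            logger.error("grid cell %s failed: %s", cell, exc)
    pd.DataFrame(summary_rows).to_csv(out_dir / "final_histograms.csv", index=False)
    manifest.write(out_dir / "manifest.json")
    if failures:
        raise RuntimeError(f"{len(failures)} grid cells failed: {failures}")
    return manifest


# ---------------------------------------------------------------------------
# fixtures

FIXTURE_NAMES = ("fig2-toy", "line-chain", "two-cluster")


def make_fixture(name: str, out_dir=None) -> tuple:
    """Small deterministic belief-annotated graphs used in tests and examples.

    * ``fig2-toy`` — an institution with three strong-belief subscribers plus
      second-hop neighbors of assorted beliefs;
    * ``line-chain`` — a belief-graded chain 6-5-4-3-2-1-0 hanging off the
      institution's one subscriber, for path-probability checks;
    * ``two-cluster`` — two complete 5-cliques (all level 6 vs all level 0)
      bridged by a single edge, a cartoon of belief silos.

    Returns (SocialGraph, Institution); writes edge-list + node CSVs when
    ``out_dir`` is given.
    """
    space = BeliefSpace()
    if name == "line-chain":
        g = nx.path_graph(7)
        beliefs = [6, 5, 4, 3, 2, 1, 0]
    elif name == "two-cluster":
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(4, 5)
        beliefs = [6] * 5 + [0] * 5
    elif name == "fig2-toy":
        # subscribers 0..2 at level 6; their neighbors 3..9 at assorted levels
        g = nx.Graph()
        g.add_nodes_from(range(10))
        g.add_edges_from(
            [(0, 3), (0, 4), (1, 4), (1, 5), (2, 5), (2, 6),
             (3, 7), (4, 8), (5, 9), (6, 9), (0, 1), (1, 2)]
        )
        beliefs = [6, 6, 6, 5, 4, 5, 3, 4, 2, 1]
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    sg = SocialGraph(g, space)
    sg.set_beliefs(beliefs)
    inst = wire_subscribers(sg, Institution(id="i1", belief=6), epsilon=0)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_edgelist_csv(sg, out_dir / f"{name}-edges.csv", out_dir / f"{name}-nodes.csv")
    return sg, inst
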