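"""Simulation configuration: one object that fully determines an experiment.

A :class:`SimulationConfig` (plus a seed) pins down the population size,
graph family, contagion rule, institutional message schedule and horizon, so
any run can be reproduced bit-identically.  Configs round-trip through YAML
or JSON files whose keys mirror the field names.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .contagion import ContagionSpec, preset
from .core import (
    BeliefSpace,
    MessageSchedule,
    build_custom_schedule,
    build_gradual_schedule,
    build_single_schedule,
    build_split_schedule,
)
from .networks import GraphSpec

SCHEDULE_NAMES = ("single", "split", "gradual", "custom")


@dataclass
class SimulationConfig:
    """Defaults reproduce the reference experimental conditions.

    N=500 agents, one institution perceived at strong belief (level 6),
    subscriber distance bound epsilon=0, horizon T=100, a 7-level belief
    scale, DCC contagion on an ER graph with the single message set, 10
    replicates.
    """

    n_agents: int = 500
    n_institutions: int = 1
    institution_belief: int = 6
    epsilon: int = 0
    horizon: int = 100
    belief_resolution: int = 7
    graph_spec: GraphSpec = field(default_factory=GraphSpec)
    contagion_spec: ContagionSpec = field(default_factory=lambda: preset("dcc"))
    schedule_name: str = "single"
    schedule_params: dict = field(default_factory=dict)
    replicates: int = 10
    seed: int | None = None
    trial_mode: str = "once"  # or "per-delivery"
    proportional_snapshot: bool = False
    event_log: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        space = BeliefSpace(self.belief_resolution)
        if self.n_agents < 1 or self.n_institutions < 0 or self.horizon < 0:
            raise ValueError("counts must be positive (n_agents >= 1, horizon >= 0)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        space.validate_level(self.institution_belief)
        if self.schedule_name not in SCHEDULE_NAMES:
            raise ValueError(f"schedule_name must be one of {SCHEDULE_NAMES}")
        if self.trial_mode not in ("once", "per-delivery"):
            raise ValueError("trial_mode must be 'once' or 'per-delivery'")

    @property
    def belief_space(self) -> BeliefSpace:
        return BeliefSpace(self.belief_resolution)

    def build_schedule(self) -> MessageSchedule:
        """Materialize the configured message schedule over the full horizon."""
        space = self.belief_space
        p = dict(self.schedule_params)
        top = space.max_level
        if self.schedule_name == "single":
            return build_single_schedule(self.horizon, p.get("level", top), space)
        if self.schedule_name == "split":
            return build_split_schedule(
                self.horizon, p.get("first", top), p.get("second", 0), space
            )
        if self.schedule_name == "gradual":
            return build_gradual_schedule(
                self.horizon,
                p.get("start", top),
                p.get("end", 0),
                p.get("interval", 10),
                space,
                hold_from=p.get("hold_from"),
            )
        runs = p.get("runs")
        if not runs:
            raise ValueError("custom schedule needs schedule_params['runs'] = [(t, level), ...]")
        return build_custom_schedule(self.horizon, runs, space)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["graph_spec"] = dataclasses.asdict(self.graph_spec)
        d["contagion_spec"] = dataclasses.asdict(self.contagion_spec)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        gs = d.get("graph_spec", {})
        if isinstance(gs, dict):
            d["graph_spec"] = GraphSpec(**gs)
        cs = d.get("contagion_spec", {})
        if isinstance(cs, str):
            d["contagion_spec"] = preset(cs)
        elif isinstance(cs, dict):
            d["contagion_spec"] = ContagionSpec(**cs)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> SimulationConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    # YAML reads custom-schedule runs as lists; schedules want (t, level) pairs
    runs = (data.get("schedule_params") or {}).get("runs")
    if runs is not None:
        data["schedule_params"]["runs"] = [tuple(r) for r in runs]
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
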