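"""Core domain types for public opinion diffusion (POD) simulations.

Beliefs about a single proposition live on a discrete, ordered scale
``{0, ..., R-1}`` (:class:`BeliefSpace`); networked agents each hold one
level, and institutional broadcasters (media-like agents) inject uniquely
identified messages carrying a belief level into the network on a fixed
:class:`MessageSchedule`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_RESOLUTION = 7


@dataclass(frozen=True)
class BeliefSpace:
    """Discrete belief scale with ``resolution`` equally spaced levels.

    Level 0 means strong disbelief in the proposition, level ``R-1`` strong
    belief, and the midpoint ``(R-1)//2`` uncertainty.  The default 7-point
    scale mirrors the Likert-style scales common in opinion surveys; other
    resolutions (2..64 and beyond) are supported for studying how the
    granularity of the scale affects cascade dynamics.
    """

    resolution: int = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        if not isinstance(self.resolution, (int, np.integer)) or self.resolution < 2:
            raise ValueError(f"belief resolution must be an integer >= 2, got {self.resolution!r}")

    @property
    def levels(self) -> np.ndarray:
        return np.arange(self.resolution)

    @property
    def max_level(self) -> int:
        return self.resolution - 1

    @property
    def midpoint(self) -> int:
        """The 'uncertain' level, halfway along the scale."""
        return (self.resolution - 1) // 2

    def validate_level(self, level) -> int:
        if not isinstance(level, (int, np.integer)):
            raise ValueError(f"belief level must be an integer, got {level!r}")
        if not 0 <= level <= self.max_level:
            raise ValueError(
                f"belief level {level} outside scale 0..{self.max_level}"
            )
        return int(level)


@dataclass
class AgentState:
    """One networked agent: a belief level plus a believe/share-once ledger.

    ``processed_messages`` records message uids the agent has already
    believed; a uid enters at most once and never leaves, which is what stops
    a cascade from circulating the same message forever.
    """

    id: int
    belief: int
    processed_messages: set = field(default_factory=set)

    def has_processed(self, uid: int) -> bool:
        return uid in self.processed_messages

    def mark_processed(self, uid: int) -> None:
        self.processed_messages.add(uid)


@dataclass(frozen=True)
class Message:
    """A single institutional broadcast: a belief level with a unique id.

    The uid is minted when the institution broadcasts and is what agents use
    to enforce the believe-once rule; two broadcasts of the same level at
    different timesteps are distinct messages.
    """

    uid: int
    content: int
    origin: str
    emitted_at: int


@dataclass
class MessageSchedule:
    """Maps each timestep ``t`` (1-based) to the belief levels broadcast then.

    The named patterns used throughout the experiments are built by
    :func:`build_single_schedule`, :func:`build_split_schedule` and
    :func:`build_gradual_schedule`; ``custom`` schedules come from explicit
    (timestep, level) runs.
    """

    name: str
    mapping: dict

    @property
    def horizon(self) -> int:
        return max(self.mapping) if self.mapping else 0

    def levels_at(self, t: int) -> tuple:
        if t not in self.mapping:
            raise KeyError(f"schedule '{self.name}' undefined at t={t}")
        return self.mapping[t]

    def emitted_sequence(self) -> list:
        """All levels in timestep order, flattened (one entry per message)."""
        out = []
        for t in sorted(self.mapping):
            out.extend(self.mapping[t])
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, lvl) for t in sorted(self.mapping) for lvl in self.mapping[t]]
        return pd.DataFrame(rows, columns=["t", "level"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_single_schedule(horizon: int, level: int, space: BeliefSpace | None = None) -> MessageSchedule:
    """Constant schedule: the same level at every timestep 1..horizon."""
    space = space or BeliefSpace()
    level = space.validate_level(level)
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    return MessageSchedule("single", {t: (level,) for t in range(1, horizon + 1)})


def build_split_schedule(
    horizon: int, first: int, second: int, space: BeliefSpace | None = None
) -> MessageSchedule:
    """Polarity-flip schedule: ``first`` up to ``horizon//2``, then ``second``."""
    space = space or BeliefSpace()
    first = space.validate_level(first)
    second = space.validate_level(second)
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    half = horizon // 2
    mapping = {t: (first,) if t <= half else (second,) for t in range(1, horizon + 1)}
    return MessageSchedule("split", mapping)


def build_gradual_schedule(
    horizon: int,
    start: int,
    end: int,
    interval: int = 10,
    space: BeliefSpace | None = None,
    hold_from: int | None = None,
) -> MessageSchedule:
    """Stepwise walk: move one level toward ``end`` every ``interval`` steps.

    Once ``end`` is reached it is held for all remaining timesteps.  With the
    defaults (start 6, end 0, interval 10 on a 100-step horizon) the terminal
    level is held from t=61.  ``hold_from``, if given, instead forces ``end``
    from that timestep onward (an alternative reading of how long the tail
    should last).
    """
    space = space or BeliefSpace()
    start = space.validate_level(start)
    end = space.validate_level(end)
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if interval < 1:
        raise ValueError("interval must be >= 1")
    n_steps = abs(start - end)
    direction = 1 if end >= start else -1
    if horizon < interval * n_steps + 1 and n_steps > 0:
        logger.warning(
            "gradual schedule: horizon %d too short to reach level %d from %d "
            "with interval %d; terminal level never held",
            horizon, end, start, interval,
        )
    mapping = {}
    for t in range(1, horizon + 1):
        idx = min((t - 1) // interval, n_steps)
        level = start + direction * idx
        if hold_from is not None and t >= hold_from:
            level = end
        mapping[t] = (level,)
    return MessageSchedule("gradual", mapping)


def build_custom_schedule(
    horizon: int, runs: Sequence, space: BeliefSpace | None = None
) -> MessageSchedule:
    """Schedule from explicit (start_timestep, level) runs.

    Each run ``(t, level)`` means "broadcast ``level`` from timestep ``t``
    until the next run begins".  The first run must start at t=1 so the
    schedule is total over 1..horizon.
    """
    space = space or BeliefSpace()
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    runs = sorted((int(t), space.validate_level(lvl)) for t, lvl in runs)
    if not runs or runs[0][0] != 1:
        raise ValueError("custom schedule runs must start at t=1")
    mapping = {}
    idx = 0
    for t in range(1, horizon + 1):
        while idx + 1 < len(runs) and runs[idx + 1][0] <= t:
            idx += 1
        mapping[t] = (runs[idx][1],)
    return MessageSchedule("custom", mapping)


@dataclass
class Institution:
    """A media-like broadcaster with a perceived belief leaning.

    Agents whose belief lies within ``epsilon`` of ``belief`` at wiring time
    subscribe (directed institution->agent edges); every message the
    institution broadcasts is delivered to all subscribers first, and spreads
    from there by agent-to-agent sharing.
    """

    id: str
    belief: int
    schedule: MessageSchedule | None = None
    subscribers: frozenset = frozenset()
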