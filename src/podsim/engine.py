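"""The cascade engine: institutional broadcasts and within-timestep cascades.

One timestep works like this: each institution mints a fresh uid for every
message its schedule emits at ``t`` and delivers it to all its subscribers.
Any agent that believes a delivery sets its belief to the message content and
shares the original message with all its neighbors; the cascade runs to
exhaustion within the timestep.  An agent believes (and therefore shares) a
given uid at most once.

By default each agent also gets at most one adoption *trial* per uid — the
first delivery decides, later copies of the same uid are ignored — so the
number of exposures that matters is the number of distinct messages an agent
receives over time, not fan-in within one cascade.  ``trial_mode=
"per-delivery"`` switches to independent trials on every delivery until the
agent believes.

Deliveries are processed in deterministic synchronous rounds (breadth-first
from the subscribers) with receivers handled in ascending-id order, so runs
are bit-reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .contagion import COGNITIVE_VARIANTS, ContagionSpec, beta_probability
from .core import BeliefSpace, Institution, Message
from .networks import SocialGraph, build_social_graph, wire_subscribers
from . import contagion as _contagion

OUTCOME_BELIEVED = "believed"
OUTCOME_REJECTED = "rejected"
OUTCOME_DUPLICATE = "ignored-duplicate"

#: sentinel sender id for institution->subscriber deliveries (agents are >= 0);
#: institution k (0-based) is encoded as -(k+1).
INSTITUTION_SENDER = -1


@dataclass
class BeliefTimeseries:
    """Per-timestep counts of agents at each belief level; rows t=0..T.

    Row 0 is the pre-broadcast initial state.  Counts in every row sum to the
    number of agents (beliefs move, agents are never created or destroyed).
    """

    counts: np.ndarray  # shape (T+1, R), int

    @property
    def horizon(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def resolution(self) -> int:
        return self.counts.shape[1]

    @property
    def n_agents(self) -> int:
        return int(self.counts[0].sum())

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    def to_frame(self, replicate: int | None = None) -> pd.DataFrame:
        t_idx, levels = np.meshgrid(
            np.arange(self.horizon + 1), np.arange(self.resolution), indexing="ij"
        )
        df = pd.DataFrame(
            {
                "t": t_idx.ravel(),
                "belief_level": levels.ravel(),
                "count": self.counts.ravel(),
                "fraction": self.fractions.ravel(),
            }
        )
        if replicate is not None:
            df.insert(0, "replicate", replicate)
        return df


@dataclass
class RunResult:
    """Everything one simulation produced: config snapshot, seed, timeseries."""

    config: SimulationConfig
    seed: int
    timeseries: BeliefTimeseries
    events: pd.DataFrame | None = None
    final_beliefs: np.ndarray | None = None


@dataclass
class BatchResult:
    """Replicate runs plus mean/variance of the fraction-believing timeseries."""

    results: list
    mean_fractions: np.ndarray  # (T+1, R)
    var_fractions: np.ndarray  # (T+1, R)

    @property
    def mean_counts(self) -> np.ndarray:
        return np.mean([r.timeseries.counts for r in self.results], axis=0)


class _EventBuffer:
    """Column-wise accumulation of per-delivery cascade events."""

    def __init__(self) -> None:
        self.t: list = []
        self.uid: list = []
        self.sender: list = []
        self.receiver: list = []
        self.outcome: list = []

    def add(self, t: int, uid: int, senders, receivers, outcome: str) -> None:
        n = len(receivers)
        if n == 0:
            return
        self.t.append(np.full(n, t, dtype=np.int64))
        self.uid.append(np.full(n, uid, dtype=np.int64))
        self.sender.append(np.asarray(senders, dtype=np.int64))
        self.receiver.append(np.asarray(receivers, dtype=np.int64))
        self.outcome.extend([outcome] * n)

    def to_frame(self) -> pd.DataFrame:
        if not self.receiver:
            return pd.DataFrame(
                columns=["t", "message_uid", "sender", "receiver", "outcome"]
            )
        return pd.DataFrame(
            {
                "t": np.concatenate(self.t),
                "message_uid": np.concatenate(self.uid),
                "sender": np.concatenate(self.sender),
                "receiver": np.concatenate(self.receiver),
                "outcome": self.outcome,
            }
        )


def _adoption_probs(
    spec: ContagionSpec,
    beliefs: np.ndarray,
    candidates: np.ndarray,
    content: int,
    indptr: np.ndarray,
    indices: np.ndarray,
    ratio_beliefs: np.ndarray,
) -> np.ndarray:
    """Vector of adoption probabilities for the candidate receivers."""
    if spec.variant == "simple":
        return np.full(candidates.size, spec.p)
    if spec.variant == "proportional":
        out = np.zeros(candidates.size)
        for i, u in enumerate(candidates):
            nb = indices[indptr[u]: indptr[u + 1]]
            if nb.size and np.mean(ratio_beliefs[nb] == content) >= spec.ratio_alpha:
                out[i] = 1.0
        return out
    return np.asarray(beta_probability(spec, beliefs[candidates], content), dtype=float)


def _cascade(
    indptr: np.ndarray,
    indices: np.ndarray,
    beliefs: np.ndarray,
    content: int,
    seeds: np.ndarray,
    spec: ContagionSpec,
    rng: np.random.Generator,
    trial_mode: str = "once",
    proportional_snapshot: bool = False,
    events: _EventBuffer | None = None,
    t: int = 0,
    uid: int = 0,
    first_sender: int = INSTITUTION_SENDER,
) -> np.ndarray:
    """Run one message to exhaustion; mutates ``beliefs``; returns believed mask."""
    n = beliefs.size
    believed = np.zeros(n, dtype=bool)
    tried = np.zeros(n, dtype=bool) if trial_mode == "once" else None
    snapshot = beliefs.copy() if proportional_snapshot else beliefs

    receivers = np.sort(np.asarray(list(seeds), dtype=np.int64))
    senders = np.full(receivers.size, first_sender, dtype=np.int64)

    while receivers.size:
        if trial_mode == "once":
            # one trial per (agent, uid): first delivery to an untried agent
            uniq, first_pos = np.unique(receivers, return_index=True)
            eligible = np.zeros(receivers.size, dtype=bool)
            eligible[first_pos] = True
            eligible &= ~tried[receivers]
        else:
            eligible = ~believed[receivers]
        cand_pos = np.flatnonzero(eligible)
        cand = receivers[cand_pos]

        probs = _adoption_probs(spec, beliefs, cand, content, indptr, indices, snapshot)
        draws = rng.random(cand.size)
        success = draws < probs

        # believe-once within the round: only a receiver's first successful
        # delivery counts; its later deliveries this round are duplicates
        # (in per-delivery mode cand may repeat receivers)
        succ_idx = np.flatnonzero(success)
        newly, first_of = np.unique(cand[succ_idx], return_index=True)
        first_success_pos = succ_idx[first_of]
        cutoff = np.full(n, cand.size, dtype=np.int64)
        cutoff[newly] = first_success_pos
        pos = np.arange(cand.size)
        after_belief = pos > cutoff[cand]

        if events is not None:
            dup_pos = np.flatnonzero(~eligible)
            events.add(t, uid, senders[dup_pos], receivers[dup_pos], OUTCOME_DUPLICATE)
            is_believed = np.zeros(cand.size, dtype=bool)
            is_believed[first_success_pos] = True
            rejected = ~success & ~after_belief
            events.add(t, uid, senders[cand_pos[is_believed]], cand[is_believed], OUTCOME_BELIEVED)
            events.add(t, uid, senders[cand_pos[rejected]], cand[rejected], OUTCOME_REJECTED)
            events.add(t, uid, senders[cand_pos[after_belief]], cand[after_belief],
                       OUTCOME_DUPLICATE)

        if trial_mode == "once":
            tried[cand] = True
        if newly.size == 0:
            break
        believed[newly] = True
        beliefs[newly] = content

        # newly-believing agents share the original message with all neighbors
        counts = indptr[newly + 1] - indptr[newly]
        receivers = np.concatenate(
            [indices[indptr[u]: indptr[u + 1]] for u in newly]
        ) if newly.size else np.empty(0, dtype=np.int64)
        senders = np.repeat(newly, counts)

    return believed


def propagate_message(
    sg: SocialGraph,
    message: Message,
    seeds: Sequence[int],
    spec: ContagionSpec,
    rng: np.random.Generator,
    trial_mode: str = "once",
    proportional_snapshot: bool = False,
) -> pd.DataFrame:
    """Cascade one message through a social graph, mutating agent beliefs.

    ``seeds`` are the initial receivers (normally an institution's
    subscribers).  Returns the per-delivery event log with outcomes
    believed / rejected / ignored-duplicate.
    """
    indptr, indices = sg.adjacency_csr()
    beliefs = sg.beliefs
    buf = _EventBuffer()
    _cascade(
        indptr, indices, beliefs, message.content, np.asarray(list(seeds)),
        spec, rng, trial_mode, proportional_snapshot,
        events=buf, t=message.emitted_at, uid=message.uid,
    )
    sg.set_beliefs(beliefs)
    return buf.to_frame()


class _Simulator:
    """Holds the per-run arrays so the timestep loop stays allocation-light."""

    def __init__(self, sg: SocialGraph, institutions: list, config: SimulationConfig,
                 rng: np.random.Generator, events: bool):
        self.indptr, self.indices = sg.adjacency_csr()
        self.beliefs = sg.beliefs
        self.institutions = institutions
        self.config = config
        self.rng = rng
        self.space = config.belief_space
        self.events = _EventBuffer() if events else None
        self._uid = 0
        spec = config.contagion_spec
        if spec.variant in COGNITIVE_VARIANTS and config.belief_resolution != 7:
            spec = _contagion.scale_spec_for_resolution(spec, self.space)
        self.spec = spec

    def histogram(self) -> np.ndarray:
        return np.bincount(self.beliefs, minlength=self.space.resolution)

    def step(self, t: int) -> np.ndarray:
        """Broadcast every scheduled message at ``t`` and return the histogram."""
        for k, inst in enumerate(self.institutions):
            if inst.schedule is None:
                continue
            for level in inst.schedule.levels_at(t):
                self._uid += 1
                seeds = np.fromiter(inst.subscribers, dtype=np.int64, count=len(inst.subscribers))
                _cascade(
                    self.indptr, self.indices, self.beliefs, level, seeds,
                    self.spec, self.rng,
                    trial_mode=self.config.trial_mode,
                    proportional_snapshot=self.config.proportional_snapshot,
                    events=self.events, t=t, uid=self._uid,
                    first_sender=-(k + 1),
                )
        return self.histogram()


def step(
    sg: SocialGraph,
    institutions: Sequence[Institution],
    t: int,
    spec: ContagionSpec,
    rng: np.random.Generator,
    trial_mode: str = "once",
) -> np.ndarray:
    """One public timestep on a SocialGraph: broadcast, cascade, histogram."""
    indptr, indices = sg.adjacency_csr()
    beliefs = sg.beliefs
    uid = getattr(sg, "_uid_counter", 0)
    for k, inst in enumerate(institutions):
        if inst.schedule is None:
            continue
        for level in inst.schedule.levels_at(t):
            uid += 1
            seeds = np.asarray(sorted(inst.subscribers), dtype=np.int64)
            _cascade(indptr, indices, beliefs, level, seeds, spec, rng,
                     trial_mode=trial_mode, t=t, uid=uid, first_sender=-(k + 1))
    sg._uid_counter = uid
    sg.set_beliefs(beliefs)
    return np.bincount(beliefs, minlength=sg.space.resolution)


def setup_simulation(config: SimulationConfig, rng: np.random.Generator) -> tuple:
    """Build the graph, assign beliefs and wire institutions per the config."""
    space = config.belief_space
    sg = build_social_graph(config.graph_spec, config.n_agents, space, rng)
    institutions = []
    schedule = config.build_schedule() if config.horizon >= 1 else None
    for k in range(config.n_institutions):
        inst = Institution(id=f"i{k + 1}", belief=config.institution_belief, schedule=schedule)
        institutions.append(wire_subscribers(sg, inst, config.epsilon))
    return sg, institutions


def run_simulation(config: SimulationConfig, seed: int | None = None) -> RunResult:
    """One full run: graph build, t=0 snapshot, then T broadcast timesteps.

    Fully deterministic given the seed (taken from the config when not passed
    explicitly).
    """
    config.validate()
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(seed)
    sg, institutions = setup_simulation(config, rng)
    sim = _Simulator(sg, institutions, config, rng, events=config.event_log)

    counts = np.zeros((config.horizon + 1, config.belief_resolution), dtype=np.int64)
    counts[0] = sim.histogram()
    for t in range(1, config.horizon + 1):
        counts[t] = sim.step(t)

    events = sim.events.to_frame() if sim.events is not None else None
    return RunResult(
        config=config, seed=seed, timeseries=BeliefTimeseries(counts),
        events=events, final_beliefs=sim.beliefs.copy(),
    )


def run_batch(
    config: SimulationConfig,
    replicates: int | None = None,
    base_seed: int | None = None,
) -> BatchResult:
    """Replicate runs with seeds base_seed + r, plus mean/variance summaries.

    Because replicate r always uses seed base_seed + r, extending a batch
    never perturbs the runs already computed.
    """
    replicates = replicates if replicates is not None else config.replicates
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if base_seed is None:
        base_seed = config.seed if config.seed is not None else 0
    results = [run_simulation(config, seed=base_seed + r) for r in range(replicates)]
    fractions = np.stack([r.timeseries.fractions for r in results])
    return BatchResult(
        results=results,
        mean_fractions=fractions.mean(axis=0),
        var_fractions=fractions.var(axis=0),
    )
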