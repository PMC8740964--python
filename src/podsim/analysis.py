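"""Quantitative apparatus for cascade results.

Why do cognitive cascades look so alike across graph topologies while simple
and proportional cascades do not?  The tools here answer that: the
probability a message survives a whole institution-to-agent path
(:func:`path_probability`), which neighbors of an agent are likely to relay a
message to it (:func:`believing_neighbor_set`), how often random graphs
contain a path of near-message believers reaching an agent
(:func:`path_census`), homophily summaries over graph ensembles, and
similarity measures between belief timeseries from different topologies
(:func:`avg_pearson`, :func:`chi2_timeseries`).
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .contagion import ContagionSpec, beta_probability
from .core import BeliefSpace, Institution
from .engine import BeliefTimeseries
from .networks import GraphSpec, SocialGraph, build_social_graph, homophily_score, wire_subscribers

logger = logging.getLogger(__name__)


def path_probability(spec: ContagionSpec, path_beliefs, message_level: int) -> float:
    """Probability a message survives a chain of agents with the given beliefs.

    The product over path agents of the pairwise adoption probability at
    distance |b_v - message|; the empty path has probability 1.  Under DCC a
    single agent at distance >= 3 collapses the whole chain toward zero.
    """
    beliefs = np.asarray(list(path_beliefs), dtype=float)
    if beliefs.size == 0:
        return 1.0
    probs = np.asarray(beta_probability(spec, beliefs, message_level), dtype=float)
    return float(np.prod(probs))


def _max_path_probability(
    sg: SocialGraph,
    institution: Institution,
    message_level: int,
    spec: ContagionSpec,
    exclude: int | None = None,
) -> dict:
    """Max-product path probability from the institution to every agent.

    Dijkstra under negative-log weights: the cost of entering node v is
    -log beta(b_v, message); subscribers are the entry points.  Nodes with
    beta = 0 are unreachable through (or at) that node.  Ties are resolved by
    ascending node id, so results are deterministic.
    """
    beliefs = sg.beliefs
    logw = {}
    for u in range(sg.n_agents):
        b = float(beta_probability(spec, int(beliefs[u]), message_level))
        logw[u] = -math.log(b) if b > 0.0 else None

    dist: dict[int, float] = {}
    heap = []
    for s in sorted(institution.subscribers):
        if s == exclude or logw[s] is None:
            continue
        heapq.heappush(heap, (logw[s], s))
    while heap:
        d, u = heapq.heappop(heap)
        if u in dist:
            continue
        dist[u] = d
        for v in sg.neighbors(u):
            if v == exclude or v in dist or logw[v] is None:
                continue
            heapq.heappush(heap, (d + logw[v], v))
    return dist


def believing_neighbor_set(
    sg: SocialGraph,
    institution: Institution,
    target: int,
    message_level: int,
    delta: float,
    spec: ContagionSpec,
) -> set:
    """Neighbors of ``target`` likely (within delta) to relay the message to it.

    A neighbor v is included iff the best institution-to-v path (not passing
    through the target itself) carries the message with probability at least
    1 - delta.  Unreachable neighbors have probability 0 and are excluded.
    """
    dist = _max_path_probability(sg, institution, message_level, spec, exclude=target)
    out = set()
    for v in sg.neighbors(target):
        if v in dist and math.exp(-dist[v]) >= 1.0 - delta:
            out.add(v)
    return out


def qualifying_path_exists(
    sg: SocialGraph,
    institution: Institution,
    target: int,
    message_level: int,
    tau: int,
) -> bool:
    """Does a tau-bounded believer path from the institution reach ``target``?

    True iff some neighbor of the target can be reached from a subscriber
    through agents all within belief distance tau of the message.  The target
    itself is exempt from the bound (the path leads *to* it, it need not
    relay), realized as reachability on the induced subgraph of qualifying
    agents with the target removed.
    """
    beliefs = sg.beliefs
    qual = np.abs(beliefs - message_level) <= tau
    qual_nodes = set(np.flatnonzero(qual).tolist())
    qual_nodes.discard(target)

    sources = [s for s in institution.subscribers if s in qual_nodes]
    targets = {v for v in sg.g.neighbors(target) if v in qual_nodes}
    if not sources or not targets:
        return False

    h = sg.g.subgraph(qual_nodes)
    seen = set()
    for comp in nx.connected_components(h):
        if any(s in comp for s in sources):
            seen |= comp
    return bool(seen & targets)


@dataclass
class PathCensusSpec:
    """Ensemble query: how often do random graphs contain a qualifying path?

    One graph at a time: generate, assign uniform beliefs, wire an
    institution at ``message_level`` with distance bound ``epsilon``, pick a
    uniformly random agent at ``target_level``, and ask whether a tau-bounded
    believer path reaches it.
    """

    tau: int
    target_level: int
    message_level: int = 6
    n_graphs: int = 100
    n_agents: int = 500
    belief_resolution: int = 7
    epsilon: int = 0
    delta: float = 0.5
    graph_spec: GraphSpec = field(default_factory=GraphSpec)

    def __post_init__(self) -> None:
        space = BeliefSpace(self.belief_resolution)
        space.validate_level(self.target_level)
        space.validate_level(self.message_level)
        if not 0 <= self.tau <= space.max_level:
            raise ValueError("tau must lie within the belief scale span")
        if self.n_graphs < 1:
            raise ValueError("n_graphs must be >= 1")


def path_census(spec: PathCensusSpec, rng: np.random.Generator) -> float:
    """Fraction of ``n_graphs`` random graphs with a qualifying path.

    Graphs with no agent at the target level are resampled (logged); each
    counted graph contributes one randomly chosen target agent.
    """
    space = BeliefSpace(spec.belief_resolution)
    hits = 0
    counted = 0
    attempts = 0
    max_attempts = spec.n_graphs * 10
    while counted < spec.n_graphs:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("too many resamples: no agents at the target level")
        sg = build_social_graph(spec.graph_spec, spec.n_agents, space, rng)
        inst = wire_subscribers(
            sg, Institution(id="i1", belief=spec.message_level), spec.epsilon
        )
        candidates = np.flatnonzero(sg.beliefs == spec.target_level)
        if candidates.size == 0:
            logger.info("no agent at level %d; resampling graph", spec.target_level)
            continue
        target = int(rng.choice(candidates))
        counted += 1
        if qualifying_path_exists(sg, inst, target, spec.message_level, spec.tau):
            hits += 1
    return hits / spec.n_graphs


# ---------------------------------------------------------------------------
# timeseries similarity


def _as_fractions(ts) -> np.ndarray:
    if isinstance(ts, BeliefTimeseries):
        return ts.fractions
    return np.asarray(ts, dtype=float)


def avg_pearson(ts_a, ts_b) -> float | None:
    """Mean Pearson correlation across belief levels between two timeseries.

    Inputs are (T+1, R) fraction-believing arrays (or BeliefTimeseries);
    levels whose series is exactly constant in either input carry no
    correlation signal and are excluded.  Returns None when every level is
    excluded — i.e. nothing changed from initial conditions on one or both
    sides, so the test cannot be performed.
    """
    a = _as_fractions(ts_a)
    b = _as_fractions(ts_b)
    if a.shape != b.shape:
        raise ValueError(f"timeseries shapes differ: {a.shape} vs {b.shape}")
    coeffs = []
    for level in range(a.shape[1]):
        sa, sb = a[:, level], b[:, level]
        if np.ptp(sa) == 0.0 or np.ptp(sb) == 0.0:
            continue
        coeffs.append(stats.pearsonr(sa, sb).statistic)
    if not coeffs:
        return None
    return float(np.mean(coeffs))


def chi2_timeseries(counts_a, counts_b, significance: float = 0.05) -> float:
    """Fraction of timesteps where the two belief distributions look homogeneous.

    At each timestep the two per-level count vectors form a 2 x R
    contingency table; a chi-square homogeneity test is run (levels empty in
    both rows are dropped; a table with a single occupied level is trivially
    homogeneous).  The score is the fraction of timesteps whose test does
    *not* reject at the given significance — higher means more similar.
    """
    a = counts_a.counts if isinstance(counts_a, BeliefTimeseries) else np.asarray(counts_a)
    b = counts_b.counts if isinstance(counts_b, BeliefTimeseries) else np.asarray(counts_b)
    if a.shape != b.shape:
        raise ValueError(f"count tables differ in shape: {a.shape} vs {b.shape}")
    keep = 0
    total = a.shape[0]
    for t in range(total):
        table = np.stack([a[t], b[t]])
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2 or table.sum(axis=1).min() == 0:
            keep += 1  # degenerate table: nothing to distinguish
            continue
        if np.array_equal(table[0], table[1]):
            keep += 1
            continue
        p = stats.chi2_contingency(table).pvalue
        if p >= significance:
            keep += 1
    return keep / total


def summarize_homophily(
    graph_spec: GraphSpec,
    n_graphs: int,
    rng: np.random.Generator,
    n_agents: int = 500,
    space: BeliefSpace | None = None,
) -> tuple:
    """Mean and variance of the homophily score over a graph ensemble."""
    if n_graphs < 2:
        raise ValueError("need at least 2 graphs for a variance")
    space = space or BeliefSpace()
    scores = []
    for _ in range(n_graphs):
        sg = build_social_graph(graph_spec, n_agents, space, rng)
        scores.append(homophily_score(sg))
    scores = np.asarray(scores)
    return float(scores.mean()), float(scores.var(ddof=1))
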