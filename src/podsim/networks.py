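"""Belief-annotated social graphs: generation, institution wiring, homophily.

Four random-graph families are supported — Erdős–Rényi (ER), Watts–Strogatz
(WS), Barabási–Albert (BA) and a single-attribute Multiplicative Attribute
Graph (MAG) whose edge probabilities depend on the two endpoints' beliefs —
plus graphs loaded from files.  ER/WS/BA construction is delegated to
networkx; the MAG specialization (independent Bernoulli edges with
probability ``theta[b_u][b_v]``) is implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import BeliefSpace, Institution

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GraphSpec:
    """Which graph family to build and with what parameters.

    Defaults match the reference experiments: ER edge probability 0.05, WS
    with 5 initial neighbors and rewiring chance 0.5, BA with 3 edges per new
    node, MAG with the homophilic distance-kernel affinity matrix.
    """

    family: str = "ER"
    er_rho: float = 0.05
    ws_k: int = 5
    ws_rho: float = 0.5
    ba_m: int = 3
    path: str | None = None

    def __post_init__(self) -> None:
        fam = self.family.upper()
        if fam not in ("ER", "WS", "BA", "MAG", "FILE"):
            raise ValueError(f"unknown graph family {self.family!r}")
        object.__setattr__(self, "family", fam)
        if not 0.0 <= self.er_rho <= 1.0:
            raise ValueError("er_rho must be in [0,1]")
        if not 0.0 <= self.ws_rho <= 1.0:
            raise ValueError("ws_rho must be in [0,1]")
        if self.ws_k < 1 or self.ba_m < 1:
            raise ValueError("ws_k and ba_m must be >= 1")
        if fam == "FILE" and not self.path:
            raise ValueError("family='file' requires a path")


@dataclass(frozen=True)
class AffinityMatrix:
    """Edge-probability lookup theta[i][j] for MAG graphs, one row per level."""

    entries: tuple

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("affinity matrix must be square")
        if np.any(arr <= 0) or np.any(arr > 1):
            raise ValueError("affinity entries must lie in (0, 1]")
        if not np.allclose(arr, arr.T):
            raise ValueError("affinity matrix must be symmetric")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.entries, dtype=float)

    @property
    def resolution(self) -> int:
        return len(self.entries)


def default_affinity(space: BeliefSpace | None = None) -> AffinityMatrix:
    """The homophilic distance kernel theta_ij = 1 / (6 + 50 (j - i)^2).

    On the 7-level scale this gives 0.167 on the diagonal decaying to 0.0006
    at distance 6, so like-believing agents connect ~280x more readily than
    opposite-pole ones.
    """
    space = space or BeliefSpace()
    i = np.arange(space.resolution)
    d = np.abs(i[:, None] - i[None, :])
    theta = 1.0 / (6.0 + 50.0 * d.astype(float) ** 2)
    return AffinityMatrix(tuple(map(tuple, theta)))


class SocialGraph:
    """An undirected agent graph plus directed institution->subscriber edges.

    Wraps a :class:`networkx.Graph` whose nodes are agent ids ``0..N-1``,
    each carrying an integer ``belief`` attribute.  Institutions are held
    separately (they are a different kind of entity, not nodes of the social
    graph).
    """

    def __init__(self, graph: nx.Graph, space: BeliefSpace | None = None):
        self.space = space or BeliefSpace()
        n = graph.number_of_nodes()
        if sorted(graph.nodes) != list(range(n)):
            graph = nx.convert_node_labels_to_integers(graph, ordering="sorted")
        self.g = graph
        self.institutions: dict[str, Institution] = {}

    # -- agents -----------------------------------------------------------
    @property
    def n_agents(self) -> int:
        return self.g.number_of_nodes()

    @property
    def beliefs(self) -> np.ndarray:
        return np.array(
            [self.g.nodes[u].get("belief", -1) for u in range(self.n_agents)], dtype=np.int64
        )

    def set_beliefs(self, beliefs) -> None:
        arr = np.asarray(beliefs, dtype=np.int64)
        if arr.shape != (self.n_agents,):
            raise ValueError("belief array length must equal the number of agents")
        if arr.min() < 0 or arr.max() > self.space.max_level:
            raise ValueError("belief outside the belief space")
        for u in range(self.n_agents):
            self.g.nodes[u]["belief"] = int(arr[u])

    def neighbors(self, u: int) -> list:
        return sorted(self.g.neighbors(u))

    def adjacency_csr(self):
        """(indptr, indices) with neighbor lists sorted by id; for the engine."""
        a = nx.to_scipy_sparse_array(self.g, nodelist=range(self.n_agents), format="csr")
        a.sort_indices()
        return a.indptr.astype(np.int64), a.indices.astype(np.int64)

    # -- institutions ------------------------------------------------------
    def add_institution(self, inst: Institution) -> None:
        bad = set(inst.subscribers) - set(range(self.n_agents))
        if bad:
            raise ValueError(f"subscribers {sorted(bad)} are not agents of the graph")
        self.institutions[inst.id] = inst

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SocialGraph(n_agents={self.n_agents}, n_edges={self.g.number_of_edges()}, "
            f"institutions={sorted(self.institutions)})"
        )


# ---------------------------------------------------------------------------
# generation


def _nx_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def assign_beliefs_uniform(
    sg: SocialGraph, space: BeliefSpace | None = None, rng: np.random.Generator | None = None
) -> SocialGraph:
    """Draw each agent's belief i.i.d. uniform over the belief scale."""
    space = space or sg.space
    rng = rng if rng is not None else np.random.default_rng()
    sg.set_beliefs(rng.integers(0, space.resolution, size=sg.n_agents))
    return sg


def generate_er(n: int, rho: float, rng: np.random.Generator) -> SocialGraph:
    """Erdős–Rényi G(n, rho): each unordered pair is an edge with probability rho."""
    if n < 2:
        raise ValueError("need at least 2 agents")
    if rho >= 1.0:
        g = nx.complete_graph(n)
    else:
        g = nx.fast_gnp_random_graph(n, rho, seed=_nx_seed(rng))
    return SocialGraph(g)


def generate_ws(n: int, k: int, rho: float, rng: np.random.Generator) -> SocialGraph:
    """Watts–Strogatz ring lattice with k nearest neighbors and rewiring chance rho."""
    if k >= n:
        raise ValueError("ws_k must be smaller than the number of agents")
    g = nx.watts_strogatz_graph(n, k, rho, seed=_nx_seed(rng))
    return SocialGraph(g)


def generate_ba(n: int, m: int, rng: np.random.Generator) -> SocialGraph:
    """Barabási–Albert preferential attachment with m edges per new node."""
    if m >= n:
        raise ValueError("ba_m must be smaller than the number of agents")
    g = nx.barabasi_albert_graph(n, m, seed=_nx_seed(rng))
    return SocialGraph(g)


def generate_mag(
    n: int, affinity: AffinityMatrix, beliefs, rng: np.random.Generator
) -> SocialGraph:
    """Single-attribute MAG: edge (u,v) with probability theta[b_u][b_v].

    Beliefs must be assigned before edges since edge probabilities depend on
    the endpoint belief pair.
    """
    beliefs = np.asarray(beliefs, dtype=np.int64)
    if beliefs.shape != (n,):
        raise ValueError("need one belief per agent before generating MAG edges")
    if beliefs.max() >= affinity.resolution or beliefs.min() < 0:
        raise ValueError("affinity matrix shape does not cover the belief levels present")
    theta = affinity.array
    iu, ju = np.triu_indices(n, k=1)
    probs = theta[beliefs[iu], beliefs[ju]]
    mask = rng.random(probs.size) < probs
    g = nx.empty_graph(n)
    g.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
    sg = SocialGraph(g, BeliefSpace(affinity.resolution))
    sg.set_beliefs(beliefs)
    return sg


def build_social_graph(
    spec: GraphSpec,
    n: int,
    space: BeliefSpace,
    rng: np.random.Generator,
    affinity: AffinityMatrix | None = None,
) -> SocialGraph:
    """Generate a graph of the requested family with uniform beliefs assigned.

    For MAG, beliefs are drawn first (edges depend on them); for the other
    families the graph is built first and beliefs assigned afterwards.
    """
    if spec.family == "MAG":
        affinity = affinity or default_affinity(space)
        beliefs = rng.integers(0, space.resolution, size=n)
        return generate_mag(n, affinity, beliefs, rng)
    if spec.family == "ER":
        sg = generate_er(n, spec.er_rho, rng)
    elif spec.family == "WS":
        sg = generate_ws(n, spec.ws_k, spec.ws_rho, rng)
    elif spec.family == "BA":
        sg = generate_ba(n, spec.ba_m, rng)
    elif spec.family == "FILE":
        sg = read_graphml(spec.path)
        if sg.n_agents != n:
            logger.warning("file graph has %d agents (config says %d)", sg.n_agents, n)
        return sg
    else:  # pragma: no cover
        raise ValueError(spec.family)
    sg.space = space
    assign_beliefs_uniform(sg, space, rng)
    return sg


# ---------------------------------------------------------------------------
# institutions and homophily


def wire_subscribers(sg: SocialGraph, institution: Institution, epsilon: int = 0) -> Institution:
    """Subscribe every agent within belief distance epsilon of the institution.

    With epsilon=0 subscribers are exactly the agents sharing the
    institution's belief.  The subscriber set is frozen at wiring time; later
    belief changes do not unsubscribe anyone.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    beliefs = sg.beliefs
    subs = frozenset(np.flatnonzero(np.abs(beliefs - institution.belief) <= epsilon).tolist())
    if not subs:
        logger.warning(
            "institution %s has no subscribers (no agent within %d of belief %d); "
            "its cascades will be inert",
            institution.id, epsilon, institution.belief,
        )
    wired = Institution(
        id=institution.id, belief=institution.belief,
        schedule=institution.schedule, subscribers=subs,
    )
    sg.add_institution(wired)
    return wired


def homophily_score(sg: SocialGraph) -> float:
    """Mean |b_u - b_v| over adjacent pairs; lower means more homophilic.

    Undefined (raises) on an edgeless graph rather than silently returning 0.
    """
    if sg.g.number_of_edges() == 0:
        raise ValueError("homophily score undefined for a graph with no edges")
    beliefs = sg.beliefs
    edges = np.asarray(sg.g.edges, dtype=np.int64)
    return float(np.mean(np.abs(beliefs[edges[:, 0]] - beliefs[edges[:, 1]])))


# ---------------------------------------------------------------------------
# file IO


def write_graphml(sg: SocialGraph, path) -> None:
    nx.write_graphml(sg.g, path)


def read_graphml(path) -> SocialGraph:
    g = nx.read_graphml(path, node_type=int)
    sg = SocialGraph(nx.Graph(g))
    beliefs = [int(g.nodes[u]["belief"]) for u in sorted(g.nodes)]
    sg.space = BeliefSpace(max(max(beliefs) + 1, 2))
    sg.set_beliefs(beliefs)
    return sg


def write_edgelist_csv(sg: SocialGraph, edges_path, nodes_path) -> None:
    """Two-file plain-text form: `src,dst` edge list and `id,belief` node table."""
    edges = pd.DataFrame(sorted(sg.g.edges), columns=["src", "dst"])
    edges.to_csv(edges_path, index=False)
    nodes = pd.DataFrame({"id": range(sg.n_agents), "belief": sg.beliefs})
    nodes.to_csv(nodes_path, index=False)


def read_edgelist_csv(edges_path, nodes_path) -> SocialGraph:
    edges = pd.read_csv(edges_path)
    nodes = pd.read_csv(nodes_path).sort_values("id")
    g = nx.empty_graph(len(nodes))
    g.add_edges_from(edges[["src", "dst"]].itertuples(index=False, name=None))
    beliefs = nodes["belief"].to_numpy()
    sg = SocialGraph(g, BeliefSpace(max(int(beliefs.max()) + 1, 2)))
    sg.set_beliefs(beliefs)
    return sg
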