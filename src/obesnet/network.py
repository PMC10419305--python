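"""Emergent dynamic social contact network.

Each monthly time slot, every agent issues a fixed number of link offers to
candidate partners.  Candidacy and acceptance encode four social
constructs:

propinquity
    only agents within Euclidean distance ``ra`` on the fixed square map
    are candidates;
homophily
    a deterministic indicator: the gender-pair-weighted BMI difference
    must not exceed ``theta_trigger``;
memory
    offers are targeted, and accepted, with probability
    ``min(1, baseline_prob + theta_mem * alpha)`` where ``alpha`` is the
    windowed edge weight (contacts in the last ``memory_window`` slots
    divided by the window length) — repeated interaction breeds repeated
    interaction;
capacity
    an agent accepts at most ``s_max`` offers per slot, in uniformly
    random order when oversubscribed.

The network itself is *derived*: an edge exists between two agents
whenever their windowed weight is positive, and all topography metrics are
computed on that induced simple graph.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from pydantic import BaseModel, Field, field_validator
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .groups import Gender
from .population import Agent, Population

__all__ = [
    "NetworkMetrics",
    "NetworkParams",
    "NetworkState",
    "bmi_colour_class",
    "build_graph",
    "compute_metrics",
    "export_network",
    "homophily_indicator",
    "memory_probability",
    "neighbourhood",
    "propinquity_set",
    "read_edge_list",
    "step_network",
]


class NetworkParams(BaseModel):
    """Structural and calibratable parameters of the contact network.

    ``theta_bmiadj`` holds the four gender-pair homophily weights in the
    order male->male, male->female, female->female, female->male; a zero
    weight disables BMI homophily for that pair (the "no homophily"
    ablation sets all four to zero).
    """

    ra: float = Field(default=2.3, gt=0.0, description="social range (map units)")
    s_max: int = Field(default=4, ge=0, description="max offers accepted per slot")
    memory_window: int = Field(default=12, ge=1, description="memory window M (months)")
    z: float = Field(default=25.0, gt=0.0, description="map side length")
    offers_per_step: int = Field(default=3, ge=0)
    theta_trigger: float = Field(default=8.0, ge=0.0)
    theta_bmiadj: list[float] = Field(default=[1.0, 1.0, 1.0, 1.0])
    theta_mem: float = Field(default=1.0, ge=0.0)
    baseline_prob: float = Field(default=0.35, ge=0.0, le=1.0)
    #: minimum windowed weight for an edge of the derived simple graph
    neighbour_weight_min: float = Field(default=0.0, ge=0.0)

    @field_validator("theta_bmiadj")
    @classmethod
    def _check_bmiadj(cls, v):
        if len(v) != 4:
            raise ValueError("theta_bmiadj needs 4 weights (mm, mf, ff, fm)")
        if any(w < 0 for w in v):
            raise ValueError("theta_bmiadj weights must be non-negative")
        return v

    def bmiadj_matrix(self) -> np.ndarray:
        """2x2 matrix indexed [source gender, target gender]."""
        mm, mf, ff, fm = self.theta_bmiadj
        return np.array([[mm, mf], [fm, ff]])


class NetworkState:
    """Interaction histories and derived windowed edge weights.

    Holds a dense contact-count matrix over the rolling memory window plus
    the per-slot interaction log needed to retire old slots.  Interactions
    are undirected events; both participants log them.
    """

    def __init__(self, n: int, memory_window: int):
        if memory_window < 1:
            raise ConfigurationError("memory window must be >= 1")
        self.memory_window = memory_window
        self.counts = np.zeros((n, n), dtype=np.int32)
        self.slots: deque[tuple[np.ndarray, np.ndarray]] = deque()
        self.slot_index = 0

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    def record_slot(self, src: np.ndarray, dst: np.ndarray) -> None:
        """Append one slot of accepted interactions and roll the window."""
        src = np.asarray(src, dtype=np.int64)
        dst = np.asarray(dst, dtype=np.int64)
        np.add.at(self.counts, (src, dst), 1)
        np.add.at(self.counts, (dst, src), 1)
        self.slots.append((src, dst))
        self.slot_index += 1
        while len(self.slots) > self.memory_window:
            old_src, old_dst = self.slots.popleft()
            np.subtract.at(self.counts, (old_src, old_dst), 1)
            np.subtract.at(self.counts, (old_dst, old_src), 1)

    def grow(self, new_n: int) -> None:
        if new_n < self.n:
            raise ValueError("cannot shrink state")
        if new_n == self.n:
            return
        counts = np.zeros((new_n, new_n), dtype=np.int32)
        counts[: self.n, : self.n] = self.counts
        self.counts = counts

    def drop_agents(self, indices: Iterable[int]) -> None:
        """Remove dead agents from all histories and derived weights."""
        idx = np.fromiter(indices, dtype=np.int64)
        if idx.size == 0:
            return
        self.counts[idx, :] = 0
        self.counts[:, idx] = 0
        dead = np.zeros(self.n, dtype=bool)
        dead[idx] = True
        self.slots = deque(
            (s[~(dead[s] | dead[d])], d[~(dead[s] | dead[d])]) for s, d in self.slots
        )

    def edge_weight(self, i: int, j: int) -> float:
        """Windowed weight alpha = contacts within window / window length."""
        return float(self.counts[i, j]) / self.memory_window

    @property
    def alpha(self) -> np.ndarray:
        return self.counts / float(self.memory_window)

    def history(self, i: int) -> list[np.ndarray]:
        """Per-slot partner lists for agent ``i`` (oldest first)."""
        out = []
        for s, d in self.slots:
            partners = np.concatenate([d[s == i], s[d == i]])
            out.append(np.sort(partners))
        return out

    @classmethod
    def from_interactions(
        cls, n: int, memory_window: int,
        slots: Sequence[Sequence[tuple[int, int]]],
    ) -> "NetworkState":
        """Build a state from explicit per-slot (p, q) interaction lists."""
        state = cls(n, memory_window)
        for slot in slots:
            if slot:
                src, dst = (np.asarray(x, dtype=np.int64) for x in zip(*slot))
            else:
                src = dst = np.empty(0, dtype=np.int64)
            state.record_slot(src, dst)
        return state


# ---------------------------------------------------------------------------
# per-agent operations (inspection views; the engine uses the vector path)
# ---------------------------------------------------------------------------

def propinquity_set(p: Agent, agents: Sequence[Agent], ra: float) -> set[int]:
    """Ids of other living agents strictly within Euclidean range ``ra``."""
    out = set()
    for q in agents:
        if q.id == p.id or not q.alive:
            continue
        if (p.pos_x - q.pos_x) ** 2 + (p.pos_y - q.pos_y) ** 2 < ra**2:
            out.add(q.id)
    return out


def homophily_indicator(p: Agent, q: Agent, theta_trigger: float,
                        theta_bmiadj: Sequence[float] | np.ndarray) -> int:
    """1 iff the gender-weighted BMI gap does not exceed the trigger.

    Directional: the weight looked up is for the (p's gender -> q's
    gender) pair, so the indicator is symmetric only when the two directed
    weights agree.
    """
    w = np.asarray(theta_bmiadj, dtype=float)
    mat = w if w.shape == (2, 2) else np.array([[w[0], w[1]], [w[3], w[2]]])
    weight = mat[int(p.gender), int(q.gender)]
    return int(weight * abs(p.bmi - q.bmi) <= theta_trigger)


def memory_probability(p: Agent | int, q: Agent | int, history: NetworkState,
                       theta_mem: float, baseline_prob: float) -> float:
    """Acceptance probability min(1, baseline + theta_mem * alpha(p, q))."""
    i = p.id if isinstance(p, Agent) else int(p)
    j = q.id if isinstance(q, Agent) else int(q)
    return min(1.0, baseline_prob + theta_mem * history.edge_weight(i, j))


def neighbourhood(p: Agent | int, history: NetworkState,
                  alive: np.ndarray | None = None,
                  weight_min: float = 0.0) -> set[int]:
    """Current network neighbourhood: partners with windowed weight > threshold."""
    i = p.id if isinstance(p, Agent) else int(p)
    alpha_row = history.counts[i] / history.memory_window
    mask = alpha_row > weight_min
    mask[i] = False
    if alive is not None:
        mask &= np.asarray(alive, dtype=bool)
    return set(np.flatnonzero(mask).tolist())


# ---------------------------------------------------------------------------
# vectorised stepping
# ---------------------------------------------------------------------------

class CandidateIndex:
    """Static propinquity pairs (directed, sorted by source).

    Positions are fixed for life, so the spatial pair set only changes at
    demographic events; the simulator rebuilds this index then.
    """

    def __init__(self, pop: Population, ra: float):
        alive_idx = np.flatnonzero(pop.alive)
        points = np.column_stack([pop.pos_x[alive_idx], pop.pos_y[alive_idx]])
        if len(alive_idx) >= 2:
            tree = cKDTree(points)
            local_pairs = tree.query_pairs(ra, output_type="ndarray")
            # query_pairs uses distance <= r; the propinquity definition is
            # strict, so drop exact-boundary pairs (measure zero in practice)
            if len(local_pairs):
                d2 = np.sum((points[local_pairs[:, 0]] - points[local_pairs[:, 1]]) ** 2, axis=1)
                local_pairs = local_pairs[d2 < ra**2]
        else:
            local_pairs = np.empty((0, 2), dtype=np.int64)
        pairs = alive_idx[local_pairs] if len(local_pairs) else np.empty((0, 2), dtype=np.int64)
        src = np.concatenate([pairs[:, 0], pairs[:, 1]])
        dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
        order = np.argsort(src, kind="stable")
        self.src = src[order]
        self.dst = dst[order]


def _segment_sample(src: np.ndarray, weights: np.ndarray, rounds: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """For each distinct source, draw ``rounds`` indices into the pair
    arrays with probability proportional to ``weights`` (with replacement).

    ``src`` must be sorted.  Returns (offer source rows, pair indices).
    """
    if len(src) == 0 or rounds == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    cw = np.cumsum(weights)
    uniq, start = np.unique(src, return_index=True)
    end = np.append(start[1:], len(src))
    base = np.where(start > 0, cw[start - 1], 0.0)
    totals = cw[end - 1] - base
    ok = totals > 0
    uniq, start, end, base, totals = (a[ok] for a in (uniq, start, end, base, totals))
    if len(uniq) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    srcs, picks = [], []
    for _ in range(rounds):
        target = base + rng.random(len(uniq)) * totals
        idx = np.searchsorted(cw, target, side="right")
        idx = np.minimum(np.maximum(idx, start), end - 1)
        srcs.append(uniq)
        picks.append(idx)
    return np.concatenate(srcs), np.concatenate(picks)


def step_network(pop: Population, params: NetworkParams, state: NetworkState,
                 rng: np.random.Generator,
                 index: CandidateIndex | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Advance the network by one time slot.

    Every living agent issues ``offers_per_step`` offers to candidates in
    its propinquity set that pass the homophily indicator, targeting them
    with probability proportional to the memory probability.  Offerees
    accept with that same probability, capped at ``s_max`` acceptances per
    slot (excess offers resolved in uniformly random order).  Accepted
    interactions are appended to both agents' histories and the memory
    window is rolled.

    Returns the accepted (source, target) index arrays for the slot.
    """
    if index is None:
        index = CandidateIndex(pop, params.ra)
    empty = np.empty(0, dtype=np.int64)
    if params.s_max == 0 or params.offers_per_step == 0 or len(index.src) == 0:
        state.record_slot(empty, empty)
        return empty, empty

    bmi = pop.bmi
    adj = params.bmiadj_matrix()
    w_pair = adj[pop.gender[index.src], pop.gender[index.dst]]
    eligible = w_pair * np.abs(bmi[index.src] - bmi[index.dst]) <= params.theta_trigger
    src_e, dst_e = index.src[eligible], index.dst[eligible]
    if len(src_e) == 0:
        state.record_slot(empty, empty)
        return empty, empty

    alpha = state.counts[src_e, dst_e] / state.memory_window
    prob = np.minimum(1.0, params.baseline_prob + params.theta_mem * alpha)

    off_src_rows, pick = _segment_sample(src_e, prob, params.offers_per_step, rng)
    if len(pick) == 0:
        state.record_slot(empty, empty)
        return empty, empty
    off_src = src_e[pick]
    off_dst = dst_e[pick]

    accept_u = rng.random(len(pick))
    passed = accept_u < prob[pick]
    off_src, off_dst = off_src[passed], off_dst[passed]
    if len(off_src) == 0:
        state.record_slot(empty, empty)
        return empty, empty

    # capacity: process offers in uniformly random order, keep the first
    # s_max per acceptor
    perm = rng.permutation(len(off_src))
    order = perm[np.argsort(off_dst[perm], kind="stable")]
    dst_sorted = off_dst[order]
    boundaries = np.flatnonzero(np.diff(dst_sorted)) + 1
    starts = np.concatenate([[0], boundaries])
    group_start = np.repeat(starts, np.diff(np.append(starts, len(dst_sorted))))
    rank = np.arange(len(dst_sorted)) - group_start
    keep = order[rank < params.s_max]
    acc_src, acc_dst = off_src[keep], off_dst[keep]
    state.record_slot(acc_src, acc_dst)
    return acc_src, acc_dst


# ---------------------------------------------------------------------------
# derived graph and topography metrics
# ---------------------------------------------------------------------------

@dataclass
class NetworkMetrics:
    """Topography metrics of the derived simple graph.

    Undefined quantities (too few nodes, zero variance) are NaN.
    """

    clustering: float
    transitivity: float
    degree_assortativity: float
    bmi_assortativity: float
    average_degree: float

    def as_dict(self) -> dict[str, float]:
        return {
            "clustering": self.clustering,
            "transitivity": self.transitivity,
            "degree_assortativity": self.degree_assortativity,
            "bmi_assortativity": self.bmi_assortativity,
            "average_degree": self.average_degree,
        }


def build_graph(pop: Population, state: NetworkState,
                weight_min: float = 0.0) -> nx.Graph:
    """Simple undirected graph induced by the network neighbourhoods.

    Nodes are all living agents (isolates included); edges carry the
    windowed weight ``alpha`` and exist where ``alpha > weight_min``.
    """
    alive_idx = np.flatnonzero(pop.alive)
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in alive_idx)
    counts = state.counts
    threshold = weight_min * state.memory_window
    sub = counts[np.ix_(alive_idx, alive_idx)]
    ii, jj = np.nonzero(np.triu(sub, k=1) > threshold)
    for i, j in zip(alive_idx[ii], alive_idx[jj]):
        g.add_edge(int(i), int(j), weight=state.edge_weight(i, j))
    return g


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def compute_metrics(pop: Population, state: NetworkState,
                    weight_min: float | None = None,
                    graph: nx.Graph | None = None) -> NetworkMetrics:
    """Topography metrics on the derived simple graph.

    ``clustering`` is the mean local clustering coefficient over agents
    with at least two neighbours — the per-node ratio of realised to
    possible links within the neighbourhood is undefined (0/0) below
    degree two, so such nodes are excluded from the mean rather than
    counted as zero.  ``transitivity`` is the global closed-triplet
    ratio, the assortativities are Pearson correlations over edge-end
    (degree, degree) and (BMI, BMI) pairs, and ``average_degree`` the
    mean neighbourhood size (isolates included).
    """
    if graph is None:
        graph = build_graph(pop, state, weight_min if weight_min is not None else 0.0)
    n = graph.number_of_nodes()
    nan = float("nan")
    if n < 2:
        return NetworkMetrics(nan, nan, nan, nan, nan)
    m = graph.number_of_edges()
    average_degree = 2.0 * m / n
    if n < 3:
        clustering = transitivity = nan
    else:
        local = nx.clustering(graph)
        defined = [c for node, c in local.items() if graph.degree(node) >= 2]
        clustering = float(np.mean(defined)) if defined else nan
        transitivity = nx.transitivity(graph)
    if m >= 1:
        deg = dict(graph.degree())
        ends = np.array([(deg[u], deg[v]) for u, v in graph.edges()], dtype=float)
        du = np.concatenate([ends[:, 0], ends[:, 1]])
        dv = np.concatenate([ends[:, 1], ends[:, 0]])
        degree_assortativity = _pearson(du, dv)
        bmi = pop.bmi
        bu = np.array([bmi[u] for u, _ in graph.edges()])
        bv = np.array([bmi[v] for _, v in graph.edges()])
        bmi_assortativity = _pearson(np.concatenate([bu, bv]), np.concatenate([bv, bu]))
    else:
        degree_assortativity = bmi_assortativity = nan
    return NetworkMetrics(
        clustering=float(clustering),
        transitivity=float(transitivity),
        degree_assortativity=degree_assortativity,
        bmi_assortativity=bmi_assortativity,
        average_degree=float(average_degree),
    )


def bmi_colour_class(bmi: float) -> str:
    """Display class used for network plots: green < 25, orange >= 25,
    red > 30, black > 40 (morbid obesity)."""
    if bmi > 40:
        return "black"
    if bmi > 30:
        return "red"
    if bmi >= 25:
        return "orange"
    return "green"


def export_network(pop: Population, state: NetworkState, path, fmt: str = "edgelist",
                   weight_min: float = 0.0) -> None:
    """Write the derived weighted graph as a TSV edge list or GraphML.

    GraphML nodes carry age, gender, BMI and the BMI colour class.
    """
    graph = build_graph(pop, state, weight_min)
    path = Path(path)
    if fmt == "edgelist":
        with open(path, "w") as fh:
            fh.write("source_id\ttarget_id\tweight\n")
            for u, v, data in sorted(graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{data['weight']:.10g}\n")
    elif fmt == "graphml":
        bmi = pop.bmi
        for node in graph.nodes():
            graph.nodes[node]["age"] = float(pop.age[node])
            graph.nodes[node]["gender"] = str(Gender(int(pop.gender[node])))
            graph.nodes[node]["bmi"] = float(bmi[node])
            graph.nodes[node]["bmi_class"] = bmi_colour_class(float(bmi[node]))
        nx.write_graphml(graph, path)
    else:
        raise ConfigurationError(f"unknown export format {fmt!r} (edgelist, graphml)")


def read_edge_list(path) -> nx.Graph:
    """Read a TSV edge list written by :func:`export_network`."""
    graph = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("source_id"):
            raise ConfigurationError(f"{path}: not an obesnet edge list")
        for line in fh:
            u, v, w = line.split("\t")
            graph.add_edge(int(u), int(v), weight=float(w))
    return graph
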