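"""Ancestry-group assignment: PC-plane density clustering and IBD communities.

Two complementary stages mirror how population groups are delineated in
large biobanks:

* **DBSCAN on the top-2 principal components** selects the dense "core"
  genetic cluster of a candidate group (declared ethnicity or country of
  birth), discarding admixed or mislabelled outliers as noise.
* **Community detection on the IBD-sharing graph** partitions individuals
  by recent shared ancestry.  Nodes are individuals; the edge weight is the
  summed length of identity-by-descent segments strictly between 3 and
  30 cM (short segments are unreliable calls, very long ones indicate close
  relatives rather than population structure).  Communities are found with
  a Leiden-style algorithm (local moving, refinement, aggregation) that
  optimises weighted modularity at a resolution parameter, and are then
  annotated by majority vote of reference samples with known origins.

Both algorithms are implemented here in full; the implementations are
deliberately deterministic given a seed so that assignments are
reproducible run to run.
"""

from __future__ import annotations

import logging
from collections import defaultdict, deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptySelectionError, ValidationError

__all__ = [
    "PCPoint",
    "Partition",
    "dbscan",
    "select_core_cluster",
    "build_ibd_graph",
    "modularity",
    "detect_communities",
    "annotate_communities",
]

logger = logging.getLogger(__name__)

NOISE = -1


@dataclass(frozen=True)
class PCPoint:
    """A sample's coordinates in the top-2 principal-component plane."""

    id: str
    pc1: float
    pc2: float
    declared_group: str | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pc1) and np.isfinite(self.pc2)):
            raise ValidationError(f"non-finite PC coordinates for {self.id}")


def _as_points_frame(points) -> pd.DataFrame:
    if isinstance(points, pd.DataFrame):
        df = points[["id", "pc1", "pc2"]].copy()
    else:
        df = pd.DataFrame(
            [(p.id, p.pc1, p.pc2) for p in points], columns=["id", "pc1", "pc2"]
        )
    if df["id"].duplicated().any():
        raise ValidationError("duplicate point ids")
    return df.sort_values("id", kind="stable").reset_index(drop=True)


def dbscan(
    points: Sequence[PCPoint] | pd.DataFrame, eps: float, min_pts: int
) -> dict[str, int]:
    """Density-based clustering with noise, on 2-D Euclidean coordinates.

    A point is *core* when at least ``min_pts`` points (itself included)
    lie within ``eps``.  Clusters are the connected components of core
    points under the within-``eps`` relation, numbered 0, 1, ... in order
    of their smallest member id.  A non-core point within ``eps`` of a core
    point is a *border* point and joins the cluster of its smallest-id core
    neighbour (a deterministic, input-order-invariant tie rule); all other
    points are labelled noise (-1).

    Returns a mapping id -> cluster label.
    """
    if eps <= 0:
        raise ValidationError("eps must be positive")
    if min_pts < 1:
        raise ValidationError("min_pts must be >= 1")
    df = _as_points_frame(points)
    n = len(df)
    if n == 0:
        return {}
    coords = df[["pc1", "pc2"]].to_numpy()
    tree = cKDTree(coords)
    neighbours = tree.query_ball_point(coords, r=eps)  # includes self
    neighbours = [sorted(nb) for nb in neighbours]
    core = np.array([len(nb) >= min_pts for nb in neighbours])

    labels = np.full(n, NOISE)
    cluster = 0
    for i in range(n):  # ids are sorted, so clusters number by smallest member id
        if not core[i] or labels[i] != NOISE:
            continue
        queue = deque([i])
        labels[i] = cluster
        while queue:
            j = queue.popleft()
            for k in neighbours[j]:
                if core[k] and labels[k] == NOISE:
                    labels[k] = cluster
                    queue.append(k)
        cluster += 1
    # border points: smallest-id core neighbour decides the cluster
    for i in range(n):
        if core[i]:
            continue
        core_nb = [k for k in neighbours[i] if core[k]]
        labels[i] = labels[core_nb[0]] if core_nb else NOISE
    return dict(zip(df["id"], (int(l) for l in labels)))


def select_core_cluster(
    labels: Mapping[str, int], seed_group: Iterable[str]
) -> list[str]:
    """Retain the cluster holding the largest share of the seed group.

    The seed group is the set of samples with the candidate label (e.g. a
    declared ethnicity); the returned ids are every member of the winning
    cluster.  Ties go to the smallest cluster label and are logged; if all
    seed members are noise there is nothing to select.
    """
    seed = [s for s in seed_group if s in labels]
    votes: dict[int, int] = defaultdict(int)
    for s in seed:
        if labels[s] != NOISE:
            votes[labels[s]] += 1
    if not votes:
        raise EmptySelectionError("every seed-group member was labelled noise")
    best = max(votes.values())
    winners = sorted(c for c, v in votes.items() if v == best)
    if len(winners) > 1:
        logger.info("seed-group tie between clusters %s; keeping %d", winners, winners[0])
    keep = winners[0]
    return sorted(i for i, c in labels.items() if c == keep)


def build_ibd_graph(
    segments: pd.DataFrame, min_cm: float = 3.0, max_cm: float = 30.0
) -> nx.Graph:
    """Sum filtered IBD segment lengths into an undirected weighted graph.

    Only segments with ``min_cm < length < max_cm`` (strict bounds) are
    retained; the edge weight for a pair is the sum of its retained segment
    lengths in cM.  Self-pairs are rejected.
    """
    required = {"id_a", "id_b", "length_cm"}
    if not required <= set(segments.columns):
        raise ValidationError(f"segments need columns {sorted(required)}")
    if (segments["id_a"] == segments["id_b"]).any():
        raise ValidationError("self-pair in segment list")
    kept = segments[(segments["length_cm"] > min_cm) & (segments["length_cm"] < max_cm)]
    g = nx.Graph()
    # canonical (min, max) pair ordering so A-B and B-A accumulate together
    a = kept["id_a"].to_numpy()
    b = kept["id_b"].to_numpy()
    swap = a > b
    lo = np.where(swap, b, a)
    hi = np.where(swap, a, b)
    summed = (
        pd.DataFrame({"lo": lo, "hi": hi, "w": kept["length_cm"].to_numpy()})
        .groupby(["lo", "hi"], sort=True)["w"]
        .sum()
    )
    for (u, v), w in summed.items():
        g.add_edge(u, v, weight=float(w))
    return g


@dataclass
class Partition:
    """A community assignment with its (weighted) modularity."""

    membership: dict[str, int] = field(default_factory=dict)
    modularity: float = 0.0

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = defaultdict(list)
        for node, c in self.membership.items():
            out[c].append(node)
        return {c: sorted(members) for c, members in out.items()}


def modularity(
    graph: nx.Graph, membership: Mapping[str, int], resolution: float = 1.0
) -> float:
    """Weighted Newman-Girvan modularity of a node partition.

    Q = Σ_c [ w_in(c)/m  −  γ (d(c) / 2m)² ], with w_in the internal edge
    weight, d the summed weighted degree and m the total edge weight.
    """
    m = graph.size(weight="weight")
    if m == 0:
        return 0.0
    w_in: dict[int, float] = defaultdict(float)
    deg: dict[int, float] = defaultdict(float)
    for node, c in membership.items():
        deg[c] += graph.degree(node, weight="weight")
    for u, v, w in graph.edges(data="weight", default=1.0):
        if membership[u] == membership[v]:
            w_in[membership[u]] += w
    return sum(
        w_in.get(c, 0.0) / m - resolution * (d / (2.0 * m)) ** 2
        for c, d in deg.items()
    )


# ---------------------------------------------------------------------------
# Leiden-style optimiser internals.  The graph is flattened to integer nodes
# and repeatedly (1) greedily moved node-by-node, (2) refined within
# communities, (3) aggregated, until modularity stops improving.
# ---------------------------------------------------------------------------


class _Agg:
    """Aggregated graph level: integer nodes, adjacency dicts, self-loops."""

    def __init__(self, n: int):
        self.n = n
        self.adj: list[dict[int, float]] = [dict() for _ in range(n)]
        self.self_w = np.zeros(n)  # collapsed internal weight
        self.strength = np.zeros(n)  # Σ adjacent weight + 2·self_w
        self.m2 = 0.0  # total degree = 2 · total weight

    def add_edge(self, u: int, v: int, w: float) -> None:
        if u == v:
            self.self_w[u] += w
        else:
            self.adj[u][v] = self.adj[u].get(v, 0.0) + w
            self.adj[v][u] = self.adj[v].get(u, 0.0) + w

    def finalise(self) -> None:
        for i in range(self.n):
            self.strength[i] = sum(self.adj[i].values()) + 2.0 * self.self_w[i]
        self.m2 = float(self.strength.sum())


def _local_move(agg: _Agg, memb: np.ndarray, order: np.ndarray, gamma: float) -> bool:
    """Greedy node moves (queue-based) until no move improves modularity."""
    comm_tot = np.zeros(agg.n)
    np.add.at(comm_tot, memb, agg.strength)
    queue = deque(order)
    queued = np.ones(agg.n, dtype=bool)
    moved_any = False
    while queue:
        v = queue.popleft()
        queued[v] = False
        c_old = memb[v]
        w_to: dict[int, float] = defaultdict(float)
        for u, w in agg.adj[v].items():
            w_to[memb[u]] += w
        comm_tot[c_old] -= agg.strength[v]
        best_c, best_gain = c_old, w_to.get(c_old, 0.0) - (
            agg.strength[v] * comm_tot[c_old] * gamma / agg.m2
        )
        for c in sorted(w_to):
            if c == c_old:
                continue
            gain = w_to[c] - agg.strength[v] * comm_tot[c] * gamma / agg.m2
            if gain > best_gain + 1e-12:
                best_c, best_gain = c, gain
        memb[v] = best_c
        comm_tot[best_c] += agg.strength[v]
        if best_c != c_old:
            moved_any = True
            for u in agg.adj[v]:
                if memb[u] != best_c and not queued[u]:
                    queue.append(u)
                    queued[u] = True
    return moved_any


def _refine(agg: _Agg, memb: np.ndarray, gamma: float) -> np.ndarray:
    """Split each community into well-merged sub-communities (singletons up)."""
    sub = np.arange(agg.n)
    sub_tot = agg.strength.copy()
    sub_size = np.ones(agg.n, dtype=int)
    for v in range(agg.n):
        if sub_size[sub[v]] > 1:
            continue  # only isolated nodes may merge, as in Leiden refinement
        w_to: dict[int, float] = defaultdict(float)
        for u, w in agg.adj[v].items():
            if memb[u] == memb[v]:
                w_to[sub[u]] += w
        best_s, best_gain = sub[v], 0.0
        for s in sorted(w_to):
            if s == sub[v]:
                continue
            gain = w_to[s] - agg.strength[v] * sub_tot[s] * gamma / agg.m2
            if gain > best_gain + 1e-12:
                best_s, best_gain = s, gain
        if best_s != sub[v]:
            sub_tot[sub[v]] -= agg.strength[v]
            sub_tot[best_s] += agg.strength[v]
            sub_size[sub[v]] -= 1
            sub_size[best_s] += 1
            sub[v] = best_s
    return sub


def _compress(labels: np.ndarray) -> tuple[np.ndarray, int]:
    uniq, dense = np.unique(labels, return_inverse=True)
    return dense, len(uniq)


def _aggregate(
    agg: _Agg, refined: np.ndarray, memb: np.ndarray
) -> tuple[_Agg, np.ndarray, np.ndarray]:
    dense, k = _compress(refined)
    new = _Agg(k)
    for v in range(agg.n):
        if agg.self_w[v]:
            new.add_edge(dense[v], dense[v], agg.self_w[v])
        for u, w in agg.adj[v].items():
            if u < v:
                new.add_edge(dense[v], dense[u], w)
    new.finalise()
    init = np.zeros(k, dtype=int)
    init[dense] = memb  # refined sub-communities inherit their community
    init, _ = _compress(init)
    return new, dense, init


def detect_communities(
    graph: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> Partition:
    """Leiden-style community detection on a weighted IBD-sharing graph.

    Repeats greedy local moving, refinement and aggregation until weighted
    modularity (at the given ``resolution``) stops improving, then runs a
    final local-moving pass on the flat partition so that no single node
    move can improve the objective.  ``seed`` fixes the node visiting
    order.  The returned ``Partition.modularity`` is recomputed from the
    returned membership with :func:`modularity`.
    """
    if resolution <= 0:
        raise ValidationError("resolution must be positive")
    nodes = sorted(graph.nodes)
    if not nodes:
        return Partition({}, 0.0)
    index = {node: i for i, node in enumerate(nodes)}
    n0 = len(nodes)

    def level0() -> _Agg:
        agg = _Agg(n0)
        for u, v, w in graph.edges(data="weight", default=1.0):
            agg.add_edge(index[u], index[v], float(w))
        agg.finalise()
        return agg

    rng = np.random.default_rng(seed)
    agg = level0()
    memb = np.arange(agg.n)
    flat = np.arange(n0)  # original node -> current agg node
    if agg.m2 > 0:
        while True:
            moved = _local_move(agg, memb, rng.permutation(agg.n), resolution)
            n_comms = len(set(memb.tolist()))
            if not moved or n_comms == agg.n:
                break
            refined = _refine(agg, memb, resolution)
            agg, dense, memb = _aggregate(agg, refined, memb)
            flat = dense[flat]
        # final stabilising pass on the flat partition of the original graph
        agg0 = level0()
        memb0, _ = _compress(memb[flat])
        _local_move(agg0, memb0, rng.permutation(n0), resolution)
    else:
        memb0 = np.zeros(n0, dtype=int)

    # relabel 0..k-1 in order of first appearance over sorted node ids
    relabel: dict[int, int] = {}
    membership: dict[str, int] = {}
    for node in nodes:
        c = int(memb0[index[node]])
        if c not in relabel:
            relabel[c] = len(relabel)
        membership[node] = relabel[c]
    return Partition(membership, modularity(graph, membership, resolution))


def annotate_communities(
    partition: Partition, reference_labels: Mapping[str, str]
) -> dict[int, str]:
    """Name each community by majority vote of its reference samples.

    Communities without any labelled reference are named ``"unlabelled"``;
    exact ties produce a joint slash-separated name and are logged.
    """
    names: dict[int, str] = {}
    for c, members in sorted(partition.communities().items()):
        votes: dict[str, int] = defaultdict(int)
        for node in members:
            if node in reference_labels:
                votes[reference_labels[node]] += 1
        if not votes:
            names[c] = "unlabelled"
            continue
        best = max(votes.values())
        winners = sorted(l for l, v in votes.items() if v == best)
        if len(winners) > 1:
            logger.info("community %d label tie %s", c, winners)
        names[c] = "/".join(winners)
        logger.info(
            "community %d -> %s (%d/%d reference votes)",
            c, names[c], best, sum(votes.values()),
        )
    return names
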