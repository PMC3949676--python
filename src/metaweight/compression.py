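"""Greedy compression of node-weighted graphs.

A node-weighted graph is abstracted by repeatedly applying two operations:

* **merge** -- two (super)nodes become one supernode; each superedge to a
  neighbour is re-weighted as the member-count weighted mean of the two
  previous (super)edge weights (absent edges contribute 0) and is kept only
  if the new weight clears a configurable threshold (default 0.5: keeping a
  mostly-absent edge would cost more error than the space it saves).
  Internal node pairs are summarised the same way by a self-superedge.
* **edge removal** -- a single superedge is deleted.

After either operation any (super)node left without incident superedges is
dropped and its members recorded as removed.

Fidelity is measured against the *decompressed* graph (superedge weights
broadcast to all member pairs): removed nodes are charged their node weight,
and every retained unordered node pair is charged the absolute edge-weight
change scaled by the mean node weight of the pair.  This covers the four
error sources of compression: spurious edges inside/around supernodes, lost
edges, lost nodes, and altered edge weights.  The metric is an L1 distance
on retained pairs, hence satisfies the triangle inequality, so the total
error is upper-bounded by the sum of per-step increments; the greedy loop
therefore scores each candidate operation by (distance increment) / (size
decrease) and executes the cheapest, stopping once the compression ratio

    cr = (#supernodes + #superedges) / (|V| + |E|)

reaches the target.  Candidate merges are restricted to node pairs within a
small hop distance (default 2): nodes with no common neighbour cannot merge
cheaply, and the restriction bounds the per-iteration cost.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .graph import Pathway, SuperGraph
from .stats import spearman

__all__ = [
    "WeightedGraph",
    "CompressedGraph",
    "CompressionResult",
    "PathwaySimilarity",
    "identity_compression",
    "decompress",
    "distance",
    "superedge_weight",
    "merge_pair",
    "remove_edge",
    "compress_to_ratio",
    "compress_sweep",
    "compressed_weight_profile",
    "shared_compressed_part",
    "pathway_similarity",
    "rank_pathways",
]

Edge = tuple[str, str]  # sorted pair of (super)node ids; self-pairs allowed


def _key(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass
class WeightedGraph:
    """Nodes with non-negative weights; undirected edges with weights in [0, 1].

    Original metabolic graphs have weight 1.0 on every edge; decompressed
    graphs carry fractional weights.
    """

    node_weight: dict[str, float]
    edge_weight: dict[Edge, float]

    def __post_init__(self) -> None:
        for (u, v), w in self.edge_weight.items():
            if u not in self.node_weight or v not in self.node_weight:
                raise ValueError(f"edge ({u}, {v}) references missing node")
            if u == v:
                raise ValueError(f"self-edge at {u!r} not allowed")
            if not np.isfinite(w):
                raise ValueError(f"non-finite weight on edge ({u}, {v})")

    @classmethod
    def from_supergraph(
        cls,
        sg: SuperGraph,
        weights: Mapping[str, float],
        default: float = 0.0,
    ) -> "WeightedGraph":
        nodes = {v: float(weights.get(v, default)) for v in sg.nodes}
        edges = {_key(*sorted(e)): 1.0 for e in sg.edges}
        return cls(node_weight=nodes, edge_weight=edges)

    @property
    def size(self) -> int:
        return len(self.node_weight) + len(self.edge_weight)


@dataclass(frozen=True)
class OpRecord:
    op: str  # "merge" or "delete"
    args: tuple[str, ...]
    delta_distance: float
    delta_size: int
    cr_after: float


@dataclass
class CompressedGraph:
    """Supernodes (disjoint member sets), weighted superedges, and provenance.

    ``node_weight`` keeps the original weights of all retained members so the
    graph decompresses without external state.  A supernode's id is the
    lexicographically smallest member id.
    """

    supernodes: dict[str, frozenset[str]]
    superedges: dict[Edge, float]
    node_weight: dict[str, float]
    removed_nodes: tuple[str, ...] = ()
    operation_log: tuple[OpRecord, ...] = ()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sid, members in self.supernodes.items():
            if not members:
                raise ValueError(f"empty supernode {sid!r}")
            if seen & members:
                raise ValueError("supernode member sets overlap")
            seen |= members
        for (a, b), w in self.superedges.items():
            if a not in self.supernodes or b not in self.supernodes:
                raise ValueError(f"superedge ({a}, {b}) references missing supernode")
            if not 0.0 <= w <= 1.0 + 1e-12:
                raise ValueError(f"superedge weight {w} outside [0, 1]")

    def supernode_weight(self, sid: str) -> float:
        members = self.supernodes[sid]
        return sum(self.node_weight[m] for m in members) / len(members)

    @property
    def retained(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.supernodes.values():
            out |= members
        return frozenset(out)

    @property
    def size(self) -> int:
        return len(self.supernodes) + len(self.superedges)


@dataclass
class CompressionResult:
    compressed: CompressedGraph
    cr: float
    distance: float
    distance_bound: float


@dataclass(frozen=True)
class PathwaySimilarity:
    pathway_id: str
    rn: int
    ce: int
    sim: float


def identity_compression(graph: WeightedGraph) -> CompressedGraph:
    """Every node its own supernode; superedges mirror the original edges."""
    return CompressedGraph(
        supernodes={v: frozenset((v,)) for v in graph.node_weight},
        superedges=dict(graph.edge_weight),
        node_weight=dict(graph.node_weight),
    )


def decompress(compressed: CompressedGraph) -> WeightedGraph:
    """Expand supernodes back to original node identities.

    Every cross pair between two superedge endpoints (and every internal
    pair under a self-superedge) receives the superedge weight; pairs not
    covered by any superedge have weight 0 (no stored edge).
    """
    nodes = {v: compressed.node_weight[v] for v in compressed.retained}
    edges: dict[Edge, float] = {}
    for (sa, sb), w in compressed.superedges.items():
        if w == 0.0:
            continue
        if sa == sb:
            members = sorted(compressed.supernodes[sa])
            pairs = itertools.combinations(members, 2)
        else:
            pairs = itertools.product(compressed.supernodes[sa],
                                      compressed.supernodes[sb])
        for u, v in pairs:
            edges[_key(u, v)] = w
    return WeightedGraph(node_weight=nodes, edge_weight=edges)


def distance(
    original: WeightedGraph,
    decompressed: WeightedGraph,
    c_node: float = 1.0,
) -> float:
    """Node-weight-scaled distance between a graph and its decompression.

    d = sum over removed nodes v of q(v) * c_node
      + sum over unordered retained pairs {u, v} of
            (q(u) + q(v)) / 2 * |w_orig(u, v) - w_dec(u, v)|

    with absent edges carrying weight 0.  The pairwise term is symmetric in
    its two edge-weight arguments and is an L1 metric over pairs, so for
    graphs on a common node set d obeys the triangle inequality.  Nodes in
    ``decompressed`` that are foreign to ``original`` raise ``ValueError``.
    """
    q = original.node_weight
    retained = set(decompressed.node_weight)
    foreign = retained - set(q)
    if foreign:
        raise ValueError(f"decompressed graph has foreign nodes {foreign!r}")
    d = sum(q[v] * c_node for v in set(q) - retained)
    keys = set(original.edge_weight) | set(decompressed.edge_weight)
    for u, v in keys:
        if u in retained and v in retained:
            diff = abs(original.edge_weight.get((u, v), 0.0)
                       - decompressed.edge_weight.get((u, v), 0.0))
            d += (q[u] + q[v]) / 2.0 * diff
    return d


def superedge_weight(size_u: int, w_un: float, size_v: int, w_vn: float) -> float:
    """Weight of the superedge from a merged pair to a neighbour.

    Member-count weighted mean of the two previous weights (absent edges
    contribute 0); this minimises the pairwise distance term between the
    two sequential compressed graphs.
    """
    return (size_u * w_un + size_v * w_vn) / (size_u + size_v)


# --------------------------------------------------------------------------
# internal mutable state + analytic operation evaluation


class _State:
    def __init__(self, cg: CompressedGraph):
        self.members: dict[str, frozenset[str]] = dict(cg.supernodes)
        self.q: dict[str, float] = dict(cg.node_weight)
        self.qsum: dict[str, float] = {
            sid: sum(self.q[m] for m in ms) for sid, ms in self.members.items()}
        self.edges: dict[Edge, float] = dict(cg.superedges)
        self.adj: dict[str, set[str]] = {sid: set() for sid in self.members}
        self.selfedge: set[str] = set()
        for (a, b) in self.edges:
            if a == b:
                self.selfedge.add(a)
            else:
                self.adj[a].add(b)
                self.adj[b].add(a)
        self.removed: list[str] = list(cg.removed_nodes)
        self.log: list[OpRecord] = list(cg.operation_log)

    @property
    def size(self) -> int:
        return len(self.members) + len(self.edges)

    def to_compressed(self) -> CompressedGraph:
        return CompressedGraph(
            supernodes=dict(self.members),
            superedges=dict(self.edges),
            node_weight={m: self.q[m] for ms in self.members.values()
                         for m in ms},
            removed_nodes=tuple(self.removed),
            operation_log=tuple(self.log),
        )

    def _degree_ids(self, sid: str) -> set[str]:
        nb = set(self.adj[sid])
        if sid in self.selfedge:
            nb.add(sid)
        return nb

    def _drop_supernode(self, sid: str) -> None:
        for n in list(self.adj[sid]):
            self.adj[n].discard(sid)
            self.edges.pop(_key(sid, n), None)
        self.edges.pop((sid, sid), None)
        self.selfedge.discard(sid)
        del self.adj[sid]
        self.removed.extend(sorted(self.members[sid]))
        del self.members[sid]
        del self.qsum[sid]

    # -- merge -------------------------------------------------------------

    def eval_merge(self, u: str, v: str, keep_thr: float, c_node: float):
        """Analytic (delta_distance, delta_size, plan) for merging u and v."""
        su, sv = len(self.members[u]), len(self.members[v])
        qu, qv = self.qsum[u], self.qsum[v]
        neighbors = (self.adj[u] | self.adj[v]) - {u, v}
        dd = 0.0
        kept: dict[str, float] = {}
        isolated: list[str] = []
        for n in sorted(neighbors):
            wun = self.edges.get(_key(u, n), 0.0)
            wvn = self.edges.get(_key(v, n), 0.0)
            wn = superedge_weight(su, wun, sv, wvn)
            keep = wn >= keep_thr and wn > 0.0
            sn, qn = len(self.members[n]), self.qsum[n]
            if keep:
                kept[n] = wn
                dd += ((sn * qu + su * qn) / 2.0 * abs(wun - wn)
                       + (sn * qv + sv * qn) / 2.0 * abs(wvn - wn))
            else:
                n_isolated = (self._degree_ids(n) <= {u, v})
                if n_isolated:
                    isolated.append(n)
                    dd += c_node * qn
                else:
                    dd += ((sn * qu + su * qn) / 2.0 * wun
                           + (sn * qv + sv * qn) / 2.0 * wvn)
        # internal pairs -> self-superedge
        w_uv = self.edges.get(_key(u, v), 0.0)
        w_uu = self.edges.get((u, u), 0.0)
        w_vv = self.edges.get((v, v), 0.0)
        pairs_cross = su * sv
        pairs_u = su * (su - 1) // 2
        pairs_v = sv * (sv - 1) // 2
        total_pairs = pairs_cross + pairs_u + pairs_v
        w_self = ((pairs_cross * w_uv + pairs_u * w_uu + pairs_v * w_vv)
                  / total_pairs)
        keep_self = w_self >= keep_thr and w_self > 0.0
        merged_survives = bool(kept) or keep_self
        if merged_survives:
            w_new = w_self if keep_self else 0.0
            dd += ((sv * qu + su * qv) / 2.0 * abs(w_uv - w_new)
                   + (su - 1) * qu / 2.0 * abs(w_uu - w_new)
                   + (sv - 1) * qv / 2.0 * abs(w_vv - w_new))
        else:
            # the merged supernode itself would be isolated: members removed
            dd = c_node * (qu + qv)
            kept = {}
            keep_self = False
            isolated = []
            for n in sorted(neighbors):
                if self._degree_ids(n) <= {u, v}:
                    isolated.append(n)
                    dd += c_node * self.qsum[n]
        # size accounting
        incident_before = {k for k in self.edges if u in k or v in k}
        nodes_after = (1 if merged_survives else 0)
        edges_after = len(kept) + (1 if keep_self else 0)
        d_nodes = 2 + len(isolated) - nodes_after
        d_edges = len(incident_before) - edges_after
        # edges between isolated neighbours and u/v are already in incident_before
        d_size = d_nodes + d_edges
        plan = (u, v, kept, keep_self, w_self, isolated, merged_survives)
        return dd, d_size, plan

    def apply_merge(self, plan) -> None:
        u, v, kept, keep_self, w_self, isolated, survives = plan
        members_w = self.members[u] | self.members[v]
        qsum_w = self.qsum[u] + self.qsum[v]
        for n in isolated:
            self._drop_supernode(n)
        # detach u and v entirely
        for sid in (u, v):
            for n in list(self.adj[sid]):
                self.adj[n].discard(sid)
                self.edges.pop(_key(sid, n), None)
            self.edges.pop((sid, sid), None)
            self.selfedge.discard(sid)
            del self.adj[sid]
            del self.members[sid]
            del self.qsum[sid]
        self.edges.pop(_key(u, v), None)
        if not survives:
            self.removed.extend(sorted(members_w))
            return
        w = min(members_w)
        self.members[w] = frozenset(members_w)
        self.qsum[w] = qsum_w
        self.adj[w] = set()
        for n, wn in kept.items():
            self.edges[_key(w, n)] = wn
            self.adj[w].add(n)
            self.adj[n].add(w)
        if keep_self:
            self.edges[(w, w)] = w_self
            self.selfedge.add(w)

    # -- delete ------------------------------------------------------------

    def eval_delete(self, key: Edge, c_node: float):
        s, t = key
        w = self.edges[key]
        dd = 0.0
        d_size = 1
        drops: list[str] = []
        if s == t:
            ss, qs = len(self.members[s]), self.qsum[s]
            if not self.adj[s]:
                dd = c_node * qs
                drops = [s]
                d_size += 1
            else:
                dd = (ss - 1) * qs / 2.0 * w
        else:
            s_iso = self._degree_ids(s) == {t}
            t_iso = self._degree_ids(t) == {s}
            if s_iso:
                dd += c_node * self.qsum[s]
                drops.append(s)
                d_size += 1
            if t_iso:
                dd += c_node * self.qsum[t]
                drops.append(t)
                d_size += 1
            if not s_iso and not t_iso:
                ss, st = len(self.members[s]), len(self.members[t])
                dd = (st * self.qsum[s] + ss * self.qsum[t]) / 2.0 * w
        return dd, d_size, (key, drops)

    def apply_delete(self, plan) -> None:
        key, drops = plan
        s, t = key
        del self.edges[key]
        if s != t:
            self.adj[s].discard(t)
            self.adj[t].discard(s)
        else:
            self.selfedge.discard(s)
        for sid in drops:
            self._drop_supernode(sid)


# --------------------------------------------------------------------------
# public single-operation API


def merge_pair(
    compressed: CompressedGraph,
    u: str,
    v: str,
    keep_threshold: float = 0.5,
    c_node: float = 1.0,
) -> CompressedGraph:
    """Merge supernodes *u* and *v*; returns a new compressed graph."""
    if u == v:
        raise ValueError("cannot merge a supernode with itself")
    if u not in compressed.supernodes or v not in compressed.supernodes:
        raise ValueError(f"cannot merge absent supernode(s) {u!r}, {v!r}")
    state = _State(compressed)
    orig_size = state.size  # size bookkeeping is relative; cr left to callers
    dd, d_size, plan = state.eval_merge(u, v, keep_threshold, c_node)
    state.apply_merge(plan)
    state.log.append(OpRecord("merge", (u, v), dd, d_size,
                              state.size / max(orig_size, 1)))
    return state.to_compressed()


def remove_edge(
    compressed: CompressedGraph,
    edge: Edge | Iterable[str],
    c_node: float = 1.0,
) -> CompressedGraph:
    """Delete one superedge (endpoints left isolated are dropped too)."""
    a, b = tuple(edge)
    key = _key(a, b)
    if key not in compressed.superedges:
        raise ValueError(f"superedge {key!r} not present")
    state = _State(compressed)
    orig_size = state.size
    dd, d_size, plan = state.eval_delete(key, c_node)
    state.apply_delete(plan)
    state.log.append(OpRecord("delete", key, dd, d_size,
                              state.size / max(orig_size, 1)))
    return state.to_compressed()


# --------------------------------------------------------------------------
# greedy driver


def _merge_candidates(state: _State, hops: int) -> set[Edge]:
    pairs: set[Edge] = set()
    for s in state.members:
        reach = set(state.adj[s])
        if hops >= 2:
            for n in list(reach):
                reach |= state.adj[n]
        reach.discard(s)
        for t in reach:
            pairs.add(_key(s, t))
    return pairs


def compress_to_ratio(
    graph: WeightedGraph,
    target_cr: float,
    candidate_hops: int = 2,
    keep_threshold: float = 0.5,
    c_node: float = 1.0,
) -> CompressionResult:
    """Greedily compress *graph* until cr <= ``target_cr``.

    Each iteration evaluates every candidate merge (supernode pairs within
    ``candidate_hops``) and every superedge deletion, scores them by
    (distance increment) / (size decrease), and executes the cheapest; ties
    break on the operation name and then lexicographic ids.  If no operation
    can shrink the graph further the achieved ratio is reported instead of
    failing.  The result carries both the exact final distance and the
    sum-of-increments upper bound.
    """
    if not 0 < target_cr <= 1:
        raise ValueError("target_cr must be in (0, 1]")
    state = _State(identity_compression(graph))
    orig_size = max(graph.size, 1)
    bound = 0.0
    cr = state.size / orig_size
    while cr > target_cr + 1e-12:
        best = None  # (score, op, ids, dd, d_size, plan)
        for key in sorted(state.edges):
            dd, d_size, plan = state.eval_delete(key, c_node)
            cand = (dd / d_size, "delete", key, dd, d_size, plan)
            if best is None or cand[:3] < best[:3]:
                best = cand
        for (u, v) in sorted(_merge_candidates(state, candidate_hops)):
            dd, d_size, plan = state.eval_merge(u, v, keep_threshold, c_node)
            cand = (dd / d_size, "merge", (u, v), dd, d_size, plan)
            if best is None or cand[:3] < best[:3]:
                best = cand
        if best is None:
            break
        _, op, ids, dd, d_size, plan = best
        if op == "delete":
            state.apply_delete(plan)
        else:
            state.apply_merge(plan)
        bound += dd
        cr = state.size / orig_size
        state.log.append(OpRecord(op, tuple(ids), dd, d_size, cr))
    compressed = state.to_compressed()
    exact = distance(graph, decompress(compressed), c_node=c_node)
    return CompressionResult(compressed=compressed, cr=cr, distance=exact,
                             distance_bound=bound)


def compress_sweep(
    graph: WeightedGraph,
    targets: Sequence[float],
    candidate_hops: int = 2,
    keep_threshold: float = 0.5,
    c_node: float = 1.0,
) -> dict[float, CompressionResult]:
    """Compression results at several target ratios from one greedy pass.

    The greedy operation sequence does not depend on the target ratio (the
    target only decides where to stop), so a single pass to the deepest
    target with snapshots at each intermediate target is equivalent to -- and
    much cheaper than -- one :func:`compress_to_ratio` call per target.
    """
    pending = sorted(set(targets), reverse=True)
    deepest = pending[-1]
    state = _State(identity_compression(graph))
    orig_size = max(graph.size, 1)
    bound = 0.0
    out: dict[float, CompressionResult] = {}

    def snapshot(cr: float) -> None:
        while pending and cr <= pending[0] + 1e-12:
            target = pending.pop(0)
            compressed = state.to_compressed()
            out[target] = CompressionResult(
                compressed=compressed, cr=cr,
                distance=distance(graph, decompress(compressed),
                                  c_node=c_node),
                distance_bound=bound)

    cr = state.size / orig_size
    snapshot(cr)
    while pending:
        best = None
        for key in sorted(state.edges):
            dd, d_size, plan = state.eval_delete(key, c_node)
            cand = (dd / d_size, "delete", key, dd, d_size, plan)
            if best is None or cand[:3] < best[:3]:
                best = cand
        for (u, v) in sorted(_merge_candidates(state, candidate_hops)):
            dd, d_size, plan = state.eval_merge(u, v, keep_threshold, c_node)
            cand = (dd / d_size, "merge", (u, v), dd, d_size, plan)
            if best is None or cand[:3] < best[:3]:
                best = cand
        if best is None:
            break
        _, op, ids, dd, d_size, plan = best
        if op == "delete":
            state.apply_delete(plan)
        else:
            state.apply_merge(plan)
        bound += dd
        cr = state.size / orig_size
        state.log.append(OpRecord(op, tuple(ids), dd, d_size, cr))
        snapshot(cr)
    # unreachable targets report the achieved state
    for target in pending:
        compressed = state.to_compressed()
        out[target] = CompressionResult(
            compressed=compressed, cr=cr,
            distance=distance(graph, decompress(compressed), c_node=c_node),
            distance_bound=bound)
    assert deepest in out
    return out


# --------------------------------------------------------------------------
# analyses over compression results


def compressed_weight_profile(
    result: CompressionResult,
    original: WeightedGraph,
) -> float:
    """Mean original node weight over the enzymes retained after compression."""
    retained = result.compressed.retained
    if not retained:
        return float("nan")
    return float(np.mean([original.node_weight[v] for v in retained]))


def shared_compressed_part(
    result_a: CompressionResult,
    result_b: CompressionResult,
    weights: Mapping[str, float],
) -> float | None:
    """Mean weight (per *weights*) of enzymes retained in both compressions.

    Returns None when the shared retained set is empty (shared part
    undefined).
    """
    shared = result_a.compressed.retained & result_b.compressed.retained
    if not shared:
        return None
    return float(np.mean([weights[v] for v in shared]))


def pathway_similarity(
    pathway_graph: WeightedGraph,
    result: CompressionResult,
    pathway_id: str = "",
    edge_threshold: float = 0.5,
) -> PathwaySimilarity:
    """Similarity between a pathway and its compressed form.

    rn counts pathway nodes absent from the retained set; ce counts node
    pairs whose edge presence changed between the original pathway graph and
    the decompressed graph, where a decompressed pair counts as an edge iff
    its weight >= ``edge_threshold``.  sim = 1 - (rn + ce) / (|V| + |E|),
    floored at 0.
    """
    dec = decompress(result.compressed)
    nodes = set(pathway_graph.node_weight)
    retained = set(dec.node_weight) & nodes
    rn = len(nodes - retained)
    orig_edges = {k for k, w in pathway_graph.edge_weight.items() if w > 0}
    dec_edges = {k for k, w in dec.edge_weight.items()
                 if w >= edge_threshold and k[0] in nodes and k[1] in nodes}
    # edges incident to removed nodes are gone from the decompressed graph
    dec_edges = {k for k in dec_edges if k[0] in retained and k[1] in retained}
    ce = len(orig_edges ^ dec_edges)
    denom = len(nodes) + len(orig_edges)
    sim = max(0.0, 1.0 - (rn + ce) / denom) if denom else 1.0
    return PathwaySimilarity(pathway_id=pathway_id, rn=rn, ce=ce, sim=sim)


def rank_pathways(
    sims_a: Mapping[str, PathwaySimilarity],
    sims_b: Mapping[str, PathwaySimilarity],
    names: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-domain descending-similarity ranking and the cross-domain rho.

    Pathways are ranked within each domain by descending similarity, ties by
    pathway name; the returned rho is the Spearman correlation of the two
    domains' similarity vectors over the common pathways.
    """
    common = sorted(set(sims_a) & set(sims_b))
    if len(common) < 3:
        raise ValueError("need at least 3 common pathways to rank")
    names = names or {}

    def ranks(sims: Mapping[str, PathwaySimilarity]) -> dict[str, int]:
        order = sorted(common,
                       key=lambda p: (-sims[p].sim, names.get(p, p)))
        return {p: i + 1 for i, p in enumerate(order)}

    ra, rb = ranks(sims_a), ranks(sims_b)
    df = pd.DataFrame({
        "pathway_id": common,
        "name": [names.get(p, p) for p in common],
        "sim_A": [sims_a[p].sim for p in common],
        "sim_B": [sims_b[p].sim for p in common],
        "rank_A": [ra[p] for p in common],
        "rank_B": [rb[p] for p in common],
    }).sort_values("rank_A").reset_index(drop=True)
    rho = spearman([sims_a[p].sim for p in common],
                   [sims_b[p].sim for p in common]).rho
    return df, rho
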