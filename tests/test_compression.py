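"""Node-weighted graph compression: operations, distance, greedy driver."""

import itertools

import numpy as np
import pytest

from metaweight.compression import (CompressedGraph, WeightedGraph,
                                    compress_to_ratio,
                                    compressed_weight_profile, decompress,
                                    distance, identity_compression,
                                    merge_pair, pathway_similarity,
                                    rank_pathways, remove_edge,
                                    shared_compressed_part, superedge_weight)

from oracles import (distance_oracle, exhaustive_compression_search,
                     expand_oracle)


def graph(nodes, edges):
    """nodes: {id: q}; edges: {(u, v): w} or iterable of pairs (w=1)."""
    if not isinstance(edges, dict):
        edges = {tuple(sorted(e)): 1.0 for e in edges}
    else:
        edges = {tuple(sorted(k)): w for k, w in edges.items()}
    return WeightedGraph(node_weight=dict(nodes), edge_weight=edges)


def random_graph(rng, n, p=0.5):
    nodes = {f"n{i}": float(rng.uniform(0.1, 1.0)) for i in range(n)}
    edges = {}
    ids = sorted(nodes)
    for u, v in itertools.combinations(ids, 2):
        if rng.random() < p:
            edges[(u, v)] = 1.0
    return graph(nodes, edges)


def two_hop_pairs(cg: CompressedGraph):
    adj = {s: set() for s in cg.supernodes}
    for a, b in cg.superedges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    pairs = set()
    for s in cg.supernodes:
        reach = set(adj[s])
        for nb in list(reach):
            reach |= adj[nb]
        reach.discard(s)
        pairs.update(tuple(sorted((s, t))) for t in reach)
    return sorted(pairs)


class TestDecompress:
    def test_identity_roundtrip_exact(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, 7)
        back = decompress(identity_compression(g))
        assert back.node_weight == g.node_weight
        assert back.edge_weight == g.edge_weight

    def test_self_superedge_expands_internal_pair(self):
        cg = CompressedGraph(
            supernodes={"a": frozenset({"a", "b"})},
            superedges={("a", "a"): 1.0},
            node_weight={"a": 0.5, "b": 0.7})
        dec = decompress(cg)
        assert dec.edge_weight == {("a", "b"): 1.0}

    def test_random_compression_matches_expansion_oracle(self):
        rng = np.random.default_rng(1)
        members = {"s0": frozenset({"n0", "n1", "n2"}),
                   "s1": frozenset({"n3", "n4"}),
                   "s2": frozenset({"n5"}),
                   "s3": frozenset({"n6", "n7"})}
        superedges = {("s0", "s1"): 0.8, ("s1", "s2"): 0.6,
                      ("s0", "s0"): 0.9, ("s2", "s3"): 1.0}
        q = {f"n{i}": float(rng.random()) for i in range(8)}
        cg = CompressedGraph(supernodes=members, superedges=superedges,
                             node_weight=q)
        dec = decompress(cg)
        expected = expand_oracle(members, superedges)
        assert {frozenset(k): w for k, w in dec.edge_weight.items()} == \
            pytest.approx(expected)


class TestDistance:
    def test_self_distance_zero(self):
        g = random_graph(np.random.default_rng(2), 6)
        assert distance(g, g) == 0.0

    def test_single_removed_node(self):
        g = graph({"a": 0.6, "b": 0.3}, {})
        dec = graph({"b": 0.3}, {})
        assert distance(g, dec) == pytest.approx(0.6)

    def test_pairwise_term_symmetric(self):
        rng = np.random.default_rng(3)
        nodes = {f"n{i}": float(rng.random()) for i in range(6)}
        e1 = {k: float(rng.random())
              for k in itertools.combinations(sorted(nodes), 2)
              if rng.random() < 0.6}
        e2 = {k: float(rng.random())
              for k in itertools.combinations(sorted(nodes), 2)
              if rng.random() < 0.6}
        g1, g2 = graph(nodes, e1), graph(nodes, e2)
        assert distance(g1, g2) == pytest.approx(distance(g2, g1))

    def test_triangle_inequality_random_triples(self):
        rng = np.random.default_rng(4)
        nodes = {f"n{i}": float(rng.uniform(0.1, 1)) for i in range(5)}
        keys = list(itertools.combinations(sorted(nodes), 2))
        for _ in range(200):
            gs = []
            for _ in range(3):
                e = {k: float(rng.random()) for k in keys
                     if rng.random() < 0.7}
                gs.append(graph(nodes, e))
            d01 = distance(gs[0], gs[1])
            d12 = distance(gs[1], gs[2])
            d02 = distance(gs[0], gs[2])
            assert d02 <= d01 + d12 + 1e-9

    def test_foreign_node_rejected(self):
        g = graph({"a": 1.0}, {})
        with pytest.raises(ValueError, match="foreign"):
            distance(g, graph({"z": 1.0}, {}))

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(5)
        g = random_graph(rng, 6)
        cg = identity_compression(g)
        cg = merge_pair(cg, "n0", "n1")
        dec = decompress(cg)
        got = distance(g, dec)
        expected = distance_oracle(
            g.node_weight, g.edge_weight, dec.edge_weight,
            set(dec.node_weight))
        assert got == pytest.approx(expected)


class TestSuperedgeWeight:
    def test_singleton_mean(self):
        assert superedge_weight(1, 1.0, 1, 0.0) == 0.5

    def test_both_connected(self):
        assert superedge_weight(1, 1.0, 1, 1.0) == 1.0

    def test_member_count_weighting(self):
        assert superedge_weight(3, 1.0, 1, 0.0) == 0.75


class TestMergePair:
    def test_structural_twins_lossless(self):
        g = graph({"t1": 0.5, "t2": 0.5, "x": 0.8, "y": 0.2},
                  [("t1", "x"), ("t1", "y"), ("t2", "x"), ("t2", "y")])
        cg = merge_pair(identity_compression(g), "t1", "t2")
        assert cg.operation_log[-1].delta_distance == pytest.approx(0.0)
        assert distance(g, decompress(cg)) == pytest.approx(0.0)

    def test_isolated_neighbor_dropped(self):
        # merge pattern: the merged supernode keeps strong links, a weakly
        # linked pendant neighbour loses its only edge and is removed
        g = graph({"a": 0.9, "b1": 0.9, "b2": 0.9, "n1": 0.5, "n3": 0.1},
                  [("b1", "b2"), ("a", "n1"), ("b1", "n1"), ("a", "n3")])
        cg = identity_compression(g)
        cg = merge_pair(cg, "b1", "b2")      # supernode of size 2
        cg = merge_pair(cg, "a", "b1")       # now 1/3 < 0.5 to n3 -> dropped
        assert "n3" in cg.removed_nodes
        assert "n1" in cg.retained
        sids = set(cg.supernodes)
        assert sids == {"a", "n1"}
        assert cg.supernodes["a"] == frozenset({"a", "b1", "b2"})

    def test_merge_absent_node_rejected(self):
        g = graph({"a": 1.0, "b": 1.0}, [("a", "b")])
        with pytest.raises(ValueError):
            merge_pair(identity_compression(g), "a", "zz")
        with pytest.raises(ValueError):
            merge_pair(identity_compression(g), "a", "a")

    def test_delta_matches_decompress_and_compare_oracle(self):
        rng = np.random.default_rng(6)
        for trial in range(20):
            g = random_graph(rng, 6, p=0.5)
            cg0 = identity_compression(g)
            pairs = two_hop_pairs(cg0)
            if not pairs:
                continue
            u, v = pairs[rng.integers(len(pairs))]
            cg1 = merge_pair(cg0, u, v)
            # sequential distance: between the two decompressed graphs
            d_seq = distance(decompress(cg0), decompress(cg1))
            assert cg1.operation_log[-1].delta_distance == \
                pytest.approx(d_seq, abs=1e-9), trial

    def test_member_sets_partition_retained(self):
        rng = np.random.default_rng(7)
        g = random_graph(rng, 8, p=0.4)
        cg = identity_compression(g)
        for _ in range(4):
            pairs = two_hop_pairs(cg)
            if not pairs:
                break
            u, v = pairs[rng.integers(len(pairs))]
            cg = merge_pair(cg, u, v)
            members = [m for s in cg.supernodes.values() for m in s]
            assert len(members) == len(set(members))
            assert set(members) | set(cg.removed_nodes) == set(g.node_weight)


class TestRemoveEdge:
    def test_pendant_edge_removes_leaf(self):
        g = graph({"a": 0.5, "b": 0.5, "c": 0.1},
                  [("a", "b"), ("b", "c")])
        cg = remove_edge(identity_compression(g), ("b", "c"))
        assert "c" in cg.removed_nodes
        assert set(cg.supernodes) == {"a", "b"}

    def test_triangle_edge_keeps_endpoints(self):
        g = graph({"a": 1, "b": 1, "c": 1},
                  [("a", "b"), ("b", "c"), ("a", "c")])
        cg = remove_edge(identity_compression(g), ("a", "b"))
        assert cg.removed_nodes == ()
        assert len(cg.superedges) == 2

    def test_absent_edge_rejected(self):
        g = graph({"a": 1, "b": 1}, [("a", "b")])
        with pytest.raises(ValueError):
            remove_edge(identity_compression(g), ("a", "zz"))

    def test_delta_matches_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            g = random_graph(rng, 6, p=0.5)
            cg0 = identity_compression(g)
            edges = sorted(cg0.superedges)
            if not edges:
                continue
            e = edges[rng.integers(len(edges))]
            cg1 = remove_edge(cg0, e)
            d_seq = distance(decompress(cg0), decompress(cg1))
            assert cg1.operation_log[-1].delta_distance == \
                pytest.approx(d_seq, abs=1e-9)


class TestGreedy:
    def test_target_one_is_identity(self):
        g = random_graph(np.random.default_rng(9), 6)
        res = compress_to_ratio(g, 1.0)
        assert res.cr == 1.0
        assert res.distance == 0.0
        back = decompress(res.compressed)
        assert back.edge_weight == g.edge_weight

    def test_cr_strictly_decreases_per_operation(self):
        g = random_graph(np.random.default_rng(10), 10, p=0.4)
        res = compress_to_ratio(g, 0.3)
        crs = [rec.cr_after for rec in res.compressed.operation_log]
        assert all(b < a for a, b in zip(crs, crs[1:]))
        assert res.cr <= 0.3

    def test_distance_bounded_by_increment_sum(self):
        for seed in range(5):
            g = random_graph(np.random.default_rng(seed), 12, p=0.35)
            res = compress_to_ratio(g, 0.4)
            assert res.distance <= res.distance_bound + 1e-9

    def test_greedy_between_optimal_and_worst(self):
        # full enumeration of operation sequences on small graphs
        def apply_ops(cg):
            out = []
            for u, v in two_hop_pairs(cg):
                out.append(("merge", merge_pair(cg, u, v)))
            for e in sorted(cg.superedges):
                out.append(("delete", remove_edge(cg, e)))
            return out

        for seed in (0, 1, 2, 3):
            rng = np.random.default_rng(seed)
            g = random_graph(rng, 5, p=0.6)
            target = 0.55
            span = exhaustive_compression_search(g, target, apply_ops)
            res = compress_to_ratio(g, target)
            if span is None:
                continue
            lo, hi = span
            assert lo - 1e-9 <= res.distance <= hi + 1e-9, seed

    def test_lossless_twin_merges_reach_optimal(self):
        # two pairs of structural twins: greedy should compress losslessly
        g = graph({"a1": 0.4, "a2": 0.4, "b1": 0.7, "b2": 0.7},
                  [("a1", "b1"), ("a1", "b2"), ("a2", "b1"), ("a2", "b2")])
        # size 4 + 4 = 8; merging twins -> 2 supernodes + 1 superedge = 3
        res = compress_to_ratio(g, 0.5)
        assert res.distance == pytest.approx(0.0)

    def test_distance_monotone_in_target(self):
        g = random_graph(np.random.default_rng(11), 14, p=0.3)
        dists = []
        for cr in (0.9, 0.7, 0.5, 0.3):
            dists.append(compress_to_ratio(g, cr).distance_bound)
        assert all(b >= a - 1e-9 for a, b in zip(dists, dists[1:]))

    def test_sweep_matches_per_target_runs(self):
        from metaweight.compression import compress_sweep
        g = random_graph(np.random.default_rng(13), 12, p=0.35)
        targets = (0.8, 0.6, 0.4)
        sweep = compress_sweep(g, targets)
        for cr in targets:
            single = compress_to_ratio(g, cr)
            assert sweep[cr].cr == single.cr
            assert sweep[cr].compressed.supernodes == \
                single.compressed.supernodes
            assert sweep[cr].compressed.superedges == \
                single.compressed.superedges
            assert sweep[cr].distance == pytest.approx(single.distance)

    def test_unreachable_target_reports_achieved(self):
        g = graph({"a": 1.0}, {})  # single node, nothing to do
        res = compress_to_ratio(g, 0.2)
        assert res.cr == 1.0


class TestProfiles:
    def test_identity_profile_is_overall_mean(self):
        g = graph({"a": 0.2, "b": 0.4, "c": 0.9}, [("a", "b"), ("b", "c")])
        res = compress_to_ratio(g, 1.0)
        assert compressed_weight_profile(res, g) == pytest.approx(0.5)

    def test_removing_low_weight_pendant_raises_mean(self):
        g = graph({"a": 0.9, "b": 0.9, "low": 0.05},
                  [("a", "b"), ("b", "low")])
        cg = remove_edge(identity_compression(g), ("b", "low"))
        from metaweight.compression import CompressionResult
        res = CompressionResult(compressed=cg, cr=cg.size / g.size,
                                distance=0.0, distance_bound=0.0)
        assert compressed_weight_profile(res, g) > np.mean([0.9, 0.9, 0.05])

    def test_shared_part_disjoint_is_missing(self):
        g1 = graph({"a": 1.0, "b": 1.0}, [("a", "b")])
        g2 = graph({"c": 1.0, "d": 1.0}, [("c", "d")])
        r1 = compress_to_ratio(g1, 1.0)
        r2 = compress_to_ratio(g2, 1.0)
        assert shared_compressed_part(r1, r2, {"a": 1.0, "b": 1.0}) is None

    def test_shared_part_identical_compressions(self):
        g = random_graph(np.random.default_rng(12), 8, p=0.4)
        res = compress_to_ratio(g, 0.5)
        got = shared_compressed_part(res, res, g.node_weight)
        assert got == pytest.approx(compressed_weight_profile(res, g))


class TestPathwaySimilarity:
    def test_identity_compression_full_similarity(self):
        g = graph({"a": 1, "b": 1, "c": 1}, [("a", "b"), ("b", "c")])
        res = compress_to_ratio(g, 1.0)
        assert pathway_similarity(g, res).sim == 1.0

    def test_everything_removed_zero(self):
        g = graph({"a": 0.1, "b": 0.1}, [("a", "b")])
        cg = CompressedGraph(supernodes={}, superedges={}, node_weight={},
                             removed_nodes=("a", "b"))
        from metaweight.compression import CompressionResult
        res = CompressionResult(compressed=cg, cr=0.0, distance=0.2,
                                distance_bound=0.2)
        ps = pathway_similarity(g, res)
        assert ps.sim == 0.0 and ps.rn == 2 and ps.ce == 1

    def test_one_merge_hand_count(self):
        # 5-node path a-b-c-d-e; merge a,b (adjacent, sizes 1/1)
        g = graph({x: 0.5 for x in "abcde"},
                  [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
        cg = merge_pair(identity_compression(g), "a", "b")
        from metaweight.compression import CompressionResult
        res = CompressionResult(compressed=cg, cr=cg.size / g.size,
                                distance=0.0, distance_bound=0.0)
        ps = pathway_similarity(g, res)
        # internal self-edge keeps a-b; superedge to c (0.5) broadcasts to
        # both members, adding a spurious a-c edge: rn=0, ce=1
        assert ps.rn == 0
        assert ps.ce == 1
        assert ps.sim == pytest.approx(1.0 - 1 / 9)

    def test_rank_pathways_identity_and_reversal(self):
        from metaweight.compression import PathwaySimilarity as PS
        sims = {f"p{i}": PS(f"p{i}", 0, 0, s)
                for i, s in enumerate([0.9, 0.5, 0.7, 0.3])}
        table, rho = rank_pathways(sims, sims)
        assert rho == pytest.approx(1.0)
        assert list(table.pathway_id[:1]) == ["p0"]
        rev = {p: PS(p, 0, 0, 1 - sims[p].sim) for p in sims}
        _, rho_rev = rank_pathways(sims, rev)
        assert rho_rev == pytest.approx(-1.0)
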