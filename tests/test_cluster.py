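import networkx as nx
import numpy as np
import pandas as pd
import pytest

from oracles import dbscan_oracle

from hfemap.cluster import (
    annotate_communities,
    build_ibd_graph,
    dbscan,
    detect_communities,
    modularity,
    select_core_cluster,
)
from hfemap.errors import EmptySelectionError, ValidationError
from hfemap.synthetic import PCGroup, simulate_ibd_segments, simulate_pc_cloud


def _random_instance(rng) -> pd.DataFrame:
    n = rng.integers(5, 51)
    xy = rng.uniform(0, 4, size=(n, 2))
    return pd.DataFrame({"id": [f"p{i:02d}" for i in range(n)],
                         "pc1": xy[:, 0], "pc2": xy[:, 1]})


class TestDBSCAN:
    def test_single_blob_is_one_cluster_without_noise(self):
        pc = simulate_pc_cloud([PCGroup("A", (0, 0), 0.2, 60)], seed=0)
        labels = dbscan(pc, eps=0.5, min_pts=5)
        assert set(labels.values()) == {0}

    def test_two_blobs_and_distant_singletons(self):
        pc = simulate_pc_cloud(
            [PCGroup("A", (0, 0), 0.2, 50), PCGroup("B", (10, 10), 0.2, 50)],
            noise_n=3, noise_box=(40, 50, 40, 50), seed=1,
        )
        labels = dbscan(pc, eps=0.6, min_pts=5)
        by_label = pd.Series(labels)
        assert set(by_label.values) == {0, 1, -1}
        assert (by_label == -1).sum() == 3

    def test_matches_brute_force_reachability_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(40):
            df = _random_instance(rng)
            eps = float(rng.uniform(0.2, 1.2))
            min_pts = int(rng.integers(2, 6))
            assert dbscan(df, eps, min_pts) == dbscan_oracle(df, eps, min_pts)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        df = _random_instance(rng)
        shuffled = df.sample(frac=1, random_state=2)
        assert dbscan(df, 0.5, 3) == dbscan(shuffled, 0.5, 3)

    def test_parameter_validation(self):
        df = _random_instance(np.random.default_rng(0))
        with pytest.raises(ValidationError):
            dbscan(df, eps=0.0, min_pts=3)
        with pytest.raises(ValidationError):
            dbscan(df, eps=1.0, min_pts=0)


class TestCoreClusterSelection:
    def test_seed_group_inside_one_cluster(self):
        labels = {"a1": 0, "a2": 0, "b1": 1}
        assert select_core_cluster(labels, ["a1", "a2"]) == ["a1", "a2"]

    def test_majority_cluster_wins(self):
        labels = {f"s{i}": (0 if i < 9 else 1) for i in range(10)}
        kept = select_core_cluster(labels, labels.keys())
        assert kept == [f"s{i}" for i in range(9)]

    def test_tie_goes_to_smallest_label(self):
        labels = {"a": 0, "b": 1, "x": 0, "y": 1}
        assert select_core_cluster(labels, ["a", "b"]) == ["a", "x"]

    def test_all_noise_is_an_error(self):
        with pytest.raises(EmptySelectionError):
            select_core_cluster({"a": -1, "b": -1}, ["a", "b"])


class TestIBDGraph:
    def test_short_segment_excluded(self):
        segs = pd.DataFrame({"id_a": ["x"], "id_b": ["y"], "length_cm": [2.0]})
        assert build_ibd_graph(segs).number_of_edges() == 0

    def test_lengths_sum_per_pair(self):
        segs = pd.DataFrame(
            {"id_a": ["x", "y"], "id_b": ["y", "x"], "length_cm": [5.0, 10.0]}
        )
        g = build_ibd_graph(segs)
        assert g["x"]["y"]["weight"] == pytest.approx(15.0)

    def test_boundary_lengths_are_strictly_excluded(self):
        segs = pd.DataFrame(
            {"id_a": ["x", "x"], "id_b": ["y", "z"], "length_cm": [30.0, 3.0]}
        )
        assert build_ibd_graph(segs).number_of_edges() == 0

    def test_total_weight_conserves_retained_length(self):
        segs = simulate_ibd_segments([("a", 15), ("b", 15)], 1.0, 0.2, seed=3)
        g = build_ibd_graph(segs)
        assert g.size(weight="weight") == pytest.approx(segs["length_cm"].sum())

    def test_self_pairs_rejected(self):
        segs = pd.DataFrame({"id_a": ["x"], "id_b": ["x"], "length_cm": [5.0]})
        with pytest.raises(ValidationError):
            build_ibd_graph(segs)


def _two_cliques() -> nx.Graph:
    g = nx.Graph()
    for base in ("l", "r"):
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(f"{base}{i}", f"{base}{j}", weight=1.0)
    return g


class TestCommunityDetection:
    def test_disconnected_cliques_split_exactly(self):
        part = detect_communities(_two_cliques(), seed=0)
        comms = part.communities()
        assert len(comms) == 2
        assert sorted(map(tuple, comms.values())) == [
            tuple(f"l{i}" for i in range(5)),
            tuple(f"r{i}" for i in range(5)),
        ]

    def test_modularity_recomputes_identically(self):
        g = _two_cliques()
        part = detect_communities(g, seed=0)
        nx_q = nx.community.modularity(
            g, [set(m) for m in part.communities().values()], weight="weight"
        )
        assert part.modularity == pytest.approx(nx_q, abs=1e-12)
        assert part.modularity == pytest.approx(modularity(g, part.membership))

    def test_beats_singleton_partition(self):
        g = _two_cliques()
        part = detect_communities(g, seed=0)
        singletons = {n: i for i, n in enumerate(sorted(g.nodes))}
        assert part.modularity >= modularity(g, singletons)

    def test_partition_is_node_move_stable(self):
        segs = simulate_ibd_segments(
            [("a", 25), ("b", 25), ("c", 25)], 1.2, 0.1, seed=9
        )
        g = build_ibd_graph(segs)
        part = detect_communities(g, seed=2)
        base = modularity(g, part.membership)
        comms = set(part.membership.values())
        for node in g.nodes:
            for target in comms:
                if target == part.membership[node]:
                    continue
                trial = dict(part.membership)
                trial[node] = target
                assert modularity(g, trial) <= base + 1e-9

    def test_empty_graph_gives_empty_partition(self):
        part = detect_communities(nx.Graph(), seed=0)
        assert part.membership == {} and part.modularity == 0.0

    def test_planted_partition_recovery_matches_leidenalg(self):
        """Cross-check the in-package optimiser against the reference library."""
        import igraph as ig
        import leidenalg
        from sklearn.metrics import adjusted_rand_score

        segs = simulate_ibd_segments(
            [(f"c{i}", 40) for i in range(4)], 2.0, 0.05, seed=21
        )
        g = build_ibd_graph(segs)
        part = detect_communities(g, seed=1)
        nodes = sorted(g.nodes)
        ours = [part.membership[n] for n in nodes]

        h = ig.Graph.TupleList(
            ((u, v, w) for u, v, w in g.edges(data="weight")), weights=True
        )
        ref = leidenalg.find_partition(
            h, leidenalg.ModularityVertexPartition, weights="weight", seed=1
        )
        ref_by_name = dict(zip(h.vs["name"], ref.membership))
        theirs = [ref_by_name[n] for n in nodes]
        assert adjusted_rand_score(ours, theirs) > 0.9

    def test_seeded_runs_are_reproducible(self):
        segs = simulate_ibd_segments([("a", 30), ("b", 30)], 1.5, 0.1, seed=4)
        g = build_ibd_graph(segs)
        assert detect_communities(g, seed=7) == detect_communities(g, seed=7)


class TestAnnotation:
    def test_unanimous_references_name_the_community(self):
        part = detect_communities(_two_cliques(), seed=0)
        refs = {f"l{i}": "NW Ireland" for i in range(5)}
        names = annotate_communities(part, refs)
        assert set(names.values()) == {"NW Ireland", "unlabelled"}

    def test_majority_vote(self):
        part = detect_communities(_two_cliques(), seed=0)
        refs = {"l0": "A", "l1": "A", "l2": "A", "l3": "B", "l4": "B"}
        left = part.membership["l0"]
        assert annotate_communities(part, refs)[left] == "A"

    def test_exact_tie_produces_joint_label(self):
        part = detect_communities(_two_cliques(), seed=0)
        refs = {"l0": "B", "l1": "A"}
        left = part.membership["l0"]
        assert annotate_communities(part, refs)[left] == "A/B"
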