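"""Overlap detection, community clustering, graph shapes, tandem periods."""

import numpy as np
import pytest

import replowpass as rp
from replowpass._seq import random_seq, revcomp
from replowpass.clustering import (classify_graph_shape, cluster_representative,
                                   detect_tandem_period, overlap_graph)
from tests.conftest import find_overlaps_oracle


def _edge_set(edges):
    return {(e.read_a, e.read_b) for e in edges}


class TestFindOverlaps:
    def test_identical_reads_edge_with_full_identity(self):
        rng = np.random.default_rng(0)
        s = random_seq(rng, 100)
        edges = rp.find_overlaps([("a", s), ("b", s)])
        assert len(edges) == 1
        assert edges[0].identity == 1.0 and edges[0].shorter_coverage == 1.0

    def test_exact_substring_covers_shorter_read_fully(self):
        rng = np.random.default_rng(1)
        a = random_seq(rng, 100)
        edges = rp.find_overlaps([("A", a), ("B", a[20:80])])
        assert len(edges) == 1 and edges[0].shorter_coverage == 1.0

    def test_random_read_pairs_never_connect(self):
        rng = np.random.default_rng(2)
        reads = [(f"r{i}", random_seq(rng, 250)) for i in range(46)]
        assert rp.find_overlaps(reads) == []  # 1035 random pairs, 0 edges

    def test_strand_symmetry(self):
        # reverse-complementing any read changes no edge
        rng = np.random.default_rng(3)
        base = random_seq(rng, 300)
        reads = [(f"r{i}", base[s:s + 150]) for i, s in
                 enumerate([0, 50, 100, 150])]
        flipped = [(rid, revcomp(seq) if i % 2 else seq)
                   for i, (rid, seq) in enumerate(reads)]
        assert _edge_set(rp.find_overlaps(reads)) == \
            _edge_set(rp.find_overlaps(flipped))

    def test_seed_filter_equals_exhaustive_alignment(self):
        rng = np.random.default_rng(4)
        unit = random_seq(rng, 400)
        reads = []
        for i in range(30):
            start = int(rng.integers(0, 300))
            seq = (unit * 2)[start:start + int(rng.integers(80, 200))]
            reads.append((f"fam{i}", seq if i % 2 else revcomp(seq)))
        reads += [(f"bg{i}", random_seq(rng, 150)) for i in range(20)]
        fast = rp.find_overlaps(reads, use_seed_filter=True)
        slow = rp.find_overlaps(reads, use_seed_filter=False)
        assert _edge_set(fast) == _edge_set(slow)
        assert _edge_set(fast) == find_overlaps_oracle(reads)


class TestBuildClusters:
    def test_tandem_reads_cluster_background_stays_single(self):
        rng = np.random.default_rng(5)
        monomer = random_seq(rng, 43)
        array = monomer * 30
        fam = [(f"t{i}", (array[s:s + 250]))
               for i, s in enumerate(rng.integers(0, 800, size=30))]
        bg = [(f"b{i}", random_seq(rng, 250)) for i in range(30)]
        reads = fam + bg
        edges = rp.find_overlaps(reads)
        clusters, singletons = rp.build_clusters([r for r, _ in reads], edges)
        assert len(clusters) == 1 and clusters[0].size == 30
        assert set(clusters[0].members) == {r for r, _ in fam}
        assert len(singletons) == 30

    def test_two_families_give_two_clusters_matching_truth(self):
        rng = np.random.default_rng(6)
        m1, m2 = random_seq(rng, 50), random_seq(rng, 60)
        reads = []
        for name, mono in (("x", m1), ("y", m2)):
            array = mono * 30
            for i in range(25):
                s = int(rng.integers(0, 500))
                reads.append((f"{name}{i}", array[s:s + 240]))
        edges = rp.find_overlaps(reads)
        clusters, singletons = rp.build_clusters([r for r, _ in reads], edges)
        assert len(clusters) == 2 and not singletons
        memberships = [{m[0] for m in cl.members} for cl in clusters]
        assert {frozenset(m) for m in memberships} == {frozenset("x"), frozenset("y")}

    def test_empty_edge_set_gives_only_singletons(self):
        clusters, singletons = rp.build_clusters(["a", "b", "c"], [])
        assert clusters == [] and singletons == ["a", "b", "c"]

    def test_cluster_ids_stable_under_input_permutation(self):
        rng = np.random.default_rng(7)
        m1, m2 = random_seq(rng, 50), random_seq(rng, 55)
        reads = []
        for name, mono, n in (("x", m1, 20), ("y", m2, 12)):
            array = mono * 30
            for i in range(n):
                s = int(rng.integers(0, 400))
                reads.append((f"{name}{i}", array[s:s + 230]))
        edges = rp.find_overlaps(reads)
        clusters, _ = rp.build_clusters([r for r, _ in reads], edges)
        perm = list(reads)[::-1]
        edges2 = rp.find_overlaps(perm)
        clusters2, _ = rp.build_clusters([r for r, _ in perm], edges2)
        assert [(c.id, sorted(c.members)) for c in clusters] == \
            [(c.id, sorted(c.members)) for c in clusters2]


class TestClusterSummary:
    def test_proportions_and_half_coverage_rank(self):
        clusters = [rp.ReadCluster("CL1", [f"a{i}" for i in range(60)]),
                    rp.ReadCluster("CL2", [f"b{i}" for i in range(30)]),
                    rp.ReadCluster("CL3", [f"c{i}" for i in range(10)])]
        df = rp.cluster_summary(clusters, total_reads=200)
        assert df["proportion"].tolist() == [0.30, 0.15, 0.05]
        assert df["cumulative_proportion"].tolist() == pytest.approx([0.30, 0.45, 0.50])
        assert df.attrs["k_half"] == 3
        assert df.attrs["clustered_fraction"] == pytest.approx(0.5)

    def test_no_clusters_zero_fraction(self):
        df = rp.cluster_summary([], total_reads=100)
        assert df.attrs["clustered_fraction"] == 0.0
        assert df.attrs["k_half"] is None

    def test_zero_total_reads_error(self):
        with pytest.raises(ValueError):
            rp.cluster_summary([], total_reads=0)


class TestGraphShape:
    def _component_cluster(self, reads, which=0):
        edges = rp.find_overlaps(reads)
        clusters, _ = rp.build_clusters([r for r, _ in reads], edges,
                                        community_split=False)
        graph = overlap_graph([r for r, _ in reads], edges)
        return clusters[which], graph

    def test_long_unit_tandem_ring_is_circular(self):
        # 2 kb unit >> read length: reads tile the unit circle
        rng = np.random.default_rng(8)
        unit = random_seq(rng, 2000)
        array = unit * 14
        reads = []
        for i in range(150):
            s = int(rng.integers(0, len(array) - 260))
            seq = array[s:s + 250]
            reads.append((f"t{i}", seq if i % 2 else revcomp(seq)))
        cluster, graph = self._component_cluster(reads)
        assert cluster.size > 120
        assert classify_graph_shape(cluster, graph) == "circular"

    def test_dispersed_element_is_linear(self):
        # 5 kb element: reads tile a line, ends are eccentric
        rng = np.random.default_rng(9)
        element = random_seq(rng, 5000)
        reads = [(f"d{i}", element[s:s + 250]) for i, s in
                 enumerate(rng.integers(0, 4750, size=120))]
        cluster, graph = self._component_cluster(reads)
        assert classify_graph_shape(cluster, graph) == "linear"

    def test_short_monomer_satellite_is_globular(self):
        rng = np.random.default_rng(10)
        monomer = random_seq(rng, 43)
        array = monomer * 40
        reads = [(f"s{i}", array[s:s + 250]) for i, s in
                 enumerate(rng.integers(0, 1400, size=40))]
        cluster, graph = self._component_cluster(reads)
        assert classify_graph_shape(cluster, graph) == "globular"

    def test_small_cluster_is_other(self):
        cluster = rp.ReadCluster("CL1", [f"r{i}" for i in range(5)])
        import networkx as nx
        g = nx.complete_graph([f"r{i}" for i in range(5)])
        assert classify_graph_shape(cluster, g) == "other"


class TestTandemPeriod:
    def test_exact_pentamer_repeat(self):
        assert detect_tandem_period("ACGTT" * 20) == 5

    def test_random_sequence_has_no_period(self):
        rng = np.random.default_rng(11)
        seq = random_seq(rng, 300)
        # brute-force confirmation: no lag reaches 80% matching positions
        from replowpass._seq import encode
        codes = encode(seq)
        best = max(float((codes[:-p] == codes[p:]).mean())
                   for p in range(1, 101))
        assert best < 0.8
        assert detect_tandem_period(seq) is None

    def test_diverged_satellite_array_recovers_monomer_length(self):
        rng = np.random.default_rng(12)
        fam = rp.RepeatFamilySpec("sat", "tandem", 43, 40, 40, divergence=0.02)
        foot = fam.footprint("male")
        spec = rp.GenomeSimSpec((fam,), 1000, foot + 1000, foot + 1000, seed=13)
        pair = rp.build_genome_pair(spec)
        row = pair.layout.query("sex == 'male'").iloc[0]
        segment = pair.male[row.start:row.start + 400]
        assert detect_tandem_period(segment) == 43

    def test_period_from_cluster_representative(self):
        rng = np.random.default_rng(14)
        monomer = random_seq(rng, 43)
        array = monomer * 40
        reads = [(f"s{i}", array[s:s + 250]) for i, s in
                 enumerate(rng.integers(0, 1400, size=20))]
        edges = rp.find_overlaps(reads)
        clusters, _ = rp.build_clusters([r for r, _ in reads], edges)
        seqs = dict(reads)
        rep = cluster_representative(clusters[0], seqs)
        assert detect_tandem_period(seqs[rep]) == 43
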