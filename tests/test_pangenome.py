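"""Pan-genome construction: filtering, pre-clustering, MCL, partitions, Heaps."""

import networkx as nx
import numpy as np
import pytest

from conftest import label_of_gene, truth_gene_sets
from oracles import reference_mcl
from stalkscan.genome_io import GeneRecord, Genome
from stalkscan.pangenome import (
    SimilarityGraph,
    accumulation_and_heaps,
    build_pangenome,
    build_pangenomes_sweep,
    build_similarity_graph,
    filter_partial,
    fit_heaps,
    mcl_cluster,
    partition_pangenome,
    precluster,
)
from stalkscan.simulate import random_protein


def _gene(gid, seq, genome="G1", contig="c1", rank=0, start=None):
    start = start or (rank * 1000 + 1)
    return GeneRecord(gene_id=gid, genome_id=genome, contig_id=contig,
                      start=start, end=start + 3 * len(seq) + 2, strand="+",
                      locus_rank=rank, protein_seq=seq)


class TestFilterPartial:
    def test_length_filter(self):
        genes = [_gene("a", "M" * 35), _gene("b", "M" * 40, rank=1),
                 _gene("c", "M" * 300, rank=2)]
        kept, rejected = filter_partial(genes, min_len=40)
        assert [g.gene_id for g in kept] == ["b", "c"]
        assert [g.gene_id for g in rejected] == ["a"]

    def test_internal_stop_rejected(self):
        genes = [_gene("a", "MKL" * 20 + "*" + "MKL" * 20)]
        kept, rejected = filter_partial(genes, 40)
        assert not kept and len(rejected) == 1

    def test_all_valid(self):
        genes = [_gene("a", "MKLV" * 30)]
        kept, rejected = filter_partial(genes, 40)
        assert kept and not rejected


class TestPrecluster:
    def test_identical_absorbed(self):
        rng = np.random.default_rng(0)
        seq = random_protein(rng, 120)
        genes = [_gene("a", seq), _gene("b", seq, genome="G2")]
        members = precluster(genes)
        assert members == {"a": ["b"]}

    def test_divergent_stay_separate(self):
        rng = np.random.default_rng(1)
        a = random_protein(rng, 150)
        b = random_protein(rng, 150)
        members = precluster([_gene("a", a), _gene("b", b, genome="G2")])
        assert set(members) == {"a", "b"}
        assert members["a"] == [] and members["b"] == []

    def test_planted_duplicates_collapse(self):
        """Exact duplicates across genomes collapse to distinct-sequence count."""
        rng = np.random.default_rng(2)
        seqs = [random_protein(rng, 140) for _ in range(5)]
        genes = []
        for i, s in enumerate(seqs):
            for g in range(3):  # each sequence duplicated in 3 genomes
                genes.append(_gene(f"s{i}g{g}", s, genome=f"G{g}"))
        members = precluster(genes)
        assert len(members) == len(seqs)
        assert all(len(v) == 2 for v in members.values())


class TestSimilarityGraph:
    def test_triangle(self):
        rng = np.random.default_rng(3)
        seq = random_protein(rng, 200)
        reps = [_gene(f"g{i}", seq, genome=f"G{i}") for i in range(3)]
        sim = build_similarity_graph(reps, min_pid=90)
        assert sim.graph.number_of_edges() == 3

    def test_threshold_semantics(self):
        from stalkscan.simulate import diversify_family

        rng = np.random.default_rng(4)
        base = random_protein(rng, 300)
        (a, b), realized = diversify_family(base, 2, 55.0, rng)
        pid = realized[0, 1]
        reps = [_gene("a", a), _gene("b", b, genome="G2")]
        assert build_similarity_graph(reps, min_pid=pid + 1).graph.number_of_edges() == 0
        assert build_similarity_graph(reps, min_pid=pid - 5).graph.number_of_edges() == 1

    def test_edges_match_exhaustive_all_pairs(self):
        """Graph equals brute-force all-pairs align_pair on a 20-seq fixture."""
        from itertools import combinations

        from stalkscan.align import align_pair
        from stalkscan.simulate import diversify_family

        rng = np.random.default_rng(5)
        reps = []
        for f in range(5):
            base = random_protein(rng, 250)
            seqs, _ = diversify_family(base, 4, 70.0, rng)
            for i, s in enumerate(seqs):
                reps.append(_gene(f"f{f}m{i}", s, genome=f"G{i}"))
        min_pid, min_cov = 50.0, 25.0
        sim = build_similarity_graph(reps, min_pid, min_cov)
        expected = set()
        for x, y in combinations(reps, 2):
            st = align_pair(x.protein_seq, y.protein_seq)
            if st.pid >= min_pid and st.query_cov >= min_cov \
                    and st.subject_cov >= min_cov:
                expected.add(frozenset((x.gene_id, y.gene_id)))
        got = {frozenset(e) for e in sim.graph.edges}
        assert got == expected


def _sim_from_edges(edges):
    g = nx.Graph()
    for (u, v), w in edges.items():
        g.add_edge(u, v, pid=w)
    return SimilarityGraph(graph=g, threshold=0.0, min_cov=0.0)


class TestMCL:
    def test_disjoint_triangles(self):
        edges = {("a", "b"): 60, ("b", "c"): 60, ("a", "c"): 60,
                 ("x", "y"): 70, ("y", "z"): 70, ("x", "z"): 70}
        clusters = mcl_cluster(_sim_from_edges(edges))
        assert sorted(sorted(c) for c in clusters) == [["a", "b", "c"],
                                                       ["x", "y", "z"]]

    def test_isolated_node_singleton(self):
        g = nx.Graph()
        g.add_node("solo")
        clusters = mcl_cluster(SimilarityGraph(graph=g, threshold=0, min_cov=0))
        assert clusters == [{"solo"}]

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl_cluster(_sim_from_edges({("a", "b"): 50}), inflation=1.0)

    def test_barbell_splits_and_matches_oracle(self):
        """Two K6 joined by one weak edge -> 2 clusters of 6, same as the
        independent matrix-iteration reference."""
        edges = {}
        left = [f"l{i}" for i in range(6)]
        right = [f"r{i}" for i in range(6)]
        for grp in (left, right):
            for i in range(6):
                for j in range(i + 1, 6):
                    edges[(grp[i], grp[j])] = 100.0
        edges[("l0", "r0")] = 1.0
        clusters = mcl_cluster(_sim_from_edges(edges), inflation=1.5)
        expected = reference_mcl(left + right, edges, inflation=1.5)
        assert sorted(sorted(c) for c in clusters) == expected
        assert sorted(len(c) for c in clusters) == [6, 6]

    @pytest.mark.parametrize("seed", range(8))
    def test_random_graphs_match_oracle(self, seed):
        """Partitions equal the reference on random graphs <= 12 nodes."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        nodes = [f"n{i:02d}" for i in range(n)]
        edges = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    edges[(nodes[i], nodes[j])] = float(rng.integers(30, 101))
        got = mcl_cluster(_sim_from_edges(edges))
        # isolated nodes don't appear in the edge-built graph; add them
        present = {x for e in edges for x in e}
        singletons = [[x] for x in nodes if x not in present]
        expected = reference_mcl(sorted(present), edges) + singletons
        assert sorted(sorted(c) for c in got) + sorted(singletons) \
            == sorted(expected)


class TestBuildPangenome:
    def test_identical_genomes_full_core(self):
        rng = np.random.default_rng(6)
        seqs = [random_protein(rng, 150) for _ in range(8)]
        genomes = []
        for gid in ("A", "B"):
            genes = [_gene(f"{gid}_{i}", s, genome=gid, rank=i)
                     for i, s in enumerate(seqs)]
            genomes.append(Genome(gid, genes))
        pan = build_pangenome(genomes, 50.0)
        part = partition_pangenome(pan)
        assert len(pan.families) == 8
        assert part.n_core == 8 and part.n_accessory == 0 and part.n_unique == 0

    def test_disjoint_genomes_all_unique(self):
        rng = np.random.default_rng(7)
        genomes = []
        for gid in ("A", "B"):
            genes = [_gene(f"{gid}_{i}", random_protein(rng, 150),
                           genome=gid, rank=i) for i in range(6)]
            genomes.append(Genome(gid, genes))
        pan = build_pangenome(genomes, 30.0)
        part = partition_pangenome(pan)
        assert part.n_core == 0 and part.n_unique == len(pan.families) == 12

    def test_duplicate_genome_ids_rejected(self):
        rng = np.random.default_rng(8)
        g = Genome("A", [_gene("A_1", random_protein(rng, 100), genome="A")])
        with pytest.raises(ValueError, match="duplicate"):
            build_pangenome([g, g], 50.0)

    def test_membership_is_partition(self, small_pan50, small_community):
        genomes, _ = small_community
        all_genes = {g.gene_id for gen in genomes for g in gen.genes}
        seen = []
        for fam in small_pan50.families:
            seen.extend(fam.all_gene_ids())
        assert len(seen) == len(set(seen))
        assert set(seen) == all_genes  # nothing filtered at this scale

    def test_matrix_consistent_with_families(self, small_pan50):
        for fam in small_pan50.families:
            for gid in small_pan50.genomes:
                assert int(small_pan50.matrix.loc[gid, fam.family_id]) \
                    == len(fam.members.get(gid, []))

    def test_truth_reconciliation(self, default_pan50, default_community):
        """Recovered families reconcile exactly against the truth ledger:
        no family mixes two planted families, and every planted family
        whose minimum realized pairwise identity clears the threshold is
        recovered intact."""
        genomes, truth = default_community
        lab = label_of_gene(truth)
        by_label = {}
        for fam in default_pan50.families:
            labs = {lab[g] for g in fam.all_gene_ids()}
            assert len(labs) == 1, f"family {fam.family_id} mixes {labs}"
            by_label.setdefault(labs.pop(), []).append(fam)
        gene_sets = truth_gene_sets(truth)
        n_splits = 0
        for label, fams in by_label.items():
            planted = truth.families[label]
            if len(fams) == 1:
                assert frozenset(fams[0].all_gene_ids()) == gene_sets[label]
            else:
                n_splits += 1
                assert planted.realized_pairwise_min is not None
                assert planted.realized_pairwise_min < default_pan50.threshold + 5
        assert len(default_pan50.families) == len(truth.families) + n_splits

    def test_partition_matches_truth_patterns(self, default_pan50,
                                              default_community):
        _, truth = default_community
        part = partition_pangenome(default_pan50)
        n = len(default_pan50.genomes)
        want = {"core": 0, "accessory": 0, "unique": 0}
        for fam in truth.families.values():
            k = len(fam.presence())
            want["core" if k == n else "unique" if k == 1 else "accessory"] += 1
        assert part.n_core == want["core"]
        assert part.n_accessory == want["accessory"]
        assert part.n_unique == want["unique"]

    def test_threshold_refinement(self, small_community):
        """Families at threshold t+10 are subsets of families at t."""
        genomes, _ = small_community
        pans = build_pangenomes_sweep(genomes, [50.0, 60.0, 70.0])
        for lo, hi in ((50.0, 60.0), (60.0, 70.0)):
            coarse = [set(f.all_gene_ids()) for f in pans[lo].families]
            for fam in pans[hi].families:
                fine = set(fam.all_gene_ids())
                assert any(fine <= c for c in coarse)

    def test_sweep_equals_individual_builds(self, small_community):
        genomes, _ = small_community
        pans = build_pangenomes_sweep(genomes, [50.0, 70.0])
        for t in (50.0, 70.0):
            solo = build_pangenome(genomes, t)
            assert sorted(frozenset(f.all_gene_ids()) for f in pans[t].families) \
                == sorted(frozenset(f.all_gene_ids()) for f in solo.families)


class TestPartition:
    def test_small_example(self):
        rng = np.random.default_rng(9)
        shared = random_protein(rng, 150)
        pair = random_protein(rng, 150)
        genomes = []
        for i, gid in enumerate(("A", "B", "C")):
            genes = [_gene(f"{gid}_core", shared, genome=gid, rank=0)]
            if gid in ("A", "B"):
                genes.append(_gene(f"{gid}_pair", pair, genome=gid, rank=1))
            if gid == "C":
                genes.append(_gene("C_solo", random_protein(rng, 150),
                                   genome=gid, rank=1))
            genomes.append(Genome(gid, genes))
        part = partition_pangenome(build_pangenome(genomes, 50.0))
        assert (part.n_core, part.n_accessory, part.n_unique) == (1, 1, 1)


class TestAccumulationHeaps:
    def test_every_genome_new_families_gives_gamma_one(self):
        rng = np.random.default_rng(10)
        genomes = []
        for gi in range(6):
            gid = f"G{gi}"
            genes = [_gene(f"{gid}_{i}", random_protein(rng, 130),
                           genome=gid, rank=i) for i in range(5)]
            genomes.append(Genome(gid, genes))
        pan = build_pangenome(genomes, 30.0)
        curve, fit = accumulation_and_heaps(pan, n_perm=5, seed=0)
        assert fit.gamma == pytest.approx(1.0, abs=1e-9)
        assert fit.is_open
        assert list(curve.points["pan_median"]) == [5, 10, 15, 20, 25, 30]

    def test_identical_genomes_closed(self):
        rng = np.random.default_rng(11)
        seqs = [random_protein(rng, 130) for _ in range(6)]
        genomes = []
        for gid in ("A", "B", "C", "D"):
            genomes.append(Genome(gid, [
                _gene(f"{gid}_{i}", s, genome=gid, rank=i)
                for i, s in enumerate(seqs)]))
        pan = build_pangenome(genomes, 50.0)
        _, fit = accumulation_and_heaps(pan, n_perm=5, seed=0)
        assert abs(fit.gamma) < 1e-9
        assert not fit.is_open

    def test_monotone_curves(self, default_pan50):
        curve, _ = accumulation_and_heaps(default_pan50, n_perm=10, seed=1)
        pan_med = curve.points["pan_median"].to_numpy()
        core_med = curve.points["core_median"].to_numpy()
        assert (np.diff(pan_med) >= 0).all()
        assert (np.diff(core_med) <= 0).all()

    def test_noiseless_power_law_recovered_exactly(self):
        ns = np.arange(1, 17)
        sizes = 1000.0 * ns ** 0.3
        fit = fit_heaps(ns, sizes)
        assert fit.kappa == pytest.approx(1000.0, rel=1e-9)
        assert fit.gamma == pytest.approx(0.3, abs=1e-12)

    def test_permutation_invariance_under_seed(self, small_pan50):
        c1, f1 = accumulation_and_heaps(small_pan50, n_perm=8, seed=5)
        c2, f2 = accumulation_and_heaps(small_pan50, n_perm=8, seed=5)
        assert c1.points.equals(c2.points)
        assert f1 == f2
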