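"""FST, chord distances, NJ trees and source ranking."""

import numpy as np
import pytest

from founderflow import (GenotypeTable, assign_source, chord_distance_matrix,
                         fst_matrix, fst_permutation_test,
                         neighbor_joining_with_bootstrap, pairwise_fst)
from founderflow.differentiation import DistanceMatrix, _bipartitions, nj_tree


def random_table(rng, n_pops=2, n_loci=2, n_alleles=4, n_ind=12):
    pops = [f"P{i}" for i in range(n_pops)]
    genos = {}
    for p in pops:
        freqs = rng.dirichlet(np.ones(n_alleles), size=n_loci)
        inds = []
        for _ in range(n_ind):
            row = []
            for l in range(n_loci):
                a = sorted(rng.choice(n_alleles, size=2, p=freqs[l]) + 1)
                row.append((int(a[0]), int(a[1])))
            inds.append(row)
        genos[p] = inds
    return GenotypeTable(pops, [f"L{l}" for l in range(n_loci)], genos)


class TestPairwiseFst:
    def test_fixed_difference_gives_one(self, fixed_difference_table):
        assert pairwise_fst(fixed_difference_table, "A", "B") == pytest.approx(1.0)

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            t = random_table(rng)
            mine = pairwise_fst(t, "P0", "P1")
            assert mine == pytest.approx(wc_theta_multilocus(t), abs=1e-10)

    def test_null_on_panmictic_samples(self):
        rng = np.random.default_rng(7)
        freqs = rng.dirichlet(np.ones(6), size=3)
        genos = {}
        for p in ("X", "Y"):
            inds = []
            for _ in range(500):
                row = []
                for l in range(3):
                    a = sorted(rng.choice(6, size=2, p=freqs[l]) + 1)
                    row.append((int(a[0]), int(a[1])))
                inds.append(row)
            genos[p] = inds
        t = GenotypeTable(["X", "Y"], ["L0", "L1", "L2"], genos)
        assert abs(pairwise_fst(t, "X", "Y")) < 0.01

    def test_symmetry_and_relabeling(self, two_pop_table):
        t = two_pop_table
        assert pairwise_fst(t, "A", "B") == pytest.approx(
            pairwise_fst(t, "B", "A"))
        relabeled = GenotypeTable(
            t.population_ids, t.locus_ids,
            {p: [[None if g is None else (g[0] + 10, g[1] + 10) for g in ind]
                 for ind in t.genotypes[p]] for p in t.population_ids})
        assert pairwise_fst(relabeled, "A", "B") == pytest.approx(
            pairwise_fst(t, "A", "B"))

    def test_monomorphic_only_is_nan(self):
        t = GenotypeTable(["A", "B"], ["L1"], {
            "A": [[(1, 1)]] * 4, "B": [[(1, 1)]] * 4})
        assert np.isnan(pairwise_fst(t, "A", "B"))


def wc_theta_multilocus(table):
    """Per-locus transcription combined by summing components over loci."""
    num = den = 0.0
    for locus in table.locus_ids:
        j = table.locus_ids.index(locus)
        pops = [[ind[j] for ind in table.genotypes[p] if ind[j] is not None]
                for p in table.population_ids]
        alleles = sorted({a for pop in pops for g in pop for a in g})
        if len(alleles) < 2:
            continue
        r = len(pops)
        n = np.array([len(g) for g in pops], dtype=float)
        nbar = n.mean()
        nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
        for allele in alleles:
            p = np.array([sum((g[0] == allele) + (g[1] == allele)
                              for g in pop) / (2 * len(pop)) for pop in pops])
            h = np.array([sum(1 for g in pop if g[0] != g[1] and allele in g)
                          / len(pop) for pop in pops])
            pbar = (n * p).sum() / (r * nbar)
            s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n * h).sum() / (r * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            num += a
            den += a + b + hbar / 2
    return num / den


class TestPermutationTest:
    def test_fixed_difference_minimal_p(self, fixed_difference_table):
        p = fst_permutation_test(fixed_difference_table, "A", "B",
                                 reps=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_identical_populations_nonsignificant(self):
        genos = [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)], [(1, 1)], [(2, 2)]]
        t = GenotypeTable(["A", "B"], ["L1"], {"A": genos, "B": list(genos)})
        p = fst_permutation_test(t, "A", "B", reps=199, seed=2)
        assert p > 0.05

    def test_deterministic_under_seed(self, fixed_difference_table):
        p1 = fst_permutation_test(fixed_difference_table, "A", "B",
                                  reps=199, seed=5)
        p2 = fst_permutation_test(fixed_difference_table, "A", "B",
                                  reps=199, seed=5)
        assert p1 == p2

    def test_rejects_tiny_reps(self, fixed_difference_table):
        with pytest.raises(ValueError):
            fst_permutation_test(fixed_difference_table, "A", "B", reps=10)


class TestChordDistance:
    def make_table(self, fA, fB, n=50, seed=0):
        rng = np.random.default_rng(seed)
        genos = {}
        for pop, f in (("A", fA), ("B", fB)):
            inds = []
            for _ in range(n):
                a = sorted(rng.choice(len(f), size=2, p=f) + 1)
                inds.append([(int(a[0]), int(a[1]))])
            genos[pop] = inds
        return GenotypeTable(["A", "B"], ["L1"], genos)

    def test_identical_frequencies_zero(self):
        t = GenotypeTable(["A", "B"], ["L1"], {
            "A": [[(1, 2)]] * 10, "B": [[(1, 2)]] * 10})
        assert chord_distance_matrix(t).get("A", "B") == pytest.approx(0.0)

    def test_disjoint_support_is_one(self, fixed_difference_table):
        d = chord_distance_matrix(fixed_difference_table)
        assert d.get("A", "B") == pytest.approx(1.0)

    def test_symmetric_zero_diagonal(self, two_pop_table):
        d = chord_distance_matrix(two_pop_table)
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)


def random_additive_tree(rng, n_taxa):
    """Random unrooted binary tree topology with positive branch lengths,
    returned as (taxa, distance matrix, set of internal bipartitions)."""
    import itertools

    taxa = [f"T{i}" for i in range(n_taxa)]
    # grow a tree by random leaf attachment; represent as edge list
    nodes = {0: None}
    edges = {}  # node -> (parent, length)
    next_id = 1

    # start from a star of 3 leaves around internal node 0
    leaf_of = {}
    for i in range(3):
        edges[next_id] = (0, rng.uniform(0.5, 2.0))
        leaf_of[taxa[i]] = next_id
        next_id += 1
    for i in range(3, n_taxa):
        # split a random existing edge with a new internal node
        child = int(rng.choice(list(edges)))
        parent, length = edges[child]
        mid = next_id; next_id += 1
        cut = rng.uniform(0.2, 0.8) * length
        edges[mid] = (parent, length - cut)
        edges[child] = (mid, cut)
        leaf = next_id; next_id += 1
        edges[leaf] = (mid, rng.uniform(0.5, 2.0))
        leaf_of[taxa[i]] = leaf

    def path_to_root(node):
        out = []
        while node in edges:
            parent, length = edges[node]
            out.append((node, length))
            node = parent
        return out

    dm = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        pi = path_to_root(leaf_of[taxa[i]])
        pj = path_to_root(leaf_of[taxa[j]])
        nodes_i = {n for n, _ in pi}
        nodes_j = {n for n, _ in pj}
        d = sum(l for n, l in pi if n not in nodes_j) \
            + sum(l for n, l in pj if n not in nodes_i)
        dm[i, j] = dm[j, i] = d

    # bipartitions: for each internal edge (child is internal), leaves below
    children = {}
    for child, (parent, _) in edges.items():
        children.setdefault(parent, []).append(child)

    def leaves_below(node):
        if node not in children:
            return {t for t, l in leaf_of.items() if l == node}
        out = set()
        for c in children[node]:
            out |= leaves_below(c)
        return out

    ref = taxa[0]
    bps = set()
    for child in edges:
        if child in children:  # internal edge
            side = frozenset(leaves_below(child))
            if ref in side:
                side = frozenset(set(taxa) - side)
            if 1 < len(side) < n_taxa - 1:
                bps.add(side)
    return taxa, dm, bps


class TestNeighborJoining:
    def test_additive_four_taxon_example(self):
        labels = ["A", "B", "C", "D"]
        m = np.array([[0, 2, 4, 5],
                      [2, 0, 4, 5],
                      [4, 4, 0, 5],
                      [5, 5, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(labels, m, kind="chord"))
        taxa = frozenset(labels)
        bps = _bipartitions(tree, taxa)
        assert frozenset({"C", "D"}) in bps or frozenset({"A", "B"}) in bps
        # exact branch lengths from the generating tree
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(1.0, abs=1e-9)
        assert lengths["B"] == pytest.approx(1.0, abs=1e-9)
        assert lengths["C"] == pytest.approx(2.0, abs=1e-9)
        assert lengths["D"] == pytest.approx(3.0, abs=1e-9)

    def test_three_taxa_unique_topology(self):
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], m, kind="chord"))
        assert {t.name for t in tree.tips()} == {"A", "B", "C"}

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            taxa, dm, true_bps = random_additive_tree(rng, n)
            tree = nj_tree(DistanceMatrix(taxa, dm, kind="chord"))
            got = set(_bipartitions(tree, frozenset(taxa)))
            assert got == true_bps
            # NJ path distances reproduce the additive matrix
            tip = {t.name: t for t in tree.tips()}
            for i in range(n):
                for j in range(i + 1, n):
                    d = tip[taxa[i]].distance(tip[taxa[j]])
                    assert d == pytest.approx(dm[i, j], abs=1e-9)


class TestBootstrap:
    def test_identical_loci_full_support(self, small_scenario):
        from founderflow.synthetic import sample_dataset
        table, _, _ = sample_dataset(small_scenario)
        # duplicate a single locus so every pseudoreplicate is identical
        j = 0
        genos = {p: [[ind[j]] * 4 for ind in table.genotypes[p]]
                 for p in table.population_ids}
        t1 = GenotypeTable(table.population_ids, ["L"] * 1 + ["L2", "L3", "L4"],
                           genos)
        st = neighbor_joining_with_bootstrap(t1, reps=50, seed=0)
        assert all(v == 100.0 for v in st.supports.values())

    def test_reproducible_under_seed(self, small_scenario):
        from founderflow.synthetic import sample_dataset
        table, _, _ = sample_dataset(small_scenario)
        s1 = neighbor_joining_with_bootstrap(table, reps=30, seed=4)
        s2 = neighbor_joining_with_bootstrap(table, reps=30, seed=4)
        assert s1.supports == s2.supports
        assert s1.newick == s2.newick

    def test_newick_parseable(self, small_scenario):
        from founderflow.synthetic import sample_dataset
        import dendropy
        table, _, _ = sample_dataset(small_scenario)
        st = neighbor_joining_with_bootstrap(table, reps=20, seed=1)
        tree = dendropy.Tree.get(data=st.newick, schema="newick")
        assert {l.taxon.label for l in tree.leaf_node_iter()} \
            == set(table.population_ids)


class TestAssignSource:
    def test_identical_source_ranks_first(self):
        rng = np.random.default_rng(3)
        f = rng.dirichlet(np.ones(5))
        def draw(n):
            return [[tuple(sorted(rng.choice(5, size=2, p=f) + 1))]
                    for _ in range(n)]
        shared = draw(60)
        t = GenotypeTable(
            ["SRC", "OTHER", "INTRO"], ["L1"],
            {"SRC": [list(x) for x in shared],
             "OTHER": [[(9, 9)]] * 60,
             "INTRO": [list(x) for x in shared]})
        ranking = assign_source(fst_matrix(t), "INTRO")
        assert ranking.iloc[0]["population"] == "SRC"
        assert abs(ranking.iloc[0]["theta"]) < 0.05

    def test_equidistant_ties_reported(self):
        t = GenotypeTable(
            ["A", "B", "I"], ["L1"],
            {"A": [[(1, 1)]] * 10, "B": [[(1, 1)]] * 10,
             "I": [[(2, 2)]] * 10})
        ranking = assign_source(fst_matrix(t), "I")
        assert ranking["tied"].all()
        assert list(ranking["rank"]) == [1, 1]

    def test_nan_ranks_last(self):
        t = GenotypeTable(
            ["A", "B", "I"], ["L1"],
            {"A": [[(1, 1)]] * 10,          # monomorphic with I -> NaN
             "B": [[(1, 2)]] * 10,
             "I": [[(1, 1)]] * 10})
        ranking = assign_source(fst_matrix(t), "I")
        assert ranking.iloc[-1]["population"] == "A"
        assert np.isnan(ranking.iloc[-1]["theta"])
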