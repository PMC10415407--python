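"""Haplotype networks, TN93/NJ phylogenetics, and delimitation statistics."""

import itertools
import math
import subprocess

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from riboprofiler import popgen
from riboprofiler.popgen import (
    DistanceMatrix,
    clade_distances,
    collapse_haplotypes,
    jackknife_support,
    nj_tree,
    pairwise_mutation_steps,
    rodrigo_prd,
    rosenberg_pab,
    simulate_coalescent_tree,
    tcs_network,
    tn93_distance,
    tn93_matrix,
)
from riboprofiler.seqio import SeqRecord


class TestCollapse:
    def test_five_copies_one_haplotype(self):
        hs = collapse_haplotypes(["ACGT"] * 5)
        assert len(hs) == 1 and hs.multiplicities == [5]

    def test_single_site_difference_two_haplotypes(self):
        hs = collapse_haplotypes(["ACGT", "ACGA"])
        assert len(hs) == 2

    def test_ambiguity_codes_compared_literally(self):
        hs = collapse_haplotypes(["ACWT", "ACAT", "ACWT"])
        assert len(hs) == 2 and hs.multiplicities == [2, 1]

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            collapse_haplotypes(["ACGT", "ACG"])


class TestMutationSteps:
    def test_substitutions_counted_per_site(self):
        assert pairwise_mutation_steps("AAAA", "AATT") == 2

    def test_gap_run_is_single_event(self):
        assert pairwise_mutation_steps("AA--A", "AATTA") == 1
        assert pairwise_mutation_steps("A--A--A", "ATTATTA") == 2

    def test_shared_gaps_ignored(self):
        assert pairwise_mutation_steps("A--A", "A--A") == 0


class TestTcsNetwork:
    def test_single_step_pair_one_edge(self):
        net = tcs_network(collapse_haplotypes(["AAAA", "AAAT"]))
        g = net.graph
        assert g.number_of_edges() == 1 and not net.median_nodes

    def test_two_step_pair_gets_one_median(self):
        net = tcs_network(collapse_haplotypes(["AAAA", "AATT"]), limit_override=2)
        assert len(net.median_nodes) == 1
        assert net.graph.number_of_edges() == 2

    def test_sixteen_combinations_form_four_hypercube(self):
        sites = [0, 5, 10, 15]
        base = list("ACGTACGTACGTACGTACGT")
        seqs = []
        for combo in itertools.product(*(["AT"] * 4)):
            s = base[:]
            for k, c in zip(sites, combo):
                s[k] = c
            seqs.append("".join(s))
        net = tcs_network(collapse_haplotypes(seqs))
        g = net.graph
        assert g.number_of_nodes() == 16 and g.number_of_edges() == 32
        assert all(d == 4 for _, d in g.degree())
        # shortest-path steps equal Hamming distance (homoplasy-free)
        nodes = list(g.nodes())
        for a, b in itertools.combinations(nodes[:8], 2):
            ham = sum(x != y for x, y in zip(g.nodes[a]["sequence"],
                                            g.nodes[b]["sequence"]))
            assert nx.shortest_path_length(g, a, b) == ham

    def test_components_beyond_limit_stay_separate(self):
        net = tcs_network(collapse_haplotypes(["AAAAAAAA", "TTTTTTTT"]),
                          limit_override=3)
        assert nx.number_connected_components(net.graph) == 2

    def test_connection_limit_scales_with_alignment_length(self):
        short = popgen.parsimony_connection_limit(100)
        long_ = popgen.parsimony_connection_limit(1000)
        assert 1 <= short < long_


class TestTn93:
    def test_identical_sequences_zero(self):
        assert tn93_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_on_counted_frequencies(self):
        # 100 sites, balanced composition, 10 A<->G transitions only
        a = ("ACGT" * 25)
        b = list(a)
        swapped = 0
        for i, c in enumerate(a):
            if c == "A" and swapped < 10:
                b[i] = "G"
                swapped += 1
        b = "".join(b)
        # independent evaluation from hand-counted quantities
        pooled = a + b
        gA, gC, gG, gT = (pooled.count(x) / len(pooled) for x in "ACGT")
        gR, gY = gA + gG, gC + gT
        P1, P2, Q = 0.10, 0.0, 0.0
        k1 = 2 * gA * gG / gR
        k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
        expected = -k1 * math.log(1 - P1 / k1) - k3 * math.log(1.0)
        assert tn93_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_jukes_cantor_in_symmetric_limit(self, rng):
        a = "".join(rng.choice(list("ACGT"), 40000))
        b = list(a)
        # apply symmetric substitutions: every base equally likely
        idx = rng.choice(len(a), 2000, replace=False)
        for i in idx:
            b[i] = str(rng.choice([c for c in "ACGT" if c != a[i]]))
        b = "".join(b)
        p = float(np.mean([x != y for x, y in zip(a, b)]))
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert abs(tn93_distance(a, b) - jc) < 5e-4

    def test_exact_jc_equivalence_with_uniform_counts(self):
        # balanced composition with P1 = P2 = Q/4 (the equal-frequency,
        # equal-rate regime): TN93 collapses to Jukes-Cantor analytically
        a = "ACGT" * 300
        b = list(a)
        events = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                  ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G"),
                  ("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
        used = set()
        for src, dst in events:
            i = next(k for k in range(len(a)) if a[k] == src and k not in used)
            used.add(i)
            b[i] = dst
        d = tn93_distance(a, "".join(b))
        p = 12 / len(a)
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * p / 3), abs=1e-9)

    def test_symmetry(self, rng):
        a = "".join(rng.choice(list("ACGT"), 300))
        b = "".join(rng.choice(list("ACGT"), 300))
        assert tn93_distance(a, b) == pytest.approx(tn93_distance(b, a))

    def test_saturation_returns_infinity(self):
        assert tn93_distance("AAAA", "GGGG") == math.inf

    def test_zero_comparable_sites_rejected(self):
        with pytest.raises(ValueError):
            tn93_distance("----", "AAAA")

    def test_matches_ape_dist_dna(self, rng, tmp_path):
        n, L = 5, 600
        anc = rng.choice(list("ACGT"), L)
        seqs = []
        for _ in range(n):
            s = anc.copy()
            for j in rng.choice(L, int(rng.integers(5, 60)), replace=False):
                s[j] = rng.choice([c for c in "ACGT" if c != s[j]])
            seqs.append("".join(s))
        fa = tmp_path / "a.fa"
        fa.write_text("".join(f">s{i}\n{s}\n" for i, s in enumerate(seqs)))
        out = tmp_path / "d.csv"
        subprocess.run(
            ["Rscript", "-e",
             f'library(ape); a <- read.dna("{fa}", format="fasta"); '
             f'write.csv(as.matrix(dist.dna(a, model="TN93")), "{out}")'],
            check=True, capture_output=True)
        import pandas as pd
        ref = pd.read_csv(out, index_col=0).to_numpy()
        for i in range(n):
            for j in range(i + 1, n):
                assert tn93_distance(seqs[i], seqs[j]) == pytest.approx(
                    ref[i, j], abs=1e-4)


def _additive_matrix_from_random_tree(rng, n):
    """Random binary tree with positive branch lengths -> leaf distance matrix."""
    import dendropy
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n, taxon_namespace=taxa,
        rng=__import__("random").Random(int(rng.integers(1 << 30))))
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = float(rng.uniform(0.1, 2.0))
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in taxa]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[i], taxa[j])
    return labels, d, tree


class TestNeighborJoining:
    def test_additive_example_recovered_with_branch_lengths(self):
        dm = DistanceMatrix(["A", "B", "C", "D"],
                            np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                                      [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float))
        tree = nj_tree(dm)
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float))
        tree = nj_tree(dm)
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 0.0, "B": 2.0, "C": 3.0})

    def test_tie_break_is_deterministic(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(list("ABCD"), d)
        t1 = nj_tree(dm).to_newick()
        t2 = nj_tree(dm).to_newick()
        assert t1 == t2

    def test_twenty_random_additive_trees_recovered(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            labels, d, tree = _additive_matrix_from_random_tree(rng, n)
            built = nj_tree(DistanceMatrix(labels, d))
            # additivity: leaf-to-leaf path lengths in the built tree equal d
            import dendropy
            dt = dendropy.Tree.get(data=built.to_newick(), schema="newick")
            pdm = dt.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in dt.taxon_namespace}
            for i in range(n):
                for j in range(i + 1, n):
                    got = pdm.distance(taxa[labels[i]], taxa[labels[j]])
                    assert got == pytest.approx(d[i, j], rel=1e-6, abs=1e-6)

    def test_matches_skbio_topology(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        n = 7
        labels, d, _ = _additive_matrix_from_random_tree(rng, n)
        ours = nj_tree(DistanceMatrix(labels, d))
        theirs = skbio_nj(SkbioDM(d, ids=labels))
        import dendropy
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=ours.to_newick(), schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=str(theirs).replace("root", ""),
                               schema="newick", taxon_namespace=tns)
        from dendropy.calculate import treecompare
        assert treecompare.symmetric_difference(t1, t2) == 0

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.0]])))


class TestJackknife:
    def _two_clades(self, rng, n_diffs=25, width=494, per_group=4):
        anc = rng.choice(list("ACGT"), width)
        other = anc.copy()
        for i in rng.choice(width, n_diffs, replace=False):
            other[i] = [c for c in "ACGT" if c != other[i]][0]
        recs = []
        for g, base in (("x", anc), ("y", other)):
            for k in range(per_group):
                s = base.copy()
                # one private substitution per tip so distances are distinct
                j = rng.integers(0, width)
                s[j] = [c for c in "ACGT" if c != s[j]][0]
                recs.append(SeqRecord(f"{g}{k}", "".join(s)))
        return recs

    def test_deep_split_has_near_full_support(self, rng):
        recs = self._two_clades(rng)
        tree = jackknife_support(recs, replicates=200, seed=1)
        split = frozenset(f"x{k}" for k in range(4))
        supports = {}
        labels = frozenset(tree.leaf_labels)
        for node in tree.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf() or node.label is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            pick = min(side, labels - side, key=lambda s: (len(s), tuple(sorted(s))))
            supports[pick] = int(node.label)
        assert supports.get(split, 0) >= 99

    def test_identical_sequences_have_no_supported_bipartitions(self):
        recs = [SeqRecord(f"s{i}", "ACGTACGTACGTACGT") for i in range(5)]
        tree = jackknife_support(recs, replicates=50, seed=2)
        assert tree.bipartitions() == set()

    def test_same_seed_same_supports(self, rng):
        recs = self._two_clades(rng)
        t1 = jackknife_support(recs, replicates=100, seed=9).to_newick()
        t2 = jackknife_support(recs, replicates=100, seed=9).to_newick()
        assert t1 == t2


def _enumerate_histories_recip_mono(a, b):
    """Brute-force over all labeled coalescent histories of a+b tips."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def count(state):
        # state: tuple of frozensets (current lineages as tip-label sets)
        lineages = [set(s) for s in state]
        k = len(lineages)
        if k == 1:
            return 1, 1  # (total histories, histories keeping both groups pure)
        total = ok = 0
        for i in range(k):
            for j in range(i + 1, k):
                merged = lineages[i] | lineages[j]
                rest = [lineages[x] for x in range(k) if x not in (i, j)]
                new_state = tuple(sorted((frozenset(s) for s in rest + [merged]),
                                         key=lambda s: tuple(sorted(s))))
                t, o = count(new_state)
                total += t
                # purity: a merged lineage may not mix groups unless it is
                # the final root join
                mixes = any(x.startswith("a") for x in merged) and \
                    any(x.startswith("b") for x in merged)
                ok += o if (not mixes or k == 2) else 0
        return total, ok

    tips = tuple(sorted([frozenset([f"a{i}"]) for i in range(a)] +
                        [frozenset([f"b{i}"]) for i in range(b)],
                        key=lambda s: tuple(sorted(s))))
    total, ok = count(tips)
    return ok / total


class TestRosenberg:
    def test_two_singletons_always_monophyletic(self):
        assert rosenberg_pab(1, 1) == 1.0

    def test_small_exact_values(self):
        assert rosenberg_pab(2, 1) == pytest.approx(1 / 3)
        assert rosenberg_pab(2, 2) == pytest.approx(1 / 9)

    def test_agrees_with_labeled_history_enumeration_to_six_tips(self):
        for a in range(1, 6):
            for b in range(1, 7 - a):
                assert rosenberg_pab(a, b) == pytest.approx(
                    _enumerate_histories_recip_mono(a, b), abs=1e-12)

    def test_invalid_group_sizes_rejected(self):
        with pytest.raises(ValueError):
            rosenberg_pab(0, 3)


class TestRodrigo:
    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(0)
        pvals = []
        while len(pvals) < 120:
            tree = simulate_coalescent_tree(10, rng)
            cands = [nd for nd in tree.tree.preorder_node_iter()
                     if nd.parent_node is not None and not nd.is_leaf()
                     and 2 <= sum(1 for _ in nd.leaf_iter()) <= 8]
            if not cands:
                continue
            nd = cands[rng.integers(0, len(cands))]
            clade = {lf.taxon.label for lf in nd.leaf_iter()}
            pvals.append(rodrigo_prd(tree, clade, n_sim=99,
                                     seed=int(rng.integers(1 << 30))))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_extreme_stem_length_is_significant(self):
        tree = simulate_coalescent_tree(10, np.random.default_rng(5))
        cands = [nd for nd in tree.tree.preorder_node_iter()
                 if nd.parent_node is not None and not nd.is_leaf()
                 and sum(1 for _ in nd.leaf_iter()) >= 2]
        nd = cands[0]
        nd.edge.length = (nd.edge.length or 0.1) * 500
        clade = {lf.taxon.label for lf in nd.leaf_iter()}
        assert rodrigo_prd(tree, clade, n_sim=499, seed=1) <= 0.05

    def test_deterministic_given_seed(self):
        tree = simulate_coalescent_tree(8, np.random.default_rng(3))
        cands = [nd for nd in tree.tree.preorder_node_iter()
                 if nd.parent_node is not None and not nd.is_leaf()
                 and sum(1 for _ in nd.leaf_iter()) >= 2]
        clade = {lf.taxon.label for lf in cands[0].leaf_iter()}
        p1 = rodrigo_prd(tree, clade, n_sim=99, seed=7)
        p2 = rodrigo_prd(tree, clade, n_sim=99, seed=7)
        assert p1 == p2

    def test_singleton_clade_rejected(self):
        tree = simulate_coalescent_tree(5, np.random.default_rng(1))
        with pytest.raises(ValueError):
            rodrigo_prd(tree, {"t0"}, n_sim=10, seed=0)


class TestCladeDistances:
    def test_synthetic_one_percent_divergence_recovered(self, rng):
        width = 2000
        anc = rng.choice(list("ACGT"), width)
        other = anc.copy()
        for i in rng.choice(width, 20, replace=False):  # 1% divergence
            other[i] = [c for c in "ACGT" if c != other[i]][0]
        recs = [SeqRecord(f"a{k}", "".join(anc)) for k in range(3)] + \
               [SeqRecord(f"b{k}", "".join(other)) for k in range(3)]
        dm = tn93_matrix(recs)
        res = clade_distances(dm, {r.id: r.id[0] for r in recs})
        inter = {r.clade: r.inter_distance for r in res}
        assert inter["a"] == pytest.approx(0.01, abs=0.002)

    def test_identical_group_zero_intra(self):
        recs = [SeqRecord(f"a{k}", "ACGTACGT") for k in range(3)] + \
               [SeqRecord("b0", "ACGTACGA"), SeqRecord("b1", "ACGTACGA")]
        dm = tn93_matrix(recs)
        res = {r.clade: r for r in clade_distances(dm, {r.id: r.id[0] for r in recs})}
        assert res["a"].intra_distance == 0.0

    def test_singleton_group_intra_undefined(self):
        recs = [SeqRecord("a0", "ACGTACGT"), SeqRecord("a1", "ACGTACGT"),
                SeqRecord("b0", "ACGTACGA")]
        dm = tn93_matrix(recs)
        res = {r.clade: r for r in clade_distances(dm, {r.id: r.id[0] for r in recs})}
        assert math.isnan(res["b"].intra_distance)

    def test_taxon_missing_from_grouping_rejected(self):
        recs = [SeqRecord("a0", "ACGT"), SeqRecord("a1", "ACGT"),
                SeqRecord("b0", "ACGA")]
        dm = tn93_matrix(recs)
        with pytest.raises(ValueError):
            clade_distances(dm, {"a0": "a", "a1": "a"})
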