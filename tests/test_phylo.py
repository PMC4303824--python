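"""Distance matrices, NJ exactness, rooting, topology classes, ratios."""

import math

import dendropy
import networkx as nx
import numpy as np
import pytest

from regen_evo import (
    CladeMap,
    ProteinAlignment,
    SimulationConfig,
    bootstrap_support,
    classify_topology,
    mf_fp_ratio,
    midpoint_root,
    neighbor_joining,
    protein_distance_matrix,
    read_newick,
    simulate_family,
    write_newick,
)
from regen_evo.phylo import _splits, patristic_matrix

SIX_LEAF_MAP = CladeMap(
    {"m1": "metazoa", "m2": "metazoa", "f1": "fungi", "f2": "fungi",
     "p1": "plant", "p2": "plant"}
)


def random_additive_tree(rng, n_leaves):
    """Independent oracle: random unrooted tree as a weighted graph,
    leaf distances by shortest paths."""
    G = nx.Graph()
    counter = [0]

    def internal():
        counter[0] += 1
        return f"i{counter[0]}"

    center = internal()
    for l in range(3):
        G.add_edge(f"L{l:02d}", center, weight=float(rng.uniform(0.1, 1.0)))
    for l in range(3, n_leaves):
        edges = list(G.edges())
        u, v = edges[int(rng.integers(0, len(edges)))]
        w = G[u][v]["weight"]
        t = float(rng.uniform(0.2, 0.8))
        x = internal()
        G.remove_edge(u, v)
        G.add_edge(u, x, weight=w * t)
        G.add_edge(x, v, weight=w * (1.0 - t))
        G.add_edge(f"L{l:02d}", x, weight=float(rng.uniform(0.1, 1.0)))
    labels = sorted(n for n in G if n.startswith("L"))
    dist = dict(nx.all_pairs_dijkstra_path_length(G, weight="weight"))
    D = np.array([[dist[a][b] for b in labels] for a in labels])
    return labels, D


class TestProteinDistance:
    def test_identical_sequences_have_zero_distance(self):
        aln = ProteinAlignment({"a": "ACDEF", "b": "ACDEF", "c": "ACDEF"})
        _, D, _ = protein_distance_matrix(aln)
        assert np.allclose(D, 0.0)

    def test_kimura_formula_value(self):
        # p = 0.1 over 10 columns -> d = -ln(1 - 0.1 - 0.002)
        aln = ProteinAlignment(
            {"a": "AAAAAAAAAA", "b": "CAAAAAAAAA", "c": "AAAAAAAAAA"}
        )
        ids, D, _ = protein_distance_matrix(aln)
        expected = -math.log(1 - 0.1 - 0.2 * 0.01)
        assert D[ids.index("a"), ids.index("b")] == pytest.approx(expected)
        assert expected == pytest.approx(0.10756, abs=5e-5)

    def test_saturation_cap_and_flag(self):
        aln = ProteinAlignment({"a": "AAAA", "b": "CCCC", "c": "AAAA"})
        ids, D, sat = protein_distance_matrix(aln, max_distance=10.0)
        i, j = ids.index("a"), ids.index("b")
        assert D[i, j] == 10.0 and sat[i, j]

    def test_zero_overlap_pair_rejected(self):
        aln = ProteinAlignment({"a": "AA--", "b": "--CC", "c": "AACC"})
        with pytest.raises(ValueError, match="overlap"):
            protein_distance_matrix(aln)

    def test_symmetry_on_random_alignment(self):
        rng = np.random.default_rng(5)
        rows = {
            f"s{i}": "".join(rng.choice(list("ACDEFGHIKL"), size=40))
            for i in range(6)
        }
        _, D, _ = protein_distance_matrix(ProteinAlignment(rows))
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0.0)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(D, ["a", "b", "c"])
        labels, P = patristic_matrix(tree)
        assert np.allclose(P, D)

    def test_four_taxon_split_and_lengths(self):
        # ((a:1,b:1):1,(c:1,d:1):1) by path summation
        D = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float
        )
        tree = neighbor_joining(D, ["a", "b", "c", "d"])
        assert frozenset("ab") in {
            frozenset(s) for s in _splits(tree)
        } or frozenset("cd") in {frozenset(s) for s in _splits(tree)}
        _, P = patristic_matrix(tree)
        assert np.allclose(P, D)

    def test_recovers_random_additive_matrices(self):
        rng = np.random.default_rng(11)
        for rep in range(50):
            n = int(rng.integers(6, 13))
            labels, D = random_additive_tree(rng, n)
            tree = neighbor_joining(D, labels)
            out_labels, P = patristic_matrix(tree)
            assert out_labels == labels
            assert np.allclose(P, D, atol=1e-8)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(3)
        labels, D = random_additive_tree(rng, 7)
        t1 = neighbor_joining(D, labels)
        perm = list(rng.permutation(len(labels)))
        t2 = neighbor_joining(D[np.ix_(perm, perm)], [labels[i] for i in perm])
        assert {frozenset(s) for s in _splits(t1)} == {
            frozenset(s) for s in _splits(t2)
        }

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(D, list("abc"))


class TestPatristic:
    def test_matches_dendropy_oracle(self):
        rng = np.random.default_rng(8)
        labels, D = random_additive_tree(rng, 8)
        tree = neighbor_joining(D, labels)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        mine_labels, mine = patristic_matrix(tree)
        for i, a in enumerate(mine_labels):
            for j, b in enumerate(mine_labels):
                if i < j:
                    assert mine[i, j] == pytest.approx(
                        pdm.patristic_distance(taxa[a], taxa[b])
                    )


class TestMidpointRoot:
    def test_root_lands_on_longest_path(self):
        rooted = midpoint_root(read_newick("((a:1,b:1):1,c:4);"))
        # longest path a-c (or b-c) = 6; midpoint 3 from each end, on c's edge
        kids = {
            (c.taxon.label if c.is_leaf() else "internal"): c.edge.length
            for c in rooted.seed_node.child_nodes()
        }
        # root equidistant (3) from a and c; the old degree-2 root is
        # suppressed, merging its edge into the (a,b) side: 1 + 1 = 2
        assert kids == pytest.approx({"c": 3.0, "internal": 2.0})

    def test_balanced_tree_roots_on_central_edge(self):
        rooted = midpoint_root(read_newick("((a:1,b:1):1,(c:1,d:1):1);"))
        sides = [
            frozenset(l.taxon.label for l in c.leaf_iter())
            for c in rooted.seed_node.child_nodes()
        ]
        assert frozenset("ab") in sides and frozenset("cd") in sides

    def test_idempotent_on_rooted_input(self):
        once = midpoint_root(read_newick("((a:1,b:1):1,c:4);"))
        twice = midpoint_root(once)
        assert write_newick(twice) == write_newick(once)

    def test_all_zero_lengths_rejected(self):
        with pytest.raises(ValueError):
            midpoint_root(read_newick("((a:0,b:0):0,c:0);"))


class TestClassifyTopology:
    def test_opisthokonta_clade_is_tol_like(self):
        t = read_newick("(((m1:1,m2:1):1,(f1:1,f2:1):1):1,(p1:1,p2:1):2);")
        call = classify_topology(t, SIX_LEAF_MAP)
        assert call.category == "tol_like"
        assert all(call.monophyly.values())

    def test_fungi_with_plants_is_autotrophic_paraphyly(self):
        t = read_newick("((m1:1,m2:1):2,((f1:1,f2:1):1,(p1:1,p2:1):1):1);")
        assert classify_topology(t, SIX_LEAF_MAP).category == "autotrophic_paraphyly"

    def test_metazoa_with_plants_is_fungi_outgroup(self):
        t = read_newick("((f1:1,f2:1):2,((m1:1,m2:1):1,(p1:1,p2:1):1):1);")
        assert classify_topology(t, SIX_LEAF_MAP).category == "fungi_outgroup"

    def test_interleaved_fungi_is_unresolved(self):
        t = read_newick("((f1:1,(p1:1,p2:1):1):1,(f2:1,(m1:1,m2:1):1):1);")
        call = classify_topology(t, SIX_LEAF_MAP)
        assert call.category == "unresolved"
        assert not call.monophyly["fungi"]

    def test_empty_clade_rejected(self):
        t = read_newick("((m1:1,m2:1):1,(f1:1,f2:1):1);")
        with pytest.raises(ValueError, match="plant"):
            classify_topology(t, SIX_LEAF_MAP)


class TestMfFpRatio:
    def test_hand_computed_example(self):
        t = read_newick("((m1:1,m2:1):1,((f1:1,f2:1):1,(p1:1,p2:1):1):1);")
        # all mf paths = 5, all fp paths = 4
        assert mf_fp_ratio(t, SIX_LEAF_MAP) == pytest.approx(1.25)

    def test_monotone_in_metazoan_scaling(self):
        ratios = []
        for k in (1.0, 2.0, 4.0):
            t = read_newick(
                f"((m1:{k},m2:{k}):{k},((f1:1,f2:1):1,(p1:1,p2:1):1):1);"
            )
            ratios.append(mf_fp_ratio(t, SIX_LEAF_MAP))
        assert ratios[0] < ratios[1] < ratios[2]

    def test_swapping_metazoa_and_plants_inverts_ratio(self):
        t = read_newick("((m1:1,m2:1):1,((f1:1,f2:1):1,(p1:1,p2:1):1):1);")
        swapped = CladeMap(
            {k: {"metazoa": "plant", "plant": "metazoa"}.get(v, v)
             for k, v in SIX_LEAF_MAP.entries.items()}
        )
        assert mf_fp_ratio(t, swapped) == pytest.approx(
            1.0 / mf_fp_ratio(t, SIX_LEAF_MAP)
        )


class TestBootstrap:
    def test_same_seed_same_supports(self, small_tol_family):
        aln = small_tol_family.protein_aln
        t1 = bootstrap_support(aln, n_reps=10, seed=4)
        t2 = bootstrap_support(aln, n_reps=10, seed=4)
        assert write_newick(t1) == write_newick(t2)

    def test_single_replicate_supports_are_binary(self, small_tol_family):
        t = bootstrap_support(small_tol_family.protein_aln, n_reps=1, seed=0)
        labels = {n.label for n in t.postorder_internal_node_iter() if n.label}
        assert labels <= {"0.000", "1.000"}

    def test_clean_signal_gives_high_clade_support(self):
        fam = simulate_family(SimulationConfig(n_per_clade=3, n_codons=300, seed=2))
        tree = bootstrap_support(fam.protein_aln, n_reps=40, seed=5)
        splits = _splits(tree)
        everyone = frozenset(fam.clade_map.entries)
        for clade in fam.clade_map.clade_order:
            members = frozenset(
                i for i, c in fam.clade_map.entries.items() if c == clade
            )
            node = splits.get(members) or splits.get(everyone - members)
            assert node is not None, f"{clade} split absent from point tree"
            assert float(node.label) >= 0.9

    def test_short_alignment_rejected(self):
        aln = ProteinAlignment({"a": "A", "b": "C", "c": "D"})
        with pytest.raises(ValueError):
            bootstrap_support(aln, n_reps=2, seed=0)
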