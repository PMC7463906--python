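import math

import numpy as np
import pytest

from genophen import seqdist, synthdata
from genophen.distmat import DistanceMatrix
from genophen.seqdist import (
    MarkerAlignment,
    bootstrap_support,
    concatenate,
    evolutionary_distance,
    neighbor_joining,
    read_alignment_fasta,
    read_newick,
    tree_bipartitions,
    tree_distance_matrix,
    write_alignment_fasta,
    write_newick,
)

def _toy_pair():
    # TN93 on this pair is frozen below from an independent run of
    # ape::dist.dna(model="TN93") on the same two sequences.
    s1 = "ACGT" * 25
    l2 = list(s1)
    for i in (0, 4, 8, 12, 16):
        l2[i] = "G"  # A->G transitions
    for i in (1, 5, 9, 13):
        l2[i] = "T"  # C->T transitions
    for i in (2, 6, 10, 14, 18, 22):
        l2[i] = "C"  # G->C transversions
    return MarkerAlignment("toy", ("A", "B"), (s1, "".join(l2)))


class TestAlignmentIO:
    def test_round_trip(self, tmp_path):
        aln = MarkerAlignment("x", ("t one", "t2"), ("ACGT-", "ACGTN"))
        p = tmp_path / "x.fasta"
        write_alignment_fasta(aln, p)
        back = read_alignment_fasta(p, "x")
        assert back.taxa[1] == "t2" and back.sequences == aln.sequences

    def test_ragged_alignment_names_offender(self):
        with pytest.raises(ValueError, match="'B'"):
            MarkerAlignment("x", ("A", "B"), ("ACGTACGTAC", "ACGTACGTA"))

    def test_duplicate_header_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nACGT\n>a\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_alignment_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_alignment_fasta(p)

    def test_lowercase_uppercased(self):
        aln = MarkerAlignment("x", ("A",), ("acgt",))
        assert aln.sequences == ("ACGT",)


class TestConcatenate:
    def test_lengths_add(self):
        a = MarkerAlignment("ITS", ("x", "y"), ("A" * 600, "C" * 600))
        b = MarkerAlignment("LSU", ("y", "x"), ("G" * 570, "T" * 570))
        c = concatenate([a, b], name="ITS_LSU")
        assert c.length == 1170
        # taxon order of the first alignment; sequences matched by label
        assert c.taxa == ("x", "y")
        assert c.sequences[0] == "A" * 600 + "T" * 570

    def test_single_alignment_identity(self):
        a = MarkerAlignment("ITS", ("x", "y"), ("ACGT", "AGGT"))
        c = concatenate([a])
        assert c.taxa == a.taxa and c.sequences == a.sequences

    def test_disjoint_taxa_error_lists_difference(self):
        a = MarkerAlignment("a", ("x", "y"), ("AC", "AC"))
        b = MarkerAlignment("b", ("x", "z"), ("AC", "AC"))
        with pytest.raises(ValueError, match="missing=\\['y'\\]"):
            concatenate([a, b])


class TestDistances:
    def test_identical_sequences_zero_every_model(self):
        aln = MarkerAlignment("x", ("A", "B"), ("ACGTACGT", "ACGTACGT"))
        for model in ("p", "JC69", "K80", "TN93"):
            assert evolutionary_distance(aln, model)["A", "B"] == 0.0

    def test_jc69_closed_form(self):
        aln = MarkerAlignment("x", ("A", "B"), ("ACGTACGTAC", "ACGTACGTAT"))
        assert evolutionary_distance(aln, "p")["A", "B"] == pytest.approx(0.1)
        d = evolutionary_distance(aln, "JC69")["A", "B"]
        assert d == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), abs=1e-9)
        assert d == pytest.approx(0.107326, abs=1e-6)

    def test_k80_closed_form(self):
        # 2 transitions + 1 transversion on 10 sites: P=0.2, Q=0.1
        aln = MarkerAlignment("x", ("A", "B"), ("ACGTACGTAC", "GCGTGCGTCC"))
        d = evolutionary_distance(aln, "K80")["A", "B"]
        assert d == pytest.approx(-0.5 * math.log(0.5) - 0.25 * math.log(0.8), abs=1e-9)
        assert d == pytest.approx(0.402360, abs=1e-6)

    def test_tn93_matches_ape(self):
        d = evolutionary_distance(_toy_pair(), "TN93")["A", "B"]
        assert d == pytest.approx(0.169718986, abs=1e-9)

    def test_correction_inflates_p_distance(self, rng):
        # JC69 >= p for 0 < p < 0.5 on random pairs
        for _ in range(20):
            L = 200
            s1 = rng.integers(0, 4, L)
            s2 = s1.copy()
            k = rng.integers(1, 80)
            pos = rng.choice(L, size=k, replace=False)
            s2[pos] = (s2[pos] + rng.integers(1, 4, size=k)) % 4
            dec = np.frombuffer(b"ACGT", dtype=np.uint8)
            aln = MarkerAlignment(
                "x", ("A", "B"),
                (dec[s1].tobytes().decode(), dec[s2].tobytes().decode()),
            )
            p = evolutionary_distance(aln, "p")["A", "B"]
            jc = evolutionary_distance(aln, "JC69")["A", "B"]
            assert jc >= p

    def test_deletion_modes(self):
        aln = MarkerAlignment(
            "x", ("A", "B", "C"), ("ACGTAC", "ACGTAT", "AC-TAC")
        )
        comp = evolutionary_distance(aln, "p", deletion="complete")
        pair = evolutionary_distance(aln, "p", deletion="pairwise")
        # complete deletion drops the gapped column for every pair
        assert comp["A", "B"] == pytest.approx(1 / 5)
        # pairwise keeps it for A-B
        assert pair["A", "B"] == pytest.approx(1 / 6)

    def test_saturation_error_names_pair(self):
        aln = MarkerAlignment("x", ("A", "B"), ("AAAA", "CCCC"))
        with pytest.raises(ValueError, match="A.*B"):
            evolutionary_distance(aln, "JC69")

    def test_k80_agrees_with_jc69_on_jc_data(self):
        # under JC69 evolution, K80 and JC69 estimates agree within 3 SE
        aln = synthdata.simulate_marker_alignment(
            synthdata.DEFAULT_TREE, 20000, 1.0, seed=4
        )
        jc = evolutionary_distance(aln, "JC69")
        k80 = evolutionary_distance(aln, "K80")
        p = evolutionary_distance(aln, "p")
        for i, a in enumerate(aln.taxa):
            for b in aln.taxa[i + 1:]:
                se = math.sqrt(p[a, b] * (1 - p[a, b]) / 20000)
                assert abs(jc[a, b] - k80[a, b]) < 3 * se + 1e-12


class TestNeighborJoining:
    def test_worked_four_taxon_example(self):
        D = DistanceMatrix(
            ("A", "B", "C", "D"),
            np.array(
                [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
            ),
        )
        tree = neighbor_joining(D)
        splits = tree_bipartitions(tree)
        assert frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})}) in splits
        # leaf edges 1,2,3,4 and internal edge 1
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        np.testing.assert_allclose(
            tree_distance_matrix(tree).reorder(D.labels).values, D.values, atol=1e-9
        )

    def test_three_taxon_closed_form(self):
        D = DistanceMatrix.from_condensed(("a", "b", "c"), [3.0, 4.0, 5.0])
        tree = neighbor_joining(D)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_additive_recovery_random_trees(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            D, _ = synthdata.random_additive_matrix(n, rng)
            tree = neighbor_joining(D)
            P = tree_distance_matrix(tree).reorder(D.labels)
            np.testing.assert_allclose(P.values, D.values, atol=1e-9)

    def test_ultrametric_path_metric_reproduced(self):
        # equidistant 4-taxon matrix: any resolution valid, paths must match
        D = DistanceMatrix(
            ("a", "b", "c", "d"), np.full((4, 4), 2.0) - 2.0 * np.eye(4)
        )
        tree = neighbor_joining(D)
        P = tree_distance_matrix(tree).reorder(D.labels)
        np.testing.assert_allclose(P.values, D.values, atol=1e-9)

    def test_matches_skbio_topology(self, rng):
        skbio = pytest.importorskip("skbio")
        D, _ = synthdata.random_additive_matrix(6, rng)
        ours = neighbor_joining(D)
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(D.values, ids=list(D.labels)))
        sk = read_newick_from_string(str(sk_tree))
        assert tree_bipartitions(ours) == tree_bipartitions(sk)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError, match="3"):
            neighbor_joining(DistanceMatrix(("a", "b"), np.array([[0, 1], [1, 0.]])))


def read_newick_from_string(s):
    import dendropy

    return dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)


class TestBootstrap:
    def test_identical_columns_repeated_full_support(self):
        # every resample of identical columns rebuilds the same split
        aln = MarkerAlignment(
            "x", ("A", "B", "C", "D"),
            ("A" * 200, "A" * 200, "C" * 200, "C" * 200),
        )
        tree = bootstrap_support(aln, model="p", n_reps=25, seed=0)
        labels = [
            int(nd.label)
            for nd in tree.preorder_node_iter()
            if nd.label is not None and not nd.is_leaf()
        ]
        assert labels and all(v == 100 for v in labels)

    def test_single_replicate_supports_binary(self):
        aln = synthdata.simulate_marker_alignment(
            synthdata.DEFAULT_TREE, 500, 1.0, seed=3
        )
        tree = bootstrap_support(aln, n_reps=1, seed=1)
        vals = {
            int(nd.label)
            for nd in tree.preorder_node_iter()
            if nd.label is not None and not nd.is_leaf()
        }
        assert vals <= {0, 100}

    def test_true_split_high_support_long_alignment(self):
        aln = synthdata.simulate_marker_alignment(
            synthdata.DEFAULT_TREE, 5000, 1.0, seed=5
        )
        tree = bootstrap_support(aln, n_reps=200, seed=7)
        # the generating tree separates (cerevisiae,paradoxus) | rest
        for nd in tree.preorder_node_iter():
            if nd.is_leaf() or nd.parent_node is None or nd.label is None:
                continue
            below = {l.taxon.label for l in nd.leaf_iter()}
            if below in ({"S_cerevisiae", "S_paradoxus"},
                         {"S_bayanus", "S_pastorianus"}):
                assert int(nd.label) >= 95

    def test_deterministic_under_seed(self):
        aln = synthdata.simulate_marker_alignment(
            synthdata.DEFAULT_TREE, 800, 1.0, seed=6
        )
        t1 = bootstrap_support(aln, n_reps=30, seed=9)
        t2 = bootstrap_support(aln, n_reps=30, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_taxon_order_equivariance(self):
        aln = synthdata.simulate_marker_alignment(
            synthdata.DEFAULT_TREE, 800, 1.0, seed=8
        )
        perm = MarkerAlignment(
            aln.locus_name,
            tuple(reversed(aln.taxa)),
            tuple(reversed(aln.sequences)),
        )
        def supports(tree):
            leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
            out = {}
            for nd in tree.preorder_node_iter():
                if nd.is_leaf() or nd.parent_node is None or nd.label is None:
                    continue
                below = frozenset(l.taxon.label for l in nd.leaf_iter())
                out[frozenset({below, leaves - below})] = int(nd.label)
            return out

        assert supports(bootstrap_support(aln, n_reps=40, seed=3)) == supports(
            bootstrap_support(perm, n_reps=40, seed=3)
        )


class TestNewickIO:
    def test_round_trip_three_leaf_star(self, tmp_path):
        D = DistanceMatrix.from_condensed(("a", "b", "c"), [3.0, 4.0, 5.0])
        tree = neighbor_joining(D)
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        assert {l.taxon.label for l in back.leaf_node_iter()} == {"a", "b", "c"}
        np.testing.assert_allclose(
            tree_distance_matrix(back).reorder(D.labels).values, D.values, atol=1e-9
        )

    def test_supports_serialized_as_integers(self, tmp_path):
        aln = synthdata.simulate_marker_alignment(
            synthdata.DEFAULT_TREE, 1000, 1.0, seed=10
        )
        tree = bootstrap_support(aln, n_reps=20, seed=2)
        p = tmp_path / "b.nwk"
        write_newick(tree, p)
        text = p.read_text()
        assert ")" in text and ":" in text

    def test_labels_with_spaces_quoted(self, tmp_path):
        D = DistanceMatrix.from_condensed(("a x", "b", "c"), [3.0, 4.0, 5.0])
        tree = neighbor_joining(D)
        p = tmp_path / "s.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        assert {l.taxon.label for l in back.leaf_node_iter()} == {"a x", "b", "c"}
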