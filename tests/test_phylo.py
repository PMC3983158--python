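import numpy as np
import pytest

from famevo.align import Scoring, global_align
from famevo.io import SeqRecord, SeqRecordSet
from famevo.motifs import CATALYTIC_MOTIFS
from famevo.phylo import (
    DistanceMatrix,
    MultipleAlignment,
    assign_groups,
    bootstrap_support,
    nj_tree,
    pdistance_matrix,
    progressive_align,
    root_with_outgroup,
)
from famevo.tree import PhyloTree, TreeNode
from tests.conftest import random_leafy_tree, tree_leaf_distances


def _mutate(seq, n, rng):
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    out = list(seq)
    for pos in rng.choice(len(seq), size=n, replace=False):
        out[pos] = aa[int(rng.integers(0, 20))]
    return "".join(out)


class TestProgressiveAlign:
    def test_identical_pair_gapless(self):
        seqs = SeqRecordSet([SeqRecord("a", "MKTAYI"), SeqRecord("b", "MKTAYI")])
        aln = progressive_align(seqs)
        assert aln.rows == ["MKTAYI", "MKTAYI"]

    def test_pairwise_case_equals_global_dp(self):
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        other = _mutate(base, 6, rng)[:55]
        seqs = SeqRecordSet([SeqRecord("a", base), SeqRecord("b", other)])
        aln = progressive_align(seqs)
        pair = global_align(base, other, Scoring.protein())
        # same optimal score implies equivalent alignment quality
        assert aln.ungapped(0) == base and aln.ungapped(1) == other
        score = 0.0
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        go, ge = -11.0, -1.0
        in_gap = None
        for x, y in zip(aln.rows[0], aln.rows[1]):
            if x != "-" and y != "-":
                score += blosum[x, y]
                in_gap = None
            else:
                which = "a" if x == "-" else "b"
                score += ge if in_gap == which else go
                in_gap = which
        assert score == pytest.approx(pair.score)

    def test_gap_strip_round_trip(self, genome):
        _, proteins, _, _, truth = genome
        family = proteins.subset(truth.family_member_ids)
        aln = progressive_align(family)
        for i, gid in enumerate(aln.ids):
            assert aln.ungapped(i) == family[gid].residues

    def test_motifs_align_in_common_columns(self, genome):
        _, proteins, _, _, truth = genome
        family = proteins.subset(truth.family_member_ids)
        aln = progressive_align(family)
        # family members carry motifs at homologous scaffold positions;
        # each motif occurrence must occupy the same columns in every row
        for consensus in CATALYTIC_MOTIFS.values():
            starts = set()
            for row in aln.rows:
                degapped_to_col = [
                    j for j, ch in enumerate(row) if ch != "-"
                ]
                seq = row.replace("-", "")
                pos = seq.find(consensus)
                if pos < 0:  # tolerate single-mismatch copies
                    continue
                starts.add(degapped_to_col[pos])
            assert len(starts) == 1

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            progressive_align(SeqRecordSet([SeqRecord("a", "MKT")]))


class TestPDistance:
    def test_simple_mismatch_fraction(self):
        aln = MultipleAlignment(ids=["a", "b"], rows=["AAAA", "AAAT"])
        d = pdistance_matrix(aln)
        assert d.values[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion(self):
        aln = MultipleAlignment(ids=["a", "b"], rows=["AA-A", "AAAA"])
        d = pdistance_matrix(aln)
        assert d.values[0, 1] == 0.0

    def test_identical_rows_zero(self):
        aln = MultipleAlignment(ids=["a", "b"], rows=["ACDE", "ACDE"])
        assert pdistance_matrix(aln).values[0, 1] == 0.0

    def test_no_shared_columns_names_pair(self):
        aln = MultipleAlignment(ids=["x", "y"], rows=["AA--", "--AA"])
        with pytest.raises(ValueError, match="x.*y"):
            pdistance_matrix(aln)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
        )
        tree = nj_tree(d)
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths == pytest.approx({"A": 0.05, "B": 0.15, "C": 0.25})

    def test_ultrametric_cherries_paired(self):
        # two clear cherries (A,B) and (C,D)
        m = np.array(
            [
                [0.0, 0.1, 1.0, 1.0],
                [0.1, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.1],
                [1.0, 1.0, 0.1, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], m))
        assert frozenset({"A", "B"}) in tree.splits() or frozenset(
            {"C", "D"}
        ) in tree.splits()

    @pytest.mark.parametrize("seed", range(30))
    def test_additive_matrix_exact_recovery(self, seed):
        rng = np.random.default_rng(seed)
        truth = random_leafy_tree(int(rng.integers(5, 13)), rng)
        ids, d = tree_leaf_distances(truth)
        recovered = nj_tree(DistanceMatrix(ids, d))
        assert recovered.splits() == truth.splits()
        ids2, d2 = tree_leaf_distances(recovered)
        perm = [ids2.index(i) for i in ids]
        assert np.allclose(d, d2[np.ix_(perm, perm)], atol=1e-9)

    def test_matches_independent_library_nj(self):
        # scikit-bio's nj as an independent topology oracle
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from famevo.tree import read_newick

        rng = np.random.default_rng(99)
        for _ in range(5):
            truth = random_leafy_tree(7, rng)
            ids, d = tree_leaf_distances(truth)
            mine = nj_tree(DistanceMatrix(ids, d))
            theirs = skbio.tree.nj(SkbioDM(d, ids))
            parsed = read_newick(str(theirs))
            assert mine.splits() == parsed.splits()

    def test_non_finite_distance_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = np.inf
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"], m)


class TestBootstrap:
    def _clade_alignment(self, rng, n_per_clade=3, length=120, within=2, between=45):
        base1 = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
        base2 = _mutate(base1, between, rng)
        rows, ids = [], []
        for k in range(n_per_clade):
            ids.append(f"a{k}")
            rows.append(_mutate(base1, within, rng))
        for k in range(n_per_clade):
            ids.append(f"b{k}")
            rows.append(_mutate(base2, within, rng))
        return MultipleAlignment(ids=ids, rows=rows)

    def test_separated_clades_full_support(self):
        rng = np.random.default_rng(12)
        aln = self._clade_alignment(rng)
        tree, info = bootstrap_support(aln, n_reps=100, seed=5)
        supports = tree.splits(with_support=True)
        clade = frozenset({"b0", "b1", "b2"})
        assert supports[clade] == 100.0
        assert info["valid"] == 100

    def test_single_replicate_support_binary(self):
        rng = np.random.default_rng(3)
        aln = self._clade_alignment(rng)
        tree, _ = bootstrap_support(aln, n_reps=1, seed=1)
        values = set(tree.splits(with_support=True).values())
        assert values <= {0.0, 100.0}

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(8)
        aln = self._clade_alignment(rng)
        t1, _ = bootstrap_support(aln, n_reps=25, seed=9)
        t2, _ = bootstrap_support(aln, n_reps=25, seed=9)
        assert t1.splits(with_support=True) == t2.splits(with_support=True)


class TestRootingAndGroups:
    def _tree(self):
        # ((A,B),(C,D)) unrooted with D as outgroup candidate
        ab = TreeNode(length=0.2, children=[TreeNode("A", 0.1), TreeNode("B", 0.1)])
        return PhyloTree(
            TreeNode(children=[ab, TreeNode("C", 0.3), TreeNode("D", 0.6)]),
            rooted=False,
        )

    def test_single_outgroup_pendant_root(self):
        rooted = root_with_outgroup(self._tree(), ["D"])
        assert rooted.rooted
        sides = [frozenset(c.leaf_names()) for c in rooted.root.children]
        assert frozenset({"D"}) in sides

    def test_unknown_outgroup_rejected(self):
        with pytest.raises(ValueError, match="Z"):
            root_with_outgroup(self._tree(), ["Z"])

    def test_non_monophyletic_outgroup_rejected(self):
        with pytest.raises(ValueError, match="monophyletic"):
            root_with_outgroup(self._tree(), ["A", "C"])

    def test_outgroup_clade_rooting_makes_ingroup_monophyletic(self):
        rng = np.random.default_rng(21)
        rows = {}
        base_in = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        base_out = _mutate(base_in, 50, rng)
        for k in range(4):
            rows[f"in{k}"] = _mutate(base_in, 3, rng)
        for k in range(2):
            rows[f"out{k}"] = _mutate(base_out, 3, rng)
        aln = MultipleAlignment(ids=list(rows), rows=list(rows.values()))
        tree = nj_tree(pdistance_matrix(aln))
        rooted = root_with_outgroup(tree, ["out0", "out1"])
        groups = assign_groups(
            rooted,
            {l: ("out" if l.startswith("out") else "in") for l in rooted.leaf_names},
        )
        assert groups["in"]["monophyletic"]
        assert groups["out"]["monophyletic"]

    def test_group_monophyly_flags(self):
        m = TreeNode(children=[TreeNode("m1", 0.1), TreeNode("m2", 0.1)], length=0.1)
        d = TreeNode(children=[TreeNode("d1", 0.1), TreeNode("d2", 0.1)], length=0.1)
        tree = PhyloTree(TreeNode(children=[m, d]), rooted=True)
        report = assign_groups(
            tree, {"m1": "mono", "m2": "mono", "d1": "eudi", "d2": "eudi"}
        )
        assert report["mono"]["monophyletic"] and report["eudi"]["monophyletic"]

    def test_interleaved_labels_not_monophyletic(self):
        a = TreeNode(children=[TreeNode("m1", 0.1), TreeNode("d1", 0.1)], length=0.1)
        b = TreeNode(children=[TreeNode("m2", 0.1), TreeNode("d2", 0.1)], length=0.1)
        tree = PhyloTree(TreeNode(children=[a, b]), rooted=True)
        report = assign_groups(
            tree, {"m1": "mono", "m2": "mono", "d1": "eudi", "d2": "eudi"}
        )
        assert not report["mono"]["monophyletic"]
        assert not report["eudi"]["monophyletic"]

    def test_unlabeled_leaf_rejected(self):
        tree = self._tree()
        with pytest.raises(ValueError, match="unlabeled"):
            assign_groups(tree, {"A": "x"})
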