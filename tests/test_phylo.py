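import itertools

import numpy as np
import pytest
from Bio import Align

from genefam import phylo
from genefam.io_formats import SequenceRecord
from genefam.tree import TreeNode, parse_newick, robinson_foulds
from tests.conftest import random_protein


def biopython_score(a, b, gap_open=10.0, gap_extend=0.5):
    """Independent affine-gap oracle."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = \
        Align.substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner.score(a, b)


def random_additive_tree(labels, rng):
    """Random binary tree with positive branch lengths."""
    nodes = [TreeNode(label=lab, length=float(rng.uniform(0.5, 3.0)))
             for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(children=[nodes[i], nodes[j]],
                          length=float(rng.uniform(0.5, 3.0)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return TreeNode(children=nodes)


class TestPairwiseAlign:
    def test_self_alignment(self):
        aln = phylo.pairwise_align("MKVLA", "MKVLA")
        assert aln.identity_pct == 100.0
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_four_of_five_identity(self):
        aln = phylo.pairwise_align("MKVLA", "MKVIA")
        assert aln.identity_pct == pytest.approx(80.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            phylo.pairwise_align("", "MKV")

    def test_score_matches_independent_oracle(self, rng):
        for _ in range(10):
            a = random_protein(rng, int(rng.integers(50, 200)))
            b = random_protein(rng, int(rng.integers(50, 200)))
            aln = phylo.pairwise_align(a, b)
            assert aln.score == pytest.approx(biopython_score(a, b))

    def test_identity_symmetric(self, rng):
        for _ in range(5):
            a = random_protein(rng, 60)
            b = random_protein(rng, 70)
            assert phylo.percent_identity(a, b) == pytest.approx(
                phylo.percent_identity(b, a))


class TestBuildMsa:
    def test_identical_sequences_no_gaps(self):
        records = [SequenceRecord("a", "", "MKVLAW"),
                   SequenceRecord("b", "", "MKVLAW")]
        msa = phylo.build_msa(records)
        assert all("-" not in r.residues for r in msa.records)

    def test_one_gap_column_matches_pairwise(self):
        records = [SequenceRecord("a", "", "ACDEF"),
                   SequenceRecord("b", "", "ACEF")]
        msa = phylo.build_msa(records)
        rows = {r.id: r.residues for r in msa.records}
        pw = phylo.pairwise_align("ACDEF", "ACEF")
        assert rows["a"] == pw.aligned_a
        assert rows["b"] == pw.aligned_b

    def test_degap_reproduces_inputs(self, family_records):
        msa = phylo.build_msa(family_records[:10])
        originals = {r.id: r.residues for r in family_records[:10]}
        for row in msa.records:
            assert row.residues.replace("-", "") == originals[row.id]

    def test_column_count_at_least_longest_input(self, rng):
        records = [SequenceRecord(f"r{i}", "",
                                  random_protein(rng,
                                                 int(rng.integers(20, 60))))
                   for i in range(5)]
        msa = phylo.build_msa(records)
        assert msa.n_columns >= max(len(r.residues) for r in records)


class TestPdistance:
    def _msa(self, rows):
        return phylo.MultipleAlignment(
            [SequenceRecord(f"r{i}", "", row)
             for i, row in enumerate(rows)])

    def test_identical_rows_zero(self):
        dm = phylo.msa_pdistance(self._msa(["ACDE", "ACDE"]))
        assert dm.values[0, 1] == 0.0

    def test_gap_column_excluded_pairwise(self):
        dm = phylo.msa_pdistance(self._msa(["AC-D", "ACED"]))
        assert dm.values[0, 1] == 0.0

    def test_no_shared_columns_raises(self):
        with pytest.raises(ValueError, match="r0.*r1"):
            phylo.msa_pdistance(self._msa(["AC--", "--DE"]))

    def test_matches_brute_force_recount(self, rng):
        alphabet = "ACDE-"
        rows = ["".join(alphabet[i] for i in rng.integers(0, 5, 30))
                for _ in range(5)]
        rows = [r if r.replace("-", "") else r[:-1] + "A" for r in rows]
        dm = phylo.msa_pdistance(self._msa(rows), on_empty="max")
        for i, j in itertools.combinations(range(5), 2):
            shared = mism = 0
            for x, y in zip(rows[i], rows[j]):
                if x != "-" and y != "-":
                    shared += 1
                    mism += x != y
            expected = mism / shared if shared else 1.0
            assert dm.values[i, j] == pytest.approx(expected)


class TestNjTree:
    def test_known_additive_four_taxa(self):
        labels = ["A", "B", "C", "D"]
        matrix = np.array([[0, 3, 5, 6],
                           [3, 0, 6, 7],
                           [5, 6, 0, 7],
                           [6, 7, 7, 0]], dtype=float)
        tree = phylo.nj_tree(phylo.DistanceMatrix(labels, matrix))
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        dm = phylo.additive_tree_distances(tree)
        assert np.allclose(dm.values, matrix)

    def test_three_taxa_closed_form(self):
        matrix = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = phylo.nj_tree(phylo.DistanceMatrix(["X", "Y", "Z"], matrix))
        dm = phylo.additive_tree_distances(tree)
        assert np.allclose(dm.values, matrix)

    def test_label_permutation_invariance(self, rng):
        labels = [f"t{i}" for i in range(8)]
        tree = random_additive_tree(labels, rng)
        matrix = phylo.additive_tree_distances(tree)
        reference = phylo.nj_tree(matrix)
        for _ in range(20):
            order = rng.permutation(len(labels))
            shuffled = phylo.DistanceMatrix(
                [matrix.labels[i] for i in order],
                matrix.values[np.ix_(order, order)])
            assert robinson_foulds(reference,
                                   phylo.nj_tree(shuffled)) == 0

    def test_recovers_random_additive_trees(self, rng):
        for n in (4, 5, 6, 7, 8):
            labels = [f"x{i}" for i in range(n)]
            truth = random_additive_tree(labels, rng)
            dm = phylo.additive_tree_distances(truth)
            recovered = phylo.nj_tree(dm)
            assert robinson_foulds(truth, recovered) == 0
            back = phylo.additive_tree_distances(recovered)
            assert np.allclose(back.values, dm.values)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            phylo.DistanceMatrix(["a", "b"],
                                 np.array([[0, 1], [2, 0.0]]))


def _divergent_pairs_msa(rng, n_pairs=4, length=60):
    """Pairs of near-identical rows, pairs far apart."""
    records = []
    for p in range(n_pairs):
        base = random_protein(rng, length)
        mutant = list(base)
        for k in rng.integers(0, length, size=3):
            mutant[k] = "A" if mutant[k] != "A" else "C"
        records.append(SequenceRecord(f"p{p}x", "", base))
        records.append(SequenceRecord(f"p{p}y", "", "".join(mutant)))
    return phylo.MultipleAlignment(records)


class TestBootstrap:
    def test_distinct_pairs_get_high_cherry_support(self, rng):
        msa = _divergent_pairs_msa(rng)
        tree = phylo.bootstrap_support(msa, reps=100, seed=3)
        cherries = [n for n in tree.preorder()
                    if len(n.children) == 2
                    and all(c.is_leaf for c in n.children)]
        assert len(cherries) >= 3
        assert all(n.support >= 95 for n in cherries)

    def test_single_rep_supports_binary(self, rng):
        msa = _divergent_pairs_msa(rng)
        tree = phylo.bootstrap_support(msa, reps=1, seed=0)
        supports = [n.support for n in tree.preorder()
                    if n.support is not None]
        assert supports and set(supports) <= {0, 100}

    def test_fixed_seed_reproducible(self, rng):
        msa = _divergent_pairs_msa(rng)
        t1 = phylo.bootstrap_support(msa, reps=30, seed=5)
        t2 = phylo.bootstrap_support(msa, reps=30, seed=5)
        s1 = [n.support for n in t1.preorder()]
        s2 = [n.support for n in t2.preorder()]
        assert s1 == s2


class TestCutSubfamilies:
    def _two_clade_tree(self, support):
        left = "(" + ",".join(f"a{i}:0.1" for i in range(5)) + ")"
        right = "(" + ",".join(f"b{i}:0.1" for i in range(5)) + ")"
        text = f"({left}{support}:1.0,{right}{support}:1.0);"
        return parse_newick(text)

    def test_two_supported_clades(self):
        part = phylo.cut_subfamilies(self._two_clade_tree(99))
        labels = set(part.subfamily_of.values())
        assert len(labels) == 2
        for label in labels:
            members = part.members(label)
            assert len(members) == 5
            assert len({m[0] for m in members}) == 1

    def test_all_weak_supports_gives_singletons(self):
        part = phylo.cut_subfamilies(self._two_clade_tree(10))
        assert len(set(part.subfamily_of.values())) == 10

    def test_forged_subfamilies_recovered(self, forge, family_tree):
        part = phylo.cut_subfamilies(family_tree)
        truth = forge.truth.subfamily_of
        correct = 0
        used = set()
        by_truth = {}
        for gene, sub in truth.items():
            by_truth.setdefault(sub, set()).add(gene)
        by_pred = {}
        for gene, sub in part.subfamily_of.items():
            by_pred.setdefault(sub, set()).add(gene)
        for sub, members in sorted(by_truth.items(),
                                   key=lambda kv: -len(kv[1])):
            best = max((p for p in by_pred if p not in used),
                       key=lambda p: len(by_pred[p] & members))
            used.add(best)
            overlap = by_pred[best] & members
            if len(by_pred[best]) <= len(overlap) + 2:
                correct += len(overlap)
        assert correct / len(truth) >= 0.9


class TestFindParalogPairs:
    def test_cherry_above_threshold_reported(self):
        tree = parse_newick("((A:1,B:1)99:1,C:2);")
        pairs = phylo.find_paralog_pairs(tree, lambda a, b: 85.0)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("A", "B")]

    def test_cherry_below_threshold_excluded(self):
        tree = parse_newick("((A:1,B:1)99:1,C:2);")
        assert phylo.find_paralog_pairs(tree, lambda a, b: 60.0) == []

    def test_forged_pairs_recovered_exactly(self, forge, family_tree):
        pairs = phylo.find_paralog_pairs(
            family_tree,
            lambda a, b: phylo.percent_identity(forge.protein_of[a],
                                                forge.protein_of[b]))
        got = {(p.gene_a, p.gene_b) for p in pairs}
        assert got == set(forge.truth.pair_ids)

    def test_forged_identities_in_range(self, forge, family_tree):
        pairs = phylo.find_paralog_pairs(
            family_tree,
            lambda a, b: phylo.percent_identity(forge.protein_of[a],
                                                forge.protein_of[b]))
        for pair in pairs:
            assert 70.0 <= pair.identity_pct <= 100.0
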