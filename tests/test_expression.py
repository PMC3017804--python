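import numpy as np
import pandas as pd
import pytest

from genefam import expression as expr
from genefam.io_formats import SequenceRecord

NT = "ACGT"


def random_nt(rng, length):
    return "".join(NT[i] for i in rng.integers(0, 4, length))


class TestMatchEsts:
    def test_exact_substring_hit(self, rng):
        cds = random_nt(rng, 600)
        records = [SequenceRecord("g1", "", cds)]
        est = SequenceRecord("e1", "", cds[100:250])
        hits = expr.match_ests(records, [est])
        assert len(hits) == 1
        assert hits[0].gene_id == "g1"
        assert hits[0].identity_pct == pytest.approx(100.0)
        assert hits[0].alignment_length == 150

    def test_95_percent_match_rejected(self, rng):
        cds = random_nt(rng, 400)
        chunk = list(cds[50:150])
        for k in (10, 30, 50, 70, 90):
            chunk[k] = NT[(NT.index(chunk[k]) + 1) % 4]
        hits = expr.match_ests([SequenceRecord("g1", "", cds)],
                               [SequenceRecord("e1", "", "".join(chunk))])
        assert hits == []

    def test_short_match_rejected(self, rng):
        cds = random_nt(rng, 400)
        est = SequenceRecord("e1", "", cds[10:95])
        assert expr.match_ests([SequenceRecord("g1", "", cds)], [est]) == []

    def test_acceptance_monotone_in_identity_threshold(self, rng):
        cds_records = [SequenceRecord(f"g{i}", "", random_nt(rng, 500))
                       for i in range(3)]
        ests = []
        for i, rec in enumerate(cds_records):
            chunk = list(rec.residues[i * 50:i * 50 + 200])
            for k in range(0, 200, 67):
                chunk[k] = NT[(NT.index(chunk[k]) + 1) % 4]
            ests.append(SequenceRecord(f"e{i}", "", "".join(chunk)))
        previous = None
        for threshold in (90.0, 96.0, 98.0, 99.5):
            hits = expr.match_ests(cds_records, ests,
                                   min_identity_pct=threshold)
            ids = {h.est_id for h in hits}
            if previous is not None:
                assert ids <= previous
            previous = ids

    def test_forged_counts_match_truth(self, full_forge):
        truth = full_forge.truth
        cds = [c for c in full_forge.genome.cds
               if c.id in set(truth.family_members)]
        ests, library_of = [], {}
        for lib, records in full_forge.ests.libraries.items():
            for rec in records:
                ests.append(rec)
                library_of[rec.id] = lib
        hits = expr.match_ests(cds, ests, library_of=library_of)
        assert not ({h.est_id for h in hits}
                    & set(truth.near_miss_est_ids))
        manifest = dict(zip(full_forge.ests.manifest.library_id,
                            full_forge.ests.manifest.tissue))
        counts, _ = expr.digital_northern(
            hits, manifest, all_genes=truth.family_members,
            tissues=list(full_forge.genome.config.tissues))
        for gene, per_tissue in truth.est_counts.items():
            for tissue, n in per_tissue.items():
                assert counts.loc[gene, tissue] == n


class TestDigitalNorthern:
    def _hits(self):
        return [expr.ESTHit("e1", "g1", 99.0, 150, "L1"),
                expr.ESTHit("e2", "g1", 99.0, 150, "L1"),
                expr.ESTHit("e3", "g2", 99.0, 120, "L2")]

    def test_counts_cells(self):
        counts, absent = expr.digital_northern(
            self._hits(), {"L1": "shoot_meristem", "L2": "root"},
            all_genes=["g1", "g2", "g3"])
        assert counts.loc["g1", "shoot_meristem"] == 2
        assert counts.loc["g2", "root"] == 1
        assert absent == ["g3"]

    def test_sum_equals_hit_count(self):
        counts, _ = expr.digital_northern(
            self._hits(), {"L1": "a", "L2": "b"})
        assert counts.to_numpy().sum() == 3

    def test_unknown_library_rejected(self):
        with pytest.raises(KeyError, match="unknown library"):
            expr.digital_northern(self._hits(), {"L1": "a"})


class TestCollapseProbes:
    def test_median_of_three(self):
        matrix = pd.DataFrame([[2.0], [4.0], [9.0]],
                              index=["p1", "p2", "p3"], columns=["t"])
        out = expr.collapse_probes(matrix, {"p1": ["g"], "p2": ["g"],
                                            "p3": ["g"]})
        assert out.loc["g", "t"] == 4.0

    def test_shared_probe_copied_to_each_gene(self):
        matrix = pd.DataFrame([[7.0]], index=["p1"], columns=["t"])
        out = expr.collapse_probes(matrix, {"p1": ["g1", "g2"]})
        assert out.loc["g1", "t"] == 7.0
        assert out.loc["g2", "t"] == 7.0

    def test_forged_probe_table_collapses_to_truth(self, full_forge):
        out = expr.collapse_probes(full_forge.expression.probe_matrix,
                                   full_forge.expression.probe_to_gene)
        expected = full_forge.expression.expected_collapsed
        assert np.allclose(out.loc[expected.index].to_numpy(),
                           expected.to_numpy())


class TestNormalize:
    def test_row_max(self):
        matrix = pd.DataFrame([[2.0, 4.0, 8.0]], index=["g"],
                              columns=list("abc"))
        out = expr.normalize_matrix(matrix, "row_max")
        assert list(out.loc["g"]) == [0.25, 0.5, 1.0]

    def test_log2_offset(self):
        matrix = pd.DataFrame([[7.0]], index=["g"], columns=["a"])
        assert expr.normalize_matrix(matrix, "log2").loc["g", "a"] == 3.0

    def test_row_max_idempotent(self, rng):
        matrix = pd.DataFrame(rng.random((5, 4)) * 10,
                              index=list("abcde"), columns=list("wxyz"))
        once = expr.normalize_matrix(matrix, "row_max")
        twice = expr.normalize_matrix(once, "row_max")
        assert np.allclose(once.to_numpy(), twice.to_numpy())

    def test_zero_row_left_alone(self):
        matrix = pd.DataFrame([[0.0, 0.0]], index=["g"],
                              columns=["a", "b"])
        out = expr.normalize_matrix(matrix, "row_max")
        assert list(out.loc["g"]) == [0.0, 0.0]


def scipy_average_linkage(matrix):
    """Independent oracle for merge heights."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform
    dist = expr._pearson_distance(matrix)
    return linkage(squareform(dist, checks=False), method="average")


class TestHcluster:
    def test_identical_rows_merge_first_at_zero(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0],
                               [1.0, 2.0, 3.0],
                               [3.0, 1.0, 0.0]],
                              index=list("abc"), columns=list("xyz"))
        dendro = expr.hcluster(matrix)
        i, j, height = dendro.merges[0]
        assert {i, j} == {0, 1}
        assert height == pytest.approx(0.0)

    def test_anticorrelated_distance_two(self):
        matrix = np.array([[1.0, 2, 3, 4], [4.0, 3, 2, 1]])
        dist = expr._pearson_distance(matrix)
        assert dist[0, 1] == pytest.approx(2.0)

    def test_merge_heights_match_naive_oracle(self, rng):
        for _ in range(10):
            matrix = rng.random((10, 6)) * 5
            mine = expr.hcluster(pd.DataFrame(matrix))
            oracle = scipy_average_linkage(matrix)
            assert np.allclose(sorted(h for _, _, h in mine.merges),
                               sorted(oracle[:, 2]), atol=1e-9)

    def test_invariant_under_row_permutation(self, rng):
        matrix = rng.random((8, 5))
        base = expr.hcluster(pd.DataFrame(matrix,
                                          index=[f"g{i}" for i in range(8)]))
        order = rng.permutation(8)
        shuffled = expr.hcluster(pd.DataFrame(
            matrix[order], index=[f"g{i}" for i in order]))
        assert np.allclose(sorted(h for _, _, h in base.merges),
                           sorted(h for _, _, h in shuffled.merges))

    def test_newick_export_parses(self):
        from genefam.tree import parse_newick
        matrix = pd.DataFrame(np.arange(12.0).reshape(4, 3) % 5,
                              index=list("abcd"), columns=list("xyz"))
        dendro = expr.hcluster(matrix)
        tree = parse_newick(dendro.newick())
        assert tree.leaf_labels() == {"a", "b", "c", "d"}


class TestPeakCalls:
    def test_argmax_and_tie_break(self):
        matrix = pd.DataFrame(
            [[1.0, 5.0, 2.0], [4.0, 4.0, 1.0]],
            index=["g1", "g2"], columns=["MC", "FC", "DX"])
        calls, summary = expr.peak_tissue_calls(matrix)
        by_gene = {c.gene_id: c for c in calls}
        assert by_gene["g1"].tissue == "FC" and not by_gene["g1"].tied
        assert by_gene["g2"].tissue == "MC" and by_gene["g2"].tied
        assert summary["counts"] == {"MC": 1, "FC": 1, "DX": 0}
        assert summary["percentages"]["MC"] == 50

    def test_forged_noise_free_peaks(self):
        from genefam.synthetic_data import (ForgeConfig, forge_expression,
                                            forge_genome)
        config = ForgeConfig(seed=6, expression_noise_sd=0.0)
        genome = forge_genome(config)
        result = forge_expression(config, genome.truth)
        calls, _ = expr.peak_tissue_calls(result.matrix)
        for call in calls:
            assert call.tissue == genome.truth.peak_tissue_of[call.gene_id]


class TestClassifyDivergence:
    def _matrix(self):
        return pd.DataFrame(
            [[1.0, 2, 3, 4], [1.0, 2, 3, 4], [4.0, 3, 2, 1],
             [5.0, 5, 5, 5]],
            index=["a", "b", "c", "flat"], columns=list("wxyz"))

    def test_identical_profiles_conserved(self):
        calls = expr.classify_divergence([("a", "b")], self._matrix())
        assert calls[0].klass == "conserved"
        assert calls[0].pearson_r == pytest.approx(1.0)

    def test_anticorrelated_diverged(self):
        calls = expr.classify_divergence([("a", "c")], self._matrix())
        assert calls[0].klass == "diverged"
        assert calls[0].pearson_r == pytest.approx(-1.0)

    def test_zero_variance_unclassified(self):
        calls = expr.classify_divergence([("a", "flat")], self._matrix())
        assert calls[0].klass == "unclassified"

    def test_missing_member_unclassified(self):
        calls = expr.classify_divergence([("a", "nope")], self._matrix())
        assert calls[0].klass == "unclassified"


class TestQpcr:
    def test_worked_example(self):
        assert expr.qpcr_relative(25.0, 20.0) == pytest.approx(0.03125)

    def test_equal_cts_give_one(self):
        assert expr.qpcr_relative(20.0, 20.0) == 1.0

    def test_triplicate_mean_path(self):
        mean_ct = np.mean([24.9, 25.0, 25.1])
        assert expr.qpcr_relative(float(mean_ct), 20.0) \
            == pytest.approx(0.03125)

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError):
            expr.qpcr_relative(25.0, 20.0, efficiency=0.0)
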