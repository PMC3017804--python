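import pytest

from genefam import genome_org as go
from genefam.io_formats import GeneModel, GenomeAnnotation
from tests.test_synthetic_data import brute_force_tandem_groups


def gene(gid, chrom, start, length=1000, rank=0):
    return GeneModel(gene_id=gid, chromosome=chrom, strand="+",
                     span=(start, start + length - 1),
                     exons=((start, start + length - 1),),
                     cds_segments=(), locus_rank=rank)


def annotation_with(models):
    annotation = GenomeAnnotation(
        models={m.gene_id: m for m in models},
        chromosome_lengths={})
    annotation.assign_locus_ranks()
    return annotation


def chain(chrom, *starts):
    """Genes every ~start with background filler to define ranks."""
    models = []
    for i, start in enumerate(starts):
        models.append(gene(f"f{i}", chrom, start))
    return models


class TestDetectTandem:
    def _fixture(self, gap_loci, distance_bp):
        """Two family genes separated by gap_loci background genes and a
        given start-to-end distance."""
        models = [gene("fam1", "LG_I", 1000)]
        second_start = 1000 + distance_bp - 1000
        step = (second_start - 2000) // (gap_loci + 1) if gap_loci else 0
        for k in range(gap_loci):
            models.append(gene(f"bg{k}", "LG_I", 2000 + k * max(step, 10),
                               length=10))
        models.append(gene("fam2", "LG_I", second_start))
        return annotation_with(models)

    def test_three_intervening_40kb_clustered(self):
        annotation = self._fixture(3, 40_000)
        clusters = go.detect_tandem_clusters(annotation, {"fam1", "fam2"})
        assert [c.members for c in clusters] == [("fam1", "fam2")]

    def test_boundary_five_intervening_99900bp_clustered(self):
        annotation = self._fixture(5, 99_900)
        clusters = go.detect_tandem_clusters(annotation, {"fam1", "fam2"})
        assert len(clusters) == 1

    def test_six_intervening_not_clustered(self):
        annotation = self._fixture(6, 40_000)
        assert go.detect_tandem_clusters(annotation,
                                         {"fam1", "fam2"}) == []

    def test_over_100kb_not_clustered(self):
        annotation = self._fixture(3, 100_500)
        assert go.detect_tandem_clusters(annotation,
                                         {"fam1", "fam2"}) == []

    def test_rank_gap_alternative_reading(self):
        annotation = self._fixture(5, 40_000)
        strict = go.detect_tandem_clusters(annotation, {"fam1", "fam2"},
                                           count_rule="rank_gap")
        assert strict == []

    def test_equals_brute_force_on_forged_genomes(self, forge):
        family = set(forge.truth.family_members)
        clusters = go.detect_tandem_clusters(forge.annotation, family)
        assert sorted(c.members for c in clusters) == \
            brute_force_tandem_groups(forge.annotation, family)

    def test_invariant_under_row_renaming(self, forge):
        family = set(forge.truth.family_members)
        renamed = GenomeAnnotation(
            models={f"X_{gid}": GeneModel(
                gene_id=f"X_{gid}", chromosome=m.chromosome,
                strand=m.strand, span=m.span, exons=m.exons,
                cds_segments=m.cds_segments, locus_rank=m.locus_rank)
                for gid, m in forge.annotation.models.items()},
            chromosome_lengths=dict(forge.annotation.chromosome_lengths))
        clusters = go.detect_tandem_clusters(
            renamed, {f"X_{g}" for g in family})
        original = go.detect_tandem_clusters(forge.annotation, family)
        stripped = sorted(tuple(m[2:] for m in c.members)
                          for c in clusters)
        assert stripped == sorted(c.members for c in original)


class TestConfirmTandem:
    def test_identity_80_confirmed_45_rejected(self):
        cluster = go.TandemCluster("LG_I", ("a", "b"), 5000)
        confirmed, raw = go.confirm_tandem_pairs(
            [cluster], lambda a, b: 80.0)
        assert raw == 1 and len(confirmed) == 1
        confirmed, _ = go.confirm_tandem_pairs(
            [cluster], lambda a, b: 45.0)
        assert confirmed == []

    def test_forged_arrays_confirmed_decoys_rejected(self, forge):
        from genefam.phylo import percent_identity
        family = set(forge.truth.family_members)
        clusters = go.detect_tandem_clusters(forge.annotation, family)
        confirmed, _ = go.confirm_tandem_pairs(
            clusters,
            lambda a, b: percent_identity(forge.protein_of[a],
                                          forge.protein_of[b]))
        confirmed_genes = {g for a, b, _ in confirmed for g in (a, b)}
        array_genes = {g for arr in forge.truth.tandem_arrays for g in arr}
        decoy_genes = {g for c in forge.truth.tandem_decoy_clusters
                       for g in c}
        assert array_genes <= confirmed_genes
        assert not (decoy_genes & confirmed_genes)


class TestBlockRetention:
    def _setup(self):
        blocks = [go.BlockPair("B1", ("LG_I", 1, 50_000),
                               ("LG_II", 1, 50_000)),
                  go.BlockPair("B2", ("LG_I", 100_000, 150_000),
                               ("LG_II", 100_000, 150_000))]
        models = [gene("both_a", "LG_I", 5_000),
                  gene("both_b", "LG_II", 9_000),
                  gene("lonely", "LG_I", 105_000),
                  gene("free", "LG_I", 300_000),
                  gene("scaff", "scaffold_9", 100)]
        return annotation_with(models), blocks

    def test_calls_and_summary(self):
        annotation, blocks = self._setup()
        family = {"both_a", "both_b", "lonely", "free", "scaff"}
        summary, calls = go.classify_block_retention(annotation, family,
                                                     blocks)
        assert calls == {"both_a": "both_retained",
                         "both_b": "both_retained",
                         "lonely": "one_sided",
                         "free": "outside"}
        assert summary.n_mapped == 4
        assert summary.n_one_sided_blocks == 1

    def test_paper_counts_fixture_gives_73(self):
        models, blocks, family = [], [], set()
        for p in range(28):
            chrom_a, chrom_b = "LG_I", "LG_II"
            base = 1 + p * 2_000_000
            blocks.append(go.BlockPair(
                f"B{p}", (chrom_a, base, base + 99_999),
                (chrom_b, base, base + 99_999)))
            # 87 both-retained genes spread over the 28 pairs
        placed = 0
        pair_idx = 0
        while placed < 87:
            block = blocks[pair_idx % 28]
            side = block.interval_a if placed % 2 == 0 else block.interval_b
            gid = f"ret{placed}"
            models.append(gene(gid, side[0],
                               side[1] + 100 + (placed // 56) * 2_000))
            family.add(gid)
            placed += 1
            pair_idx += placed % 2 == 0
        # one-sided blocks: 9 pairs with genes on one side only
        for k in range(14):
            base = 60_000_000 + (k % 9) * 2_000_000
            if k < 9:
                blocks.append(go.BlockPair(
                    f"OS{k}", ("LG_III", base, base + 99_999),
                    ("LG_IV", base, base + 99_999)))
            gid = f"one{k}"
            models.append(gene(gid, "LG_III", base + 100 + (k // 9) * 2000))
            family.add(gid)
        # 19 genes outside any block
        for k in range(19):
            gid = f"out{k}"
            models.append(gene(gid, "LG_V", 1 + k * 1_000_000))
            family.add(gid)
        annotation = annotation_with(models)
        summary, _ = go.classify_block_retention(annotation, family, blocks)
        assert summary.n_mapped == 120
        assert summary.n_both_retained == 87
        assert summary.retained_pct == 73

    def test_forged_retention_matches_truth(self, forge):
        family = set(forge.truth.family_members)
        summary, calls = go.classify_block_retention(
            forge.annotation, family, forge.blocks)
        expected = {g: v if v != "outside" else "outside"
                    for g, v in forge.truth.retention_of.items()}
        assert calls == expected
        assert summary.n_both_retained + summary.n_one_sided \
            + summary.n_outside == summary.n_mapped


class TestPairOrigin:
    def test_examples(self):
        blocks = [go.BlockPair("B1", ("LG_I", 1, 50_000),
                               ("LG_II", 1, 50_000))]
        models = [gene("a", "LG_I", 5_000), gene("b", "LG_II", 9_000),
                  gene("c", "scaffold_1", 100), gene("d", "LG_I", 90_000)]
        annotation = annotation_with(models)
        calls = go.classify_pair_origin(
            [("a", "b"), ("c", "d")], blocks, [], annotation)
        assert calls[("a", "b")] == "segmental"
        assert calls[("c", "d")] == "untraceable_scaffold"

    def test_tandem_precedence_over_segmental(self):
        blocks = [go.BlockPair("B1", ("LG_I", 1, 50_000),
                               ("LG_I", 100_000, 150_000))]
        models = [gene("a", "LG_I", 5_000), gene("b", "LG_I", 8_000)]
        annotation = annotation_with(models)
        cluster = go.TandemCluster("LG_I", ("a", "b"), 4_000)
        calls = go.classify_pair_origin([("a", "b")], blocks, [cluster],
                                        annotation)
        assert calls[("a", "b")] == "tandem"

    def test_forged_origins_match_truth(self, forge):
        family = set(forge.truth.family_members)
        clusters = go.detect_tandem_clusters(forge.annotation, family)
        calls = go.classify_pair_origin(forge.truth.pair_ids, forge.blocks,
                                        clusters, forge.annotation)
        assert calls == forge.truth.pair_origin_of


class TestAdjacencyScreen:
    def test_20kb_screen(self):
        models = [gene("a", "LG_I", 1_000), gene("b", "LG_I", 15_000),
                  gene("c", "LG_I", 80_000)]
        annotation = annotation_with(models)
        pairs = go.adjacency_screen(annotation, {"a", "b", "c"})
        assert pairs == [("a", "b")]
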