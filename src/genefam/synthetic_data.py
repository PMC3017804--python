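"""Forge annotated genomes, EST libraries and expression matrices with
planted, machine-readable truth.

Layout guarantees
-----------------
Gene slots sit on a fixed pitch (36 kb) so that any two family genes fewer
than three slots apart satisfy the tandem rule and any two at three or
more slots do not (108 kb > the 100 kb bound).  Planted tandem arrays and
decoy clusters occupy consecutive slots; every other family placement
keeps at least a three-slot gap.  Homeologous block intervals claim three
slots plus a two-slot spacer, one planted pair per block pair, so
retention statistics stay per-pair binomial.

Randomness is split into one child stream per artifact (genome, ESTs,
expression), all spawned from the master seed, so regenerating one
artifact never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .domain_census import load_packaged_profile
from .genome_org import BlockPair
from .io_formats import (GeneModel, GenomeAnnotation, SequenceRecord,
                         write_fasta, write_gff3, write_matrix_tsv)

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"

# one deterministic codon per amino acid keeps reverse translation simple;
# homologous proteins still yield ~unrelated third positions because each
# gene draws its own synonymous wobble below
_CODON = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX"]

DEFAULT_TISSUES = (
    "shoot_meristem", "young_leaf", "mature_leaf", "root",
    "differentiating_xylem", "phloem", "cambium", "female_catkin",
    "male_catkin",
)


class ForgeError(ValueError):
    pass


@dataclass
class ForgeConfig:
    seed: int = 0
    n_chromosomes: int = 3
    genes_per_chromosome: int = 72
    family_size: int = 40
    n_subfamilies: int = 6
    subfamily_divergence: float = 0.5
    member_divergence: float = 0.25
    pair_divergence: float = 0.10
    n_block_pairs: int = 15
    block_slots: int = 3
    block_gap_slots: int = 2
    block_retention_prob: float = 0.8
    tandem_array_sizes: tuple[int, ...] = (2, 3)
    n_tandem_decoy_clusters: int = 1
    n_scaffold_pairs: int = 1
    n_outside_singletons: int = 2
    n_truncated_decoys: int = 5
    decoy_domain_fraction: float = 0.4
    intron_change_prob: float = 0.3
    slot_pitch: int = 36_000
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    ests_per_library: int = 60
    near_miss_per_library: int = 3
    est_error_rate: float = 0.01
    est_min_len: int = 120
    est_max_len: int = 300
    expression_noise_sd: float = 2.0
    diverged_pair_fraction: float = 0.3
    partial_pair_r: float = 0.55
    n_unprobed_genes: int = 2

    def validate(self) -> None:
        for name in ("subfamily_divergence", "member_divergence",
                     "pair_divergence", "block_retention_prob",
                     "est_error_rate", "diverged_pair_fraction",
                     "intron_change_prob", "decoy_domain_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ForgeError(f"{name}={value} outside [0, 1]")
        if not self.tissues:
            raise ForgeError("tissue list is empty")
        total_genes = self.n_chromosomes * self.genes_per_chromosome
        if self.family_size > total_genes:
            raise ForgeError("family_size exceeds total gene count")
        if any(s < 2 for s in self.tandem_array_sizes):
            raise ForgeError("tandem arrays need at least two members")
        if any(s > self.block_slots for s in self.tandem_array_sizes):
            raise ForgeError("tandem array larger than a block interval")


@dataclass
class TruthSet:
    family_members: list[str] = field(default_factory=list)
    subfamily_of: dict[str, str] = field(default_factory=dict)
    reference_of: dict[str, str] = field(default_factory=dict)
    paralog_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    pair_origin_of: dict[tuple[str, str], str] = field(default_factory=dict)
    tandem_arrays: list[list[str]] = field(default_factory=list)
    tandem_decoy_clusters: list[list[str]] = field(default_factory=list)
    retention_of: dict[str, str] = field(default_factory=dict)
    truncated_decoys: list[str] = field(default_factory=list)
    scaffold_members: list[str] = field(default_factory=list)
    structure_change_of_pair: dict[tuple[str, str], str] = \
        field(default_factory=dict)
    expression_class_of_pair: dict[tuple[str, str], str] = \
        field(default_factory=dict)
    peak_tissue_of: dict[str, str] = field(default_factory=dict)
    unprobed_genes: list[str] = field(default_factory=list)
    near_miss_est_ids: list[str] = field(default_factory=list)
    est_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def pair_ids(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, _ in self.paralog_pairs]

    def to_json(self) -> str:
        def keyed(mapping):
            return {"|".join(k) if isinstance(k, tuple) else k: v
                    for k, v in mapping.items()}

        payload = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            payload[f.name] = keyed(value) if isinstance(value, dict) \
                else value
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class ForgeResult:
    config: ForgeConfig
    annotation: GenomeAnnotation
    proteins: list[SequenceRecord]
    cds: list[SequenceRecord]
    references: list[SequenceRecord]
    blocks: list[BlockPair]
    truth: TruthSet

    @property
    def protein_of(self) -> dict[str, str]:
        return {r.id: r.residues for r in self.proteins}


# ---------------------------------------------------------------------------
# sequence helpers


def _random_aa(rng, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))


def _mutate(seq: str, rate: float, rng) -> str:
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = [c for c in AA if c != out[i]]
        out[i] = choices[rng.integers(0, 19)]
    return "".join(out)


def _reverse_translate(protein: str, rng) -> str:
    parts = []
    for aa in protein:
        codons = _CODON[aa]
        parts.append(codons[rng.integers(0, len(codons))])
    return "".join(parts)


def chromosome_label(i: int) -> str:
    return f"LG_{_ROMAN[i]}" if i < len(_ROMAN) else f"LG_{i + 1}"


# ---------------------------------------------------------------------------
# genome forge


class _SlotLayout:
    """Per-chromosome slot bookkeeping with tandem-safe spacing."""

    def __init__(self, config: ForgeConfig):
        self.config = config
        self.n_slots = config.genes_per_chromosome
        self.block_cursor = {c: 0 for c in range(config.n_chromosomes)}
        self.free_cursor: dict[int, int] = {}
        self.used: dict[tuple[int, int], str] = {}   # (chrom, slot) -> role

    def claim_block_interval(self, chrom: int) -> list[int]:
        claim = self.config.block_slots + self.config.block_gap_slots
        start = self.block_cursor[chrom]
        if start + claim > self.n_slots:
            raise ForgeError(
                f"infeasible geometry: chromosome {chrom} cannot fit "
                "another block interval")
        self.block_cursor[chrom] = start + claim
        return list(range(start, start + self.config.block_slots))

    def finish_blocks(self) -> None:
        for chrom in self.block_cursor:
            self.free_cursor[chrom] = self.block_cursor[chrom]

    def claim_free(self, n_consecutive: int = 1, stride: int = 4
                   ) -> tuple[int, list[int]]:
        """First chromosome with room; advances by a tandem-safe stride."""
        for chrom in sorted(self.free_cursor,
                            key=lambda c: self.free_cursor[c]):
            start = self.free_cursor[chrom]
            advance = stride if stride >= n_consecutive \
                else n_consecutive + 2
            if start + max(n_consecutive, advance) <= self.n_slots:
                self.free_cursor[chrom] = start + advance
                return chrom, list(range(start, start + n_consecutive))
        raise ForgeError("infeasible geometry: free slots exhausted")


def _split_cds(total: int, n_exons: int, rng) -> list[int]:
    """CDS exon lengths (bp); each exon >= 30 bp."""
    if n_exons == 1:
        return [total]
    while True:
        cuts = sorted(rng.choice(np.arange(30, total - 29), size=n_exons - 1,
                                 replace=False))
        lengths = np.diff([0, *cuts, total]).tolist()
        if min(lengths) >= 30:
            return lengths


def _make_model(gene_id: str, chrom_label: str, slot: int, protein_len: int,
                config: ForgeConfig, rng,
                exon_split: list[int] | None = None,
                strand: str | None = None) -> \
        tuple[GeneModel, list[int], str]:
    cds_len = protein_len * 3
    if exon_split is None:
        n_exons = int(rng.integers(1, 5))
        exon_split = _split_cds(cds_len, n_exons, rng)
    introns = [int(rng.integers(100, 401)) for _ in exon_split[:-1]]
    start = slot * config.slot_pitch + 1 + int(rng.integers(0, 200))
    exons = []
    pos = start
    for i, elen in enumerate(exon_split):
        exons.append((pos, pos + elen - 1))
        if i < len(introns):
            pos = pos + elen + introns[i]
    end = exons[-1][1]
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    model = GeneModel(gene_id=gene_id, chromosome=chrom_label, strand=strand,
                      span=(start, end), exons=tuple(exons),
                      cds_segments=tuple(exons))
    return model, exon_split, strand


def forge_genome(config: ForgeConfig) -> ForgeResult:
    """Build an annotated genome with a planted domain family."""
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(3)[0])
    profile = load_packaged_profile()
    consensus = profile.consensus
    dom_w = len(consensus)
    truth = TruthSet()

    # --- family unit plan -------------------------------------------------
    sizes = config.tandem_array_sizes
    n_arrays = len(sizes)
    used = (sum(sizes) + n_arrays                     # arrays + partners
            + 2 * config.n_tandem_decoy_clusters
            + 2 * config.n_scaffold_pairs
            + config.n_outside_singletons)
    remaining = config.family_size - used
    if remaining < 0:
        raise ForgeError("family_size too small for configured units")
    n_plain_pairs = remaining // 2
    n_extra_singletons = remaining % 2
    if n_plain_pairs + n_arrays > config.n_block_pairs:
        raise ForgeError(
            "infeasible geometry: need more block pairs than configured")

    # --- subfamily ancestors and references -------------------------------
    ancestors = []
    for s in range(config.n_subfamilies):
        dom = _mutate(consensus, config.subfamily_divergence / 2, rng)
        tail = _random_aa(rng, 80)
        ancestors.append((dom, tail))
    references = [
        SequenceRecord(f"REF{s + 1:02d}", f"subfamily SUB{s + 1} ancestor",
                       dom + tail)
        for s, (dom, tail) in enumerate(ancestors)]

    def member_base(subfam: int, loner: bool = False) -> str:
        # every unit draws a fresh random tail: paralog partners (derived
        # below) stay near-identical across domain AND tail, while any two
        # distinct units share only domain similarity and so never clear
        # the paralog identity bar; subfamily signal lives in the domain
        dom, tail = ancestors[subfam]
        return _mutate(dom, config.member_divergence / 2, rng) \
            + _random_aa(rng, len(tail))

    def derive(base: str, divergence: float) -> str:
        dom = _mutate(base[:dom_w], divergence / 2, rng)
        tail = _mutate(base[dom_w:], divergence, rng)
        return dom + tail

    # --- geometry ---------------------------------------------------------
    layout = _SlotLayout(config)
    intervals: list[tuple[int, list[int]]] = []      # (chrom_idx, slots)
    for t in range(2 * config.n_block_pairs):
        chrom = t % config.n_chromosomes
        intervals.append((chrom, layout.claim_block_interval(chrom)))
    layout.finish_blocks()

    blocks = []
    for p in range(config.n_block_pairs):
        (ca, slots_a), (cb, slots_b) = intervals[2 * p], intervals[2 * p + 1]
        blocks.append(BlockPair(
            pair_id=f"BLK{p + 1:03d}",
            interval_a=(chromosome_label(ca),
                        slots_a[0] * config.slot_pitch + 1,
                        (slots_a[-1] + 1) * config.slot_pitch),
            interval_b=(chromosome_label(cb),
                        slots_b[0] * config.slot_pitch + 1,
                        (slots_b[-1] + 1) * config.slot_pitch),
        ))

    # placements: gene_id -> (chrom_idx | scaffold label, slot, protein)
    serial = iter(range(1, 10_000))
    placements: dict[str, tuple[object, int, str]] = {}
    block_side_occupants: dict[tuple[int, str], list[str]] = {}

    def new_id() -> str:
        return f"G{next(serial):04d}"

    def place_in_block(pair_idx: int, side: str, offset: int, gene: str,
                       protein: str) -> None:
        chrom, slots = intervals[2 * pair_idx + (0 if side == "a" else 1)]
        placements[gene] = (chrom, slots[offset], protein)
        block_side_occupants.setdefault((pair_idx, side), []).append(gene)

    subfam_cycle = iter(np.arange(10_000) % config.n_subfamilies)

    def record_member(gene: str, subfam: int) -> None:
        truth.family_members.append(gene)
        truth.subfamily_of[gene] = f"SUB{subfam + 1}"
        truth.reference_of[gene] = f"REF{subfam + 1:02d}"

    def record_pair(a: str, b: str, divergence: float, origin: str) -> None:
        a, b = sorted((a, b))
        truth.paralog_pairs.append((a, b, divergence))
        truth.pair_origin_of[(a, b)] = origin

    # tandem arrays inside their own block pairs
    partner_singletons: list[str] = []
    for array_idx, size in enumerate(sizes):
        subfam = int(next(subfam_cycle))
        base = member_base(subfam)
        members = [base, derive(base, config.pair_divergence)]
        for extra in range(size - 2):
            members.append(derive(base, 2.5 * config.pair_divergence))
        gene_ids = []
        for offset, protein in enumerate(members):
            gene = new_id()
            gene_ids.append(gene)
            place_in_block(array_idx, "a", offset, gene, protein)
            record_member(gene, subfam)
        truth.tandem_arrays.append(gene_ids)
        record_pair(gene_ids[0], gene_ids[1], config.pair_divergence,
                    "tandem")
        # partner-side singleton keeps the array block both-retained
        psub = int(next(subfam_cycle))
        gene = new_id()
        partner_singletons.append(gene)
        place_in_block(array_idx, "b", 0, gene,
                       member_base(psub, loner=True))
        record_member(gene, psub)

    # the two partner singletons of the first two arrays form a pair sitting
    # on two *different* block pairs: a planted divergent_blocks case
    if len(partner_singletons) >= 2:
        a, b = partner_singletons[0], partner_singletons[1]
        protein_a = placements[a][2]
        protein_b = derive(protein_a, config.pair_divergence)
        placements[b] = (placements[b][0], placements[b][1], protein_b)
        truth.subfamily_of[b] = truth.subfamily_of[a]
        truth.reference_of[b] = truth.reference_of[a]
        record_pair(a, b, config.pair_divergence, "divergent_blocks")

    # plain pairs, one per remaining block pair
    for p in range(n_plain_pairs):
        pair_idx = n_arrays + p
        subfam = int(next(subfam_cycle))
        base = member_base(subfam)
        partner = derive(base, config.pair_divergence)
        gene_a, gene_b = new_id(), new_id()
        place_in_block(pair_idx, "a", 0, gene_a, base)
        retained = bool(rng.random() < config.block_retention_prob)
        if retained:
            place_in_block(pair_idx, "b", 0, gene_b, partner)
            origin = "segmental"
        else:
            chrom, slots = layout.claim_free()
            placements[gene_b] = (chrom, slots[0], partner)
            origin = "outside_blocks"
        record_member(gene_a, subfam)
        record_member(gene_b, subfam)
        record_pair(gene_a, gene_b, config.pair_divergence, origin)

    # decoy tandem clusters: co-located family genes from far subfamilies
    for _ in range(config.n_tandem_decoy_clusters):
        sa = int(next(subfam_cycle))
        sb = (sa + config.n_subfamilies // 2) % config.n_subfamilies
        chrom, slots = layout.claim_free(n_consecutive=2, stride=5)
        cluster = []
        for slot, subfam in zip(slots, (sa, sb)):
            gene = new_id()
            cluster.append(gene)
            placements[gene] = (
                chrom, slot,
                member_base(subfam, loner=True))
            record_member(gene, subfam)
        truth.tandem_decoy_clusters.append(cluster)

    # scaffold pairs: one member unplaced
    for s in range(config.n_scaffold_pairs):
        subfam = int(next(subfam_cycle))
        base = member_base(subfam)
        partner = derive(base, config.pair_divergence)
        gene_a, gene_b = new_id(), new_id()
        chrom, slots = layout.claim_free()
        placements[gene_a] = (chrom, slots[0], base)
        placements[gene_b] = (f"scaffold_{s + 1}", 0, partner)
        truth.scaffold_members.append(gene_b)
        record_member(gene_a, subfam)
        record_member(gene_b, subfam)
        record_pair(gene_a, gene_b, config.pair_divergence,
                    "untraceable_scaffold")

    # free-floating singletons
    for _ in range(config.n_outside_singletons + n_extra_singletons):
        subfam = int(next(subfam_cycle))
        gene = new_id()
        chrom, slots = layout.claim_free()
        placements[gene] = (
            chrom, slots[0],
            member_base(subfam, loner=True))
        record_member(gene, subfam)

    # truncated decoys: partial domain only
    decoy_len = max(1, int(config.decoy_domain_fraction * dom_w))
    for _ in range(config.n_truncated_decoys):
        gene = new_id()
        fragment = _mutate(consensus[:decoy_len], 0.2, rng)
        protein = fragment + _random_aa(rng, 150)
        chrom, slots = layout.claim_free(stride=1)
        placements[gene] = (chrom, slots[0], protein)
        truth.truncated_decoys.append(gene)

    # background genes fill every remaining slot
    occupied = {(c, s) for c, s, _ in
                ((p[0], p[1], None) for p in placements.values())
                if not isinstance(c, str)}
    for chrom in range(config.n_chromosomes):
        for slot in range(config.genes_per_chromosome):
            if (chrom, slot) in occupied:
                continue
            gene = new_id()
            placements[gene] = (chrom, slot,
                                _random_aa(rng, int(rng.integers(120, 351))))
    # scaffolds carry two background genes each
    n_scaffolds = max(1, config.n_scaffold_pairs)
    for s in range(n_scaffolds):
        for slot in (1, 2):
            gene = new_id()
            placements[gene] = (f"scaffold_{s + 1}", slot,
                                _random_aa(rng, int(rng.integers(120, 351))))

    # --- emit annotation and sequences ------------------------------------
    annotation = GenomeAnnotation()
    proteins, cds = [], []
    pair_partner_split: dict[str, list[int]] = {}
    # base members of structure-conserved pairs share their exon split
    pair_lookup = {a: b for a, b, _ in truth.paralog_pairs}
    for gene in sorted(placements):
        where, slot, protein = placements[gene]
        chrom_label_ = where if isinstance(where, str) \
            else chromosome_label(where)
        split, strand = pair_partner_split.pop(gene, (None, None))
        model, used_split, used_strand = _make_model(
            gene, chrom_label_, slot, len(protein), config, rng, split,
            strand)
        if gene in pair_lookup:                      # gene is an "a" member
            # partner shares strand so transcription-order structure and
            # phases compare cleanly
            partner = pair_lookup[gene]
            if rng.random() < config.intron_change_prob \
                    and len(used_split) >= 2:
                merged = ([used_split[0] + used_split[1]] + used_split[2:])
                pair_partner_split[partner] = (merged, used_strand)
                truth.structure_change_of_pair[(gene, partner)] = \
                    "intron_loss"
            else:
                pair_partner_split[partner] = (list(used_split),
                                               used_strand)
                truth.structure_change_of_pair[(gene, partner)] = "same"
        annotation.models[gene] = model
        proteins.append(SequenceRecord(gene, "", protein))
        cds.append(SequenceRecord(gene, "", _reverse_translate(protein, rng)))

    for chrom in range(config.n_chromosomes):
        annotation.chromosome_lengths[chromosome_label(chrom)] = \
            (config.genes_per_chromosome + 1) * config.slot_pitch
    for s in range(n_scaffolds):
        annotation.chromosome_lengths[f"scaffold_{s + 1}"] = \
            4 * config.slot_pitch
    annotation.assign_locus_ranks()
    annotation.validate()

    # --- retention truth from placement bookkeeping -----------------------
    for gene in truth.family_members:
        where = placements[gene][0]
        if isinstance(where, str):
            continue                                  # scaffold: unmapped
        verdict = "outside"
        for (pair_idx, side), members in block_side_occupants.items():
            if gene not in members:
                continue
            other = "b" if side == "a" else "a"
            verdict = "both_retained" if block_side_occupants.get(
                (pair_idx, other)) else "one_sided"
            break
        truth.retention_of[gene] = verdict

    truth.family_members.sort()
    return ForgeResult(config, annotation, proteins, cds, references,
                       blocks, truth)


# ---------------------------------------------------------------------------
# EST forge


@dataclass
class ESTForge:
    libraries: dict[str, list[SequenceRecord]]       # library id -> records
    manifest: pd.DataFrame                           # library_id, tissue


def forge_est_libraries(config: ForgeConfig, cds_records,
                        truth: TruthSet) -> ESTForge:
    """Sample error-bearing subsequences of family CDS into per-tissue
    libraries, plus planted 94-96% identity near-misses."""
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(3)[1])
    cds_of = {r.id: r.residues for r in cds_records}
    sources = [g for g in truth.family_members
               if len(cds_of[g]) >= config.est_min_len + 10]
    if not sources:
        raise ForgeError("no CDS long enough to sample ESTs from")
    libraries: dict[str, list[SequenceRecord]] = {}
    rows = []
    truth.est_counts = {g: {t: 0 for t in config.tissues} for g in sources}
    for tissue in config.tissues:
        lib = f"LIB_{tissue}"
        rows.append({"library_id": lib, "tissue": tissue})
        records = []
        for i in range(config.ests_per_library):
            gene = sources[rng.integers(0, len(sources))]
            seq = _sample_est(cds_of[gene], config, rng,
                              config.est_error_rate)
            records.append(SequenceRecord(
                f"EST_{tissue}_{i + 1:05d}", f"source={gene}", seq))
            truth.est_counts[gene][tissue] += 1
        for i in range(config.near_miss_per_library):
            gene = sources[rng.integers(0, len(sources))]
            seq = _near_miss_est(cds_of[gene], config, rng)
            est_id = f"ESTNM_{tissue}_{i + 1:05d}"
            records.append(SequenceRecord(est_id, f"source={gene}", seq))
            truth.near_miss_est_ids.append(est_id)
        libraries[lib] = records
    return ESTForge(libraries, pd.DataFrame(rows))


def _sample_est(cds: str, config: ForgeConfig, rng, error_rate: float) -> str:
    max_len = min(config.est_max_len, len(cds))
    length = int(rng.integers(config.est_min_len, max_len + 1))
    start = int(rng.integers(0, len(cds) - length + 1))
    chunk = list(cds[start:start + length])
    for i in np.nonzero(rng.random(length) < error_rate)[0]:
        chunk[i] = NT[(NT.index(chunk[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(chunk)


def _near_miss_est(cds: str, config: ForgeConfig, rng) -> str:
    """Identity pinned into (94, 96): evenly spread substitutions so no
    100 bp window clears the acceptance threshold."""
    max_len = min(config.est_max_len, len(cds))
    length = int(rng.integers(max(config.est_min_len, 150), max_len + 1))
    start = int(rng.integers(0, len(cds) - length + 1))
    chunk = list(cds[start:start + length])
    n_sub = int(round(0.05 * length))
    positions = [int((k + 0.5) * length / n_sub) for k in range(n_sub)]
    for i in positions:
        chunk[i] = NT[(NT.index(chunk[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(chunk)


# ---------------------------------------------------------------------------
# expression forge


@dataclass
class ExpressionForge:
    matrix: pd.DataFrame                  # gene x tissue abundances
    probe_matrix: pd.DataFrame            # probe x tissue
    probe_to_gene: dict[str, list[str]]   # probe id -> gene ids
    expected_collapsed: pd.DataFrame      # oracle for probe collapse
    qpcr: pd.DataFrame                    # gene, tissue, ct_mean, ct_ref_mean


def _exact_r_partner(base: np.ndarray, target_r: float, rng) -> np.ndarray:
    """Row with *exactly* the requested sample Pearson r against base."""
    centered = base - base.mean()
    u = centered / np.linalg.norm(centered)
    raw = rng.normal(size=base.size)
    raw -= raw.mean()
    raw -= (raw @ u) * u
    e = raw / np.linalg.norm(raw)
    z = target_r * u + np.sqrt(1.0 - target_r ** 2) * e
    return base.mean() + z * np.linalg.norm(centered)


def forge_expression(config: ForgeConfig, truth: TruthSet) -> ExpressionForge:
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(3)[2])
    tissues = list(config.tissues)
    n_t = len(tissues)
    genes = list(truth.family_members)
    pair_of = {}
    for a, b, _ in truth.paralog_pairs:
        pair_of[a] = b

    n_pairs = len(truth.paralog_pairs)
    n_div = int(round(config.diverged_pair_fraction * n_pairs))
    n_cons = (n_pairs - n_div + 1) // 2
    classes = (["diverged"] * n_div + ["conserved"] * n_cons
               + ["partially_redundant"] * (n_pairs - n_div - n_cons))
    order = rng.permutation(n_pairs)
    class_of_pair = {}
    for rank, pair_pos in enumerate(order):
        a, b, _ = truth.paralog_pairs[pair_pos]
        class_of_pair[(a, b)] = classes[rank]
    truth.expression_class_of_pair = class_of_pair

    rows: dict[str, np.ndarray] = {}
    for gene in genes:
        if gene in rows:
            continue
        peak = int(rng.integers(0, n_t))
        base = rng.normal(0.0, 1.0, size=n_t)
        base[peak] = base.max() + 2.5
        rows[gene] = base
        partner = pair_of.get(gene)
        if partner is not None:
            cls = class_of_pair[(gene, partner)]
            if cls == "conserved":
                rows[partner] = base.copy()
            elif cls == "partially_redundant":
                rows[partner] = _exact_r_partner(base, config.partial_pair_r,
                                                 rng)
            else:
                rows[partner] = _exact_r_partner(base, 0.0, rng)

    clean = pd.DataFrame(
        {t: [100.0 + 20.0 * rows[g][i] for g in genes]
         for i, t in enumerate(tissues)}, index=genes)
    truth.peak_tissue_of = {g: clean.loc[g].idxmax() for g in genes}
    noisy = clean + rng.normal(0.0, config.expression_noise_sd,
                               size=clean.shape)
    matrix = noisy.clip(lower=0.0)

    # probe-level table: 1-3 probes per gene, two genes share one probe,
    # a few genes carry no probe at all
    unprobed = genes[-config.n_unprobed_genes:] \
        if config.n_unprobed_genes else []
    truth.unprobed_genes = list(unprobed)
    probed = [g for g in genes if g not in unprobed]
    multipliers = {1: [1.0], 2: [0.9, 1.1], 3: [0.9, 1.0, 1.1]}
    probe_rows, probe_map = {}, {}
    shared_done = False
    expected = {}
    counter = iter(range(1, 10_000))
    i = 0
    while i < len(probed):
        gene = probed[i]
        paired = set(pair_of) | set(pair_of.values())
        if not shared_done and i + 1 < len(probed) \
                and probed[i + 1] not in paired and gene not in paired:
            partner = probed[i + 1]
            probe = f"P{next(counter):04d}"
            probe_rows[probe] = matrix.loc[gene].to_numpy()
            probe_map[probe] = [gene, partner]
            expected[gene] = probe_rows[probe]
            expected[partner] = probe_rows[probe]
            shared_done = True
            i += 2
            continue
        k = (i % 3) + 1
        probes = []
        for mult in multipliers[k]:
            probe = f"P{next(counter):04d}"
            probe_rows[probe] = matrix.loc[gene].to_numpy() * mult
            probe_map[probe] = [gene]
            probes.append(probe)
        expected[gene] = np.median(
            np.stack([probe_rows[p] for p in probes]), axis=0)
        i += 1

    probe_matrix = pd.DataFrame.from_dict(probe_rows, orient="index",
                                          columns=tissues)
    expected_collapsed = pd.DataFrame.from_dict(expected, orient="index",
                                                columns=tissues) \
        .sort_index()

    qpcr_rows = []
    for gene in genes:
        for tissue in tissues:
            abundance = max(float(matrix.loc[gene, tissue]), 1.0)
            qpcr_rows.append({
                "gene": gene, "tissue": tissue,
                "ct_mean": 20.0 - np.log2(abundance / 100.0),
                "ct_ref_mean": 20.0,
            })
    return ExpressionForge(matrix, probe_matrix, probe_map,
                           expected_collapsed, pd.DataFrame(qpcr_rows))


# ---------------------------------------------------------------------------
# bundle


@dataclass
class FullForge:
    genome: ForgeResult
    ests: ESTForge
    expression: ExpressionForge

    @property
    def truth(self) -> TruthSet:
        return self.genome.truth

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome.proteins, out / "proteins.fasta")
        write_fasta(self.genome.cds, out / "cds.fasta")
        write_fasta(self.genome.references, out / "references.fasta")
        write_gff3(self.genome.annotation, out / "genome.gff3")
        pd.DataFrame([
            {"pair_id": b.pair_id,
             "chr_a": b.interval_a[0], "start_a": b.interval_a[1],
             "end_a": b.interval_a[2],
             "chr_b": b.interval_b[0], "start_b": b.interval_b[1],
             "end_b": b.interval_b[2]} for b in self.genome.blocks
        ]).to_csv(out / "blocks.tsv", sep="\t", index=False)
        for lib, records in self.ests.libraries.items():
            write_fasta(records, out / f"{lib}.fasta")
        self.ests.manifest.to_csv(out / "est_manifest.tsv", sep="\t",
                                  index=False)
        write_matrix_tsv(self.expression.matrix, out / "expression.tsv")
        write_matrix_tsv(self.expression.probe_matrix,
                         out / "probe_matrix.tsv")
        pd.DataFrame([
            {"probe_id": p, "gene_id": g}
            for p, gs in self.expression.probe_to_gene.items() for g in gs
        ]).to_csv(out / "probe_map.tsv", sep="\t", index=False)
        self.expression.qpcr.to_csv(out / "qpcr.tsv", sep="\t", index=False)
        (out / "truth.json").write_text(self.truth.to_json())


def forge_all(config: ForgeConfig) -> FullForge:
    genome = forge_genome(config)
    ests = forge_est_libraries(config, genome.cds, genome.truth)
    expression = forge_expression(config, genome.truth)
    return FullForge(genome, ests, expression)
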