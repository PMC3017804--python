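"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are GFF3-style: 1-based, inclusive at both ends.
Any half-open conversion is confined to the helpers in this module.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
NT_ALPHABET = frozenset("ACGTN")

_ALPHABETS = {"aa": AA_ALPHABET, "nt": NT_ALPHABET}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record over a declared alphabet."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneModel:
    """One annotated locus; exon/CDS intervals are 1-based inclusive."""

    gene_id: str
    chromosome: str
    strand: str
    span: tuple[int, int]
    exons: tuple[tuple[int, int], ...]
    cds_segments: tuple[tuple[int, int], ...]
    locus_rank: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")
        for s, e in (self.span, *self.exons, *self.cds_segments):
            if s > e:
                raise FormatError(f"{self.gene_id}: interval start {s} > end {e}")
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise FormatError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = e
        for cs, ce in self.cds_segments:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise FormatError(
                    f"{self.gene_id}: CDS segment ({cs},{ce}) outside exon bounds"
                )

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


@dataclass
class GenomeAnnotation:
    """Gene models keyed by id, plus chromosome lengths."""

    models: dict[str, GeneModel] = field(default_factory=dict)
    chromosome_lengths: dict[str, int] = field(default_factory=dict)

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        found = [m for m in self.models.values() if m.chromosome == chromosome]
        return sorted(found, key=lambda m: m.start)

    def assign_locus_ranks(self) -> None:
        """Rank genes 1..n by span start within each chromosome."""
        for chrom in {m.chromosome for m in self.models.values()}:
            for rank, model in enumerate(self.genes_on(chrom), start=1):
                self.models[model.gene_id] = GeneModel(
                    gene_id=model.gene_id,
                    chromosome=model.chromosome,
                    strand=model.strand,
                    span=model.span,
                    exons=model.exons,
                    cds_segments=model.cds_segments,
                    locus_rank=rank,
                )

    def validate(self) -> None:
        for model in self.models.values():
            length = self.chromosome_lengths.get(model.chromosome)
            if length is not None and model.end > length:
                raise FormatError(
                    f"{model.gene_id} extends past end of {model.chromosome}"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, alphabet: str,
               allow_gaps: bool = False) -> list[SequenceRecord]:
    """Parse a FASTA file, validating ids and residues.

    Parameters
    ----------
    path : str or Path
        FASTA file with ``>id description`` headers.
    alphabet : {"aa", "nt"}
        Residue alphabet to enforce (uppercase only).
    allow_gaps : bool
        Accept "-" characters (aligned FASTA).
    """
    allowed = _ALPHABETS[alphabet]
    if allow_gaps:
        allowed = allowed | {"-"}
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq)
        for pos, ch in enumerate(residues, start=1):
            if ch not in allowed:
                raise FormatError(
                    f"illegal {alphabet} character {ch!r} in record "
                    f"{rec.id!r} at position {pos}"
                )
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, desc, residues))
    return records


def write_fasta(records, path) -> None:
    """Write records with 60-column wrapping; deterministic byte output."""
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise FormatError(f"malformed GFF3 attribute {chunk!r}")
        key, _, value = chunk.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(path, splice_policy: str = "first") -> GenomeAnnotation:
    """Read gene/mRNA/exon/CDS rows into a GenomeAnnotation.

    One GeneModel is built per gene from its first mRNA (``splice_policy=
    "first"``, the default) or one per mRNA (``splice_policy="all"``, ids
    suffixed with the transcript id).  Locus ranks are assigned by start
    position within each chromosome.
    """
    if splice_policy not in ("first", "all"):
        raise ValueError(f"unknown splice_policy {splice_policy!r}")
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    mrna_order: dict[str, list[str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    seq_lengths: dict[str, int] = {}
    seen_max: dict[str, int] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    seq_lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {lineno}: expected 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attr_text = fields
            start, end = int(start), int(end)
            attrs = _parse_attributes(attr_text)
            seen_max[chrom] = max(seen_max.get(chrom, 0), end)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"line {lineno}: gene without ID")
                genes[gid] = {"chrom": chrom, "strand": strand,
                              "span": (start, end)}
                mrna_order.setdefault(gid, [])
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if parent is None:
                    raise FormatError(f"line {lineno}: mRNA missing Parent")
                mrna_parent[mid] = parent
                mrna_order.setdefault(parent, []).append(mid)
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(f"line {lineno}: {ftype} missing Parent")
                target = exons if ftype == "exon" else cds
                target.setdefault(parent, []).append((start, end))

    annotation = GenomeAnnotation()
    for gid, info in genes.items():
        transcripts = mrna_order.get(gid) or [None]
        chosen = transcripts if splice_policy == "all" else transcripts[:1]
        for mid in chosen:
            key = mid if mid is not None else gid
            model_exons = tuple(sorted(exons.get(key, [info["span"]])))
            model_cds = tuple(sorted(cds.get(key, [])))
            model_id = gid if splice_policy == "first" else (mid or gid)
            annotation.models[model_id] = GeneModel(
                gene_id=model_id,
                chromosome=info["chrom"],
                strand=info["strand"],
                span=info["span"],
                exons=model_exons,
                cds_segments=model_cds,
            )
    for chrom, end in seen_max.items():
        annotation.chromosome_lengths[chrom] = max(
            seq_lengths.get(chrom, 0), end
        )
    annotation.assign_locus_ranks()
    annotation.validate()
    return annotation


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    lines = ["##gff-version 3"]
    for chrom in sorted(annotation.chromosome_lengths):
        length = annotation.chromosome_lengths[chrom]
        lines.append(f"##sequence-region {chrom} 1 {length}")
    for chrom in sorted(annotation.chromosome_lengths):
        for model in annotation.genes_on(chrom):
            gid = model.gene_id
            base = [model.chromosome, "genefam"]
            tail = [".", model.strand, "."]
            lines.append("\t".join(
                base + ["gene", str(model.start), str(model.end)]
                + tail + [f"ID={gid}"]))
            mid = f"{gid}.1"
            lines.append("\t".join(
                base + ["mRNA", str(model.start), str(model.end)]
                + tail + [f"ID={mid};Parent={gid}"]))
            for s, e in model.exons:
                lines.append("\t".join(
                    base + ["exon", str(s), str(e)] + tail + [f"Parent={mid}"]))
            for s, e in model.cds_segments:
                lines.append("\t".join(
                    [model.chromosome, "genefam", "CDS", str(s), str(e),
                     ".", model.strand, "0", f"Parent={mid}"]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV matrices

def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a gene x column TSV matrix (first column = gene id)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].tolist()
        raise FormatError(f"duplicate row labels {dupes}")
    if (frame == ".").any().any():
        raise FormatError('"." is forbidden as a numeric placeholder')
    return frame.astype(float)


def write_matrix_tsv(frame: pd.DataFrame, path) -> None:
    buf = io.StringIO()
    frame.to_csv(buf, sep="\t", lineterminator="\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_block_pairs_tsv(path) -> pd.DataFrame:
    """Homeologous block-pair table: pair_id, chrA..endA, chrB..endB."""
    cols = ["pair_id", "chr_a", "start_a", "end_a", "chr_b", "start_b", "end_b"]
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise FormatError(f"block-pair table missing columns {missing}")
    return frame[cols]
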