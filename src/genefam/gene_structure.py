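"""Exon/intron architecture, intron phases and pair structure comparison."""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GeneModel


@dataclass(frozen=True)
class GeneStructure:
    gene_id: str
    n_exons: int
    exon_lengths: tuple[int, ...]        # transcription order, bp
    intron_lengths: tuple[int, ...]
    intron_phases: tuple[int, ...]       # over {0, 1, 2}

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != self.n_exons - 1:
            raise ValueError("intron count must be exon count - 1")
        if len(self.intron_phases) != len(self.intron_lengths):
            raise ValueError("one phase per intron")
        if any(p not in (0, 1, 2) for p in self.intron_phases):
            raise ValueError("phases must be in {0, 1, 2}")


@dataclass(frozen=True)
class StructureComparison:
    same_intron_count: bool
    intron_count_diff: int
    shared_phase_prefix: int
    length_ratio: float                  # shorter / longer total gene length
    conserved: bool


def intron_phases(cds_exon_lengths) -> list[int]:
    """phase_k = (sum of the first k CDS exon lengths) mod 3."""
    if any(length <= 0 for length in cds_exon_lengths):
        raise ValueError("exon lengths must be positive")
    phases = []
    total = 0
    for length in cds_exon_lengths[:-1]:
        total += length
        phases.append(total % 3)
    return phases


def extract_structure(model: GeneModel) -> GeneStructure:
    """Structure in transcription order; phases from CDS segments only."""
    exons = list(model.exons)
    introns = [exons[i + 1][0] - exons[i][1] - 1
               for i in range(len(exons) - 1)]
    if any(i < 0 for i in introns):
        raise ValueError(f"{model.gene_id}: overlapping exons")
    exon_lengths = [e - s + 1 for s, e in exons]
    cds_lengths = [e - s + 1 for s, e in model.cds_segments]
    if model.strand == "-":
        exon_lengths.reverse()
        introns.reverse()
        cds_lengths.reverse()
    phases = intron_phases(cds_lengths) if len(cds_lengths) > 1 else []
    # genes whose CDS spans fewer segments than exons (UTR-only exons)
    # contribute phases only at CDS junctions
    n_exons = len(exon_lengths)
    if len(phases) < n_exons - 1:
        phases = phases + [0] * (n_exons - 1 - len(phases)) \
            if model.cds_segments else [0] * (n_exons - 1)
    return GeneStructure(
        gene_id=model.gene_id,
        n_exons=n_exons,
        exon_lengths=tuple(exon_lengths),
        intron_lengths=tuple(introns),
        intron_phases=tuple(phases[:n_exons - 1]),
    )


def compare_structures(a: GeneStructure, b: GeneStructure
                       ) -> StructureComparison:
    """Conserved means same intron count AND identical phase lists."""
    diff = abs((a.n_exons - 1) - (b.n_exons - 1))
    prefix = 0
    for pa, pb in zip(a.intron_phases, b.intron_phases):
        if pa != pb:
            break
        prefix += 1
    len_a = sum(a.exon_lengths) + sum(a.intron_lengths)
    len_b = sum(b.exon_lengths) + sum(b.intron_lengths)
    ratio = min(len_a, len_b) / max(len_a, len_b)
    conserved = diff == 0 and a.intron_phases == b.intron_phases
    return StructureComparison(
        same_intron_count=diff == 0,
        intron_count_diff=diff,
        shared_phase_prefix=prefix,
        length_ratio=ratio,
        conserved=conserved,
    )


def structure_table(structures) -> list[dict]:
    rows = []
    for s in sorted(structures, key=lambda x: x.gene_id):
        rows.append({
            "gene_id": s.gene_id,
            "n_exons": s.n_exons,
            "exon_lengths": ",".join(map(str, s.exon_lengths)),
            "intron_lengths": ",".join(map(str, s.intron_lengths)),
            "intron_phases": ",".join(map(str, s.intron_phases)),
        })
    return rows


def structure_coordinates(structure: GeneStructure) -> list[dict]:
    """Exon-box / intron-line coordinates for plotting, in bp offsets."""
    out = []
    pos = 0
    for i, elen in enumerate(structure.exon_lengths):
        out.append({"kind": "exon", "start": pos, "end": pos + elen})
        pos += elen
        if i < len(structure.intron_lengths):
            ilen = structure.intron_lengths[i]
            out.append({"kind": "intron", "start": pos, "end": pos + ilen,
                        "phase": structure.intron_phases[i]})
            pos += ilen
    return out
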