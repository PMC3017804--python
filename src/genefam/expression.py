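"""Digital-northern EST counting, expression matrices, clustering, peak
calls, duplicate-divergence classes and qPCR relative quantification.

Identity convention for EST matching: the denominator is the number of
aligned columns *including* internal gap columns, each of which counts as
non-identical (stricter than BLAST's ungapped-denominator convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phylo
from .io_formats import SequenceRecord
from .pipeline import percent_round

log = logging.getLogger(__name__)

_NT_MATRIX = "NUC.4.4"


@dataclass(frozen=True)
class ESTHit:
    est_id: str
    gene_id: str
    identity_pct: float
    alignment_length: int
    library: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError("identity_pct outside [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")


@dataclass(frozen=True)
class DivergenceCall:
    gene_a: str
    gene_b: str
    pearson_r: float | None
    klass: str                           # conserved/partially_redundant/...
    reason: str = ""


@dataclass(frozen=True)
class PeakCall:
    gene_id: str
    tissue: str
    tied: bool


# ---------------------------------------------------------------------------
# EST matching


def _kmer_index(cds_records, k: int) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for gi, rec in enumerate(cds_records):
        seq = rec.residues
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos:pos + k], []).append((gi, pos))
    return index


def _gapped_identity(aligned_a: str, aligned_b: str) -> tuple[float, int]:
    """(identity % over all aligned columns incl. gaps, aligned length)."""
    length = len(aligned_a)
    same = sum(1 for x, y in zip(aligned_a, aligned_b)
               if x == y and x != "-")
    return 100.0 * same / length, length


def match_ests(cds_records: list[SequenceRecord],
               est_records: list[SequenceRecord],
               min_identity_pct: float = 96.0, min_len: int = 100,
               k: int = 11,
               library_of: dict[str, str] | None = None) -> list[ESTHit]:
    """K-mer-seeded EST-to-CDS matching.

    Seeds of length ``k`` nominate (gene, diagonal) candidates; the
    best-covered diagonal per gene is refined by gapped global alignment
    of the overlapping segments.  A hit is accepted iff identity is
    strictly above ``min_identity_pct`` and the aligned length is at least
    ``min_len``.  One best gene per EST is kept (highest identity, then
    longest alignment, then lexicographic gene id).
    """
    index = _kmer_index(cds_records, k)
    hits: list[ESTHit] = []
    for est in est_records:
        seq = est.residues
        diag_votes: dict[tuple[int, int], int] = {}
        for pos in range(len(seq) - k + 1):
            for gi, cpos in index.get(seq[pos:pos + k], ()):
                key = (gi, cpos - pos)
                diag_votes[key] = diag_votes.get(key, 0) + 1
        per_gene: dict[int, tuple[int, int]] = {}
        for (gi, diag), votes in diag_votes.items():
            if gi not in per_gene or votes > per_gene[gi][1]:
                per_gene[gi] = (diag, votes)
        best: ESTHit | None = None
        for gi, (diag, _) in per_gene.items():
            cds = cds_records[gi].residues
            est_lo = max(0, -diag)
            est_hi = min(len(seq), len(cds) - diag)
            if est_hi - est_lo < min_len:
                continue
            seg_e = seq[est_lo:est_hi]
            seg_c = cds[est_lo + diag:est_hi + diag]
            same = sum(1 for x, y in zip(seg_e, seg_c) if x == y)
            ident = 100.0 * same / len(seg_e)
            length = len(seg_e)
            if ident <= min_identity_pct and ident >= min_identity_pct - 8:
                # close call: gapped refinement may rescue indel-bearing
                # matches the ungapped diagonal undercounts
                aln = phylo.pairwise_align(
                    seg_e, seg_c, substitution=_NT_MATRIX,
                    gap_open=5.0, gap_extend=2.0)
                ident, length = _gapped_identity(aln.aligned_a,
                                                 aln.aligned_b)
            if ident > min_identity_pct and length >= min_len:
                candidate = ESTHit(
                    est.id, cds_records[gi].id, ident, length,
                    None if library_of is None else library_of.get(est.id))
                if best is None or (
                        candidate.identity_pct, candidate.alignment_length,
                        ) > (best.identity_pct, best.alignment_length) or (
                        candidate.identity_pct == best.identity_pct
                        and candidate.alignment_length
                        == best.alignment_length
                        and candidate.gene_id < best.gene_id):
                    best = candidate
        if best is not None:
            hits.append(best)
    return hits


def digital_northern(hits: list[ESTHit], manifest: dict[str, str],
                     all_genes=None, tissues=None
                     ) -> tuple[pd.DataFrame, list[str]]:
    """Integer counts per gene x tissue, plus the EST-absent gene list."""
    tissue_order = list(tissues) if tissues is not None else \
        sorted(set(manifest.values()))
    for hit in hits:
        if hit.library not in manifest:
            raise KeyError(f"unknown library {hit.library!r} for "
                           f"{hit.est_id}")
    genes = sorted({h.gene_id for h in hits}
                   | (set(all_genes) if all_genes else set()))
    counts = pd.DataFrame(0, index=genes, columns=tissue_order, dtype=int)
    for hit in hits:
        counts.loc[hit.gene_id, manifest[hit.library]] += 1
    absent = [g for g in genes if counts.loc[g].sum() == 0]
    return counts, absent


# ---------------------------------------------------------------------------
# Matrix operations


def collapse_probes(probe_matrix: pd.DataFrame,
                    probe_to_gene: dict[str, list[str]]) -> pd.DataFrame:
    """Per-gene median across probes; a shared probe copies its value to
    every gene it maps to."""
    gene_probes: dict[str, list[str]] = {}
    for probe in probe_matrix.index:
        genes = probe_to_gene.get(probe)
        if not genes:
            log.warning("probe %s unmapped; dropped", probe)
            continue
        for gene in genes:
            gene_probes.setdefault(gene, []).append(probe)
    rows = {gene: probe_matrix.loc[probes].median(axis=0)
            for gene, probes in gene_probes.items()}
    out = pd.DataFrame(rows).T.sort_index()
    out.columns = probe_matrix.columns
    return out


def normalize_matrix(matrix: pd.DataFrame, mode: str) -> pd.DataFrame:
    """"row_max": divide each row by its maximum; "log2": log2(x + 1)."""
    if mode == "log2":
        return np.log2(matrix + 1.0)
    if mode == "row_max":
        maxima = matrix.max(axis=1)
        zero_rows = maxima[maxima <= 0].index.tolist()
        if zero_rows:
            log.warning("rows with zero maximum left as zeros: %s",
                        zero_rows)
        safe = maxima.replace(0, 1.0)
        return matrix.div(safe, axis=0)
    raise ValueError(f"unknown mode {mode!r}")


def _pearson_distance(matrix: np.ndarray) -> np.ndarray:
    """1 - Pearson over rows; zero-variance rows sit at distance 1 from
    everything (and 0 from themselves)."""
    n = matrix.shape[0]
    sd = matrix.std(axis=1)
    out = np.ones((n, n))
    np.fill_diagonal(out, 0.0)
    good = sd > 0
    if good.sum() >= 2:
        sub = np.corrcoef(matrix[good])
        idx = np.nonzero(good)[0]
        out[np.ix_(idx, idx)] = 1.0 - sub
        np.fill_diagonal(out, 0.0)
    return out


@dataclass
class Dendrogram:
    merges: list[tuple[int, int, float]]  # (cluster_i, cluster_j, height)
    leaf_order: list[int]
    labels: list[str]

    def newick(self) -> str:
        from .tree import TreeNode, write_newick
        nodes = {i: TreeNode(label=lab)
                 for i, lab in enumerate(self.labels)}
        next_id = len(self.labels)
        for i, j, height in self.merges:
            nodes[next_id] = TreeNode(children=[nodes.pop(i), nodes.pop(j)])
            for child in nodes[next_id].children:
                child.length = round(height / 2, 6)
            next_id += 1
        root = nodes[max(nodes)]
        return write_newick(root)


def hcluster(matrix: pd.DataFrame) -> Dendrogram:
    """Agglomerative average-linkage clustering on 1 - Pearson distance.

    Ties break toward the smallest cluster index; output is invariant (up
    to relabeling) under row permutation.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two rows")
    labels = list(matrix.index)
    dist = _pearson_distance(matrix.to_numpy(dtype=float))
    active: dict[int, list[int]] = {i: [i] for i in range(len(labels))}
    cdist: dict[tuple[int, int], float] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            cdist[(i, j)] = float(dist[i, j])
    merges = []
    next_id = len(labels)
    while len(active) > 1:
        (ci, cj), height = min(cdist.items(), key=lambda kv: (kv[1], kv[0]))
        members = active.pop(ci) + active.pop(cj)
        cdist = {key: v for key, v in cdist.items()
                 if ci not in key and cj not in key}
        for other, members_o in active.items():
            d = float(np.mean([dist[a, b] for a in members
                               for b in members_o]))
            cdist[(min(other, next_id), max(other, next_id))] = d
        active[next_id] = members
        merges.append((ci, cj, height))
        next_id += 1
    leaf_order = active[next_id - 1]
    return Dendrogram(merges, leaf_order, labels)


# ---------------------------------------------------------------------------
# Peak tissue and divergence calls


def peak_tissue_calls(matrix: pd.DataFrame) -> tuple[list[PeakCall], dict]:
    """Argmax per row (ties -> first tissue in declared order, flagged),
    plus a per-tissue count/percentage summary."""
    calls = []
    for gene in matrix.index:
        row = matrix.loc[gene]
        top = row.max()
        winners = [t for t in matrix.columns if row[t] == top]
        calls.append(PeakCall(gene, winners[0], tied=len(winners) > 1))
    counts = {t: sum(1 for c in calls if c.tissue == t)
              for t in matrix.columns}
    summary = {
        "counts": counts,
        "percentages": {t: percent_round(n, len(calls))
                        for t, n in counts.items()},
        "n_genes": len(calls),
    }
    return calls, summary


def classify_divergence(pairs, matrix: pd.DataFrame,
                        r_conserved: float = 0.8,
                        r_diverged: float = 0.3) -> list[DivergenceCall]:
    """Pearson r across tissues -> conserved / partially_redundant /
    diverged; missing or flat members -> unclassified."""
    calls = []
    for pair in pairs:
        a, b = sorted(pair[:2])
        if a not in matrix.index or b not in matrix.index:
            calls.append(DivergenceCall(a, b, None, "unclassified",
                                        "member missing from matrix"))
            continue
        va = matrix.loc[a].to_numpy(dtype=float)
        vb = matrix.loc[b].to_numpy(dtype=float)
        if va.std() == 0 or vb.std() == 0:
            calls.append(DivergenceCall(a, b, None, "unclassified",
                                        "zero-variance member"))
            continue
        r = float(np.corrcoef(va, vb)[0, 1])
        if r >= r_conserved:
            klass = "conserved"
        elif r < r_diverged:
            klass = "diverged"
        else:
            klass = "partially_redundant"
        calls.append(DivergenceCall(a, b, r, klass))
    return calls


def qpcr_relative(ct_target: float, ct_reference: float,
                  efficiency: float = 2.0) -> float:
    """relative = efficiency ** -(ct_target - ct_reference)."""
    if efficiency <= 0:
        raise ValueError("efficiency must be positive")
    if ct_target <= 0 or ct_reference <= 0:
        raise ValueError("Ct values must be positive")
    return efficiency ** -(ct_target - ct_reference)
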