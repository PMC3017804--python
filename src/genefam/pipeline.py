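"""Run orchestration, shared reporting conventions and the full pipeline.

A run executes: census -> phylogeny -> genome organization -> gene
structure -> motifs -> expression, either on files under an input
directory or on a freshly forged genome.  Reports land under an output
directory; ``summary.json`` is byte-deterministic for a fixed config and
seed (timestamps live in ``manifest.json`` only).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)


def percent_round(numerator: int, denominator: int) -> int:
    """Integer percentage, round-half-up (87/120 -> 73)."""
    if denominator == 0:
        raise ZeroDivisionError("percent_round with zero denominator")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return int(value.quantize(Decimal(1), rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    """Every stage threshold in one place.

    Values mirror the source study's stated rules where it states them
    (tandem geometry, EST acceptance, E<1-style census acceptance);
    bootstrap reps and motif bounds default to desk scale with the
    study-scale values reachable here.
    """

    seed: int = 0
    # census
    census_accept_p: float = 1.0
    census_n_shuffles: int = 300
    census_min_coverage: float = 0.7
    # phylogeny
    bootstrap_reps: int = 100            # study scale: 1000
    subfamily_min_support: int = 50
    subfamily_min_size: int = 2
    paralog_min_identity: float = 70.0
    # genome organization
    tandem_max_intervening: int = 5
    tandem_max_span_bp: int = 100_000
    adjacency_screen_bp: int = 20_000
    tandem_confirm_identity: float = 50.0
    # motifs
    motif_max_motifs: int = 8            # study scale: 20
    motif_w_min: int = 6
    motif_w_max: int = 50                # study scale: 200
    motif_n_starts: int = 3
    motif_ic_floor: float = 2.0
    # expression
    est_min_identity: float = 96.0       # strict >
    est_min_len: int = 100
    divergence_r_conserved: float = 0.8
    divergence_r_diverged: float = 0.3
    qpcr_efficiency: float = 2.0

    def validate(self) -> None:
        checks = [
            0.0 < self.census_accept_p <= 100.0,
            self.census_n_shuffles >= 100,
            0.0 <= self.census_min_coverage <= 1.0,
            self.bootstrap_reps >= 1,
            0 <= self.subfamily_min_support <= 100,
            0.0 <= self.paralog_min_identity <= 100.0,
            self.tandem_max_intervening >= 0,
            self.tandem_max_span_bp > 0,
            self.motif_w_min >= 2,
            self.motif_w_max >= self.motif_w_min,
            0.0 <= self.est_min_identity <= 100.0,
            -1.0 <= self.divergence_r_diverged
            <= self.divergence_r_conserved <= 1.0,
            self.qpcr_efficiency > 0,
        ]
        if not all(checks):
            raise ValueError("pipeline config outside legal ranges")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class RunReport:
    summary: dict = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def audit_percentages(self) -> None:
        """Every reported percentage must equal percent_round of its
        printed counts."""
        for key, entry in self.summary.items():
            if not isinstance(entry, dict):
                continue
            pct = entry.get("pct")
            if pct is None:
                continue
            recomputed = percent_round(entry["n"], entry["of"])
            if pct != recomputed:
                raise AssertionError(
                    f"summary {key}: printed {pct}% != percent_round"
                    f"({entry['n']}, {entry['of']}) = {recomputed}")

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.audit_percentages()
        (out / "summary.json").write_text(
            json.dumps(self.summary, indent=1, sort_keys=True) + "\n")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True) + "\n")
        for name, frame in self.tables.items():
            frame.to_csv(out / f"{name}.tsv", sep="\t",
                         index=bool(frame.index.name))


def run_pipeline(config: PipelineConfig, outdir,
                 input_dir=None, forge_config=None) -> RunReport:
    """Execute all stages; forge inputs when ``forge_config`` is given."""
    from . import (domain_census, expression, gene_structure, genome_org,
                   motif_em, phylo, synthetic_data)
    from .io_formats import (read_block_pairs_tsv, read_fasta, read_gff3,
                             read_matrix_tsv)
    from .tree import write_newick

    config.validate()
    t_start = time.time()
    report = RunReport()
    report.manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "python": platform.python_version(),
        "started_unix": t_start,
        "stages": [],
    }
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage: %s", name)
        report.manifest["stages"].append(name)

    # ----- inputs ---------------------------------------------------------
    if forge_config is not None:
        stage("forge")
        forge = synthetic_data.forge_all(forge_config)
        forge.write(out / "inputs")
        input_dir = out / "inputs"
    elif input_dir is None:
        raise ValueError("need input_dir or forge_config")
    input_dir = Path(input_dir)

    proteins = read_fasta(input_dir / "proteins.fasta", "aa")
    annotation = read_gff3(input_dir / "genome.gff3")
    references = []
    if (input_dir / "references.fasta").exists():
        references = read_fasta(input_dir / "references.fasta", "aa")
    blocks = []
    if (input_dir / "blocks.tsv").exists():
        frame = read_block_pairs_tsv(input_dir / "blocks.tsv")
        blocks = [genome_org.BlockPair(
            row.pair_id, (row.chr_a, int(row.start_a), int(row.end_a)),
            (row.chr_b, int(row.start_b), int(row.end_b)))
            for row in frame.itertuples()]
    protein_of = {r.id: r.residues for r in proteins}

    # ----- census ---------------------------------------------------------
    stage("census")
    profile = domain_census.load_packaged_profile()
    hits = domain_census.scan_proteins(
        proteins, profile, n_shuffles=config.census_n_shuffles,
        accept_p=config.census_accept_p, seed=config.seed)
    census = domain_census.filter_truncated(
        hits, min_coverage=config.census_min_coverage)
    census = domain_census.assign_orthologs(census, references, protein_of)
    family = sorted(c.gene_id for c in census if not c.truncated)
    report.tables["census"] = pd.DataFrame(
        domain_census.census_table(census))
    report.summary["census"] = {
        "n_scanned": len(proteins), "n_hits": len(hits),
        "n_family": len(family),
        "n_truncated": sum(c.truncated for c in census),
    }

    # ----- phylogeny ------------------------------------------------------
    stage("phylo")
    family_recs = [r for r in proteins if r.id in set(family)]
    msa = phylo.build_msa(family_recs)
    tree = phylo.bootstrap_support(msa, reps=config.bootstrap_reps,
                                   seed=config.seed)
    (out / "family_tree.nwk").write_text(write_newick(tree) + "\n")
    partition = phylo.cut_subfamilies(
        tree, min_support=config.subfamily_min_support,
        min_size=config.subfamily_min_size)

    def identity_fn(a, b):
        return phylo.percent_identity(protein_of[a], protein_of[b])

    pairs = phylo.find_paralog_pairs(
        tree, identity_fn, min_identity=config.paralog_min_identity)
    report.tables["subfamilies"] = pd.DataFrame(
        sorted(partition.subfamily_of.items()),
        columns=["gene_id", "subfamily"])
    report.tables["paralog_pairs"] = pd.DataFrame(
        [{"gene_a": p.gene_a, "gene_b": p.gene_b,
          "identity_pct": round(p.identity_pct, 1)} for p in pairs])
    n_sf = len(set(partition.subfamily_of.values()))
    report.summary["phylo"] = {
        "n_subfamilies": n_sf,
        "n_paralog_pairs": len(pairs),
        "pair_coverage": {"n": 2 * len(pairs), "of": len(family),
                          "pct": percent_round(2 * len(pairs),
                                               len(family))},
    }

    # ----- genome organization -------------------------------------------
    stage("genome_org")
    clusters = genome_org.detect_tandem_clusters(
        annotation, set(family),
        max_intervening=config.tandem_max_intervening,
        max_span_bp=config.tandem_max_span_bp)
    adjacency = genome_org.adjacency_screen(
        annotation, set(family), max_distance_bp=config.adjacency_screen_bp)
    confirmed, raw_pairs = genome_org.confirm_tandem_pairs(
        clusters, identity_fn, min_identity=config.tandem_confirm_identity)
    retention, calls = genome_org.classify_block_retention(
        annotation, set(family), blocks)
    origins = genome_org.classify_pair_origin(
        [(p.gene_a, p.gene_b) for p in pairs], blocks, clusters, annotation)
    n_cluster_genes = sum(len(c.members) for c in clusters)
    report.tables["tandem_clusters"] = pd.DataFrame(
        [{"chromosome": c.chromosome, "members": ",".join(c.members),
          "span_bp": c.span_bp} for c in clusters])
    report.tables["retention_calls"] = pd.DataFrame(
        sorted(calls.items()), columns=["gene_id", "call"])
    report.tables["pair_origins"] = pd.DataFrame(
        [{"gene_a": a, "gene_b": b, "origin": o}
         for (a, b), o in sorted(origins.items())])
    report.summary["genome_org"] = {
        "n_tandem_clusters": len(clusters),
        "n_cluster_genes": n_cluster_genes,
        "tandem_gene_share": {
            "n": n_cluster_genes, "of": len(family),
            "pct": percent_round(n_cluster_genes, len(family))},
        "n_adjacent_pairs_20kb": len(adjacency),
        "n_raw_cluster_pairs": raw_pairs,
        "n_confirmed_tandem_pairs": len(confirmed),
        "retention": {
            "n_mapped": retention.n_mapped,
            "n_both_retained": retention.n_both_retained,
            "n_one_sided": retention.n_one_sided,
            "n_outside": retention.n_outside,
            "retained": {"n": retention.n_both_retained,
                         "of": retention.n_mapped,
                         "pct": retention.retained_pct},
        },
        "pair_origins": {o: sum(1 for v in origins.values() if v == o)
                         for o in genome_org.ORIGINS},
    }

    # ----- gene structure -------------------------------------------------
    stage("gene_structure")
    structures = {g: gene_structure.extract_structure(annotation.models[g])
                  for g in family if g in annotation.models}
    comparisons = []
    for p in pairs:
        if p.gene_a in structures and p.gene_b in structures:
            comp = gene_structure.compare_structures(
                structures[p.gene_a], structures[p.gene_b])
            comparisons.append((p, comp))
    report.tables["gene_structure"] = pd.DataFrame(
        gene_structure.structure_table(structures.values()))
    report.tables["structure_pairs"] = pd.DataFrame(
        [{"gene_a": p.gene_a, "gene_b": p.gene_b,
          "conserved": c.conserved,
          "intron_count_diff": c.intron_count_diff,
          "length_ratio": round(c.length_ratio, 3)}
         for p, c in comparisons])
    n_cons = sum(1 for _, c in comparisons if c.conserved)
    report.summary["gene_structure"] = {
        "n_pairs_compared": len(comparisons),
        "n_structure_conserved": n_cons,
    }

    # ----- motifs ---------------------------------------------------------
    stage("motifs")
    motifs = motif_em.discover_motifs(
        family_recs, max_motifs=config.motif_max_motifs,
        w_min=config.motif_w_min, w_max=config.motif_w_max,
        n_starts=config.motif_n_starts, seed=config.seed,
        ic_floor=config.motif_ic_floor)
    motif_map = motif_em.assign_motif_map(family_recs, motifs)
    shared = []
    for p in pairs:
        frac, ordered = motif_em.compare_motif_maps(
            motif_map.occurrences.get(p.gene_a, []),
            motif_map.occurrences.get(p.gene_b, []))
        shared.append((p, frac, ordered))
    report.tables["motif_map"] = pd.DataFrame(
        [{"gene_id": g, "motif_id": m, "offset": off,
          "score": round(s, 2)}
         for g, occs in sorted(motif_map.occurrences.items())
         for m, off, s in occs])
    report.summary["motifs"] = {
        "n_motifs": len(motifs),
        "n_pairs_shared_composition": sum(
            1 for _, frac, _ in shared if frac >= 1.0),
    }
    bg = motif_em._background_freqs(motif_em._encode_all(family_recs))
    motif_em.write_meme_minimal(motifs, bg, out / "motifs.meme.txt")

    # ----- expression -----------------------------------------------------
    stage("expression")
    expr_summary = {}
    manifest_path = input_dir / "est_manifest.tsv"
    if manifest_path.exists():
        manifest_frame = pd.read_csv(manifest_path, sep="\t")
        manifest = dict(zip(manifest_frame.library_id,
                            manifest_frame.tissue))
        cds = read_fasta(input_dir / "cds.fasta", "nt")
        est_records, library_of = [], {}
        for lib in manifest:
            lib_path = input_dir / f"{lib}.fasta"
            if not lib_path.exists():
                continue
            for rec in read_fasta(lib_path, "nt"):
                est_records.append(rec)
                library_of[rec.id] = lib
        est_hits = expression.match_ests(
            [c for c in cds if c.id in set(family)], est_records,
            min_identity_pct=config.est_min_identity,
            min_len=config.est_min_len, library_of=library_of)
        counts, absent = expression.digital_northern(
            est_hits, manifest, all_genes=family,
            tissues=sorted(set(manifest.values())))
        report.tables["digital_northern"] = counts.rename_axis("gene_id")
        expr_summary["est"] = {
            "n_ests": len(est_records), "n_hits": len(est_hits),
            "n_genes_with_est": len(family) - len(absent),
            "n_genes_est_absent": len(absent),
        }
    else:
        report.manifest["stages"].append("expression.est_skipped")

    matrix_path = input_dir / "expression.tsv"
    if matrix_path.exists():
        matrix = read_matrix_tsv(matrix_path)
        probe_path = input_dir / "probe_matrix.tsv"
        if probe_path.exists():
            probe_matrix = read_matrix_tsv(probe_path)
            probe_map_frame = pd.read_csv(input_dir / "probe_map.tsv",
                                          sep="\t")
            probe_to_gene: dict[str, list[str]] = {}
            for row in probe_map_frame.itertuples():
                probe_to_gene.setdefault(row.probe_id, []).append(
                    row.gene_id)
            collapsed = expression.collapse_probes(probe_matrix,
                                                   probe_to_gene)
        else:
            collapsed = matrix
        normalized = expression.normalize_matrix(collapsed, "row_max")
        dendro = expression.hcluster(normalized)
        (out / "expression_dendrogram.nwk").write_text(
            dendro.newick() + "\n")
        peaks, peak_summary = expression.peak_tissue_calls(collapsed)
        divergence = expression.classify_divergence(
            [(p.gene_a, p.gene_b) for p in pairs], collapsed,
            r_conserved=config.divergence_r_conserved,
            r_diverged=config.divergence_r_diverged)
        report.tables["peak_calls"] = pd.DataFrame(
            [{"gene_id": c.gene_id, "peak_tissue": c.tissue,
              "tied": c.tied} for c in peaks])
        report.tables["divergence_calls"] = pd.DataFrame(
            [{"gene_a": c.gene_a, "gene_b": c.gene_b,
              "pearson_r": None if c.pearson_r is None
              else round(c.pearson_r, 4), "class": c.klass}
             for c in divergence])
        klasses = [c.klass for c in divergence]
        expr_summary["peaks"] = peak_summary
        expr_summary["divergence"] = {
            k: klasses.count(k)
            for k in ("conserved", "partially_redundant", "diverged",
                      "unclassified")}
    else:
        report.manifest["stages"].append("expression.matrix_skipped")

    qpcr_path = input_dir / "qpcr.tsv"
    if qpcr_path.exists():
        qpcr = pd.read_csv(qpcr_path, sep="\t")
        qpcr["relative"] = [
            expression.qpcr_relative(row.ct_mean, row.ct_ref_mean,
                                     config.qpcr_efficiency)
            for row in qpcr.itertuples()]
        report.tables["qpcr_relative"] = qpcr
    if expr_summary:
        report.summary["expression"] = expr_summary

    report.manifest["elapsed_s"] = round(time.time() - t_start, 2)
    report.write(out)
    return report
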