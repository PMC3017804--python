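"""Tandem detection, homeologous-block retention and pair-origin calls.

Chromosome labels starting with ``LG_`` are linkage groups; anything else
is an unplaced scaffold and is excluded from linkage-group statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import GenomeAnnotation
from .pipeline import percent_round

log = logging.getLogger(__name__)


def is_linkage_group(chromosome: str) -> bool:
    return chromosome.startswith("LG_")


@dataclass(frozen=True)
class BlockPair:
    pair_id: str
    interval_a: tuple[str, int, int]       # (chromosome, start, end) 1-based
    interval_b: tuple[str, int, int]

    def __post_init__(self) -> None:
        for chrom, start, end in (self.interval_a, self.interval_b):
            if start > end:
                raise ValueError(f"{self.pair_id}: empty interval on {chrom}")


@dataclass(frozen=True)
class TandemCluster:
    chromosome: str
    members: tuple[str, ...]               # ordered by position
    span_bp: int


@dataclass(frozen=True)
class RetentionSummary:
    n_mapped: int
    n_both_retained: int
    n_one_sided: int
    n_outside: int
    n_one_sided_blocks: int

    def __post_init__(self) -> None:
        if self.n_both_retained + self.n_one_sided + self.n_outside \
                != self.n_mapped:
            raise ValueError("retention counts do not partition n_mapped")

    @property
    def retained_pct(self) -> int:
        return percent_round(self.n_both_retained, self.n_mapped)


ORIGINS = ("tandem", "segmental", "untraceable_scaffold",
           "divergent_blocks", "outside_blocks")


def _in_interval(model, interval, mode: str) -> bool:
    chrom, start, end = interval
    if model.chromosome != chrom:
        return False
    if mode == "midpoint":
        mid = (model.start + model.end) // 2
        return start <= mid <= end
    return start >= 1 and model.start >= start and model.end <= end


def detect_tandem_clusters(annotation: GenomeAnnotation,
                           family_ids: set[str],
                           max_intervening: int = 5,
                           max_span_bp: int = 100_000,
                           count_rule: str = "intervening"
                           ) -> list[TandemCluster]:
    """Connected components of the tandem link relation.

    Two family genes on one chromosome are linked when the number of
    intervening annotated loci (rank gap - 1) is <= ``max_intervening`` and
    the start-to-end distance is <= ``max_span_bp``; both bounds inclusive.
    ``count_rule="rank_gap"`` applies the alternative reading (rank gap
    itself <= the threshold).
    """
    if count_rule not in ("intervening", "rank_gap"):
        raise ValueError(f"unknown count_rule {count_rule!r}")
    clusters: list[TandemCluster] = []
    by_chrom: dict[str, list] = {}
    for gid in family_ids:
        model = annotation.models.get(gid)
        if model is None:
            continue
        by_chrom.setdefault(model.chromosome, []).append(model)
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda m: m.start)
        # union-find over chained links
        parent = list(range(len(genes)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                gap = genes[j].locus_rank - genes[i].locus_rank
                intervening = gap - 1 if count_rule == "intervening" else gap
                distance = genes[j].end - genes[i].start
                if intervening <= max_intervening and distance <= max_span_bp:
                    parent[find(j)] = find(i)
        groups: dict[int, list] = {}
        for i, g in enumerate(genes):
            groups.setdefault(find(i), []).append(g)
        for members in groups.values():
            if len(members) < 2:
                continue
            clusters.append(TandemCluster(
                chromosome=chrom,
                members=tuple(m.gene_id for m in members),
                span_bp=members[-1].end - members[0].start,
            ))
    return sorted(clusters, key=lambda c: (c.chromosome, c.members))


def adjacency_screen(annotation: GenomeAnnotation, family_ids: set[str],
                     max_distance_bp: int = 20_000) -> list[tuple[str, str]]:
    """Optional pre-report: family gene pairs within a fixed bp distance."""
    pairs = []
    by_chrom: dict[str, list] = {}
    for gid in family_ids:
        model = annotation.models.get(gid)
        if model is not None:
            by_chrom.setdefault(model.chromosome, []).append(model)
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda m: m.start)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if genes[j].start - genes[i].end <= max_distance_bp:
                    pairs.append(tuple(sorted(
                        (genes[i].gene_id, genes[j].gene_id))))
    return sorted(set(pairs))


def confirm_tandem_pairs(clusters: list[TandemCluster], identity_fn,
                         min_identity: float = 50.0):
    """Within-cluster pairs kept when protein identity >= min_identity.

    Returns (confirmed pairs with identity, raw within-cluster pair count).
    """
    confirmed = []
    raw = 0
    for cluster in clusters:
        members = cluster.members
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                raw += 1
                a, b = sorted((members[i], members[j]))
                try:
                    ident = identity_fn(a, b)
                except KeyError:
                    log.warning("missing protein for %s/%s; pair skipped",
                                a, b)
                    continue
                if ident >= min_identity:
                    confirmed.append((a, b, ident))
    return sorted(confirmed), raw


def classify_block_retention(annotation: GenomeAnnotation,
                             family_ids: set[str],
                             blocks: list[BlockPair],
                             membership: str = "full_span"
                             ) -> tuple[RetentionSummary, dict[str, str]]:
    """Per-gene both_retained / one_sided / outside calls on linkage groups.

    A family gene inside one interval of a block pair whose partner
    interval also holds a family gene is both_retained; inside a block
    whose partner holds none is one_sided; in no block, outside.  Scaffold
    genes are excluded from n_mapped.  A gene covered by several block
    pairs is both_retained if any pairing qualifies.
    """
    mapped = [annotation.models[g] for g in sorted(family_ids)
              if g in annotation.models
              and is_linkage_group(annotation.models[g].chromosome)]
    occupancy: dict[tuple[str, str], list[str]] = {}
    for model in mapped:
        for block in blocks:
            for side, interval in (("a", block.interval_a),
                                   ("b", block.interval_b)):
                if _in_interval(model, interval, membership):
                    occupancy.setdefault((block.pair_id, side), []).append(
                        model.gene_id)
    calls: dict[str, str] = {}
    one_sided_blocks: set[str] = set()
    for block in blocks:
        has_a = bool(occupancy.get((block.pair_id, "a")))
        has_b = bool(occupancy.get((block.pair_id, "b")))
        if has_a != has_b:
            one_sided_blocks.add(block.pair_id)
    for model in mapped:
        verdict = "outside"
        for block in blocks:
            in_a = _in_interval(model, block.interval_a, membership)
            in_b = _in_interval(model, block.interval_b, membership)
            if not (in_a or in_b):
                continue
            partner_key = (block.pair_id, "b" if in_a else "a")
            if occupancy.get(partner_key):
                verdict = "both_retained"
                break
            verdict = "one_sided"
        calls[model.gene_id] = verdict
    summary = RetentionSummary(
        n_mapped=len(mapped),
        n_both_retained=sum(v == "both_retained" for v in calls.values()),
        n_one_sided=sum(v == "one_sided" for v in calls.values()),
        n_outside=sum(v == "outside" for v in calls.values()),
        n_one_sided_blocks=len(one_sided_blocks),
    )
    return summary, calls


def classify_pair_origin(pairs: list[tuple[str, str]],
                         blocks: list[BlockPair],
                         clusters: list[TandemCluster],
                         annotation: GenomeAnnotation,
                         membership: str = "full_span") -> dict:
    """One origin call per pair; precedence tandem > segmental."""
    cluster_of: dict[str, int] = {}
    for i, cluster in enumerate(clusters):
        for gid in cluster.members:
            cluster_of[gid] = i
    calls: dict[tuple[str, str], str] = {}
    for raw_pair in pairs:
        a, b = sorted(raw_pair)
        ma, mb = annotation.models[a], annotation.models[b]
        if not is_linkage_group(ma.chromosome) \
                or not is_linkage_group(mb.chromosome):
            calls[(a, b)] = "untraceable_scaffold"
            continue
        if a in cluster_of and cluster_of.get(b) == cluster_of[a]:
            calls[(a, b)] = "tandem"
            continue
        segmental = False
        a_in_block = b_in_block = False
        for block in blocks:
            a_a = _in_interval(ma, block.interval_a, membership)
            a_b = _in_interval(ma, block.interval_b, membership)
            b_a = _in_interval(mb, block.interval_a, membership)
            b_b = _in_interval(mb, block.interval_b, membership)
            a_in_block |= a_a or a_b
            b_in_block |= b_a or b_b
            if (a_a and b_b) or (a_b and b_a):
                segmental = True
        if segmental:
            calls[(a, b)] = "segmental"
        elif a_in_block and b_in_block:
            calls[(a, b)] = "divergent_blocks"
        else:
            calls[(a, b)] = "outside_blocks"
    return calls
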