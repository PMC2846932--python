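"""Tandem-cluster detection, segmental-block assignment, expansion classes.

Tandem duplication is called when same-family genes sit close together on a
chromosome: rank gap (number of genes apart) at most ``max_gene_gap`` and
start-to-start distance at most ``max_bp`` (100 kb for compact genomes such
as Arabidopsis, 350 kb for soybean and rice).  The distance criteria are
applied per adjacent family-member pair and chained transitively, so a long
array qualifies as one cluster even when its overall span exceeds the cap.

Segmental duplication is called from paired chromosomal block intervals
with homologous anchor genes; blocks can be supplied (from genome-scale
synteny studies) or inferred de novo around a candidate lectin pair by
comparing 50-kb flanking windows for collinear homologous gene pairs.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_io import GeneModel, GenomeAnnotation, Interval
from .family_classifier import FamilyAssignment

EXPANSION_CLASSES = ("tandem", "segmental", "both", "other")


@dataclass
class TandemCluster:
    cluster_id: str
    family: str
    chromosome: str
    members: list[str]  # gene_ids ordered by rank
    span: Interval

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SegmentalBlockPair:
    block_id: str
    interval_a: Interval
    interval_b: Interval
    anchors: list[tuple[str, str]] = field(default_factory=list)
    provenance: str = "given"  # or "inferred"


@dataclass(frozen=True)
class ExpansionClass:
    gene_id: str
    expansion: str  # tandem | segmental | both | other

    def __post_init__(self):
        if self.expansion not in EXPANSION_CLASSES:
            raise ValueError(f"unknown expansion class {self.expansion!r}")


class RanksMissingError(RuntimeError):
    pass


def _require_ranks(genes: Iterable[GeneModel]) -> None:
    for gene in genes:
        if gene.rank is None:
            raise RanksMissingError(
                f"gene {gene.gene_id} has no rank; run compute_gene_ranks first"
            )


def tandem_pair_predicate(
    a: GeneModel, b: GeneModel, max_gene_gap: int, max_bp: int
) -> bool:
    """True iff two same-chromosome genes satisfy both closeness criteria."""
    if a.locus.chromosome != b.locus.chromosome:
        return False
    if abs(a.rank - b.rank) > max_gene_gap:
        return False
    return abs(a.locus.start - b.locus.start) <= max_bp


def find_tandem_clusters(
    family_genes: Mapping[str, str],
    annotation: GenomeAnnotation,
    max_gene_gap: int = 10,
    max_bp: int = 350_000,
) -> list[TandemCluster]:
    """Maximal chains of nearby same-family genes; singletons are not clusters.

    ``family_genes`` maps gene_id -> family.  Within each (family,
    chromosome) group, genes sorted by rank are chained whenever consecutive
    members satisfy the pairwise predicate; because rank gaps and
    start-to-start distances are monotone along the sorted order, this
    chaining equals the transitive closure of the predicate over all pairs.
    """
    genes = [annotation.genes[g] for g in family_genes if g in annotation.genes]
    _require_ranks(genes)
    groups: dict[tuple[str, str], list[GeneModel]] = {}
    for gene in genes:
        key = (family_genes[gene.gene_id], gene.locus.chromosome)
        groups.setdefault(key, []).append(gene)

    clusters = []
    for (family, chrom) in sorted(groups):
        ordered = sorted(groups[(family, chrom)], key=lambda g: g.rank)
        chain = [ordered[0]]
        chains = []
        for gene in ordered[1:]:
            if tandem_pair_predicate(chain[-1], gene, max_gene_gap, max_bp):
                chain.append(gene)
            else:
                chains.append(chain)
                chain = [gene]
        chains.append(chain)
        for chain in chains:
            if len(chain) < 2:
                continue
            span = Interval(
                chrom,
                min(g.locus.start for g in chain),
                max(g.locus.end for g in chain),
                ".",
            )
            clusters.append(
                TandemCluster(
                    cluster_id=f"TC_{family}_{chrom}_{chain[0].rank}",
                    family=family,
                    chromosome=chrom,
                    members=[g.gene_id for g in chain],
                    span=span,
                )
            )
    return clusters


def collapse_tandem_arrays(
    gene_ids: Iterable[str], clusters: Iterable[TandemCluster]
) -> list[str]:
    """Replace each tandem array by its first-rank member.

    Tandemly arrayed genes are treated as a single gene copy when counting
    segmental duplicates, so one representative (the lowest-rank member)
    stands for the whole array.
    """
    rep_of: dict[str, str] = {}
    for cluster in clusters:
        for member in cluster.members:
            rep_of[member] = cluster.members[0]
    out, seen = [], set()
    for gid in gene_ids:
        rep = rep_of.get(gid, gid)
        if rep not in seen:
            seen.add(rep)
            out.append(rep)
    return out


def read_block_table(path) -> list[SegmentalBlockPair]:
    """Block list TSV (block_id, chrA, startA, endA, chrB, startB, endB).

    File coordinates are 1-based inclusive and converted to the internal
    0-based half-open convention here.
    """
    frame = pd.read_csv(path, sep="\t")
    blocks = []
    for row in frame.itertuples(index=False):
        blocks.append(
            SegmentalBlockPair(
                block_id=str(row.block_id),
                interval_a=Interval(str(row.chrA), int(row.startA) - 1, int(row.endA)),
                interval_b=Interval(str(row.chrB), int(row.startB) - 1, int(row.endB)),
            )
        )
    return blocks


def write_block_table(blocks: Iterable[SegmentalBlockPair], path) -> None:
    rows = []
    for b in blocks:
        rows.append(
            {
                "block_id": b.block_id,
                "chrA": b.interval_a.chromosome,
                "startA": b.interval_a.start + 1,
                "endA": b.interval_a.end,
                "chrB": b.interval_b.chromosome,
                "startB": b.interval_b.start + 1,
                "endB": b.interval_b.end,
            }
        )
    pd.DataFrame(
        rows,
        columns=["block_id", "chrA", "startA", "endA", "chrB", "startB", "endB"],
    ).to_csv(path, sep="\t", index=False)


def assign_segmental_from_blocks(
    representatives: Iterable[str],
    blocks: Iterable[SegmentalBlockPair],
    family_of: Mapping[str, str],
    annotation: GenomeAnnotation,
    clusters: Iterable[TandemCluster] = (),
) -> list[tuple[str, str, str]]:
    """Pairs (gene, gene', block_id): same family, one in each block interval.

    Only array representatives are matched against blocks; a representative
    counts as inside a block interval when any member of its array lies
    there (the array, treated as a single gene copy, is located wherever
    its members are).  Every member of a matched array then inherits the
    array's segmental status (see :func:`segmental_gene_set`).
    """
    members_of: dict[str, list[str]] = {}
    for cluster in clusters:
        members_of[cluster.members[0]] = list(cluster.members)

    def in_interval(rep: GeneModel, interval: Interval) -> bool:
        for member in members_of.get(rep.gene_id, [rep.gene_id]):
            gene = annotation.genes.get(member)
            if gene is not None and interval.contains(gene.locus):
                return True
        return False

    reps = [annotation.genes[g] for g in representatives if g in annotation.genes]
    pairs = []
    for block in blocks:
        in_a = [g for g in reps if in_interval(g, block.interval_a)]
        in_b = [g for g in reps if in_interval(g, block.interval_b)]
        for ga in in_a:
            for gb in in_b:
                if ga.gene_id == gb.gene_id:
                    continue
                fa = family_of.get(ga.gene_id)
                if fa is not None and fa == family_of.get(gb.gene_id):
                    pair = tuple(sorted((ga.gene_id, gb.gene_id)))
                    pairs.append((pair[0], pair[1], block.block_id))
    return sorted(set(pairs))


def segmental_gene_set(
    pairs: Iterable[tuple[str, str, str]], clusters: Iterable[TandemCluster]
) -> set[str]:
    """All genes with segmental status, expanding representatives to arrays."""
    members_of: dict[str, list[str]] = {}
    for cluster in clusters:
        members_of[cluster.members[0]] = list(cluster.members)
    genes: set[str] = set()
    for a, b, _block in pairs:
        for gid in (a, b):
            genes.update(members_of.get(gid, [gid]))
    return genes


def _longest_monotone_chain(values: Sequence[int]) -> int:
    """Length of the longest strictly increasing or decreasing subsequence."""

    def lis(seq: Sequence[int]) -> int:
        tails: list[int] = []
        for v in seq:
            i = bisect_left(tails, v)
            if i == len(tails):
                tails.append(v)
            else:
                tails[i] = v
        return len(tails)

    return max(lis(values), lis([-v for v in values]))


def infer_block_from_flanks(
    gene_pair: tuple[str, str],
    annotation: GenomeAnnotation,
    homology_pairs: Iterable[tuple[str, str]],
    flank_bp: int = 50_000,
    min_extra_anchors: int = 2,
) -> SegmentalBlockPair | None:
    """Infer a duplicated block around a candidate gene pair from its flanks.

    Besides the seed pair itself, at least ``min_extra_anchors`` homologous
    gene pairs must link the two flanking windows (locus extended by
    ``flank_bp`` on both sides) in a consistent relative order — co-linear
    or fully reversed, measured as the longest monotone chain of partner
    positions.  Returns None (with no block) when the two windows overlap on
    the same chromosome ("self-overlap") or the anchor evidence is short.
    """
    ga, gb = (annotation.genes[g] for g in gene_pair)
    win_a = Interval(
        ga.locus.chromosome,
        max(ga.locus.start - flank_bp, 0),
        ga.locus.end + flank_bp,
    )
    win_b = Interval(
        gb.locus.chromosome,
        max(gb.locus.start - flank_bp, 0),
        gb.locus.end + flank_bp,
    )
    if win_a.overlaps(win_b):
        return None

    homolog = set()
    for x, y in homology_pairs:
        homolog.add((x, y))
        homolog.add((y, x))

    genes_a = [
        g for g in annotation.genes_on(win_a.chromosome)
        if win_a.contains(g.locus) and g.gene_id != ga.gene_id
    ]
    genes_b = [
        g for g in annotation.genes_on(win_b.chromosome)
        if win_b.contains(g.locus) and g.gene_id != gb.gene_id
    ]
    pos_b = {g.gene_id: i for i, g in enumerate(genes_b)}

    anchors: list[tuple[str, str, int]] = []
    used_b: set[str] = set()
    for g in genes_a:  # genes_a already position-sorted
        partners = [h.gene_id for h in genes_b
                    if (g.gene_id, h.gene_id) in homolog and h.gene_id not in used_b]
        if partners:
            partner = partners[0]
            used_b.add(partner)
            anchors.append((g.gene_id, partner, pos_b[partner]))

    if len(anchors) < min_extra_anchors:
        return None
    chain = _longest_monotone_chain([a[2] for a in anchors])
    if chain < min_extra_anchors:
        return None

    all_a = [ga] + [annotation.genes[a] for a, _, _ in anchors]
    all_b = [gb] + [annotation.genes[b] for _, b, _ in anchors]
    span_a = Interval(
        win_a.chromosome,
        min(g.locus.start for g in all_a),
        max(g.locus.end for g in all_a),
    )
    span_b = Interval(
        win_b.chromosome,
        min(g.locus.start for g in all_b),
        max(g.locus.end for g in all_b),
    )
    return SegmentalBlockPair(
        block_id=f"INF_{ga.gene_id}_{gb.gene_id}",
        interval_a=span_a,
        interval_b=span_b,
        anchors=[(ga.gene_id, gb.gene_id)] + [(a, b) for a, b, _ in anchors],
        provenance="inferred",
    )


def classify_expansion(
    gene_ids: Iterable[str],
    clusters: Iterable[TandemCluster],
    segmental_genes: set[str],
) -> list[ExpansionClass]:
    """Partition genes into tandem / segmental / both / other."""
    tandem_genes = {m for c in clusters for m in c.members}
    out = []
    for gid in gene_ids:
        in_t, in_s = gid in tandem_genes, gid in segmental_genes
        if in_t and in_s:
            cls = "both"
        elif in_t:
            cls = "tandem"
        elif in_s:
            cls = "segmental"
        else:
            cls = "other"
        out.append(ExpansionClass(gene_id=gid, expansion=cls))
    return out


def round_percent(numerator: int, denominator: int) -> int:
    """Integer percent, rounding halves away from zero (43.5 -> 44)."""
    if denominator == 0:
        return 0
    return int(100.0 * numerator / denominator + 0.5)


def expansion_summary(
    classes: Iterable[ExpansionClass],
    family_of: Mapping[str, str],
    species_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-species, per-family counts and integer percentages by class.

    'tandem_involved' counts tandem+both; 'segmental_involved' counts
    segmental+both, matching how genes "involved in" each duplication mode
    are totalled.
    """
    classes = list(classes)
    species_map = species_of or {}
    rows = []
    keys = sorted(
        {
            (species_map.get(c.gene_id, "all"), family_of.get(c.gene_id, "?"))
            for c in classes
        }
    )
    for sp, family in keys:
        members = [
            c
            for c in classes
            if species_map.get(c.gene_id, "all") == sp
            and family_of.get(c.gene_id, "?") == family
        ]
        n = len(members)
        counts = {cls: sum(m.expansion == cls for m in members) for cls in EXPANSION_CLASSES}
        t_inv = counts["tandem"] + counts["both"]
        s_inv = counts["segmental"] + counts["both"]
        rows.append(
            {
                "species": sp,
                "family": family,
                "total": n,
                **counts,
                "tandem_involved": t_inv,
                "segmental_involved": s_inv,
                "tandem_pct": round_percent(t_inv, n),
                "segmental_pct": round_percent(s_inv, n),
                "other_pct": round_percent(counts["other"], n),
            }
        )
    return pd.DataFrame(rows)
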