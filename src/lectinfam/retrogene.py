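"""Retrogene detection: intronless paralogs with retroposition hallmarks.

A retrogene is born when a reverse-transcribed mRNA reinserts into the
genome; the copy is intronless and, until erosion hides them, carries
target-site duplications (TSDs — short identical direct repeats flanking
the insertion) and a 3' poly(A) tract.  Candidates are single-exon genes
with a strong protein-level match (>=70% query coverage, e-value <= 1e-8)
to a multi-exon family member; flank scans then grade each candidate's
evidence tier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .genome_io import GeneModel, GenomeAnnotation, Interval
from .duplication import TandemCluster

BLAST12_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HomologyHit:
    query: str
    subject: str
    evalue: float
    query_coverage: float
    percent_identity: float


@dataclass(frozen=True)
class TSDHit:
    repeat: str
    left_position: int   # offset of repeat start back from the gene 5' boundary
    right_position: int  # offset of repeat start past the gene 3' boundary
    length: int
    mismatches: int = 0


@dataclass(frozen=True)
class PolyAHit:
    start_offset: int  # bp downstream of the gene end
    run_length: int
    adenine_fraction: float


@dataclass
class RetrogeneCall:
    retrogene: str  # single-exon gene
    parent: str     # >=2-exon gene
    evalue: float
    query_coverage: float
    tsd: TSDHit | None = None
    polya: PolyAHit | None = None

    @property
    def tier(self) -> str:
        if self.tsd and self.polya:
            return "+both"
        if self.tsd:
            return "+TSD"
        if self.polya:
            return "+polyA"
        return "homology_only"


def read_homology_table(path, protein_lengths: Mapping[str, int]) -> list[HomologyHit]:
    """12-column BLAST tabular dialect; coverage needs query protein lengths."""
    frame = pd.read_csv(path, sep="\t", names=BLAST12_COLUMNS, comment="#")
    hits = []
    for row in frame.itertuples(index=False):
        qlen = protein_lengths.get(str(row.qseqid))
        if qlen is None or qlen <= 0:
            continue
        coverage = (abs(int(row.qend) - int(row.qstart)) + 1) / qlen
        hits.append(
            HomologyHit(
                query=str(row.qseqid),
                subject=str(row.sseqid),
                evalue=float(row.evalue),
                query_coverage=min(coverage, 1.0),
                percent_identity=float(row.pident),
            )
        )
    return hits


def find_retro_candidates(
    annotation: GenomeAnnotation,
    lectin_genes: Iterable[str],
    homology: Iterable[HomologyHit],
    min_coverage: float = 0.70,
    max_evalue: float = 1e-8,
) -> list[RetrogeneCall]:
    """Single-exon lectins matching a multi-exon lectin at >=70% coverage.

    The best-e-value qualifying multi-exon subject is designated the
    parental gene of each candidate (ties broken by subject id so the
    result is independent of input order).
    """
    lectins = {g for g in lectin_genes if g in annotation.genes}
    single = {g for g in lectins if annotation.genes[g].is_intronless}
    multi = {g for g in lectins if annotation.genes[g].exon_count >= 2}

    best: dict[str, HomologyHit] = {}
    for hit in homology:
        if hit.query not in single or hit.subject not in multi:
            continue
        if hit.query_coverage < min_coverage or hit.evalue > max_evalue:
            continue
        cur = best.get(hit.query)
        if cur is None or (hit.evalue, hit.subject) < (cur.evalue, cur.subject):
            best[hit.query] = hit
    return [
        RetrogeneCall(
            retrogene=q,
            parent=h.subject,
            evalue=h.evalue,
            query_coverage=h.query_coverage,
        )
        for q, h in sorted(best.items())
    ]


def detect_polyA(
    downstream_seq: str,
    window: int = 200,
    min_run: int = 8,
    min_purity: float = 0.8,
) -> PolyAHit | None:
    """Best A-rich run in the first ``window`` bp downstream of a gene.

    Scans every substring of length >= ``min_run`` whose adenine fraction is
    at least ``min_purity``; the best tract carries the most adenines
    (ties: higher purity, then earliest start), so a pure run is preferred
    over a longer dilution of the same adenines.  Sequences are expected
    5'->3' on the gene's coding strand, so the tract is always sought in
    the sense orientation.
    """
    seq = downstream_seq[:window].upper()
    n = len(seq)
    prefix = [0] * (n + 1)
    for i, base in enumerate(seq):
        prefix[i + 1] = prefix[i] + (base == "A")
    best: tuple[int, float, int, int] | None = None  # (a_count, purity, -start, length)
    for start in range(n):
        for end in range(start + min_run, n + 1):
            a_count = prefix[end] - prefix[start]
            length = end - start
            purity = a_count / length
            if purity >= min_purity:
                key = (a_count, purity, -start, length)
                if best is None or key > best:
                    best = key
    if best is None:
        return None
    a_count, purity, neg_start, length = best
    return PolyAHit(start_offset=-neg_start, run_length=length, adenine_fraction=purity)


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def detect_tsd(
    upstream_seq: str,
    downstream_seq: str,
    min_len: int = 4,
    max_len: int = 20,
    max_mismatch: int = 0,
    search_bp: int = 100,
) -> TSDHit | None:
    """Direct repeat flanking an insertion: longest match near the boundaries.

    Compares the last ``search_bp`` of the upstream flank against the first
    ``search_bp`` of the downstream flank (both 5'->3' on the gene strand).
    Returns the longest repeat of length in [min_len, max_len] with at most
    ``max_mismatch`` mismatches; ties are broken by total proximity to the
    two insertion boundaries.
    """
    up = upstream_seq[-search_bp:].upper()
    down = downstream_seq[:search_bp].upper()
    best: tuple[int, int, int, int, int, str] | None = None
    # (length, -total_distance, -mismatches, -up_dist, -down_dist, repeat)
    for length in range(min(max_len, len(up), len(down)), min_len - 1, -1):
        found_at_len = False
        for i in range(len(up) - length, -1, -1):
            up_sub = up[i : i + length]
            up_dist = len(up) - (i + length)  # bp back from upstream boundary
            for j in range(0, len(down) - length + 1):
                mm = _mismatches(up_sub, down[j : j + length])
                if mm <= max_mismatch:
                    key = (length, -(up_dist + j), -mm, -up_dist, -j, down[j : j + length])
                    if best is None or key > best:
                        best = key
                    found_at_len = True
        if found_at_len:
            break  # longest length found; shorter repeats cannot beat it
    if best is None:
        return None
    length, _neg_total, neg_mm, neg_up, neg_down, repeat = best
    return TSDHit(
        repeat=repeat,
        left_position=-neg_up,
        right_position=-neg_down,
        length=length,
        mismatches=-neg_mm,
    )


def gene_flank_sequences(
    gene: GeneModel, chromosome_seq: str, flank_bp: int
) -> tuple[str, str]:
    """(upstream, downstream) flank sequences, 5'->3' on the gene's strand."""
    left = chromosome_seq[max(gene.locus.start - flank_bp, 0) : gene.locus.start]
    right = chromosome_seq[gene.locus.end : gene.locus.end + flank_bp]
    if gene.locus.strand == "-":
        return reverse_complement(right), reverse_complement(left)
    return left, right


def call_retrogenes(
    candidates: Iterable[RetrogeneCall],
    annotation: GenomeAnnotation,
    genome_seq: Mapping[str, str],
    flank_bp: int = 1_000,
    polya_window: int = 200,
    polya_min_run: int = 8,
    polya_min_purity: float = 0.8,
    tsd_min_len: int = 4,
    tsd_max_len: int = 20,
    tsd_search_bp: int = 100,
) -> list[RetrogeneCall]:
    """Annotate each homology candidate with its hallmark evidence tier.

    Homology-only calls are retained (hallmarks erode over evolutionary
    time); the tier records which of TSD and poly(A) survive.
    """
    out = []
    for call in candidates:
        gene = annotation.genes[call.retrogene]
        chrom_seq = genome_seq.get(gene.locus.chromosome, "")
        upstream, downstream = gene_flank_sequences(gene, chrom_seq, flank_bp)
        call.tsd = detect_tsd(
            upstream,
            downstream,
            min_len=tsd_min_len,
            max_len=tsd_max_len,
            search_bp=tsd_search_bp,
        )
        call.polya = detect_polyA(
            downstream,
            window=polya_window,
            min_run=polya_min_run,
            min_purity=polya_min_purity,
        )
        out.append(call)
    return out


def retro_tandem_expansion(
    calls: Iterable[RetrogeneCall], clusters: Iterable[TandemCluster]
) -> list[tuple[RetrogeneCall, TandemCluster]]:
    """Retrogenes that later seeded tandem arrays (retro-then-tandem)."""
    cluster_of: dict[str, TandemCluster] = {}
    for cluster in clusters:
        for member in cluster.members:
            cluster_of[member] = cluster
    return [
        (call, cluster_of[call.retrogene])
        for call in calls
        if call.retrogene in cluster_of
    ]


def calls_to_frame(calls: Iterable[RetrogeneCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "retrogene": c.retrogene,
                "parent": c.parent,
                "evalue": c.evalue,
                "query_coverage": round(c.query_coverage, 4),
                "tier": c.tier,
                "tsd_repeat": c.tsd.repeat if c.tsd else "",
                "tsd_length": c.tsd.length if c.tsd else 0,
                "polya_run": c.polya.run_length if c.polya else 0,
                "polya_fraction": round(c.polya.adenine_fraction, 3) if c.polya else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "retrogene", "parent", "evalue", "query_coverage", "tier",
            "tsd_repeat", "tsd_length", "polya_run", "polya_fraction",
        ],
    )
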