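"""Canonical data model for genes and genomic intervals, plus format I/O.

All internal coordinates are 0-based, half-open ``[start, end)``.  GFF3 is
1-based inclusive and is converted at the read/write boundary; BED passes
through unchanged.  Every base-pair window in the pipeline (100 kb / 350 kb
tandem caps, 50 kb flanks) is computed in this one convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-", ".")


class Gff3ParseError(ValueError):
    """Raised on a malformed GFF3 line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class AnnotationValidationError(ValueError):
    """Raised when gene structure violates the data-model invariants."""


@dataclass(frozen=True, order=True)
class Interval:
    """A strand-aware genomic interval, 0-based half-open."""

    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chromosome}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Interval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class GeneModel:
    """One gene locus with its representative (longest-mRNA) exon chain.

    ``rank`` is the gene's ordinal position along its chromosome; it is
    assigned by :func:`compute_gene_ranks`, never read from a file, and
    defines the "N genes apart" distance used by tandem clustering.
    """

    gene_id: str
    species: str
    locus: Interval
    exons: list[Interval] = field(default_factory=list)
    rank: int | None = None

    def __post_init__(self):
        if not self.exons:
            self.exons = [self.locus]
        for exon in self.exons:
            if not self.locus.contains(exon):
                raise AnnotationValidationError(
                    f"exon {exon} outside locus of gene {self.gene_id}"
                )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise AnnotationValidationError(
                    f"overlapping exons in gene {self.gene_id}: {a} / {b}"
                )

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def is_intronless(self) -> bool:
        return self.exon_count == 1

    def introns(self) -> list[Interval]:
        """Intervals between consecutive exons (empty for intronless genes)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    Interval(self.locus.chromosome, a.end, b.start, self.locus.strand)
                )
        return out


@dataclass
class GenomeAnnotation:
    """All gene models of one species plus chromosome lengths."""

    species: str
    genes: dict[str, GeneModel] = field(default_factory=dict)
    chromosome_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for gene in self.genes.values():
            self._check_gene(gene)

    def _check_gene(self, gene: GeneModel) -> None:
        chrom = gene.locus.chromosome
        if chrom in self.chromosome_lengths:
            if gene.locus.end > self.chromosome_lengths[chrom]:
                raise AnnotationValidationError(
                    f"gene {gene.gene_id} extends past end of {chrom}"
                )

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise AnnotationValidationError(f"duplicate gene_id {gene.gene_id}")
        self._check_gene(gene)
        self.genes[gene.gene_id] = gene

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        """Genes on one chromosome in the deterministic rank order."""
        picked = [g for g in self.genes.values() if g.locus.chromosome == chromosome]
        picked.sort(key=_rank_sort_key)
        return picked

    def chromosomes(self) -> list[str]:
        return sorted({g.locus.chromosome for g in self.genes.values()})


def _rank_sort_key(gene: GeneModel):
    # start, then end, then id: deterministic ordering so downstream
    # clustering is reproducible across input shufflings
    return (gene.locus.start, gene.locus.end, gene.gene_id)


def compute_gene_ranks(annotation: GenomeAnnotation) -> GenomeAnnotation:
    """Assign per-chromosome ordinal ranks 0..n-1 to every gene, in place.

    The rank gap ``|rank_a - rank_b|`` between two genes on the same
    chromosome is the "genes apart" distance of the tandem-duplication
    criterion.
    """
    for chrom in annotation.chromosomes():
        for rank, gene in enumerate(annotation.genes_on(chrom)):
            gene.rank = rank
    return annotation


def extract_flank(
    gene: GeneModel,
    side: str,
    width_bp: int,
    chromosome_lengths: Mapping[str, int] | None = None,
) -> Interval:
    """Strand-aware flanking window adjacent to a gene locus.

    "Upstream" is 5' of the gene on its own strand: left of the locus for
    ``+`` (or unknown) strand, right of it for ``-``.  The window is clipped
    to ``[0, chromosome_length]`` when the length is known.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError(f"side must be 'upstream' or 'downstream', got {side!r}")
    if width_bp <= 0:
        raise ValueError(f"width_bp must be positive, got {width_bp}")
    locus = gene.locus
    left = (side == "upstream") == (locus.strand != "-")
    if left:
        start, end = locus.start - width_bp, locus.start
    else:
        start, end = locus.end, locus.end + width_bp
    start = max(start, 0)
    if chromosome_lengths and locus.chromosome in chromosome_lengths:
        end = min(end, chromosome_lengths[locus.chromosome])
    if start >= end:
        # fully clipped away: degenerate 1-bp-less-than-nothing window is not
        # representable; return the smallest legal stub at the boundary
        boundary = locus.start if left else locus.end
        start = max(boundary - 1, 0)
        end = start + 1
    return Interval(locus.chromosome, start, end, locus.strand)


# ---------------------------------------------------------------------------
# GFF3


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for piece in text.strip().split(";"):
        piece = piece.strip()
        if not piece:
            continue
        if "=" not in piece:
            raise ValueError(f"bad attribute {piece!r}")
        key, value = piece.split("=", 1)
        out[key] = value
    return out


def read_gff3(path, species: str | None = None) -> GenomeAnnotation:
    """Read gene/mRNA/exon features into a :class:`GenomeAnnotation`.

    One GeneModel per gene, keeping only the representative transcript: the
    mRNA with the greatest total exon length (ties: more exons, then mRNA
    id).  ``##sequence-region`` pragmas supply chromosome lengths.
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    mrna_exons: dict[str, list[Interval]] = {}
    chrom_lengths: dict[str, int] = {}
    sp = species or "unknown"

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise Gff3ParseError(
                    f"expected 9 tab-separated columns, got {len(cols)}", lineno
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
                attrs = _parse_attributes(attrs_s)
            except ValueError as exc:
                raise Gff3ParseError(str(exc), lineno) from None
            if start1 < 1 or end1 < start1:
                raise Gff3ParseError(
                    f"bad coordinates {start_s}..{end_s}", lineno
                )
            if strand not in ("+", "-", "."):
                raise Gff3ParseError(f"bad strand {strand!r}", lineno)
            # 1-based inclusive -> 0-based half-open
            iv = Interval(chrom, start1 - 1, end1, strand)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise Gff3ParseError("gene feature without ID", lineno)
                genes[gid] = {"locus": iv, "line": lineno}
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if mid is None or parent is None:
                    raise Gff3ParseError("mRNA needs ID and Parent", lineno)
                mrna_parent[mid] = parent
                mrna_exons.setdefault(mid, [])
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise Gff3ParseError("exon needs Parent", lineno)
                mrna_exons.setdefault(parent, []).append(iv)

    annotation = GenomeAnnotation(species=sp, chromosome_lengths=chrom_lengths)
    for gid, rec in genes.items():
        transcripts = [m for m, p in mrna_parent.items() if p == gid]
        best_exons: list[Interval] = []
        if transcripts:
            def tkey(mid: str):
                exons = mrna_exons.get(mid, [])
                return (sum(e.length for e in exons), len(exons), mid)

            best = max(transcripts, key=tkey)
            best_exons = mrna_exons.get(best, [])
        for exon in best_exons:
            if not rec["locus"].contains(exon):
                raise AnnotationValidationError(
                    f"exon {exon} outside gene {gid} (gene at line {rec['line']})"
                )
        annotation.add(
            GeneModel(gene_id=gid, species=sp, locus=rec["locus"], exons=best_exons)
        )
    return annotation


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    """Write genes back out as gene/mRNA/exon GFF3, 1-based inclusive."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for chrom in sorted(annotation.chromosome_lengths):
            out.write(
                f"##sequence-region {chrom} 1 {annotation.chromosome_lengths[chrom]}\n"
            )
        for chrom in annotation.chromosomes():
            for gene in annotation.genes_on(chrom):
                loc = gene.locus
                row = [
                    chrom, "lectinfam", "gene", str(loc.start + 1), str(loc.end),
                    ".", loc.strand if loc.strand != "." else ".", ".",
                    f"ID={gene.gene_id}",
                ]
                out.write("\t".join(row) + "\n")
                mid = f"{gene.gene_id}.1"
                row[2], row[8] = "mRNA", f"ID={mid};Parent={gene.gene_id}"
                out.write("\t".join(row) + "\n")
                for exon in gene.exons:
                    erow = [
                        chrom, "lectinfam", "exon", str(exon.start + 1), str(exon.end),
                        ".", loc.strand, ".", f"Parent={mid}",
                    ]
                    out.write("\t".join(erow) + "\n")


# ---------------------------------------------------------------------------
# FASTA / BED / TSV plumbing


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as out:
        writer = SeqIO.FastaIO.FastaWriter(out, wrap=60)
        writer.write_file(records)


@dataclass(frozen=True)
class BedRecord:
    interval: Interval
    name: str
    score: float = 0.0


def read_bed(path) -> list[BedRecord]:
    """BED6 (or BED4/3); BED is already 0-based half-open."""
    records = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"line {lineno}: BED needs >=3 columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else f"feature{lineno}"
            score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
            strand = cols[5] if len(cols) > 5 else "."
            records.append(BedRecord(Interval(chrom, start, end, strand), name, score))
    return records


def write_bed(records: Iterable[BedRecord], path) -> None:
    with open(path, "w") as out:
        for rec in records:
            iv = rec.interval
            out.write(
                f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{rec.name}\t"
                f"{rec.score:g}\t{iv.strand}\n"
            )


def read_tsv_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)
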