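"""Classify each gene's positional relationship to transposable elements.

Four transposon superfamilies matter here (MULE, CACTA, hAT, Helitron,
plus a catch-all 'other'); their annotations arrive as BED6 with the
superfamily encoded in the name field as ``element_id|superfamily``.  Each
gene is scanned against all elements within its 50-kb flank windows and
assigned the most specific relationship found:

    gene_within_te > te_within_intron > te_within_exon_region
    > te_in_flank > none
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .genome_io import BedRecord, GeneModel, Interval

TE_SUPERFAMILIES = ("MULE", "CACTA", "hAT", "Helitron", "other")

TE_CLASSES = (
    "gene_within_te",
    "te_within_intron",
    "te_within_exon_region",
    "te_in_flank",
    "none",
)


@dataclass(frozen=True)
class TEAnnotation:
    element_id: str
    superfamily: str
    interval: Interval

    def __post_init__(self):
        if self.superfamily not in TE_SUPERFAMILIES:
            raise ValueError(f"unknown TE superfamily {self.superfamily!r}")


@dataclass(frozen=True)
class TEOverlapClass:
    gene_id: str
    te_class: str
    element_id: str = ""


def te_annotations_from_bed(records: Iterable[BedRecord]) -> list[TEAnnotation]:
    """BED name field 'element_id|superfamily' -> TEAnnotation."""
    out = []
    for rec in records:
        if "|" in rec.name:
            element_id, superfamily = rec.name.rsplit("|", 1)
        else:
            element_id, superfamily = rec.name, "other"
        if superfamily not in TE_SUPERFAMILIES:
            superfamily = "other"
        out.append(TEAnnotation(element_id, superfamily, rec.interval))
    return out


def _relationship(gene: GeneModel, te: TEAnnotation, flank_bp: int) -> str:
    if te.interval.chromosome != gene.locus.chromosome:
        return "none"
    if te.interval.contains(gene.locus):
        return "gene_within_te"
    for intron in gene.introns():
        if intron.contains(te.interval):
            return "te_within_intron"
    if any(te.interval.overlaps(exon) for exon in gene.exons):
        return "te_within_exon_region"
    window = Interval(
        gene.locus.chromosome,
        max(gene.locus.start - flank_bp, 0),
        gene.locus.end + flank_bp,
    )
    if window.overlaps(te.interval):
        return "te_in_flank"
    return "none"


def classify_te_overlap(
    gene: GeneModel, te_annotations: Iterable[TEAnnotation], flank_bp: int = 50_000
) -> TEOverlapClass:
    """Most specific (gene, element) relationship over all elements.

    Among elements tying on class, the one whose interval starts first is
    reported, so the call is independent of annotation order.
    """
    best_rank = len(TE_CLASSES) - 1  # index of "none"
    best: TEAnnotation | None = None
    for te in te_annotations:
        rel = _relationship(gene, te, flank_bp)
        rank = TE_CLASSES.index(rel)
        if rank < best_rank or (
            rank == best_rank
            and best is not None
            and rank < len(TE_CLASSES) - 1
            and (te.interval.start, te.element_id)
            < (best.interval.start, best.element_id)
        ):
            best_rank, best = rank, te
    if best is None or best_rank == len(TE_CLASSES) - 1:
        return TEOverlapClass(gene.gene_id, "none")
    return TEOverlapClass(gene.gene_id, TE_CLASSES[best_rank], best.element_id)


def te_overlap_table(
    genes: Iterable[GeneModel],
    te_annotations: Iterable[TEAnnotation],
    flank_bp: int = 50_000,
) -> pd.DataFrame:
    tes = list(te_annotations)
    rows = []
    for gene in genes:
        call = classify_te_overlap(gene, tes, flank_bp)
        rows.append(
            {"gene_id": call.gene_id, "te_class": call.te_class,
             "element_id": call.element_id}
        )
    return pd.DataFrame(rows, columns=["gene_id", "te_class", "element_id"])
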