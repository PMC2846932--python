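"""Assign genes to the 12 plant lectin families from profile-domain hits.

Each lectin family is defined by a single carbohydrate-binding domain model
(B_lectin, Lectin_legB, Jacalin, ...).  Genes carrying additional unrelated
domains (kinase, F-box, glycoside hydrolases, ...) are chimerolectins; the
extra domains are recorded but do not affect the family call.  Members whose
best hit covers too little of the domain model are flagged ``partial``
(pseudogene-like) and are excluded from the evolutionary analyses by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

FAMILY_NAMES = (
    "B_lectin",
    "Lectin_legB",
    "Jacalin",
    "Phloem",
    "Lectin_C",
    "Chitin_bind_1",
    "Ricin_B_Lectin",
    "Gal_lectin",
    "Gal_binding_Lectin",
    "Calreticulin",
    "EEA",
    "LysM",
)

# Default domain-model -> family map.  Phloem and EEA have no standard
# profile accession, so custom profile names stand in for them; EUL is the
# Euonymus-lectin domain that defines the EEA family.  Model lengths are in
# amino acids and set the denominator of the coverage fraction.
_DEFAULT_CATALOG_ROWS = [
    ("B_lectin", "B_lectin", 109),
    ("Lectin_legB", "Lectin_legB", 230),
    ("Jacalin", "Jacalin", 140),
    ("PHLOEM_CUSTOM", "Phloem", 180),
    ("Lectin_C", "Lectin_C", 110),
    ("Chitin_bind_1", "Chitin_bind_1", 40),
    ("Ricin_B_lectin", "Ricin_B_Lectin", 130),
    ("Gal_lectin", "Gal_lectin", 180),
    ("Gal-bind_lectin", "Gal_binding_Lectin", 135),
    ("Calreticulin", "Calreticulin", 390),
    ("EUL_CUSTOM", "EEA", 150),
    ("LysM", "LysM", 44),
]


class DomainTableError(ValueError):
    pass


@dataclass(frozen=True)
class FamilyCatalog:
    """Mapping from domain model names to the 12 lectin families."""

    domain_to_family: Mapping[str, str]
    model_lengths: Mapping[str, int]

    def __post_init__(self):
        for domain, family in self.domain_to_family.items():
            if family not in FAMILY_NAMES:
                raise ValueError(f"unknown family {family!r} for domain {domain!r}")
            if domain not in self.model_lengths:
                raise ValueError(f"no model length for domain {domain!r}")

    @classmethod
    def default(cls) -> "FamilyCatalog":
        return cls(
            domain_to_family={d: f for d, f, _ in _DEFAULT_CATALOG_ROWS},
            model_lengths={d: n for d, _, n in _DEFAULT_CATALOG_ROWS},
        )

    @classmethod
    def from_tsv(cls, path) -> "FamilyCatalog":
        frame = pd.read_csv(path, sep="\t")
        return cls(
            domain_to_family=dict(zip(frame["domain"], frame["family"])),
            model_lengths=dict(zip(frame["domain"], frame["model_len"])),
        )

    def to_tsv(self, path) -> None:
        rows = [
            {"domain": d, "family": f, "model_len": self.model_lengths[d]}
            for d, f in self.domain_to_family.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def is_lectin_domain(self, domain: str) -> bool:
        return domain in self.domain_to_family


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    domain: str
    evalue: float
    ali_from: int
    ali_to: int
    hmm_from: int
    hmm_to: int
    model_len: int

    @property
    def model_coverage(self) -> float:
        """Fraction of the domain model spanned by this hit."""
        return (self.hmm_to - self.hmm_from + 1) / self.model_len


@dataclass
class FamilyAssignment:
    gene_id: str
    family: str
    best_evalue: float
    completeness: str = "complete"  # or "partial"
    other_domains: list[str] = field(default_factory=list)

    @property
    def is_partial(self) -> bool:
        return self.completeness == "partial"


class AmbiguousFamilyWarning(UserWarning):
    """A gene hit two distinct lectin families; the best e-value wins."""


def read_domain_table(path, evalue_cutoff: float = 1.0) -> list[DomainHit]:
    """Read a per-domain hit table and drop hits above the e-value cutoff.

    Columns mirror the per-domain fields of hmmscan tabular output:
    gene_id, domain, evalue, ali_from, ali_to, hmm_from, hmm_to, model_len
    (1-based inclusive protein/model coordinates).
    """
    frame = pd.read_csv(path, sep="\t")
    required = [
        "gene_id", "domain", "evalue", "ali_from", "ali_to",
        "hmm_from", "hmm_to", "model_len",
    ]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DomainTableError(f"missing columns: {missing}")
    hits = []
    for row in frame.itertuples(index=False):
        if row.evalue < 0:
            raise DomainTableError(f"negative e-value for {row.gene_id}")
        if min(row.ali_from, row.ali_to, row.hmm_from, row.hmm_to) < 1:
            raise DomainTableError(f"non-positive coordinate for {row.gene_id}")
        if row.evalue > evalue_cutoff:
            continue
        hits.append(
            DomainHit(
                gene_id=str(row.gene_id),
                domain=str(row.domain),
                evalue=float(row.evalue),
                ali_from=int(row.ali_from),
                ali_to=int(row.ali_to),
                hmm_from=int(row.hmm_from),
                hmm_to=int(row.hmm_to),
                model_len=int(row.model_len),
            )
        )
    return hits


def assign_families(
    hits: Iterable[DomainHit], catalog: FamilyCatalog | None = None
) -> list[FamilyAssignment]:
    """One family per gene: the family of its best-e-value lectin domain.

    Multiple hits of the same lectin domain in one gene (hololectins)
    collapse into a single assignment; non-lectin domains are recorded as
    ``other_domains``.  A gene hitting two distinct lectin families gets the
    better e-value and an :class:`AmbiguousFamilyWarning`.
    """
    catalog = catalog or FamilyCatalog.default()
    by_gene: dict[str, list[DomainHit]] = {}
    for hit in hits:
        by_gene.setdefault(hit.gene_id, []).append(hit)

    assignments = []
    for gene_id in sorted(by_gene):
        gene_hits = by_gene[gene_id]
        lectin = [h for h in gene_hits if catalog.is_lectin_domain(h.domain)]
        if not lectin:
            continue
        best = min(lectin, key=lambda h: (h.evalue, h.domain))
        families_hit = {catalog.domain_to_family[h.domain] for h in lectin}
        if len(families_hit) > 1:
            warnings.warn(
                f"gene {gene_id} hits {len(families_hit)} lectin families "
                f"({sorted(families_hit)}); assigning best e-value "
                f"({catalog.domain_to_family[best.domain]})",
                AmbiguousFamilyWarning,
                stacklevel=2,
            )
        other = sorted(
            {h.domain for h in gene_hits if not catalog.is_lectin_domain(h.domain)}
        )
        assignments.append(
            FamilyAssignment(
                gene_id=gene_id,
                family=catalog.domain_to_family[best.domain],
                best_evalue=best.evalue,
                other_domains=other,
            )
        )
    return assignments


def flag_partial(
    assignment: FamilyAssignment,
    hits: Iterable[DomainHit],
    catalog: FamilyCatalog | None = None,
    min_model_coverage: float = 0.7,
) -> FamilyAssignment:
    """Mark an assignment ``partial`` if its best hit covers < 70% of the model.

    The coverage threshold operationalizes manual curation of members with
    incomplete domain structure; the bound is inclusive (coverage exactly at
    the threshold counts as complete).
    """
    catalog = catalog or FamilyCatalog.default()
    gene_hits = [
        h
        for h in hits
        if h.gene_id == assignment.gene_id
        and catalog.is_lectin_domain(h.domain)
        and catalog.domain_to_family[h.domain] == assignment.family
    ]
    if not gene_hits:
        raise ValueError(f"no hits for assignment {assignment.gene_id}")
    best = min(gene_hits, key=lambda h: (h.evalue, h.domain))
    assignment.completeness = (
        "complete" if best.model_coverage >= min_model_coverage else "partial"
    )
    return assignment


def classify_genes(
    hits: Iterable[DomainHit],
    catalog: FamilyCatalog | None = None,
    min_model_coverage: float = 0.7,
) -> list[FamilyAssignment]:
    """assign_families followed by flag_partial for every gene."""
    catalog = catalog or FamilyCatalog.default()
    hits = list(hits)
    assignments = assign_families(hits, catalog)
    for assignment in assignments:
        flag_partial(assignment, hits, catalog, min_model_coverage)
    return assignments


def summarize_families(
    assignments: Iterable[FamilyAssignment],
    species_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-species, per-family counts split by completeness.

    Returns a tidy frame (species, family, complete, partial, total) with
    one row per family per species; families with no members get zero rows.
    """
    rows = []
    assignments = list(assignments)
    species_map = species_of or {}
    species_seen = sorted(
        {species_map.get(a.gene_id, "all") for a in assignments}
    ) or ["all"]
    for sp in species_seen:
        for family in FAMILY_NAMES:
            members = [
                a
                for a in assignments
                if a.family == family and species_map.get(a.gene_id, "all") == sp
            ]
            n_partial = sum(a.is_partial for a in members)
            rows.append(
                {
                    "species": sp,
                    "family": family,
                    "complete": len(members) - n_partial,
                    "partial": n_partial,
                    "total": len(members),
                }
            )
    return pd.DataFrame(rows)
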