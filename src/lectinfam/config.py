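"""Analysis configuration: every threshold of the pipeline in one place.

Per-species profiles carry the genome-dependent tandem distance cap
(100 kb for compact genomes, 350 kb for soybean/rice) and the gene-id
prefix rules used to resolve species on gene-tree leaves.  The config file
is a flat YAML mapping; every key below can be overridden there or by CLI
flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class SpeciesProfile:
    name: str
    tandem_max_bp: int
    prefix: str


DEFAULT_PROFILES = {
    "soybean": SpeciesProfile("soybean", 350_000, "Glyma"),
    "rice": SpeciesProfile("rice", 350_000, "LOC_Os"),
    "arabidopsis": SpeciesProfile("arabidopsis", 100_000, "AT"),
}


@dataclass
class AnalysisConfig:
    species: tuple[str, ...] = ("soybean", "rice", "arabidopsis")
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    # tandem clustering
    max_gene_gap: int = 10
    # flank windows (segmental anchor inference, TE scan, retro hallmarks)
    flank_bp: int = 50_000
    min_extra_anchors: int = 2
    # family classification
    domain_evalue_cutoff: float = 1.0
    partial_min_coverage: float = 0.7
    # retrogene homology filter
    retro_min_coverage: float = 0.70
    retro_max_evalue: float = 1e-8
    # hallmark scans
    tsd_min_len: int = 4
    tsd_max_len: int = 20
    tsd_search_bp: int = 100
    polya_window: int = 200
    polya_min_run: int = 8
    polya_min_purity: float = 0.8
    # expression
    min_fold: float = 2.0
    alpha: float = 0.05
    pseudocount: float = 1.0
    # ancestry
    divergence_my: float = 150.0  # monocot/dicot split, 140-150 MYA
    seed: int = 0

    def __post_init__(self):
        for key in (
            "max_gene_gap", "flank_bp", "min_extra_anchors",
            "domain_evalue_cutoff", "partial_min_coverage",
            "retro_min_coverage", "tsd_min_len", "tsd_max_len",
            "tsd_search_bp", "polya_window", "polya_min_run",
            "polya_min_purity", "min_fold", "alpha", "pseudocount",
            "divergence_my",
        ):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be positive")
        if not (140.0 <= self.divergence_my <= 150.0):
            raise ValueError("divergence_my must lie in [140, 150]")
        for sp in self.species:
            if sp not in self.profiles:
                raise ValueError(f"no profile for species {sp!r}")

    def tandem_max_bp(self, species: str) -> int:
        return self.profiles[species].tandem_max_bp

    def species_prefixes(self) -> dict[str, str]:
        return {p.prefix: p.name for p in self.profiles.values()}

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        profiles = dict(DEFAULT_PROFILES)
        for name, spec in (data.pop("profiles", None) or {}).items():
            profiles[name] = SpeciesProfile(
                name=name,
                tandem_max_bp=int(spec["tandem_max_bp"]),
                prefix=str(spec["prefix"]),
            )
        species = tuple(data.pop("species", ("soybean", "rice", "arabidopsis")))
        return cls(species=species, profiles=profiles, **data)

    def to_file(self, path) -> None:
        data = asdict(self)
        data["profiles"] = {
            name: {"tandem_max_bp": p.tandem_max_bp, "prefix": p.prefix}
            for name, p in self.profiles.items()
        }
        data["species"] = list(self.species)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
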