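"""Synthetic genomes, gene trees, homology tables and expression matrices.

The generator emulates the statistical structure the analysis assumes —
pure-birth gene-family growth along a three-species tree, tandem /
segmental / retro / dispersed duplicate placement on chromosomes, planted
retroposition hallmarks, fabricated protein-homology tables, transposon
annotations, and replicated stress/tissue expression — together with a
ground-truth manifest, so every pipeline stage can be tested against known
answers without any genome download.

Gene births follow a Poisson process per ancestral gene at rate ``r`` per
100 MY, so the expected extant count is ``N_anc * (1 + r*T/100)`` and the
surviving-copy birth-rate estimator recovers ``r`` exactly in expectation.
No gene loss is simulated by default, which makes the true number of
root-era lineages equal to the ancestral family size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    BedRecord,
    GeneModel,
    GenomeAnnotation,
    Interval,
    write_bed,
    write_fasta,
    write_gff3,
)
from .duplication import SegmentalBlockPair, write_block_table
from .family_classifier import FamilyCatalog
from .te_overlap import TEAnnotation

MECHANISMS = ("ancestral", "tandem", "segmental", "retro", "dispersed")

SPECIES_PREFIX = {"soybean": "Glyma", "rice": "LOC_Os", "arabidopsis": "AT"}

FAMILY_CODE = {
    "B_lectin": "BL",
    "Lectin_legB": "LB",
    "Jacalin": "JA",
    "Phloem": "PH",
    "Lectin_C": "LC",
    "Chitin_bind_1": "CB",
    "Ricin_B_Lectin": "RB",
    "Gal_lectin": "GL",
    "Gal_binding_Lectin": "GB",
    "Calreticulin": "CR",
    "EEA": "EE",
    "LysM": "LY",
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; every random draw flows from ``seed``."""

    seed: int = 0
    species: tuple[str, ...] = ("soybean", "rice", "arabidopsis")
    divergence_my: float = 150.0
    # genes per 100 MY per ancestral gene, per lineage (the B-lectin rates)
    birth_rates: dict = field(
        default_factory=lambda: {"soybean": 13.3, "rice": 10.9, "arabidopsis": 4.4}
    )
    # ancestral (root-era) gene count per simulated family
    ancestral_sizes: dict = field(
        default_factory=lambda: {"B_lectin": 5, "Jacalin": 4, "LysM": 2}
    )
    # duplication-mechanism mix; remainder of 1 is dispersed
    p_tandem: float = 0.45
    p_segmental: float = 0.30
    p_retro: float = 0.05
    # genome shape: lectins are a sparse minority of all genes, as in real
    # plant genomes, so chance same-family adjacency stays rare
    n_chromosomes: int = 8
    fillers_per_chromosome: int = 150
    chromosome_margin_bp: int = 60_000
    tandem_max_gap_genes: int = 2  # fillers allowed between tandem copies
    family_separation_genes: int = 18  # exclusion radius for non-tandem placement
    segmental_window_genes: int = 2  # fillers copied on each side of the donor
    # retro hallmark geometry
    tsd_length_range: tuple[int, int] = (4, 15)
    polya_length_range: tuple[int, int] = (8, 30)
    tsd_erosion: float = 0.0  # per-base mutation probability of planted TSDs
    polya_erosion: float = 0.0
    n_decoy_single_exon: int = 0  # extra intronless lectins with no retro origin
    partial_fraction: float = 0.0  # lectins emitted with partial domain hits
    # TE planting: class -> number of target genes per species
    te_class_counts: dict = field(
        default_factory=lambda: {
            "gene_within_te": 1,
            "te_within_intron": 1,
            "te_within_exon_region": 1,
            "te_in_flank": 2,
        }
    )
    n_te_far: int = 2  # elements planted beyond every 50-kb window
    # expression
    contrasts: tuple = (
        ("Mg", "biotic"),
        ("Xoo", "biotic"),
        ("cold", "abiotic"),
        ("drought", "abiotic"),
        ("salt", "abiotic"),
    )
    n_replicates: int = 3
    de_fraction: float = 0.3
    fold_set: tuple[float, ...] = (2.0, 4.0, 8.0)
    noise_cv: float = 0.2
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    n_tissues: int = 6
    tissue_specific_fraction: float = 0.15

    def mechanism_probs(self) -> tuple[float, float, float, float]:
        p_disp = 1.0 - self.p_tandem - self.p_segmental - self.p_retro
        if p_disp < -1e-9:
            raise ValueError("mechanism probabilities exceed 1")
        return (self.p_tandem, self.p_segmental, self.p_retro, max(p_disp, 0.0))


@dataclass
class SimGene:
    gene_id: str
    species: str
    family: str
    mechanism: str
    parent: str  # empty for ancestral genes
    ancestral_unit: int
    exon_count: int = 2


@dataclass
class FamilySim:
    family: str
    n_ancestral: int
    genes: list[SimGene]
    newick: str

    def genes_of(self, species: str) -> list[SimGene]:
        return [g for g in self.genes if g.species == species]


# ---------------------------------------------------------------------------
# family evolution


def _newick_of(node) -> str:
    if isinstance(node, str):
        return node
    return "(" + ",".join(_newick_of(c) for c in node) + ")"


def simulate_family_evolution(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, FamilySim]:
    """Pure-birth growth of each family along the three lineages.

    Each of the ``N_anc`` ancestral genes speciates into one base copy per
    lineage; along each lineage new copies arise as a Poisson count with
    mean ``r * T / 100`` per ancestral gene, each tagged with a mechanism
    drawn from the configured mix and attached to a uniformly chosen
    existing copy (its simulation parent).  The emitted Newick tree has the
    true topology, so ancestral-unit counting has an exact truth.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    probs = config.mechanism_probs()
    out: dict[str, FamilySim] = {}
    for family in sorted(config.ancestral_sizes):
        n_anc = int(config.ancestral_sizes[family])
        code = FAMILY_CODE.get(family, family[:2].upper())
        genes: list[SimGene] = []
        unit_trees = []
        for unit in range(n_anc):
            lineage_clades = []
            for species in config.species:
                prefix = SPECIES_PREFIX[species]
                base_id = f"{prefix}{code}{unit:02d}g000"
                base = SimGene(
                    gene_id=base_id,
                    species=species,
                    family=family,
                    mechanism="ancestral",
                    parent="",
                    ancestral_unit=unit,
                )
                lineage_genes = [base]
                rate = float(config.birth_rates[species])
                n_new = int(rng.poisson(rate * config.divergence_my / 100.0))
                # nested lists so new cherries can be spliced in at a leaf
                clade: list = [base_id]
                leaves = [base_id]
                non_retro_leaves = [base_id]
                for k in range(1, n_new + 1):
                    mech = ("tandem", "segmental", "retro", "dispersed")[
                        int(rng.choice(4, p=probs))
                    ]
                    # a retrogene needs a spliced (multi-exon) template, so
                    # its parent is drawn from the non-retro copies
                    pool = non_retro_leaves if mech == "retro" else leaves
                    attach = pool[int(rng.integers(len(pool)))]
                    new_id = f"{prefix}{code}{unit:02d}g{k:03d}"
                    lineage_genes.append(
                        SimGene(
                            gene_id=new_id,
                            species=species,
                            family=family,
                            mechanism=mech,
                            parent=attach,
                            ancestral_unit=unit,
                        )
                    )
                    _splice(clade, attach, new_id)
                    leaves.append(new_id)
                    if mech != "retro":
                        non_retro_leaves.append(new_id)
                genes.extend(lineage_genes)
                lineage_clades.append(_unwrap(clade))
            # species-tree-shaped join: ((soybean, arabidopsis), rice)
            by_species = dict(zip(config.species, lineage_clades))
            unit_trees.append(
                (
                    (by_species["soybean"], by_species["arabidopsis"]),
                    by_species["rice"],
                )
                if set(config.species) == {"soybean", "rice", "arabidopsis"}
                else tuple(lineage_clades)
            )
        # pre-divergence duplications join the ancestral units at the root
        tree = unit_trees[0]
        for extra in unit_trees[1:]:
            tree = (tree, extra)
        out[family] = FamilySim(
            family=family,
            n_ancestral=n_anc,
            genes=genes,
            newick=_newick_of(tree) + ";",
        )
    return out


def _splice(clade: list, target: str, new_leaf: str) -> bool:
    """Replace leaf ``target`` with the cherry (target, new_leaf) in place."""
    for i, item in enumerate(clade):
        if item == target:
            clade[i] = [target, new_leaf]
            return True
        if isinstance(item, list) and _splice(item, target, new_leaf):
            return True
    return False


def _unwrap(node):
    """Nested lists -> nested tuples; single-child lists collapse."""
    if isinstance(node, list):
        if len(node) == 1:
            return _unwrap(node[0])
        return tuple(_unwrap(c) for c in node)
    return node


# ---------------------------------------------------------------------------
# genome placement


@dataclass
class RetroPlant:
    gene_id: str
    tsd_seq: str
    polya_len: int
    tsd_intact: bool
    polya_intact: bool


@dataclass
class PlacedGenome:
    species: str
    annotation: GenomeAnnotation
    sequences: dict[str, str]
    blocks: list[SegmentalBlockPair]
    anchor_pairs: list[tuple[str, str]]  # homologous filler pairs inside blocks
    retro_plants: list[RetroPlant]
    decoy_genes: list[str] = field(default_factory=list)


def _make_exons(chrom: str, start: int, end: int, k: int, strand: str,
                rng: np.random.Generator) -> list[Interval]:
    """Split [start, end) into k exons with introns of >=400 bp."""
    length = end - start
    if k <= 1 or length < k * 150 + (k - 1) * 400:
        return [Interval(chrom, start, end, strand)]
    intron = 400
    exon_total = length - (k - 1) * intron
    cuts = sorted(rng.choice(np.arange(1, exon_total), size=k - 1, replace=False))
    sizes = np.diff([0, *cuts, exon_total])
    exons = []
    pos = start
    for size in sizes:
        exons.append(Interval(chrom, pos, pos + int(size), strand))
        pos += int(size) + intron
    return exons


def place_genes_on_genome(
    families: Mapping[str, FamilySim],
    species: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PlacedGenome:
    """Realise one species' simulated genes as an annotated genome.

    Tandem copies are inserted within at most ``tandem_max_gap_genes``
    filler genes of their parent; segmental copies carry a window of
    neighbouring fillers to a new chromosome (recording the true block and
    its filler anchor pairs); retro and dispersed copies land uniformly.
    Random nucleotide sequence is emitted for every chromosome and retro
    hallmarks are stamped around each retro insertion.
    """
    prefix = SPECIES_PREFIX[species]
    chroms = [f"{prefix}_chr{i + 1}" for i in range(config.n_chromosomes)]
    # token: dict(id, family or None, exons, kind, strand)
    layout: dict[str, list[dict]] = {c: [] for c in chroms}
    filler_counter = 0

    def new_filler() -> dict:
        nonlocal filler_counter
        filler_counter += 1
        return {
            "id": f"{prefix}FILLER_g{filler_counter:04d}",
            "family": None,
            "exons": int(rng.integers(1, 4)),
            "kind": "filler",
            "strand": "+" if rng.random() < 0.5 else "-",
        }

    sim_genes_all = [g for fam in families.values() for g in fam.genes_of(species)]
    # the genome must be sparse enough that same-family exclusion zones fit;
    # scale filler density to the largest family's non-tandem gene count
    sep = config.family_separation_genes
    by_family: dict[str, int] = {}
    for g in sim_genes_all:
        if g.mechanism != "tandem":
            by_family[g.family] = by_family.get(g.family, 0) + 1
    max_nontandem = max(by_family.values(), default=0)
    needed = 2 * max_nontandem * (2 * sep + 1)
    fillers = max(config.fillers_per_chromosome, -(-needed // config.n_chromosomes))

    for chrom in chroms:
        layout[chrom] = [new_filler() for _ in range(fillers)]

    def locate(gene_id: str) -> tuple[str, int]:
        for chrom in chroms:
            for idx, token in enumerate(layout[chrom]):
                if token["id"] == gene_id:
                    return chrom, idx
        raise KeyError(gene_id)

    sim_genes = sim_genes_all
    retro_ids = {g.gene_id for g in sim_genes if g.mechanism == "retro"}

    def lectin_token(g: SimGene) -> dict:
        n_exons = 1 if g.mechanism == "retro" else int(rng.integers(2, 4))
        g.exon_count = n_exons
        return {
            "id": g.gene_id,
            "family": g.family,
            "exons": n_exons,
            "kind": "lectin",
            "strand": "+" if g.mechanism == "retro" or rng.random() < 0.5 else "-",
        }

    def insert_avoiding_family(token: dict, window: int | None = None) -> None:
        """Place a token at a uniform slot away from same-family genes.

        Dispersed, retro and ancestral copies must not land within tandem
        range of a same-family gene, or the mechanism ground truth would be
        ill-defined (a dispersed copy next to a relative is operationally a
        tandem copy).  Rejection-samples up to 100 slots before giving up.
        """
        window = window or sep
        fam = token["family"]
        for _ in range(100):
            chrom = chroms[int(rng.integers(len(chroms)))]
            idx = int(rng.integers(len(layout[chrom]) + 1))
            nearby = layout[chrom][max(idx - window, 0) : idx + window]
            if fam is None or all(t["family"] != fam for t in nearby):
                layout[chrom].insert(idx, token)
                return
        layout[chrom].insert(idx, token)

    # single pass in birth order so every parent is placed before its child
    block_plans = []
    for g in sim_genes:
        token = lectin_token(g)
        if g.mechanism == "tandem":
            chrom, pidx = locate(g.parent)
            gap = int(rng.integers(0, config.tandem_max_gap_genes + 1))
            insert_at = min(pidx + 1 + gap, len(layout[chrom]))
            layout[chrom].insert(insert_at, token)
        elif g.mechanism == "segmental":
            # carry a window of neighbouring fillers to a new chromosome
            chrom, pidx = locate(g.parent)
            w = config.segmental_window_genes
            lo, hi = max(pidx - w, 0), min(pidx + w + 1, len(layout[chrom]))
            source = layout[chrom][lo:hi]
            copies, anchor_pairs = [], []
            for src in source:
                if src["id"] == g.parent:
                    copies.append(token)
                elif src["kind"] == "filler":
                    filler_counter += 1
                    copy = dict(src, id=f"{src['id']}c{filler_counter:04d}")
                    copies.append(copy)
                    anchor_pairs.append((src["id"], copy["id"]))
                # other lectins in the window stay put; they are not anchors
            dest_choices = [c for c in chroms if c != chrom] or [chrom]
            dest = dest_choices[int(rng.integers(len(dest_choices)))]
            # keep the copied window clear of same-family genes too
            dest_idx = None
            sep = config.family_separation_genes
            for _ in range(100):
                cand = int(rng.integers(len(layout[dest]) + 1))
                nearby = layout[dest][max(cand - sep, 0) : cand + sep]
                if all(t["family"] != g.family for t in nearby):
                    dest_idx = cand
                    break
            if dest_idx is None:
                dest_idx = int(rng.integers(len(layout[dest]) + 1))
            layout[dest][dest_idx:dest_idx] = copies
            block_plans.append(
                {
                    "source_ids": [t["id"] for t in source],
                    "dest_ids": [t["id"] for t in copies],
                    "anchors": anchor_pairs,
                    "lectin_pair": (g.parent, g.gene_id),
                }
            )
        else:  # ancestral, retro, dispersed: uniform away from relatives
            insert_avoiding_family(token)

    # decoy intronless lectins: single exon, no retro origin, no parent
    decoys = []
    for d in range(config.n_decoy_single_exon):
        fam = sorted(config.ancestral_sizes)[d % len(config.ancestral_sizes)]
        token = {
            "id": f"{prefix}DECOY_g{d:04d}",
            "family": fam,
            "exons": 1,
            "kind": "decoy",
            "strand": "+",
        }
        insert_avoiding_family(token)
        decoys.append(token["id"])

    # coordinates
    annotation = GenomeAnnotation(species=species)
    margin = config.chromosome_margin_bp
    placed_iv: dict[str, Interval] = {}
    for chrom in chroms:
        cursor = margin
        for token in layout[chrom]:
            length = (
                int(rng.integers(1800, 2601))
                if token["kind"] != "filler"
                else int(rng.integers(900, 2401))
            )
            n_ex = token["exons"]
            if n_ex > 1:
                length = max(length, n_ex * 200 + (n_ex - 1) * 400 + 100)
            locus = Interval(chrom, cursor, cursor + length, token["strand"])
            exons = _make_exons(chrom, cursor, cursor + length, n_ex, token["strand"], rng)
            annotation.add(
                GeneModel(
                    gene_id=token["id"], species=species, locus=locus, exons=exons
                )
            )
            placed_iv[token["id"]] = locus
            cursor += length + int(rng.integers(1500, 4001))
        annotation.chromosome_lengths[chrom] = cursor + margin

    # true blocks, now that coordinates exist
    blocks, all_anchor_pairs = [], []
    for bi, plan in enumerate(block_plans):
        src_ivs = [placed_iv[i] for i in plan["source_ids"] if i in placed_iv]
        dst_ivs = [placed_iv[i] for i in plan["dest_ids"] if i in placed_iv]
        if not src_ivs or not dst_ivs:
            continue
        iv_a = Interval(
            src_ivs[0].chromosome,
            min(i.start for i in src_ivs),
            max(i.end for i in src_ivs),
        )
        iv_b = Interval(
            dst_ivs[0].chromosome,
            min(i.start for i in dst_ivs),
            max(i.end for i in dst_ivs),
        )
        blocks.append(
            SegmentalBlockPair(
                block_id=f"{prefix}_BLK{bi:03d}",
                interval_a=iv_a,
                interval_b=iv_b,
                anchors=[plan["lectin_pair"]] + plan["anchors"],
                provenance="given",
            )
        )
        all_anchor_pairs.extend(plan["anchors"])

    # sequence + retro hallmarks
    sequences = {}
    base_bytes = np.frombuffer(b"ACGT", dtype="u1")
    for chrom in chroms:
        n = annotation.chromosome_lengths[chrom]
        draws = rng.integers(0, 4, size=n, dtype=np.uint8)
        sequences[chrom] = base_bytes[draws].tobytes().decode("ascii")
    retro_plants = []
    for g in sorted(retro_ids):
        locus = placed_iv[g]
        seq = list(sequences[locus.chromosome])
        tsd_len = int(rng.integers(*config.tsd_length_range))
        tsd = "".join("ACGT"[i] for i in rng.integers(0, 4, size=tsd_len))
        polya_len = int(rng.integers(*config.polya_length_range))
        spacer = int(rng.integers(0, 6))
        seq[locus.start - tsd_len : locus.start] = list(tsd)
        seq[locus.end : locus.end + polya_len] = list("A" * polya_len)
        right_at = locus.end + polya_len + spacer
        seq[right_at : right_at + tsd_len] = list(tsd)
        tsd_intact = polya_intact = True
        if config.tsd_erosion > 0:
            for pos in list(range(locus.start - tsd_len, locus.start)) + list(
                range(right_at, right_at + tsd_len)
            ):
                if rng.random() < config.tsd_erosion:
                    seq[pos] = str(rng.choice([b for b in "ACGT" if b != seq[pos]]))
                    tsd_intact = False
        if config.polya_erosion > 0:
            for pos in range(locus.end, locus.end + polya_len):
                if rng.random() < config.polya_erosion:
                    seq[pos] = str(rng.choice(["C", "G", "T"]))
                    polya_intact = False
        sequences[locus.chromosome] = "".join(seq)
        retro_plants.append(
            RetroPlant(
                gene_id=g,
                tsd_seq=tsd,
                polya_len=polya_len,
                tsd_intact=tsd_intact,
                polya_intact=polya_intact,
            )
        )

    return PlacedGenome(
        species=species,
        annotation=annotation,
        sequences=sequences,
        blocks=blocks,
        anchor_pairs=all_anchor_pairs,
        retro_plants=retro_plants,
        decoy_genes=decoys,
    )


# ---------------------------------------------------------------------------
# homology + domain tables


def synthesize_homology_table(
    families: Mapping[str, FamilySim],
    placed: PlacedGenome,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_decoy_rows: int = 30,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Fabricate a 12-column BLAST-style table from true paralogy.

    True child->parent pairs get coverage ~ U(0.75, 1) and e-value
    10^-U(10, 60); segmental filler anchors get the same treatment; decoy
    rows alternate failing the coverage and the e-value filter.  Entries
    are emitted symmetrically.
    """
    lengths: dict[str, int] = {}
    for gene in placed.annotation:
        lengths[gene.gene_id] = max(sum(e.length for e in gene.exons) // 3, 50)

    rows = []

    def add_pair(q: str, s: str, qcov: float, evalue: float) -> None:
        for a, b in ((q, s), (s, q)):
            qlen = lengths[a]
            qend = max(int(round(qcov * qlen)), 1)
            rows.append(
                {
                    "qseqid": a, "sseqid": b,
                    "pident": round(float(rng.uniform(75, 99)), 1),
                    "length": qend, "mismatch": int(rng.integers(0, 20)),
                    "gapopen": int(rng.integers(0, 4)),
                    "qstart": 1, "qend": qend,
                    "sstart": 1, "send": qend,
                    "evalue": evalue,
                    "bitscore": round(float(rng.uniform(80, 400)), 1),
                }
            )

    species_genes = {
        g.gene_id: g
        for fam in families.values()
        for g in fam.genes_of(placed.species)
    }
    for gid in sorted(species_genes):
        g = species_genes[gid]
        if g.parent and g.parent in lengths and gid in lengths:
            add_pair(
                gid, g.parent,
                float(rng.uniform(0.75, 1.0)),
                10.0 ** -float(rng.uniform(10, 60)),
            )
    for q, s in placed.anchor_pairs:
        if q in lengths and s in lengths:
            add_pair(q, s, float(rng.uniform(0.75, 1.0)), 10.0 ** -float(rng.uniform(10, 60)))

    lectin_ids = sorted(species_genes) + list(placed.decoy_genes)
    for d in range(n_decoy_rows):
        q = lectin_ids[int(rng.integers(len(lectin_ids)))]
        s = lectin_ids[int(rng.integers(len(lectin_ids)))]
        if q == s:
            continue
        if d % 2 == 0:
            add_pair(q, s, float(rng.uniform(0.2, 0.6)), 10.0 ** -float(rng.uniform(10, 40)))
        else:
            add_pair(q, s, float(rng.uniform(0.75, 1.0)), 10.0 ** -float(rng.uniform(0, 7)))
    frame = pd.DataFrame(rows)
    return frame, lengths


def synthesize_domain_hits(
    families: Mapping[str, FamilySim],
    placed: PlacedGenome,
    config: SimulationConfig,
    rng: np.random.Generator,
    catalog: FamilyCatalog | None = None,
) -> pd.DataFrame:
    """Per-gene domain-hit rows driving the family classifier.

    Each lectin gene gets one hit of its family's domain model at full
    coverage; a configured fraction instead get a truncated (partial) hit.
    Decoy single-exon genes also get full hits so they enter the analysis.
    """
    catalog = catalog or FamilyCatalog.default()
    family_domain = {f: d for d, f in catalog.domain_to_family.items()}
    rows = []
    gene_family = {
        g.gene_id: g.family
        for fam in families.values()
        for g in fam.genes_of(placed.species)
    }
    for d in placed.decoy_genes:
        fam = sorted(config.ancestral_sizes)[0]
        gene_family[d] = fam
    for gid in sorted(gene_family):
        fam = gene_family[gid]
        domain = family_domain[fam]
        model_len = catalog.model_lengths[domain]
        partial = rng.random() < config.partial_fraction
        if partial:
            hmm_to = int(model_len * rng.uniform(0.3, 0.6))
        else:
            hmm_to = model_len
        rows.append(
            {
                "gene_id": gid,
                "domain": domain,
                "evalue": 10.0 ** -float(rng.uniform(20, 80)),
                "ali_from": 1,
                "ali_to": hmm_to,
                "hmm_from": 1,
                "hmm_to": hmm_to,
                "model_len": model_len,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TE planting


def plant_te_annotations(
    placed: PlacedGenome,
    families: Mapping[str, FamilySim],
    config: SimulationConfig,
    rng: np.random.Generator,
    flank_bp: int = 50_000,
) -> tuple[list[TEAnnotation], dict[str, str]]:
    """Plant elements realising each overlap class on well-separated genes.

    Returns (annotations, truth) where truth maps targeted gene_id -> the
    planted class.  Target genes are kept >= 120 kb apart (or on different
    chromosomes) so each gene sees only its own element.
    """
    superfams = ["MULE", "CACTA", "hAT", "Helitron"]
    lectins = sorted(
        g.gene_id for fam in families.values() for g in fam.genes_of(placed.species)
    )
    order = list(rng.permutation(len(lectins)))
    chosen: list[GeneModel] = []
    truth: dict[str, str] = {}
    annotations: list[TEAnnotation] = []
    te_idx = 0

    def far_enough(gene: GeneModel) -> bool:
        for other in chosen:
            if other.locus.chromosome == gene.locus.chromosome and (
                abs(other.locus.start - gene.locus.start) < 120_000
            ):
                return False
        return True

    wanted = [
        (cls, n) for cls, n in sorted(config.te_class_counts.items()) for _ in range(n)
    ]
    for cls, _ in wanted:
        picked = None
        for i in order:
            gene = placed.annotation.genes[lectins[i]]
            if gene.gene_id in truth or not far_enough(gene):
                continue
            if cls == "te_within_intron":
                introns = [iv for iv in gene.introns() if iv.length >= 320]
                if not introns:
                    continue
            picked = gene
            break
        if picked is None:
            continue
        locus = picked.locus
        te_idx += 1
        superfamily = superfams[te_idx % len(superfams)]
        if cls == "gene_within_te":
            iv = Interval(locus.chromosome, max(locus.start - 500, 0), locus.end + 500)
        elif cls == "te_within_intron":
            intron = max(
                (iv for iv in picked.introns() if iv.length >= 320),
                key=lambda iv: iv.length,
            )
            iv = Interval(locus.chromosome, intron.start + 10, intron.end - 10)
        elif cls == "te_within_exon_region":
            exon = picked.exons[0]
            mid = (exon.start + exon.end) // 2
            iv = Interval(locus.chromosome, max(exon.start - 50, 0), mid)
        elif cls == "te_in_flank":
            start = locus.end + int(rng.integers(5_000, flank_bp - 2_000))
            iv = Interval(locus.chromosome, start, start + 1_500)
        else:
            raise ValueError(cls)
        annotations.append(TEAnnotation(f"TE{te_idx:03d}", superfamily, iv))
        truth[picked.gene_id] = cls
        chosen.append(picked)

    # far elements inside the trailing chromosome margin (> 50 kb from genes)
    for k in range(config.n_te_far):
        chrom = sorted(placed.annotation.chromosome_lengths)[
            k % len(placed.annotation.chromosome_lengths)
        ]
        n = placed.annotation.chromosome_lengths[chrom]
        te_idx += 1
        annotations.append(
            TEAnnotation(
                f"TE{te_idx:03d}",
                superfams[te_idx % len(superfams)],
                Interval(chrom, n - 4_000, n - 2_000),
            )
        )
    return annotations, truth


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionTruth:
    de_labels: dict[str, dict[str, str]]  # gene -> contrast -> up/down/ns
    tissue_specific: dict[str, bool]


def simulate_expression(
    gene_ids: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionTruth]:
    """Replicated stress + tissue signal matrix with known DE labels.

    Baselines are log-normal; each contrast regulates a ``de_fraction`` of
    genes by a fold drawn from ``fold_set`` (up or down with equal
    probability); replicate noise is multiplicative with the configured
    CV.  Tissue-specific genes express in 1-2 tissues and are near-silent
    elsewhere.
    """
    genes = list(gene_ids)
    n = len(genes)
    baseline = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    )
    contrast_names = [c[0] for c in config.contrasts]
    de_labels: dict[str, dict[str, str]] = {g: {} for g in genes}
    columns: dict[str, np.ndarray] = {}
    meta_rows = []

    def noisy(mean_vec: np.ndarray) -> np.ndarray:
        factor = rng.normal(1.0, config.noise_cv, size=mean_vec.shape)
        return np.maximum(mean_vec * np.maximum(factor, 0.01), 0.0)

    for rep in range(1, config.n_replicates + 1):
        name = f"control_r{rep}"
        columns[name] = noisy(baseline)
        meta_rows.append(
            {"sample": name, "condition": "control", "replicate": rep,
             "tissue": "", "category": ""}
        )
    for cname, category in config.contrasts:
        is_de = rng.random(n) < config.de_fraction
        fold = rng.choice(config.fold_set, size=n)
        up = rng.random(n) < 0.5
        mean = baseline.copy()
        for i in range(n):
            if is_de[i]:
                mean[i] = baseline[i] * fold[i] if up[i] else baseline[i] / fold[i]
                de_labels[genes[i]][cname] = "up" if up[i] else "down"
            else:
                de_labels[genes[i]][cname] = "ns"
        for rep in range(1, config.n_replicates + 1):
            name = f"{cname}_r{rep}"
            columns[name] = noisy(mean)
            meta_rows.append(
                {"sample": name, "condition": cname, "replicate": rep,
                 "tissue": "", "category": category}
            )

    tissues = [f"tissue{i + 1}" for i in range(config.n_tissues)]
    specific = rng.random(n) < config.tissue_specific_fraction
    tissue_truth = {}
    tissue_mean = np.zeros((n, len(tissues)))
    for i in range(n):
        if specific[i]:
            k = int(rng.integers(1, 3))
            on = rng.choice(len(tissues), size=k, replace=False)
            tissue_mean[i, on] = baseline[i] * 3
            tissue_mean[i, [j for j in range(len(tissues)) if j not in on]] = 0.1
        else:
            tissue_mean[i, :] = baseline[i]
        tissue_truth[genes[i]] = bool(specific[i])
    for j, tissue in enumerate(tissues):
        for rep in range(1, 3):
            name = f"{tissue}_r{rep}"
            columns[name] = noisy(tissue_mean[:, j])
            meta_rows.append(
                {"sample": name, "condition": tissue, "replicate": rep,
                 "tissue": tissue, "category": ""}
            )

    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id")).round(3)
    samples = pd.DataFrame(meta_rows)
    return values, samples, ExpressionTruth(de_labels, tissue_truth)


# ---------------------------------------------------------------------------
# dataset emission


def emit_dataset(directory, config: SimulationConfig) -> dict:
    """Write a complete, internally consistent dataset; deterministic by seed.

    Per species: GFF3 annotation, genomic FASTA, domain-hit TSV, homology
    table (12-column, headerless), protein-length sidecar, TE BED, true
    block table, expression matrices; shared: per-family Newick gene trees,
    ground-truth manifest TSV and a JSON run-metadata file.  Returns a dict
    of everything in memory for direct pipeline use.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    families = simulate_family_evolution(config, rng)

    trees_dir = directory / "trees"
    trees_dir.mkdir(exist_ok=True)
    for family in sorted(families):
        (trees_dir / f"{family}.nwk").write_text(families[family].newick + "\n")

    manifest_rows = []
    result = {"config": config, "families": families, "species": {}}
    for species in config.species:
        placed = place_genes_on_genome(families, species, config, rng)
        homology, lengths = synthesize_homology_table(families, placed, config, rng)
        hits = synthesize_domain_hits(families, placed, config, rng)
        tes, te_truth = plant_te_annotations(placed, families, config, rng)
        lectin_ids = sorted(
            g.gene_id for fam in families.values() for g in fam.genes_of(species)
        )
        expr_values, expr_samples, expr_truth = simulate_expression(
            lectin_ids, config, rng
        )

        write_gff3(placed.annotation, directory / f"{species}.gff3")
        write_fasta(placed.sequences, directory / f"{species}.fa")
        homology.to_csv(
            directory / f"{species}_homology.tsv", sep="\t", index=False, header=False
        )
        pd.DataFrame(
            sorted(lengths.items()), columns=["gene_id", "protein_length"]
        ).to_csv(directory / f"{species}_protein_lengths.tsv", sep="\t", index=False)
        hits.to_csv(directory / f"{species}_domain_hits.tsv", sep="\t", index=False)
        write_bed(
            [
                BedRecord(te.interval, f"{te.element_id}|{te.superfamily}")
                for te in tes
            ],
            directory / f"{species}_te.bed",
        )
        write_block_table(placed.blocks, directory / f"{species}_blocks.tsv")
        expr_values.to_csv(directory / f"{species}_expression.tsv", sep="\t")
        expr_samples.to_csv(
            directory / f"{species}_samples.tsv", sep="\t", index=False
        )

        retro_by_id = {r.gene_id: r for r in placed.retro_plants}
        for fam in sorted(families):
            for g in families[fam].genes_of(species):
                plant = retro_by_id.get(g.gene_id)
                manifest_rows.append(
                    {
                        "gene_id": g.gene_id,
                        "species": species,
                        "family": g.family,
                        "mechanism": g.mechanism,
                        "parent": g.parent,
                        "ancestral_unit": g.ancestral_unit,
                        "exon_count": g.exon_count,
                        "tsd_planted": plant.tsd_seq if plant else "",
                        "polya_planted": plant.polya_len if plant else 0,
                        "te_class": te_truth.get(g.gene_id, ""),
                        "de_contrasts": ";".join(
                            c
                            for c, s in sorted(
                                expr_truth.de_labels.get(g.gene_id, {}).items()
                            )
                            if s != "ns"
                        ),
                        "tissue_specific": int(
                            expr_truth.tissue_specific.get(g.gene_id, False)
                        ),
                    }
                )
        result["species"][species] = {
            "placed": placed,
            "homology": homology,
            "protein_lengths": lengths,
            "domain_hits": hits,
            "te_annotations": tes,
            "te_truth": te_truth,
            "expression": (expr_values, expr_samples),
            "expression_truth": expr_truth,
        }

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)
    meta = {
        "seed": config.seed,
        "species": list(config.species),
        "divergence_my": config.divergence_my,
        "birth_rates": config.birth_rates,
        "ancestral_sizes": config.ancestral_sizes,
        "mechanism_mix": dict(
            zip(("tandem", "segmental", "retro", "dispersed"), config.mechanism_probs())
        ),
    }
    (directory / "run_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    result["manifest"] = manifest
    return result
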