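"""Stage implementations behind the CLI: each reads/writes TSV artifacts.

Stages run in dependency order (classify -> tandem -> segmental ->
ancestry -> retro -> te -> express -> report); a stage raises
:class:`DependencyError` naming itself and the missing upstream artifact
when its inputs are absent.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import duplication, expression, family_classifier, genome_io, phylo, retrogene
from .config import AnalysisConfig
from .te_overlap import te_annotations_from_bed, te_overlap_table

log = logging.getLogger("lectinfam")

STAGE_ORDER = (
    "classify", "tandem", "segmental", "ancestry", "retro", "te", "express",
    "report",
)


class DependencyError(RuntimeError):
    def __init__(self, stage: str, missing: str):
        super().__init__(
            f"stage '{stage}' requires missing artifact: {missing}"
        )
        self.stage = stage
        self.missing = missing


def _need(stage: str, path: Path) -> Path:
    if not path.exists():
        raise DependencyError(stage, str(path))
    return path


def _load_annotation(stage: str, data_dir: Path, species: str):
    path = _need(stage, data_dir / f"{species}.gff3")
    annotation = genome_io.read_gff3(path, species=species)
    genome_io.compute_gene_ranks(annotation)
    return annotation


def _load_families(stage: str, out_dir: Path, species: str) -> pd.DataFrame:
    return pd.read_csv(
        _need(stage, out_dir / f"{species}_families.tsv"), sep="\t"
    )


def _complete_family_map(frame: pd.DataFrame) -> dict[str, str]:
    # partial (pseudogene-like) members are excluded from evolution analyses
    keep = frame[frame["completeness"] == "complete"]
    return dict(zip(keep["gene_id"], keep["family"]))


def stage_classify(config: AnalysisConfig, data_dir: Path, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    all_assignments, species_of = [], {}
    for species in config.species:
        path = _need("classify", data_dir / f"{species}_domain_hits.tsv")
        hits = family_classifier.read_domain_table(
            path, evalue_cutoff=config.domain_evalue_cutoff
        )
        assignments = family_classifier.classify_genes(
            hits, min_model_coverage=config.partial_min_coverage
        )
        rows = [
            {
                "gene_id": a.gene_id,
                "family": a.family,
                "best_evalue": a.best_evalue,
                "completeness": a.completeness,
                "other_domains": ";".join(a.other_domains),
            }
            for a in assignments
        ]
        pd.DataFrame(
            rows,
            columns=["gene_id", "family", "best_evalue", "completeness", "other_domains"],
        ).to_csv(out_dir / f"{species}_families.tsv", sep="\t", index=False)
        all_assignments.extend(assignments)
        species_of.update({a.gene_id: species for a in assignments})
        log.info("classify[%s]: %d genes assigned", species, len(assignments))
    summary = family_classifier.summarize_families(all_assignments, species_of)
    summary.to_csv(out_dir / "family_summary.tsv", sep="\t", index=False)


def stage_tandem(config: AnalysisConfig, data_dir: Path, out_dir: Path) -> None:
    for species in config.species:
        annotation = _load_annotation("tandem", data_dir, species)
        family_of = _complete_family_map(_load_families("tandem", out_dir, species))
        clusters = duplication.find_tandem_clusters(
            family_of,
            annotation,
            max_gene_gap=config.max_gene_gap,
            max_bp=config.tandem_max_bp(species),
        )
        rows = [
            {
                "cluster_id": c.cluster_id,
                "family": c.family,
                "chromosome": c.chromosome,
                "n_members": len(c),
                "members": ";".join(c.members),
                "span_start": c.span.start,
                "span_end": c.span.end,
            }
            for c in clusters
        ]
        pd.DataFrame(
            rows,
            columns=["cluster_id", "family", "chromosome", "n_members",
                     "members", "span_start", "span_end"],
        ).to_csv(out_dir / f"{species}_clusters.tsv", sep="\t", index=False)
        log.info("tandem[%s]: %d clusters", species, len(rows))


def _read_clusters(stage: str, out_dir: Path, species: str):
    frame = pd.read_csv(_need(stage, out_dir / f"{species}_clusters.tsv"), sep="\t")
    clusters = []
    for row in frame.itertuples(index=False):
        members = str(row.members).split(";")
        clusters.append(
            duplication.TandemCluster(
                cluster_id=row.cluster_id,
                family=row.family,
                chromosome=row.chromosome,
                members=members,
                span=genome_io.Interval(
                    row.chromosome, int(row.span_start), int(row.span_end)
                ),
            )
        )
    return clusters


def stage_segmental(config: AnalysisConfig, data_dir: Path, out_dir: Path) -> None:
    for species in config.species:
        annotation = _load_annotation("segmental", data_dir, species)
        family_of = _complete_family_map(
            _load_families("segmental", out_dir, species)
        )
        clusters = _read_clusters("segmental", out_dir, species)
        blocks = duplication.read_block_table(
            _need("segmental", data_dir / f"{species}_blocks.tsv")
        )
        reps = duplication.collapse_tandem_arrays(sorted(family_of), clusters)
        pairs = duplication.assign_segmental_from_blocks(
            reps, blocks, family_of, annotation, clusters
        )
        seg_genes = duplication.segmental_gene_set(pairs, clusters)
        pd.DataFrame(
            pairs, columns=["gene_a", "gene_b", "block_id"]
        ).to_csv(out_dir / f"{species}_segmental_pairs.tsv", sep="\t", index=False)
        classes = duplication.classify_expansion(
            sorted(family_of), clusters, seg_genes
        )
        pd.DataFrame(
            [{"gene_id": c.gene_id, "expansion": c.expansion} for c in classes]
        ).to_csv(out_dir / f"{species}_expansion.tsv", sep="\t", index=False)
        summary = duplication.expansion_summary(
            classes, family_of, {g: species for g in family_of}
        )
        summary.to_csv(
            out_dir / f"{species}_expansion_summary.tsv", sep="\t", index=False
        )
        log.info("segmental[%s]: %d pairs", species, len(pairs))


def stage_ancestry(config: AnalysisConfig, data_dir: Path, out_dir: Path) -> None:
    trees_dir = _need("ancestry", data_dir / "trees")
    prefixes = config.species_prefixes()
    rows = []
    for tree_path in sorted(trees_dir.glob("*.nwk")):
        family = tree_path.stem
        tree = phylo.read_newick_species(tree_path, prefixes)
        leaves = tree.leaves()
        n_by_species = {
            sp: sum(l.species == sp for l in leaves) for sp in config.species
        }
        subset3 = frozenset(config.species)
        count3 = phylo.count_ancestral_units(tree, subset3).count
        subset2 = frozenset({"soybean", "arabidopsis"}) & subset3
        count2 = (
            phylo.count_ancestral_units(tree, subset2).count
            if len(subset2) == 2
            else 0
        )
        for sp in config.species:
            rate = (
                phylo.estimate_birth_rate(
                    n_by_species[sp], count3, config.divergence_my,
                    family=family, lineage=sp,
                ).rate_rounded
                if count3 >= 1
                else float("nan")
            )
            rows.append(
                {
                    "family": family,
                    "lineage": sp,
                    "n_extant": n_by_species[sp],
                    "n_anc_3species": count3,
                    "n_anc_dicots": count2,
                    "divergence_my": config.divergence_my,
                    "birth_rate": rate,
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "ancestry.tsv", sep="\t", index=False)
    log.info("ancestry: %d family x lineage rows", len(rows))


def stage_retro(config: AnalysisConfig, data_dir: Path, out_dir: Path) -> None:
    for species in config.species:
        annotation = _load_annotation("retro", data_dir, species)
        families = _load_families("retro", out_dir, species)
        lengths_frame = pd.read_csv(
            _need("retro", data_dir / f"{species}_protein_lengths.tsv"), sep="\t"
        )
        lengths = dict(
            zip(lengths_frame["gene_id"], lengths_frame["protein_length"])
        )
        homology = retrogene.read_homology_table(
            _need("retro", data_dir / f"{species}_homology.tsv"), lengths
        )
        genome_seq = genome_io.read_fasta(_need("retro", data_dir / f"{species}.fa"))
        clusters = _read_clusters("retro", out_dir, species)
        candidates = retrogene.find_retro_candidates(
            annotation,
            list(families["gene_id"]),
            homology,
            min_coverage=config.retro_min_coverage,
            max_evalue=config.retro_max_evalue,
        )
        calls = retrogene.call_retrogenes(
            candidates,
            annotation,
            genome_seq,
            flank_bp=max(config.tsd_search_bp, config.polya_window) + 50,
            polya_window=config.polya_window,
            polya_min_run=config.polya_min_run,
            polya_min_purity=config.polya_min_purity,
            tsd_min_len=config.tsd_min_len,
            tsd_max_len=config.tsd_max_len,
            tsd_search_bp=config.tsd_search_bp,
        )
        frame = retrogene.calls_to_frame(calls)
        seeded = retrogene.retro_tandem_expansion(calls, clusters)
        frame["seeded_tandem_cluster"] = [
            next((c.cluster_id for call2, c in seeded if call2.retrogene == r), "")
            for r in frame["retrogene"]
        ]
        frame.to_csv(out_dir / f"{species}_retrogenes.tsv", sep="\t", index=False)
        log.info("retro[%s]: %d calls", species, len(frame))


def stage_te(config: AnalysisConfig, data_dir: Path, out_dir: Path) -> None:
    for species in config.species:
        annotation = _load_annotation("te", data_dir, species)
        families = _load_families("te", out_dir, species)
        records = genome_io.read_bed(_need("te", data_dir / f"{species}_te.bed"))
        tes = te_annotations_from_bed(records)
        genes = [annotation.genes[g] for g in families["gene_id"]
                 if g in annotation.genes]
        table = te_overlap_table(genes, tes, flank_bp=config.flank_bp)
        table.to_csv(out_dir / f"{species}_te_overlap.tsv", sep="\t", index=False)
        log.info("te[%s]: %d genes classified", species, len(table))


def stage_express(config: AnalysisConfig, data_dir: Path, out_dir: Path) -> None:
    for species in config.species:
        values_path = _need("express", data_dir / f"{species}_expression.tsv")
        samples_path = _need("express", data_dir / f"{species}_samples.tsv")
        families = _load_families("express", out_dir, species)
        matrix = expression.ExpressionMatrix.from_tsv(values_path, samples_path)
        meta = matrix.samples
        stress_conditions = meta.loc[
            (meta["category"].fillna("") != ""), ["condition", "category"]
        ].drop_duplicates()
        contrasts = [
            expression.ContrastSpec(row.condition, "control", row.condition, row.category)
            for row in stress_conditions.itertuples(index=False)
        ]
        calls_by_contrast = {}
        call_rows = []
        for contrast in contrasts:
            calls = expression.call_differential(
                matrix, contrast,
                min_fold=config.min_fold,
                alpha=config.alpha,
                pseudocount=config.pseudocount,
            )
            calls_by_contrast[contrast.name] = calls
            call_rows.extend(
                {
                    "gene_id": c.gene_id,
                    "contrast": c.contrast,
                    "fold_change": round(c.fold_change, 4),
                    "p_value": c.p_value,
                    "status": c.status,
                    "tested": int(c.tested),
                }
                for c in calls
            )
        pd.DataFrame(call_rows).to_csv(
            out_dir / f"{species}_de_calls.tsv", sep="\t", index=False
        )
        summary = expression.summarize_stress_sets(
            calls_by_contrast, contrasts, total_genes=len(matrix.values)
        )
        summary.to_frame().to_csv(
            out_dir / f"{species}_stress_summary.tsv", sep="\t", index=False
        )

        units: dict[str, list[str]] = {}
        for cluster in _read_clusters("express", out_dir, species):
            units[cluster.cluster_id] = list(cluster.members)
        pairs = pd.read_csv(
            _need("express", out_dir / f"{species}_segmental_pairs.tsv"), sep="\t"
        )
        for row in pairs.itertuples(index=False):
            units[f"pair_{row.gene_a}_{row.gene_b}"] = [row.gene_a, row.gene_b]
        family_of = dict(zip(families["gene_id"], families["family"]))
        divergence = expression.divergence_summary(
            units, calls_by_contrast, family_of
        )
        divergence.to_csv(
            out_dir / f"{species}_divergence.tsv", sep="\t", index=False
        )
        log.info("express[%s]: %d contrasts", species, len(contrasts))


def stage_report(config: AnalysisConfig, data_dir: Path, out_dir: Path) -> None:
    from .report import generate_report

    text = generate_report(out_dir, config)
    (out_dir / "report.txt").write_text(text)
    log.info("report written to %s", out_dir / "report.txt")


STAGES = {
    "classify": stage_classify,
    "tandem": stage_tandem,
    "segmental": stage_segmental,
    "ancestry": stage_ancestry,
    "retro": stage_retro,
    "te": stage_te,
    "express": stage_express,
    "report": stage_report,
}


def run_pipeline(
    config: AnalysisConfig, data_dir, out_dir, stages=None
) -> None:
    """Run the requested stages in dependency order."""
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wanted = list(stages) if stages else list(STAGE_ORDER)
    for stage in wanted:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    manifest = {
        "stages": [s for s in STAGE_ORDER if s in wanted],
        "seed": config.seed,
        "thresholds": {
            "max_gene_gap": config.max_gene_gap,
            "flank_bp": config.flank_bp,
            "retro_min_coverage": config.retro_min_coverage,
            "retro_max_evalue": config.retro_max_evalue,
            "min_fold": config.min_fold,
            "alpha": config.alpha,
            "divergence_my": config.divergence_my,
        },
    }
    for stage in manifest["stages"]:
        log.info("running stage %s", stage)
        STAGES[stage](config, data_dir, out_dir)
    (out_dir / "pipeline_log.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
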