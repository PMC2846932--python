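"""Consolidated text report over the pipeline's TSV artifacts.

Each section prints the numbers exactly as they stand in the underlying
artifact tables; unions in the stress section are shown with their
inclusion-exclusion decomposition.  Missing artifacts yield explicit
"no data" sections rather than errors, so a partial pipeline still
reports cleanly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import AnalysisConfig


def _section(title: str) -> str:
    return f"\n== {title} ==\n"


def _maybe_read(path: Path) -> pd.DataFrame | None:
    if not path.exists():
        return None
    frame = pd.read_csv(path, sep="\t")
    return frame if not frame.empty else None


def generate_report(out_dir, config: AnalysisConfig | None = None) -> str:
    out_dir = Path(out_dir)
    config = config or AnalysisConfig()
    lines = ["lectin gene-family evolution report", "=" * 36]

    lines.append(_section("Family counts (complete / partial)"))
    summary = _maybe_read(out_dir / "family_summary.tsv")
    if summary is None:
        lines.append("no data")
    else:
        nonzero = summary[summary["total"] > 0]
        for row in nonzero.itertuples(index=False):
            lines.append(
                f"{row.species:<12} {row.family:<20} "
                f"{row.complete:>4} complete  {row.partial:>3} partial"
            )
        totals = nonzero.groupby("species")["total"].sum()
        for sp, n in totals.items():
            lines.append(f"{sp}: {n} lectin genes")

    lines.append(_section("Ancestral units and birth rates"))
    ancestry = _maybe_read(out_dir / "ancestry.tsv")
    if ancestry is None:
        lines.append("no data")
    else:
        for row in ancestry.itertuples(index=False):
            lines.append(
                f"{row.family:<14} {row.lineage:<12} N_extant={row.n_extant:<4} "
                f"N_anc={row.n_anc_3species:<3} T={row.divergence_my:g} MY "
                f"rate={row.birth_rate} /100MY/ancestral gene"
            )

    lines.append(_section("Expansion mechanisms"))
    any_exp = False
    for species in config.species:
        frame = _maybe_read(out_dir / f"{species}_expansion_summary.tsv")
        if frame is None:
            continue
        any_exp = True
        for row in frame.itertuples(index=False):
            lines.append(
                f"{species:<12} {row.family:<20} total={row.total:<4} "
                f"tandem={row.tandem} segmental={row.segmental} "
                f"both={row.both} other={row.other} "
                f"({row.tandem_pct}% / {row.segmental_pct}% involved)"
            )
    if not any_exp:
        lines.append("no data")

    lines.append(_section("Retrogenes"))
    any_retro = False
    for species in config.species:
        frame = _maybe_read(out_dir / f"{species}_retrogenes.tsv")
        if frame is None:
            continue
        any_retro = True
        lines.append(f"{species}: {len(frame)} putative retrogenes")
        for row in frame.itertuples(index=False):
            cluster = row.seeded_tandem_cluster
            seeded = (
                f"; seeded {cluster}" if not pd.isna(cluster) and cluster else ""
            )
            lines.append(
                f"  {row.retrogene} <- {row.parent} tier={row.tier}{seeded}"
            )
    if not any_retro:
        lines.append("no data")

    lines.append(_section("TE overlap"))
    any_te = False
    for species in config.species:
        frame = _maybe_read(out_dir / f"{species}_te_overlap.tsv")
        if frame is None:
            continue
        any_te = True
        counts = frame["te_class"].value_counts()
        parts = ", ".join(f"{cls}={n}" for cls, n in counts.items())
        lines.append(f"{species}: {parts}")
    if not any_te:
        lines.append("no data")

    lines.append(_section("Stress regulation (with inclusion-exclusion)"))
    any_stress = False
    for species in config.species:
        frame = _maybe_read(out_dir / f"{species}_stress_summary.tsv")
        if frame is None:
            continue
        any_stress = True
        by_set = dict(zip(frame["set"], frame["count"]))
        pct = dict(zip(frame["set"], frame["percent"]))
        lines.append(f"{species}:")
        for name in frame["set"]:
            lines.append(f"  {name}: {by_set[name]} ({pct[name]}%)")
        if {"biotic", "abiotic", "biotic_and_abiotic", "any"} <= by_set.keys():
            lines.append(
                f"  union check: |any| = {by_set['biotic']} + {by_set['abiotic']}"
                f" - {by_set['biotic_and_abiotic']} = {by_set['any']}"
            )
    if not any_stress:
        lines.append("no data")

    lines.append(_section("Expression divergence of duplicated genes"))
    any_div = False
    for species in config.species:
        frame = _maybe_read(out_dir / f"{species}_divergence.tsv")
        if frame is None:
            continue
        any_div = True
        for row in frame.itertuples(index=False):
            lines.append(
                f"{species:<12} {row.family:<20} {row.divergent}/{row.units} "
                f"divergent ({row.percent_divergent}%)"
            )
    if not any_div:
        lines.append("no data")

    return "\n".join(lines) + "\n"
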