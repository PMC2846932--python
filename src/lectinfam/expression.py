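"""Stress-response and tissue expression analysis of duplicated genes.

Differential expression under a stress contrast follows a two-part rule:
at least a 2-fold difference between the mean stress and mean control
signals, and a significant classical (equal-variance) two-sample t-test on
the replicate signals (alpha = 0.05, two-sided, no multiple-testing
correction by default; Welch and Benjamini-Hochberg variants are available
behind flags).  Tag-count platforms (MPSS-style) are normalised to
tags-per-million before the same rule; contrasts without replication get
fold-only calls flagged untested.

Family-level stress summaries use inclusion-exclusion over the per-contrast
regulated gene sets; expression divergence of a tandem cluster or
segmental block pair is declared when any two members disagree in status
under any contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .duplication import round_percent

STATUSES = ("up", "down", "ns")


class ContrastError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """genes x samples signal matrix with per-sample metadata.

    ``values``: DataFrame indexed by gene_id, columns = sample names.
    ``samples``: DataFrame with columns (sample, condition, replicate,
    tissue, category); 'category' tags each stress condition biotic or
    abiotic.  ``platform`` is 'microarray' (signals used as-is) or
    'tag_count' (normalised to tags-per-million on load).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    platform: str = "microarray"

    def __post_init__(self):
        if self.platform not in ("microarray", "tag_count"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression signals must be finite")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("expression signals must be non-negative")
        missing = set(self.samples["sample"]) - set(self.values.columns)
        if missing:
            raise ValueError(f"samples missing from matrix: {sorted(missing)}")
        if self.platform == "tag_count":
            # tags-per-million normalisation so the fold rule compares
            # libraries of different depth on one scale
            totals = self.values.sum(axis=0).replace(0, 1)
            self.values = self.values / totals * 1e6

    def condition_columns(self, condition: str) -> list[str]:
        mask = self.samples["condition"] == condition
        return list(self.samples.loc[mask, "sample"])

    @classmethod
    def from_tsv(cls, values_path, samples_path, platform: str = "microarray"):
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t")
        return cls(values=values, samples=samples, platform=platform)


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    control: str
    stress: str
    category: str  # biotic | abiotic

    def __post_init__(self):
        if self.category not in ("biotic", "abiotic"):
            raise ValueError(f"category must be biotic/abiotic, got {self.category!r}")


@dataclass(frozen=True)
class DECall:
    gene_id: str
    contrast: str
    fold_change: float
    p_value: float
    status: str  # up | down | ns
    tested: bool = True


def call_differential(
    matrix: ExpressionMatrix,
    contrast: ContrastSpec,
    min_fold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    welch: bool = False,
    fdr: bool = False,
) -> list[DECall]:
    """2-fold + t-test rule per gene for one stress/control contrast.

    fold = (mean_stress + pseudocount)/(mean_control + pseudocount);
    up if fold >= min_fold with p < alpha, down if fold <= 1/min_fold with
    p < alpha, else ns.  With fewer than 2 replicates on either side the
    fold-only call is returned with ``tested=False``.
    """
    ctrl_cols = matrix.condition_columns(contrast.control)
    stress_cols = matrix.condition_columns(contrast.stress)
    if not ctrl_cols or not stress_cols:
        raise ContrastError(
            f"contrast {contrast.name}: conditions "
            f"{contrast.control!r}/{contrast.stress!r} not both present"
        )
    ctrl = matrix.values[ctrl_cols].to_numpy(dtype=float)
    stress = matrix.values[stress_cols].to_numpy(dtype=float)
    folds = (stress.mean(axis=1) + pseudocount) / (ctrl.mean(axis=1) + pseudocount)

    testable = ctrl.shape[1] >= 2 and stress.shape[1] >= 2
    if testable:
        with np.errstate(invalid="ignore", divide="ignore"):
            _t, pvals = stats.ttest_ind(
                stress, ctrl, axis=1, equal_var=not welch
            )
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
    else:
        pvals = np.ones(len(folds))

    if fdr and testable:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            i = m - rank_from_top  # 1-based rank
            running = min(running, pvals[idx] * m / i)
            adj[idx] = running
        pvals = adj

    calls = []
    for gene_id, fold, p in zip(matrix.values.index, folds, pvals):
        passes_p = (p < alpha) if testable else True
        if fold >= min_fold and passes_p:
            status = "up"
        elif fold <= 1.0 / min_fold and passes_p:
            status = "down"
        else:
            status = "ns"
        calls.append(
            DECall(
                gene_id=str(gene_id),
                contrast=contrast.name,
                fold_change=float(fold),
                p_value=float(p),
                status=status,
                tested=testable,
            )
        )
    return calls


def regulated_set(calls: Iterable[DECall]) -> set[str]:
    return {c.gene_id for c in calls if c.status != "ns"}


@dataclass
class StressSummary:
    """Per-contrast regulated sets and their inclusion-exclusion unions."""

    total_genes: int
    per_contrast: dict[str, set[str]] = field(default_factory=dict)
    biotic: set[str] = field(default_factory=set)
    abiotic: set[str] = field(default_factory=set)

    @property
    def any_stress(self) -> set[str]:
        return self.biotic | self.abiotic

    @property
    def biotic_abiotic_overlap(self) -> set[str]:
        return self.biotic & self.abiotic

    def percent(self, genes: set[str]) -> int:
        return round_percent(len(genes), self.total_genes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"set": name, "count": len(genes), "percent": self.percent(genes)}
            for name, genes in [
                *sorted(self.per_contrast.items()),
                ("biotic", self.biotic),
                ("abiotic", self.abiotic),
                ("biotic_and_abiotic", self.biotic_abiotic_overlap),
                ("any", self.any_stress),
            ]
        ]
        return pd.DataFrame(rows)


def summarize_stress_sets(
    calls_by_contrast: Mapping[str, Iterable[DECall]],
    contrasts: Iterable[ContrastSpec],
    total_genes: int,
) -> StressSummary:
    """Union the per-contrast regulated sets into biotic/abiotic/any.

    Every reported union obeys |A or B| = |A| + |B| - |A and B| exactly
    because the summary is computed on the gene sets themselves.
    """
    contrasts = list(contrasts)
    summary = StressSummary(total_genes=total_genes)
    by_name = {c.name: c for c in contrasts}
    for name, calls in calls_by_contrast.items():
        if name not in by_name:
            raise ContrastError(f"calls for unknown contrast {name!r}")
        genes = regulated_set(calls)
        summary.per_contrast[name] = genes
        if by_name[name].category == "biotic":
            summary.biotic |= genes
        else:
            summary.abiotic |= genes
    return summary


def call_tissue_specific(
    matrix: ExpressionMatrix,
    tissues: Sequence[str] | None = None,
    theta: float = 5.0,
    max_tissues: int = 2,
    min_signal_share: float = 0.9,
) -> dict[str, bool]:
    """Preferential expression in at most ``max_tissues`` tissues.

    A gene is tissue-specific iff it is expressed (mean signal > theta) in
    between 1 and ``max_tissues`` tissues and its top ``max_tissues``
    tissues carry at least ``min_signal_share`` of its total signal.
    """
    meta = matrix.samples
    if tissues is None:
        tissues = [t for t in meta["tissue"].dropna().unique() if t]
    if len(tissues) < 3:
        raise ValueError("tissue-specificity needs >=3 tissues")
    means = {}
    for tissue in tissues:
        cols = list(meta.loc[meta["tissue"] == tissue, "sample"])
        means[tissue] = matrix.values[cols].mean(axis=1)
    tissue_means = pd.DataFrame(means)
    out = {}
    for gene_id, row in tissue_means.iterrows():
        expressed = int((row > theta).sum())
        total = float(row.sum())
        top_share = (
            float(row.nlargest(max_tissues).sum()) / total if total > 0 else 0.0
        )
        out[str(gene_id)] = (
            1 <= expressed <= max_tissues and top_share >= min_signal_share
        )
    return out


def cluster_divergence(
    member_ids: Iterable[str],
    calls_by_contrast: Mapping[str, Iterable[DECall]],
) -> bool | None:
    """Divergent iff two members disagree in status under some contrast.

    Members absent from the expression data are excluded; returns None when
    fewer than two members have calls (divergence undefined).
    """
    members = list(member_ids)
    status: dict[str, dict[str, str]] = {}
    for contrast, calls in calls_by_contrast.items():
        for call in calls:
            if call.gene_id in members:
                status.setdefault(call.gene_id, {})[contrast] = call.status
    covered = [m for m in members if m in status]
    if len(covered) < 2:
        return None
    for contrast in calls_by_contrast:
        seen = {status[m].get(contrast, "ns") for m in covered}
        if len(seen) > 1:
            return True
    return False


def divergence_summary(
    units: Mapping[str, Iterable[str]],
    calls_by_contrast: Mapping[str, Iterable[DECall]],
    family_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Fraction of divergent units (clusters or blocks), overall and per family.

    ``units`` maps unit id -> member gene_ids.  Units with undefined
    divergence (fewer than two members with data) are excluded from the
    denominators and counted in 'no_data'.
    """
    family_of = family_of or {}
    rows = []
    flags = {
        unit_id: cluster_divergence(members, calls_by_contrast)
        for unit_id, members in units.items()
    }
    families = sorted(
        {
            family_of.get(next(iter(units[u]), ""), "all")
            for u in units
        }
    ) or ["all"]

    def family_key(unit_id: str) -> str:
        members = list(units[unit_id])
        return family_of.get(members[0], "all") if members else "all"

    for fam in families + (["all"] if families != ["all"] else []):
        picked = [
            u for u in units if fam == "all" or family_key(u) == fam
        ]
        evaluable = [u for u in picked if flags[u] is not None]
        divergent = [u for u in evaluable if flags[u]]
        rows.append(
            {
                "family": fam,
                "units": len(evaluable),
                "divergent": len(divergent),
                "no_data": len(picked) - len(evaluable),
                "percent_divergent": round_percent(len(divergent), len(evaluable)),
            }
        )
    return pd.DataFrame(rows)
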