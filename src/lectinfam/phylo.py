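"""Ancestral-unit counting on species-labeled gene trees and birth rates.

The number of ancestral units of a gene family — gene lineages already
present in the most recent common ancestor (MRCA) of a set of species — is
read off a gene tree by LCA reconciliation against the species tree: each
gene-tree node maps to the lowest species-tree node containing all species
below it, a node whose mapping equals a child's mapping is a duplication,
and the ancestral units are the speciation nodes mapped to the species-tree
root of the compared subset.  This is the parsimony-minimal (loss-blind)
count, hence a lower bound ("at least N units").

The per-lineage birth rate of surviving gene copies is then

    rate = 100 * ((N_extant - N_anc) / N_anc) / T

in genes per 100 million years (MY) per ancestral gene, with T the
divergence time of the compared species (monocot/dicot split: 140-150 MYA,
default 150).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy

DEFAULT_SPECIES_TREE = (("soybean", "arabidopsis"), "rice")

DEFAULT_SPECIES_PREFIXES = {
    "Glyma": "soybean",
    "LOC_Os": "rice",
    "AT": "arabidopsis",
}


class SpeciesResolutionError(ValueError):
    pass


@dataclass(frozen=True)
class AncestralUnitCount:
    species_subset: frozenset[str]
    count: int


@dataclass(frozen=True)
class BirthRate:
    family: str
    lineage: str
    n_extant: int
    n_ancestral: int
    divergence_my: float
    rate: float  # genes per 100 MY per ancestral gene

    @property
    def rate_rounded(self) -> float:
        return round(self.rate, 1)


# ---------------------------------------------------------------------------
# species tree as nested tuples: leaves are species names, internal nodes
# are 2-tuples of subtrees; small enough that no tree library is needed


def species_tree_leaves(node) -> frozenset[str]:
    if isinstance(node, tuple):
        out: set[str] = set()
        for child in node:
            out |= species_tree_leaves(child)
        return frozenset(out)
    return frozenset({node})


def restrict_species_tree(node, subset: frozenset[str]):
    """Species tree restricted to a subset of leaves (suppressing unaries)."""
    if not isinstance(node, tuple):
        return node if node in subset else None
    kept = [restrict_species_tree(c, subset) for c in node]
    kept = [c for c in kept if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return tuple(kept)


def _species_lca(node, species: frozenset[str]):
    """Lowest node of the species tree whose leaf set contains ``species``."""
    if isinstance(node, tuple):
        for child in node:
            if species <= species_tree_leaves(child):
                return _species_lca(child, species)
    return node


# ---------------------------------------------------------------------------
# gene trees


@dataclass
class GeneLeaf:
    gene_id: str
    species: str


class GeneTreeNode:
    """Rooted gene-tree node; leaves carry (gene_id, species)."""

    __slots__ = ("children", "leaf")

    def __init__(self, children=None, leaf: GeneLeaf | None = None):
        self.children: list["GeneTreeNode"] = children or []
        self.leaf = leaf

    @property
    def is_leaf(self) -> bool:
        return self.leaf is not None

    def leaves(self) -> list[GeneLeaf]:
        if self.is_leaf:
            return [self.leaf]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def species_below(self) -> frozenset[str]:
        return frozenset(l.species for l in self.leaves())

    def min_leaf_label(self) -> str:
        return min(l.gene_id for l in self.leaves())


def resolve_species(label: str, species_map: Mapping[str, str]) -> str:
    """Species from a gene label via longest matching id prefix."""
    best = None
    for prefix, species in species_map.items():
        if label.startswith(prefix) and (best is None or len(prefix) > len(best[0])):
            best = (prefix, species)
    if best is None:
        raise SpeciesResolutionError(f"cannot resolve species for leaf {label!r}")
    return best[1]


def _resolve_multifurcations(node: GeneTreeNode) -> GeneTreeNode:
    """Deterministic caterpillar resolution: children sorted by min leaf id.

    Resolution of a polytomy can only merge same-mapping nodes into nested
    duplications; it never raises the speciation-node count.
    """
    if node.is_leaf:
        return node
    children = sorted(
        (_resolve_multifurcations(c) for c in node.children),
        key=lambda c: c.min_leaf_label(),
    )
    while len(children) > 2:
        merged = GeneTreeNode(children=[children[0], children[1]])
        children = [merged] + children[2:]
    node.children = children
    return node


def _from_dendropy(node: dendropy.Node, species_map: Mapping[str, str]) -> GeneTreeNode:
    if node.is_leaf():
        label = node.taxon.label if node.taxon else (node.label or "")
        label = label.replace(" ", "_")
        return GeneTreeNode(leaf=GeneLeaf(label, resolve_species(label, species_map)))
    return GeneTreeNode(
        children=[_from_dendropy(c, species_map) for c in node.child_nodes()]
    )


def read_newick_species(
    source,
    species_map: Mapping[str, str] | None = None,
    midpoint_root_unrooted: bool = True,
) -> GeneTreeNode:
    """Parse a Newick gene tree and resolve every leaf to a species.

    ``source`` is a path or a Newick string.  Trees read as unrooted (root
    with 3+ children) are midpoint-rooted, then any remaining
    multifurcations are resolved deterministically (sorted caterpillars) so
    counts are reproducible.
    """
    species_map = species_map or DEFAULT_SPECIES_PREFIXES
    text = source
    if not str(source).strip().startswith("("):
        with open(source) as fh:
            text = fh.read()
    tree = dendropy.Tree.get(data=str(text), schema="newick")
    unrooted = len(tree.seed_node.child_nodes()) > 2
    if unrooted and midpoint_root_unrooted:
        if all(e.length is None for e in tree.edges()):
            for e in tree.edges():
                e.length = 1.0
        tree.reroot_at_midpoint(update_bipartitions=True)
    root = _from_dendropy(tree.seed_node, species_map)
    errors = []
    for leaf in root.leaves():
        if not leaf.species:
            errors.append(leaf.gene_id)
    if errors:
        raise SpeciesResolutionError(f"unresolved leaves: {errors}")
    return _resolve_multifurcations(root)


def prune_to_species(node: GeneTreeNode, subset: frozenset[str]) -> GeneTreeNode | None:
    """Restrict a gene tree to leaves of the given species, suppressing unaries."""
    if node.is_leaf:
        return node if node.leaf.species in subset else None
    kept = [prune_to_species(c, subset) for c in node.children]
    kept = [c for c in kept if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return GeneTreeNode(children=kept)


def lca_species_map(gene_tree: GeneTreeNode, species_tree=DEFAULT_SPECIES_TREE):
    """LCA reconciliation: each gene-tree node -> its species-tree node.

    Returns a list of (node, mapping, is_duplication) in postorder; a node
    is a duplication iff its mapping equals the mapping of one of its
    children.
    """
    out: list[tuple[GeneTreeNode, object, bool]] = []

    def visit(node: GeneTreeNode):
        if node.is_leaf:
            m = node.leaf.species
            out.append((node, m, False))
            return m
        child_maps = [visit(c) for c in node.children]
        species = node.species_below()
        m = _species_lca(species_tree, species)
        is_dup = any(cm == m for cm in child_maps)
        out.append((node, m, is_dup))
        return m

    visit(gene_tree)
    return out


def count_ancestral_units(
    gene_tree: GeneTreeNode,
    species_subset: Iterable[str],
    species_tree=DEFAULT_SPECIES_TREE,
) -> AncestralUnitCount:
    """Count MRCA gene lineages for a set of species on one gene tree.

    The tree is pruned to leaves of the subset; the count is the number of
    speciation nodes mapping to the root R of the restricted species tree
    (no child also maps to R).  A tree whose surviving leaves all come from
    one species contributes 0 units (fully lineage-specific family).
    """
    subset = frozenset(species_subset)
    if not subset:
        raise ValueError("species subset must be non-empty")
    pruned = prune_to_species(gene_tree, subset)
    if pruned is None:
        return AncestralUnitCount(subset, 0)
    restricted = restrict_species_tree(species_tree, subset)
    if not isinstance(restricted, tuple):
        # subset collapses to a single species-tree leaf: no pre-divergence era
        return AncestralUnitCount(subset, 0)
    count = 0
    for node, mapping, is_dup in lca_species_map(pruned, restricted):
        if not node.is_leaf and mapping == restricted and not is_dup:
            count += 1
    return AncestralUnitCount(subset, count)


def estimate_birth_rate(
    n_extant: int,
    n_ancestral: int,
    divergence_my: float = 150.0,
    family: str = "",
    lineage: str = "",
) -> BirthRate:
    """Birth rate of surviving gene copies per 100 MY per ancestral gene."""
    if n_ancestral < 1:
        raise ValueError("rate undefined: family absent from the ancestor")
    if divergence_my <= 0:
        raise ValueError("divergence time must be positive")
    rate = 100.0 * ((n_extant - n_ancestral) / n_ancestral) / divergence_my
    return BirthRate(
        family=family,
        lineage=lineage,
        n_extant=n_extant,
        n_ancestral=n_ancestral,
        divergence_my=divergence_my,
        rate=rate,
    )
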