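"""Independent brute-force oracles shared by the unit and acceptance tests.

Every function here recomputes an expected result by direct enumeration or
set arithmetic, deliberately avoiding the package's own algorithms, so the
tests compare two independent routes to the same quantity.
"""

from __future__ import annotations

import functools
import itertools

from lectinfam.phylo import GeneLeaf, GeneTreeNode


# ---------------------------------------------------------------------------
# gene-tree enumeration and reconciliation


def enumerate_species_trees(counts: tuple) -> tuple:
    """All rooted binary species-labeled tree shapes up to isomorphism.

    ``counts`` is a sorted tuple of (species, multiplicity).  Leaves are
    distinguishable only by species, so enumerating shapes up to
    isomorphism covers every distinct input of a function that depends only
    on the species labeling.
    """

    @functools.lru_cache(maxsize=None)
    def rec(c):
        total = sum(n for _, n in c)
        if total == 1:
            return (c[0][0],)
        out = set()
        species = [s for s, _ in c]
        ns = [n for _, n in c]
        for left_ns in itertools.product(*[range(n + 1) for n in ns]):
            lt = sum(left_ns)
            if lt == 0 or lt == total:
                continue
            right_ns = tuple(n - l for n, l in zip(ns, left_ns))
            lc = tuple((s, n) for s, n in zip(species, left_ns) if n)
            rc = tuple((s, n) for s, n in zip(species, right_ns) if n)
            if (lc, rc) > (rc, lc):
                continue  # unordered split: count each partition once
            for a in rec(lc):
                for b in rec(rc):
                    out.add((a, b) if repr(a) <= repr(b) else (b, a))
        return tuple(sorted(out, key=repr))

    return rec(counts)


def all_labeled_trees(n_leaves: int, species: tuple) -> list:
    trees = []
    for ns in itertools.product(*[range(n_leaves + 1)] * len(species)):
        if sum(ns) != n_leaves or any(x == 0 for x in ns):
            continue
        trees.extend(enumerate_species_trees(tuple(zip(species, ns))))
    return trees


def nested_to_gene_tree(node, counter=None) -> GeneTreeNode:
    """Nested species tuples -> GeneTreeNode with unique gene ids."""
    if counter is None:
        counter = [0]
    if isinstance(node, str):
        counter[0] += 1
        return GeneTreeNode(leaf=GeneLeaf(f"g{counter[0]:04d}", node))
    return GeneTreeNode(
        children=[nested_to_gene_tree(c, counter) for c in node]
    )


def root_lineage_count_oracle(tree, left_side: frozenset, right_side: frozenset) -> int:
    """Ancestral-unit count by direct root-split set tests.

    A node's lineage existed before the root divergence iff its leaf
    species touch both sides of the root split; the count is the number of
    maximal such clades (nodes touching both sides whose children each
    touch only one side).
    """

    def touches_both(s: frozenset) -> bool:
        return bool(s & left_side) and bool(s & right_side)

    def rec(node):
        if isinstance(node, str):
            return frozenset([node]), 0
        s0, c0 = rec(node[0])
        s1, c1 = rec(node[1])
        s, c = s0 | s1, c0 + c1
        if touches_both(s) and not touches_both(s0) and not touches_both(s1):
            c += 1
        return s, c

    return rec(tree)[1]


def lca_mapping_oracle(tree, species_tree):
    """node -> species-tree node by explicit set-union LCA per node."""

    def leaves_of(node):
        if isinstance(node, tuple):
            out = set()
            for child in node:
                out |= leaves_of(child)
            return frozenset(out)
        return frozenset([node])

    def lca(node, wanted):
        if isinstance(node, tuple):
            for child in node:
                if wanted <= leaves_of(child):
                    return lca(child, wanted)
        return node

    out = []

    def rec(node):
        if node.is_leaf:
            out.append((node, node.leaf.species))
            return frozenset([node.leaf.species])
        sets = [rec(c) for c in node.children]
        merged = frozenset().union(*sets)
        out.append((node, lca(species_tree, merged)))
        return merged

    rec(tree)
    return out


# ---------------------------------------------------------------------------
# sequence-scan oracles


def polya_oracle(seq: str, window: int, min_run: int, min_purity: float):
    """Best A-rich substring by scanning every (start, end) pair.

    Best = most adenines, then highest purity, then earliest start.
    """
    s = seq[:window].upper()
    best = None  # (a_count, purity, -start, length)
    for start in range(len(s)):
        for end in range(start + min_run, len(s) + 1):
            sub = s[start:end]
            a_count = sub.count("A")
            purity = a_count / len(sub)
            if purity >= min_purity:
                key = (a_count, purity, -start, len(sub))
                if best is None or key > best:
                    best = key
    if best is None:
        return None
    return (best[3], best[1], -best[2])  # (run_length, purity, start)


def tsd_oracle(up: str, down: str, min_len: int, max_len: int, search_bp: int):
    """Longest exact direct repeat near the boundaries, by full enumeration.

    Returns (length, up_dist, down_dist, repeat) of the best repeat under
    (longest, then smallest total boundary distance) or None.
    """
    u = up[-search_bp:].upper()
    d = down[:search_bp].upper()
    best = None
    for length in range(min_len, min(max_len, len(u), len(d)) + 1):
        for i in range(len(u) - length + 1):
            for j in range(len(d) - length + 1):
                if u[i : i + length] == d[j : j + length]:
                    up_dist = len(u) - (i + length)
                    # longest, then nearest the boundaries, then nearest the
                    # upstream boundary (the documented tie order)
                    key = (length, -(up_dist + j), -up_dist, -j)
                    if best is None or key > best[0]:
                        best = (key, (length, up_dist, j, d[j : j + length]))
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# tandem clustering closure oracle


def tandem_closure_oracle(genes, max_gene_gap: int, max_bp: int):
    """Connected components of the pairwise tandem predicate over ALL pairs.

    ``genes`` is a list of (gene_id, family, chromosome, rank, start).
    Returns the set of frozensets of gene_ids with component size >= 2.
    """
    parent = {g[0]: g[0] for g in genes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(genes, 2):
        if a[1] != b[1] or a[2] != b[2]:
            continue
        if abs(a[3] - b[3]) > max_gene_gap:
            continue
        if abs(a[4] - b[4]) > max_bp:
            continue
        parent[find(a[0])] = find(b[0])

    comps = {}
    for g in genes:
        comps.setdefault(find(g[0]), set()).add(g[0])
    return {frozenset(c) for c in comps.values() if len(c) >= 2}
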