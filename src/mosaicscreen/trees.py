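"""Tree engine: neighbor joining, bootstrap supports, newick I/O, queries.

Trees are held as :class:`PhyloTree`, a thin wrapper around a
:class:`dendropy.Tree` plus a tag saying which scale the internal-edge
supports live on (``bootstrap_pct`` in [0, 100] or ``posterior`` in [0, 1]).
Supports are stored as a ``support`` attribute on internal nodes and written
to newick as internal node labels, the dominant convention in the wild.

Neighbor joining is the Saitou-Nei agglomeration: repeatedly join the pair
minimising ``Q(i,j) = (m-2) d(i,j) - r(i) - r(j)``, assign pendant lengths by
the three-point formulas, and reduce the matrix with
``d(u,k) = (d(i,k) + d(j,k) - d(i,j)) / 2``.  On an additive matrix this
recovers the generating topology and branch lengths exactly.  Two
determinism rules keep runs bit-reproducible: Q-ties are broken by the
lexicographically smallest pair of cluster representatives, and negative
branch-length estimates are clamped to zero with the deficit moved to the
sibling edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import dendropy
import numpy as np

from .errors import (
    ConfigError,
    InvalidMatrixError,
    InvalidTaxaSetError,
    UnknownTaxonError,
)
from .msa import Alignment, SATURATION_P, p_distance_matrix, poisson_correct

__all__ = [
    "PhyloTree",
    "BOOTSTRAP_PCT",
    "POSTERIOR",
    "read_newick",
    "write_newick",
    "neighbor_joining",
    "bootstrap_supports",
    "patristic_distance",
    "distances_from_leaf",
    "collapse_single_genus_clades",
    "supported_bipartition",
    "reroot_on_clade",
    "set_all_supports",
]

BOOTSTRAP_PCT = "bootstrap_pct"
POSTERIOR = "posterior"

_SCALE_RANGE = {BOOTSTRAP_PCT: (0.0, 100.0), POSTERIOR: (0.0, 1.0)}


@dataclass
class PhyloTree:
    """Leaf-labelled tree with branch lengths and per-edge supports."""

    tree: dendropy.Tree
    support_scale: str = BOOTSTRAP_PCT

    def __post_init__(self):
        if self.support_scale not in _SCALE_RANGE:
            raise ConfigError(f"unknown support scale {self.support_scale!r}")

    # -- basic queries ------------------------------------------------------

    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def leaf_node(self, label: str) -> dendropy.Node:
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon.label == label:
                return leaf
        raise UnknownTaxonError(label)

    def is_rooted(self) -> bool:
        return bool(self.tree.is_rooted)

    def copy(self) -> "PhyloTree":
        return read_newick(write_newick(self), support_scale=self.support_scale,
                           rooted=self.is_rooted())

    def bipartition_supports(self) -> dict[frozenset, float | None]:
        """Internal bipartitions keyed by their canonical side."""
        leaves = frozenset(self.leaf_labels())
        ref = min(leaves)
        out: dict[frozenset, float | None] = {}
        for node, side in _internal_sides(self.tree, leaves):
            key = side if ref not in side else leaves - side
            prev = out.get(key)
            support = getattr(node, "support", None)
            out[key] = support if prev is None else prev
        return out


def _leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset]:
    sets: dict[dendropy.Node, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset((node.taxon.label,))
        else:
            sets[node] = frozenset().union(*(sets[c] for c in node.child_nodes()))
    return sets


def _internal_sides(tree: dendropy.Tree, leaves: frozenset):
    """Yield (node, leafset-below) for nodes defining internal bipartitions."""
    n = len(leaves)
    sets = _leafsets(tree)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = sets[node]
        if 2 <= len(side) <= n - 2:
            yield node, side


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _format_support(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return format(v, "g")


def read_newick(source: str | Path, support_scale: str = BOOTSTRAP_PCT,
                rooted: bool | None = None) -> PhyloTree:
    """Parse newick; numeric internal node labels become edge supports.

    ``source`` may be a newick string or a path to a file.  The support scale
    is declared out-of-band (both 0-1 and 0-100 conventions occur in the
    wild); default is bootstrap percentages.
    """
    text = source
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "(" not in source):
        text = Path(source).read_text(encoding="utf-8")
    tree = dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    lo, hi = _SCALE_RANGE.get(support_scale, (0.0, 100.0))
    for node in tree.preorder_node_iter():
        support = None
        if not node.is_leaf() and node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                support = None
        if support is not None and not (lo <= support <= hi):
            raise ConfigError(
                f"support {support} outside {support_scale} range [{lo}, {hi}]")
        node.support = support
        node.label = None
    if rooted is not None:
        tree.is_rooted = rooted
    return PhyloTree(tree=tree, support_scale=support_scale)


def write_newick(pt: PhyloTree, dest: str | Path | None = None) -> str:
    """Serialise with supports as internal node labels; round-trip stable."""
    tree = pt.tree
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        support = getattr(node, "support", None)
        node.label = _format_support(support) if support is not None else None
    text = tree.as_string(schema="newick", unquoted_underscores=True,
                          suppress_rooting=True,
                          real_value_format_specifier=".17g")
    text = text.strip() + "\n"
    if dest is not None:
        Path(dest).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm) -> PhyloTree:
    """Saitou-Nei NJ on a distance matrix (skbio ``DistanceMatrix`` or
    ``(labels, square ndarray)``); returns an unrooted tree over all labels."""
    if isinstance(dm, tuple):
        labels, data = list(dm[0]), np.asarray(dm[1], dtype=float)
    else:
        labels, data = list(dm.ids), np.asarray(dm.data, dtype=float)
    if data.ndim != 2 or data.shape[0] != data.shape[1] or data.shape[0] != len(labels):
        raise InvalidMatrixError(f"matrix shape {data.shape} does not match "
                                 f"{len(labels)} labels")
    if np.isnan(data).any():
        raise InvalidMatrixError("distance matrix contains NaN")
    if not np.allclose(data, data.T, atol=1e-12, rtol=0.0):
        raise InvalidMatrixError("distance matrix is not symmetric")
    if len(labels) < 2:
        raise InvalidMatrixError("need at least two labels")
    return PhyloTree(tree=_nj_core(labels, data), support_scale=BOOTSTRAP_PCT)


def _nj_core(labels: Sequence[str], data: np.ndarray) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace()
    n0 = len(labels)
    nodes: list[dendropy.Node | None] = []
    for label in labels:
        taxon = dendropy.Taxon(label=label)
        ns.add_taxon(taxon)
        node = dendropy.Node(taxon=taxon)
        node.support = None
        nodes.append(node)
    reps = list(labels)
    D = np.array(data, dtype=float)
    active = list(range(n0))

    while len(active) > 3:
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        m = len(active)
        r = sub.sum(axis=1)
        # r_i + r_j first: keeps Q bit-symmetric so mirror ties stay paired
        Q = (m - 2) * sub - (r[:, None] + r[None, :])
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q == qmin)
        best = min(
            ((a, b) for a, b in ties if a < b),
            key=lambda ab: tuple(sorted((reps[idx[ab[0]]], reps[idx[ab[1]]]))),
        )
        a, b = best
        ga, gb = idx[a], idx[b]
        dab = sub[a, b]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        if la < 0.0:
            la, lb = 0.0, dab
        elif lb < 0.0:
            la, lb = dab, 0.0
        parent = dendropy.Node()
        parent.support = None
        parent.add_child(nodes[ga])
        parent.add_child(nodes[gb])
        nodes[ga].edge.length = la
        nodes[gb].edge.length = lb
        # reduce: reuse slot ga for the merged cluster, retire gb
        rest = idx[(idx != ga) & (idx != gb)]
        dnew = 0.5 * (D[ga, rest] + D[gb, rest] - dab)
        np.maximum(dnew, 0.0, out=dnew)
        D[ga, rest] = dnew
        D[rest, ga] = dnew
        D[ga, ga] = 0.0
        nodes[ga] = parent
        nodes[gb] = None
        reps[ga] = min(reps[ga], reps[gb])
        active.remove(gb)

    center = dendropy.Node()
    center.support = None
    if len(active) == 3:
        a, b, c = active
        la = max(0.0, 0.5 * (D[a, b] + D[a, c] - D[b, c]))
        lb = max(0.0, 0.5 * (D[a, b] + D[b, c] - D[a, c]))
        lc = max(0.0, 0.5 * (D[a, c] + D[b, c] - D[a, b]))
        for g, length in ((a, la), (b, lb), (c, lc)):
            center.add_child(nodes[g])
            nodes[g].edge.length = length
    elif len(active) == 2:
        a, b = active
        half = D[a, b] / 2.0
        for g in (a, b):
            center.add_child(nodes[g])
            nodes[g].edge.length = half
    else:  # single taxon: degenerate, but keep total
        center.add_child(nodes[active[0]])
        nodes[active[0]].edge.length = 0.0

    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _bipartition_keys(tree: dendropy.Tree, bit_of: dict[str, int],
                      full_mask: int, ref_bit: int, n: int) -> set[int]:
    keys: set[int] = set()
    masks: dict[dendropy.Node, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[node] = bit_of[node.taxon.label]
        else:
            m = 0
            for c in node.child_nodes():
                m |= masks[c]
            masks[node] = m
            if node is tree.seed_node:
                continue
            size = m.bit_count()
            if 2 <= size <= n - 2:
                keys.add(m if not (m & ref_bit) else full_mask ^ m)
    return keys


def bootstrap_supports(aln: Alignment, n_reps: int,
                       model: Literal["p_distance", "poisson"] = "poisson",
                       seed: int = 0) -> PhyloTree:
    """NJ point tree with column-resampling bootstrap supports.

    Builds the point-estimate tree from the full alignment, then ``n_reps``
    trees from alignments whose columns are resampled with replacement (same
    length); each internal edge's support is the percentage of replicates
    containing the same leaf bipartition.  Deterministic given ``seed``.

    Replicate pairs that lose all comparable columns in the resampling are
    treated as saturated (capped distance) rather than aborting the replicate.
    """
    if n_reps < 1:
        raise ConfigError(f"n_reps must be >= 1, got {n_reps}")
    if model not in ("p_distance", "poisson"):
        raise ConfigError(f"unknown distance model {model!r}")
    from .msa import pairwise_distance  # local import to avoid cycle at import time

    labels = list(aln.ids)
    point = neighbor_joining(pairwise_distance(aln, model=model))

    order = sorted(labels)
    bit_of = {label: 1 << i for i, label in enumerate(order)}
    full_mask = (1 << len(order)) - 1
    ref_bit = bit_of[order[0]]
    n = len(order)

    rng = np.random.default_rng(seed)
    counts: dict[int, int] = {}
    L = aln.n_cols
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        p, n_comp = p_distance_matrix(aln.matrix[:, cols])
        p = np.where(np.isnan(p), SATURATION_P, p)
        d = p if model == "p_distance" else poisson_correct(p)
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        rep_tree = _nj_core(labels, d)
        for key in _bipartition_keys(rep_tree, bit_of, full_mask, ref_bit, n):
            counts[key] = counts.get(key, 0) + 1

    leaves = frozenset(labels)
    for node, side in _internal_sides(point.tree, leaves):
        mask = 0
        for label in side:
            mask |= bit_of[label]
        if mask & ref_bit:
            mask = full_mask ^ mask
        node.support = 100.0 * counts.get(mask, 0) / n_reps
    return point


# ---------------------------------------------------------------------------
# Distance queries
# ---------------------------------------------------------------------------

def distances_from_leaf(pt: PhyloTree, label: str) -> dict[str, float]:
    """Patristic distance from one leaf to every leaf (including itself)."""
    start = pt.leaf_node(label)
    dist: dict[dendropy.Node, float] = {start: 0.0}
    stack = [start]
    while stack:
        node = stack.pop()
        neighbours: list[tuple[dendropy.Node, float]] = []
        if node.parent_node is not None:
            neighbours.append((node.parent_node, node.edge.length or 0.0))
        for child in node.child_nodes():
            neighbours.append((child, child.edge.length or 0.0))
        for other, length in neighbours:
            if other not in dist:
                dist[other] = dist[node] + length
                stack.append(other)
    return {leaf.taxon.label: dist[leaf] for leaf in pt.tree.leaf_node_iter()}


def patristic_distance(pt: PhyloTree, a: str, b: str) -> float:
    """Sum of branch lengths on the unique path between two leaves."""
    if a == b:
        pt.leaf_node(a)  # existence check
        return 0.0
    node_a = pt.leaf_node(a)
    node_b = pt.leaf_node(b)
    # climb from a, recording cumulative lengths to each ancestor
    up: dict[dendropy.Node, float] = {}
    node, acc = node_a, 0.0
    while node is not None:
        up[node] = acc
        acc += node.edge.length or 0.0
        node = node.parent_node
    node, acc = node_b, 0.0
    while node not in up:
        acc += node.edge.length or 0.0
        node = node.parent_node
    return acc + up[node]


# ---------------------------------------------------------------------------
# Single-genus collapsing
# ---------------------------------------------------------------------------

def collapse_single_genus_clades(pt: PhyloTree, taxonomy,
                                 protected: Iterable[str] = ()) -> PhyloTree:
    """Collapse monophyletic single-genus clades to one representative leaf.

    Clades are read on the side of each bipartition away from the protected
    set (the query); within an eligible clade the lexicographically smallest
    leaf is kept.  Pruning repeats until a fixpoint: collapsing one clade can
    expose a larger single-genus clade.  Protected leaves are never pruned.
    """
    work = pt.copy()
    leaves = set(work.leaf_labels())
    for label in leaves:
        taxonomy.entry(label)  # raises UnknownTaxonError on unregistered leaf
    protected_set = set(protected) & leaves
    ref = min(protected_set) if protected_set else min(leaves)
    # orient the tree away from the reference so 'clade' is well-defined
    ref_node = work.leaf_node(ref)
    length = ref_node.edge.length or 0.0
    work.tree.reroot_at_edge(ref_node.edge, length1=length / 2.0,
                             length2=length / 2.0, update_bipartitions=False)
    work.tree.is_rooted = True

    genus = {label: taxonomy.genus_of(label) for label in leaves}
    while True:
        sets = _leafsets(work.tree)
        to_prune: set[str] = set()
        stack = list(work.tree.seed_node.child_nodes())
        while stack:
            node = stack.pop()
            if node.is_leaf():
                continue
            below = sets[node]
            genera = {genus[l] for l in below}
            if len(genera) == 1 and not (below & protected_set):
                keep = min(below)
                to_prune |= below - {keep}
                continue  # maximal clade found; do not descend
            stack.extend(node.child_nodes())
        if not to_prune:
            break
        work.tree.prune_taxa_with_labels(sorted(to_prune),
                                         suppress_unifurcations=True)
    _deroot(work.tree)
    work.tree.is_rooted = pt.is_rooted()
    return work


def _deroot(tree: dendropy.Tree) -> None:
    """Collapse a degree-2 seed node so the tree is properly unrooted."""
    seed = tree.seed_node
    children = seed.child_nodes()
    if len(children) != 2:
        return
    # merge the two seed edges into one, hanging one child under the other
    a, b = children
    if a.is_leaf() and b.is_leaf():
        return  # two-taxon tree: nothing sensible to collapse
    new_seed = a if not a.is_leaf() else b
    other = b if new_seed is a else a
    total = (a.edge.length or 0.0) + (b.edge.length or 0.0)
    seed.remove_child(a)
    seed.remove_child(b)
    new_seed.add_child(other)
    other.edge.length = total
    tree.seed_node = new_seed
    new_seed.edge.length = None


# ---------------------------------------------------------------------------
# Supported monophyly
# ---------------------------------------------------------------------------

def supported_bipartition(pt: PhyloTree, taxa: Iterable[str],
                          min_support: float
                          ) -> Literal["present", "present_unsupported", "absent"]:
    """Does an internal edge split off exactly ``taxa``, and how supported?

    ``present`` requires the edge to exist with support >= ``min_support``
    (inclusive boundary: a support exactly at the threshold passes) on the
    tree's own scale.  Singleton sets are trivially monophyletic with maximal
    support.  Edges that exist without a recorded support are
    ``present_unsupported``.
    """
    leaves = frozenset(pt.leaf_labels())
    taxa_set = frozenset(taxa)
    if not taxa_set or not taxa_set < leaves:
        raise InvalidTaxaSetError(
            "taxa must be a non-empty proper subset of the leaf set")
    n = len(leaves)
    if len(taxa_set) in (1, n - 1):
        return "present"  # pendant edge; trivially monophyletic
    complement = leaves - taxa_set
    for node, side in _internal_sides(pt.tree, leaves):
        if side == taxa_set or side == complement:
            support = getattr(node, "support", None)
            if support is None:
                return "present_unsupported"
            return "present" if support >= min_support else "present_unsupported"
    return "absent"


# ---------------------------------------------------------------------------
# Rooting / helpers
# ---------------------------------------------------------------------------

def reroot_on_clade(pt: PhyloTree, side_labels: Iterable[str]) -> PhyloTree:
    """Root a copy of the tree on the edge separating ``side_labels``.

    The edge length is split evenly across the two new root edges; supports
    survive via their bipartitions, which rerooting does not change.
    """
    side = frozenset(side_labels)
    leaves = frozenset(pt.leaf_labels())
    if not side or not side <= leaves:
        raise InvalidTaxaSetError("rooting side must be a subset of the leaves")
    supports = pt.bipartition_supports()
    work = pt.copy()
    sets = _leafsets(work.tree)
    target = None
    for node in work.tree.preorder_node_iter():
        if node is work.tree.seed_node:
            continue
        if sets[node] == side or sets[node] == leaves - side:
            target = node
            break
    if target is None:
        raise InvalidTaxaSetError(f"no edge separates {sorted(side)}")
    length = target.edge.length or 0.0
    work.tree.reroot_at_edge(target.edge, length1=length / 2.0,
                             length2=length / 2.0, update_bipartitions=False)
    work.tree.is_rooted = True
    # restore supports by bipartition key
    ref = min(leaves)
    for node, node_side in _internal_sides(work.tree, leaves):
        key = node_side if ref not in node_side else leaves - node_side
        node.support = supports.get(key)
    return work


def set_all_supports(pt: PhyloTree, value: float | None) -> PhyloTree:
    """Return a copy with every internal edge support set to ``value``."""
    out = pt.copy()
    leaves = frozenset(out.leaf_labels())
    for node, _side in _internal_sides(out.tree, leaves):
        node.support = value
    return out
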