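"""Topology classification of supported gene trees into transfer categories.

A gene tree for a *Euglena gracilis* query is sorted into one of:

``CR_RED``
    the query sits in a supported clade with Chromalveolata+Rhizaria (CR)
    members whose red-algal affiliation is established either inside the
    clade (red algae nested with the CR members) or by a supported sister
    group composed of red algae;
``CR_GREEN``
    the supported query+CR clade is sister to a green (algae/plant) clade;
``RED_OTHER``
    the query+CR clade is supported but its sister is mixed, unsupported,
    or otherwise unclear;
``GREEN``
    no red-lineage affiliation, but the query sits in a supported clade of
    green algae/plants only (the expected signal of the green secondary
    endosymbiont);
``UNCLASSIFIED``
    everything else, including query+red clades with no CR member (the
    triose-phosphate isomerase situation, deliberately not designated a
    'red lineage' gene).

Monophyly calls use the either-or support rule: a clade passes at >= 70 on
bootstrap-scaled trees or >= 0.9 on posterior-scaled trees, boundaries
inclusive; a single tree carries one scale.  Where the original screen relied
on manual topology checks, the rules here are explicit and deterministic, and
every decision records the supporting edge so a human can audit the call.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import NoOutgroupError, UnknownTaxonError
from .taxonomy import LineageGroup, TaxonomyMap
from .trees import BOOTSTRAP_PCT, PhyloTree, _leafsets, reroot_on_clade

__all__ = [
    "Category",
    "ClassifyConfig",
    "GeneClassification",
    "TableSummary",
    "root_tree",
    "red_lineage_monophyly",
    "classify_gene_tree",
    "peranema_coclade",
    "summarize_table",
]

#: groups allowed inside a 'red lineage' defining clade alongside the query
_RED_CLADE_GROUPS = frozenset({LineageGroup.CR, LineageGroup.RED,
                               LineageGroup.EUGLENID})


class Category(str, enum.Enum):
    CR_RED = "CR_RED"
    CR_GREEN = "CR_GREEN"
    RED_OTHER = "RED_OTHER"
    GREEN = "GREEN"
    UNCLASSIFIED = "UNCLASSIFIED"


RED_LINEAGE_CATEGORIES = frozenset({Category.CR_RED, Category.CR_GREEN,
                                    Category.RED_OTHER})


@dataclass(frozen=True)
class ClassifyConfig:
    """Thresholds and rooting preferences for topology classification.

    ``min_bootstrap``/``min_posterior`` are the monophyly acceptance
    thresholds on their respective scales.  ``outgroup_groups`` is an ordered
    preference list for rooting; the first group present in a tree wins.
    ``sister_majority`` is the fraction of sister-clade leaves that must
    belong to RED (or GREEN) before the sister is labelled as such; sisters
    below the majority are 'unclear'.
    """

    min_bootstrap: float = 70.0
    min_posterior: float = 0.9
    outgroup_groups: tuple[LineageGroup, ...] = (
        LineageGroup.CYANOBACTERIA,
        LineageGroup.OTHER_BACTERIA,
        LineageGroup.UNIKONT,
    )
    sister_majority: float = 0.8

    def threshold_for(self, scale: str) -> float:
        return self.min_bootstrap if scale == BOOTSTRAP_PCT else self.min_posterior


@dataclass
class GeneClassification:
    gene_id: str
    category: Category
    defining_support: float | None
    support_scale: str
    root_group_used: LineageGroup | None
    peranema_in_clade: bool
    defining_clade: frozenset[str]
    notes: str = ""


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def root_tree(pt: PhyloTree, taxonomy: TaxonomyMap,
              cfg: ClassifyConfig | None = None) -> tuple[PhyloTree, LineageGroup]:
    """Root on the edge subtending the maximal clade of the preferred outgroup.

    Walks ``cfg.outgroup_groups`` in order; the first group with any leaf in
    the tree is used.  Among the bipartition sides composed purely of that
    group, the largest (ties: lexicographically smallest) becomes the
    outgroup clade.  Raises :class:`NoOutgroupError` if no listed group is
    represented at all.
    """
    cfg = cfg or ClassifyConfig()
    leaves = frozenset(pt.leaf_labels())
    groups = {label: taxonomy.group_of(label) for label in leaves}
    for og in cfg.outgroup_groups:
        members = frozenset(l for l in leaves if groups[l] is og)
        if not members:
            continue
        candidates = [frozenset((l,)) for l in members]
        sets = _leafsets(pt.tree)
        for node in pt.tree.preorder_node_iter():
            if node is pt.tree.seed_node or node.is_leaf():
                continue
            side = sets[node]
            for part in (side, leaves - side):
                if part and part <= members:
                    candidates.append(part)
        best = sorted(candidates, key=lambda s: (-len(s), min(s)))[0]
        rooted = reroot_on_clade(pt, best)
        return rooted, og
    raise NoOutgroupError(
        f"no outgroup group {[g.value for g in cfg.outgroup_groups]} in tree")


# ---------------------------------------------------------------------------
# Red-lineage monophyly
# ---------------------------------------------------------------------------

def _clade_walk(rooted: PhyloTree, query: str):
    """Yield (node, leafset) for query ancestors, smallest clade first."""
    sets = _leafsets(rooted.tree)
    node = rooted.leaf_node(query).parent_node
    while node is not None and node is not rooted.tree.seed_node:
        yield node, sets[node]
        node = node.parent_node


def red_lineage_monophyly(rooted: PhyloTree, query: str, taxonomy: TaxonomyMap,
                          cfg: ClassifyConfig | None = None
                          ) -> tuple[bool, float | None, frozenset[str] | None]:
    """Is the query in a supported clade of red-lineage (CR/red) sequences?

    Walks the query's ancestors while the clade's other members stay within
    {CR, RED, EUGLENID}; among those, the *largest* clade that contains at
    least one CR or red-algal member and whose subtending edge meets the
    support threshold is the defining clade.  Taking the largest qualifying
    clade (rather than the smallest) makes the call robust to queries nested
    deep inside the CR assemblage, where the smallest supported clade's
    sister is simply more CR.
    """
    cfg = cfg or ClassifyConfig()
    thr = cfg.threshold_for(rooted.support_scale)
    best: tuple[float, frozenset[str]] | None = None
    for node, clade in _clade_walk(rooted, query):
        others = clade - {query}
        groups = {taxonomy.group_of(l) for l in others}
        if not groups <= _RED_CLADE_GROUPS:
            break
        has_evidence = bool(groups & {LineageGroup.CR, LineageGroup.RED})
        support = getattr(node, "support", None)
        if has_evidence and support is not None and support >= thr:
            best = (support, clade)
    if best is None:
        return False, None, None
    return True, best[0], best[1]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _group_fractions(labels: Iterable[str], taxonomy: TaxonomyMap
                     ) -> dict[LineageGroup, float]:
    labels = list(labels)
    out: dict[LineageGroup, float] = {}
    for label in labels:
        g = taxonomy.group_of(label)
        out[g] = out.get(g, 0.0) + 1.0
    return {g: c / len(labels) for g, c in out.items()}


def classify_gene_tree(pt: PhyloTree, query: str, taxonomy: TaxonomyMap,
                       cfg: ClassifyConfig | None = None,
                       gene_id: str | None = None) -> GeneClassification:
    """Classify one supported gene tree for one query sequence."""
    cfg = cfg or ClassifyConfig()
    gene_id = gene_id if gene_id is not None else query
    leaves = pt.leaf_labels()
    if query not in leaves:
        raise UnknownTaxonError(query)
    if len(leaves) < 4:
        raise ValueError(f"tree has {len(leaves)} leaves; need >= 4")
    thr = cfg.threshold_for(pt.support_scale)
    rooted, root_group = root_tree(pt, taxonomy, cfg)

    ok, support, clade = red_lineage_monophyly(rooted, query, taxonomy, cfg)
    if ok:
        return _classify_red(rooted, query, taxonomy, cfg, gene_id,
                             support, clade, root_group, thr)

    # no red-lineage affiliation: is the query in a supported green clade?
    for node, walk_clade in _clade_walk(rooted, query):
        others = walk_clade - {query}
        groups = {taxonomy.group_of(l) for l in others}
        if groups <= {LineageGroup.EUGLENID}:
            continue  # not yet a mixed clade; keep walking
        node_support = getattr(node, "support", None)
        if node_support is None or node_support < thr:
            continue  # smallest *supported* mixed clade decides
        if groups <= {LineageGroup.GREEN, LineageGroup.EUGLENID}:
            return GeneClassification(
                gene_id=gene_id, category=Category.GREEN,
                defining_support=node_support, support_scale=pt.support_scale,
                root_group_used=root_group, peranema_in_clade=False,
                defining_clade=frozenset(walk_clade),
                notes="query in supported green clade")
        break
    return GeneClassification(
        gene_id=gene_id, category=Category.UNCLASSIFIED,
        defining_support=None, support_scale=pt.support_scale,
        root_group_used=root_group, peranema_in_clade=False,
        defining_clade=frozenset(), notes="no supported algal affiliation")


def _classify_red(rooted: PhyloTree, query: str, taxonomy: TaxonomyMap,
                  cfg: ClassifyConfig, gene_id: str, support: float,
                  clade: frozenset[str], root_group: LineageGroup,
                  thr: float) -> GeneClassification:
    groups_in = {taxonomy.group_of(l) for l in clade - {query}}
    peranema = peranema_coclade(clade, taxonomy)
    common = dict(gene_id=gene_id, defining_support=support,
                  support_scale=rooted.support_scale,
                  root_group_used=root_group, peranema_in_clade=peranema,
                  defining_clade=clade)

    if LineageGroup.CR not in groups_in:
        # red-algae-only association (the TIM pattern): not designated
        return GeneClassification(
            category=Category.UNCLASSIFIED, **{**common,
            "peranema_in_clade": False, "notes":
            "query monophyletic with red algae but no CR member; "
            "not designated a red-lineage gene"})

    if LineageGroup.RED in groups_in:
        return GeneClassification(
            category=Category.CR_RED, **common,
            notes="red algae nested with CR members inside the defining clade")

    # defining clade is query+CR only: adjudicate by the sister group
    sets = _leafsets(rooted.tree)
    node = rooted.leaf_node(query).parent_node
    while node is not None and sets[node] != clade:
        node = node.parent_node
    parent = node.parent_node
    sister = frozenset().union(*(sets[c] for c in parent.child_nodes()
                                 if c is not node))
    parent_support = getattr(parent, "support", None)
    sister_supported = (parent is rooted.tree.seed_node
                        or (parent_support is not None and parent_support >= thr))
    frac = _group_fractions(sister, taxonomy)
    if sister_supported and frac.get(LineageGroup.RED, 0.0) >= cfg.sister_majority:
        return GeneClassification(
            category=Category.CR_RED, **common,
            notes=f"sister clade {frac.get(LineageGroup.RED, 0):.0%} red algae")
    if sister_supported and frac.get(LineageGroup.GREEN, 0.0) >= cfg.sister_majority:
        return GeneClassification(
            category=Category.CR_GREEN, **common,
            notes=f"sister clade {frac.get(LineageGroup.GREEN, 0):.0%} green")
    why = "unsupported" if not sister_supported else "mixed/unclear composition"
    return GeneClassification(
        category=Category.RED_OTHER, **common,
        notes=f"sister group of the euglenid+CR clade is {why}")


def peranema_coclade(clade: Iterable[str], taxonomy: TaxonomyMap) -> bool:
    """True iff the clade contains an OTU of the eukaryovorous genus Peranema."""
    return any(taxonomy.genus_of(l) == "Peranema" for l in clade)


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

@dataclass
class TableSummary:
    counts: dict[Category, int]
    genes: dict[Category, list[str]]
    peranema_count: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_dict(self) -> dict:
        return {
            "counts": {c.value: self.counts[c] for c in Category},
            "genes": {c.value: self.genes[c] for c in Category},
            "peranema_count": self.peranema_count,
            "total": self.total,
        }


def summarize_table(classifications: Sequence[GeneClassification]) -> TableSummary:
    """Per-category gene counts and the Peranema co-occurrence tally."""
    counts = {c: 0 for c in Category}
    genes: dict[Category, list[str]] = {c: [] for c in Category}
    peranema = 0
    for cl in classifications:
        counts[cl.category] += 1
        genes[cl.category].append(cl.gene_id)
        if cl.peranema_in_clade:
            peranema += 1
    return TableSummary(counts=counts, genes=genes, peranema_count=peranema)
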