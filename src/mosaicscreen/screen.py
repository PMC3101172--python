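"""Stage-1 screen: E-value gates, per-gene trees, closest-lineage reports.

The original gene-mining pipeline ran two similarity filters before any tree
was built: a gene entered the screen only if it had a green-plant hit with
E-value strictly below 1e-5, and its homologue set was the hits with E-value
strictly below 0.001, capped at 500.  Both inequalities are strict, matching
the screen's stated thresholds.  Hit tables are consumed, never produced:
running BLAST is out of scope.

After trimming and bootstrapped NJ inference, single-genus clades are
collapsed to one representative and the lineage group of the leaf
patristically closest to the query is reported, excluding the query's own
group so conspecific or congeneric sequences cannot mask the signal.  The
tallies count the nearest single OTU, not a nearest-clade majority; report
files say so in their header.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, NoEligibleTaxonError, StageError
from .msa import Alignment, drop_gappy_taxa, read_fasta, trim_gappy_columns
from .taxonomy import LineageGroup, TaxonomyMap
from .trees import (PhyloTree, bootstrap_supports, collapse_single_genus_clades,
                    distances_from_leaf, write_newick)

__all__ = [
    "HitRecord",
    "ScreenConfig",
    "ClosestTaxonReport",
    "ScreenResult",
    "read_hit_table",
    "stage1_gate",
    "stage2_select",
    "closest_taxon",
    "tally_by_group",
    "analyze_family",
    "screen_alignments",
    "reports_to_tsv",
    "tally_to_tsv",
]


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    evalue: float
    subject_group: LineageGroup

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue}")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and inference settings for the screen.

    The E-value defaults are the screen's two published gates (first step
    strictly below 1e-5 against green plants, second step strictly below
    0.001 with at most 500 homologues).  Trimming removes columns over 50%
    gaps, then rows over 75% gaps; both fractions are surfaced here because
    'indel-rich' has no canonical definition.
    """

    stage1_evalue_max: float = 1e-5
    stage2_evalue_max: float = 1e-3
    max_hits: int = 500
    n_bootstrap: int = 100
    col_max_gap_frac: float = 0.5
    taxon_max_gap_frac: float = 0.75
    distance_model: str = "poisson"
    seed: int = 0

    def __post_init__(self):
        if self.stage1_evalue_max <= 0 or self.stage2_evalue_max <= 0:
            raise ConfigError("E-value thresholds must be positive")
        if self.max_hits < 4:
            raise ConfigError(f"max_hits must be >= 4, got {self.max_hits}")
        if self.n_bootstrap < 1:
            raise ConfigError("n_bootstrap must be >= 1")
        if self.distance_model not in ("p_distance", "poisson"):
            raise ConfigError(f"unknown distance model {self.distance_model!r}")


@dataclass(frozen=True)
class ClosestTaxonReport:
    query_id: str
    closest_otu: str
    closest_group: LineageGroup
    distance: float
    tied_otus: tuple[str, ...] = ()


@dataclass
class ScreenResult:
    gene_id: str
    alignment: Alignment            # after trimming
    supported_tree: PhyloTree       # full bootstrapped NJ tree
    collapsed_tree: PhyloTree       # after single-genus collapsing
    closest: ClosestTaxonReport


# ---------------------------------------------------------------------------
# Hit-table gates
# ---------------------------------------------------------------------------

def read_hit_table(source: str | Path | io.TextIOBase,
                   taxonomy: TaxonomyMap) -> list[HitRecord]:
    """TSV with columns query_id, subject_id, evalue; groups from taxonomy."""
    df = pd.read_csv(source, sep="\t", comment="#",
                     dtype={"query_id": str, "subject_id": str})
    return [
        HitRecord(query_id=row.query_id, subject_id=row.subject_id,
                  evalue=float(row.evalue),
                  subject_group=taxonomy.group_of(row.subject_id))
        for row in df.itertuples()
    ]


def _single_query(hits: Sequence[HitRecord]) -> None:
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hit list mixes queries: {sorted(queries)}")


def stage1_gate(hits: Sequence[HitRecord], cfg: ScreenConfig) -> bool:
    """First screening gate: a green-plant hit strictly below the threshold."""
    _single_query(hits)
    return any(h.subject_group is LineageGroup.GREEN
               and h.evalue < cfg.stage1_evalue_max for h in hits)


def stage2_select(hits: Sequence[HitRecord],
                  cfg: ScreenConfig) -> list[HitRecord]:
    """Homologue selection: E-value strictly below threshold, capped count."""
    _single_query(hits)
    kept = [h for h in hits if h.evalue < cfg.stage2_evalue_max]
    kept.sort(key=lambda h: (h.evalue, h.subject_id))
    return kept[: cfg.max_hits]


# ---------------------------------------------------------------------------
# Closest-taxon scan
# ---------------------------------------------------------------------------

def closest_taxon(tree: PhyloTree, query: str, taxonomy: TaxonomyMap,
                  exclude_groups: Iterable[LineageGroup] = (
                      LineageGroup.EUGLENID,)) -> ClosestTaxonReport:
    """Leaf minimising patristic distance to the query.

    Leaves whose group is excluded (by default the query's own euglenid
    group) are ignored.  Exact distance ties are all recorded and broken
    lexicographically.
    """
    excluded = frozenset(exclude_groups)
    dist = distances_from_leaf(tree, query)
    eligible = {l: d for l, d in dist.items()
                if l != query and taxonomy.group_of(l) not in excluded}
    if not eligible:
        raise NoEligibleTaxonError(
            f"no non-excluded leaf besides the query {query!r}")
    dmin = min(eligible.values())
    tied = sorted(l for l, d in eligible.items() if d == dmin)
    return ClosestTaxonReport(
        query_id=query, closest_otu=tied[0],
        closest_group=taxonomy.group_of(tied[0]), distance=dmin,
        tied_otus=tuple(tied) if len(tied) > 1 else ())


def tally_by_group(reports: Iterable[ClosestTaxonReport]
                   ) -> dict[LineageGroup, int]:
    """Gene counts per closest lineage group; every group present."""
    tally = {g: 0 for g in LineageGroup}
    for rep in reports:
        tally[rep.closest_group] += 1
    return tally


# ---------------------------------------------------------------------------
# Per-gene analysis
# ---------------------------------------------------------------------------

def _gene_seed(base_seed: int, gene_id: str) -> int:
    return (base_seed ^ zlib.crc32(gene_id.encode("utf-8"))) & 0x7FFFFFFF


def analyze_family(aln: Alignment, query: str, taxonomy: TaxonomyMap,
                   cfg: ScreenConfig | None = None,
                   gene_id: str | None = None) -> ScreenResult:
    """Trim, infer the bootstrapped NJ tree, collapse, and scan one family.

    Order of operations: gap-rich columns are removed first, then gap-rich
    taxa (never the query); supports are computed on the full tree; the
    single-genus collapse happens afterwards and the patristic scan runs on
    the collapsed tree.
    """
    cfg = cfg or ScreenConfig()
    gene_id = gene_id or query
    trimmed = trim_gappy_columns(aln, cfg.col_max_gap_frac)
    trimmed = drop_gappy_taxa(trimmed, cfg.taxon_max_gap_frac, query=query)
    tree = bootstrap_supports(trimmed, cfg.n_bootstrap,
                              model=cfg.distance_model,
                              seed=_gene_seed(cfg.seed, gene_id))
    collapsed = collapse_single_genus_clades(tree, taxonomy,
                                             protected={query})
    closest = closest_taxon(collapsed, query, taxonomy)
    return ScreenResult(gene_id=gene_id, alignment=trimmed,
                        supported_tree=tree, collapsed_tree=collapsed,
                        closest=closest)


def screen_alignments(alignments: Mapping[str, Alignment] | str | Path,
                      taxonomy: TaxonomyMap, cfg: ScreenConfig | None = None,
                      query_prefix: str = "Euglena",
                      out_dir: str | Path | None = None,
                      logger=None) -> list[ScreenResult]:
    """Screen a set of per-gene alignments (mapping or directory of FASTA).

    Each gene's query row is the first OTU whose label starts with
    ``query_prefix``.  Results are returned sorted by gene id; when
    ``out_dir`` is given, per-gene newick trees plus report and tally TSVs
    are written there.  Genes that fail (no query row, too few taxa) raise
    :class:`StageError` unless a logger is provided, in which case they are
    logged and skipped.
    """
    cfg = cfg or ScreenConfig()
    if not isinstance(alignments, Mapping):
        aln_dir = Path(alignments)
        files = sorted(aln_dir.glob("*.fasta")) + sorted(aln_dir.glob("*.fa"))
        alignments = {f.stem: read_fasta(f) for f in files}
    results: list[ScreenResult] = []
    for gene_id in sorted(alignments):
        aln = alignments[gene_id]
        query = next((i for i in aln.ids if i.startswith(query_prefix)), None)
        try:
            if query is None:
                raise StageError("screen", gene_id,
                                 f"no OTU with prefix {query_prefix!r}")
            result = analyze_family(aln, query, taxonomy, cfg, gene_id=gene_id)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - converted to stage record
            err = StageError("screen", gene_id, str(exc))
            if logger is None:
                raise err from exc
            logger.warning(str(err))
            continue
        results.append(result)
        if logger is not None:
            logger.info(
                "gene=%s taxa=%d cols=%d closest=%s group=%s dist=%.4f",
                gene_id, result.alignment.n_rows, result.alignment.n_cols,
                result.closest.closest_otu, result.closest.closest_group.value,
                result.closest.distance)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        trees_dir = out_dir / "trees"
        trees_dir.mkdir(exist_ok=True)
        for result in results:
            write_newick(result.supported_tree,
                         trees_dir / f"{result.gene_id}.nwk")
            write_newick(result.collapsed_tree,
                         trees_dir / f"{result.gene_id}.collapsed.nwk")
        reports_to_tsv(results, out_dir / "report.tsv")
        tally_to_tsv(tally_by_group(r.closest for r in results),
                     out_dir / "tally.tsv")
    return results


def reports_to_tsv(results: Iterable[ScreenResult],
                   dest: str | Path | io.TextIOBase) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            reports_to_tsv(results, fh)
        return
    dest.write("# closest = nearest single OTU by patristic distance on the "
               "collapsed tree (not a nearest-clade majority)\n")
    dest.write("gene_id\tquery\tclosest_otu\tclosest_group\tdistance\ttied_otus\n")
    for r in results:
        c = r.closest
        dest.write(f"{r.gene_id}\t{c.query_id}\t{c.closest_otu}\t"
                   f"{c.closest_group.value}\t{c.distance:.6f}\t"
                   f"{','.join(c.tied_otus)}\n")


def tally_to_tsv(tally: Mapping[LineageGroup, int],
                 dest: str | Path | io.TextIOBase) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            tally_to_tsv(tally, fh)
        return
    dest.write("group\tcount\n")
    for group in LineageGroup:
        dest.write(f"{group.value}\t{tally.get(group, 0)}\n")
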