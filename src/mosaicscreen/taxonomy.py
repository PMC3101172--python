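"""Lineage groups and the OTU -> (genus, group) registry.

The screen reasons about nine fixed lineage groups.  ``CR`` bundles the
Chromalveolata sub-groups (stramenopiles, alveolates, cryptophytes including
their nucleomorphs, haptophytes) with Rhizaria, because red-algal-derived
secondary plastids are scattered across exactly that assemblage.  ``RED``
covers red algae only; ``GREEN`` covers green algae (prasinophytes included)
and land plants.  Glaucophytes get their own code: they appear in the taxon
palette but play no role in the classification rules.

OTU labels follow the underscore convention ``Genus_species[_suffix]`` so the
genus can be extracted deterministically without any taxonomy service; a
numeric or descriptive suffix distinguishes paralogs and nucleomorph entries.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

from .errors import MalformedLabelError, UnknownTaxonError

__all__ = [
    "LineageGroup",
    "TaxonEntry",
    "TaxonomyMap",
    "assign_group",
    "genus_of",
    "read_taxonomy",
    "write_taxonomy",
    "default_taxonomy",
]


class LineageGroup(str, enum.Enum):
    """Closed set of lineage-group codes used throughout the pipeline."""

    EUGLENID = "EUGLENID"
    OTHER_EXCAVATA = "OTHER_EXCAVATA"
    CR = "CR"
    RED = "RED"
    GREEN = "GREEN"
    GLAUCOPHYTE = "GLAUCOPHYTE"
    UNIKONT = "UNIKONT"
    CYANOBACTERIA = "CYANOBACTERIA"
    OTHER_BACTERIA = "OTHER_BACTERIA"

    @property
    def display_name(self) -> str:
        return _DISPLAY_NAMES[self]


_DISPLAY_NAMES: dict[LineageGroup, str] = {
    LineageGroup.EUGLENID: "euglenids",
    LineageGroup.OTHER_EXCAVATA: "other excavates",
    LineageGroup.CR: "Chromalveolata + Rhizaria",
    LineageGroup.RED: "red algae",
    LineageGroup.GREEN: "green algae and land plants",
    LineageGroup.GLAUCOPHYTE: "glaucophytes",
    LineageGroup.UNIKONT: "unikonts",
    LineageGroup.CYANOBACTERIA: "cyanobacteria",
    LineageGroup.OTHER_BACTERIA: "other eubacteria",
}

#: Groups whose members count as 'red lineage' evidence: red algae plus the
#: secondary algae (and relatives) whose plastids trace to red algae.
RED_LINEAGE_GROUPS = frozenset({LineageGroup.CR, LineageGroup.RED})


@dataclass(frozen=True)
class TaxonEntry:
    genus: str
    group: LineageGroup
    subgroup: str = ""


class TaxonomyMap:
    """Mapping of OTU labels to (genus, lineage group, optional subgroup).

    Lookups of unregistered labels raise :class:`UnknownTaxonError`; there is
    deliberately no silent default, since a mis-binned taxon would corrupt
    every downstream monophyly call.
    """

    def __init__(self, entries: Mapping[str, TaxonEntry] | None = None):
        self._entries: dict[str, TaxonEntry] = dict(entries or {})
        for label, entry in self._entries.items():
            _validate_entry(label, entry)

    def register(self, otu_id: str, genus: str, group: LineageGroup | str,
                 subgroup: str = "") -> None:
        entry = TaxonEntry(genus=genus, group=LineageGroup(group), subgroup=subgroup)
        _validate_entry(otu_id, entry)
        self._entries[otu_id] = entry

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonomyMap) and self._entries == other._entries

    def entry(self, otu_id: str) -> TaxonEntry:
        try:
            return self._entries[otu_id]
        except KeyError:
            raise UnknownTaxonError(otu_id) from None

    def group_of(self, otu_id: str) -> LineageGroup:
        return self.entry(otu_id).group

    def genus_of(self, otu_id: str) -> str:
        return self.entry(otu_id).genus

    def labels_in_group(self, group: LineageGroup) -> list[str]:
        return sorted(l for l, e in self._entries.items() if e.group is group)

    def items(self):
        return self._entries.items()


def _validate_entry(label: str, entry: TaxonEntry) -> None:
    if not label:
        raise MalformedLabelError("empty OTU label")
    if not entry.genus:
        raise MalformedLabelError(f"empty genus for OTU {label!r}")


def assign_group(otu_label: str, taxonomy: TaxonomyMap) -> LineageGroup:
    """Return the lineage group of a registered OTU label."""
    return taxonomy.group_of(otu_label)


def genus_of(otu_label: str) -> str:
    """Extract the genus token from a ``Genus_species[_suffix]`` label."""
    if not otu_label:
        raise MalformedLabelError("empty OTU label")
    if "_" not in otu_label:
        raise MalformedLabelError(
            f"label {otu_label!r} has no '_' separator; expected Genus_species")
    genus = otu_label.split("_", 1)[0]
    if not genus:
        raise MalformedLabelError(f"label {otu_label!r} has an empty genus token")
    return genus


# ---------------------------------------------------------------------------
# TSV interface: columns otu_id, genus, group_code, subgroup ('' allowed);
# '#' starts a comment line; UTF-8.
# ---------------------------------------------------------------------------

_COLUMNS = ("otu_id", "genus", "group_code", "subgroup")


def read_taxonomy(source: str | Path | io.TextIOBase) -> TaxonomyMap:
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return read_taxonomy(fh)
    tm = TaxonomyMap()
    header_seen = False
    for raw in source:
        line = raw.rstrip("\n")
        if not line or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if not header_seen:
            header_seen = True
            if fields[: len(_COLUMNS) - 1] == list(_COLUMNS[:-1]):
                continue  # header row; subgroup column optional
        while len(fields) < 4:
            fields.append("")
        otu_id, genus, group_code, subgroup = fields[:4]
        try:
            group = LineageGroup(group_code)
        except ValueError:
            raise UnknownTaxonError(f"{otu_id} (unknown group code {group_code!r})")
        tm.register(otu_id, genus, group, subgroup)
    return tm


def write_taxonomy(taxonomy: TaxonomyMap, dest: str | Path | io.TextIOBase) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            write_taxonomy(taxonomy, fh)
        return
    dest.write("\t".join(_COLUMNS) + "\n")
    for otu_id in sorted(taxonomy):
        e = taxonomy.entry(otu_id)
        dest.write(f"{otu_id}\t{e.genus}\t{e.group.value}\t{e.subgroup}\n")


# ---------------------------------------------------------------------------
# Default registry: the organisms named in the study plus the standard model
# taxa the simulator samples from.  Nucleomorph entries map to CR with
# subgroup 'nucleomorph' (cryptophyte nucleomorph sequences are red-lineage
# evidence, e.g. for ClpP and the hypothetical oxidoreductase-domain protein).
# ---------------------------------------------------------------------------

_DEFAULT_TABLE: list[tuple[str, LineageGroup, str]] = [
    # euglenids
    ("Euglena_gracilis", LineageGroup.EUGLENID, "euglenophyte"),
    ("Eutreptiella_gymnastica", LineageGroup.EUGLENID, "euglenophyte"),
    ("Peranema_trichophorum", LineageGroup.EUGLENID, "eukaryovorous"),
    # other excavates
    ("Trypanosoma_brucei", LineageGroup.OTHER_EXCAVATA, "kinetoplastid"),
    ("Leishmania_major", LineageGroup.OTHER_EXCAVATA, "kinetoplastid"),
    ("Naegleria_gruberi", LineageGroup.OTHER_EXCAVATA, "heterolobosean"),
    ("Giardia_intestinalis", LineageGroup.OTHER_EXCAVATA, ""),
    ("Monocercomonoides_sp", LineageGroup.OTHER_EXCAVATA, ""),
    # Chromalveolata + Rhizaria
    ("Thalassiosira_pseudonana", LineageGroup.CR, "stramenopile"),
    ("Phaeodactylum_tricornutum", LineageGroup.CR, "stramenopile"),
    ("Thraustochytrium_aureum", LineageGroup.CR, "stramenopile"),
    ("Aureococcus_anophagefferens", LineageGroup.CR, "pelagophyte"),
    ("Emiliania_huxleyi", LineageGroup.CR, "haptophyte"),
    ("Perkinsus_marinus", LineageGroup.CR, "alveolate"),
    ("Bigelowiella_natans", LineageGroup.CR, "rhizarian"),
    ("Guillardia_theta", LineageGroup.CR, "cryptophyte"),
    ("Guillardia_theta_nucleomorph", LineageGroup.CR, "nucleomorph"),
    # red algae
    ("Galdieria_sulphuraria", LineageGroup.RED, ""),
    ("Cyanidioschyzon_merolae", LineageGroup.RED, ""),
    ("Porphyra_yezoensis", LineageGroup.RED, ""),
    # green algae and land plants
    ("Ostreococcus_tauri", LineageGroup.GREEN, "prasinophyte"),
    ("Ostreococcus_lucimarinus", LineageGroup.GREEN, "prasinophyte"),
    ("Micromonas_pusilla", LineageGroup.GREEN, "prasinophyte"),
    ("Pyramimonas_parkeae", LineageGroup.GREEN, "prasinophyte"),
    ("Chlamydomonas_reinhardtii", LineageGroup.GREEN, "chlorophyte"),
    ("Chlorogonium_elongatum", LineageGroup.GREEN, "chlorophyte"),
    ("Arabidopsis_thaliana", LineageGroup.GREEN, "land plant"),
    # glaucophytes
    ("Cyanophora_paradoxa", LineageGroup.GLAUCOPHYTE, ""),
    # unikonts
    ("Monosiga_brevicollis", LineageGroup.UNIKONT, "choanoflagellate"),
    ("Homo_sapiens", LineageGroup.UNIKONT, "animal"),
    ("Saccharomyces_cerevisiae", LineageGroup.UNIKONT, "fungus"),
    # bacterial outgroups
    ("Synechocystis_sp", LineageGroup.CYANOBACTERIA, ""),
    ("Nostoc_sp", LineageGroup.CYANOBACTERIA, ""),
    ("Escherichia_coli", LineageGroup.OTHER_BACTERIA, ""),
]


def default_taxonomy() -> TaxonomyMap:
    """Registry covering the taxa named in the study and the simulator palette."""
    tm = TaxonomyMap()
    for label, group, subgroup in _DEFAULT_TABLE:
        tm.register(label, genus_of(label), group, subgroup)
    return tm
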