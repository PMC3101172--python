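"""Protein alignment handling: I/O, gap trimming, distances, indel signatures.

An :class:`Alignment` stores equal-length uppercase residue rows over the 20
amino-acid letters plus ``-`` (gap) and ``X`` (ambiguous/missing; EST
translations are full of these).  All column coordinates are 0-based
half-open.

Distances are protein p-distances computed over the columns where both rows
carry an unambiguous residue, optionally Poisson-corrected, ``d = -ln(1-p)``,
with a saturation cap so the matrix stays finite for downstream
neighbor joining.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix

from .errors import (
    EmptyAlignmentError,
    InvalidCandidateSetError,
    NoOverlapError,
    QueryTooGappyError,
    TooFewTaxaError,
)

__all__ = [
    "Alignment",
    "IndelSignature",
    "read_fasta",
    "write_fasta",
    "trim_gappy_columns",
    "drop_gappy_taxa",
    "pairwise_distance",
    "find_shared_indels",
    "signatures_to_tsv",
    "SATURATION_P",
]

GAP = ord("-")
MISSING = ord("X")

#: p-distances at or above this are treated as saturated and capped at
#: ``-ln(1 - SATURATION_P)`` under the Poisson correction.
SATURATION_P = 0.99

_ALPHABET = set(b"ACDEFGHIKLMNPQRSTVWY-X*")


@dataclass(frozen=True)
class Alignment:
    """Immutable multiple protein alignment.

    ``matrix`` is a ``(n_rows, n_cols)`` uint8 array of ASCII codes; rows are
    ordered and ids unique.
    """

    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix shape does not match ids")
        if self.matrix.shape[1] < 1:
            raise EmptyAlignmentError("alignment has zero columns")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate OTU ids in alignment")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        ids, seqs = [], []
        for otu_id, seq in records:
            ids.append(otu_id)
            seqs.append(seq.upper())
        if not ids:
            raise EmptyAlignmentError("no sequences")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        matrix = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
        matrix = matrix.reshape(len(ids), -1).copy()
        bad = set(np.unique(matrix).tobytes()) - {c for c in _ALPHABET}
        if bad:
            raise ValueError(f"non-protein characters in alignment: {sorted(chr(b) for b in bad)}")
        return cls(ids=tuple(ids), matrix=matrix)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, otu_id: str) -> str:
        return self.matrix[self.ids.index(otu_id)].tobytes().decode("ascii")

    def rows(self) -> Iterable[tuple[str, str]]:
        for i, otu_id in enumerate(self.ids):
            yield otu_id, self.matrix[i].tobytes().decode("ascii")

    def gap_mask(self) -> np.ndarray:
        return self.matrix == GAP

    def column_gap_fraction(self) -> np.ndarray:
        return self.gap_mask().mean(axis=0)

    def row_gap_fraction(self) -> np.ndarray:
        return self.gap_mask().mean(axis=1)

    def take_columns(self, cols: np.ndarray) -> "Alignment":
        return Alignment(ids=self.ids, matrix=self.matrix[:, cols].copy())

    def take_rows(self, keep_ids: Sequence[str]) -> "Alignment":
        idx = [self.ids.index(i) for i in keep_ids]
        return Alignment(ids=tuple(keep_ids), matrix=self.matrix[idx].copy())


def read_fasta(source: str | Path | io.TextIOBase) -> Alignment:
    """Read an aligned FASTA file (gap character '-')."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(source, "fasta")]
    if not records:
        raise EmptyAlignmentError(f"no FASTA records in {source}")
    return Alignment.from_records(records)


def write_fasta(aln: Alignment, dest: str | Path | io.TextIOBase) -> None:
    """Write aligned FASTA, wrapped at 60 columns, preserving row order."""
    records = [SeqRecord(Seq(seq), id=otu_id, description="") for otu_id, seq in aln.rows()]
    SeqIO.write(records, dest, "fasta")


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------

def trim_gappy_columns(aln: Alignment, max_gap_frac: float = 0.5) -> Alignment:
    """Remove indel-rich columns.

    Retains exactly the columns whose gap fraction is <= ``max_gap_frac``;
    row order and ids are untouched.  Removing every column raises
    :class:`EmptyAlignmentError`.
    """
    keep = aln.column_gap_fraction() <= max_gap_frac
    if not keep.any():
        raise EmptyAlignmentError(
            f"all {aln.n_cols} columns exceed gap fraction {max_gap_frac}")
    if keep.all():
        return aln
    return aln.take_columns(np.flatnonzero(keep))


def drop_gappy_taxa(aln: Alignment, max_gap_frac: float = 0.75,
                    query: str | None = None) -> Alignment:
    """Remove rows whose gap fraction exceeds ``max_gap_frac``.

    The designated query row is never removed: if it exceeds the threshold
    the whole gene is rejected with :class:`QueryTooGappyError`.  Dropping
    rows below four taxa (the minimum for an informative unrooted topology)
    raises :class:`TooFewTaxaError`.
    """
    frac = aln.row_gap_fraction()
    too_gappy = frac > max_gap_frac
    if query is not None:
        if query not in aln.ids:
            raise KeyError(f"query {query!r} not in alignment")
        qi = aln.ids.index(query)
        if too_gappy[qi]:
            raise QueryTooGappyError(
                f"query {query!r} gap fraction {frac[qi]:.3f} > {max_gap_frac}")
    if not too_gappy.any():
        return aln
    keep_ids = [otu for otu, drop in zip(aln.ids, too_gappy) if not drop]
    if len(keep_ids) < 4:
        raise TooFewTaxaError(
            f"only {len(keep_ids)} rows remain after taxon trimming")
    return aln.take_rows(keep_ids)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _comparable_mask(matrix: np.ndarray) -> np.ndarray:
    return (matrix != GAP) & (matrix != MISSING)


def p_distance_matrix(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised p-distance over all row pairs.

    Returns ``(p, n_comparable)``; entries with zero comparable columns hold
    ``nan`` in ``p``.  This is the hot path reused by every bootstrap
    replicate, hence the all-pairs broadcasting.
    """
    valid = _comparable_mask(matrix)
    comp = valid[:, None, :] & valid[None, :, :]
    diff = (matrix[:, None, :] != matrix[None, :, :]) & comp
    n_comp = comp.sum(axis=2)
    n_diff = diff.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_comp > 0, n_diff / np.maximum(n_comp, 1), np.nan)
    np.fill_diagonal(p, 0.0)
    return p, n_comp

def poisson_correct(p: np.ndarray) -> np.ndarray:
    """Poisson-corrected distance ``-ln(1-p)`` with a saturation cap."""
    capped = np.minimum(p, SATURATION_P)
    with np.errstate(invalid="ignore"):
        return -np.log1p(-capped)


def pairwise_distance(aln: Alignment,
                      model: Literal["p_distance", "poisson"] = "poisson"
                      ) -> DistanceMatrix:
    """Pairwise protein distances between all alignment rows.

    Comparisons use only columns where both rows are non-gap and non-X.
    A pair with no comparable columns raises :class:`NoOverlapError` naming
    the pair.
    """
    if aln.n_rows < 2:
        raise ValueError("need at least two rows for a distance matrix")
    if model not in ("p_distance", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    p, n_comp = p_distance_matrix(aln.matrix)
    no_overlap = (n_comp == 0)
    np.fill_diagonal(no_overlap, False)
    if no_overlap.any():
        i, j = np.argwhere(no_overlap)[0]
        raise NoOverlapError(aln.ids[i], aln.ids[j])
    d = p if model == "p_distance" else poisson_correct(p)
    d = (d + d.T) / 2.0  # exact symmetry despite float reduction order
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(aln.ids))


# ---------------------------------------------------------------------------
# Shared-indel signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndelSignature:
    """A maximal column run where gap state separates carriers from the rest.

    ``deletion_block``: every carrier is gapped, every other row is not.
    ``insertion_block``: the converse.  Both are diagnostic of common
    ancestry of the carrier set, independently of tree support values.
    """

    start_col: int
    end_col: int  # half-open
    state: Literal["insertion_block", "deletion_block"]
    carriers: frozenset[str]

    @property
    def length(self) -> int:
        return self.end_col - self.start_col


def find_shared_indels(aln: Alignment, min_len: int,
                       candidate_set: Iterable[str]) -> list[IndelSignature]:
    """Scan for indel blocks shared exclusively by ``candidate_set``.

    Returns maximal runs of length >= ``min_len`` of columns where the
    candidate rows and all other rows are on opposite sides of the gap/non-gap
    divide.  Universal gap columns are not discriminative and never match.
    """
    carriers = frozenset(candidate_set)
    if not carriers:
        raise InvalidCandidateSetError("candidate set is empty")
    unknown = carriers - set(aln.ids)
    if unknown:
        raise InvalidCandidateSetError(f"candidates not in alignment: {sorted(unknown)}")
    if carriers == set(aln.ids):
        raise InvalidCandidateSetError("candidate set equals the full row set")

    in_set = np.array([otu in carriers for otu in aln.ids])
    gaps = aln.gap_mask()
    cand_all_gap = gaps[in_set].all(axis=0)
    cand_none_gap = ~gaps[in_set].any(axis=0)
    rest_all_gap = gaps[~in_set].all(axis=0)
    rest_none_gap = ~gaps[~in_set].any(axis=0)

    state = np.zeros(aln.n_cols, dtype=np.int8)  # 0 none, 1 deletion, 2 insertion
    state[cand_all_gap & rest_none_gap] = 1
    state[cand_none_gap & rest_all_gap] = 2

    out: list[IndelSignature] = []
    col = 0
    while col < aln.n_cols:
        s = state[col]
        if s == 0:
            col += 1
            continue
        end = col
        while end < aln.n_cols and state[end] == s:
            end += 1
        if end - col >= min_len:
            out.append(IndelSignature(
                start_col=col, end_col=end,
                state="deletion_block" if s == 1 else "insertion_block",
                carriers=carriers))
        col = end
    return out


def signatures_to_tsv(signatures: Iterable[IndelSignature],
                      dest: str | Path | io.TextIOBase) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            signatures_to_tsv(signatures, fh)
        return
    dest.write("carriers\tstart_col\tend_col\tstate\n")
    for sig in signatures:
        dest.write(f"{','.join(sorted(sig.carriers))}\t{sig.start_col}\t"
                   f"{sig.end_col}\t{sig.state}\n")
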