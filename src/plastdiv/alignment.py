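"""Aligned genome sets and the column <-> ungapped-position bijection.

The central container is :class:`AlignedGenomeSet`: an n x L gapped multiple
alignment of near-identical plastomes with one designated reference
accession.  Columns are 0-based; ungapped positions are 0-based per
accession.  :class:`CoordinateMap` maintains the monotone map between the
two coordinate systems for one accession.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _seq
from .errors import (
    DuplicateIdError,
    MissingReferenceError,
    RaggedAlignmentError,
)


class CoordinateMap:
    """Bijection between alignment columns and ungapped positions.

    For gap columns :meth:`position` returns ``None``; :meth:`previous_position`
    returns the ungapped position of the nearest preceding non-gap column
    (used to inherit feature context for gap-in-reference columns).
    """

    def __init__(self, gapped_codes: np.ndarray):
        self._nongap = gapped_codes != _seq.GAP
        # cumulative position; -1 before the first base
        cum = np.cumsum(self._nongap) - 1
        self._col_to_pos = np.where(self._nongap, cum, -1)
        self._prev_pos = cum  # nearest preceding (or own) ungapped position
        self._pos_to_col = np.flatnonzero(self._nongap)

    @property
    def ungapped_length(self) -> int:
        return len(self._pos_to_col)

    @property
    def alignment_length(self) -> int:
        return len(self._col_to_pos)

    def position(self, col: int) -> int | None:
        """Ungapped position of column ``col``, or None on a gap."""
        p = self._col_to_pos[col]
        return int(p) if p >= 0 else None

    def previous_position(self, col: int) -> int | None:
        """Ungapped position of ``col`` or of the nearest preceding base."""
        p = self._prev_pos[col]
        return int(p) if p >= 0 else None

    def column(self, pos: int) -> int:
        """Alignment column holding ungapped position ``pos``."""
        return int(self._pos_to_col[pos])

    def columns(self, start: int, end: int) -> np.ndarray:
        """Alignment columns for the ungapped interval [start, end)."""
        return self._pos_to_col[start:end]

    @property
    def col_to_pos(self) -> np.ndarray:
        """Vectorised column -> position array (-1 on gaps)."""
        return self._col_to_pos

    @property
    def prev_pos(self) -> np.ndarray:
        """Vectorised column -> nearest preceding position array."""
        return self._prev_pos


@dataclass
class AlignedGenomeSet:
    """An n x L gapped alignment with accession ids and a reference.

    ``matrix`` holds uppercase ASCII codes (A/C/G/T/N/-) with one row per
    accession, in the order of ``accessions``.
    """

    accessions: list[str]
    matrix: np.ndarray
    reference_id: str
    _maps: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.accessions):
            raise RaggedAlignmentError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.accessions)} accessions"
            )
        if self.matrix.shape[1] < 1:
            raise RaggedAlignmentError("alignment must have at least one column")
        if len(set(self.accessions)) != len(self.accessions):
            dupes = {a for a in self.accessions if self.accessions.count(a) > 1}
            raise DuplicateIdError(f"duplicate accession ids: {sorted(dupes)}")
        if self.reference_id not in self.accessions:
            raise MissingReferenceError(
                f"reference id {self.reference_id!r} not among accessions"
            )
        if np.any((self.matrix == _seq.GAP).all(axis=0)):
            raise RaggedAlignmentError("alignment contains an all-gap column")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        """Number of alignment columns L."""
        return self.matrix.shape[1]

    @property
    def reference_index(self) -> int:
        return self.accessions.index(self.reference_id)

    def row(self, accession: str) -> np.ndarray:
        return self.matrix[self.accessions.index(accession)]

    def sequence(self, accession: str) -> str:
        return _seq.to_str(self.row(accession))

    def ungapped(self, accession: str) -> str:
        row = self.row(accession)
        return _seq.to_str(row[row != _seq.GAP])

    def coordinate_map(self, accession: str) -> CoordinateMap:
        if accession not in self._maps:
            self._maps[accession] = CoordinateMap(self.row(accession))
        return self._maps[accession]

    @property
    def reference_map(self) -> CoordinateMap:
        return self.coordinate_map(self.reference_id)

    # -- construction ---------------------------------------------------
    @classmethod
    def from_sequences(
        cls, rows: dict[str, str], reference_id: str
    ) -> "AlignedGenomeSet":
        ids = list(rows)
        lengths = {len(s) for s in rows.values()}
        if len(lengths) > 1:
            raise RaggedAlignmentError(f"unequal record lengths: {sorted(lengths)}")
        mat = np.vstack([_seq.to_array(rows[i].upper()) for i in ids])
        return cls(ids, mat, reference_id)


def read_alignment(path: str | Path, reference_id: str) -> AlignedGenomeSet:
    """Read an aligned FASTA into an :class:`AlignedGenomeSet`.

    Lowercase bases are normalised to uppercase.  Raises
    :class:`RaggedAlignmentError` for unequal record lengths,
    :class:`DuplicateIdError` for repeated ids and
    :class:`MissingReferenceError` when ``reference_id`` is absent.
    """
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise DuplicateIdError(f"duplicate accession id: {rec.id!r}")
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise RaggedAlignmentError(f"no FASTA records in {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise RaggedAlignmentError(f"unequal record lengths: {sorted(lengths)}")
    mat = np.vstack([_seq.to_array(s) for s in seqs])
    return AlignedGenomeSet(ids, mat, reference_id)


def write_alignment(aln: AlignedGenomeSet, path: str | Path) -> None:
    """Write the alignment back out as FASTA (one gapped record per accession)."""
    records = [
        SeqRecord(Seq(aln.sequence(a)), id=a, description="") for a in aln.accessions
    ]
    SeqIO.write(records, str(path), "fasta")
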