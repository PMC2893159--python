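"""Alignment container, FASTA/Stockholm I/O, and the ungapped-column view.

All covariation statistics in this package operate on the *analyzed* columns
of an alignment: those containing no gap character in any sequence. Gapped
columns are excluded entirely because a gap is an explicit statement that no
homologous residue exists, which breaks the positional-homology assumption
the statistics rest on.

Coordinates are 0-based internally; user-facing reports are 1-based
alignment coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
#: Characters accepted as gaps on input; all are normalized to ``GAP``.
GAP_CHARS = frozenset({"-", "."})
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity codes are kept (as extra symbols) rather than dropped, but flagged.
AMBIGUITY_CODES = frozenset({"B", "Z", "X", "J", "U", "O"})
_VALID = frozenset(AMINO_ACIDS) | AMBIGUITY_CODES | {GAP}


class AlignmentError(ValueError):
    """Raised for malformed or degenerate alignments."""


@dataclass(frozen=True)
class Alignment:
    """A rectangular protein multiple sequence alignment.

    Parameters
    ----------
    ids : sequence identifiers, one per row.
    rows : aligned residue strings (uppercase), all the same length.
           Gap characters are normalized to ``-`` at construction.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if not self.rows:
            raise AlignmentError("empty alignment")
        norm = tuple(_normalize_row(r) for r in self.rows)
        object.__setattr__(self, "rows", norm)
        width = len(norm[0])
        if width == 0:
            raise AlignmentError("alignment has zero columns")
        for ident, row in zip(self.ids, norm):
            if len(row) != width:
                raise AlignmentError(
                    f"ragged alignment: sequence {ident!r} has length "
                    f"{len(row)}, expected {width}"
                )
            bad = set(row) - _VALID
            if bad:
                raise AlignmentError(
                    f"sequence {ident!r} contains invalid characters {sorted(bad)}"
                )
        ambiguous = sorted(set("".join(norm)) & AMBIGUITY_CODES)
        if ambiguous:
            warnings.warn(
                f"alignment contains ambiguity codes {ambiguous}; they are "
                "counted as distinct symbols in entropy calculations",
                stacklevel=2,
            )

    @property
    def depth(self) -> int:
        """Number of sequences."""
        return len(self.rows)

    @property
    def width(self) -> int:
        """Number of aligned columns."""
        return len(self.rows[0])

    def column(self, j: int) -> str:
        """Residues of column ``j`` (0-based), top to bottom."""
        return "".join(row[j] for row in self.rows)

    def to_array(self) -> np.ndarray:
        """``(depth, width)`` array of single-character strings."""
        return np.array([list(r) for r in self.rows], dtype="U1")

    def permuted(self, order: Sequence[int]) -> "Alignment":
        """Alignment with rows reordered by ``order``."""
        return Alignment(
            tuple(self.ids[i] for i in order), tuple(self.rows[i] for i in order)
        )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        ids, rows = zip(*pairs)
        return cls(tuple(ids), tuple(str(r).upper() for r in rows))


@dataclass(frozen=True)
class ColumnMask:
    """Original 0-based indices of columns with no gap in any sequence."""

    analyzed: tuple[int, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.analyzed)

    def to_original(self, k: int) -> int:
        """Original column index of analyzed column ``k``."""
        return self.analyzed[k]

    def runs(self) -> list[tuple[int, int]]:
        """Maximal runs of *consecutive original* columns, as (start, stop)
        half-open index ranges into ``analyzed``."""
        if not self.analyzed:
            return []
        out = []
        start = 0
        for k in range(1, len(self.analyzed)):
            if self.analyzed[k] != self.analyzed[k - 1] + 1:
                out.append((start, k))
                start = k
        out.append((start, len(self.analyzed)))
        return out


def _normalize_row(row: str) -> str:
    row = row.upper()
    for g in GAP_CHARS:
        if g != GAP and g in row:
            row = row.replace(g, GAP)
    return row


def ungapped_mask(aln: Alignment) -> ColumnMask:
    """Columns containing no gap character in any sequence, in order.

    A single gap excludes a column entirely: no occupancy threshold is
    applied, because gapped columns violate positional homology.
    """
    arr = aln.to_array()
    keep = ~(arr == GAP).any(axis=0)
    return ColumnMask(tuple(int(j) for j in np.nonzero(keep)[0]))


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read and validate an alignment from FASTA or Stockholm.

    Both ``-`` and ``.`` are accepted as gaps and normalized to ``-``.
    Ambiguity codes (B, Z, X, ...) are preserved and flagged with a warning.
    """
    path = Path(path)
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    if not path.exists():
        raise FileNotFoundError(f"alignment file not found: {path}")
    if path.stat().st_size == 0:
        raise AlignmentError(f"empty alignment file: {path}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        # Biopython raises ValueError both for parse failures and for ragged
        # FASTA records; surface the first offending sequence where possible.
        raise AlignmentError(f"could not parse {path} as {format}: {exc}") from exc
    if len(msa) == 0:
        raise AlignmentError(f"no sequences in {path}")
    return Alignment.from_pairs((rec.id, str(rec.seq)) for rec in msa)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment in FASTA or Stockholm format."""
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(row), id=ident, description="")
        for ident, row in zip(aln.ids, aln.rows)
    )
    AlignIO.write(msa, str(path), format)
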