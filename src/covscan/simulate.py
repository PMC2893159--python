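"""Synthetic misalignment experiments: shift injection and block constructions.

``inject_shift`` emulates a registration error: within one gap-free segment,
a fraction of the sequences is moved one column left or right, the way a
progressive or structure-based aligner can misplace a whole subpopulation.
``build_block_experiment`` builds the two didactic constructions — a fully
conserved N-terminal block (no entropy, hence no covariation) and its
half-shifted counterpart, in which every analyzed block column holds two
equiprobable residues in perfect lockstep (maximal covariation from pure
alignment error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msa import GAP, AMINO_ACIDS, Alignment

__all__ = ["ShiftSpec", "ShiftManifest", "inject_shift", "revert_shift", "build_block_experiment"]


@dataclass(frozen=True)
class ShiftSpec:
    """One-column shift injection into an inclusive column interval.

    ``round(fraction * depth)`` sequences are chosen uniformly at random;
    each moves its segment residues one column left or right with equal
    probability. The cell vacated at one segment end is filled with the
    adjacent flanking column's residue (the flank itself is unchanged); the
    residue pushed off the other end leaves the segment and is recorded in
    the manifest.
    """

    start: int        # inclusive, 0-based
    stop: int         # inclusive, 0-based
    fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if self.stop < self.start:
            raise ValueError("segment stop precedes start")


@dataclass(frozen=True)
class ShiftManifest:
    spec: ShiftSpec
    records: tuple[tuple[int, str, int, str], ...] = field(default=())
    # (row index, sequence id, direction -1|+1, displaced terminal residue)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["row", "id", "direction", "displaced"]
        )


def inject_shift(aln: Alignment, spec: ShiftSpec) -> tuple[Alignment, ShiftManifest]:
    """Shift a random fraction of sequences by one column within a segment."""
    a, b = spec.start, spec.stop
    if a < 1 or b > aln.width - 2:
        raise ValueError(
            "segment must leave at least one flanking column on each side"
        )
    for ident, row in zip(aln.ids, aln.rows):
        if GAP in row[a : b + 1]:
            raise ValueError(f"segment contains a gap in sequence {ident!r}")
    rng = np.random.default_rng(spec.seed)
    n_shift = round(spec.fraction * aln.depth)
    chosen = rng.choice(aln.depth, size=n_shift, replace=False)
    directions = rng.choice([-1, 1], size=n_shift)
    rows = list(aln.rows)
    records = []
    for idx, direction in zip(chosen, directions):
        row = rows[idx]
        seg = row[a : b + 1]
        if direction == 1:  # right: import from left flank, discard last
            displaced = seg[-1]
            new_seg = row[a - 1] + seg[:-1]
        else:  # left: import from right flank, discard first
            displaced = seg[0]
            new_seg = seg[1:] + row[b + 1]
        rows[idx] = row[:a] + new_seg + row[b + 1 :]
        records.append((int(idx), aln.ids[idx], int(direction), displaced))
    manifest = ShiftManifest(spec=spec, records=tuple(records))
    return Alignment(aln.ids, tuple(rows)), manifest


def revert_shift(aln: Alignment, manifest: ShiftManifest) -> Alignment:
    """Undo an injected shift exactly, using the manifest's displaced residues."""
    a, b = manifest.spec.start, manifest.spec.stop
    rows = list(aln.rows)
    for idx, _ident, direction, displaced in manifest.records:
        row = rows[idx]
        seg = row[a : b + 1]
        if direction == 1:  # was shifted right: move back left, restore tail
            orig_seg = seg[1:] + displaced
        else:
            orig_seg = displaced + seg[:-1]
        rows[idx] = row[:a] + orig_seg + row[b + 1 :]
    return Alignment(aln.ids, tuple(rows))


def build_block_experiment(
    background: Alignment, block_width: int = 4, shifted: bool = False
) -> Alignment:
    """Prepend a conserved or half-shifted block to a background alignment.

    Unshifted: every sequence gains the same ``block_width`` residues plus an
    all-gap spacer column — the block columns are analyzed, carry zero
    entropy, and so zero covariation. Shifted: a ``block_width + 1``-column
    block in which half the sequences carry the residues in columns
    1..block_width with a trailing gap and the other half carry a leading
    gap with the residues in columns 2..block_width+1; the middle
    ``block_width - 1`` columns are gap-free in all rows, each holding two
    residue types at 50/50 in perfect lockstep.
    """
    if block_width < 2:
        raise ValueError("block_width must be at least 2")
    letters = AMINO_ACIDS[:block_width]
    depth = background.depth
    ids, rows = background.ids, background.rows
    if shifted and depth % 2:
        warnings.warn("odd depth: dropping the last sequence to halve evenly", stacklevel=2)
        ids, rows, depth = ids[:-1], rows[:-1], depth - 1
    if shifted:
        half = depth // 2
        new_rows = tuple(
            (letters + GAP if i < half else GAP + letters) + row
            for i, row in enumerate(rows)
        )
    else:
        new_rows = tuple(letters + GAP + row for row in rows)
    return Alignment(ids, new_rows)
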