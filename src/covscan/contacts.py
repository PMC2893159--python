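"""Benchmark covariation predictions against structure contacts.

Two residues are in contact when any pair of their non-hydrogen atoms lies
within 6 Å. Predictions are scored by the fraction of top-ranked pairs in
contact, restricted to pairs at least 10 alignment positions apart (closer
pairs are trivially in contact). Also provides the score cutoff achieving a
requested contact accuracy, overlap (Venn) partitions between methods'
retained pairs, and the family-eligibility filters used to decide whether
an alignment carries enough sequences and covariation signal for contact
prediction at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .msa import GAP, Alignment, ColumnMask, ungapped_mask

__all__ = [
    "ResidueCoordinates",
    "ContactMap",
    "read_pdb_coordinates",
    "map_columns_to_residues",
    "build_contact_map",
    "topn_accuracy",
    "accuracy_cutoff",
    "overlap_analysis",
    "curation_filter",
]

# 3-letter -> 1-letter for the 20 standard residues
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class ResidueCoordinates:
    """Non-hydrogen atom coordinates per residue, in structure order.

    ``keys`` identify residues (index within the chain); ``letters`` carry
    the one-letter residue type for alignment mapping.
    """

    keys: tuple[int, ...]
    letters: tuple[str, ...]
    atoms: tuple[np.ndarray, ...]  # each (n_atoms, 3), Å

    def __len__(self) -> int:
        return len(self.keys)


def read_pdb_coordinates(
    path: str | Path, chain: str | None = None, model: int = 0
) -> ResidueCoordinates:
    """Heavy-atom coordinates of one chain's amino-acid residues.

    First model only; first altloc conformer; waters and hetero groups are
    skipped. ``chain`` defaults to the first chain in the model.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    mdl = list(structure)[model]
    chains = {c.id: c for c in mdl}
    if chain is None:
        chain = next(iter(chains))
    if chain not in chains:
        raise KeyError(f"chain {chain!r} not in structure (has {sorted(chains)})")
    keys, letters, atoms = [], [], []
    for idx, residue in enumerate(chains[chain]):
        hetflag = residue.id[0]
        if hetflag != " " or residue.resname not in _THREE_TO_ONE:
            continue
        coords = [
            atom.coord
            for atom in residue
            if atom.element != "H" and (atom.altloc in ("", " ", "A"))
        ]
        if not coords:
            warnings.warn(
                f"residue {residue.resname}{residue.id[1]} has no heavy atoms; excluded",
                stacklevel=2,
            )
            continue
        keys.append(idx)
        letters.append(_THREE_TO_ONE[residue.resname])
        atoms.append(np.asarray(coords, dtype=float))
    return ResidueCoordinates(tuple(keys), tuple(letters), tuple(atoms))


@dataclass(frozen=True)
class ContactMap:
    """Symmetric boolean contact relation over residue indices."""

    contacts: np.ndarray  # (n, n) bool, diagonal False
    threshold: float

    def __call__(self, i: int, j: int) -> bool:
        return bool(self.contacts[i, j])

    def to_frame(self) -> pd.DataFrame:
        iu, ju = np.nonzero(np.triu(self.contacts, k=1))
        return pd.DataFrame({"res_i": iu, "res_j": ju})


def build_contact_map(coords: ResidueCoordinates, threshold: float = 6.0) -> ContactMap:
    """Contact iff the minimum inter-residue heavy-atom distance <= threshold Å."""
    n = len(coords)
    if n < 2:
        raise ValueError("need at least two residues with atoms")
    contacts = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d2 = (
                (coords.atoms[i][:, None, :] - coords.atoms[j][None, :, :]) ** 2
            ).sum(-1)
            if d2.min() <= threshold**2:
                contacts[i, j] = contacts[j, i] = True
    return ContactMap(contacts=contacts, threshold=threshold)


def map_columns_to_residues(
    aln: Alignment, structure_row: str, coords: ResidueCoordinates
) -> dict[int, int]:
    """Map analyzed alignment columns to residue indices of the structure.

    The structure's own sequence row in the alignment drives the mapping:
    its k-th non-gap character corresponds to the k-th residue of the chain.
    Columns whose aligned letter disagrees with the structure's residue type
    are reported and dropped.
    """
    if structure_row not in aln.ids:
        raise KeyError(f"structure sequence {structure_row!r} not in alignment")
    row = aln.rows[aln.ids.index(structure_row)]
    mask = ungapped_mask(aln)
    ordinal = 0
    col_to_res: dict[int, int] = {}
    analyzed = set(mask.analyzed)
    mismatches = []
    for col, ch in enumerate(row):
        if ch == GAP:
            continue
        if col in analyzed and ordinal < len(coords):
            if ch == coords.letters[ordinal]:
                col_to_res[col] = ordinal
            else:
                mismatches.append(col)
        ordinal += 1
    if mismatches:
        warnings.warn(
            f"{len(mismatches)} columns disagree with the structure's residues "
            f"and were dropped (first at column {mismatches[0] + 1})",
            stacklevel=2,
        )
    return col_to_res


def _filter_pairs(
    pairs: pd.DataFrame, min_separation: int
) -> pd.DataFrame:
    sep = (pairs["col_i"] - pairs["col_j"]).abs()
    return pairs[sep >= min_separation].reset_index(drop=True)


def topn_accuracy(
    ranked: pd.DataFrame,
    contacts: ContactMap,
    col_to_res: dict[int, int] | None = None,
    min_separation: int = 10,
    n_max: int = 20,
) -> pd.DataFrame:
    """Fraction of the top-n ranked pairs in contact, for n = 1..n_max.

    ``ranked`` must have 1-based ``col_i``/``col_j`` and descending-score
    order (ties resolved by the stable order of the frame). ``col_to_res``
    maps 0-based columns to residue indices; identity when omitted. Pairs
    with unmapped columns are skipped.
    """
    pairs = _filter_pairs(ranked, min_separation)
    flags = []
    for _, p in pairs.iterrows():
        ci, cj = int(p["col_i"]) - 1, int(p["col_j"]) - 1
        if col_to_res is not None:
            if ci not in col_to_res or cj not in col_to_res:
                continue
            ci, cj = col_to_res[ci], col_to_res[cj]
        flags.append(contacts(ci, cj))
    if not flags:
        warnings.warn("no rankable pairs after filtering; empty curve", stacklevel=2)
        return pd.DataFrame(columns=["n", "fraction_in_contact"])
    flags_arr = np.asarray(flags[:n_max], dtype=float)
    cum = np.cumsum(flags_arr) / np.arange(1, flags_arr.size + 1)
    return pd.DataFrame(
        {"n": np.arange(1, flags_arr.size + 1), "fraction_in_contact": cum}
    )


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float | None
    retained: pd.DataFrame
    n_in_contact: int

    @property
    def attained(self) -> bool:
        return self.cutoff is not None


def accuracy_cutoff(
    scored: pd.DataFrame,
    contacts: ContactMap,
    accuracy: float = 0.8,
    col_to_res: dict[int, int] | None = None,
    min_separation: int = 10,
) -> CutoffResult:
    """Lowest score cutoff whose retained pairs reach the requested accuracy.

    Scans every distinct score as a candidate threshold; among pairs with
    score >= cutoff (after the separation filter), the fraction in contact
    must be >= ``accuracy``. Returns a sentinel (``cutoff=None``, empty
    retained set) when unattainable.
    """
    pairs = _filter_pairs(scored, min_separation).copy()
    in_contact = []
    keep = []
    for _, p in pairs.iterrows():
        ci, cj = int(p["col_i"]) - 1, int(p["col_j"]) - 1
        if col_to_res is not None:
            if ci not in col_to_res or cj not in col_to_res:
                keep.append(False)
                in_contact.append(False)
                continue
            ci, cj = col_to_res[ci], col_to_res[cj]
        keep.append(True)
        in_contact.append(contacts(ci, cj))
    pairs = pairs[np.asarray(keep, dtype=bool)].reset_index(drop=True)
    pairs["in_contact"] = np.asarray(in_contact)[np.asarray(keep, dtype=bool)]
    if not len(pairs) or not pairs["in_contact"].any():
        return CutoffResult(None, pairs.iloc[0:0], 0)
    best: CutoffResult | None = None
    for cutoff in sorted(pairs["score"].unique()):
        retained = pairs[pairs["score"] >= cutoff]
        frac = retained["in_contact"].mean()
        if frac >= accuracy:
            best = CutoffResult(
                float(cutoff), retained.reset_index(drop=True),
                int(retained["in_contact"].sum()),
            )
            break  # lowest qualifying cutoff
    if best is None:
        return CutoffResult(None, pairs.iloc[0:0], 0)
    return best


def overlap_analysis(
    method_pairs: dict[str, set[tuple[int, int]]],
    contacts: ContactMap | None = None,
    col_to_res: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Venn-style partition of per-method retained pair sets.

    One row per non-empty region of the set partition (``members`` names
    the methods whose sets the region belongs to), with total pair count
    and — when a contact map is given — the number in contact. A final
    ``union`` row reports the grand totals.
    """
    if len(method_pairs) < 2:
        raise ValueError("need at least two methods to overlap")
    names = sorted(method_pairs)
    normalized = {
        m: {tuple(sorted(p)) for p in s} for m, s in method_pairs.items()
    }
    union = set().union(*normalized.values())

    def contact_count(pairs: set[tuple[int, int]]) -> int | None:
        if contacts is None:
            return None
        cnt = 0
        for ci, cj in pairs:
            i, j = ci - 1, cj - 1
            if col_to_res is not None:
                if i not in col_to_res or j not in col_to_res:
                    continue
                i, j = col_to_res[i], col_to_res[j]
            cnt += contacts(i, j)
        return cnt

    records = []
    for r in range(len(names), 0, -1):
        for members in combinations(names, r):
            region = set.intersection(*(normalized[m] for m in members))
            for other in names:
                if other not in members:
                    region -= normalized[other]
            if region:
                records.append(
                    {
                        "members": "&".join(members),
                        "total": len(region),
                        "in_contact": contact_count(region),
                    }
                )
    records.append(
        {"members": "union", "total": len(union), "in_contact": contact_count(union)}
    )
    return pd.DataFrame(records)


def curation_filter(
    aln: Alignment,
    zp: np.ndarray | None = None,
    mask: ColumnMask | None = None,
    has_structure: bool = False,
    min_depth: int = 126,
    min_ungapped: int = 50,
    zp_cutoff: float = 4.5,
) -> pd.DataFrame:
    """Family-eligibility report for contact prediction.

    Criteria: a structure is available; more than 125 sequences (depth at
    least ``min_depth``); at least ``min_ungapped`` ungapped positions; and
    the covariation-information check — at least L/10 pairs with
    Zp >= ``zp_cutoff``, L being the alignment width.
    """
    if mask is None:
        mask = ungapped_mask(aln)
    rows = [
        ("has_structure", has_structure, int(has_structure), 1),
        ("depth", aln.depth >= min_depth, aln.depth, min_depth),
        ("ungapped_positions", len(mask) >= min_ungapped, len(mask), min_ungapped),
    ]
    if zp is not None:
        needed = aln.width / 10.0
        iu = np.triu_indices(zp.shape[0], k=1)
        n_high = int((zp[iu] >= zp_cutoff).sum())
        rows.append(("covariation_information", n_high >= needed, n_high, needed))
    report = pd.DataFrame(rows, columns=["criterion", "passed", "value", "required"])
    return report
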