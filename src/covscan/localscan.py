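"""Sliding-window local-covariation screen for systematic misalignment.

A registration (shift) error shared by a subpopulation of sequences inflates
covariation among the affected columns: each shifted column "knows" which
rows were shifted, so neighbouring columns become mutually informative for a
reason that has nothing to do with coevolution. The screen computes the mean
pairwise Zp over sliding windows of ungapped columns; windows with mean
Zp >= 2.5 (width 6) warrant investigation, and a family with five or more
such windows is likely to contain a systematic misalignment.

Windows never span an excluded (gapped) column: they slide within maximal
runs of consecutive ungapped columns, so a window always covers a contiguous
stretch of the original alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .msa import ColumnMask

__all__ = ["WindowEntry", "WindowProfile", "window_scan", "flag_windows", "flag_family"]


@dataclass(frozen=True)
class WindowEntry:
    start: int                 # original alignment coordinate, 1-based
    columns: tuple[int, ...]   # original 0-based member columns
    mean_zp: float             # mean over all within-window pairs
    mean_entropy: float        # mean H of member columns, bits (stored positive)


@dataclass(frozen=True)
class WindowProfile:
    width: int
    entries: tuple[WindowEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start": [e.start for e in self.entries],
                "end": [e.columns[-1] + 1 for e in self.entries],
                "mean_zp": [e.mean_zp for e in self.entries],
                "mean_entropy": [e.mean_entropy for e in self.entries],
            }
        )

    def to_bed(self) -> pd.DataFrame:
        """0-based half-open intervals for browser-style viewers."""
        return pd.DataFrame(
            {
                "start": [e.start - 1 for e in self.entries],
                "end": [e.columns[-1] + 1 for e in self.entries],
                "score": [e.mean_zp for e in self.entries],
            }
        )


def window_scan(
    zp: np.ndarray, H: np.ndarray, mask: ColumnMask, width: int = 6
) -> WindowProfile:
    """Mean pairwise Zp and mean entropy in sliding windows of ungapped runs.

    One entry per window of ``width`` consecutive analyzed columns inside
    each run of consecutive original columns; each window averages
    C(width, 2) pair scores. Start coordinates are 1-based original.
    """
    entries: list[WindowEntry] = []
    n_pairs = comb(width, 2)
    for run_start, run_stop in mask.runs():
        for k in range(run_start, run_stop - width + 1):
            members = range(k, k + width)
            sub = zp[np.ix_(members, members)]
            mean_zp = float(sub[np.triu_indices(width, k=1)].sum() / n_pairs)
            entries.append(
                WindowEntry(
                    start=mask.to_original(k) + 1,
                    columns=tuple(mask.to_original(m) for m in members),
                    mean_zp=mean_zp,
                    mean_entropy=float(np.mean(H[list(members)])),
                )
            )
    if not entries:
        warnings.warn(
            f"fewer than {width} consecutive ungapped columns in every run; "
            "window profile is empty",
            stacklevel=2,
        )
    return WindowProfile(width=width, entries=tuple(entries))


def flag_windows(profile: WindowProfile, threshold: float = 2.5) -> list[WindowEntry]:
    """Windows with mean Zp >= threshold, highest first."""
    hits = [e for e in profile.entries if e.mean_zp >= threshold]
    return sorted(hits, key=lambda e: -e.mean_zp)


def flag_family(
    profile: WindowProfile, threshold: float = 2.5, min_windows: int = 5
) -> tuple[bool, list[WindowEntry]]:
    """Is this family likely systematically misaligned?

    True iff at least ``min_windows`` windows reach ``threshold``; the
    witnessing windows are returned either way.
    """
    hits = flag_windows(profile, threshold)
    return len(hits) >= min_windows, hits
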