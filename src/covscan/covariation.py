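"""Non-parametric intra-molecular covariation statistics.

Five pairwise statistics over the ungapped columns of a protein alignment:

``MI``
    mutual information, ``H(i) + H(j) - H(i,j)`` in bits, from plug-in
    (maximum-likelihood) frequency estimates with no pseudocounts and no
    sequence weighting.
``MIp``
    product-corrected MI: ``MI(i,j) - MIbar_i * MIbar_j / MIbar``, where
    ``MIbar_i`` is the mean MI of column *i* with all other columns and
    ``MIbar`` the grand mean over all pairs. The product term estimates the
    background signal shared-phylogeny contributes to every pair.
``Zp``
    MIp standardized over the upper triangle: ``(MIp - mean) / sd``. The
    conventional significance cutoff is 4.5.
``Zpx``
    signed geometric mean of the two position-wise Z-scores of MIp,
    emphasizing pairs that are extreme relative to *both* positions' own
    score distributions rather than the global one.
``dZp`` (``delta_zp``)
    for each position, the gap between consecutive descending-sorted Zp
    values scaled by that position's interquartile range; a pair's score is
    the larger of its two directional gaps. Rewards pairs that stand clear
    of the rest of their positions' lists.

The Little-Chen residual construction (``residual_oracle``) — per-position
Z-scores of OLS residuals of MI on the mean of the two positions' MIbar —
is provided as an independent route to (essentially) the same quantity as
Zpx and is used for cross-validation.

All standardizations use the sample standard deviation (ddof=1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .msa import Alignment, ColumnMask, ungapped_mask

__all__ = [
    "DegenerateAlignmentError",
    "DegeneratePositionError",
    "PositionStats",
    "CovariationAnalysis",
    "CovariationResults",
    "column_entropy",
    "mutual_information",
    "mi_matrix",
    "mip_correct",
    "zp_standardize",
    "position_zscores",
    "zpx_matrix",
    "signed_root",
    "delta_zp_matrix",
    "residual_regression",
    "residual_oracle",
    "significant_pairs",
]


class DegenerateAlignmentError(ValueError):
    """The alignment carries no covariation signal (e.g. fully conserved)."""


class DegeneratePositionError(ValueError):
    """A position's score distribution has zero spread."""


# ---------------------------------------------------------------------------
# elementary information-theoretic quantities


def column_entropy(counts: Mapping[str, float] | Sequence[float]) -> float:
    """Shannon entropy in bits of one column's residue counts.

    Plug-in estimator: probabilities are counts divided by their total.
    Raises on an all-zero table.
    """
    values = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else counts, dtype=float
    )
    if (values < 0).any():
        raise ValueError("negative counts")
    total = values.sum()
    if total == 0:
        raise ValueError("entropy of an empty column is undefined")
    p = values[values > 0] / total
    return float(-(p * np.log2(p)).sum())


def mutual_information(col_i: str, col_j: str) -> float:
    """MI in bits between two gap-free aligned columns of equal depth."""
    if len(col_i) != len(col_j):
        raise ValueError("columns differ in depth")
    pairs: dict[tuple[str, str], int] = {}
    ci: dict[str, int] = {}
    cj: dict[str, int] = {}
    for a, b in zip(col_i, col_j):
        pairs[a, b] = pairs.get((a, b), 0) + 1
        ci[a] = ci.get(a, 0) + 1
        cj[b] = cj.get(b, 0) + 1
    mi = (
        column_entropy(ci)
        + column_entropy(cj)
        - column_entropy(list(pairs.values()))
    )
    return max(mi, 0.0)  # clamp floating-point negatives; MI >= 0 analytically


def _encode(aln: Alignment, mask: ColumnMask) -> np.ndarray:
    """Integer-code the analyzed columns: (depth, n_analyzed) int array."""
    arr = aln.to_array()[:, list(mask.analyzed)]
    _, codes = np.unique(arr, return_inverse=True)
    return codes.reshape(arr.shape)


def _entropy_from_codes(codes: np.ndarray) -> float:
    counts = np.bincount(codes)
    return _entropy_from_counts(counts)


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    h = float(-(p * np.log2(p)).sum())
    return 0.0 if h == 0.0 else h  # avoid -0.0 for conserved columns


def entropies(aln: Alignment, mask: ColumnMask | None = None) -> np.ndarray:
    """Per-analyzed-column Shannon entropy in bits."""
    if mask is None:
        mask = ungapped_mask(aln)
    codes = _encode(aln, mask)
    return np.array([_entropy_from_codes(codes[:, k]) for k in range(codes.shape[1])])


def mi_matrix(aln: Alignment, mask: ColumnMask | None = None) -> np.ndarray:
    """Symmetric MI matrix (bits) over all pairs of analyzed columns."""
    if mask is None:
        mask = ungapped_mask(aln)
    codes = _encode(aln, mask)
    n = codes.shape[1]
    nsym = int(codes.max()) + 1 if codes.size else 1
    h = np.array([_entropy_from_codes(codes[:, k]) for k in range(n)])
    mi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint = np.bincount(codes[:, i] * nsym + codes[:, j])
            hij = _entropy_from_counts(joint)
            mi[i, j] = mi[j, i] = max(h[i] + h[j] - hij, 0.0)
    return mi


# ---------------------------------------------------------------------------
# derived statistics


@dataclass(frozen=True)
class PositionStats:
    """Per-column MI summaries feeding the product correction."""

    H: np.ndarray          # per-column entropy, bits
    MIbar: np.ndarray      # mean MI of each column with all other columns
    MIbar_overall: float   # grand mean MI over the upper triangle


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _degenerate_spread(spread, values) -> np.ndarray:
    """Spread indistinguishable from zero at floating precision."""
    scale = np.maximum(1.0, np.max(np.abs(values)))
    return np.asarray(spread) <= 1e-12 * scale


def mip_correct(
    mi: np.ndarray, H: np.ndarray | None = None
) -> tuple[np.ndarray, PositionStats]:
    """Product correction: ``MIp[i,j] = MI[i,j] - MIbar_i*MIbar_j / MIbar``."""
    n = mi.shape[0]
    if n < 3:
        raise DegenerateAlignmentError("product correction needs >= 3 columns")
    mibar = (mi.sum(axis=1)) / (n - 1)  # diagonal is zero
    overall = float(_upper(mi).mean())
    if overall == 0.0:
        raise DegenerateAlignmentError(
            "overall mean MI is zero (fully conserved alignment): "
            "no covariation signal to correct"
        )
    mip = mi - np.outer(mibar, mibar) / overall
    np.fill_diagonal(mip, 0.0)
    if H is None:
        H = np.zeros(n)
    return mip, PositionStats(H=np.asarray(H, dtype=float), MIbar=mibar, MIbar_overall=overall)


def zp_standardize(mip: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Z-scores of MIp over the upper triangle; returns (Zp, mean, sd)."""
    vals = _upper(mip)
    if vals.size < 2:
        raise DegenerateAlignmentError("Zp needs >= 2 pairs")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if _degenerate_spread(sd, vals):
        raise DegenerateAlignmentError("MIp values have zero spread")
    zp = (mip - mean) / sd
    np.fill_diagonal(zp, 0.0)
    return zp, mean, sd


def position_zscores(mip: np.ndarray, on_degenerate: str = "raise") -> np.ndarray:
    """Row-wise Z-scores: ``Zx[i, j] = (MIp[i,j] - mean_i) / sd_i``.

    The mean and sd for row *i* are over its off-diagonal entries. The
    returned matrix is *not* symmetric: ``Zx[i, j]`` scores pair (i, j)
    within position i's own distribution. A position whose MIp row is
    constant (typically a fully conserved column) has no defined Z-scores:
    with ``on_degenerate='raise'`` this is an error, with ``'nan'`` the
    row becomes NaN.
    """
    n = mip.shape[0]
    if n < 4:
        raise DegenerateAlignmentError("position-wise Z-scores need >= 3 partners")
    mask = ~np.eye(n, dtype=bool)
    rows = np.where(mask, mip, np.nan)
    means = np.nanmean(rows, axis=1)
    sds = np.nanstd(rows, axis=1, ddof=1)
    bad = np.nonzero(_degenerate_spread(sds, mip))[0]
    if bad.size:
        if on_degenerate == "raise":
            raise DegeneratePositionError(
                f"column {bad[0]} has a constant MIp distribution"
            )
        sds = sds.copy()
        sds[bad] = np.nan
    zx = (mip - means[:, None]) / sds[:, None]
    np.fill_diagonal(zx, 0.0)
    return zx


def signed_root(product: np.ndarray, both_nonneg: np.ndarray) -> np.ndarray:
    """Signed square root: ``+sqrt(p)`` where both factors were >= 0, else
    ``-sqrt(|p|)``. Keeps both-negative products from ranking as strong."""
    return np.where(both_nonneg, np.sqrt(np.abs(product)), -np.sqrt(np.abs(product)))


def zpx_matrix(zx: np.ndarray) -> np.ndarray:
    """Signed geometric mean of the two directional Z-scores of each pair."""
    product = zx * zx.T
    both = (zx >= 0) & (zx.T >= 0)
    zpx = signed_root(product, both)
    np.fill_diagonal(zpx, 0.0)
    return zpx


def delta_zp_matrix(
    zp: np.ndarray, return_lists: bool = False, on_degenerate: str = "raise"
) -> np.ndarray | tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """IQR-scaled sequential rank-gap statistic.

    For each position *i*, its Zp values with all partners are sorted
    descending into a list L_i (ties broken by ascending partner index);
    the directional score of the pair ranked k is
    ``(L_i[k] - L_i[k+1]) / IQR_i`` with the last-ranked pair scored 0, and
    ``IQR_i`` the 75th minus 25th percentile of L_i (linear-interpolation
    quantiles). The pair score is the larger of its two directional scores.
    """
    n = zp.shape[0]
    if n < 6:
        raise DegenerateAlignmentError("delta-Zp needs >= 5 partners per position")
    directional = np.zeros((n, n))
    lists: list[np.ndarray] = []
    iqrs = np.zeros(n)
    partners_all = np.arange(n)
    for i in range(n):
        partners = partners_all[partners_all != i]
        vals = zp[i, partners]
        # stable sort: descending Zp, then ascending partner index
        order = np.lexsort((partners, -vals))
        L = vals[order]
        iqr = float(np.percentile(L, 75) - np.percentile(L, 25))
        if _degenerate_spread(iqr, L):
            if on_degenerate == "raise":
                raise DegeneratePositionError(
                    f"IQR of position {i}'s Zp list is zero"
                )
            iqr = np.nan
        gaps = np.zeros(L.size)
        gaps[:-1] = (L[:-1] - L[1:]) / iqr
        directional[i, partners[order]] = gaps
        lists.append(L)
        iqrs[i] = iqr
    with np.errstate(invalid="ignore"):
        dzp = np.fmax(directional, directional.T)  # ignores a one-sided NaN
    np.fill_diagonal(dzp, 0.0)
    if return_lists:
        return dzp, lists, iqrs
    return dzp


def residual_regression(mi: np.ndarray) -> tuple[float, float, np.ndarray]:
    """OLS of MI(i,j) on the mean of the two positions' MIbar values.

    Returns (slope, intercept, residual matrix). The residual is the
    Little-Chen replacement for MIp: both subtract an estimate of the
    shared-phylogeny background from MI.
    """
    n = mi.shape[0]
    if n < 4:
        raise DegenerateAlignmentError("residual statistic needs >= 4 columns")
    mibar = mi.sum(axis=1) / (n - 1)
    x_mat = (mibar[:, None] + mibar[None, :]) / 2.0
    iu = np.triu_indices(n, k=1)
    x, y = x_mat[iu], mi[iu]
    if np.ptp(x) == 0.0:  # constant regressor: fit the mean
        slope, intercept = 0.0, float(y.mean())
    else:
        slope, intercept = np.polyfit(x, y, 1)
    resid = mi - (intercept + slope * x_mat)
    np.fill_diagonal(resid, 0.0)
    return float(slope), float(intercept), resid


def residual_oracle(
    mi: np.ndarray, return_product: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Little-Chen-style residual statistic.

    MI(i,j) is regressed (OLS) on the mean of the two positions' MIbar
    values across all pairs; the per-position Z-scores of the residuals are
    combined by the same signed-root product as Zpx. Returns the rooted
    matrix, plus the raw product matrix if ``return_product``.
    """
    _, _, resid = residual_regression(mi)
    zx = position_zscores(resid)
    product = zx * zx.T
    both = (zx >= 0) & (zx.T >= 0)
    rooted = signed_root(product, both)
    np.fill_diagonal(rooted, 0.0)
    if return_product:
        signed_product = np.where(both, np.abs(product), -np.abs(product))
        np.fill_diagonal(signed_product, 0.0)
        return rooted, signed_product
    return rooted


def significant_pairs(
    matrix: np.ndarray,
    cutoff: float = 4.5,
    min_separation: int = 10,
    mask: ColumnMask | None = None,
) -> pd.DataFrame:
    """Ranked pairs with score >= cutoff and |i-j| >= min_separation.

    Separation is measured in original alignment coordinates (via ``mask``
    when given, else analyzed indices are taken as original). The returned
    frame has 1-based columns ``col_i``/``col_j`` and is sorted by
    descending score with ties broken by (smaller i, smaller j).
    """
    n = matrix.shape[0]
    coords = (
        np.asarray(mask.analyzed) if mask is not None else np.arange(n)
    )
    iu, ju = np.triu_indices(n, k=1)
    sep = np.abs(coords[iu] - coords[ju])
    score = matrix[iu, ju]
    keep = (score >= cutoff) & (sep >= min_separation)
    frame = pd.DataFrame(
        {
            "col_i": coords[iu][keep] + 1,
            "col_j": coords[ju][keep] + 1,
            "score": score[keep],
        }
    )
    frame = frame.sort_values(
        ["score", "col_i", "col_j"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return frame


# ---------------------------------------------------------------------------
# model / results


class CovariationAnalysis:
    """Covariation model of a protein multiple sequence alignment.

    Computes the full family of statistics on the ungapped columns::

        results = CovariationAnalysis(alignment).fit()
        results.summary()

    Parameters
    ----------
    alignment : the MSA to analyze. Columns containing any gap are excluded.
    """

    def __init__(self, alignment: Alignment):
        self.alignment = alignment
        self.mask = ungapped_mask(alignment)

    @classmethod
    def from_file(cls, path, format: str = "fasta") -> "CovariationAnalysis":
        from .msa import read_alignment

        return cls(read_alignment(path, format))

    def fit(self) -> "CovariationResults":
        """Compute MI, MIp, Zp, Zpx and dZp over analyzed column pairs."""
        if len(self.mask) < 6:
            raise DegenerateAlignmentError(
                f"only {len(self.mask)} ungapped columns; need at least 6"
            )
        H = entropies(self.alignment, self.mask)
        mi = mi_matrix(self.alignment, self.mask)
        mip, pos_stats = mip_correct(mi, H)
        zp, zp_mean, zp_sd = zp_standardize(mip)
        # positions with constant MIp rows (fully conserved columns) have no
        # position-wise Z; they get NaN in Zpx/dZp rather than failing the fit
        zx = position_zscores(mip, on_degenerate="nan")
        if np.isnan(zx).any():
            n_bad = int(np.isnan(zx).any(axis=1).sum())
            warnings.warn(
                f"{n_bad} position(s) have degenerate MIp distributions; "
                "their Zpx/dZp scores are NaN",
                stacklevel=2,
            )
        zpx = zpx_matrix(zx)
        dzp, lists, iqrs = delta_zp_matrix(zp, return_lists=True, on_degenerate="nan")
        return CovariationResults(
            model=self,
            H=H,
            mi=mi,
            mip=mip,
            zp=zp,
            zpx=zpx,
            delta_zp=dzp,
            per_position_z=zx,
            position_stats=pos_stats,
            zp_mean=zp_mean,
            zp_sd=zp_sd,
            ordered_lists=lists,
            iqr=iqrs,
        )


@dataclass
class CovariationResults:
    """Fitted covariation statistics for one alignment.

    Matrices are indexed by *analyzed* column (see ``mask`` for original
    coordinates); reports translate to 1-based alignment coordinates.
    """

    model: CovariationAnalysis
    H: np.ndarray
    mi: np.ndarray
    mip: np.ndarray
    zp: np.ndarray
    zpx: np.ndarray
    delta_zp: np.ndarray
    per_position_z: np.ndarray
    position_stats: PositionStats
    zp_mean: float
    zp_sd: float
    ordered_lists: list[np.ndarray]
    iqr: np.ndarray

    _STATS = ("mi", "mip", "zp", "zpx", "delta_zp")

    @property
    def mask(self) -> ColumnMask:
        return self.model.mask

    def matrix(self, statistic: str) -> np.ndarray:
        if statistic not in self._STATS:
            raise KeyError(f"unknown statistic {statistic!r}; one of {self._STATS}")
        return getattr(self, statistic)

    def significant_pairs(
        self, statistic: str = "zp", cutoff: float = 4.5, min_separation: int = 10
    ) -> pd.DataFrame:
        return significant_pairs(
            self.matrix(statistic), cutoff, min_separation, self.mask
        )

    def pair_frame(self, min_separation: int = 0) -> pd.DataFrame:
        """Long table of all analyzed pairs with every statistic."""
        n = self.zp.shape[0]
        coords = np.asarray(self.mask.analyzed)
        iu, ju = np.triu_indices(n, k=1)
        frame = pd.DataFrame({"col_i": coords[iu] + 1, "col_j": coords[ju] + 1})
        for s in self._STATS:
            frame[s] = self.matrix(s)[iu, ju]
        sep = np.abs(frame["col_i"] - frame["col_j"])
        return frame[sep >= min_separation].reset_index(drop=True)

    def window_scan(self, width: int = 6):
        from .localscan import window_scan

        return window_scan(self.zp, self.H, self.mask, width=width)

    def summary(self, top: int = 10, min_separation: int = 10) -> pd.DataFrame:
        """Top pairs by Zp, with all five statistics side by side."""
        frame = self.pair_frame(min_separation=min_separation)
        return (
            frame.sort_values("zp", ascending=False)
            .head(top)
            .reset_index(drop=True)
        )

    def __str__(self) -> str:
        aln = self.model.alignment
        lines = [
            "Covariation results",
            f"  sequences: {aln.depth}   columns: {aln.width}"
            f"   analyzed (ungapped): {len(self.mask)}",
            f"  MIp mean {self.zp_mean:.4g}, sd {self.zp_sd:.4g}",
            "",
            self.summary().to_string(index=False, float_format="%.3f"),
        ]
        return "\n".join(lines)
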