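"""Unit and property tests for the covariation statistics.

Brute-force oracles (naive loops, independent of the vectorized paths) are
defined at the top and frozen expected values computed from them inline.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import covscan as cs
from covscan import (
    Alignment,
    DegenerateAlignmentError,
    DegeneratePositionError,
    column_entropy,
    mutual_information,
)
from covscan.covariation import (
    delta_zp_matrix,
    mi_matrix,
    mip_correct,
    position_zscores,
    residual_oracle,
    residual_regression,
    significant_pairs,
    zp_standardize,
    zpx_matrix,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles


def brute_delta_zp(zp):
    """Naive sort + type-7 quantile implementation of the rank-gap statistic."""
    n = zp.shape[0]
    directional = np.zeros((n, n))
    for i in range(n):
        partners = [j for j in range(n) if j != i]
        ranked = sorted(partners, key=lambda j: (-zp[i, j], j))
        values = [zp[i, j] for j in ranked]
        iqr = np.percentile(values, 75) - np.percentile(values, 25)
        for k, j in enumerate(ranked):
            if k == len(ranked) - 1:
                directional[i, j] = 0.0
            else:
                directional[i, j] = (values[k] - values[k + 1]) / iqr
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = max(directional[i, j], directional[j, i])
    return out, directional


def random_symmetric(rng, n):
    m = rng.normal(size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


# ---------------------------------------------------------------------------
# column entropy


@pytest.mark.parametrize(
    "counts, expected",
    [
        ({"A": 10}, 0.0),                       # conserved column: no entropy
        ({"A": 5, "C": 5}, 1.0),                # two residues at 50/50
        ([1] * 20, np.log2(20)),                # uniform over the 20 residues
        ({"A": 3, "C": 1}, 2.0 - 0.75 * np.log2(3)),  # hand computation
    ],
)
def test_column_entropy_known_values(counts, expected):
    assert column_entropy(counts) == pytest.approx(expected, abs=1e-12)


def test_column_entropy_rejects_empty_and_negative():
    with pytest.raises(ValueError):
        column_entropy({"A": 0})
    with pytest.raises(ValueError):
        column_entropy([2, -1])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=25))
def test_column_entropy_bounds(counts):
    if sum(counts) == 0:
        return
    h = column_entropy(counts)
    k = sum(c > 0 for c in counts)
    assert -1e-12 <= h <= np.log2(max(k, 1)) + 1e-12


# ---------------------------------------------------------------------------
# mutual information


@pytest.mark.parametrize(
    "ci, cj, expected",
    [
        ("AAAA", "CCCC", 0.0),      # both conserved: nothing can covary
        ("AACC", "DDEE", 1.0),      # binary lockstep: MI = H = 1 bit
        ("AACC", "ACAC", 0.0),      # independent margins
        ("ACDE", "ACDE", 2.0),      # identity map on 4 symbols
    ],
)
def test_mutual_information_known_values(ci, cj, expected):
    assert mutual_information(ci, cj) == pytest.approx(expected, abs=1e-12)
    assert mutual_information(cj, ci) == pytest.approx(expected, abs=1e-12)


def test_mutual_information_depth_mismatch():
    with pytest.raises(ValueError):
        mutual_information("AAA", "AAAA")


def test_mi_matrix_matches_pairwise_brute_force(toy_alignment):
    m = mi_matrix(toy_alignment)
    for i in range(4):
        for j in range(i + 1, 6):
            expected = mutual_information(
                toy_alignment.column(i), toy_alignment.column(j)
            )
            assert m[i, j] == pytest.approx(expected, abs=1e-12)


def test_mi_bounded_by_column_entropies(background_results):
    res = background_results
    n = res.mi.shape[0]
    iu = np.triu_indices(n, k=1)
    assert (res.mi[iu] >= 0).all()
    cap = np.minimum(res.H[:, None], res.H[None, :])
    assert (res.mi <= cap + 1e-9).all()
    assert np.array_equal(res.mi, res.mi.T)


# ---------------------------------------------------------------------------
# product correction


def test_mip_constant_mi_corrects_to_zero():
    n = 5
    mi = np.full((n, n), 0.37)
    np.fill_diagonal(mi, 0.0)
    mip, stats = mip_correct(mi)
    iu = np.triu_indices(n, k=1)
    assert mip[iu] == pytest.approx(np.zeros(len(iu[0])), abs=1e-12)
    assert stats.MIbar_overall == pytest.approx(0.37)


def test_mip_three_column_hand_computation():
    # MI pairs (0.2, 0.2, 0.8): MIbar = (0.2, 0.5, 0.5), overall mean 0.4
    mi = np.array([[0, 0.2, 0.2], [0.2, 0, 0.8], [0.2, 0.8, 0]], dtype=float)
    mip, stats = mip_correct(mi)
    assert stats.MIbar == pytest.approx([0.2, 0.5, 0.5])
    assert mip[0, 1] == pytest.approx(0.2 - 0.2 * 0.5 / 0.4)   # -0.05
    assert mip[0, 2] == pytest.approx(-0.05)
    assert mip[1, 2] == pytest.approx(0.8 - 0.5 * 0.5 / 0.4)   # 0.175


def test_mip_fully_conserved_alignment_is_degenerate():
    aln = Alignment(("a", "b", "c"), ("AAAA", "AAAA", "AAAA"))
    mi = mi_matrix(aln)
    assert mi.max() == 0.0
    with pytest.raises(DegenerateAlignmentError, match="conserved"):
        mip_correct(mi)


# ---------------------------------------------------------------------------
# Zp standardization


def test_zp_is_standardized(background_results):
    iu = np.triu_indices(background_results.zp.shape[0], k=1)
    vals = background_results.zp[iu]
    assert abs(vals.mean()) < 1e-9
    assert abs(vals.std(ddof=1) - 1) < 1e-9


def test_zp_analytic_single_outlier():
    # 4 columns, six pair values: five zeros and one v
    v = 0.6
    mip = np.zeros((4, 4))
    mip[2, 3] = mip[3, 2] = v
    zp, mean, sd = zp_standardize(mip)
    assert mean == pytest.approx(v / 6)
    assert sd == pytest.approx(v / np.sqrt(6))
    assert zp[2, 3] == pytest.approx(5 / np.sqrt(6))
    # a pair exactly at the mean scores 0
    mip2 = np.array([[0, 1.0, 2.0], [1.0, 0, 3.0], [2.0, 3.0, 0]])
    zp2, mean2, _ = zp_standardize(mip2)
    assert mean2 == pytest.approx(2.0)
    assert zp2[0, 2] == pytest.approx(0.0)


def test_zp_zero_spread_is_degenerate():
    mip = np.full((4, 4), 0.2)
    np.fill_diagonal(mip, 0.0)
    with pytest.raises(DegenerateAlignmentError):
        zp_standardize(mip)


# ---------------------------------------------------------------------------
# position-wise Z and Zpx


def test_position_zscores_rows_standardized_and_match_loops():
    rng = np.random.default_rng(3)
    mip = random_symmetric(rng, 6)
    zx = position_zscores(mip)
    for i in range(6):
        row = [mip[i, j] for j in range(6) if j != i]
        mu, sd = np.mean(row), np.std(row, ddof=1)
        for j in range(6):
            if j != i:
                assert zx[i, j] == pytest.approx((mip[i, j] - mu) / sd)
        vals = [zx[i, j] for j in range(6) if j != i]
        assert np.mean(vals) == pytest.approx(0, abs=1e-12)
        assert np.std(vals, ddof=1) == pytest.approx(1)


def test_position_zscores_constant_row_is_degenerate():
    mip = np.zeros((5, 5))
    mip[1, 2] = mip[2, 1] = 1.0  # rows 0, 3, 4 constant at 0
    with pytest.raises(DegeneratePositionError, match="column 0"):
        position_zscores(mip)


def test_position_zscores_affine_invariance():
    # shifting/scaling each row leaves its Z-scores unchanged
    rng = np.random.default_rng(4)
    mip = random_symmetric(rng, 7)
    scales = rng.uniform(0.5, 3.0, 7)
    shifts = rng.normal(size=7)
    transformed = mip * scales[:, None] + shifts[:, None]
    np.fill_diagonal(transformed, 0.0)
    zx_ref = position_zscores(mip)
    # rebuild row-by-row because the transform breaks matrix symmetry
    n = 7
    mask = ~np.eye(n, dtype=bool)
    rows = np.where(mask, transformed, np.nan)
    mu = np.nanmean(rows, axis=1)
    sd = np.nanstd(rows, axis=1, ddof=1)
    zx_t = (transformed - mu[:, None]) / sd[:, None]
    np.fill_diagonal(zx_t, 0.0)
    assert zx_t == pytest.approx(zx_ref, abs=1e-9)


@pytest.mark.parametrize(
    "zi, zj, expected",
    [
        (2.0, 2.0, 2.0),               # sqrt of a square
        (4.0, 1.0, 2.0),               # geometric mean
        (-2.0, 3.0, -np.sqrt(6)),      # mixed signs: negative root
        (-2.0, -3.0, -np.sqrt(6)),     # both negative must not rank as strong
        (0.0, 5.0, 0.0),
    ],
)
def test_zpx_signed_root_convention(zi, zj, expected):
    zx = np.zeros((4, 4))
    zx[0, 1], zx[1, 0] = zi, zj
    zpx = zpx_matrix(zx)
    assert zpx[0, 1] == pytest.approx(expected)
    assert zpx[1, 0] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# delta-Zp


def test_delta_zp_matches_brute_force_on_random_matrices():
    rng = np.random.default_rng(7)
    for _ in range(100):
        zp = random_symmetric(rng, 8)
        expected, _ = brute_delta_zp(zp)
        got = delta_zp_matrix(zp)
        assert np.array_equal(got, expected)


def test_delta_zp_directional_gap_from_ordered_list():
    # position 0's Zp list is [9, 3, 2, 1, 0, -1]; the top pair's gap is
    # (9-3)/IQR with linear-interpolation quantiles
    rng = np.random.default_rng(11)
    zp = random_symmetric(rng, 7)
    values = [9.0, 3.0, 2.0, 1.0, 0.0, -1.0]
    for j, v in enumerate(values, start=1):
        zp[0, j] = zp[j, 0] = v
    _, directional = brute_delta_zp(zp)
    iqr = np.percentile(values, 75) - np.percentile(values, 25)
    assert directional[0, 1] == pytest.approx(6.0 / iqr)
    dzp = delta_zp_matrix(zp)
    # pair score is the larger of the two directional gaps
    assert dzp[0, 1] == pytest.approx(max(directional[0, 1], directional[1, 0]))


def test_delta_zp_constant_list_is_degenerate():
    zp = np.zeros((7, 7))
    with pytest.raises(DegeneratePositionError):
        delta_zp_matrix(zp)


def test_delta_zp_last_ranked_pair_scores_zero_from_that_side():
    rng = np.random.default_rng(9)
    zp = random_symmetric(rng, 8)
    _, directional = brute_delta_zp(zp)
    for i in range(8):
        worst = min((j for j in range(8) if j != i), key=lambda j: (zp[i, j], -j))
        assert directional[i, worst] == 0.0


# ---------------------------------------------------------------------------
# residual (Little-Chen) construction


def test_residual_regression_constant_mi_gives_zero_residuals():
    mi = np.full((5, 5), 0.4)
    np.fill_diagonal(mi, 0.0)
    _, _, resid = residual_regression(mi)
    assert resid == pytest.approx(np.zeros((5, 5)), abs=1e-12)


def test_residual_statistic_tracks_zpx_on_synthetic_background(background_alignment):
    res = cs.CovariationAnalysis(background_alignment).fit()
    mi = res.mi
    rooted = residual_oracle(mi)
    iu = np.triu_indices(mi.shape[0], k=1)
    r = np.corrcoef(rooted[iu], res.zpx[iu])[0, 1]
    assert r > 0.9


def test_residual_vs_mip_regression_is_near_identity(background_alignment):
    res = cs.CovariationAnalysis(background_alignment).fit()
    _, _, resid = residual_regression(res.mi)
    iu = np.triu_indices(res.mi.shape[0], k=1)
    slope, intercept = np.polyfit(res.mip[iu], resid[iu], 1)
    assert slope == pytest.approx(1.0, abs=0.05)
    assert intercept == pytest.approx(0.0, abs=0.01)


# ---------------------------------------------------------------------------
# significant pairs and whole-model behaviour


def test_significant_pairs_selection_and_ordering():
    n = 12
    m = np.zeros((n, n))
    m[0, 11] = m[11, 0] = 9.0   # separation 11: kept
    m[2, 5] = m[5, 2] = 8.0     # separation 3: dropped
    out = significant_pairs(m, cutoff=4.5, min_separation=10)
    assert list(out.itertuples(index=False)) == [(1, 12, 9.0)]
    # cutoff above the maximum: empty
    assert significant_pairs(m, cutoff=10.0, min_separation=0).empty
    # no cutoff, no separation: all C(n,2) pairs
    assert len(significant_pairs(m, cutoff=-np.inf, min_separation=0)) == 66


def test_all_statistics_invariant_under_row_permutation(toy_alignment):
    rng = np.random.default_rng(5)
    order = rng.permutation(toy_alignment.depth)
    res_a = cs.CovariationAnalysis(toy_alignment).fit()
    res_b = cs.CovariationAnalysis(toy_alignment.permuted(order)).fit()
    for stat in ("mi", "mip", "zp", "zpx", "delta_zp"):
        assert np.array_equal(res_a.matrix(stat), res_b.matrix(stat))


def test_results_summary_and_pair_frame(toy_alignment):
    res = cs.CovariationAnalysis(toy_alignment).fit()
    frame = res.pair_frame()
    assert len(frame) == 66  # C(12,2)
    assert set(frame.columns) == {"col_i", "col_j", "mi", "mip", "zp", "zpx", "delta_zp"}
    top = res.summary(top=5, min_separation=0)
    assert len(top) == 5
    assert (top["zp"].values == np.sort(top["zp"].values)[::-1]).all()
    assert "Covariation results" in str(res)


def test_fit_tolerates_fully_conserved_column():
    # a conserved column has MIbar 0 and a constant MIp row: Zp stays
    # defined, Zpx/dZp go NaN for that position, nothing crashes
    bg = cs.simulate_background(60, 12, seed=2)
    rows = tuple("W" + r for r in bg.rows)
    res = cs.CovariationAnalysis(Alignment(bg.ids, rows)).fit()
    assert res.H[0] == 0.0
    assert np.isfinite(res.zp).all()
    assert np.isnan(res.zpx[0, 1:]).all()
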