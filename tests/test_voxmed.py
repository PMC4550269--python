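import numpy as np
import pytest

from voxmediate.voxmed import (
    cluster_threshold_mc,
    cluster_threshold_perm,
    compact_mask,
    label_clusters,
    mediation_scan,
    standardized_ols,
)


@pytest.fixture
def rng():
    return np.random.default_rng(21)


# standardized OLS ---------------------------------------------------------

def test_standardized_ols_identity_and_orthogonal(rng):
    x = rng.standard_normal(100)
    beta, p = standardized_ols(x * 3.0 + 2.0, x)
    assert beta == pytest.approx(1.0) and p < 1e-30

    y0 = rng.standard_normal(100)
    y_orth = y0 - x * (x @ y0) / (x @ x)
    y_orth = y_orth - y_orth.mean()
    x_c = x - x.mean()
    y_orth = y_orth - x_c * (x_c @ y_orth) / (x_c @ x_c)  # orthogonal to centred x
    beta, _ = standardized_ols(y_orth, x)
    assert abs(beta) < 1e-10


def test_standardized_ols_matches_normal_equations_oracle():
    """Six-point toy dataset against a hand-rolled normal-equations solve."""
    y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
    x = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0])
    cov = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 2.0])
    z = lambda v: (v - v.mean()) / v.std(ddof=1)
    D = np.column_stack([np.ones(6), z(x), z(cov)])
    beta_oracle = np.linalg.inv(D.T @ D) @ D.T @ z(y)
    beta, _ = standardized_ols(y, x, cov)
    assert beta == pytest.approx(beta_oracle[1], abs=1e-10)


def test_standardized_ols_errors(rng):
    x = rng.standard_normal(30)
    with pytest.raises(ValueError, match="zero variance"):
        standardized_ols(np.ones(30), x)
    with pytest.raises(ValueError, match="zero variance"):
        standardized_ols(x, np.ones(30))
    with pytest.raises(ValueError, match="collinear"):
        standardized_ols(rng.standard_normal(30), x, covariates=x.copy())


# mediation scan -----------------------------------------------------------

def test_scan_conjunction_gate_blocks_everything(rng):
    """If step 1 is non-significant no voxel can be significant, whatever
    the maps look like."""
    n = 60
    x = rng.standard_normal(n)
    g = rng.integers(0, 2, n).astype(float)
    y0 = rng.standard_normal(n)
    # orthogonalise y to [1, x, g] so the total effect is exactly zero
    D = np.column_stack([np.ones(n), x, g])
    y = y0 - D @ np.linalg.lstsq(D, y0, rcond=None)[0]
    stack = np.tile(x[:, None], (1, 50)) + 0.01 * rng.standard_normal((n, 50))
    mm = mediation_scan(x, y, g, stack)
    assert mm.p_c > 0.99 and not mm.sig.any()


def test_scan_constant_voxel_marked_nonsignificant(rng):
    n = 50
    x, g = rng.standard_normal(n), rng.integers(0, 2, n).astype(float)
    y = x + rng.standard_normal(n)
    stack = rng.standard_normal((n, 5))
    stack[:, 2] = 7.0
    mm = mediation_scan(x, y, g, stack)
    assert not mm.sig[2] and mm.ab[2] == 0.0 and mm.p_a[2] == 1.0


def test_scan_planted_cluster_and_false_positive_bound(rng):
    """With a strong planted mediator block, significant voxels concentrate
    there; the out-of-block false-positive count stays within a binomial
    bound of the nominal joint null rate times the step-1 gate."""
    n, V = 298, 4000
    x = rng.standard_normal(n)
    g = (rng.random(n) < 0.32).astype(float)
    m_lat = -0.4 * x + np.sqrt(1 - 0.16) * rng.standard_normal(n)
    y = 0.4 * x + 0.4 * m_lat + rng.standard_normal(n)
    stack = rng.standard_normal((n, V))
    planted = np.arange(30)
    stack[:, planted] = m_lat[:, None] + 0.6 * rng.standard_normal((n, 30))
    mm = mediation_scan(x, y, g, stack)
    assert mm.sig[planted].mean() > 0.8
    # null voxels: joint rate alpha^2 given the (significant) step-1 gate
    null_rate = mm.sig[30:].mean()
    assert null_rate < 0.0025 + 4 * np.sqrt(0.0025 / (V - 30))


# cluster labelling --------------------------------------------------------

def test_label_clusters_cases():
    grid = np.zeros((5, 5, 5), bool)
    grid[0, 0, 0] = grid[4, 4, 4] = True
    table, _ = label_clusters(grid)
    assert len(table) == 2 and set(table["size_vox"]) == {1}

    block = np.zeros((4, 4, 4), bool)
    block[1:3, 1:3, 1:3] = True
    for conn in (6, 18, 26):
        table, _ = label_clusters(block, connectivity=conn)
        assert len(table) == 1 and table.loc[0, "size_vox"] == 8

    diag = np.zeros((4, 4, 4), bool)
    diag[1, 1, 1] = diag[2, 2, 2] = True
    assert len(label_clusters(diag, connectivity=26)[0]) == 1
    assert len(label_clusters(diag, connectivity=6)[0]) == 2

    empty, _ = label_clusters(np.zeros((3, 3, 3), bool))
    assert empty.empty


def test_label_clusters_peak_and_mni():
    mask = np.zeros((5, 5, 5), bool)
    mask[1:4, 2, 2] = True
    ab = np.zeros((5, 5, 5))
    ab[2, 2, 2] = -0.9  # peak by |ab|
    ab[1, 2, 2] = 0.5
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    affine[:3, 3] = -6.0
    table, _ = label_clusters(mask, ab, affine, voxel_volume_mm3=27.0)
    row = table.iloc[0]
    assert row["peak_ab"] == -0.9
    assert (row["peak_x"], row["peak_y"], row["peak_z"]) == (0.0, 0.0, 0.0)
    assert row["size_mm3"] == 81.0


# Monte-Carlo threshold ----------------------------------------------------

def test_compact_mask_exact_size_and_compactness():
    mask = compact_mask(500)
    assert mask.sum() == 500
    com = np.array(np.nonzero(mask)).mean(axis=1)
    centre = (np.asarray(mask.shape) - 1) / 2
    assert np.allclose(com, centre, atol=0.5)


def test_mc_threshold_degenerate_and_independent_cases():
    # voxel_p = 1: every voxel supra, one giant component
    thr = cluster_threshold_mc(200, fwhm=(0, 0, 0), voxel_p=1.0, n_iter=20, seed=0)
    assert thr == 200
    # unsmoothed noise at voxel_p = 0.001 on a 10k mask: isolated voxels.
    # Poisson oracle for adjacent pairs: expected 10000 * c/2 * 0.001^2 pairs
    # per field = 0.03 (6-connectivity, c=6) -> P(max >= 2) ~ 0.03 -> thr <= 2;
    # with c=26 the pair rate is 0.13 -> thr = 3.
    thr6 = cluster_threshold_mc(
        10_000, fwhm=(0, 0, 0), voxel_p=0.001, n_iter=200, connectivity=6, seed=1
    )
    assert thr6 <= 2
    thr26 = cluster_threshold_mc(
        10_000, fwhm=(0, 0, 0), voxel_p=0.001, n_iter=200, connectivity=26, seed=1
    )
    assert thr26 <= 3


def test_mc_threshold_monotone_in_fwhm_and_voxel_p():
    common = dict(mask_size=8000, voxel_size=3.0, alpha=0.05, n_iter=150, seed=3)
    t_smooth = [
        cluster_threshold_mc(fwhm=(f, f, f), voxel_p=0.001, **common)
        for f in (0.0, 6.0, 12.0)
    ]
    assert t_smooth == sorted(t_smooth)
    t_p = [
        cluster_threshold_mc(fwhm=(8.0, 8.0, 8.0), voxel_p=p, **common)
        for p in (0.0001, 0.001, 0.01)
    ]
    assert t_p == sorted(t_p)


def test_mc_threshold_validation():
    with pytest.raises(ValueError):
        cluster_threshold_mc(100, (8, 8, 8), voxel_p=1.5)
    with pytest.raises(ValueError):
        cluster_threshold_mc(100, (-1, 8, 8), voxel_p=0.01)


# permutation threshold ----------------------------------------------------

def null_data(rng, n=60, V=216):
    pool = rng.integers(1, 4, size=(n, 98)).astype(float)
    Y = rng.standard_normal(n)
    g = (rng.random(n) < 0.32).astype(float)
    stack = rng.standard_normal((n, V))
    mask = np.ones((6, 6, 6), bool)
    return pool, Y, g, stack, mask


def test_perm_threshold_pure_noise_small(rng):
    pool, Y, g, stack, mask = null_data(rng)
    thr = cluster_threshold_perm(pool, Y, g, stack, mask, n_perm=200, seed=5)
    assert thr <= 3


def test_perm_threshold_degenerate_alpha(rng):
    pool, Y, g, stack, mask = null_data(rng)
    assert cluster_threshold_perm(pool, Y, g, stack, mask, n_perm=120, alpha=1.0, seed=6) == 0


def test_perm_threshold_warns_small_nperm(rng):
    pool, Y, g, stack, mask = null_data(rng)
    with pytest.warns(UserWarning, match="unstable"):
        cluster_threshold_perm(pool, Y, g, stack, mask, n_perm=50, seed=7)


def test_perm_threshold_signal_loci_excluded_matches_noise(rng):
    """When the loci that truly drive the score are absent from the pool,
    the permutation null is exchangeable with the pure-noise case."""
    n, V = 60, 216
    pool, _, g, stack, mask = null_data(rng)
    true_codes = rng.integers(1, 4, size=(n, 10)).astype(float)
    x = (true_codes @ rng.normal(size=10))
    x = (x - x.mean()) / x.std()
    m = -0.4 * x + rng.standard_normal(n)
    y = 0.4 * x + 0.4 * m + rng.standard_normal(n)
    planted_stack = stack.copy()
    planted_stack[:, :8] = m[:, None] + 0.5 * rng.standard_normal((n, 8))
    thr_signal = cluster_threshold_perm(pool, y, g, planted_stack, mask, n_perm=200, seed=8)
    thr_noise = cluster_threshold_perm(pool, rng.standard_normal(n), g, stack, mask, n_perm=200, seed=8)
    assert abs(thr_signal - thr_noise) <= 1


def test_perm_and_mc_thresholds_agree_on_matched_null(rng):
    """Unit-weight permutation on spatially smoothed null stacks agrees with
    the Monte-Carlo threshold at matched smoothness within 2 voxels."""
    from scipy.ndimage import gaussian_filter

    n, grid = 80, (12, 12, 12)
    mask = np.ones(grid, bool)
    sigma = 6.0 / 3.0 / (2 * np.sqrt(2 * np.log(2)))
    stack = np.stack(
        [gaussian_filter(rng.standard_normal(grid), sigma, mode="wrap")[mask] for _ in range(n)]
    )
    pool = rng.integers(1, 4, size=(n, 98)).astype(float)
    Y = rng.standard_normal(n)
    g = (rng.random(n) < 0.32).astype(float)
    thr_perm = cluster_threshold_perm(
        pool, Y, g, stack, mask, n_perm=300, weight_policy="unit", seed=9
    )
    thr_mc = cluster_threshold_mc(
        int(mask.sum()), (6.0, 6.0, 6.0), 3.0, voxel_p=0.000125,
        n_iter=600, grid=grid, seed=10,
    )
    assert abs(thr_perm - thr_mc) <= 2
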