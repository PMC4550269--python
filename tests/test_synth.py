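import numpy as np
import pytest

from voxmediate.pathmodel import fit_path_model
from voxmediate.preprocess import framewise_displacement
from voxmediate.reho import reho_map
from voxmediate.synth import (
    SyntheticConfig,
    cluster_mask,
    gen_bold,
    gen_genotype_pool,
    gen_genotypes,
    gen_motion,
    gen_subjects,
)


def small_cfg(**kw):
    defaults = dict(n_subjects=50, grid_dims=(8, 8, 8), n_timepoints=40, seed=0)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


# config validation --------------------------------------------------------

def test_config_validation():
    with pytest.raises(ValueError, match="frequencies"):
        small_cfg(mafs=(0.6,) * 10)
    with pytest.raises(ValueError, match="frequencies"):
        small_cfg(mafs=(0.0,) * 10)
    with pytest.raises(ValueError, match="outside"):
        small_cfg(cluster_voxels=np.array([[9, 0, 0]]))
    with pytest.raises(ValueError, match="time points"):
        small_cfg(n_timepoints=10)


# genotypes ----------------------------------------------------------------

def test_hwe_code_frequencies_at_half():
    cfg = small_cfg(n_subjects=10_000, mafs=(0.5,) * 10)
    codes = gen_genotypes(cfg).to_numpy()
    freqs = [np.mean(codes == c) for c in (1, 2, 3)]
    np.testing.assert_allclose(freqs, [0.25, 0.50, 0.25], atol=0.02)


def test_degenerate_maf_all_major():
    cfg = small_cfg(n_subjects=1000, mafs=(1e-9,) * 10)
    assert (gen_genotypes(cfg).to_numpy() == 1).all()


def test_heterozygote_fraction_binomial_oracle():
    cfg = small_cfg(n_subjects=5000, mafs=(0.2,) * 10)
    codes = gen_genotypes(cfg).to_numpy()
    assert np.mean(codes == 2) == pytest.approx(2 * 0.2 * 0.8, abs=0.02)


def test_genotypes_reproducible_and_pool_shape():
    cfg = small_cfg()
    a = gen_genotypes(cfg)
    b = gen_genotypes(cfg)
    assert a.equals(b)
    pool = gen_genotype_pool(cfg)
    assert pool.shape == (50, 98)
    assert set(np.unique(pool.to_numpy())) <= {1, 2, 3}


# subjects -----------------------------------------------------------------

def test_noiseless_equations_recover_raw_coefficients():
    """As residual noise vanishes (a tiny exogenous mediator residual keeps
    the outcome design identifiable) the raw regression equations recover
    the generating coefficients to >= 4 decimals on the
    standardized-outcome scale."""
    cfg = small_cfg(
        n_subjects=400, path_a=-0.3, path_b=0.5, path_c_prime=0.4,
        gender_effect=0.0, noise_sd_m=1e-3, noise_sd_y=1e-9,
    )
    geno = gen_genotypes(cfg)
    table, m = gen_subjects(cfg, geno)
    x = table["gene_score"].to_numpy()
    x = (x - x.mean()) / x.std(ddof=1)
    y_star = (table["sps"].to_numpy() - cfg.sps_mean) / cfg.sps_sd
    g = table["gender"].to_numpy(float)
    n = len(x)
    beta_m = np.linalg.lstsq(np.column_stack([np.ones(n), x, g]), m, rcond=None)[0]
    assert beta_m[1] == pytest.approx(-0.3, abs=1e-4)
    beta_y = np.linalg.lstsq(
        np.column_stack([np.ones(n), x, m, g]), y_star, rcond=None
    )[0]
    assert beta_y[1] == pytest.approx(0.4, abs=1e-4)
    assert beta_y[2] == pytest.approx(0.5, abs=1e-4)


def test_null_paths_give_null_sample_structure():
    cfg = small_cfg(n_subjects=2000, path_a=0.0, path_b=0.0, gender_effect=0.0)
    geno = gen_genotypes(cfg)
    table, m = gen_subjects(cfg, geno)
    x = table["gene_score"].to_numpy()
    x = (x - x.mean()) / x.std()
    bound = 3.0 / np.sqrt(len(x))
    assert abs(np.corrcoef(m, x)[0, 1]) < bound
    fit = fit_path_model(x, m, table["sps"], table["gender"], n_boot=0)
    assert abs(fit.b_) < 1.5 * bound


def test_default_coefficients_recovered_in_expectation():
    """Monte-Carlo recovery oracle: at the default cohort size the mean
    fitted a-path over replicates sits within +-0.02 of the generating
    -0.176."""
    reps = 200
    a_hat = np.zeros(reps)
    for r in range(reps):
        cfg = SyntheticConfig(seed=1000 + r)
        geno = gen_genotypes(cfg)
        table, m = gen_subjects(cfg, geno)
        fit = fit_path_model(
            table["gene_score"], m, table["sps"], table["gender"], n_boot=0
        )
        a_hat[r] = fit.a_
    assert a_hat.mean() == pytest.approx(-0.176, abs=0.02)


def test_sps_scale_and_clipping_rate():
    """Trait scores live on the questionnaire scale; at the default residual
    SDs the affine rescaling clips fewer than 1% of subjects."""
    cfg = SyntheticConfig(n_subjects=298, seed=3)
    geno = gen_genotypes(cfg)
    clipped = 0
    total = 0
    for r in range(30):
        c2 = SyntheticConfig(n_subjects=298, seed=100 + r)
        table, _ = gen_subjects(c2, gen_genotypes(c2))
        sps = table["sps"].to_numpy()
        assert sps.min() >= 27.0 and sps.max() <= 189.0
        clipped += np.sum((sps == 27.0) | (sps == 189.0))
        total += len(sps)
    assert clipped / total < 0.01
    del cfg, geno


def test_bootstrap_ci_covers_generating_paths():
    """Full parameter-recovery property: over replicates at the default
    cohort size, the 95% bootstrap CI covers the generating a and b in at
    least 90% of cases."""
    reps = 60
    cover_a = cover_b = 0
    for r in range(reps):
        cfg = SyntheticConfig(seed=5000 + r)
        table, m = gen_subjects(cfg, gen_genotypes(cfg))
        fit = fit_path_model(
            table["gene_score"], m, table["sps"], table["gender"],
            n_boot=400, random_state=r,
        )
        lo, hi = fit.ci_["a"]
        cover_a += lo <= cfg.path_a <= hi
        lo, hi = fit.ci_["b"]
        cover_b += lo <= cfg.path_b <= hi
    assert cover_a / reps >= 0.90
    assert cover_b / reps >= 0.90


# BOLD ---------------------------------------------------------------------

def test_bold_full_coherence_gives_w_one():
    cfg = small_cfg()
    vol = gen_bold(cfg, m_value=1e6)  # lambda saturates at 1: identical series
    cl = cluster_mask(cfg)
    W = reho_map(vol.data, np.ones(cfg.grid_dims, bool))
    inner = cl.copy()
    # cluster interior voxel: all 27 neighbours inside the cluster
    centre = tuple(np.asarray(cfg.grid_dims) // 2)
    assert W[centre] == pytest.approx(1.0, abs=1e-12)
    del inner


def test_bold_zero_coherence_matches_background():
    """At lambda = 0 cluster voxels are exchangeable with background noise.
    The comparison uses interior voxels only: grid-edge voxels have fewer
    neighbours and hence a higher null W."""
    cfg = small_cfg(n_subjects=2)
    rng = np.random.default_rng(5)
    cl = cluster_mask(cfg)
    from scipy.ndimage import binary_dilation

    interior = np.zeros(cfg.grid_dims, bool)
    interior[1:-1, 1:-1, 1:-1] = True
    background = interior & ~binary_dilation(cl)  # full 27-neighbourhoods, no cluster contact
    w_in, w_out = [], []
    for _ in range(15):
        vol = gen_bold(cfg, m_value=-1e6, rng=rng)
        W = reho_map(vol.data, np.ones(cfg.grid_dims, bool))
        w_in.append(W[cl].mean())
        w_out.append(W[background].mean())
    assert np.mean(w_in) == pytest.approx(np.mean(w_out), abs=0.01)


def test_bold_cluster_w_monotone_in_lambda():
    """Simulation oracle: mean cluster W increases strictly across the
    coherence-weight grid {0.2, 0.5, 0.8}."""
    cfg = small_cfg()
    rng = np.random.default_rng(6)
    cl = cluster_mask(cfg)
    means = []
    for lam in (0.2, 0.5, 0.8):
        m_val = np.log(lam / (1 - lam)) / cfg.coupling_k
        vals = []
        for _ in range(50):
            vol = gen_bold(cfg, m_val, rng=rng)
            W = reho_map(vol.data, np.ones(cfg.grid_dims, bool))
            vals.append(W[cl].mean())
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_bold_band_limited_signal_survives_filtering():
    from voxmediate.preprocess import bandpass_filter

    cfg = small_cfg(n_timepoints=120)
    vol = gen_bold(cfg, m_value=1e6)
    centre = tuple(np.asarray(cfg.grid_dims) // 2)
    before = vol.data[centre] - vol.data[centre].mean()
    out = bandpass_filter(vol)
    after = out.data[centre]
    assert np.corrcoef(before, after)[0, 1] > 0.99


# motion -------------------------------------------------------------------

def test_motion_zero_step_and_linearity():
    trace = gen_motion(50, step_sd_trans=0.0, step_sd_rot=0.0, rng=0)
    fd, mean_fd = framewise_displacement(trace)
    assert mean_fd == 0.0
    t1 = gen_motion(200, step_sd_trans=0.02, step_sd_rot=4e-4, rng=1)
    t2 = gen_motion(200, step_sd_trans=0.04, step_sd_rot=8e-4, rng=1)
    _, fd1 = framewise_displacement(t1)
    _, fd2 = framewise_displacement(t2)
    assert fd2 == pytest.approx(2 * fd1, rel=1e-9)


def test_motion_deterministic_under_seed():
    np.testing.assert_array_equal(gen_motion(30, rng=7), gen_motion(30, rng=7))
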