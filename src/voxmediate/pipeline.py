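"""End-to-end pipeline driver and synthetic-dataset writer.

``run_pipeline`` executes the published stage order on files named by a
:class:`~voxmediate.config.RunConfig`:

  gene score -> temporal preprocessing -> ReHo -> demean/smooth ->
  voxel-wise mediation scan -> Monte-Carlo and permutation cluster-extent
  thresholds -> stricter threshold applied -> ROI extraction -> path model
  with bootstrap CIs -> leave-one-out validation

and writes per-stage outputs plus a plain-text run report.  Every random
stage derives its generator from the config seed, so a run is reproducible
from its config alone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, preprocess, reho, synth, voxmed
from .config import RunConfig
from .genescore import compute_gene_score
from .pathmodel import (
    PathMediationModel,
    classify_effect,
    describe_phenotype,
    extract_roi_mean,
    loo_validate,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "generate_dataset"]


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def _stage(report: list[str], name: str, text: str = "") -> None:
    line = f"[{name}] {text}".rstrip()
    logger.info(line)
    report.append(line)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage on the files named in ``config``; returns a result
    dict and writes maps, tables and ``report.txt`` under ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: list[str] = [f"seed = {config.seed}"]
    results: dict = {}

    stage = "score"
    try:
        genotypes = io.read_table(config.genotypes)
        weights = io.read_table(config.weights, index_col=0)["weight"]
        pheno = io.read_table(config.phenotypes)
        scores = compute_gene_score(genotypes, weights)
        subjects = pheno.join(scores, how="inner")
        if subjects["gene_score"].isna().any():
            raise ValueError("missing gene scores after join")
        io.write_table(subjects, outdir / "scores.tsv")
        _stage(report, stage, f"{len(subjects)} subjects scored over {len(weights)} loci")

        stage = "preprocess+reho"
        grey = io.read_mask(config.grey_mask)
        gmask = io.read_mask(config.global_mask)
        wmask = io.read_mask(config.wm_mask)
        cmask = io.read_mask(config.csf_mask)
        manifest = io.read_table(config.manifest)
        manifest = manifest.loc[subjects.index]

        n_vox = int(grey.sum())
        stack = np.zeros((len(subjects), n_vox))
        motion_rows = []
        affine = None
        vs = None
        for i, (sid, row) in enumerate(manifest.iterrows()):
            vol = io.read_volume(row["volume"], tr=config.tr_override)
            motion = io.read_motion(row["motion"], degrees=config.motion_degrees)
            if not preprocess.max_motion_check(motion):
                raise ValueError(f"subject {sid} exceeds the motion criterion")
            vol = preprocess.temporal_pipeline(
                vol, motion, gmask, wmask, cmask,
                n_discard=config.n_discard,
                low=config.band_low, high=config.band_high,
            )
            affine, vs = vol.affine, vol.voxel_size
            w = reho.reho_map(vol.data, grey, tie_correction=config.tie_correction)
            w = reho.normalize_reho(w, grey, mode=config.demean_mode)
            w = reho.gaussian_smooth(w, fwhm=config.fwhm_smooth, voxel_size=tuple(vs))
            stack[i] = w[grey]
            msum = preprocess.motion_summary(motion[config.n_discard:])
            _, mean_fd = preprocess.framewise_displacement(motion[config.n_discard:])
            motion_rows.append(
                {"subject_id": sid, "mean_fd": mean_fd, **msum}
            )
        motion_df = pd.DataFrame(motion_rows).set_index("subject_id")
        io.write_table(motion_df, outdir / "motion_summary.tsv")
        _stage(report, stage, f"{len(subjects)} subjects, {n_vox} grey-matter voxels")

        stage = "motion-checks"
        X = subjects["gene_score"].to_numpy(float)
        Y = subjects["sps"].to_numpy(float)
        gender = subjects["gender"].to_numpy(float)
        for idx_name in ("trans_index", "rot_index", "mean_fd"):
            vals = motion_df[idx_name].to_numpy()
            if np.std(vals) == 0:
                _stage(report, stage, f"{idx_name}: constant, correlations undefined")
                continue
            _stage(
                report, stage,
                f"{idx_name}: r(score)={_corr(vals, X):+.3f} r(sps)={_corr(vals, Y):+.3f}",
            )

        stage = "mediation-scan"
        mm = voxmed.mediation_scan(X, Y, gender, stack, alpha=config.alpha)
        io.write_map(mm.to_volume(grey, "ab"), affine, outdir / "ab_map.nii")
        io.write_map(mm.to_volume(grey, "sig").astype(float), affine, outdir / "sig_mask.nii")
        results["mediation_map"] = mm
        _stage(
            report, stage,
            f"c={mm.c:+.4f} (p={mm.p_c:.2e}); {int(mm.sig.sum())} voxels pass "
            f"the three-step conjunction at alpha={config.alpha}",
        )

        stage = "smoothness"
        group_mean = stack.mean(axis=0)
        resid_maps = []
        for i in range(min(len(subjects), 20)):  # subject maps vs group mean
            vol3 = np.zeros(grey.shape)
            vol3[grey] = stack[i] - group_mean
            resid_maps.append(vol3)
        fwhm_est = reho.estimate_fwhm(resid_maps, grey, voxel_size=tuple(vs))
        _stage(report, stage, "FWHM est = (%.2f, %.2f, %.2f) mm" % fwhm_est)

        stage = "mc-threshold"
        rng = np.random.default_rng(config.seed)
        mc_thr = voxmed.cluster_threshold_mc(
            mask_size=n_vox,
            fwhm=fwhm_est,
            voxel_size=float(np.mean(vs)),
            voxel_p=config.voxel_p,
            alpha=config.alpha,
            n_iter=config.n_mc_iter,
            connectivity=config.connectivity,
            seed=rng,
        )
        _stage(report, stage, f"min significant extent = {mc_thr} voxels "
                              f"({config.n_mc_iter} iterations)")

        stage = "perm-threshold"
        if config.n_perm > 0:
            pool = io.read_table(config.pool_genotypes)
            pool = pool.loc[subjects.index]
            perm_thr = voxmed.cluster_threshold_perm(
                pool.to_numpy(float), Y, gender, stack, grey,
                n_perm=config.n_perm,
                alpha=config.alpha,
                alpha_voxel=config.alpha,
                weight_policy=config.perm_weight_policy,
                connectivity=config.connectivity,
                seed=np.random.default_rng(config.seed + 1),
            )
            min_keep = max(mc_thr, perm_thr + 1)
            _stage(report, stage,
                   f"95th-percentile null max extent = {perm_thr} voxels "
                   f"({config.n_perm} permutations)")
        else:
            perm_thr = None
            min_keep = mc_thr
            _stage(report, stage,
                   "n_perm=0: permutation threshold skipped, MC-only correction")
            logger.warning("permutation threshold disabled (n_perm=0)")
        chosen = "permutation" if (perm_thr is not None and perm_thr + 1 > mc_thr) \
            else "Monte-Carlo"
        _stage(report, "threshold",
               f"stricter rule: {chosen}; clusters kept at size >= {min_keep}")

        stage = "clusters"
        sig_vol = mm.to_volume(grey, "sig").astype(bool)
        ab_vol = mm.to_volume(grey, "ab")
        table, labels = voxmed.label_clusters(
            sig_vol, ab_vol, affine,
            connectivity=config.connectivity,
            voxel_volume_mm3=float(np.prod(vs)),
        )
        surviving = table[table["size_vox"] >= min_keep].reset_index(drop=True)
        io.write_table(
            surviving.drop(columns=["members"]), outdir / "clusters.tsv", index=False
        )
        results["clusters"] = surviving
        _stage(report, stage, f"{len(table)} clusters, {len(surviving)} survive")

        stage = "path-model"
        results["roi_fits"] = []
        for _, cl in surviving.iterrows():
            members = np.array(cl["members"])
            sel = labels[tuple(members.T)][0]
            roi_mask_flat = (labels == sel)[grey]
            roi = extract_roi_mean(stack, roi_mask_flat)
            model = PathMediationModel(
                n_boot=config.n_boot,
                ci_method=config.ci_method,
                alpha=config.alpha,
                random_state=config.seed + 10 + int(cl["cluster_id"]),
            ).fit(X, roi, Y, gender)
            verdict = classify_effect(model)
            _, r_loo = loo_validate(X, roi, Y, gender)
            results["roi_fits"].append(
                {"cluster_id": int(cl["cluster_id"]), "model": model,
                 "effect": verdict, "loo_r": r_loo}
            )
            ci = model.ci_.get("ab", (float("nan"),) * 2)
            _stage(
                report, stage,
                f"cluster {int(cl['cluster_id'])} ({int(cl['size_vox'])} vox): "
                f"a={model.a_:+.3f} b={model.b_:+.3f} c={model.c_:+.3f} "
                f"c'={model.c_prime_:+.3f} ab={model.ab_:+.4f} "
                f"[{ci[0]:+.4f}, {ci[1]:+.4f}] "
                f"suppression={model.suppression_pct_:+.2f}% R2={model.r2_y_:.3f} "
                f"LOO r={r_loo:.3f} -> {verdict}",
            )
        if surviving.empty:
            _stage(report, stage, "no surviving clusters; ROI model skipped")

        stage = "descriptives"
        desc = describe_phenotype(Y, gender)
        results["describe"] = desc
        _stage(report, stage,
               f"SPS mean={desc['overall']['mean']:.2f} sd={desc['overall']['sd']:.2f}")

    except Exception as exc:
        report.append(f"[FAILED at stage {stage}] {exc}")
        (outdir / "report.txt").write_text("\n".join(report) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    results["report"] = "\n".join(report)
    return results


# ---------------------------------------------------------------------------

def generate_dataset(config: synth.SyntheticConfig, outdir) -> RunConfig:
    """Write a complete synthetic dataset in the pipeline's input formats.

    Produces genotype/pool/weights/phenotype TSVs, per-subject 4-D NIfTI
    volumes and motion files, mask volumes, a manifest, and a ready-to-run
    YAML config; returns the corresponding :class:`RunConfig`.
    """
    outdir = Path(outdir)
    (outdir / "volumes").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genotypes = synth.gen_genotypes(config, rng)
    pool = synth.gen_genotype_pool(config, rng)
    subjects, m_latent = synth.gen_subjects(config, genotypes, rng)
    io.write_table(genotypes, outdir / "genotypes.tsv")
    io.write_table(pool, outdir / "pool_genotypes.tsv")
    io.write_table(
        pd.DataFrame({"locus_id": list(config.locus_ids),
                      "weight": list(config.weights)}).set_index("locus_id"),
        outdir / "weights.tsv",
    )
    io.write_table(subjects[["gender", "sps"]], outdir / "phenotypes.tsv")

    affine = synth.default_affine(config)
    grid = config.grid_dims
    grey = np.ones(grid, dtype=bool)
    wm = np.zeros(grid, dtype=bool)
    wm[:2, :2, :2] = True
    csf = np.zeros(grid, dtype=bool)
    csf[-2:, -2:, -2:] = True
    cl = synth.cluster_mask(config)
    if (wm & cl).any() or (csf & cl).any():
        raise ValueError("planted cluster collides with the nuisance mask blocks")
    grey_analysis = grey & ~wm & ~csf
    io.write_map(grey_analysis.astype(float), affine, outdir / "grey_mask.nii")
    io.write_map(grey.astype(float), affine, outdir / "global_mask.nii")
    io.write_map(wm.astype(float), affine, outdir / "wm_mask.nii")
    io.write_map(csf.astype(float), affine, outdir / "csf_mask.nii")
    io.write_map(cl.astype(float), affine, outdir / "planted_cluster.nii")

    rows = []
    for sid, m in zip(subjects.index, m_latent):
        vol = synth.gen_bold(config, m, rng)
        motion = synth.gen_motion(config.n_timepoints, rng=rng)
        vpath = outdir / "volumes" / f"{sid}_bold.nii.gz"
        mpath = outdir / "volumes" / f"{sid}_motion.txt"
        io.write_volume(vol, vpath)
        io.write_motion(motion, mpath)
        rows.append({"subject_id": sid, "volume": str(vpath), "motion": str(mpath)})
    io.write_table(pd.DataFrame(rows).set_index("subject_id"),
                   outdir / "manifest.tsv")

    run = RunConfig(
        genotypes=str(outdir / "genotypes.tsv"),
        pool_genotypes=str(outdir / "pool_genotypes.tsv"),
        weights=str(outdir / "weights.tsv"),
        phenotypes=str(outdir / "phenotypes.tsv"),
        manifest=str(outdir / "manifest.tsv"),
        grey_mask=str(outdir / "grey_mask.nii"),
        global_mask=str(outdir / "global_mask.nii"),
        wm_mask=str(outdir / "wm_mask.nii"),
        csf_mask=str(outdir / "csf_mask.nii"),
        seed=config.seed,
    )
    run.to_yaml(outdir / "run_config.yaml")
    return run
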