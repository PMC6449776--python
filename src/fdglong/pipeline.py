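"""End-to-end pipeline: simulate -> (PVC) -> SUVR -> ROI LMM -> voxelwise -> survival.

``run_pipeline`` executes the whole analysis on a synthetic phantom
cohort and writes CSV tables plus a machine-readable run manifest into
a run directory.  Identical configuration and seed produce byte-identical
CSV outputs; per-image noise seeds are derived deterministically from
the configured seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .cohortstats import chi2_2x2, fleming_harrington_test, kaplan_meier, survival_records
from .longmodel import fit_roi_lmm, summarize_regions
from .phantom import (
    REFERENCE_REGION,
    make_atlas,
    render_visit_image,
    simulate_cohort,
)
from .pvc import PSFModel, PVCConfig, reblurred_van_cittert
from .roistats import build_suvr_table, compute_suvr, mean_percent_change
from .voxelstats import permutation_cluster_fwer

__all__ = ["run_pipeline"]

logger = logging.getLogger("fdglong")


def _image_seed(base_seed: int, subject_index: int, visit_index: int) -> int:
    ss = np.random.SeedSequence([base_seed, subject_index, visit_index])
    return int(ss.generate_state(1)[0] % (2**31))


def _setup_logging(run_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(run_dir / "pipeline.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        stream = logging.StreamHandler(sys.stderr)
        stream.setLevel(logging.WARNING)
        logger.addHandler(stream)
    return handler


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage on a simulated cohort and write results to a run directory.

    Outputs: ``suvr_long.csv`` (PVC and, if requested, non-PVC rows),
    ``percent_change.csv``, ``lmm_report.csv``, ``clusters_<group>_<pvc>.csv``,
    ``survival_summary.json`` and ``manifest.json``.
    """
    run_dir = Path(config.out_dir) / f"run_seed{config.seed}"
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(run_dir)
    stage = "setup"
    try:
        # --- simulate -------------------------------------------------
        stage = "simulate"
        atlas = make_atlas(
            config.grid_shape,
            config.n_regions,
            voxel_size_mm=config.voxel_size_mm,
            seed=config.seed,
        )
        subjects, truth = simulate_cohort(
            n_per_group=config.n_per_group,
            scan_months=config.scan_months,
            seed=config.seed,
            region_names=tuple(atlas.names[k] for k in sorted(atlas.names)),
            subject_intercept_sd=config.subject_intercept_sd,
            noise_sd=config.noise_sd,
            atrophy_rates=config.atrophy,
        )
        logger.info("simulated %d subjects, %d regions", len(subjects), config.n_regions)

        # --- render, PVC, SUVR ---------------------------------------
        psf = PSFModel(config.psf_fwhm_mm)
        pvc_config = PVCConfig(config.alpha, config.tol_percent, config.max_iter)
        variants = [True] if config.apply_pvc else [False]
        if config.apply_pvc and config.compare_non_pvc:
            variants = [True, False]

        suvr_images: dict[tuple[str, int, bool], object] = {}
        visit_suvrs: dict[bool, list] = {flag: [] for flag in variants}
        pvc_iters: list[int] = []
        pvc_negatives: list[int] = []
        for si, subject in enumerate(subjects):
            for vi, month in enumerate(subject.scan_months):
                stage = "render"
                observed = render_visit_image(
                    truth,
                    subject.subject_id,
                    month,
                    atlas,
                    psf_fwhm_mm=config.psf_fwhm_mm,
                    noise_sd=config.noise_sd,
                    seed=_image_seed(config.seed, si, vi),
                )
                for flag in variants:
                    stage = "pvc" if flag else "suvr"
                    image = observed
                    if flag:
                        result = reblurred_van_cittert(observed, psf, pvc_config)
                        pvc_iters.append(result.n_iterations)
                        pvc_negatives.append(result.n_negative_voxels)
                        image = result.corrected
                    stage = "suvr"
                    suvr_img, region_suvrs = compute_suvr(image, atlas, config.reference_region)
                    if month in (0, config.followup_month):
                        suvr_images[(subject.subject_id, month, flag)] = suvr_img
                    visit_suvrs[flag].append((subject.subject_id, month, region_suvrs))
        if pvc_iters:
            logger.info(
                "PVC: median %d iterations, %d images with negative voxels",
                int(np.median(pvc_iters)),
                int(np.sum(np.asarray(pvc_negatives) > 0)),
            )

        stage = "tables"
        suvr_tables = {
            flag: build_suvr_table(visit_suvrs[flag], subjects, flag) for flag in variants
        }
        suvr_long = pd.concat(list(suvr_tables.values()), ignore_index=True)
        suvr_long.to_csv(run_dir / "suvr_long.csv", index=False)

        region_names = [atlas.names[k] for k in sorted(atlas.names)]
        pc_rows = []
        for flag in variants:
            for region in region_names:
                for group in ("carrier", "non-carrier"):
                    pc_rows.append(
                        {
                            "region": region,
                            "group": group,
                            "pvc": flag,
                            "mean_percent_change": mean_percent_change(
                                suvr_tables[flag], region, group
                            ),
                        }
                    )
        pd.DataFrame(pc_rows).to_csv(run_dir / "percent_change.csv", index=False)

        # --- ROI mixed model ------------------------------------------
        stage = "lmm"
        model_regions = [r for r in region_names if r != REFERENCE_REGION]
        results = {
            flag: [
                fit_roi_lmm(suvr_tables[flag], region, subjects, config.random_slope)
                for region in model_regions
            ]
            for flag in variants
        }
        if len(variants) == 2:
            report = summarize_regions(results[True], config.roi_alpha, results[False])
        else:
            report = summarize_regions(results[variants[0]], config.roi_alpha)
        report.to_csv(run_dir / "lmm_report.csv", index=False)

        # --- voxelwise ------------------------------------------------
        stage = "voxelwise"
        brain_mask = atlas.labels > 0
        for flag in variants:
            for group_name, want in (("carrier", True), ("noncarrier", False)):
                ids = [s.subject_id for s in subjects if s.carrier == want]
                baselines = [suvr_images[(sid, 0, flag)] for sid in ids]
                followups = [suvr_images[(sid, config.followup_month, flag)] for sid in ids]
                perm = permutation_cluster_fwer(
                    baselines,
                    followups,
                    mask=brain_mask,
                    cft_p=config.cft_p,
                    n_permutations=config.n_permutations,
                    seed=config.seed,
                )
                tag = "pvc" if flag else "nopvc"
                perm.table.to_csv(run_dir / f"clusters_{group_name}_{tag}.csv", index=False)
                n_sig = int((perm.table["corrected_p"] < config.cluster_alpha).sum())
                logger.info(
                    "voxelwise %s (%s): %d clusters, %d significant at alpha=%.2g",
                    group_name,
                    tag,
                    len(perm.table),
                    n_sig,
                    config.cluster_alpha,
                )

        # --- cohort statistics ----------------------------------------
        stage = "survival"
        records = survival_records(subjects)
        conv_c = int(records[records["group"] == "carrier"]["event"].sum())
        conv_n = int(records[records["group"] == "non-carrier"]["event"].sum())
        n_c = int((records["group"] == "carrier").sum())
        n_n = int((records["group"] == "non-carrier").sum())
        chi2, p_conv = chi2_2x2(conv_c, n_c - conv_c, conv_n, n_n - conv_n, tail="one")
        fh_stat, fh_p = fleming_harrington_test(records, config.fh_weight_p, config.fh_weight_q)
        km_summary = {}
        for group in ("carrier", "non-carrier"):
            kmf = kaplan_meier(records, group)
            km_summary[group] = {
                "final_survival": float(kmf.survival_function_.iloc[-1, 0]),
                "n": int(n_c if group == "carrier" else n_n),
                "events": int(conv_c if group == "carrier" else conv_n),
            }
        survival_summary = {
            "converters_carrier": conv_c,
            "converters_noncarrier": conv_n,
            "conversion_chi2": chi2,
            "conversion_p_one_tailed": p_conv,
            "fleming_harrington_stat": fh_stat,
            "fleming_harrington_p": fh_p,
            "kaplan_meier": km_summary,
        }
        with open(run_dir / "survival_summary.json", "w", encoding="utf-8") as fh:
            json.dump(survival_summary, fh, indent=2, sort_keys=True)

        # --- manifest --------------------------------------------------
        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config": config.to_dict(),
            "seed": config.seed,
            "n_subjects": len(subjects),
            "pvc_median_iterations": (int(np.median(pvc_iters)) if pvc_iters else None),
            "pvc_images_with_negative_voxels": (
                int(np.sum(np.asarray(pvc_negatives) > 0)) if pvc_negatives else None
            ),
        }
        with open(run_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        logger.error("pipeline stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return run_dir
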