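"""Partial volume correction on the standard phantom: convergence and recovery.

Blurs one noiseless phantom visit with the 8 mm PSF, runs the reblurred
Van Cittert deconvolution (alpha 1.5, 1% stopping rule) and tabulates
per-region contrast recovery against the known ground truth.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

import fdglong as fl

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0) -> None:
    RESULTS.mkdir(exist_ok=True)
    atlas = fl.make_atlas((40, 48, 40), 10, seed=7)
    names = tuple(atlas.names[k] for k in sorted(atlas.names))
    _, truth = fl.simulate_cohort(4, seed=seed, region_names=names)
    blurred = fl.render_visit_image(
        truth, "sub000", 0, atlas, psf_fwhm_mm=8.0, noise_sd=0.0
    )
    result = fl.reblurred_van_cittert(blurred, fl.PSFModel(8.0))
    print(f"PVC converged in {result.n_iterations} iterations "
          f"(change history %: {[round(c, 3) for c in result.change_history]})")
    print(f"negative voxels after correction: {result.n_negative_voxels} "
          "(outside-brain ringing; not clipped, flux is conserved)")

    blurred_means = fl.roi_means(blurred, atlas)
    pvc_means = fl.roi_means(result.corrected, atlas)
    counts = atlas.voxel_counts()
    lut = np.zeros(max(atlas.names) + 1)
    for lab, name in atlas.names.items():
        lut[lab] = truth.value("sub000", 0, name)
    truth_img = lut[atlas.labels]

    rows = []
    for region in names:
        mask = atlas.mask(region)
        shell = ndimage.binary_dilation(mask, iterations=2) & ~mask
        tv = truth.value("sub000", 0, region)
        rows.append(
            {
                "region": region,
                "voxels": counts[region],
                "truth": tv,
                "surround": truth_img[shell].mean(),
                "blurred_mean": blurred_means[region],
                "pvc_mean": pvc_means[region],
                "blurred_abs_error": abs(blurred_means[region] - tv),
                "pvc_abs_error": abs(pvc_means[region] - tv),
            }
        )
    table = pd.DataFrame(rows)
    table["recovered"] = table["pvc_abs_error"] < table["blurred_abs_error"]
    table.to_csv(RESULTS / "pvc_recovery.csv", index=False)
    n_rec = int(table["recovered"].sum())
    print(f"contrast recovery improved in {n_rec}/{len(table)} regions "
          f"(worst small region: {table.loc[table.voxels.idxmin(), 'region']}, "
          f"error {table.loc[table.voxels.idxmin(), 'blurred_abs_error']:.3f} -> "
          f"{table.loc[table.voxels.idxmin(), 'pvc_abs_error']:.3f})")
    print(f"wrote {RESULTS/'pvc_recovery.csv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
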