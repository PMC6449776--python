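"""Reference-normalised SUVR images, ROI summaries and percent-change tables.

SUVR (standardized uptake value ratio) divides every voxel by the mean
uptake of a reference region — here cerebellum — so that global scaling
of the tracer signal cancels.  The global cortex composite is the
voxel-count-weighted mean over a fixed union of cortical regions, i.e.
exactly the ROI mean of the merged mask.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .phantom import LabelAtlas, SubjectRecord
from .volume import VolumeImage

__all__ = [
    "GLOBAL_CORTEX_MEMBERS",
    "roi_means",
    "compute_suvr",
    "global_cortex",
    "mean_percent_change",
    "build_suvr_table",
]

#: Cortical union defining the global-cortex composite.
GLOBAL_CORTEX_MEMBERS = (
    "orbital_frontal",
    "prefrontal",
    "superior_frontal",
    "lateral_temporal",
    "parietal",
    "posterior_precuneus",
    "occipital",
    "anterior_cingulate",
    "posterior_cingulate",
)


def roi_means(image: VolumeImage, atlas: LabelAtlas) -> dict[str, float]:
    """Arithmetic mean of voxel values within each labelled region.

    Background (label 0) is excluded; empty regions are dropped with a
    warning rather than reported as NaN.
    """
    if image.shape != atlas.labels.shape:
        raise ValueError(f"image grid {image.shape} != atlas grid {atlas.labels.shape}")
    labels = atlas.labels.ravel()
    sums = np.bincount(labels, weights=image.values.ravel(), minlength=max(atlas.names) + 1)
    counts = np.bincount(labels, minlength=max(atlas.names) + 1)
    means: dict[str, float] = {}
    for lab, name in atlas.names.items():
        if counts[lab] == 0:
            warnings.warn(f"region {name!r} is empty; excluded from ROI means", stacklevel=2)
            continue
        means[name] = float(sums[lab] / counts[lab])
    return means


def compute_suvr(
    image: VolumeImage,
    atlas: LabelAtlas,
    reference: str = "cerebellum",
) -> tuple[VolumeImage, dict[str, float]]:
    """Scale the image by the reference-region mean and summarise per ROI.

    Returns the SUVR image and the ROI means of the scaled image; the
    reference region's SUVR is 1 by construction.
    """
    means = roi_means(image, atlas)
    if reference not in means:
        raise KeyError(f"reference region {reference!r} missing or empty")
    ref_mean = means[reference]
    if ref_mean <= 0:
        raise ValueError(f"reference mean must be positive, got {ref_mean}")
    suvr_image = image.with_values(image.values / ref_mean)
    region_suvrs = {name: m / ref_mean for name, m in means.items()}
    return suvr_image, region_suvrs


def global_cortex(
    region_suvrs: dict[str, float],
    atlas: LabelAtlas,
    members: tuple[str, ...] = GLOBAL_CORTEX_MEMBERS,
) -> float:
    """Voxel-count-weighted mean SUVR over the union of member regions."""
    counts = atlas.voxel_counts()
    missing = [m for m in members if m not in region_suvrs or m not in counts]
    if missing:
        raise KeyError(f"global-cortex members missing from atlas or SUVRs: {missing}")
    weights = np.array([counts[m] for m in members], dtype=float)
    values = np.array([region_suvrs[m] for m in members], dtype=float)
    return float((weights * values).sum() / weights.sum())


def mean_percent_change(table: pd.DataFrame, region: str, group: str) -> float:
    """Mean consecutive-interval percent change of SUVR for one region and group.

    For each subject and each consecutive pair of visits the relative
    change ``100 * (next - prev) / prev`` is computed; the statistic is
    the plain mean over all intervals of all subjects in the group
    (negative = decline).  Subjects with a single visit contribute
    nothing; zero-denominator intervals are excluded with a warning.
    """
    if group not in ("carrier", "non-carrier"):
        raise ValueError(f"group must be 'carrier' or 'non-carrier', got {group!r}")
    want_carrier = group == "carrier"
    sub = table[(table["region"] == region) & (table["carrier"] == want_carrier)]
    changes: list[float] = []
    for _, traj in sub.groupby("subject_id"):
        traj = traj.sort_values("month")
        s = traj["suvr"].to_numpy(dtype=float)
        if len(s) < 2:
            continue
        prev, nxt = s[:-1], s[1:]
        zero = prev == 0
        if zero.any():
            warnings.warn("zero-denominator interval excluded from percent change", stacklevel=2)
        valid = ~zero
        changes.extend(100.0 * (nxt[valid] - prev[valid]) / prev[valid])
    return float(np.mean(changes)) if changes else float("nan")


def build_suvr_table(
    visit_suvrs: list[tuple[str, int, dict[str, float]]],
    subjects: list[SubjectRecord],
    pvc_flag: bool,
) -> pd.DataFrame:
    """Assemble (subject, month, region) ROI SUVRs into the long-format table."""
    carrier_of = {s.subject_id: s.carrier for s in subjects}
    rows = [
        (sid, month, region, suvr, pvc_flag)
        for sid, month, suvrs in visit_suvrs
        for region, suvr in suvrs.items()
    ]
    table = pd.DataFrame(rows, columns=["subject_id", "month", "region", "suvr", "pvc"])
    table["carrier"] = table["subject_id"].map(carrier_of)
    return table.sort_values(["subject_id", "month", "region"], ignore_index=True)
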