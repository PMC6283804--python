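"""Absolute region activities at the SPECT time point.

The quantitative SPECT volume (counts converted to MBq by a scalar camera
calibration factor) anchors the absolute scale of every time-activity
curve.  Organs are read out through their anatomical labels; the tumor is
segmented by volume matching: the highest-activity voxels inside the
hepatic lobe boundary are selected until the reported tumor volume is
reached, which realizes the clinical "fixed threshold chosen so the
recovered volume equals the reported volume" rule exactly to one voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RegionLabel
from .synthetic import SpectStudy

__all__ = [
    "AbsoluteActivityMeasurement",
    "SpectStudy",
    "calibrate",
    "organ_activity",
    "entire_liver_activity",
    "tumor_segmentation_volume_matched",
]


@dataclass(frozen=True)
class AbsoluteActivityMeasurement:
    """Absolute activity of one region at the SPECT acquisition time."""

    region: RegionLabel
    activity_MBq: float
    volume_mL: float
    time_h: float

    def __post_init__(self) -> None:
        if self.activity_MBq < 0:
            raise ValueError("activity must be >= 0")
        if self.volume_mL <= 0:
            raise ValueError("volume must be positive")


def calibrate(count_volume: np.ndarray, calibration_counts_per_MBq: float) -> np.ndarray:
    """Convert a reconstructed count volume to MBq per voxel (linear)."""
    if calibration_counts_per_MBq <= 0:
        raise ValueError("calibration factor must be positive")
    return np.asarray(count_volume, dtype=float) / calibration_counts_per_MBq


def organ_activity(
    study: SpectStudy,
    region: RegionLabel,
    include_labels: tuple[RegionLabel, ...] | None = None,
) -> AbsoluteActivityMeasurement:
    """Integrate activity over an organ's labeled voxels.

    ``include_labels`` widens the mask (used for the entire liver, which
    includes the tumor voxels).
    """
    labels = include_labels if include_labels is not None else (region,)
    mask = np.isin(study.labels, [int(r) for r in labels])
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError(f"label {region.name} is empty in the label volume")
    return AbsoluteActivityMeasurement(
        region=region,
        activity_MBq=float(study.activity_MBq[mask].sum()),
        volume_mL=n * study.voxel_volume_mL,
        time_h=study.time_h,
    )


def entire_liver_activity(study: SpectStudy) -> AbsoluteActivityMeasurement:
    """Entire-liver readout: liver plus tumor voxels (the clinical S-values
    exist for the whole organ only; healthy-liver dose is out of scope)."""
    return organ_activity(
        study, RegionLabel.LIVER, include_labels=(RegionLabel.LIVER, RegionLabel.TUMOR)
    )


def tumor_segmentation_volume_matched(
    study: SpectStudy,
    lobe_boundary: np.ndarray,
    target_volume_mL: float,
) -> tuple[np.ndarray, AbsoluteActivityMeasurement]:
    """Volume-matched tumor segmentation inside a lobe boundary.

    Selects the k = round(target_volume / voxel_volume) highest-activity
    voxels inside the boundary; ties at the implied threshold are broken by
    deterministic voxel (C-order) index.  The segmented volume therefore
    equals the target to within one voxel.
    """
    lobe_boundary = np.asarray(lobe_boundary, dtype=bool)
    if lobe_boundary.shape != study.activity_MBq.shape:
        raise ValueError("lobe boundary must be congruent with the SPECT volume")
    if target_volume_mL <= 0:
        raise ValueError("target volume must be positive")
    n_boundary = int(np.count_nonzero(lobe_boundary))
    k = int(round(target_volume_mL / study.voxel_volume_mL))
    if k < 1:
        raise ValueError("target volume is below one voxel")
    if k > n_boundary:
        raise ValueError(
            f"target volume ({k} voxels) exceeds the boundary ({n_boundary} voxels)"
        )
    flat_idx = np.flatnonzero(lobe_boundary.ravel())
    values = study.activity_MBq.ravel()[flat_idx]
    top = flat_idx[np.argsort(-values, kind="stable")[:k]]
    mask = np.zeros(study.activity_MBq.size, dtype=bool)
    mask[top] = True
    mask = mask.reshape(study.activity_MBq.shape)
    measurement = AbsoluteActivityMeasurement(
        region=RegionLabel.TUMOR,
        activity_MBq=float(study.activity_MBq[mask].sum()),
        volume_mL=k * study.voxel_volume_mL,
        time_h=study.time_h,
    )
    return mask, measurement
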