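"""Lesion feature extraction from SUV volumes with integer label masks.

Four features per lesion ROI:

* ``suv_max``   — maximum SUV over the ROI's voxels (dimensionless, g/mL)
* ``suv_mean``  — arithmetic mean SUV over the ROI's voxels
* ``volume_cc`` — voxel count x voxel volume, in cm^3 (1 cm^3 = 1 mL)
* ``suv_total`` — sum of SUV over ROI voxels x voxel volume in cm^3
  (the PSMA analog of total lesion glycolysis), so that
  ``suv_total == suv_mean * volume_cc`` identically.

ROIs are disjoint integer labels (0 = background).  Anisotropic voxels are
supported; the voxel volume is dx*dy*dz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import StructuralError, ValidationError

__all__ = [
    "LabeledImage",
    "LesionMeasurement",
    "extract_features",
    "measurements_to_frame",
    "read_labeled_image",
    "write_labeled_image",
    "write_feature_csv",
    "read_feature_csv",
]

logger = logging.getLogger(__name__)

#: Exact column order of the lesion feature CSV.
FEATURE_CSV_COLUMNS = [
    "patient_id",
    "lesion_id",
    "timepoint",
    "suv_max",
    "suv_mean",
    "suv_total",
    "volume_cc",
]


@dataclass(frozen=True)
class LabeledImage:
    """A 3-D SUV volume with a same-shape integer lesion label mask."""

    suv: np.ndarray
    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    patient_id: str
    timepoint: str  # "test" or "retest"

    def __post_init__(self) -> None:
        if self.suv.shape != self.labels.shape:
            raise StructuralError(
                f"SUV shape {self.suv.shape} != label shape {self.labels.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise StructuralError("labels must be an integer array")
        if self.labels.min() < 0:
            raise StructuralError("labels must be nonnegative")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValidationError("voxel sizes must be positive")
        if self.timepoint not in ("test", "retest"):
            raise ValidationError(f"timepoint must be 'test' or 'retest', got {self.timepoint!r}")


@dataclass(frozen=True)
class LesionMeasurement:
    """One lesion's four features at one time point."""

    patient_id: str
    lesion_id: int
    timepoint: str
    suv_max: float
    suv_mean: float
    suv_total: float
    volume_cc: float


def extract_features(image: LabeledImage) -> list[LesionMeasurement]:
    """Extract the four lesion features for every distinct nonzero label.

    An empty mask yields an empty list with a logged warning.  Non-finite SUV
    values inside any ROI raise :class:`ValidationError` (corrupt input is
    never silently excluded).
    """
    from scipy import ndimage

    labels = image.labels
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        logger.warning(
            "empty label mask for patient %s (%s): no lesions extracted",
            image.patient_id,
            image.timepoint,
        )
        return []
    roi = labels > 0
    if not np.all(np.isfinite(image.suv[roi])):
        raise ValidationError(
            f"non-finite SUV voxels inside ROIs for patient {image.patient_id}"
        )
    voxel_cc = float(np.prod(image.voxel_size_mm)) / 1000.0
    suv = image.suv.astype(np.float64, copy=False)
    maxima = ndimage.maximum(suv, labels, ids)
    sums = ndimage.sum_labels(suv, labels, ids)
    counts = ndimage.sum_labels(np.ones_like(suv), labels, ids)
    out = []
    for lid, mx, sm, ct in zip(ids, np.atleast_1d(maxima), np.atleast_1d(sums), np.atleast_1d(counts)):
        out.append(
            LesionMeasurement(
                patient_id=image.patient_id,
                lesion_id=int(lid),
                timepoint=image.timepoint,
                suv_max=float(mx),
                suv_mean=float(sm / ct),
                suv_total=float(sm * voxel_cc),
                volume_cc=float(ct * voxel_cc),
            )
        )
    return out


def measurements_to_frame(measurements: list[LesionMeasurement]) -> pd.DataFrame:
    """Stack measurements into the canonical long-format feature table."""
    return pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "lesion_id": m.lesion_id,
                "timepoint": m.timepoint,
                "suv_max": m.suv_max,
                "suv_mean": m.suv_mean,
                "suv_total": m.suv_total,
                "volume_cc": m.volume_cc,
            }
            for m in measurements
        ],
        columns=FEATURE_CSV_COLUMNS,
    )


# ---------------------------------------------------------------------------
# NIfTI / CSV round-trips


def read_labeled_image(
    suv_path: str | Path,
    labels_path: str | Path,
    patient_id: str,
    timepoint: str,
) -> LabeledImage:
    """Load an SUV NIfTI and its integer label NIfTI as a LabeledImage.

    Voxel sizes come from the image header zooms; the two files must agree on
    shape.
    """
    import nibabel as nib

    suv_img = nib.load(str(suv_path))
    lab_img = nib.load(str(labels_path))
    suv = np.asarray(suv_img.dataobj, dtype=np.float64)
    labels = np.rint(np.asarray(lab_img.dataobj)).astype(np.int32)
    zooms = tuple(float(z) for z in suv_img.header.get_zooms()[:3])
    return LabeledImage(
        suv=suv, labels=labels, voxel_size_mm=zooms, patient_id=patient_id, timepoint=timepoint
    )


def write_labeled_image(image: LabeledImage, suv_path: str | Path, labels_path: str | Path) -> None:
    """Write a LabeledImage as an SUV NIfTI + integer label NIfTI pair."""
    import nibabel as nib

    affine = np.diag(list(image.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(image.suv.astype(np.float32), affine), str(suv_path))
    nib.save(nib.Nifti1Image(image.labels.astype(np.int16), affine), str(labels_path))


def write_feature_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame[FEATURE_CSV_COLUMNS].to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in FEATURE_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"feature CSV missing columns: {missing}")
    return frame[FEATURE_CSV_COLUMNS]
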