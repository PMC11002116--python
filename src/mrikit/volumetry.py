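"""Mask statistics, slice-gap-corrected volumes and edema correction.

Multislice 2D acquisitions leave a physical gap between adjacent slices
that plain voxel counting misses. The total volume of a mask is therefore

    V = N_total * V_vox + CV_gap,        V_vox = X_vox * Y_vox * thickness

where the gap correction sums, over every inter-slice gap flanked by
non-empty mask slices on *both* sides, the gap area estimated as the mean
of the two adjacent slice areas times the gap width:

    A_gap_i = (N_back + N_front) / 2 * X_vox * Y_vox
    CV_gap  = sum_i A_gap_i * slice_gap.

For models with post-injury hemispheric swelling (stroke, TBI), per-slice
lesion areas can be corrected for edema from the ipsi-/contralateral
hemisphere areas by one of three published area-ratio methods (Reglodi,
Belayev, and a per-slice-area variant of Gerriets); all three reduce to
the identity when the hemispheres are symmetric.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .core import BinaryMask, Geometry, ImageVolume
from .errors import ConsistencyError, GeometryError, ParameterError

__all__ = [
    "MaskStatistics",
    "SliceAreas",
    "EdemaMethod",
    "mask_statistics",
    "mask_volume",
    "slice_areas",
    "edema_correct_slice",
    "edema_corrected_volume",
]


class EdemaMethod(str, enum.Enum):
    REGLODI = "reglodi"
    BELAYEV = "belayev"
    GERRIETS_MODIFIED = "gerriets_modified"


@dataclass(frozen=True)
class MaskStatistics:
    """Volume and intensity summary of one mask over one image.

    ``total_volume`` includes the slice-gap correction. The IQR is Q3 - Q1
    with linear-interpolation quantiles. An empty mask yields n_voxels 0
    and NaN summaries rather than an error.
    """

    total_volume: float
    mean: float
    sd: float
    median: float
    iqr: float
    min: float
    max: float
    n_voxels: int

    def to_dict(self) -> dict:
        return {
            "total_volume_mm3": self.total_volume,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "iqr": self.iqr,
            "min": self.min,
            "max": self.max,
            "n_voxels": self.n_voxels,
        }


@dataclass(frozen=True)
class SliceAreas:
    """Per-slice areas (mm^2) entering the edema-corrected volume."""

    original: np.ndarray
    ipsilateral: np.ndarray
    contralateral: np.ndarray
    corrected: np.ndarray
    warnings: tuple = ()


def _as_slices(mask: BinaryMask) -> np.ndarray:
    """Mask as (x, y, slice), promoting a single 2D slice."""
    return mask.data if mask.data.ndim == 3 else mask.data[:, :, None]


def slice_voxel_counts(mask: BinaryMask) -> np.ndarray:
    return _as_slices(mask).sum(axis=(0, 1)).astype(np.int64)


def mask_statistics(image: ImageVolume, mask: BinaryMask) -> MaskStatistics:
    """Summary statistics of the image intensities inside the mask."""
    mask.check_grid(image)
    arr = image.data
    if arr.ndim > 3:  # statistics over the first frame of dynamic data
        arr = arr[(...,) + (0,) * (arr.ndim - 3)]
    vals = arr[mask.data]
    vol = mask_volume(mask, image.geometry)
    if vals.size == 0:
        nan = float("nan")
        return MaskStatistics(vol, nan, nan, nan, nan, nan, nan, 0)
    q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation
    return MaskStatistics(
        total_volume=vol,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=0)),
        median=float(np.median(vals)),
        iqr=float(q3 - q1),
        min=float(vals.min()),
        max=float(vals.max()),
        n_voxels=int(vals.size),
    )


def mask_volume(mask: BinaryMask, geometry: Geometry) -> float:
    """Total mask volume in mm^3, slice-gap correction included.

    Voxel volume times count, plus one gap term for every inter-slice gap
    whose two adjacent slices both contain mask voxels. An empty mask has
    volume 0.
    """
    counts = slice_voxel_counts(mask)
    base = float(counts.sum()) * geometry.voxel_volume
    if geometry.slice_gap == 0 or len(counts) < 2:
        return base
    cv_gap = 0.0
    for n_back, n_front in zip(counts[:-1], counts[1:]):
        if n_back > 0 and n_front > 0:
            a_gap = (n_back + n_front) / 2.0 * geometry.voxel_area
            cv_gap += a_gap * geometry.slice_gap
    return base + cv_gap


def edema_correct_slice(
    a_original: float,
    a_ipsilateral: float,
    a_contralateral: float,
    method: EdemaMethod | str,
) -> float:
    """Edema-corrected ROI area (mm^2) on one slice.

    reglodi:            A_orig * A_contra / A_ipsi
    belayev:            A_orig * (1 - (A_ipsi - A_contra) / A_contra)
    gerriets_modified:  (A_c + A_i) - (A_c + A_i - A_orig) * (A_c + A_i) / (2 A_c)

    All three return A_original unchanged for symmetric hemispheres. The
    result may be negative under extreme asymmetry (Belayev when
    A_ipsi > 2 A_contra, Gerriets under large swelling); it is returned
    as-is with a warning so the caller decides, since clamping would
    silently alter the published formulas.
    """
    method = EdemaMethod(method)
    if a_original < 0:
        raise ParameterError(f"A_original must be >= 0, got {a_original}")
    if method is EdemaMethod.REGLODI and a_ipsilateral <= 0:
        raise ZeroDivisionError(
            f"reglodi correction needs A_ipsilateral > 0, got {a_ipsilateral}"
        )
    if method in (EdemaMethod.BELAYEV, EdemaMethod.GERRIETS_MODIFIED) and (
        a_contralateral <= 0
    ):
        raise ZeroDivisionError(
            f"{method.value} correction needs A_contralateral > 0, "
            f"got {a_contralateral}"
        )
    if method is EdemaMethod.REGLODI:
        corrected = a_original * a_contralateral / a_ipsilateral
    elif method is EdemaMethod.BELAYEV:
        corrected = a_original * (
            1.0 - (a_ipsilateral - a_contralateral) / a_contralateral
        )
    else:
        total = a_contralateral + a_ipsilateral
        corrected = total - (total - a_original) * total / (2.0 * a_contralateral)
    if corrected < 0:
        warnings.warn(
            f"{method.value} correction produced a negative area "
            f"({corrected:.4g} mm^2); propagated unclamped",
            stacklevel=2,
        )
    return float(corrected)


def compute_slice_areas(
    roi: BinaryMask,
    ipsi: BinaryMask,
    contra: BinaryMask,
    geometry: Geometry,
    method: EdemaMethod | str,
) -> SliceAreas:
    """Per-slice original and edema-corrected ROI areas.

    Slices with an empty ROI contribute a corrected area of 0 and skip the
    hemisphere-ratio formula entirely, so empty slices can never raise a
    division-domain error.
    """
    method = EdemaMethod(method)
    roi.check_grid(ipsi)
    roi.check_grid(contra)
    area = geometry.voxel_area
    n_roi = slice_voxel_counts(roi).astype(float)
    n_ipsi = slice_voxel_counts(ipsi).astype(float)
    n_contra = slice_voxel_counts(contra).astype(float)

    bad = [
        int(z)
        for z in np.nonzero(n_roi)[0]
        if np.any(_as_slices(roi)[:, :, z] & ~_as_slices(ipsi)[:, :, z])
    ]
    if bad:
        raise ConsistencyError(
            f"ROI voxels fall outside the ipsilateral hemisphere on slices {bad}"
        )

    corrected = np.zeros_like(n_roi)
    notes = []
    for z in range(len(n_roi)):
        if n_roi[z] == 0:
            continue
        try:
            corrected[z] = edema_correct_slice(
                n_roi[z] * area, n_ipsi[z] * area, n_contra[z] * area, method
            )
        except ZeroDivisionError as exc:
            raise ZeroDivisionError(f"slice {z}: {exc}") from exc
        if corrected[z] < 0:
            notes.append(f"slice {z}: negative corrected area {corrected[z]:.4g}")
    return SliceAreas(
        original=n_roi * area,
        ipsilateral=n_ipsi * area,
        contralateral=n_contra * area,
        corrected=corrected,
        warnings=tuple(notes),
    )


def edema_corrected_volume(
    roi: BinaryMask,
    ipsi: BinaryMask,
    contra: BinaryMask,
    geometry: Geometry,
    method: EdemaMethod | str,
) -> float:
    """Edema-corrected ROI volume in mm^3.

    Corrected per-slice areas are multiplied by the slice thickness and
    summed; the slice-gap correction reuses the gap rule with the
    *corrected* areas, counting only gaps flanked by slices of nonzero
    corrected area.
    """
    areas = compute_slice_areas(roi, ipsi, contra, geometry, method)
    a = areas.corrected
    total = float(a.sum()) * geometry.slice_thickness
    if geometry.slice_gap > 0 and len(a) >= 2:
        for back, front in zip(a[:-1], a[1:]):
            if back != 0 and front != 0:
                total += (back + front) / 2.0 * geometry.slice_gap
    return total
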