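"""Image registration orchestration over pluggable transform engines.

The module separates *what* is registered (moving/fixed pairs, the
two-step parameter-image workflow, time-series realignment) from *how*
(the engine). A lightweight built-in engine recovers in-plane rigid
motion — translation by phase correlation plus a coarse-to-fine grid
search over rotation angle — which covers motion correction of
time-series data and makes the whole module testable without any heavy
optimizer. Engines with affine or B-spline non-rigid models (e.g. a
SimpleITK-based one) plug in through the same two-method contract:

    register(moving, fixed, model) -> (warped_array, transform_dict)
    apply(transform, array, order) -> warped_array

and every engine must satisfy ``apply(register(m, f).transform, m) ==
register(m, f).warped`` bit-for-bit for the same engine version.

Resampling uses linear interpolation for images and nearest-neighbor for
masks and label maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .core import ImageVolume
from .errors import CapabilityError, DimensionalityError, GeometryError

__all__ = [
    "TransformResult",
    "BuiltinRigidEngine",
    "register",
    "register_via_parameter_image",
    "align_timeseries",
]


@dataclass
class TransformResult:
    """Outcome of one registration call.

    ``transform`` is a JSON-serializable parameter dict tagged with its
    model; re-applying it to the original moving image reproduces
    ``warped`` exactly (same engine, same version).
    """

    warped: ImageVolume
    transform: dict
    engine_id: str


class BuiltinRigidEngine:
    """In-plane rigid registration: phase-correlation translation plus a
    coarse-to-fine search over rotation angle.

    Works on 2D and 3D arrays; for 3D the rotation is about the slice
    axis (in-plane motion, the dominant mode in slice-based acquisitions)
    while the translation is estimated in all dims. Deterministic.
    """

    engine_id = "builtin-rigid-v1"
    capabilities = ("translation", "rigid")

    def __init__(self, max_angle: float = 15.0, upsample_factor: int = 20):
        self.max_angle = float(max_angle)
        self.upsample_factor = int(upsample_factor)

    # -- engine contract ----------------------------------------------------
    def register(self, moving: np.ndarray, fixed: np.ndarray, model: str = "rigid"):
        if model not in self.capabilities:
            raise CapabilityError(
                f"{self.engine_id} supports {self.capabilities}, not {model!r}"
            )
        if moving.shape != fixed.shape:
            raise GeometryError(
                f"built-in engine needs equal grids, got {moving.shape} vs {fixed.shape}"
            )
        if model == "translation":
            angles = [0.0]
        else:
            coarse = np.arange(-self.max_angle, self.max_angle + 1e-9, 1.0)
            angles = list(coarse)
        best = self._best_over_angles(moving, fixed, angles)
        if model == "rigid" and self.max_angle > 0:
            fine = np.arange(best[0] - 0.9, best[0] + 0.9 + 1e-9, 0.1)
            best = self._best_over_angles(moving, fixed, fine, seed_best=best)
        angle, shift, _ = best
        transform = {
            "model": model,
            "angle_deg": float(angle),
            "shift": [float(s) for s in shift],
            "shape": list(fixed.shape),
            "engine_id": self.engine_id,
        }
        return self.apply(transform, moving), transform

    def apply(self, transform: dict, image: np.ndarray, order: int = 1) -> np.ndarray:
        out = np.asarray(image, dtype=np.float64)
        if tuple(out.shape) != tuple(transform["shape"]):
            raise GeometryError(
                f"transform was estimated on grid {transform['shape']}, "
                f"cannot apply to {out.shape}"
            )
        if transform["angle_deg"] != 0.0:
            out = ndimage.rotate(
                out, transform["angle_deg"], axes=(0, 1), reshape=False,
                order=order, mode="constant", cval=0.0,
            )
        shift = transform["shift"]
        if any(s != 0 for s in shift):
            out = ndimage.shift(out, shift, order=order, mode="constant", cval=0.0)
        return out

    # -- internals ----------------------------------------------------------
    def _best_over_angles(self, moving, fixed, angles, seed_best=None):
        best = seed_best  # (angle, shift, score)
        for angle in angles:
            rotated = (
                moving
                if angle == 0.0
                else ndimage.rotate(
                    moving, angle, axes=(0, 1), reshape=False, order=1,
                    mode="constant", cval=0.0,
                )
            )
            shift, _, _ = phase_cross_correlation(
                fixed, rotated, upsample_factor=self.upsample_factor,
                normalization=None,
            )
            candidate = ndimage.shift(rotated, shift, order=1, mode="constant", cval=0.0)
            score = _ncc(candidate, fixed)
            if best is None or score > best[2] + 1e-12:
                best = (float(angle), tuple(float(s) for s in shift), score)
        return best


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def _spatial_array(vol: ImageVolume) -> np.ndarray:
    arr = vol.data
    if arr.ndim not in (2, 3):
        raise DimensionalityError(
            f"registration operates on 2D/3D images, got {arr.ndim} dims"
        )
    return arr


def register(
    moving: ImageVolume,
    fixed: ImageVolume,
    model: str = "rigid",
    engine: BuiltinRigidEngine | None = None,
) -> TransformResult:
    """Register a moving image onto a fixed image's grid."""
    engine = engine or BuiltinRigidEngine()
    if model not in engine.capabilities:
        raise CapabilityError(
            f"engine {engine.engine_id} does not support model {model!r} "
            f"(capabilities: {tuple(engine.capabilities)})"
        )
    m = _spatial_array(moving)
    f = _spatial_array(fixed)
    warped_arr, transform = engine.register(m, f, model)
    warped = ImageVolume(
        data=warped_arr,
        geometry=fixed.geometry,
        experiment_id=f"{moving.experiment_id}_to_{fixed.experiment_id}",
        affine=fixed.affine,
    )
    return TransformResult(warped=warped, transform=transform, engine_id=engine.engine_id)


def apply_transform(
    transform: dict,
    image: ImageVolume,
    engine: BuiltinRigidEngine | None = None,
    is_mask: bool = False,
) -> ImageVolume:
    """Re-apply a stored transform (nearest-neighbor for masks/labels)."""
    engine = engine or BuiltinRigidEngine()
    arr = engine.apply(transform, _spatial_array(image), order=0 if is_mask else 1)
    return ImageVolume(
        data=arr, geometry=image.geometry,
        experiment_id=f"{image.experiment_id}_warped", affine=image.affine,
    )


def register_via_parameter_image(
    moving: ImageVolume,
    parameter_image: ImageVolume,
    fixed: ImageVolume,
    model: str = "rigid",
    engine: BuiltinRigidEngine | None = None,
) -> TransformResult:
    """Two-step workflow for derived maps with unreliable contrast.

    The raw acquisition underlying the map (the "parameter image", sharing
    the moving image's grid) is registered to the fixed image; its
    optimized transform is then applied — not re-estimated — to the moving
    image. The returned transform is the parameter image's transform.
    """
    if moving.data.shape != parameter_image.data.shape:
        raise GeometryError(
            f"moving {moving.data.shape} and parameter image "
            f"{parameter_image.data.shape} are on different grids"
        )
    engine = engine or BuiltinRigidEngine()
    step1 = register(parameter_image, fixed, model=model, engine=engine)
    warped = apply_transform(step1.transform, moving, engine=engine)
    warped.geometry = fixed.geometry
    warped.affine = fixed.affine
    return TransformResult(
        warped=warped, transform=step1.transform, engine_id=engine.engine_id
    )


def align_timeseries(
    series: ImageVolume,
    reference_index: int,
    engine: BuiltinRigidEngine | None = None,
):
    """Rigidly realign every time point of a 4D/5D series to a reference.

    Frames are registered independently to the reference frame (the
    reference itself is returned unchanged), so the output is identical
    regardless of the order frames are processed in. Returns the aligned
    series and the per-frame transform log.
    """
    arr = series.data
    if arr.ndim not in (4, 5):
        raise DimensionalityError(
            f"time-series alignment needs 4D/5D data, got {arr.ndim} dims"
        )
    engine = engine or BuiltinRigidEngine()
    frames = arr.reshape(arr.shape[:3] + (-1,))
    n_frames = frames.shape[3]
    if not 0 <= reference_index < n_frames:
        raise IndexError(
            f"reference index {reference_index} out of range [0, {n_frames})"
        )
    ref = frames[..., reference_index]
    aligned = np.empty_like(frames)
    transforms = []
    for t in range(n_frames):
        if t == reference_index:
            aligned[..., t] = ref
            transforms.append({"model": "rigid", "identity": True})
            continue
        warped, transform = engine.register(frames[..., t], ref, model="rigid")
        aligned[..., t] = warped
        transforms.append(transform)
    out = ImageVolume(
        data=aligned.reshape(arr.shape),
        geometry=series.geometry,
        te_list=series.te_list,
        tr_list=series.tr_list,
        experiment_id=f"{series.experiment_id}_aligned",
        affine=series.affine,
    )
    return out, transforms
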