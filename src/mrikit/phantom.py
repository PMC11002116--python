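"""Deterministic synthetic phantoms with exact ground truth.

Every other module is exercised against data produced here: a bright
ellipsoidal "brain" on a dark background for segmentation and volumetry
(with optional lesion and per-hemisphere swelling), exact exponential
decay/recovery series for relaxometry, and rigidly shifted frame stacks
for motion correction. All randomness flows through one
``numpy.random.default_rng(seed)`` generator per call, and noise is drawn
in a fixed order (a single draw covering the full array), so identical
seeds give identical arrays on any platform.

The noise model is additive Gaussian. Magnitude MRI noise is Rician;
at the signal-to-noise ratios used here the Gaussian approximation is
standard, and the simpler model keeps ground truth exactly known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BinaryMask, Geometry, ImageVolume, MaskRole
from .errors import ParameterError

__all__ = [
    "PhantomSpec",
    "make_structural_phantom",
    "make_decay_series",
    "make_shifted_timeseries",
]

_MAX_ROTATION_DEG = 30.0  # declared range for synthetic frame motion


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a structural brain phantom.

    The brain is an axis-aligned ellipsoid; hemispheres are its halves on
    either side of the mid-sagittal plane (x = center). ``edema_scale``
    multiplies the in-plane extent of the ipsilateral (left, x < center)
    half to emulate hemispheric swelling; the optional lesion is a smaller
    ellipsoid placed inside the ipsilateral hemisphere. Intensities are
    means in arbitrary units; noise_sigma is the additive Gaussian SD.
    """

    shape: tuple = (64, 64, 10)
    brain_center: tuple | None = None
    brain_semi_axes: tuple | None = None
    lesion_center: tuple | None = None
    lesion_semi_axes: tuple | None = None
    background_intensity: float = 50.0
    brain_intensity: float = 1000.0
    lesion_intensity: float = 1400.0
    noise_sigma: float = 0.0
    edema_scale: float = 1.0
    geometry: Geometry = field(default_factory=lambda: Geometry(0.1, 0.1, 0.5, 0.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ParameterError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.edema_scale <= 0:
            raise ParameterError(f"edema_scale must be > 0, got {self.edema_scale}")


def _resolved(spec: PhantomSpec):
    shape = tuple(int(s) for s in spec.shape)
    center = spec.brain_center or tuple((s - 1) / 2.0 for s in shape)
    semi = spec.brain_semi_axes or tuple(0.35 * s for s in shape)
    return shape, np.asarray(center, float), np.asarray(semi, float)


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    """Voxel centers strictly inside the ellipsoid (<= 1 on the quadric)."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return q <= 1.0


def _check_inside(shape, center, semi_axes, what: str) -> None:
    center = np.asarray(center, float)
    semi = np.asarray(semi_axes, float)
    if np.any(center - semi < -0.5) or np.any(center + semi > np.asarray(shape) - 0.5):
        raise ParameterError(f"{what} ellipsoid exceeds the volume bounds")


def make_structural_phantom(spec: PhantomSpec):
    """Structural phantom: image plus exact brain/hemisphere/lesion masks.

    Returns ``(ImageVolume, masks)`` where ``masks`` maps
    ``brain | hemisphere_ipsi | hemisphere_contra [| lesion]`` to
    :class:`BinaryMask`. With zero noise the image takes exactly two (or
    three, with a lesion) distinct values. The hemisphere masks partition
    the brain mask by construction.
    """
    shape, center, semi = _resolved(spec)
    _check_inside(shape, center, semi * max(1.0, np.sqrt(spec.edema_scale)), "brain")

    left = _half_mask(shape, center, semi, spec.edema_scale, side="left")
    right = _half_mask(shape, center, semi, 1.0, side="right")
    brain = left | right

    image = np.full(shape, spec.background_intensity, dtype=np.float64)
    image[brain] = spec.brain_intensity

    masks = {
        "brain": BinaryMask(brain, role=MaskRole.BRAIN, parent_id="phantom"),
        "hemisphere_ipsi": BinaryMask(left, role=MaskRole.HEMISPHERE_IPSI, parent_id="phantom"),
        "hemisphere_contra": BinaryMask(right, role=MaskRole.HEMISPHERE_CONTRA, parent_id="phantom"),
    }
    if spec.lesion_center is not None:
        if spec.lesion_semi_axes is None:
            raise ParameterError("lesion_center given without lesion_semi_axes")
        _check_inside(shape, spec.lesion_center, spec.lesion_semi_axes, "lesion")
        lesion = _ellipsoid_mask(shape, spec.lesion_center, spec.lesion_semi_axes) & left
        image[lesion] = spec.lesion_intensity
        masks["lesion"] = BinaryMask(lesion, role=MaskRole.ROI, parent_id="phantom")

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sigma, size=shape)

    vol = ImageVolume(
        data=image, geometry=spec.geometry, experiment_id="phantom"
    )
    return vol, masks


def _half_mask(shape, center, semi, scale, side):
    """One ellipsoid half; in-plane semi-axes scaled by sqrt(scale) so the
    half's slice areas scale ~linearly with `scale`."""
    s = np.array(semi, float)
    s[:2] *= np.sqrt(scale)
    ell = _ellipsoid_mask(shape, center, s)
    xs = np.arange(shape[0])
    if side == "left":
        plane = xs < center[0]
    else:
        plane = xs >= center[0]
    sel = np.zeros(shape, dtype=bool)
    sel[plane, ...] = True
    return ell & sel


def make_decay_series(
    s0_map: np.ndarray,
    t_map: np.ndarray,
    timing,
    model: str = "t2_decay",
    noise_sigma: float = 0.0,
    seed: int = 0,
    geometry: Geometry | None = None,
) -> ImageVolume:
    """Exact forward relaxation model sampled at the given times.

    ``s0_map``/``t_map`` are 2D or 3D truth maps (2D maps become a single
    slice); the result is a 4D series (x, y, slice, time) with TE or TR
    list attached according to the model. Noise is additive Gaussian drawn
    in one call over the whole 4D array.
    """
    from .relaxometry import _MODEL_FUNCS  # forward models live with the fitters

    if model not in _MODEL_FUNCS:
        raise ParameterError(f"unknown model {model!r}")
    s0 = np.asarray(s0_map, dtype=np.float64)
    tv = np.asarray(t_map, dtype=np.float64)
    if s0.shape != tv.shape:
        raise ParameterError("s0_map and t_map shapes differ")
    if s0.ndim == 2:
        s0, tv = s0[:, :, None], tv[:, :, None]
    t = np.asarray(timing, dtype=np.float64)
    func = _MODEL_FUNCS[model][0]
    series = np.stack([func(ti, s0, tv) for ti in t], axis=3)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        series = series + rng.normal(0.0, noise_sigma, size=series.shape)
    geometry = geometry or Geometry(0.1, 0.1, 0.5, 0.0)
    kwargs = {"te_list": tuple(t)} if model == "t2_decay" else {"tr_list": tuple(t)}
    return ImageVolume(
        data=series, geometry=geometry, experiment_id=f"synthetic_{model}", **kwargs
    )


def make_shifted_timeseries(
    base: np.ndarray,
    transforms,
    noise_sigma: float = 0.0,
    seed: int = 0,
    geometry: Geometry | None = None,
):
    """4D series whose frame t is the base frame moved by a known rigid
    transform (dx, dy, theta_deg), plus optional noise.

    Returns ``(ImageVolume, ground_truth_transforms)``. Rotations beyond
    +/-30 degrees are rejected: the series emulates within-scan motion,
    which is small.
    """
    base = np.asarray(base, dtype=np.float64)
    if base.ndim == 2:
        base = base[:, :, None]
    if base.ndim != 3:
        raise ParameterError("base frame must be 2D or 3D")
    frames = []
    truth = []
    for dx, dy, theta in transforms:
        if abs(theta) > _MAX_ROTATION_DEG:
            raise ParameterError(
                f"rotation {theta} deg outside the declared +/-{_MAX_ROTATION_DEG} range"
            )
        frame = base
        if theta != 0.0:
            frame = ndimage.rotate(
                frame, theta, axes=(0, 1), reshape=False, order=1,
                mode="constant", cval=float(base.min()),
            )
        if dx != 0.0 or dy != 0.0:
            frame = ndimage.shift(
                frame, (dx, dy, 0.0), order=1, mode="constant", cval=float(base.min())
            )
        frames.append(frame)
        truth.append({"dx": float(dx), "dy": float(dy), "theta_deg": float(theta)})
    series = np.stack(frames, axis=3)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        series = series + rng.normal(0.0, noise_sigma, size=series.shape)
    geometry = geometry or Geometry(0.1, 0.1, 0.5, 0.0)
    vol = ImageVolume(data=series, geometry=geometry, experiment_id="synthetic_motion")
    return vol, truth
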