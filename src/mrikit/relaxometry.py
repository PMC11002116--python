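"""Voxelwise T1/T2 relaxometry and pulsed-ASL relative perfusion.

Each voxel's signal series is fitted independently with damped least
squares (Levenberg-Marquardt) using analytic Jacobians:

    t2_decay       S(TE) = S0 * exp(-TE / T2)
    t1_saturation  S(TR) = S0 * (1 - exp(-TR / T1))
    t1_inversion   S(TI) = | S0 * (1 - 2 exp(-TI / T1)) |   (magnitude data)

Series are normalized per voxel by their maximum before fitting (S0 is
rescaled back afterwards), which conditions the optimizer uniformly across
voxels; fitted maps are therefore invariant to uniform signal rescaling.

Pulsed arterial spin labeling (FAIR-type) maps come from two apparent-T1
fits — selective (labeled) and global (control) inversion — combined as a
rate difference scaled by the longitudinal relaxation time of blood:

    relative perfusion = T1_blood * (1 / T1_sel - 1 / T1_glob).

Optional multiplicative constants (blood-tissue partition coefficient,
inversion efficiency) can convert this to absolute CBF; by default the
map is relative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import BinaryMask, Geometry, ImageVolume
from .errors import DataError, GeometryError, MetadataError, ParameterError

__all__ = ["ParameterMap", "FitConfig", "fit_t2", "fit_t1", "fit_pasl"]

_MODELS = ("t2_decay", "t1_saturation", "t1_inversion", "pasl")


@dataclass
class ParameterMap:
    """Per-voxel fitted quantity with fit diagnostics.

    ``values`` holds T1/T2 in ms or relative perfusion (dimensionless
    unless the caller applies a CBF scaling); NaN marks voxels outside the
    mask or where the fit failed. ``residual_map`` is the per-voxel sum of
    squared residuals in original signal units.
    """

    values: np.ndarray
    s0_map: np.ndarray
    residual_map: np.ndarray
    converged: np.ndarray
    model: str
    geometry: Geometry
    parent_id: str = "volume"
    affine: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ParameterError(f"unknown model {self.model!r}")
        if self.affine is None:
            self.affine = np.eye(4)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for voxelwise fitting.

    ``t_bounds`` (ms) are enforced by projecting the LM solution; a
    projected voxel is flagged not-converged. ``normalize`` divides each
    series by its max before fitting and rescales S0 afterwards.
    """

    t_init: float | None = None
    t_bounds: tuple = (1.0, 10000.0)
    s0_bounds: tuple = (0.0, np.inf)
    max_iter: int = 200
    tol: float = 1e-8
    normalize: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.t_bounds
        if not (0 < lo < hi) or not np.isfinite(lo) or not np.isfinite(hi):
            raise ParameterError(f"t_bounds must be finite and positive, got {self.t_bounds}")


# ---------------------------------------------------------------------------
# Signal models and analytic Jacobians


def _model_t2(t, s0, tau):
    return s0 * np.exp(-t / tau)


def _jac_t2(t, s0, tau):
    e = np.exp(-t / tau)
    return np.column_stack([e, s0 * t / tau**2 * e])


def _model_t1sat(t, s0, tau):
    return s0 * (1.0 - np.exp(-t / tau))


def _jac_t1sat(t, s0, tau):
    e = np.exp(-t / tau)
    return np.column_stack([1.0 - e, -s0 * t / tau**2 * e])


def _model_t1inv(t, s0, tau):
    return np.abs(s0 * (1.0 - 2.0 * np.exp(-t / tau)))


def _jac_t1inv(t, s0, tau):
    e = np.exp(-t / tau)
    inner = s0 * (1.0 - 2.0 * e)
    sign = np.sign(inner)
    return np.column_stack([sign * (1.0 - 2.0 * e), sign * (-2.0 * s0 * t / tau**2 * e)])


_MODEL_FUNCS = {
    "t2_decay": (_model_t2, _jac_t2),
    "t1_saturation": (_model_t1sat, _jac_t1sat),
    "t1_inversion": (_model_t1inv, _jac_t1inv),
}


def _init_tau(t: np.ndarray, y: np.ndarray, model: str, cfg: FitConfig) -> float:
    lo, hi = cfg.t_bounds
    if cfg.t_init is not None:
        return float(np.clip(cfg.t_init, lo, hi))
    if model == "t2_decay":
        # two-point log-linear estimate from the first and last echoes
        if y[0] > 0 and y[-1] > 0 and y[0] > y[-1]:
            tau = (t[-1] - t[0]) / np.log(y[0] / y[-1])
        else:
            tau = 0.5 * (t[0] + t[-1])
    elif model == "t1_saturation":
        # timing point nearest the half-recovery signal: S = S0/2 at TR = T1 ln 2
        ymax = y.max()
        idx = int(np.argmin(np.abs(y - 0.5 * ymax)))
        tau = t[idx] / np.log(2.0)
    else:  # t1_inversion: magnitude null at TI = T1 ln 2
        idx = int(np.argmin(np.abs(y)))
        tau = t[idx] / np.log(2.0)
    if not np.isfinite(tau) or tau <= 0:
        tau = 0.5 * (t[0] + t[-1])
    return float(np.clip(tau, lo, hi))


def _fit_voxel(t: np.ndarray, y: np.ndarray, model: str, cfg: FitConfig):
    """Fit one voxel; returns (tau, s0, ssr, converged)."""
    func, jac = _MODEL_FUNCS[model]
    scale = float(np.max(np.abs(y))) if cfg.normalize else 1.0
    if scale == 0.0:
        return np.nan, np.nan, np.nan, False
    yn = y / scale

    def residuals(p):
        return func(t, p[0], p[1]) - yn

    def jacobian(p):
        return jac(t, p[0], p[1])

    p0 = np.array([max(yn.max(), 1e-6), _init_tau(t, yn, model, cfg)])
    try:
        res = least_squares(
            residuals,
            p0,
            jac=jacobian,
            method="lm",
            xtol=cfg.tol,
            ftol=cfg.tol,
            gtol=cfg.tol,
            max_nfev=cfg.max_iter * 3,
        )
    except Exception:
        return np.nan, np.nan, np.nan, False
    s0, tau = res.x
    lo, hi = cfg.t_bounds
    projected = not (lo <= tau <= hi) or not (
        cfg.s0_bounds[0] <= s0 * scale <= cfg.s0_bounds[1]
    )
    tau = float(np.clip(tau, lo, hi))
    s0 = float(np.clip(s0 * scale, *cfg.s0_bounds))
    ssr = float(np.sum((func(t, s0, tau) - y) ** 2))
    converged = bool(res.success) and not projected and tau > 0
    return tau, s0, ssr, converged


def _series_and_mask(series: ImageVolume, timing, mask, min_points: int):
    arr = series.data
    if arr.ndim != 4:
        raise GeometryError(
            f"voxelwise fitting needs a 4D series (x, y, slice, time), got {arr.ndim} dims"
        )
    t = np.asarray(timing, dtype=np.float64)
    if t.size < min_points:
        raise DataError(f"need at least {min_points} timing points, got {t.size}")
    if t.size != arr.shape[3]:
        raise MetadataError(
            f"timing list length {t.size} does not match series extent {arr.shape[3]}"
        )
    if np.any(np.diff(t) <= 0):
        raise MetadataError("timing values must be strictly increasing")
    if mask is not None:
        mask.check_grid(ImageVolume(arr[..., 0], series.geometry))
        m = mask.data
    else:
        m = np.ones(arr.shape[:3], dtype=bool)
    return arr, t, m


def _fit_map(series: ImageVolume, timing, mask, cfg: FitConfig, model: str) -> ParameterMap:
    cfg = cfg or FitConfig()
    arr, t, m = _series_and_mask(series, timing, mask, min_points=3)
    shape = arr.shape[:3]
    values = np.full(shape, np.nan)
    s0_map = np.full(shape, np.nan)
    residual_map = np.full(shape, np.nan)
    converged = np.zeros(shape, dtype=bool)
    for idx in np.argwhere(m):
        voxel = arr[idx[0], idx[1], idx[2], :]
        tau, s0, ssr, ok = _fit_voxel(t, voxel, model, cfg)
        values[tuple(idx)] = tau
        s0_map[tuple(idx)] = s0
        residual_map[tuple(idx)] = ssr
        converged[tuple(idx)] = ok
    return ParameterMap(
        values=values,
        s0_map=s0_map,
        residual_map=residual_map,
        converged=converged,
        model=model,
        geometry=series.geometry,
        parent_id=series.experiment_id,
        affine=series.affine,
    )


def fit_t2(
    series: ImageVolume,
    mask: BinaryMask | None = None,
    cfg: FitConfig | None = None,
) -> ParameterMap:
    """Voxelwise T2 map from a multi-echo series.

    Echo times come from ``series.te_list`` (ms, strictly increasing, at
    least three echoes). Voxels outside the mask are NaN.
    """
    return _fit_map(series, series.te_list, mask, cfg or FitConfig(), "t2_decay")


def fit_t1(
    series: ImageVolume,
    mask: BinaryMask | None = None,
    cfg: FitConfig | None = None,
    model: str = "t1_saturation",
    timing=None,
) -> ParameterMap:
    """Voxelwise T1 map from a variable-TR (saturation) or variable-TI
    (inversion, magnitude) series.

    ``timing`` defaults to ``series.tr_list``; pass inversion times there
    for the inversion-recovery model.
    """
    if model not in ("t1_saturation", "t1_inversion"):
        raise ParameterError(f"T1 model must be t1_saturation|t1_inversion, got {model!r}")
    timing = series.tr_list if timing is None else timing
    return _fit_map(series, timing, mask, cfg or FitConfig(), model)


def fit_pasl(
    labeled: ImageVolume,
    control: ImageVolume,
    blood_t1: float,
    ti_list=None,
    mask: BinaryMask | None = None,
    cfg: FitConfig | None = None,
    model: str = "t1_inversion",
    partition_coefficient: float = 1.0,
    inversion_efficiency: float = 1.0,
) -> ParameterMap:
    """Relative perfusion map from a pulsed-ASL acquisition pair.

    Apparent T1 is fitted voxelwise and independently for the labeled
    (slice-selective inversion) and control (global inversion) series; the
    perfusion estimate is the relaxation-rate difference scaled by the T1
    of arterial blood (ms):

        f_rel = lambda/alpha * T1_blood * (1/T1_sel - 1/T1_glob)

    with partition coefficient lambda and inversion efficiency alpha both 1
    by default (relative maps). Voxels where either fit fails are NaN.
    """
    if blood_t1 <= 0:
        raise ParameterError(f"blood_t1 must be positive, got {blood_t1}")
    if labeled.data.shape != control.data.shape:
        raise GeometryError(
            f"labeled {labeled.data.shape} and control {control.data.shape} "
            "series are on different grids"
        )
    timing = ti_list if ti_list is not None else labeled.tr_list
    cfg = cfg or FitConfig()
    sel = _fit_map(labeled, timing, mask, cfg, model)
    glob = _fit_map(control, timing, mask, cfg, model)
    with np.errstate(divide="ignore", invalid="ignore"):
        perfusion = (
            partition_coefficient
            / inversion_efficiency
            * blood_t1
            * (1.0 / sel.values - 1.0 / glob.values)
        )
    converged = sel.converged & glob.converged
    perfusion[~converged & ~np.isnan(perfusion)] = np.nan
    return ParameterMap(
        values=perfusion,
        s0_map=glob.s0_map,
        residual_map=sel.residual_map + glob.residual_map,
        converged=converged,
        model="pasl",
        geometry=labeled.geometry,
        parent_id=labeled.experiment_id,
        affine=labeled.affine,
    )
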