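"""NIfTI-1 reading/writing, JSON sidecars and session persistence.

NIfTI-1 headers carry voxel sizes but have no reliable slot for the slice
gap or for echo/repetition time lists, so those travel in a JSON sidecar
(``<image>.json`` next to ``<image>.nii[.gz]``, keys ``slice_gap``,
``te_list``, ``tr_list``, ``units``). Header pixdim wins for voxel sizes
unless the sidecar explicitly overrides them.

Sessions are directories holding one NIfTI per array plus a
``manifest.json`` with geometry, roles and the provenance log — plain
files, inspectable from any language.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import BinaryMask, Geometry, ImageVolume, MaskRole, Session
from .errors import DimensionalityError, FormatError

__all__ = [
    "load_nifti",
    "load_mask",
    "save_nifti",
    "save_session",
    "load_session",
]

_SIDECAR_KEYS = {
    "slice_gap",
    "te_list",
    "tr_list",
    "units",
    "voxel_x",
    "voxel_y",
    "slice_thickness",
}


def sidecar_path(image_path: str | Path) -> Path:
    """Path of the JSON sidecar belonging to a NIfTI file."""
    p = Path(image_path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def _read_sidecar(sidecar) -> dict:
    if sidecar is None:
        return {}
    if isinstance(sidecar, dict):
        data = dict(sidecar)
    else:
        try:
            data = json.loads(Path(sidecar).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise FormatError(f"cannot read sidecar {sidecar}: {exc}") from exc
    unknown = set(data) - _SIDECAR_KEYS
    if unknown:
        raise FormatError(f"unknown sidecar keys: {sorted(unknown)}")
    return data


def load_nifti(
    path: str | Path,
    sidecar: dict | str | Path | None = None,
    experiment_id: str | None = None,
) -> ImageVolume:
    """Load a 2-5 dimensional NIfTI-1 image as an :class:`ImageVolume`.

    Geometry comes from the header pixdim (x, y from pixdim[1..2], slice
    thickness from pixdim[3]); the slice gap defaults to 0 and the TE/TR
    lists to empty unless a sidecar provides them. If ``sidecar`` is None
    and a ``<image>.json`` file sits next to the image, it is used
    automatically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
    except Exception as exc:  # nibabel raises a zoo of types on bad files
        raise FormatError(f"{path} is not a readable NIfTI-1 file: {exc}") from exc
    if data.ndim > 5:
        raise DimensionalityError(f"{path}: {data.ndim} dims, at most 5 supported")
    if data.ndim < 2:
        raise DimensionalityError(f"{path}: {data.ndim} dims, at least 2 required")

    zooms = img.header.get_zooms()
    meta = {
        "voxel_x": float(zooms[0]) if len(zooms) > 0 else 1.0,
        "voxel_y": float(zooms[1]) if len(zooms) > 1 else 1.0,
        "slice_thickness": float(zooms[2]) if len(zooms) > 2 else 1.0,
        "slice_gap": 0.0,
        "units": "mm",
        "te_list": (),
        "tr_list": (),
    }
    if sidecar is None:
        auto = sidecar_path(path)
        if auto.exists():
            sidecar = auto
    meta.update(_read_sidecar(sidecar))

    geometry = Geometry(
        voxel_x=meta["voxel_x"],
        voxel_y=meta["voxel_y"],
        slice_thickness=meta["slice_thickness"],
        slice_gap=meta["slice_gap"],
        units_label=meta["units"],
    )
    return ImageVolume(
        data=data,
        geometry=geometry,
        te_list=tuple(meta["te_list"]),
        tr_list=tuple(meta["tr_list"]),
        experiment_id=experiment_id or path.name.split(".")[0],
        affine=np.asarray(img.affine, dtype=np.float64),
    )


def load_mask(
    path: str | Path,
    role: MaskRole | str = MaskRole.ROI,
    parent_id: str = "volume",
) -> BinaryMask:
    """Load a NIfTI of 0/1 values as a :class:`BinaryMask`."""
    vol = load_nifti(path)
    return BinaryMask(data=vol.data > 0.5, role=MaskRole(role), parent_id=parent_id)


def _geometry_sidecar(obj) -> dict:
    g = obj.geometry
    out = {"slice_gap": g.slice_gap, "units": g.units_label}
    te = getattr(obj, "te_list", ())
    tr = getattr(obj, "tr_list", ())
    if te:
        out["te_list"] = list(te)
    if tr:
        out["tr_list"] = list(tr)
    return out


def save_nifti(obj, path: str | Path) -> Path:
    """Write an ImageVolume, BinaryMask or ParameterMap to NIfTI-1.

    Images round-trip to floating-point fidelity (float64 on disk), masks
    bit-exactly as uint8 0/1, parameter maps as float32 with NaN preserved
    at unfitted voxels. Geometry that NIfTI cannot carry (slice gap, TE/TR)
    is written to the JSON sidecar next to the image.
    """
    from .relaxometry import ParameterMap  # local import avoids a cycle

    path = Path(path)
    if isinstance(obj, BinaryMask):
        arr = obj.data.astype(np.uint8)
        affine = _default_mask_affine(obj)
        img = nib.Nifti1Image(arr, affine)
    elif isinstance(obj, ImageVolume):
        img = nib.Nifti1Image(obj.data.astype(np.float64), obj.affine)
        _set_zooms(img, obj)
    elif isinstance(obj, ParameterMap):
        img = nib.Nifti1Image(obj.values.astype(np.float32), obj.affine)
    else:
        raise TypeError(f"cannot save object of type {type(obj).__name__}")
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
    if isinstance(obj, ImageVolume):
        meta = _geometry_sidecar(obj)
        if meta.get("slice_gap") or "te_list" in meta or "tr_list" in meta:
            sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _set_zooms(img: nib.Nifti1Image, vol: ImageVolume) -> None:
    g = vol.geometry
    zooms = list(img.header.get_zooms())
    zooms[0] = g.voxel_x
    if len(zooms) > 1:
        zooms[1] = g.voxel_y
    if len(zooms) > 2:
        zooms[2] = g.slice_thickness
    img.header.set_zooms(zooms)


def _default_mask_affine(mask: BinaryMask) -> np.ndarray:
    return np.eye(4)


# ---------------------------------------------------------------------------
# Session persistence


def save_session(session: Session, dirpath: str | Path) -> Path:
    """Persist a session as a directory of NIfTI files plus manifest.json."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    manifest = {"volumes": [], "masks": [], "maps": [], "provenance": session.provenance}
    for i, vol in enumerate(session.volumes):
        fname = f"volume_{i:03d}.nii.gz"
        save_nifti(vol, dirpath / fname)
        manifest["volumes"].append(
            {
                "file": fname,
                "experiment_id": vol.experiment_id,
                "geometry": vol.geometry.to_dict(),
                "te_list": list(vol.te_list),
                "tr_list": list(vol.tr_list),
            }
        )
    for i, mask in enumerate(session.masks):
        fname = f"mask_{i:03d}.nii.gz"
        save_nifti(mask, dirpath / fname)
        manifest["masks"].append(
            {"file": fname, "role": mask.role.value, "parent_id": mask.parent_id}
        )
    for i, pmap in enumerate(session.maps):
        base = f"map_{i:03d}"
        _save_map_arrays(pmap, dirpath, base)
        manifest["maps"].append(
            {
                "base": base,
                "model": pmap.model,
                "parent_id": pmap.parent_id,
                "geometry": pmap.geometry.to_dict(),
            }
        )
    (dirpath / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return dirpath


def _save_map_arrays(pmap, dirpath: Path, base: str) -> None:
    for suffix, arr in (
        ("values", pmap.values.astype(np.float64)),
        ("s0", pmap.s0_map.astype(np.float64)),
        ("residual", pmap.residual_map.astype(np.float64)),
        ("converged", pmap.converged.astype(np.uint8)),
    ):
        nib.save(
            nib.Nifti1Image(arr, pmap.affine), str(dirpath / f"{base}_{suffix}.nii.gz")
        )


def load_session(dirpath: str | Path) -> Session:
    """Load a session saved by :func:`save_session`.

    Arrays are reproduced bit-exactly and the provenance log verbatim.
    """
    from .relaxometry import ParameterMap

    dirpath = Path(dirpath)
    manifest_file = dirpath / "manifest.json"
    if not manifest_file.exists():
        raise FormatError(f"{dirpath} has no manifest.json")
    try:
        manifest = json.loads(manifest_file.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed manifest: {exc}") from exc

    session = Session(provenance=list(manifest.get("provenance", [])))
    for entry in manifest.get("volumes", []):
        f = dirpath / entry["file"]
        if not f.exists():
            raise FormatError(f"manifest references missing file {entry['file']}")
        img = nib.load(str(f))
        session.add_volume(
            ImageVolume(
                data=np.asanyarray(img.dataobj).astype(np.float64),
                geometry=Geometry.from_dict(entry["geometry"]),
                te_list=tuple(entry["te_list"]),
                tr_list=tuple(entry["tr_list"]),
                experiment_id=entry["experiment_id"],
                affine=np.asarray(img.affine),
            )
        )
    for entry in manifest.get("masks", []):
        f = dirpath / entry["file"]
        if not f.exists():
            raise FormatError(f"manifest references missing file {entry['file']}")
        img = nib.load(str(f))
        session.add_mask(
            BinaryMask(
                data=np.asanyarray(img.dataobj) > 0,
                role=MaskRole(entry["role"]),
                parent_id=entry["parent_id"],
            )
        )
    for entry in manifest.get("maps", []):
        base = entry["base"]
        arrays = {}
        for suffix in ("values", "s0", "residual", "converged"):
            f = dirpath / f"{base}_{suffix}.nii.gz"
            if not f.exists():
                raise FormatError(f"manifest references missing file {f.name}")
            arrays[suffix] = np.asanyarray(nib.load(str(f)).dataobj)
        session.add_map(
            ParameterMap(
                values=arrays["values"].astype(np.float64),
                s0_map=arrays["s0"].astype(np.float64),
                residual_map=arrays["residual"].astype(np.float64),
                converged=arrays["converged"].astype(bool),
                model=entry["model"],
                geometry=Geometry.from_dict(entry["geometry"]),
                parent_id=entry["parent_id"],
            )
        )
    return session
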