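"""Volume I/O: NIfTI for dose fields and masks, plus a compressed
multi-array bundle with a JSON sidecar for grid/lattice metadata.

Dose fields are written as float32 NIfTI (Gy), masks as uint8; the affine
is diagonal with the grid spacing and origin.  The ``.npz`` bundle stores
several congruent arrays with their shared :class:`GridSpec` for fast
round-trips inside the pipeline.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import LatticeSpec
from .grids import DoseGrid, GridSpec, RoiMask

__all__ = [
    "save_dose_nifti", "load_dose_nifti",
    "save_mask_nifti", "load_mask_nifti",
    "save_bundle", "load_bundle",
    "save_sidecar", "load_sidecar",
]


def _grid_from_nifti(img) -> GridSpec:
    aff = img.affine
    spacing = tuple(float(x) for x in np.diag(aff)[:3])
    if any(s <= 0 for s in spacing) or not np.allclose(
            aff[:3, :3], np.diag(spacing)):
        raise ValueError("only axis-aligned, positive-spacing affines are "
                         "supported")
    return GridSpec(shape=img.shape[:3], spacing=spacing,
                    origin=tuple(float(x) for x in aff[:3, 3]))


def save_dose_nifti(dose: DoseGrid, path) -> None:
    img = nib.Nifti1Image(dose.values.astype(np.float32),
                          dose.grid.to_affine())
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def load_dose_nifti(path) -> DoseGrid:
    img = nib.load(str(path))
    return DoseGrid(np.asarray(img.dataobj, dtype=float), _grid_from_nifti(img))


def save_mask_nifti(mask: RoiMask, path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), mask.grid.to_affine())
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def load_mask_nifti(path, name: str | None = None) -> RoiMask:
    img = nib.load(str(path))
    return RoiMask(name or Path(str(path)).stem,
                   np.asarray(img.dataobj) > 0, _grid_from_nifti(img))


def save_bundle(path, grid: GridSpec, **arrays) -> None:
    """Compressed multi-array container holding congruent volumes."""
    meta = json.dumps(dataclasses.asdict(grid))
    np.savez_compressed(str(path), __gridspec__=np.array(meta), **arrays)


def load_bundle(path) -> tuple[GridSpec, dict[str, np.ndarray]]:
    with np.load(str(path)) as data:
        meta = json.loads(str(data["__gridspec__"]))
        grid = GridSpec(shape=tuple(meta["shape"]),
                        spacing=tuple(meta["spacing"]),
                        origin=tuple(meta["origin"]))
        arrays = {k: data[k] for k in data.files if k != "__gridspec__"}
    return grid, arrays


def save_sidecar(path, **specs) -> None:
    """JSON sidecar for dataclass specs (GridSpec, LatticeSpec, SimParams...)."""
    payload = {}
    for key, value in specs.items():
        if dataclasses.is_dataclass(value):
            payload[key] = {"__type__": type(value).__name__,
                            **dataclasses.asdict(value)}
        else:
            payload[key] = value
    Path(str(path)).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_sidecar(path) -> dict:
    from .simulate import SimParams

    types = {"GridSpec": GridSpec, "LatticeSpec": LatticeSpec,
             "SimParams": SimParams}
    payload = json.loads(Path(str(path)).read_text())
    out = {}
    for key, value in payload.items():
        if isinstance(value, dict) and value.get("__type__") in types:
            cls = types[value.pop("__type__")]
            kwargs = {k: tuple(v) if isinstance(v, list) else v
                      for k, v in value.items()}
            out[key] = cls(**kwargs)
        else:
            out[key] = value
    return out
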