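"""File formats: NIfTI volumes, b-tables, warps, atlases, fingerprints.

Volumes are NIfTI-1 via nibabel and are reoriented to the canonical axis
order on load so that voxel-index ordering is anatomically consistent.
B-tables are plain text with one "b gx gy gz" row per volume.  Fingerprints
live in a single HDF5 file (datasets ``values`` and ``index``, metadata as
attributes) with a CSV export.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .fingerprint import DirectionAtlas, Fingerprint
from .grids import Grid
from .sdf import DiffeoMap, DirectionSet, DwiDataset, GradientScheme, SdfField

__all__ = [
    "load_btable",
    "save_btable",
    "load_dwi",
    "save_dwi",
    "load_mask",
    "save_mask",
    "load_atlas",
    "save_atlas",
    "load_warp",
    "save_warp",
    "save_sdf",
    "load_sdf",
    "save_fingerprint",
    "load_fingerprint",
    "fingerprint_to_csv",
]


def _canonical(img: nib.Nifti1Image) -> nib.Nifti1Image:
    return nib.as_closest_canonical(img)


def load_btable(path) -> GradientScheme:
    """Read a whitespace-separated "b gx gy gz" table (one row per volume)."""
    tab = np.loadtxt(path, dtype=float)
    tab = np.atleast_2d(tab)
    if tab.shape[1] != 4:
        raise ValueError("b-table must have 4 columns: b gx gy gz")
    return GradientScheme(b_values=tab[:, 0], directions=tab[:, 1:4])


def save_btable(path, scheme: GradientScheme) -> None:
    tab = np.column_stack([scheme.b_values, scheme.directions])
    np.savetxt(path, tab, fmt="%.8g")


def load_dwi(dwi_path, btable_path, brain_mask_path=None, ventricle_mask_path=None) -> DwiDataset:
    """Load a 4-D DWI volume plus its b-table (and optional masks)."""
    img = _canonical(nib.load(str(dwi_path)))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("DWI volume must be 4-D")
    scheme = load_btable(btable_path)
    brain = load_mask(brain_mask_path) if brain_mask_path else None
    vent = load_mask(ventricle_mask_path) if ventricle_mask_path else None
    return DwiDataset(signals=np.clip(data, 0.0, None), scheme=scheme, affine=img.affine,
                      brain_mask=brain, ventricle_mask=vent)


def save_dwi(path, dwi: DwiDataset) -> None:
    nib.save(nib.Nifti1Image(dwi.signals.astype(np.float32), dwi.affine), str(path))


def load_mask(path) -> np.ndarray:
    img = _canonical(nib.load(str(path)))
    return np.asarray(img.dataobj) != 0


def save_mask(path, mask: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def save_atlas(atlas_path, mask_path, atlas: DirectionAtlas) -> None:
    """Atlas as a 4-D NIfTI with 3·K components per voxel plus a mask volume."""
    shape = atlas.grid.shape
    k = atlas.k_max
    flat = atlas.fibers.reshape(shape + (3 * k,))
    nib.save(nib.Nifti1Image(flat.astype(np.float32), atlas.grid.affine), str(atlas_path))
    save_mask(mask_path, atlas.mask, atlas.grid.affine)


def load_atlas(atlas_path, mask_path) -> DirectionAtlas:
    img = _canonical(nib.load(str(atlas_path)))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] % 3:
        raise ValueError("atlas volume must be 4-D with 3*K components")
    k = data.shape[3] // 3
    fibers = data.reshape(data.shape[:3] + (k, 3))
    # renormalize against float32 round-off; zero rows stay zero
    norms = np.linalg.norm(fibers, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        fibers = np.where(norms > 0.5, fibers / norms, 0.0)
    mask = load_mask(mask_path)
    return DirectionAtlas(mask=mask, fibers=fibers, grid=Grid(data.shape[:3], img.affine))


def save_warp(path, displacement_mm: np.ndarray, affine: np.ndarray,
              jacobian: Optional[np.ndarray] = None) -> None:
    """Warp as a 3-vector displacement field (mm), optional 9-component Jacobian."""
    nib.save(nib.Nifti1Image(displacement_mm.astype(np.float32), affine), str(path))
    if jacobian is not None:
        jpath = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii(.gz)
        jfile = str(jpath) + "_jac.nii"
        flat = jacobian.reshape(jacobian.shape[:3] + (9,))
        nib.save(nib.Nifti1Image(flat.astype(np.float32), affine), jfile)


def load_warp(path, jacobian_path=None) -> DiffeoMap:
    img = _canonical(nib.load(str(path)))
    disp = np.asarray(img.dataobj, dtype=float)
    if disp.ndim != 4 or disp.shape[3] != 3:
        raise ValueError("warp must be a 4-D NIfTI with 3 displacement components (mm)")
    grid = Grid(disp.shape[:3], img.affine)
    jac = None
    if jacobian_path:
        jimg = _canonical(nib.load(str(jacobian_path)))
        jdata = np.asarray(jimg.dataobj, dtype=float)
        if jdata.ndim != 4 or jdata.shape[3] != 9:
            raise ValueError("jacobian volume must have 9 components")
        jac = jdata.reshape(grid.shape + (3, 3))
    return DiffeoMap.from_displacement(grid, disp, jacobian=jac)


def save_sdf(path, sidecar_path, sdf: SdfField) -> None:
    """SDF field as voxel×direction NIfTI plus a text sidecar of directions."""
    nib.save(nib.Nifti1Image(sdf.values.astype(np.float32), sdf.grid.affine), str(path))
    np.savetxt(sidecar_path, sdf.direction_set.units, fmt="%.10g",
               header="SDF sampling directions (unit vectors, antipodal axes)")


def load_sdf(path, sidecar_path) -> SdfField:
    img = _canonical(nib.load(str(path)))
    values = np.asarray(img.dataobj, dtype=float)
    units = np.atleast_2d(np.loadtxt(sidecar_path, dtype=float))
    units /= np.linalg.norm(units, axis=1, keepdims=True)
    return SdfField(values=np.clip(values, 0.0, None), grid=Grid(values.shape[:3], img.affine),
                    direction_set=DirectionSet(units))


def save_fingerprint(path, fp: Fingerprint) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=fp.values.astype(np.float64))
        f.create_dataset("index", data=fp.index.astype(np.int64))
        f.attrs["subject_id"] = fp.subject_id
        f.attrs["session_id"] = fp.session_id
        f.attrs["days"] = float(fp.days)
        f.attrs["atlas_hash"] = fp.atlas_hash
        f.attrs["normalized"] = bool(fp.normalized)


def load_fingerprint(path) -> Fingerprint:
    with h5py.File(path, "r") as f:
        return Fingerprint(
            values=f["values"][()],
            index=f["index"][()],
            subject_id=str(f.attrs["subject_id"]),
            session_id=str(f.attrs["session_id"]),
            days=float(f.attrs["days"]),
            atlas_hash=str(f.attrs["atlas_hash"]),
            normalized=bool(f.attrs["normalized"]),
        )


def fingerprint_to_csv(path, fp: Fingerprint) -> None:
    fp.to_frame().to_csv(path, index=False)


def load_distance_csv(path):
    """Inverse of DistanceMatrix.to_csv: returns (values, labels frame)."""
    frame = pd.read_csv(path, index_col=0)
    names = list(frame.index)
    subj, ses = zip(*[n.rsplit("_", 1) for n in names])
    labels = pd.DataFrame({"subject_id": subj, "session_id": ses})
    return frame.to_numpy(dtype=float), labels
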