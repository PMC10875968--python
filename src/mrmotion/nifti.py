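"""NIfTI-1 read/write at the package boundary.

Files carry the usual RAS+ world frame; internally the package labels axes
LR/AP/SI in an LPS-flavoured frame (see :mod:`mrmotion.geometry`).  On read,
the array is reoriented so lattice axes follow (LR, AP, SI) and RAS
coordinates are sign-flipped to LPS; writing reverses the mapping, so a
round trip preserves values bit-exactly and geometry to well below 1e-6 mm.

Only orthogonal, axis-aligned affines are supported.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .geometry import GeometryError, SliceGeometry, DynamicSlice, VolumeImage

_RAS2LPS = np.array([-1.0, -1.0, 1.0])


def _check_orthogonal(affine: np.ndarray):
    rot = affine[:3, :3]
    # exactly one non-zero per row/column
    nz = np.abs(rot) > 1e-6 * np.max(np.abs(rot))
    if not (np.all(nz.sum(axis=0) == 1) and np.all(nz.sum(axis=1) == 1)):
        raise GeometryError(f"unsupported non-orthogonal affine:\n{affine}")


def read_volume(path) -> VolumeImage:
    img = nib.load(str(path))
    affine = img.affine
    _check_orthogonal(affine)
    # reorient the array so voxel axes map to (L, P, S)
    io_ornt = nib.orientations.io_orientation(affine)
    target = nib.orientations.axcodes2ornt(("L", "P", "S"))
    xform = nib.orientations.ornt_transform(io_ornt, target)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise GeometryError("read_volume expects a 3D NIfTI (use read_dvf for vector images)")
    data = nib.orientations.apply_orientation(data, xform)
    new_affine = affine @ nib.orientations.inv_ornt_aff(xform, img.shape[:3])
    _check_orthogonal(new_affine)
    spacing = np.abs(np.diag(new_affine[:3, :3]))
    origin = _RAS2LPS * new_affine[:3, 3]
    # sanity: columns must now point along -X, -Y, +Z (i.e. L, P, S)
    direction = np.diag(_RAS2LPS) @ new_affine[:3, :3]
    if np.any(np.diag(direction) <= 0):
        raise GeometryError("failed to orient volume to LPS axes")
    return VolumeImage(values=data, spacing=spacing, origin=origin)


def _lps_affine(vol: VolumeImage) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(_RAS2LPS * vol.spacing)
    affine[:3, 3] = _RAS2LPS * vol.origin
    return affine


def write_volume(vol: VolumeImage, path, description: str = ""):
    img = nib.Nifti1Image(np.asarray(vol.values), _lps_affine(vol))
    img.header["pixdim"][1:4] = vol.spacing
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def write_dvf(values: np.ndarray, spacing, origin, path, direction_tag: str):
    """3-component displacement field as a 4D NIfTI with a direction tag."""
    vol = VolumeImage(values=np.zeros(values.shape[:3]), spacing=spacing, origin=origin)
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), _lps_affine(vol))
    img.header["descrip"] = f"DVF {direction_tag}".encode()[:79]
    img.header.set_intent("vector")
    nib.save(img, str(path))


def read_dvf(path):
    img = nib.load(str(path))
    affine = img.affine
    _check_orthogonal(affine)
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = np.abs(np.diag(affine[:3, :3]))
    origin = _RAS2LPS * affine[:3, 3]
    tag = img.header["descrip"].tobytes().decode(errors="ignore").strip("\x00")
    tag = tag.removeprefix("DVF").strip()
    return data, spacing, origin, tag


def write_slice(slc: DynamicSlice, path):
    """Store a thick slice as a 1-thick volume with its full affine.

    The through-plane pixdim carries the slice thickness; role/timing live
    in the dataset manifest.
    """
    g = slc.geometry
    affine = np.eye(4)
    cols = np.column_stack(
        [
            g.in_plane_axes[0] * g.in_plane_spacing[0],
            g.in_plane_axes[1] * g.in_plane_spacing[1],
            g.normal * g.thickness,
        ]
    )
    affine[:3, :3] = np.diag(_RAS2LPS) @ cols
    affine[:3, 3] = _RAS2LPS * g.origin
    img = nib.Nifti1Image(slc.values[:, :, None], affine)
    nib.save(img, str(path))


def read_slice(path, t_index: int, t_seconds: float, role: str, thickness: float) -> DynamicSlice:
    img = nib.load(str(path))
    affine = img.affine
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3 or data.shape[2] != 1:
        raise GeometryError("slice files must be 1-thick volumes")
    cols = np.diag(_RAS2LPS) @ affine[:3, :3]
    sp0 = np.linalg.norm(cols[:, 0])
    sp1 = np.linalg.norm(cols[:, 1])
    geom = SliceGeometry(
        origin=_RAS2LPS * affine[:3, 3],
        in_plane_axes=np.array([cols[:, 0] / sp0, cols[:, 1] / sp1]),
        normal=cols[:, 2] / np.linalg.norm(cols[:, 2]),
        in_plane_spacing=np.array([sp0, sp1]),
        shape=data.shape[:2],
        thickness=thickness,
    )
    return DynamicSlice(
        geometry=geom, values=data[:, :, 0], t_index=t_index, t_seconds=t_seconds, role=role
    )
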