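"""Medical volume I/O and resampling to a standardized grid.

The unit of work is the :class:`VolumeGrid`: a 3D scalar array in
(slice, row, col) axis order with physical voxel spacing in mm per axis.
NIfTI files are read and written through nibabel; DICOM series are read
through pydicom (one file per slice, sorted along the slice axis, with a
uniform-gap check).

``resample_volume`` interpolates a volume onto a new physical grid — by
default the 1 mm isotropic, 512 x 512-plane grid the downstream pipeline
assumes.  The grid convention is "grid of points with endpoints preserved":
output index i along an axis sits at physical coordinate i * target_spacing,
and the output length is round(extent / target_spacing) + 1 where
extent = (n_in - 1) * spacing_in.  In-plane axes are then symmetrically
center-cropped or zero-padded to the requested plane size.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import nibabel as nib

from .errors import ValidationError

__all__ = ["VolumeGrid", "read_volume", "write_volume", "resample_volume"]


@dataclass
class VolumeGrid:
    """A 3D scalar image with physical voxel spacing.

    data : (slices, rows, cols) array of intensities
    spacing : (slice-gap, row, col) voxel size in mm, all > 0
    origin_note : free-text provenance tag
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin_note: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(
                f"volume must be 3D with each axis >= 1, got shape {self.data.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self):
        return self.data.shape

    def extent_mm(self):
        """Physical span (mm) between first and last voxel centers, per axis."""
        return tuple((n - 1) * s for n, s in zip(self.data.shape, self.spacing))


def _check_finite(data: np.ndarray, where: str):
    if not np.isfinite(data).all():
        raise ValidationError(f"non-finite intensities in {where}; refusing to load")


def read_volume(path, format: str = "nifti") -> VolumeGrid:
    """Read a NIfTI file or a DICOM series directory into a VolumeGrid.

    Intensities are passed through unmodified; spacing comes from the
    header.  Volumes containing NaN/Inf are rejected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "nifti":
        img = nib.load(path)
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 3:
            raise ValidationError(f"{path}: expected a 3D NIfTI, got shape {arr.shape}")
        # nibabel axis order is (cols, rows, slices); ours is the reverse.
        data = np.ascontiguousarray(arr.T)
        zooms = img.header.get_zooms()[:3]
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        _check_finite(data, path)
        return VolumeGrid(data, spacing, origin_note=f"nifti:{path}")
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValidationError(f"unknown format {format!r}")


def _read_dicom_series(directory: str) -> VolumeGrid:
    import pydicom

    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".")
    )
    if not files:
        raise ValidationError(f"no files in DICOM directory {directory}")
    slices = []
    for f in files:
        ds = pydicom.dcmread(f)
        z = float(ds.ImagePositionPatient[2]) if "ImagePositionPatient" in ds else float(
            getattr(ds, "SliceLocation", len(slices))
        )
        slices.append((z, f, ds))
    slices.sort(key=lambda t: t[0])
    zs = np.array([z for z, _, _ in slices])
    if len(zs) < 2:
        gap = float(getattr(slices[0][2], "SliceThickness", 1.0))
    else:
        gaps = np.diff(zs)
        gap = float(np.median(gaps))
        bad = np.nonzero(np.abs(gaps - gap) > 1e-3 * max(abs(gap), 1.0))[0]
        if gap <= 0:
            raise ValidationError(f"{directory}: non-increasing slice positions")
        if bad.size:
            offenders = [
                f"{os.path.basename(slices[i][1])} -> {os.path.basename(slices[i + 1][1])}"
                f" (gap {gaps[i]:g} mm, expected {gap:g} mm)"
                for i in bad
            ]
            raise ValidationError(
                f"{directory}: inconsistent DICOM slice spacing: " + "; ".join(offenders)
            )
    first = slices[0][2]
    py, px = (float(v) for v in first.PixelSpacing)
    data = np.stack([ds.pixel_array.astype(np.float64) for _, _, ds in slices])
    _check_finite(data, directory)
    return VolumeGrid(data, (gap, py, px), origin_note=f"dicom:{directory}")


def write_volume(vol: VolumeGrid, path, format: str = "nifti") -> None:
    """Write a VolumeGrid as NIfTI, preserving dtype and spacing."""
    if format != "nifti":
        raise ValidationError(f"write_volume supports nifti only, got {format!r}")
    _check_finite(vol.data, "volume to write")
    affine = np.diag([vol.spacing[2], vol.spacing[1], vol.spacing[0], 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(vol.data.T), affine)
    img.header.set_zooms((vol.spacing[2], vol.spacing[1], vol.spacing[0]))
    nib.save(img, os.fspath(path))


def _axis_length(n_in: int, s_in: float, s_out: float) -> int:
    return max(int(round((n_in - 1) * s_in / s_out)) + 1, 1)


def _interp_along_axis(data: np.ndarray, pos: np.ndarray, axis: int, order: int):
    """Resample one axis at float positions `pos` (input index units).

    order=1 -> linear between neighbouring samples; order=0 -> nearest.
    Positions outside the grid clamp to the edge samples.
    """
    n = data.shape[axis]
    if order == 0:
        idx = np.clip(np.round(pos).astype(int), 0, n - 1)
        return np.take(data, idx, axis=axis)
    lo = np.clip(np.floor(pos).astype(int), 0, n - 1)
    hi = np.clip(lo + 1, 0, n - 1)
    frac = np.clip(pos - lo, 0.0, 1.0)
    shape = [1] * data.ndim
    shape[axis] = len(pos)
    frac = frac.reshape(shape)
    return np.take(data, lo, axis=axis) * (1.0 - frac) + np.take(data, hi, axis=axis) * frac


def _center_crop_pad_plane(data: np.ndarray, plane_size) -> np.ndarray:
    """Symmetric center-crop/zero-pad the last two axes to plane_size."""
    out_r, out_c = plane_size
    n, r, c = data.shape
    out = data
    for axis, target in ((1, out_r), (2, out_c)):
        cur = out.shape[axis]
        if cur > target:
            start = (cur - target) // 2
            sl = [slice(None)] * 3
            sl[axis] = slice(start, start + target)
            out = out[tuple(sl)]
        elif cur < target:
            before = (target - cur) // 2
            after = target - cur - before
            widths = [(0, 0)] * 3
            widths[axis] = (before, after)
            out = np.pad(out, widths)
    return out


def resample_volume(
    vol: VolumeGrid,
    target_spacing=(1.0, 1.0, 1.0),
    plane_size=(512, 512),
    interp: str = "linear",
) -> VolumeGrid:
    """Interpolate a volume onto a new grid and standardize the plane size.

    interp="linear" (images) or "nearest" (labels/masks).  With linear
    interpolation any intensity field affine in physical coordinates is
    reproduced exactly at interior points.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValidationError(f"target spacing must be positive, got {target_spacing}")
    if interp not in ("linear", "nearest"):
        raise ValidationError(f"interp must be 'linear' or 'nearest', got {interp!r}")
    order = 1 if interp == "linear" else 0

    out_shape = tuple(
        _axis_length(n, s_in, s_out)
        for n, s_in, s_out in zip(vol.shape, vol.spacing, target_spacing)
    )
    # Output index i sits at physical i*s_out -> input index i*s_out/s_in.
    # The grid is axis-aligned, so (tri)linear interpolation is separable:
    # one 1D interpolation per axis keeps peak memory at ~one volume copy.
    data = vol.data.astype(np.float64)
    for axis in range(3):
        pos = np.arange(out_shape[axis]) * (target_spacing[axis] / vol.spacing[axis])
        data = _interp_along_axis(data, pos, axis, order)
    data = _center_crop_pad_plane(data, plane_size)
    return VolumeGrid(
        data,
        target_spacing,
        origin_note=f"resampled({interp}) from {vol.origin_note or 'memory'}",
    )
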