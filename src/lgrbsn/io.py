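"""File formats: NIfTI images and fields, plain-text affines, landmark tables.

Conventions
-----------
* NIfTI-1 (.nii / .nii.gz) for scalar images, label images, and displacement
  fields.  A field is stored as a vector-valued volume with the component
  axis last (2D fields are stored as X x Y x 1 x 2 volumes); units are mm
  and the axis order/displacement convention is recorded in the header
  ``descrip`` field.
* Affine transforms are plain-text homogeneous matrices (3x3 for 2D, 4x4
  for 3D), row-major, world/mm convention: ``y = H[:d,:d] x + H[:d,d]``.
* Landmark sets are whitespace-delimited text or CSV, one point per row,
  with a ``dim=<d>`` header line; NPZ bundles hold full correspondences.
"""

from __future__ import annotations

import numpy as np

from .affine import AffineTransform
from .fields import DisplacementField, Grid, LabelImage
from .shooting import LandmarkCorrespondence

__all__ = [
    "save_label_image",
    "load_label_image",
    "save_scalar_image",
    "load_scalar_image",
    "save_displacement_field",
    "load_displacement_field",
    "save_affine_text",
    "load_affine_text",
    "save_landmarks_text",
    "load_landmarks_text",
    "save_correspondence_npz",
    "load_correspondence_npz",
]


def _nifti_affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    for a in range(grid.ndim):
        aff[a, a] = grid.spacing[a]
        aff[a, 3] = grid.origin[a]
    return aff


def _grid_from_nifti(img, ndim: int) -> Grid:
    aff = img.affine
    spacing = tuple(float(abs(aff[a, a])) or 1.0 for a in range(ndim))
    origin = tuple(float(aff[a, 3]) for a in range(ndim))
    shape = tuple(int(s) for s in img.shape[:ndim])
    return Grid(shape, spacing, origin)


def save_label_image(path, image: LabelImage):
    import nibabel as nib

    data = image.labels.astype(np.int32)
    if image.grid.ndim == 2:
        data = data[..., None]
    img = nib.Nifti1Image(data, _nifti_affine(image.grid))
    img.header["descrip"] = b"lgrbsn label image; 0=background"
    nib.save(img, str(path))


def load_label_image(path, ndim: int | None = None) -> LabelImage:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if ndim is None:
        ndim = 2 if (data.ndim == 3 and data.shape[2] == 1) or data.ndim == 2 else 3
    data = data.reshape(data.shape[:ndim])
    return LabelImage(_grid_from_nifti(img, ndim), np.round(data).astype(np.int32))


def save_scalar_image(path, grid: Grid, data: np.ndarray):
    import nibabel as nib

    arr = np.asarray(data, dtype=np.float32)
    if grid.ndim == 2:
        arr = arr[..., None]
    nib.save(nib.Nifti1Image(arr, _nifti_affine(grid)), str(path))


def load_scalar_image(path, ndim: int | None = None):
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if ndim is None:
        ndim = 2 if (data.ndim == 3 and data.shape[2] == 1) or data.ndim == 2 else 3
    return _grid_from_nifti(img, ndim), data.reshape(data.shape[:ndim])


def save_displacement_field(path, field: DisplacementField):
    import nibabel as nib

    vals = field.values.astype(np.float32)
    if field.grid.ndim == 2:
        vals = vals[:, :, None, :]  # X x Y x 1 x 2
    img = nib.Nifti1Image(vals, _nifti_affine(field.grid))
    img.header["descrip"] = (
        f"lgrbsn displacement mm; domain={field.domain}; dir={field.direction}".encode()[:79]
    )
    nib.save(img, str(path))


def load_displacement_field(
    path, domain: str = "subject", direction: str = "forward"
) -> DisplacementField:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    ncomp = data.shape[-1]
    if data.ndim == 4 and data.shape[2] == 1 and ncomp == 2:
        data = data[:, :, 0, :]
    grid = _grid_from_nifti(img, data.ndim - 1)
    desc = bytes(img.header["descrip"].tobytes()).decode(errors="ignore")
    if "domain=" in desc:
        domain = desc.split("domain=")[1].split(";")[0].strip("\x00 ")
    if "dir=" in desc:
        direction = desc.split("dir=")[1].split(";")[0].strip("\x00 ")
    return DisplacementField(grid, data, domain=domain, direction=direction)


def save_affine_text(path, A: AffineTransform):
    H = A.homogeneous()
    header = f"lgrbsn affine, homogeneous {H.shape[0]}x{H.shape[1]}, world/mm, row-major"
    np.savetxt(str(path), H, header=header)


def load_affine_text(path) -> AffineTransform:
    H = np.loadtxt(str(path))
    return AffineTransform.from_homogeneous(H)


def save_landmarks_text(path, points: np.ndarray):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    np.savetxt(str(path), pts, header=f"dim={pts.shape[1]}")


def load_landmarks_text(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(str(path)))


def save_correspondence_npz(path, corr: LandmarkCorrespondence):
    cov = corr.covariance
    np.savez(
        path,
        moving=corr.moving,
        fixed=corr.fixed,
        covariance=np.asarray(cov),
    )


def load_correspondence_npz(path) -> LandmarkCorrespondence:
    with np.load(path) as z:
        cov = z["covariance"]
        cov = float(cov) if cov.ndim == 0 else cov
        return LandmarkCorrespondence(z["moving"], z["fixed"], cov)
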