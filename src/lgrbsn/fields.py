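"""Grids, displacement fields, warping, Jacobian analysis, and overlap metrics.

All spatial quantities live on regular voxel grids with voxel-centered,
0-based indexing: the physical coordinate of index ``i`` along an axis is
``origin + i * spacing``.  Displacements are stored in physical units (mm)
so fields transfer across resolutions.

A displacement field ``u`` induces the deformation map ``U(x) = x + u(x)``.
Fields are tagged with the *domain* they are defined on (``subject`` or
``template``) and a *direction* (``forward``: subject-to-template;
``reverse``: template-to-subject).  To render a moving image on a fixed
grid, the supplied field must map fixed-domain coordinates into
moving-domain coordinates (i.e. the reverse field for subject-to-template
normalization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "Grid",
    "DisplacementField",
    "DeformationMap",
    "LabelImage",
    "compose_field_with_map",
    "jacobian_determinant",
    "count_nonpositive_jacobian",
    "warp_image",
    "dice",
]


@dataclass(frozen=True)
class Grid:
    """A regular voxel grid in 2 or 3 dimensions.

    Parameters
    ----------
    shape : tuple of int
        Voxel extents per axis; every extent must be >= 2.
    spacing : tuple of float, optional
        Physical length (mm) per voxel along each axis.  Default 1.0.
    origin : tuple of float, optional
        Physical coordinate (mm) of voxel index 0.  Default 0.0.
    """

    shape: tuple
    spacing: tuple = None
    origin: tuple = None

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        ndim = len(shape)
        if ndim not in (2, 3):
            raise ValueError(f"Grid must be 2D or 3D, got {ndim} axes")
        if any(s < 2 for s in shape):
            raise ValueError(f"all grid extents must be >= 2, got {shape}")
        spacing = self.spacing
        spacing = (1.0,) * ndim if spacing is None else tuple(float(s) for s in spacing)
        origin = self.origin
        origin = (0.0,) * ndim if origin is None else tuple(float(o) for o in origin)
        if len(spacing) != ndim or len(origin) != ndim:
            raise ValueError("spacing/origin dimensionality must equal number of axes")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def coordinates(self) -> np.ndarray:
        """Physical coordinates of all voxel centers, shape ``(*shape, ndim)``."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(self.ndim)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack(mesh, axis=-1)

    def index_coords(self, physical: np.ndarray) -> np.ndarray:
        """Convert physical coordinates (..., ndim) to fractional voxel indices."""
        physical = np.asarray(physical, dtype=float)
        return (physical - np.asarray(self.origin)) / np.asarray(self.spacing)

    def physical_coords(self, index: np.ndarray) -> np.ndarray:
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)


@dataclass
class DisplacementField:
    """A vector field ``u(x)`` on a grid, one displacement vector (mm) per voxel.

    ``values`` has shape ``(*grid.shape, grid.ndim)``.
    """

    grid: Grid
    values: np.ndarray
    domain: str = "subject"
    direction: str = "forward"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = self.grid.shape + (self.grid.ndim,)
        if self.values.shape != expected:
            raise ValueError(
                f"field values shape {self.values.shape} does not match grid "
                f"{self.grid.shape} with {self.grid.ndim} components"
            )
        if self.domain not in ("subject", "template"):
            raise ValueError(f"domain must be subject|template, got {self.domain!r}")
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"direction must be forward|reverse, got {self.direction!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("displacement field contains non-finite components")

    @classmethod
    def zeros(cls, grid: Grid, domain: str = "subject", direction: str = "forward"):
        return cls(grid, np.zeros(grid.shape + (grid.ndim,)), domain, direction)

    def as_map(self) -> "DeformationMap":
        return DeformationMap(self)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.values, axis=-1)


@dataclass
class DeformationMap:
    """The map ``U(x) = x + u(x)`` induced by a displacement field, realized lazily."""

    field: DisplacementField

    @property
    def grid(self) -> Grid:
        return self.field.grid

    def point_values(self) -> np.ndarray:
        """``U`` evaluated at every grid point: ``x + u(x)``, shape (*shape, ndim)."""
        return self.grid.coordinates() + self.field.values

    @classmethod
    def identity(cls, grid: Grid, domain: str = "subject", direction: str = "forward"):
        return cls(DisplacementField.zeros(grid, domain, direction))


@dataclass
class LabelImage:
    """Non-negative integer labels on a grid; 0 is background."""

    grid: Grid
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError(
                f"label array shape {self.labels.shape} != grid shape {self.grid.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.any(self.labels != np.round(self.labels)):
                raise ValueError("labels must be integers")
            self.labels = self.labels.astype(np.int32)
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    def label_set(self):
        """Sorted non-background labels present in the image."""
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v != 0]

    def mask(self, label=None) -> np.ndarray:
        """Binary mask of one label, or of all non-background voxels."""
        if label is None:
            return self.labels > 0
        return self.labels == label


def _check_same_axes(grid_a: Grid, grid_b: Grid):
    if grid_a.ndim != grid_b.ndim or grid_a.spacing != grid_b.spacing:
        raise ValueError(
            f"grids are incompatible: {grid_a.ndim}D spacing {grid_a.spacing} vs "
            f"{grid_b.ndim}D spacing {grid_b.spacing}"
        )


def sample_field(u: DisplacementField, physical_points: np.ndarray) -> np.ndarray:
    """Sample each component of ``u`` at arbitrary physical positions.

    Multilinear interpolation; positions outside the grid use the
    boundary-clamped value (``mode='nearest'``), which keeps downstream
    residuals finite.
    """
    pts = np.asarray(physical_points, dtype=float)
    idx = u.grid.index_coords(pts)  # (..., ndim)
    coords = np.moveaxis(idx, -1, 0)
    out = np.empty(pts.shape, dtype=float)
    for c in range(u.grid.ndim):
        out[..., c] = ndimage.map_coordinates(
            u.values[..., c], coords, order=1, mode="nearest"
        )
    return out


def compose_field_with_map(u: DisplacementField, U: DeformationMap) -> DisplacementField:
    """Sample the field ``u`` at warped positions: ``result(x) = u(U(x))``.

    This is the "compose" operator in the residual construction
    ``r = u_ab + u_ba o U_ab``.  The result lives on ``U``'s grid and keeps
    ``u``'s direction tag with ``U``'s domain tag.
    """
    if u.grid.ndim != U.grid.ndim:
        raise ValueError(
            f"dimensionality mismatch: field grid {u.grid.shape} vs map grid {U.grid.shape}"
        )
    _check_same_axes(u.grid, U.grid)
    warped_pos = U.point_values()
    vals = sample_field(u, warped_pos)
    return DisplacementField(U.grid, vals, domain=U.field.domain, direction=u.direction)


def jacobian_determinant(U: DeformationMap) -> np.ndarray:
    """Per-voxel determinant of the deformation-map Jacobian dU/dx.

    Spacing-aware derivatives: central differences in the interior,
    one-sided on boundary faces.  A positive determinant means the local
    deformation is invertible and preserves topology.
    """
    grid = U.grid
    vals = U.point_values()
    ndim = grid.ndim
    J = np.empty(grid.shape + (ndim, ndim), dtype=float)
    for i in range(ndim):
        grads = np.gradient(vals[..., i], *grid.spacing, edge_order=1)
        if ndim == 1:
            grads = [grads]
        for j in range(ndim):
            J[..., i, j] = grads[j]
    return np.linalg.det(J)


def count_nonpositive_jacobian(U: DeformationMap, mask: LabelImage | None = None) -> int:
    """Count voxels where the Jacobian determinant of ``U`` is <= 0."""
    det = jacobian_determinant(U)
    if mask is not None:
        if mask.grid.shape != U.grid.shape:
            raise ValueError(
                f"mask grid {mask.grid.shape} does not match map grid {U.grid.shape}"
            )
        return int(np.count_nonzero((det <= 0) & mask.mask()))
    return int(np.count_nonzero(det <= 0))


def warp_image(image, u_fixed_to_moving: DisplacementField, order: str = "linear"):
    """Resample an image on the fixed grid: ``out(x) = in(x + u(x))``.

    ``u_fixed_to_moving`` must map fixed-domain coordinates into the moving
    image's domain.  Label images must use ``order='nearest'``.
    Out-of-bounds samples become 0 / background.
    """
    u = u_fixed_to_moving
    if isinstance(image, LabelImage):
        if order != "nearest":
            raise ValueError("label images must be warped with order='nearest'")
        data = image.labels
        in_grid = image.grid
    else:
        data = np.asarray(image)
        in_grid = u.grid  # scalar images are assumed on a compatible grid
        if data.shape != u.grid.shape:
            raise ValueError(f"image shape {data.shape} != field grid {u.grid.shape}")
    if in_grid.ndim != u.grid.ndim:
        raise ValueError("image/field dimensionality mismatch")
    positions = u.grid.coordinates() + u.values
    idx = in_grid.index_coords(positions)
    coords = np.moveaxis(idx, -1, 0)
    spline_order = 0 if order == "nearest" else 1
    if order not in ("nearest", "linear"):
        raise ValueError(f"order must be nearest|linear, got {order!r}")
    out = ndimage.map_coordinates(
        data.astype(float), coords, order=spline_order, mode="constant", cval=0.0
    )
    if isinstance(image, LabelImage):
        return LabelImage(u.grid, np.round(out).astype(image.labels.dtype))
    return out


def dice(a, b) -> float:
    """Dice similarity coefficient 2|A^B| / (|A|+|B|) between binary masks.

    Accepts LabelImage (non-background mask) or boolean arrays.  Defined as
    1.0 when both masks are empty.
    """
    if isinstance(a, LabelImage) and isinstance(b, LabelImage):
        if a.grid.shape != b.grid.shape:
            raise ValueError(f"grid mismatch: {a.grid.shape} vs {b.grid.shape}")
        ma, mb = a.mask(), b.mask()
    else:
        ma = a.mask() if isinstance(a, LabelImage) else np.asarray(a, dtype=bool)
        mb = b.mask() if isinstance(b, LabelImage) else np.asarray(b, dtype=bool)
        if ma.shape != mb.shape:
            raise ValueError(f"mask shape mismatch: {ma.shape} vs {mb.shape}")
    total = int(ma.sum()) + int(mb.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / total
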