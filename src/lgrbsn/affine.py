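"""Initial linear alignments and concatenation into per-region warps.

The pipeline applies a single global affine ``A`` (estimated by least squares
over all matched landmarks) followed by a per-region translation ``A'_i``
(region-mask centroid shift) before the nonlinear regional registration.
The final regional warp is the concatenation

    T_i(x)      = D_i(A'_i(A(x)))            (forward, on the subject grid)
    T_i^{-1}(x) = A^{-1}(A'_i^{-1}(D_i^{-1}(x)))  (reverse, on the template grid)

expressed as displacement fields relative to each grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import DisplacementField, Grid, LabelImage, sample_field, warp_image

__all__ = [
    "AffineTransform",
    "RegionalWarp",
    "fit_affine_landmarks",
    "fit_translation",
    "apply_affine",
    "concatenate_regional",
]


@dataclass
class AffineTransform:
    """x -> M x + t in physical (mm) coordinates."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        d = self.translation.shape[0]
        if self.matrix.shape != (d, d):
            raise ValueError(
                f"matrix {self.matrix.shape} incompatible with translation dim {d}"
            )
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("affine matrix is singular")

    @property
    def ndim(self) -> int:
        return self.translation.shape[0]

    @classmethod
    def identity(cls, ndim: int) -> "AffineTransform":
        return cls(np.eye(ndim), np.zeros(ndim))

    @classmethod
    def from_translation(cls, t) -> "AffineTransform":
        t = np.asarray(t, dtype=float)
        return cls(np.eye(t.shape[0]), t)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        M_inv = np.linalg.inv(self.matrix)
        return AffineTransform(M_inv, -M_inv @ self.translation)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return AffineTransform(
            self.matrix @ other.matrix, self.matrix @ other.translation + self.translation
        )

    def homogeneous(self) -> np.ndarray:
        d = self.ndim
        H = np.eye(d + 1)
        H[:d, :d] = self.matrix
        H[:d, d] = self.translation
        return H

    @classmethod
    def from_homogeneous(cls, H) -> "AffineTransform":
        H = np.asarray(H, dtype=float)
        d = H.shape[0] - 1
        return cls(H[:d, :d], H[:d, d])


@dataclass
class RegionalWarp:
    """Per-region concatenated warp: forward on the subject grid, reverse on the template grid."""

    region_id: int
    forward: DisplacementField
    reverse: DisplacementField

    def __post_init__(self):
        if self.forward.domain != "subject" or self.forward.direction != "forward":
            raise ValueError("forward field must be subject-domain, forward-direction")
        if self.reverse.domain != "template" or self.reverse.direction != "reverse":
            raise ValueError("reverse field must be template-domain, reverse-direction")


def fit_affine_landmarks(moving, fixed) -> AffineTransform:
    """Least-squares affine mapping moving points onto fixed points.

    Minimizes sum ||M x_n + t - y_n||^2; recovers the transform exactly when
    ``fixed`` is an affine image of ``moving`` and the system has full rank.
    """
    x = np.atleast_2d(np.asarray(moving, dtype=float))
    y = np.atleast_2d(np.asarray(fixed, dtype=float))
    if x.shape != y.shape:
        raise ValueError("moving and fixed point sets must have equal shapes")
    n, d = x.shape
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} point pairs for a {d}D affine fit")
    X = np.hstack([x, np.ones((n, 1))])
    if np.linalg.matrix_rank(X) < d + 1:
        raise ValueError(
            "degenerate landmark configuration (points are affinely dependent); "
            "cannot fit an affine transform"
        )
    sol, *_ = np.linalg.lstsq(X, y, rcond=None)
    return AffineTransform(sol[:d].T, sol[d])


def _centroid(obj) -> np.ndarray:
    if isinstance(obj, LabelImage):
        mask = obj.mask()
        if not mask.any():
            raise ValueError("empty mask has no centroid")
        idx = np.argwhere(mask).astype(float)
        return obj.grid.physical_coords(idx).mean(axis=0)
    pts = np.atleast_2d(np.asarray(obj, dtype=float))
    if pts.size == 0:
        raise ValueError("empty point set has no centroid")
    return pts.mean(axis=0)


def fit_translation(moving, fixed) -> AffineTransform:
    """Translation-only alignment: centroid(fixed) - centroid(moving).

    Accepts point sets or (binary) LabelImages.  Translation-only regional
    alignment avoids over-fitting before the nonlinear registration.
    """
    return AffineTransform.from_translation(_centroid(fixed) - _centroid(moving))


def apply_affine(obj, A: AffineTransform):
    """Map points exactly, or resample an image through the induced fixed-to-moving field.

    For an image on grid G the output voxel x takes the value of the input at
    A^{-1}(x) (so the image content moves with A).
    """
    if isinstance(obj, LabelImage):
        grid = obj.grid
        coords = grid.coordinates()
        inv = A.inverse()
        u_vals = inv(coords.reshape(-1, grid.ndim)).reshape(coords.shape) - coords
        u = DisplacementField(grid, u_vals, domain="template", direction="reverse")
        return warp_image(obj, u, order="nearest")
    return A(obj)


def concatenate_regional(
    A: AffineTransform,
    A_i: AffineTransform,
    D_i_fwd: DisplacementField,
    D_i_rev: DisplacementField,
    grid_subject: Grid | None = None,
    grid_template: Grid | None = None,
    region_id: int = 0,
) -> RegionalWarp:
    """Concatenate A, A'_i and the nonlinear fields into one regional warp.

    The nonlinear fields live on the initially aligned frame; the returned
    forward displacement is expressed on the subject grid and the reverse on
    the template grid.
    """
    if D_i_fwd.grid.ndim != D_i_rev.grid.ndim or A.ndim != D_i_fwd.grid.ndim:
        raise ValueError("dimensionality mismatch between affines and fields")
    grid_s = grid_subject if grid_subject is not None else D_i_fwd.grid
    grid_t = grid_template if grid_template is not None else D_i_rev.grid

    # forward: x -> y = A'_i(A(x)) -> y + D_i(y)
    xs = grid_s.coordinates().reshape(-1, grid_s.ndim)
    y = A_i(A(xs))
    fwd_vals = (y + sample_field(D_i_fwd, y) - xs).reshape(grid_s.shape + (grid_s.ndim,))
    forward = DisplacementField(grid_s, fwd_vals, domain="subject", direction="forward")

    # reverse: x -> z = x + D_i^{-1}(x) -> A^{-1}(A'_i^{-1}(z))
    xt = grid_t.coordinates().reshape(-1, grid_t.ndim)
    z = xt + sample_field(D_i_rev, xt)
    A_inv = A.inverse()
    Ai_inv = A_i.inverse()
    rev_vals = (A_inv(Ai_inv(z)) - xt).reshape(grid_t.shape + (grid_t.ndim,))
    reverse = DisplacementField(grid_t, rev_vals, domain="template", direction="reverse")

    return RegionalWarp(region_id=region_id, forward=forward, reverse=reverse)
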