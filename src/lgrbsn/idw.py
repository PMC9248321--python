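"""Inverse-distance-weighted composition of regional warps into one global field.

Adjacent regional fields are blended over morphologically defined transition
areas.  Each region mask R_i is shrunk to a core

    R_i* = R_i - (R_i (+) SE  ^  U_{j != i} R_j (+) SE)

where ``(+)`` is binary dilation with a discrete ball structuring element
(default radius 2 voxels).  Inside its own core a region's warp applies
exactly; elsewhere (other cores excluded) the fields are mixed with Shepard
weights q_i(x) = 1 / d_i(x)^mu, where d_i is the Euclidean distance (mm) to
R_i*.  With mu > 1 the blended field has a continuous first derivative; the
default is mu = 4.  Background voxels receive the same "otherwise" formula,
so the global field covers the full grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .affine import RegionalWarp
from .fields import DisplacementField, LabelImage

__all__ = [
    "RegionPartition",
    "IDWConfig",
    "ball_structuring_element",
    "compute_cores",
    "idw_weights",
    "compose_global",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IDWConfig:
    """Shepard exponent mu (> 1 for C1 continuity) and distance floor epsilon (mm)."""

    mu: float = 4.0
    epsilon: float = 1e-9

    def __post_init__(self):
        if not (self.mu > 1):
            raise ValueError(f"mu must be > 1 for first-derivative continuity, got {self.mu}")
        if not (self.epsilon > 0):
            raise ValueError("epsilon must be > 0")


@dataclass
class RegionPartition:
    """Region masks, eroded cores R_i*, and distance maps d_i(x) driving the weights."""

    labels: LabelImage
    region_ids: list
    cores: np.ndarray  # (m, *shape) bool
    distance_maps: np.ndarray  # (m, *shape) float, mm
    structuring_radius: int = 2

    def __post_init__(self):
        m = len(self.region_ids)
        if self.cores.shape[0] != m or self.distance_maps.shape[0] != m:
            raise ValueError("cores/distance_maps first axis must equal region count")
        for k, rid in enumerate(self.region_ids):
            inside = self.labels.mask(rid)
            if np.any(self.cores[k] & ~inside):
                raise ValueError(f"core of region {rid} is not a subset of its mask")
        overlap = self.cores.sum(axis=0)
        if overlap.max(initial=0) > 1:
            raise ValueError("cores must be pairwise disjoint")
        if not np.all(np.isfinite(self.distance_maps)):
            raise ValueError("distance maps must be finite")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


def ball_structuring_element(radius: int, ndim: int) -> np.ndarray:
    """Discrete ball of the given voxel radius (Euclidean ball, inclusive)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    grids = np.indices((2 * radius + 1,) * ndim) - radius
    return (grids**2).sum(axis=0) <= radius**2


def compute_cores(labels: LabelImage, radius: int = 2) -> RegionPartition:
    """Erode each region to its core by the dilation-intersection formula.

    If the formula empties a small region, that region's undilated mask is
    used as its core with a logged warning.
    """
    region_ids = labels.label_set()
    if not region_ids:
        raise ValueError("label image contains no regions")
    ndim = labels.grid.ndim
    se = ball_structuring_element(radius, ndim)
    masks = np.stack([labels.mask(r) for r in region_ids])
    if radius > 0:
        dilated = np.stack([ndimage.binary_dilation(m, structure=se) for m in masks])
    else:
        dilated = masks.copy()

    m = len(region_ids)
    cores = np.empty_like(masks)
    for i in range(m):
        others = np.zeros(labels.grid.shape, dtype=bool)
        for j in range(m):
            if j != i:
                others |= dilated[j]
        transition = dilated[i] & others
        core = masks[i] & ~transition
        if not core.any():
            logger.warning(
                "region %s has an empty core at SE radius %d; falling back to its "
                "undilated mask", region_ids[i], radius,
            )
            core = masks[i]
        cores[i] = core

    spacing = labels.grid.spacing
    dist = np.stack(
        [ndimage.distance_transform_edt(~c, sampling=spacing) for c in cores]
    )
    return RegionPartition(
        labels=labels,
        region_ids=region_ids,
        cores=cores,
        distance_maps=dist,
        structuring_radius=radius,
    )


def idw_weights(partition: RegionPartition, cfg: IDWConfig = IDWConfig()) -> np.ndarray:
    """Per-region weight images: 1 on the own core, 0 on other cores, Shepard otherwise.

    The weights form a partition of unity (sum 1 at every voxel).
    Returns an array of shape (m, *grid.shape).
    """
    m = partition.n_regions
    d = np.maximum(partition.distance_maps, cfg.epsilon)
    q = d ** (-cfg.mu)
    w = q / q.sum(axis=0)
    any_core = partition.cores.any(axis=0)
    for i in range(m):
        w[i][any_core] = 0.0
        w[i][partition.cores[i]] = 1.0
    return w


def compose_global(
    warps: list, weights: np.ndarray, direction: str = "forward"
) -> DisplacementField:
    """Voxelwise convex combination of regional displacement fields.

    ``warps`` is a list of RegionalWarp (or bare DisplacementField) whose
    fields for the chosen direction share one grid; ``weights`` comes from
    the matching domain's partition.  Inside R_i* the result equals T_i
    exactly.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError(f"direction must be forward|reverse, got {direction!r}")
    fields = [
        (w.forward if direction == "forward" else w.reverse)
        if isinstance(w, RegionalWarp) else w
        for w in warps
    ]
    if len(fields) == 0:
        raise ValueError("need at least one regional warp")
    if weights.shape[0] != len(fields):
        raise ValueError(
            f"weight/warp count mismatch: {weights.shape[0]} weights, {len(fields)} warps"
        )
    grid = fields[0].grid
    for f in fields[1:]:
        if f.grid.shape != grid.shape or f.grid.spacing != grid.spacing:
            raise ValueError("all regional fields must share one grid for composition")
    vals = np.zeros(grid.shape + (grid.ndim,))
    for wi, f in zip(weights, fields):
        vals += wi[..., None] * f.values
    domain = "subject" if direction == "forward" else "template"
    return DisplacementField(grid, vals, domain=domain, direction=direction)
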