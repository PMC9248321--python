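"""Regional pseudo-landmark extraction and matching on labeled cortical meshes.

Dense vertices of the white-matter and pial triangular meshes serve as
pseudo-landmarks, grouped by a per-vertex region label (a cortical
parcellation).  Large regions are thinned by farthest-point downsampling and
snapped back to original vertices, and subject/template correspondence is
established through a precomputed sphere-to-sphere registration: each
template vertex, projected onto the subject's registration sphere, is
matched to the nearest same-label subject vertex (chord distance on the
unit sphere, which is order-equivalent to great-circle distance; ties break
to the lowest vertex id).

The spherical registration itself is consumed, not computed, so the module
is fully testable with synthetic labeled spheres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .shooting import LandmarkCorrespondence

__all__ = [
    "LabeledSurfaceMesh",
    "RegionalLandmarks",
    "extract_region_landmarks",
    "downsample_snap",
    "match_via_sphere",
    "load_mesh_bundle",
    "save_mesh_bundle",
    "load_ply_mesh",
    "load_freesurfer_mesh",
]


@dataclass
class LabeledSurfaceMesh:
    """Triangular mesh with per-vertex region labels and optional sphere coordinates."""

    vertices: np.ndarray  # (V, 3) mm
    faces: np.ndarray  # (F, 3) vertex indices
    labels: np.ndarray  # (V,) region id per vertex, 0 = unlabeled
    sphere: np.ndarray | None = None  # (V, 3) unit-norm registration-sphere coords

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        V = self.vertices.shape[0]
        if self.labels.shape != (V,):
            raise ValueError("need one label per vertex")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= V):
            raise ValueError("face indices out of range")
        if self.sphere is not None:
            self.sphere = np.asarray(self.sphere, dtype=float)
            if self.sphere.shape != (V, 3):
                raise ValueError("sphere coordinates must be (V, 3)")
            norms = np.linalg.norm(self.sphere, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError("sphere coordinates must have unit norm (within 1e-6)")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def region_ids(self):
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v != 0]


@dataclass
class RegionalLandmarks:
    """A region's landmark subset; points always coincide with parent vertices."""

    region_id: int
    points: np.ndarray
    vertex_ids: np.ndarray
    source: str = "pial"  # wm | pial

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=np.int64)
        if len(np.unique(self.vertex_ids)) != len(self.vertex_ids):
            raise ValueError("vertex ids must be unique")
        if self.points.shape[0] != self.vertex_ids.shape[0]:
            raise ValueError("points/vertex_ids length mismatch")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def extract_region_landmarks(
    mesh: LabeledSurfaceMesh, region_id: int, source: str = "pial"
) -> RegionalLandmarks:
    """All and only vertices carrying the region label, in ascending vertex id."""
    ids = np.flatnonzero(mesh.labels == region_id)
    if ids.size == 0:
        raise ValueError(f"region {region_id} is absent from the mesh labels")
    return RegionalLandmarks(
        region_id=int(region_id),
        points=mesh.vertices[ids],
        vertex_ids=ids,
        source=source,
    )


def _farthest_point_order(coords: np.ndarray, k: int) -> np.ndarray:
    """Indices of k points chosen by greedy farthest-point sampling."""
    n = coords.shape[0]
    chosen = np.empty(k, dtype=np.int64)
    chosen[0] = 0
    dist = np.linalg.norm(coords - coords[0], axis=1)
    for i in range(1, k):
        nxt = int(np.argmax(dist))
        chosen[i] = nxt
        dist = np.minimum(dist, np.linalg.norm(coords - coords[nxt], axis=1))
    return chosen


def downsample_snap(
    landmarks: RegionalLandmarks,
    rate: float,
    mesh: LabeledSurfaceMesh | None = None,
) -> RegionalLandmarks:
    """Thin to ceil(rate * N) landmarks by farthest-point sampling, snapped back.

    Sampling runs on the registration-sphere coordinates when the parent mesh
    provides them (uniform angular coverage), falling back to 3D Euclidean
    positions.  Selected points are snapped to the nearest original vertices,
    so the result's vertex ids are always a subset of the input's.
    """
    if not (0 < rate <= 1):
        raise ValueError(f"rate must be in (0, 1], got {rate}")
    n = landmarks.n_points
    k = int(np.ceil(rate * n))
    if k >= n:
        return RegionalLandmarks(
            landmarks.region_id,
            landmarks.points.copy(),
            landmarks.vertex_ids.copy(),
            landmarks.source,
        )
    if mesh is not None and mesh.sphere is not None:
        coords = mesh.sphere[landmarks.vertex_ids]
    else:
        coords = landmarks.points
    sel = _farthest_point_order(coords, k)
    # snap back: nearest original vertex of the same landmark set (the
    # sampled point already is one, so this is exact by construction)
    sel = np.sort(sel)
    return RegionalLandmarks(
        landmarks.region_id,
        landmarks.points[sel],
        landmarks.vertex_ids[sel],
        landmarks.source,
    )


def match_via_sphere(
    subject: LabeledSurfaceMesh,
    template_landmarks: RegionalLandmarks,
    template_sphere_in_subject_frame: np.ndarray,
    template_points: np.ndarray | None = None,
    covariance: float = 0.25,
) -> LandmarkCorrespondence:
    """Match template landmarks to subject vertices through the sphere.

    ``template_sphere_in_subject_frame`` holds the template landmarks'
    registration-sphere coordinates after projection into the subject's
    spherical space (the spherical registration is an input, not computed
    here).  Each projected vertex is matched to the nearest subject vertex of
    the same region label; ties break to the lowest vertex id.  Returns pairs
    (subject 3D vertex as moving, template 3D vertex as fixed).
    """
    if subject.sphere is None:
        raise ValueError("subject mesh has no sphere coordinates")
    proj = np.asarray(template_sphere_in_subject_frame, dtype=float)
    if proj.shape != (template_landmarks.n_points, 3):
        raise ValueError("projected sphere coordinates must be (N, 3)")
    cand = np.flatnonzero(subject.labels == template_landmarks.region_id)
    if cand.size == 0:
        raise ValueError(
            f"subject mesh has no vertices labeled {template_landmarks.region_id}"
        )
    tree = cKDTree(subject.sphere[cand])
    dist, nearest = tree.query(proj)
    # lowest-vertex-id tie-break: query all equally-near candidates
    matched = cand[nearest]
    for i in range(len(proj)):
        ties = tree.query_ball_point(proj[i], dist[i] + 1e-12)
        if len(ties) > 1:
            matched[i] = cand[min(ties)]
    fixed_pts = (
        template_points
        if template_points is not None
        else template_landmarks.points
    )
    return LandmarkCorrespondence(
        moving=subject.vertices[matched],
        fixed=np.asarray(fixed_pts, dtype=float),
        covariance=covariance,
    )


# ---------------------------------------------------------------------------
# I/O adapters.  The canonical interchange format is a plain NPZ bundle so the
# module is testable with synthetic spheres; ASCII PLY (+ label CSV) and
# FreeSurfer binary surfaces are optional adapters.
# ---------------------------------------------------------------------------


def save_mesh_bundle(path, mesh: LabeledSurfaceMesh):
    data = {"vertices": mesh.vertices, "faces": mesh.faces, "labels": mesh.labels}
    if mesh.sphere is not None:
        data["sphere"] = mesh.sphere
    np.savez(path, **data)


def load_mesh_bundle(path) -> LabeledSurfaceMesh:
    with np.load(path) as z:
        return LabeledSurfaceMesh(
            vertices=z["vertices"],
            faces=z["faces"],
            labels=z["labels"],
            sphere=z["sphere"] if "sphere" in z.files else None,
        )


def load_ply_mesh(ply_path, labels_csv=None, sphere_ply=None) -> LabeledSurfaceMesh:
    """ASCII PLY mesh + one-label-per-row CSV + optional sphere PLY (same vertex order)."""
    import trimesh

    m = trimesh.load(ply_path, process=False)
    labels = (
        np.loadtxt(labels_csv, dtype=np.int64, ndmin=1)
        if labels_csv is not None
        else np.zeros(len(m.vertices), dtype=np.int64)
    )
    sphere = None
    if sphere_ply is not None:
        s = trimesh.load(sphere_ply, process=False)
        sphere = np.asarray(s.vertices, dtype=float)
        sphere /= np.linalg.norm(sphere, axis=1, keepdims=True)
    return LabeledSurfaceMesh(
        vertices=np.asarray(m.vertices, dtype=float),
        faces=np.asarray(m.faces, dtype=np.int64),
        labels=labels,
        sphere=sphere,
    )


def load_freesurfer_mesh(surf_path, annot_path=None, sphere_path=None) -> LabeledSurfaceMesh:
    """FreeSurfer binary surface (+ .annot labels, + sphere.reg) adapter."""
    from nibabel.freesurfer import io as fsio

    verts, faces = fsio.read_geometry(surf_path)
    labels = np.zeros(len(verts), dtype=np.int64)
    if annot_path is not None:
        annot_labels, _, _ = fsio.read_annot(annot_path)
        labels = np.asarray(annot_labels, dtype=np.int64)
        labels[labels < 0] = 0
    sphere = None
    if sphere_path is not None:
        sverts, _ = fsio.read_geometry(sphere_path)
        sphere = np.asarray(sverts, dtype=float)
        sphere /= np.linalg.norm(sphere, axis=1, keepdims=True)
    return LabeledSurfaceMesh(
        vertices=np.asarray(verts, dtype=float),
        faces=np.asarray(faces, dtype=np.int64),
        labels=labels,
        sphere=sphere,
    )
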