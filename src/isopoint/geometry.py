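"""Anatomical coordinate frames and femoral surface geometry.

This module builds the femur-centred local coordinate system from the
condylar landmarks, reconstructs a triangulated femoral surface from a
point cloud via an alpha-complex over the 3-D Delaunay tetrahedralization,
and answers closest-point queries against that surface.

Conventions
-----------
All coordinates are millimetres.  The local frame has its origin at the
midpoint of the medial (MFC) and lateral (LFC) femoral condyles, with

* ``+X`` medial-lateral (positive towards the medial condyle),
* ``+Y`` anterior-posterior,
* ``+Z`` proximal-distal (positive towards the femoral shaft axis point).

Left knees are mirrored into this right-knee convention so that cohorts
mixing both sides share one coordinate distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree


class DegenerateFrameError(ValueError):
    """Landmarks do not span a valid anatomical frame."""


class SurfaceConstructionError(ValueError):
    """Point cloud cannot be triangulated into a surface."""


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite coordinates: {a}")
    return a


@dataclass(frozen=True)
class LandmarkSet:
    """Condylar landmarks plus the radiographic Schottle point.

    ``mfc``/``lfc`` are the medial/lateral femoral condyle points, ``ra``
    a point on the reconstructed femoral shaft axis, ``s_point`` the
    conventional femoral attachment landmark.  ``side`` is ``"left"`` or
    ``"right"``.
    """

    mfc: np.ndarray
    lfc: np.ndarray
    ra: np.ndarray
    s_point: np.ndarray
    side: str = "right"

    def __post_init__(self):
        for name in ("mfc", "lfc", "ra", "s_point"):
            object.__setattr__(self, name, _as_point(getattr(self, name)))
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if np.allclose(self.mfc, self.lfc):
            raise DegenerateFrameError("MFC and LFC coincide")


@dataclass(frozen=True)
class FemoralFrame:
    """Rigid map between scanner and local anatomical coordinates.

    ``rotation`` has the local axis directions as rows, so
    ``to_local(p) = rotation @ (p - origin)``.  The matrix is orthonormal
    with determinant +1.
    """

    origin: np.ndarray
    rotation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_point(self.origin))
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise DegenerateFrameError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise DegenerateFrameError("rotation is not proper (det != +1)")
        object.__setattr__(self, "rotation", R)

    def to_local(self, p) -> np.ndarray:
        """Express scanner-space point(s) in the anatomical frame."""
        p = np.asarray(p, dtype=float)
        return (p - self.origin) @ self.rotation.T

    def from_local(self, p) -> np.ndarray:
        """Express local-frame point(s) in scanner space."""
        p = np.asarray(p, dtype=float)
        return p @ self.rotation + self.origin


def build_femoral_frame(landmarks: LandmarkSet) -> FemoralFrame:
    """Construct the femur-centred anatomical frame from landmarks.

    The origin is the MFC/LFC midpoint.  X runs from LFC to MFC (flipped
    for left knees so +X is always medial), Z is the component of the
    shaft-axis point offset orthogonal to X (proximal), and Y = Z x X
    completes a right-handed triad.

    Raises
    ------
    DegenerateFrameError
        If MFC = LFC or the axis point is collinear with the condylar axis.
    """
    o = 0.5 * (landmarks.mfc + landmarks.lfc)
    x = landmarks.mfc - landmarks.lfc
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise DegenerateFrameError("MFC and LFC coincide")
    x = x / nx
    if landmarks.side == "left":
        x = -x
    za = landmarks.ra - o
    z = za - np.dot(za, x) * x
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise DegenerateFrameError("axis point collinear with condylar axis")
    z = z / nz
    y = np.cross(z, x)
    return FemoralFrame(origin=o, rotation=np.vstack([x, y, z]))


# ---------------------------------------------------------------------------
# Surface model


@dataclass
class SurfaceModel:
    """Triangulated femoral surface with cached spatial indices.

    ``vertices`` is (V, 3) float mm, ``triangles`` (T, 3) int.  Provenance
    records whether the mesh was supplied directly or derived from a point
    cloud by alpha-complex reconstruction.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    provenance: str = "mesh-input"
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if len(self.triangles) == 0:
            raise SurfaceConstructionError("surface has no triangles")
        if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
            raise SurfaceConstructionError("triangle indices out of range")

    # -- derived quantities, computed lazily and cached -------------------
    def _tri_data(self):
        if "tri" not in self._cache:
            v = self.vertices
            t = self.triangles
            a = v[t[:, 0]]
            ab = v[t[:, 1]] - a
            ac = v[t[:, 2]] - a
            centroid = a + (ab + ac) / 3.0
            # circumscribed reach of each triangle from its centroid
            r = np.maximum(
                np.linalg.norm(a - centroid, axis=1),
                np.maximum(
                    np.linalg.norm(a + ab - centroid, axis=1),
                    np.linalg.norm(a + ac - centroid, axis=1),
                ),
            )
            self._cache["tri"] = (a, ab, ac, centroid, r)
            self._cache["centroid_tree"] = cKDTree(centroid)
            self._cache["vertex_tree"] = cKDTree(v)
            self._cache["rmax"] = float(r.max())
        return self._cache["tri"]

    @property
    def vertex_tree(self) -> cKDTree:
        self._tri_data()
        return self._cache["vertex_tree"]

    def area(self) -> float:
        a, ab, ac, _, _ = self._tri_data()
        return float(0.5 * np.linalg.norm(np.cross(ab, ac), axis=1).sum())

    def transformed(self, frame: FemoralFrame) -> "SurfaceModel":
        """Surface re-expressed in the local frame (rigid, shape-preserving)."""
        return SurfaceModel(
            vertices=frame.to_local(self.vertices),
            triangles=self.triangles.copy(),
            provenance=self.provenance,
        )


def _closest_on_triangles(p: np.ndarray, a, ab, ac):
    """Closest point to ``p`` on each triangle (a, a+ab, a+ac), vectorized.

    Standard region-based point/triangle projection; returns an (n, 3)
    array of closest points.
    """
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = ap - ab
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = ap - ac
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex A
    out[m] = a[m]
    done |= m

    m = ~done & (d3 >= 0) & (d4 <= d3)  # vertex B
    out[m] = a[m] + ab[m]
    done |= m

    m = ~done & (d6 >= 0) & (d5 <= d6)  # vertex C
    out[m] = a[m] + ac[m]
    done |= m

    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge AB
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d1 / (d1 - d3)
    out[m] = a[m] + t[m, None] * ab[m]
    done |= m

    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge AC
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d2 / (d2 - d6)
    out[m] = a[m] + t[m, None] * ac[m]
    done |= m

    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge BC
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    out[m] = a[m] + ab[m] + t[m, None] * (ac[m] - ab[m])
    done |= m

    m = ~done  # interior
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = vb / denom
        w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def project_to_surface(surface: SurfaceModel, p) -> tuple[np.ndarray, float, int]:
    """Closest point on the surface to ``p``.

    Returns ``(closest, distance, triangle_id)``.  Candidate triangles are
    pruned with a KD-tree on triangle centroids: the distance to the
    nearest vertex is an upper bound, so only triangles whose centroid ball
    can beat it need exact evaluation.
    """
    p = _as_point(p)
    a, ab, ac, centroid, r = surface._tri_data()
    ub, _ = surface._cache["vertex_tree"].query(p)
    idx = surface._cache["centroid_tree"].query_ball_point(
        p, ub + surface._cache["rmax"] + 1e-9
    )
    idx = np.asarray(idx, dtype=np.int64)
    if len(idx) == 0:  # degenerate fallback: scan everything
        idx = np.arange(len(a))
    pts = _closest_on_triangles(p, a[idx], ab[idx], ac[idx])
    d = np.linalg.norm(pts - p, axis=1)
    k = int(np.argmin(d))
    return pts[k], float(d[k]), int(idx[k])


def surface_distance(surface: SurfaceModel, p) -> float:
    """Unsigned distance from ``p`` to the surface."""
    return project_to_surface(surface, p)[1]


def _tet_circumradius(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = points[tets[:, 0]]
    rows = np.stack([points[tets[:, k]] - a for k in (1, 2, 3)], axis=1)  # (n,3,3)
    rhs = 0.5 * np.einsum("nij,nij->ni", rows, rows)
    det = np.linalg.det(rows)
    ok = np.abs(det) > 1e-12
    radius = np.full(len(tets), np.inf)
    if ok.any():
        centers = np.linalg.solve(rows[ok], rhs[ok][..., None])[..., 0]
        radius[ok] = np.linalg.norm(centers, axis=1)
    return radius


def _tri_circumcenters(points: np.ndarray, tris: np.ndarray):
    """Circumcenter and circumradius of each triangle in 3-D."""
    a = points[tris[:, 0]]
    ab = points[tris[:, 1]] - a
    ac = points[tris[:, 2]] - a
    n = np.cross(ab, ac)
    n2 = np.einsum("ij,ij->i", n, n)
    ab2 = np.einsum("ij,ij->i", ab, ab)
    ac2 = np.einsum("ij,ij->i", ac, ac)
    # c = a + (|ac|^2 (n x ab) + |ab|^2 (ac x n)) / (2 n.n)
    with np.errstate(invalid="ignore", divide="ignore"):
        offset = (
            ac2[:, None] * np.cross(n, ab) + ab2[:, None] * np.cross(ac, n)
        ) / (2.0 * n2[:, None])
    centers = a + offset
    radius = np.linalg.norm(centers - a, axis=1)
    radius[n2 < 1e-20] = np.inf
    return centers, radius


DEGENERATE_AREA = 1e-6  # mm^2; smaller triangles are dropped


def _clean_triangles(vertices: np.ndarray, triangles: np.ndarray):
    """Drop degenerate triangles and unreferenced vertices, reindexing."""
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    area = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    triangles = triangles[area >= DEGENERATE_AREA]
    if len(triangles) == 0:
        raise SurfaceConstructionError("all triangles degenerate")
    used = np.unique(triangles)
    remap = np.full(len(vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return vertices[used], remap[triangles]


def default_alpha(points: np.ndarray) -> float:
    """Scale-free alpha: twice the median nearest-neighbour spacing."""
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return 2.0 * float(np.median(d[:, 1]))


def build_surface(points, alpha: float | None = None) -> SurfaceModel:
    """Reconstruct a triangulated surface from a point cloud.

    The 3-D Delaunay tetrahedralization is filtered by the alpha criterion
    (tetrahedra with circumradius <= alpha are kept); the surface consists
    of the boundary faces of the kept complex plus Delaunay faces outside
    it whose own circumradius is <= alpha.  The latter recovers thin-shell
    clouds (points sampled on a surface rather than a solid), whose
    tetrahedra all have large circumradii.

    Parameters
    ----------
    points : (n, 3) array
        Point cloud in mm; needs >= 4 non-coplanar points.
    alpha : float, optional
        Length scale in mm; defaults to twice the median nearest-neighbour
        spacing.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 4:
        raise SurfaceConstructionError("need at least 4 points")
    if alpha is None:
        alpha = default_alpha(points)
    try:
        dt = Delaunay(points)
    except Exception as exc:  # qhull raises its own error type
        raise SurfaceConstructionError(f"Delaunay failed: {exc}") from exc
    if dt.simplices.shape[1] != 4:
        raise SurfaceConstructionError("points are coplanar")
    # qhull may succeed on near-coplanar input; check true extent
    spread = np.linalg.svd(points - points.mean(axis=0), compute_uv=False)
    if spread[2] < 1e-9 * max(1.0, spread[0]):
        raise SurfaceConstructionError("points are coplanar")

    tets = dt.simplices
    keep = _tet_circumradius(points, tets) <= alpha

    face_ids = ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))
    all_faces = np.concatenate([tets[:, f] for f in face_ids])
    owner_kept = np.concatenate([keep] * 4)
    key = np.sort(all_faces, axis=1)
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    kept_count = np.bincount(inverse, weights=owner_kept.astype(float), minlength=len(uniq))

    boundary = kept_count == 1  # between kept complex and outside
    # faces outside the kept complex join the alpha complex only if they
    # are Gabriel (their diametral ball is empty of other points) and
    # small enough; this recovers thin-shell clouds without admitting
    # spurious chord faces through the interior
    candidate = (kept_count == 0) & ~boundary
    free = np.zeros(len(uniq), dtype=bool)
    if candidate.any():
        cand = uniq[candidate]
        centers, radius = _tri_circumcenters(points, cand)
        small = radius <= alpha
        gabriel = np.zeros(len(cand), dtype=bool)
        if small.any():
            tree = cKDTree(points)
            d4, i4 = tree.query(centers[small], k=4)
            own = cand[small]
            inside = d4 < radius[small][:, None] * (1.0 - 1e-9)
            foreign = (
                (i4[:, :, None] != own[:, None, :]).all(axis=2)
                if i4.ndim == 2
                else np.ones_like(d4, dtype=bool)
            )
            gabriel[small] = ~(inside & foreign).any(axis=1)
        free[candidate] = small & gabriel
    faces = uniq[boundary | free]
    if len(faces) == 0:
        raise SurfaceConstructionError(
            "alpha criterion removed every face; increase alpha"
        )
    vertices, triangles = _clean_triangles(points, faces)
    return SurfaceModel(vertices=vertices, triangles=triangles, provenance="delaunay-derived")


def surface_from_mesh(vertices, triangles) -> SurfaceModel:
    """Wrap an existing triangle mesh, removing degenerate triangles."""
    vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
    triangles = np.asarray(triangles, dtype=np.int64).reshape(-1, 3)
    v, t = _clean_triangles(vertices, triangles)
    return SurfaceModel(vertices=v, triangles=t, provenance="mesh-input")


# ---------------------------------------------------------------------------
# Per-frame containers


@dataclass
class FrameData:
    """One motion frame: femoral surface plus the patellar point cloud."""

    frame_index: int
    femur: SurfaceModel
    patella_points: np.ndarray
    flexion_angle: float | None = None

    def __post_init__(self):
        self.patella_points = np.asarray(self.patella_points, dtype=float).reshape(-1, 3)
        if len(self.patella_points) == 0:
            raise ValueError("patella point cloud is empty")


@dataclass
class KneeSequence:
    """Ordered motion frames for one knee, all in one scanner space (mm)."""

    subject_id: str
    side: str
    frames: list[FrameData]

    def __post_init__(self):
        if len(self.frames) < 3:
            raise ValueError("a knee sequence needs at least 3 frames")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def flexion_angles(self) -> np.ndarray | None:
        angles = [f.flexion_angle for f in self.frames]
        if any(a is None for a in angles):
            return None
        return np.asarray(angles, dtype=float)
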