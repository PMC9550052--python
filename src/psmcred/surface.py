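"""Region surfaces and Euclidean point-to-surface distances.

Tissue-region surfaces (scar boundary, BZ-healthy interface, ...) are
triangulated by the faces of the tetrahedral mesh, and distances to them are
exact Euclidean point-to-triangle distances.  These distances define "within
d of scar"-style constructions consistently across the package.
"""

from __future__ import annotations

import numpy as np

from .mesh import LabeledMesh


def _element_faces(elements: np.ndarray) -> np.ndarray:
    """All four faces of every tet, (4M, 3), vertex-sorted."""
    f = elements[:, [0, 1, 2, 0, 1, 3, 0, 2, 3, 1, 2, 3]].reshape(-1, 3)
    return np.sort(f, axis=1)


def region_boundary_faces(mesh: LabeledMesh, element_mask: np.ndarray) -> np.ndarray:
    """Triangles bounding the region formed by the masked elements.

    A face belongs to the boundary when exactly one element of the region
    owns it — this includes faces the region exposes on the domain boundary.
    Returns an (F, 3) array of node triples (empty when the region is empty).
    """
    sel = np.flatnonzero(element_mask)
    if sel.size == 0:
        return np.empty((0, 3), dtype=np.int64)
    faces = _element_faces(mesh.elements[sel])
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    return uniq[counts == 1]


def interface_faces(mesh: LabeledMesh, mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Triangles shared by one element of region A and one of region B."""
    faces = _element_faces(mesh.elements)
    owner = np.repeat(np.arange(mesh.n_elements), 4)
    order = np.lexsort(faces.T)
    faces = faces[order]
    owner = owner[order]
    same = np.all(faces[1:] == faces[:-1], axis=1)
    i = np.flatnonzero(same)  # face i and i+1 identical -> shared by two elements
    a, b = owner[i], owner[i + 1]
    hit = (mask_a[a] & mask_b[b]) | (mask_b[a] & mask_a[b])
    return faces[i[hit]]


def point_triangle_distances(points: np.ndarray, triangles: np.ndarray,
                             chunk: int = 2_000_000, k: int = 32) -> np.ndarray:
    """Minimum Euclidean distance from each point to a triangle set (exact).

    ``points`` is (N, 3); ``triangles`` is (F, 3, 3) vertex coordinates.
    The per-pair distance is the plane distance when the orthogonal
    projection falls inside the triangle, otherwise the nearest of the three
    edge-segment distances.  For large triangle sets a KD-tree over
    triangle centroids prefilters the ``k`` nearest candidates per point;
    points whose candidate bound cannot certify exactness fall back to the
    brute-force scan, so the result is always the exact minimum.
    """
    from scipy.spatial import cKDTree

    points = np.atleast_2d(np.asarray(points, dtype=float))
    f = triangles.shape[0]
    if f == 0:
        return np.full(points.shape[0], np.inf)
    if f <= 2 * k:
        return _brute(points, triangles, chunk)

    tri_c = triangles.mean(axis=1)
    r_max = float(np.linalg.norm(triangles - tri_c[:, None, :], axis=2).max())
    tree = cKDTree(tri_c)
    d_c, idx = tree.query(points, k=k)
    d_exact = _ptd_compute(points[:, None, :], triangles[idx])
    u = d_exact.min(axis=1)
    # a triangle outside the candidate set has centroid distance >= d_c[:, -1],
    # hence surface distance >= d_c[:, -1] - r_max; if u beats that bound the
    # candidate minimum is certified exact
    unsafe = u > d_c[:, -1] - r_max
    if unsafe.any():
        u[unsafe] = _brute(points[unsafe], triangles, chunk)
    return u


def _brute(points: np.ndarray, triangles: np.ndarray, chunk: int) -> np.ndarray:
    n = points.shape[0]
    f = triangles.shape[0]
    out = np.full(n, np.inf)
    rows = max(1, chunk // max(f, 1))
    for s in range(0, n, rows):
        p = points[s:s + rows]
        out[s:s + rows] = _ptd_compute(p[:, None, :], triangles[None, :, :, :]).min(axis=1)
    return out


def _ptd_compute(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distances for broadcastable ``p`` (..., 1, 3) vs ``tri`` (..., K, 3, 3)."""
    a = tri[..., 0, :]
    b = tri[..., 1, :]
    c = tri[..., 2, :]

    ab = b - a
    ac = c - a
    ap = p - a

    # barycentric coordinates of the projection onto the triangle plane
    d00 = np.einsum("...k,...k->...", ab, ab)
    d01 = np.einsum("...k,...k->...", ab, ac)
    d11 = np.einsum("...k,...k->...", ac, ac)
    d20 = np.einsum("...k,...k->...", ap, ab)
    d21 = np.einsum("...k,...k->...", ap, ac)
    denom = d00 * d11 - d01 * d01
    denom = np.where(denom <= 0, np.finfo(float).tiny, denom)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    inside = (v >= 0) & (w >= 0) & (v + w <= 1)

    proj = a + v[..., None] * ab + w[..., None] * ac
    d_plane = np.linalg.norm(p - proj, axis=-1)

    d_edges = np.minimum(
        _seg_dist(p, a, b),
        np.minimum(_seg_dist(p, a, c), _seg_dist(p, b, c)),
    )
    return np.where(inside, d_plane, d_edges)


def _seg_dist(p, a, b):
    ab = b - a
    t = np.einsum("...k,...k->...", p - a, ab) / np.maximum(
        np.einsum("...k,...k->...", ab, ab), np.finfo(float).tiny
    )
    t = np.clip(t, 0.0, 1.0)
    q = a + t[..., None] * ab
    return np.linalg.norm(p - q, axis=-1)


def distance_to_region_surface(mesh: LabeledMesh, points: np.ndarray,
                               element_mask: np.ndarray) -> np.ndarray:
    """Distance from points to the boundary surface of a labeled region.

    Returns +inf for every point when the region is empty.
    """
    faces = region_boundary_faces(mesh, element_mask)
    if faces.shape[0] == 0:
        return np.full(np.atleast_2d(points).shape[0], np.inf)
    return point_triangle_distances(points, mesh.nodes[faces])


def distance_to_scar_surface(mesh: LabeledMesh, points: np.ndarray) -> np.ndarray:
    """Euclidean distance from points to the triangulated scar surface."""
    from .mesh import SCAR

    return distance_to_region_surface(mesh, points, mesh.tissue_class == SCAR)


def points_within_surface_distance(mesh: LabeledMesh, points: np.ndarray,
                                   element_mask: np.ndarray, radius: float) -> np.ndarray:
    """Boolean mask: is each point within ``radius`` of the region surface?

    Equivalent to ``distance_to_region_surface(...) <= radius`` but cheaper:
    the nearest surface-vertex distance d_v brackets the exact distance in
    [d_v - e_max, d_v] (e_max the longest face edge), so only points in
    that uncertainty band need exact point-to-triangle distances.
    """
    from scipy.spatial import cKDTree

    points = np.atleast_2d(np.asarray(points, dtype=float))
    faces = region_boundary_faces(mesh, element_mask)
    if faces.shape[0] == 0:
        return np.zeros(points.shape[0], dtype=bool)
    tri = mesh.nodes[faces]
    verts = mesh.nodes[np.unique(faces)]
    d_v = cKDTree(verts).query(points)[0]
    e_max = float(np.linalg.norm(tri - tri[:, [1, 2, 0], :], axis=2).max())
    within = d_v <= radius  # exact distance is <= nearest-vertex distance
    band = ~within & (d_v <= radius + e_max)
    if band.any():
        within[band] = point_triangle_distances(points[band], tri) <= radius
    return within
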