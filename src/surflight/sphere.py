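"""Geodesic sphere templates by icosahedron subdivision.

The spherical registration space used throughout is a triangulated unit
sphere obtained by dividing every edge of a regular icosahedron into
``n_div`` equal parts, triangulating each face, and projecting all points
radially to the sphere.  ``n_div`` edge divisions give ``10 * n_div**2 + 2``
vertices; 128 divisions reproduce the 163,842-vertex resolution of the
standard high-resolution template, 40 divisions the 16,002-vertex
downsampled template.

Vertex ordering is deterministic: the 12 icosahedron vertices first, then
edge points grouped by (sorted) edge, then face-interior points grouped by
face.  Shared points on edges are indexed combinatorially rather than by
floating-point merging, so two builds are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class TriMesh:
    """Closed triangulated mesh on the unit sphere.

    Attributes
    ----------
    vertices : (V, 3) float array of unit vectors.
    faces : (F, 3) int array of vertex-index triples.
    """

    vertices: np.ndarray
    faces: np.ndarray

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (E, 2) sorted-index array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces


@dataclass
class GeodesicSphere:
    """A subdivided icosahedral sphere: the mesh plus its division order."""

    mesh: TriMesh
    n_div: int

    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices

    @property
    def n_vertices(self) -> int:
        return self.mesh.n_vertices


@dataclass
class VertexMapping:
    """Partition of high-resolution vertices among downsampled vertices.

    ``assignment[i]`` is the downsampled vertex owning high-res vertex
    ``i``; ``groups[j]`` lists the high-res vertices owned by ``j``.
    """

    assignment: np.ndarray
    groups: list = field(repr=False, default=None)

    def __post_init__(self):
        if self.groups is None:
            n_low = int(self.assignment.max()) + 1 if len(self.assignment) else 0
            groups = [[] for _ in range(n_low)]
            for hi, lo in enumerate(self.assignment):
                groups[lo].append(hi)
            self.groups = [np.asarray(g, dtype=np.int64) for g in groups]


# ---------------------------------------------------------------------------
# construction

def base_icosahedron() -> TriMesh:
    """The regular icosahedron with vertices on the unit sphere."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=np.float64)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    return TriMesh(verts, faces)


def subdivide(base: TriMesh, n_div: int) -> GeodesicSphere:
    """Divide every edge of ``base`` into ``n_div`` parts and project to the sphere.

    Each face is triangulated into ``n_div**2`` sub-faces; points shared by
    neighbouring faces (edge and corner points) are indexed once.  All new
    vertices are normalised onto the unit sphere.

    Parameters
    ----------
    base : TriMesh
        A closed triangulated mesh (normally the icosahedron).
    n_div : int
        Number of equal parts per edge; 1 returns the base mesh unchanged.
    """
    if n_div < 1:
        raise ValueError(f"n_div must be a positive integer, got {n_div}")
    n = int(n_div)
    V0 = base.n_vertices
    edges = base.edges
    edge_index = {(int(a), int(b)): k for k, (a, b) in enumerate(edges)}

    # vertex blocks: base | per-edge interior points | per-face interior points
    n_edge_pts = n - 1
    n_face_pts = (n - 1) * (n - 2) // 2
    verts = [base.vertices]

    # interior edge points, ordered along the sorted edge (a -> b)
    if n_edge_pts:
        t = np.arange(1, n)[:, None] / n
        for a, b in edges:
            pts = (1 - t) * base.vertices[a] + t * base.vertices[b]
            verts.append(pts)

    def edge_point(a: int, b: int, k: int) -> int:
        """Global index of the k-th interior point from a to b (1 <= k <= n-1)."""
        if a < b:
            e = edge_index[(a, b)]
            return V0 + e * n_edge_pts + (k - 1)
        e = edge_index[(b, a)]
        return V0 + e * n_edge_pts + (n - k - 1)

    face_base = V0 + len(edges) * n_edge_pts
    faces_out = []
    for fi, (a, b, c) in enumerate(base.faces):
        a, b, c = int(a), int(b), int(c)
        A, B, C = base.vertices[a], base.vertices[b], base.vertices[c]
        # lattice point (i, j): barycentric (n-i-j, i, j)/n; i along A->B, j along A->C
        idx = {}
        interior = []
        for i in range(n + 1):
            for j in range(n + 1 - i):
                w = n - i - j
                if (i, j) == (0, 0):
                    g = a
                elif (i, j) == (n, 0):
                    g = b
                elif (i, j) == (0, n):
                    g = c
                elif j == 0:
                    g = edge_point(a, b, i)
                elif i == 0:
                    g = edge_point(a, c, j)
                elif w == 0:
                    g = edge_point(b, c, j)
                else:
                    g = face_base + fi * n_face_pts + len(interior)
                    interior.append((A * w + B * i + C * j) / n)
                idx[(i, j)] = g
        if interior:
            verts.append(np.asarray(interior))
        for i in range(n):
            for j in range(n - i):
                faces_out.append((idx[(i, j)], idx[(i + 1, j)], idx[(i, j + 1)]))
                if i + j < n - 1:
                    faces_out.append((idx[(i + 1, j)], idx[(i + 1, j + 1)],
                                      idx[(i, j + 1)]))

    vertices = np.vstack(verts)
    vertices /= np.linalg.norm(vertices, axis=1, keepdims=True)
    mesh = TriMesh(vertices, np.asarray(faces_out, dtype=np.int64))
    return GeodesicSphere(mesh, n)


# ---------------------------------------------------------------------------
# coordinates and rotation

def cart_to_sph(v) -> tuple:
    """Cartesian unit vector -> (alpha, beta) = (longitude, latitude) in radians.

    Convention: the origin point z(0, 0) is the Cartesian (1, 0, 0);
    alpha = atan2(y, x), beta = asin(z).
    """
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v, axis=-1)
    if np.any(n < 1e-12):
        raise ValueError("zero vector has no spherical coordinates")
    v = v / n[..., None] if v.ndim > 1 else v / n
    x, y, z = v[..., 0], v[..., 1], v[..., 2]
    alpha = np.arctan2(y, x)
    beta = np.arcsin(np.clip(z, -1.0, 1.0))
    if v.ndim == 1:
        return float(alpha), float(beta)
    return alpha, beta


def sph_to_cart(alpha, beta) -> np.ndarray:
    """(longitude, latitude) -> Cartesian unit vector; inverse of cart_to_sph."""
    alpha = np.asarray(alpha, dtype=np.float64)
    beta = np.asarray(beta, dtype=np.float64)
    out = np.stack([np.cos(beta) * np.cos(alpha),
                    np.cos(beta) * np.sin(alpha),
                    np.sin(beta)], axis=-1)
    return out


def rotation_to_origin(alpha: float, beta: float) -> np.ndarray:
    """Rotation matrix taking the point p(alpha, beta) to z(0, 0) = (1, 0, 0).

    R = Ry(beta) @ Rz(-alpha): first undo the longitude about the z axis,
    then the latitude about the y axis.  Zero roll about the final axis, so
    the induced searchlight grid orientation is reproducible.
    """
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    rz = np.array([[ca, sa, 0.0], [-sa, ca, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[cb, 0.0, sb], [0.0, 1.0, 0.0], [-sb, 0.0, cb]])
    return ry @ rz


# ---------------------------------------------------------------------------
# template downsampling

def nearest_assignment(high: GeodesicSphere, low: GeodesicSphere) -> VertexMapping:
    """Assign each high-res vertex to its nearest downsampled vertex.

    Distance is Euclidean chord distance, equivalent on the unit sphere to
    angular distance.  Exact ties go to the lowest downsampled index.
    """
    tree = cKDTree(low.vertices)
    dist, idx = tree.query(high.vertices, k=2)
    # tie-break: when the two nearest are equidistant, keep the lower index
    tie = np.isclose(dist[:, 0], dist[:, 1], rtol=0.0, atol=1e-12)
    assignment = idx[:, 0].copy()
    assignment[tie] = np.minimum(idx[tie, 0], idx[tie, 1])
    groups = [[] for _ in range(low.n_vertices)]
    for hi, lo in enumerate(assignment):
        groups[lo].append(hi)
    return VertexMapping(assignment.astype(np.int64),
                         [np.asarray(g, dtype=np.int64) for g in groups])


def build_adjacency(sphere: GeodesicSphere) -> list:
    """Per-vertex neighbour lists from mesh edges (symmetric, no self-loops)."""
    neighbors = [set() for _ in range(sphere.n_vertices)]
    for a, b in sphere.mesh.edges:
        neighbors[a].add(int(b))
        neighbors[b].add(int(a))
    return [np.asarray(sorted(s), dtype=np.int64) for s in neighbors]


# ---------------------------------------------------------------------------
# external surface files

def read_sphere_surface(path) -> TriMesh:
    """Read a spherical surface (GIFTI .surf.gii or FreeSurfer geometry).

    Coordinates are normalised to the unit sphere; the file's vertex order
    is preserved.
    """
    import nibabel as nib
    p = str(path)
    if p.endswith(".gii"):
        img = nib.load(p)
        coords = img.darrays[0].data.astype(np.float64)
        faces = img.darrays[1].data.astype(np.int64)
    else:
        coords, faces = nib.freesurfer.read_geometry(p)
        coords = coords.astype(np.float64)
        faces = faces.astype(np.int64)
    coords /= np.linalg.norm(coords, axis=1, keepdims=True)
    return TriMesh(coords, faces)


def write_sphere_surface(mesh: TriMesh, path, radius: float = 100.0) -> None:
    """Export a mesh as a GIFTI surface file (scaled by ``radius``)."""
    import nibabel as nib
    coords = (mesh.vertices * radius).astype(np.float32)
    g = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(coords, intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(mesh.faces.astype(np.int32),
                                 intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(g, str(path))
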