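"""Grid searchlight layouts on the sphere.

For every vertex p(alpha, beta) of the downsampled template, the sphere is
rotated so that p lands on the origin z(0, 0); an n1 x n1 grid of square
angular cells (cell_size radians per side) is laid out around the origin,
and every high-resolution vertex falling in a cell is recorded.  A circular
mask of radius n1/2 cells trims the grid to a disk; per-trial BOLD values
are averaged within each cell to form a small image, the classifier input.

A layout record holds the vertex's spherical coordinate, the n1**2
cell-membership lists, the list of high-res vertices the vertex owns in the
downsampling, and its mesh neighbours: n1**2 + 3 fields per record (124 for
the default 11-cell grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .sphere import GeodesicSphere, VertexMapping, cart_to_sph, rotation_to_origin

LAYOUT_FORMAT_VERSION = 1


class LayoutFormatError(ValueError):
    """A layout file is corrupt or has an unsupported version."""


@dataclass(frozen=True)
class GridSpec:
    """Searchlight grid geometry: angular cell size and cells per side.

    Defaults are 1/35 radians per cell and 11 cells per side, giving a
    searchlight disk of radius 100 * (1/35) * (11/2) ~ 15.7 on a
    100-unit-radius registration sphere.
    """

    cell_size: float = 1.0 / 35.0
    n1: int = 11

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n1 < 1 or self.n1 % 2 == 0:
            raise ValueError(f"grid size n1 must be odd and >= 1, got {self.n1}")

    @property
    def stem(self) -> str:
        """File-name stem encoding the grid, e.g. '35_11'."""
        return f"{round(1.0 / self.cell_size)}_{self.n1}"


def searchlight_radius(spec: GridSpec, sphere_radius: float = 100.0) -> float:
    """Physical searchlight radius: sphere_radius * cell_size * n1 / 2."""
    return sphere_radius * spec.cell_size * (spec.n1 / 2.0)


def circular_mask(n1: int) -> np.ndarray:
    """Boolean n1 x n1 grid keeping cells whose centre lies within n1/2 cells.

    Distances are measured in cell units from the grid centre; cells on the
    boundary (distance exactly n1/2) are kept.
    """
    if n1 < 1 or n1 % 2 == 0:
        raise ValueError(f"grid size n1 must be odd and >= 1, got {n1}")
    c = (n1 - 1) / 2.0
    i, j = np.mgrid[0:n1, 0:n1]
    return (i - c) ** 2 + (j - c) ** 2 <= (n1 / 2.0) ** 2


@dataclass
class SearchlightLayout:
    """Per-downsampled-vertex searchlight records for one template pair.

    Attributes
    ----------
    coords : (V_low, 2) array of (alpha, beta) per record.
    cell_members : list over records of lists (length n1**2, row-major
        (i, j) -> i * n1 + j) of high-res vertex index arrays.
    own_members : high-res vertices grouped to each record's vertex.
    neighbors : downsampled mesh adjacency per record.
    spec : GridSpec; n_high : high-res vertex count.
    """

    coords: np.ndarray
    cell_members: list
    own_members: list
    neighbors: list
    spec: GridSpec
    n_high: int
    _operators: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_records(self) -> int:
        return len(self.coords)

    @property
    def n_fields(self) -> int:
        """Fields per record: coordinate + n1**2 cells + own members + adjacency."""
        return self.spec.n1 ** 2 + 3

    def cell_operator(self, vertex: int, mask: np.ndarray = None) -> sparse.csr_matrix:
        """Sparse (n1**2, V_high) cell-averaging operator for one record.

        Row k averages the member vertices of cell k; empty or masked-out
        cells are all-zero rows.  Cached per (vertex, mask id).
        """
        key = (vertex, None if mask is None else mask.tobytes())
        op = self._operators.get(key)
        if op is not None:
            return op
        n1 = self.spec.n1
        keep = np.ones(n1 * n1, bool) if mask is None else mask.ravel()
        rows, cols, vals = [], [], []
        for k, members in enumerate(self.cell_members[vertex]):
            if not keep[k] or len(members) == 0:
                continue
            rows.extend([k] * len(members))
            cols.extend(members)
            vals.extend([1.0 / len(members)] * len(members))
        op = sparse.csr_matrix((vals, (rows, cols)), shape=(n1 * n1, self.n_high))
        self._operators[key] = op
        return op


def build_layout(high: GeodesicSphere, low: GeodesicSphere,
                 mapping: VertexMapping, adjacency: list,
                 spec: GridSpec = GridSpec()) -> SearchlightLayout:
    """Construct the grid-searchlight layout for a template pair.

    For each downsampled vertex p: rotate all high-res vertices by the
    matrix taking p to the origin, convert to (a, b), and bin with
    i = floor(a / cell_size + n1 / 2), j = floor(b / cell_size + n1 / 2),
    keeping vertices with both indices in [0, n1).  Longitude indexes rows,
    latitude columns.
    """
    if len(mapping.assignment) != high.n_vertices:
        raise ValueError(
            f"mapping covers {len(mapping.assignment)} vertices, "
            f"high-res template has {high.n_vertices}")
    if len(adjacency) != low.n_vertices or len(mapping.groups) != low.n_vertices:
        raise ValueError("adjacency/mapping size does not match the low-res template")

    n1, cell = spec.n1, spec.cell_size
    half = n1 / 2.0
    # conservative prefilter: a vertex landing in the grid satisfies
    # cos(d) = cos(a) cos(b) >= cos^2(n1*cell/2), d its angular distance to p
    theta = np.arccos(max(np.cos(n1 * cell / 2.0) ** 2, -1.0)) + 1e-9
    chord = 2.0 * np.sin(min(theta, np.pi) / 2.0)
    tree = cKDTree(high.vertices)

    alpha, beta = cart_to_sph(low.vertices)
    coords = np.stack([alpha, beta], axis=1)
    cell_members = []
    for v in range(low.n_vertices):
        near = np.asarray(tree.query_ball_point(low.vertices[v], chord + 1e-9),
                          dtype=np.int64)
        near.sort()
        R = rotation_to_origin(coords[v, 0], coords[v, 1])
        rot = high.vertices[near] @ R.T
        a = np.arctan2(rot[:, 1], rot[:, 0])
        b = np.arcsin(np.clip(rot[:, 2], -1.0, 1.0))
        i = np.floor(a / cell + half).astype(np.int64)
        j = np.floor(b / cell + half).astype(np.int64)
        ok = (i >= 0) & (i < n1) & (j >= 0) & (j < n1)
        cells = [np.empty(0, dtype=np.int64)] * (n1 * n1)
        flat = i[ok] * n1 + j[ok]
        members = near[ok]
        order = np.argsort(flat, kind="stable")
        flat, members = flat[order], members[order]
        starts = np.searchsorted(flat, np.arange(n1 * n1))
        ends = np.searchsorted(flat, np.arange(n1 * n1), side="right")
        for k in range(n1 * n1):
            if ends[k] > starts[k]:
                cells[k] = members[starts[k]:ends[k]].copy()
        cell_members.append(cells)

    return SearchlightLayout(
        coords=coords,
        cell_members=cell_members,
        own_members=[np.asarray(g, dtype=np.int64) for g in mapping.groups],
        neighbors=[np.asarray(a, dtype=np.int64) for a in adjacency],
        spec=spec,
        n_high=high.n_vertices,
    )


def searchlight_image(patterns: np.ndarray, layout: SearchlightLayout,
                      vertex: int, mask: np.ndarray = None) -> np.ndarray:
    """Average per-trial patterns into an (trials, n1, n1) searchlight image.

    Each kept cell holds the arithmetic mean of its member vertices' values;
    empty and masked-out cells are exactly 0.
    """
    if not 0 <= vertex < layout.n_records:
        raise IndexError(f"vertex {vertex} outside layout ({layout.n_records} records)")
    patterns = np.atleast_2d(np.asarray(patterns, dtype=np.float64))
    if patterns.shape[1] != layout.n_high:
        raise ValueError(
            f"patterns have {patterns.shape[1]} columns, layout expects {layout.n_high}")
    n1 = layout.spec.n1
    op = layout.cell_operator(vertex, mask)
    flat = patterns @ op.T
    return np.asarray(flat).reshape(len(patterns), n1, n1)


def flatten_image(image: np.ndarray) -> np.ndarray:
    """Row-major flattening of (trials, n1, n1) images to (trials, n1**2)."""
    image = np.asarray(image)
    if image.ndim == 2:
        image = image[None]
    return image.reshape(image.shape[0], -1)


# ---------------------------------------------------------------------------
# serialization: ragged index lists stored as data + offsets

def _pack(lists):
    offsets = np.zeros(len(lists) + 1, dtype=np.int64)
    for k, a in enumerate(lists):
        offsets[k + 1] = offsets[k] + len(a)
    data = (np.concatenate(lists) if offsets[-1] else np.empty(0, np.int64))
    return data.astype(np.int64), offsets


def _unpack(data, offsets):
    return [data[offsets[k]:offsets[k + 1]] for k in range(len(offsets) - 1)]


def save_layout(layout: SearchlightLayout, path) -> None:
    """Write a layout to an .npz container (lossless round trip)."""
    flat_cells = [c for rec in layout.cell_members for c in rec]
    cdata, coffs = _pack(flat_cells)
    odata, ooffs = _pack(layout.own_members)
    ndata, noffs = _pack(layout.neighbors)
    np.savez_compressed(
        path,
        format_version=np.int64(LAYOUT_FORMAT_VERSION),
        cell_size=np.float64(layout.spec.cell_size),
        n1=np.int64(layout.spec.n1),
        n_high=np.int64(layout.n_high),
        coords=layout.coords,
        cell_data=cdata, cell_offsets=coffs,
        own_data=odata, own_offsets=ooffs,
        nbr_data=ndata, nbr_offsets=noffs,
    )


def load_layout(path) -> SearchlightLayout:
    """Read a layout written by :func:`save_layout`."""
    try:
        with np.load(path) as z:
            if int(z["format_version"]) != LAYOUT_FORMAT_VERSION:
                raise LayoutFormatError(
                    f"unsupported layout format version {int(z['format_version'])}")
            spec = GridSpec(cell_size=float(z["cell_size"]), n1=int(z["n1"]))
            n1 = spec.n1
            coords = z["coords"]
            flat_cells = _unpack(z["cell_data"], z["cell_offsets"])
            own = _unpack(z["own_data"], z["own_offsets"])
            nbrs = _unpack(z["nbr_data"], z["nbr_offsets"])
            n_rec = len(coords)
            if len(flat_cells) != n_rec * n1 * n1 or len(own) != n_rec or len(nbrs) != n_rec:
                raise LayoutFormatError("layout file is internally inconsistent")
            cells = [flat_cells[r * n1 * n1:(r + 1) * n1 * n1] for r in range(n_rec)]
            return SearchlightLayout(coords=coords, cell_members=cells,
                                     own_members=own, neighbors=nbrs,
                                     spec=spec, n_high=int(z["n_high"]))
    except LayoutFormatError:
        raise
    except Exception as exc:  # truncated/corrupt container
        raise LayoutFormatError(f"cannot read layout file {path}: {exc}") from exc
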