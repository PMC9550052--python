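"""Labeled tetrahedral meshes for infarcted ventricular tissue.

A :class:`LabeledMesh` couples a tetrahedral mesh with a per-element tissue
class (healthy myocardium, infarct border zone, or non-excitable scar) and a
per-element fiber direction.  All lengths are in cm, times in ms, voltages in
mV and conductivities in mS/cm throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Tissue class codes (stored as the "tissue_class" cell-data array in VTU files).
HEALTHY = 0
BZ = 1
SCAR = 2

TISSUE_NAMES = {HEALTHY: "healthy", BZ: "bz", SCAR: "scar"}


@dataclass
class LabeledMesh:
    """Tetrahedral mesh with tissue labels and fiber directions.

    Parameters
    ----------
    nodes : (N, 3) float array
        Node coordinates in cm.
    elements : (M, 4) int array
        Tetrahedra as node-index quadruples.
    tissue_class : (M,) int array
        One of HEALTHY (0), BZ (1), SCAR (2) per element.
    fiber : (M, 3) float array
        Unit fiber direction per element.
    resolution_tag : str
        Human-readable resolution label or nominal edge length.
    patient_id : str
        Identifier of the (synthetic) patient this mesh belongs to.
    """

    nodes: np.ndarray
    elements: np.ndarray
    tissue_class: np.ndarray
    fiber: np.ndarray
    resolution_tag: str = ""
    patient_id: str = ""
    # cached derived geometry
    _volumes: np.ndarray | None = field(default=None, repr=False, compare=False)
    _centroids: np.ndarray | None = field(default=None, repr=False, compare=False)
    _grads: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int32)
        self.tissue_class = np.ascontiguousarray(self.tissue_class, dtype=np.uint8)
        self.fiber = np.ascontiguousarray(self.fiber, dtype=np.float64)

    # -- basic sizes ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    # -- derived geometry ------------------------------------------------
    @property
    def element_volumes(self) -> np.ndarray:
        """Per-element volume in cm^3 (always positive)."""
        if self._volumes is None:
            self._volumes = np.abs(self._signed_volumes())
        return self._volumes

    def _signed_volumes(self) -> np.ndarray:
        x = self.nodes[self.elements]  # (M, 4, 3)
        d = x[:, 1:] - x[:, :1]  # (M, 3, 3) edge vectors from vertex 0
        return np.linalg.det(d) / 6.0

    @property
    def centroids(self) -> np.ndarray:
        """Per-element centroid, (M, 3) cm."""
        if self._centroids is None:
            self._centroids = self.nodes[self.elements].mean(axis=1)
        return self._centroids

    @property
    def shape_gradients(self) -> np.ndarray:
        """Gradients of the four linear (P1) basis functions, (M, 3, 4).

        ``shape_gradients[e] @ values[elements[e]]`` is the (constant)
        spatial gradient of the P1 interpolant of nodal ``values`` on
        element ``e`` — exact for fields linear in space.
        """
        if self._grads is None:
            x = self.nodes[self.elements]  # (M, 4, 3)
            d = (x[:, 1:] - x[:, :1]).transpose(0, 2, 1)  # columns are edges
            dinv = np.linalg.inv(d)  # (M, 3, 3)
            g = np.empty((self.n_elements, 3, 4))
            g[:, :, 1:] = dinv.transpose(0, 2, 1)
            g[:, :, 0] = -g[:, :, 1:].sum(axis=2)
            self._grads = g
        return self._grads

    @property
    def mean_edge_length(self) -> float:
        """Mean length over the unique edges of the mesh (cm)."""
        edges = self.unique_edges()
        vec = self.nodes[edges[:, 1]] - self.nodes[edges[:, 0]]
        return float(np.linalg.norm(vec, axis=1).mean())

    def unique_edges(self) -> np.ndarray:
        pairs = self.elements[:, [0, 1, 0, 2, 0, 3, 1, 2, 1, 3, 2, 3]]
        pairs = pairs.reshape(-1, 2)
        pairs = np.sort(pairs, axis=1)
        return np.unique(pairs, axis=0)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        if self.elements.min(initial=0) < 0 or self.elements.max(initial=-1) >= self.n_nodes:
            raise ValueError("element node indices out of range")
        if self.tissue_class.shape != (self.n_elements,):
            raise ValueError("tissue_class must have one entry per element")
        if not np.isin(self.tissue_class, [HEALTHY, BZ, SCAR]).all():
            raise ValueError("tissue_class values must be in {0, 1, 2}")
        if self.fiber.shape != (self.n_elements, 3):
            raise ValueError("fiber must be (n_elements, 3)")
        norms = np.linalg.norm(self.fiber, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("fiber vectors must have unit norm (1e-8)")
        if (self.element_volumes <= 0).any():
            raise ValueError("all element volumes must be positive")

    def with_tissue_class(self, tissue_class: np.ndarray) -> "LabeledMesh":
        """Copy of the mesh with a new label array (geometry shared)."""
        out = replace(self, tissue_class=np.array(tissue_class, dtype=np.uint8))
        out._volumes = self._volumes
        out._centroids = self._centroids
        out._grads = self._grads
        return out

    def class_volume(self, tissue: int) -> float:
        """Total volume (cm^3) of elements with the given tissue class."""
        return float(self.element_volumes[self.tissue_class == tissue].sum())


def build_slab_mesh(extent, spacing, origin=(0.0, 0.0, 0.0)) -> tuple[np.ndarray, np.ndarray]:
    """Structured tetrahedralization of a box.

    The box ``origin + [0, extent]`` is divided into a regular hexahedral
    grid with ``round(extent/spacing)`` cells per axis (at least one), and
    every hexahedron is split into six tetrahedra sharing its main diagonal
    (Kuhn subdivision), which is conforming without orientation flips.

    Returns ``(nodes, elements)``.
    """
    extent = np.asarray(extent, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if np.any(extent <= 0) or spacing <= 0:
        raise ValueError("extent and spacing must be positive")
    ncell = np.maximum(1, np.round(extent / spacing).astype(int))
    nx, ny, nz = ncell
    xs = [np.linspace(origin[k], origin[k] + extent[k], ncell[k] + 1) for k in range(3)]
    X, Y, Z = np.meshgrid(xs[0], xs[1], xs[2], indexing="ij")
    # node index = ix + (nx+1) * (iy + (ny+1) * iz): x fastest, z slowest
    nodes = np.stack(
        [X.transpose(2, 1, 0).ravel(), Y.transpose(2, 1, 0).ravel(), Z.transpose(2, 1, 0).ravel()],
        axis=1,
    )

    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    ix = ix.ravel()
    iy = iy.ravel()
    iz = iz.ravel()

    def nid(dx, dy, dz):
        return (ix + dx) + (nx + 1) * ((iy + dy) + (ny + 1) * (iz + dz))

    c = {
        (0, 0, 0): nid(0, 0, 0), (1, 0, 0): nid(1, 0, 0),
        (0, 1, 0): nid(0, 1, 0), (1, 1, 0): nid(1, 1, 0),
        (0, 0, 1): nid(0, 0, 1), (1, 0, 1): nid(1, 0, 1),
        (0, 1, 1): nid(0, 1, 1), (1, 1, 1): nid(1, 1, 1),
    }
    # Kuhn subdivision: six tets along the (0,0,0) -> (1,1,1) diagonal, one per
    # permutation of the three axis steps.
    paths = [
        [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)],
        [(0, 0, 0), (1, 0, 0), (1, 0, 1), (1, 1, 1)],
        [(0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 1, 1)],
        [(0, 0, 0), (0, 1, 0), (0, 1, 1), (1, 1, 1)],
        [(0, 0, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1)],
        [(0, 0, 0), (0, 0, 1), (0, 1, 1), (1, 1, 1)],
    ]
    tets = np.empty((ix.size, 6, 4), dtype=np.int64)
    for t, path in enumerate(paths):
        for v, corner in enumerate(path):
            tets[:, t, v] = c[corner]
    elements = tets.reshape(-1, 4)
    return nodes, elements


# Mean unique-edge length of the Kuhn grid as a multiple of the grid spacing
# (3 axis edges + 3 face diagonals + 1 body diagonal per interior cell).
KUHN_EDGE_FACTOR = (3.0 + 3.0 * np.sqrt(2.0) + np.sqrt(3.0)) / 7.0
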