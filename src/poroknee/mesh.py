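"""Mesh container for the mixed displacement-pressure formulation.

A :class:`RegionMesh` holds 9-node quadrilateral elements (displacement
order), the corner-node subset that carries pressure DOFs, a region label
and an in-plane fibre direction per element, plus named boundary tags:

``tags``
    dict tag-name -> sorted array of node ids (point sets: fixed base,
    rollers, rigid-femur interface, draining boundary, horn anchors, ...).
``edges``
    dict name -> (n_edges, 3) arrays of quadratic boundary edges used for
    consistent traction loads.
``surfaces``
    dict name -> ordered node-id arrays describing contact polylines
    (corner and midside nodes, walked along the surface).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import CORNER_LOCAL


@dataclass
class RegionMesh:
    nodes: np.ndarray                      # (Nn, 2) mm
    elements: np.ndarray                   # (Ne, 9) int, tensor-product local order
    region_id: np.ndarray                  # (Ne,) int
    region_names: list[str]
    fibre_dir: np.ndarray = None           # (Ne, 2) unit vectors
    tags: dict = field(default_factory=dict)
    edges: dict = field(default_factory=dict)
    surfaces: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        self.region_id = np.asarray(self.region_id, dtype=int)
        if self.fibre_dir is None:
            self.fibre_dir = np.zeros((len(self.elements), 2))
            self.fibre_dir[:, 0] = 1.0

    @property
    def pressure_nodes(self) -> np.ndarray:
        """Sorted corner-node ids (the bilinear pressure sub-mesh)."""
        return np.unique(self.elements[:, CORNER_LOCAL])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def region_elements(self, name: str) -> np.ndarray:
        rid = self.region_names.index(name)
        return np.where(self.region_id == rid)[0]

    def tag(self, name: str) -> np.ndarray:
        return self.tags.get(name, np.empty(0, dtype=int))

    def validate(self) -> None:
        ne = len(self.elements)
        if self.region_id.shape != (ne,):
            raise ValueError("region_id must have one entry per element")
        if self.region_id.min() < 0 or self.region_id.max() >= len(self.region_names):
            raise ValueError("region_id out of range")
        norms = np.linalg.norm(self.fibre_dir, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("fibre directions must be unit vectors")
        if self.elements.min() < 0 or self.elements.max() >= self.n_nodes:
            raise ValueError("element connectivity out of range")


def structured_block(mapping, nx: int, ny: int) -> tuple[np.ndarray, np.ndarray]:
    """Structured Q9 block on the unit square via ``mapping(u, v) -> (x, y)``.

    Returns (nodes, elements).  Node grid is (2*nx+1) x (2*ny+1); midside
    nodes are placed by the mapping itself, so curved boundaries (e.g.
    circular arcs parameterized by the mapping) are represented by true
    isoparametric quadratic elements.
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    gx, gy = 2 * nx + 1, 2 * ny + 1
    u = np.linspace(0.0, 1.0, gx)
    v = np.linspace(0.0, 1.0, gy)
    U, V = np.meshgrid(u, v, indexing="xy")     # V slowest: row-major rows = v
    X, Y = mapping(U.ravel(), V.ravel())
    nodes = np.column_stack([X, Y])

    def nid(ix, iy):
        return iy * gx + ix

    elems = np.empty((nx * ny, 9), dtype=int)
    k = 0
    for ey in range(ny):
        for ex in range(nx):
            ids = [nid(2 * ex + i, 2 * ey + j) for j in range(3) for i in range(3)]
            elems[k] = ids
            k += 1
    return nodes, elems


def grid_node_id(nx: int, ix: int, iy: int) -> int:
    """Node id in a structured block with nx elements along x."""
    return iy * (2 * nx + 1) + ix


def merge_blocks(blocks: list[dict]) -> RegionMesh:
    """Concatenate independent structured blocks into one RegionMesh.

    Each block dict: ``nodes``, ``elements``, ``region`` (str), ``fibre_dir``
    ((ne,2) or None), ``tags``/``edges``/``surfaces`` with block-local node
    ids.  Blocks are not stitched: all inter-block interaction in this
    package is by contact, so no node deduplication is performed.
    """
    region_names: list[str] = []
    all_nodes, all_elems, all_rid, all_fib = [], [], [], []
    tags: dict[str, list] = {}
    edges: dict[str, list] = {}
    surfaces: dict[str, np.ndarray] = {}
    offset = 0
    for b in blocks:
        n, e = np.asarray(b["nodes"], float), np.asarray(b["elements"], int)
        name = b["region"]
        if name in region_names:
            raise ValueError(f"duplicate region name {name!r}")
        rid = len(region_names)
        region_names.append(name)
        all_nodes.append(n)
        all_elems.append(e + offset)
        all_rid.append(np.full(len(e), rid))
        fd = b.get("fibre_dir")
        if fd is None:
            fd = np.tile([1.0, 0.0], (len(e), 1))
        all_fib.append(np.asarray(fd, float))
        for t, ids in b.get("tags", {}).items():
            tags.setdefault(t, []).append(np.asarray(ids, int) + offset)
        for t, eds in b.get("edges", {}).items():
            edges.setdefault(t, []).append(np.asarray(eds, int) + offset)
        for t, ids in b.get("surfaces", {}).items():
            if t in surfaces:
                raise ValueError(f"duplicate surface name {t!r}")
            surfaces[t] = np.asarray(ids, int) + offset
        offset += len(n)
    mesh = RegionMesh(
        nodes=np.vstack(all_nodes),
        elements=np.vstack(all_elems),
        region_id=np.concatenate(all_rid),
        region_names=region_names,
        fibre_dir=np.vstack(all_fib),
        tags={t: np.unique(np.concatenate(v)) for t, v in tags.items()},
        edges={t: np.vstack(v) for t, v in edges.items()},
        surfaces=surfaces,
    )
    mesh.validate()
    return mesh
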