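"""Synthetic porous-anchor geometry generation and meshing.

The porosity of swelling co-polymeric bone anchors manufactured by NaCl
salt-leaching is emulated by randomly placed, freely overlapping circular
pores (spheres in 3D) whose diameters are drawn uniformly from a band such
as 450 +/- 100 um.  Overlap is deliberately unresolved: interconnectivity of
the pore network is an emergent property of the random placement, exactly as
it is in the leaching process, and isolated "pore islands" are a physically
meaningful outcome rather than an error.

The default simulation domain is a 2D plane-strain quarter cross-section of
a cylindrical anchor (radius 4 mm) surrounded by a bone layer, rasterised on
a structured grid of right triangles (pixel FEM).  Element regions are
assigned by centroid membership; the element adjacency structure (the
osteoconnectivity matrix) records edge-sharing neighbours for every element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import Point, box
from shapely.ops import unary_union

__all__ = [
    "ANCHOR",
    "VOID",
    "BONE",
    "PoreSpec",
    "PorousDomain",
    "FEMesh",
    "generate_porous_domain",
    "mesh_domain",
    "rect_mesh",
    "build_adjacency",
    "extract_anchor_submesh",
    "find_pore_islands",
    "GeometryError",
]

# Region labels
ANCHOR = 0
VOID = 1
BONE = 2

_GEOM_TOL = 1e-9


class GeometryError(RuntimeError):
    """Raised when a porous geometry cannot be realised as requested."""


@dataclass(frozen=True)
class PoreSpec:
    """Statistical description of a salt-leached pore population.

    Parameters
    ----------
    mean_diameter_um : float
        Mean pore diameter in micrometres (e.g. 300, 450, 600).
    half_band_um : float
        Half-width of the uniform diameter band; diameters are drawn from
        ``[mean - band, mean + band]``.
    target_porosity : float
        Void volume fraction of the anchor to aim for (0 <= phi < 1); the
        manufacturing analogue is ~0.60.  Exactly 0 is accepted as the
        degenerate fully-solid limit.
    rng_seed : int
        Seed for the pore-placement random stream.
    """

    mean_diameter_um: float = 450.0
    half_band_um: float = 100.0
    target_porosity: float = 0.60
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_diameter_um <= 0:
            raise ValueError("mean_diameter_um must be positive")
        if self.mean_diameter_um - self.half_band_um <= 0:
            raise ValueError("diameter band must stay positive")
        if not (0.0 <= self.target_porosity < 1.0):
            raise ValueError("target_porosity must lie in [0, 1)")

    @property
    def min_diameter_mm(self) -> float:
        return (self.mean_diameter_um - self.half_band_um) * 1e-3

    @property
    def max_diameter_mm(self) -> float:
        return (self.mean_diameter_um + self.half_band_um) * 1e-3


@dataclass
class PorousDomain:
    """A realised quarter-slice porous anchor embedded in a bone layer.

    ``pores`` holds one row per pore: ``(x, y, diameter)`` in mm for 2D or
    ``(x, y, z, diameter)`` for 3D.  ``achieved_porosity`` is the analytic
    void fraction of the anchor cross-section (union of pore disks clipped
    to the quarter disk) for 2D, or a seeded Monte-Carlo estimate for 3D.
    """

    spec: PoreSpec
    anchor_radius: float  # mm
    slice_thickness: float  # mm
    bone_layer_thickness: float  # mm
    pores: np.ndarray
    achieved_porosity: float
    dim: int = 2

    @property
    def outer_radius(self) -> float:
        return self.anchor_radius + self.bone_layer_thickness

    def contains_void(self, points: np.ndarray) -> np.ndarray:
        """Vectorised membership test: is each (x, y) point inside any pore?"""
        pts = np.atleast_2d(points)
        mask = np.zeros(len(pts), dtype=bool)
        if len(self.pores) == 0:
            return mask
        centers = self.pores[:, : self.dim]
        radii = self.pores[:, -1] / 2.0
        for c, r in zip(centers, radii):
            d2 = np.sum((pts[:, : self.dim] - c) ** 2, axis=1)
            mask |= d2 <= r * r + _GEOM_TOL
        return mask


def _quarter_disk(radius: float):
    disk = Point(0.0, 0.0).buffer(radius, quad_segs=256)
    return disk.intersection(box(0.0, 0.0, radius, radius))


def generate_porous_domain(
    spec: PoreSpec,
    anchor_radius: float = 4.0,
    slice_thickness: float = 2.0,
    bone_layer: float = 1.0,
    max_insertions: int = 20000,
    porosity_tol: float = 0.02,
    dim: int = 2,
    mc_samples: int = 200_000,
) -> PorousDomain:
    """Place overlapping pores until the target porosity is reached.

    Pore centres are sampled uniformly inside the anchor (quarter disk in 2D,
    quarter-cylinder slice in 3D) and diameters uniformly from the spec band.
    Insertion is sequential and deterministic for a fixed seed.  A candidate
    whose acceptance would overshoot ``target + porosity_tol`` is skipped;
    generation stops once the achieved porosity is within ``porosity_tol`` of
    target (from below it stops at ``target - porosity_tol/4``).

    Raises
    ------
    GeometryError
        If the porosity target is not reached within ``max_insertions``
        candidate placements.
    """
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    rng = np.random.default_rng(spec.rng_seed)
    target = spec.target_porosity
    if target == 0.0:
        return PorousDomain(
            spec, anchor_radius, slice_thickness, bone_layer,
            np.empty((0, dim + 1)), 0.0, dim=dim,
        )

    if dim == 3:
        return _generate_3d(spec, anchor_radius, slice_thickness, bone_layer,
                            max_insertions, porosity_tol, rng, mc_samples)

    anchor = _quarter_disk(anchor_radius)
    anchor_area = anchor.area
    void_union = None
    pores: list[tuple[float, float, float]] = []
    porosity = 0.0
    stop_at = target - porosity_tol / 4.0

    for _ in range(max_insertions):
        if porosity >= stop_at:
            break
        # uniform point in the quarter disk by rejection from the square
        while True:
            x, y = rng.uniform(0.0, anchor_radius, size=2)
            if x * x + y * y <= anchor_radius**2:
                break
        d = rng.uniform(spec.min_diameter_mm, spec.max_diameter_mm)
        circle = Point(x, y).buffer(d / 2.0, quad_segs=32)
        cand = circle if void_union is None else void_union.union(circle)
        cand_porosity = cand.intersection(anchor).area / anchor_area
        if cand_porosity > target + porosity_tol:
            continue  # this pore would overshoot; draw another
        void_union = cand
        pores.append((x, y, d))
        porosity = cand_porosity
    else:
        raise GeometryError(
            f"porosity target {target:.2f} not reached within "
            f"{max_insertions} insertions (achieved {porosity:.3f}); "
            "pores may be too large for the domain"
        )

    return PorousDomain(
        spec, anchor_radius, slice_thickness, bone_layer,
        np.array(pores), porosity, dim=2,
    )


def _generate_3d(spec, anchor_radius, slice_thickness, bone_layer,
                 max_insertions, porosity_tol, rng, mc_samples):
    # Quarter-cylinder slice: x, y >= 0, r <= R, 0 <= z <= t.  Porosity is
    # estimated on a fixed Monte-Carlo point cloud drawn from the same seeded
    # stream, so the result is deterministic for a fixed spec.
    target = spec.target_porosity
    pts: list[np.ndarray] = []
    n_have = 0
    while n_have < mc_samples:
        n = mc_samples - n_have
        xy = rng.uniform(0.0, anchor_radius, size=(2 * n, 2))
        keep = xy[:, 0] ** 2 + xy[:, 1] ** 2 <= anchor_radius**2
        xy = xy[keep][:n]
        z = rng.uniform(0.0, slice_thickness, size=len(xy))
        pts.append(np.column_stack([xy, z]))
        n_have += len(xy)
    cloud = np.concatenate(pts)[:mc_samples]
    inside = np.zeros(mc_samples, dtype=bool)

    pores: list[tuple[float, float, float, float]] = []
    stop_at = target - porosity_tol / 4.0
    porosity = 0.0
    for _ in range(max_insertions):
        if porosity >= stop_at:
            break
        while True:
            x, y = rng.uniform(0.0, anchor_radius, size=2)
            if x * x + y * y <= anchor_radius**2:
                break
        z = rng.uniform(0.0, slice_thickness)
        d = rng.uniform(spec.min_diameter_mm, spec.max_diameter_mm)
        d2 = np.sum((cloud - (x, y, z)) ** 2, axis=1)
        cand = inside | (d2 <= (d / 2.0) ** 2)
        cand_porosity = cand.mean()
        if cand_porosity > target + porosity_tol:
            continue
        inside = cand
        pores.append((x, y, z, d))
        porosity = cand_porosity
    else:
        raise GeometryError(
            f"3D porosity target {target:.2f} not reached within "
            f"{max_insertions} insertions (achieved {porosity:.3f})"
        )
    return PorousDomain(
        spec, anchor_radius, slice_thickness, bone_layer,
        np.array(pores), float(porosity), dim=3,
    )


# ---------------------------------------------------------------------------
# Meshing
# ---------------------------------------------------------------------------

@dataclass
class FEMesh:
    """Linear-triangle mesh with region labels and boundary/adjacency data.

    ``adjacency`` is the osteoconnectivity structure: for element ``i`` the
    edge-sharing neighbour ids are ``adj_indices[adj_indptr[i]:adj_indptr[i+1]]``.
    ``adj_pairs`` lists every ordered neighbour pair once per direction.

    ``boundary_sets`` maps a set name to a record array with fields
    ``elem`` (owning element), ``n0``/``n1`` (edge nodes) and, for the
    internal INTERFACE set of a full domain mesh, ``elem_out`` (the bone-side
    element).
    """

    nodes: np.ndarray          # (N, 2) mm
    elems: np.ndarray          # (M, 3) int
    region: np.ndarray         # (M,) in {ANCHOR, VOID, BONE}
    thickness: float           # out-of-plane slice thickness, mm
    element_size: float
    anchor_radius: float | None = None
    outer_radius: float | None = None
    boundary_sets: dict = field(default_factory=dict)
    adj_indptr: np.ndarray | None = None
    adj_indices: np.ndarray | None = None
    adj_pairs: np.ndarray | None = None
    parent_elems: np.ndarray | None = None  # submesh -> parent element ids

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elems(self) -> int:
        return len(self.elems)

    @cached_property
    def centroids(self) -> np.ndarray:
        return self.nodes[self.elems].mean(axis=1)

    @cached_property
    def areas(self) -> np.ndarray:
        p = self.nodes[self.elems]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    @property
    def volumes(self) -> np.ndarray:
        """Element volumes in mm^3 (area x slice thickness)."""
        return self.areas * self.thickness

    def neighbors(self, elem: int) -> np.ndarray:
        if self.adj_indptr is None:
            raise RuntimeError("adjacency not built; call build_adjacency()")
        return self.adj_indices[self.adj_indptr[elem]:self.adj_indptr[elem + 1]]


def _element_edges(elems: np.ndarray) -> np.ndarray:
    """All (3M, 2) sorted node pairs, element-major, edge order (01, 12, 20)."""
    e = np.concatenate([elems[:, [0, 1]], elems[:, [1, 2]], elems[:, [2, 0]]])
    return np.sort(e, axis=1)


def build_adjacency(mesh: FEMesh) -> tuple[np.ndarray, np.ndarray]:
    """Build edge-sharing element neighbour lists (symmetric, irreflexive).

    Returns ``(indptr, indices)`` in CSR layout and caches them (plus the
    pair list and the boundary-edge table) on the mesh.
    """
    M = mesh.n_elems
    edges = _element_edges(mesh.elems)
    owner = np.tile(np.arange(M), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges_s, owner_s = edges[order], owner[order]
    same = np.all(edges_s[1:] == edges_s[:-1], axis=1)
    i = owner_s[:-1][same]
    j = owner_s[1:][same]
    pairs = np.concatenate([np.column_stack([i, j]), np.column_stack([j, i])])
    counts = np.bincount(pairs[:, 0], minlength=M)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    indices = pairs[np.argsort(pairs[:, 0], kind="stable"), 1]
    mesh.adj_indptr, mesh.adj_indices, mesh.adj_pairs = indptr, indices, pairs

    # boundary edges: those matched to exactly one element
    matched = np.zeros(len(edges_s), dtype=bool)
    matched[:-1][same] = True
    matched[1:][same] = True
    mesh._boundary_edges = (edges_s[~matched], owner_s[~matched])
    return indptr, indices


def _classify_boundaries(mesh: FEMesh) -> None:
    """Populate SYM_X / SYM_Y / OUTER / INTERFACE boundary sets."""
    if mesh.adj_indptr is None:
        build_adjacency(mesh)
    edges, owners = mesh._boundary_edges
    xy = mesh.nodes
    tol = 1e-6 * max(1.0, mesh.element_size / 0.05)
    on_x_axis = (xy[edges[:, 0], 1] < tol) & (xy[edges[:, 1], 1] < tol)
    on_y_axis = (xy[edges[:, 0], 0] < tol) & (xy[edges[:, 1], 0] < tol)
    other = ~(on_x_axis | on_y_axis)

    def _rec(mask):
        return np.rec.fromarrays(
            [owners[mask], edges[mask, 0], edges[mask, 1]],
            names=["elem", "n0", "n1"],
        )

    mesh.boundary_sets["SYM_X"] = _rec(on_x_axis)   # edges on the x-axis (y=0)
    mesh.boundary_sets["SYM_Y"] = _rec(on_y_axis)   # edges on the y-axis (x=0)
    mesh.boundary_sets["OUTER"] = _rec(other)

    # internal interface edges: non-bone element sharing an edge with bone
    e = _element_edges(mesh.elems)
    owner = np.tile(np.arange(mesh.n_elems), 3)
    order = np.lexsort((e[:, 1], e[:, 0]))
    es, os_ = e[order], owner[order]
    same = np.all(es[1:] == es[:-1], axis=1)
    a, b = os_[:-1][same], os_[1:][same]
    reg = mesh.region
    iface = (reg[a] == BONE) != (reg[b] == BONE)
    a_i, b_i = a[iface], b[iface]
    inner = np.where(reg[a_i] == BONE, b_i, a_i)
    outer = np.where(reg[a_i] == BONE, a_i, b_i)
    edge_nodes = es[:-1][same][iface]
    mesh.boundary_sets["INTERFACE"] = np.rec.fromarrays(
        [inner, edge_nodes[:, 0], edge_nodes[:, 1], outer],
        names=["elem", "n0", "n1", "elem_out"],
    )


def mesh_domain(domain: PorousDomain, element_size: float = 0.05) -> FEMesh:
    """Rasterise a porous domain on a structured right-triangle grid.

    Every grid cell is split into two triangles; a triangle is kept when its
    centroid lies inside the outer circle, and labelled BONE / VOID / ANCHOR
    by centroid membership.  Symmetry faces, the outer surface and the
    bone-anchor interface are identified, and the element adjacency
    (osteoconnectivity) structure is built.

    Raises
    ------
    ValueError
        If ``element_size`` exceeds half the minimum pore diameter — the
        pore geometry would be unresolved on such a grid.
    """
    if domain.dim != 2:
        raise NotImplementedError("meshing is supported for 2D domains only")
    if element_size <= 0:
        raise ValueError("element_size must be positive")
    if len(domain.pores) and element_size > domain.spec.min_diameter_mm / 2.0:
        raise ValueError(
            f"element_size {element_size} mm exceeds half the minimum pore "
            f"diameter ({domain.spec.min_diameter_mm} mm); refine the mesh"
        )

    R_out = domain.outer_radius
    h = element_size
    n = int(np.ceil(R_out / h - 1e-9))
    xs = np.arange(n + 1) * h
    nodes = np.column_stack(
        [np.repeat(xs, n + 1), np.tile(xs, n + 1)]
    )
    node_id = lambda i, j: i * (n + 1) + j  # noqa: E731  (i along x, j along y)

    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    n00 = node_id(ii, jj)
    n10 = node_id(ii + 1, jj)
    n11 = node_id(ii + 1, jj + 1)
    n01 = node_id(ii, jj + 1)
    # lower-right and upper-left triangles of each cell
    tri = np.concatenate([
        np.column_stack([n00, n10, n11]),
        np.column_stack([n00, n11, n01]),
    ])
    cent = nodes[tri].mean(axis=1)
    r = np.hypot(cent[:, 0], cent[:, 1])
    keep = r <= R_out
    tri, cent, r = tri[keep], cent[keep], r[keep]

    region = np.full(len(tri), ANCHOR, dtype=np.int8)
    region[r > domain.anchor_radius] = BONE
    in_anchor = r <= domain.anchor_radius
    if len(domain.pores):
        void = domain.contains_void(cent[in_anchor])
        idx = np.where(in_anchor)[0][void]
        region[idx] = VOID

    used = np.unique(tri)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    mesh = FEMesh(
        nodes=nodes[used],
        elems=remap[tri],
        region=region,
        thickness=domain.slice_thickness,
        element_size=h,
        anchor_radius=domain.anchor_radius,
        outer_radius=R_out,
    )
    build_adjacency(mesh)
    _classify_boundaries(mesh)
    return mesh


def rect_mesh(width: float, height: float, element_size: float,
              region: int = ANCHOR, thickness: float = 1.0) -> FEMesh:
    """Structured right-triangle mesh of a solid rectangle (test fixture).

    Boundary sets: SYM_X (y=0), SYM_Y (x=0), TOP (y=height), RIGHT (x=width).
    """
    nx = max(1, int(round(width / element_size)))
    ny = max(1, int(round(height / element_size)))
    xs = np.linspace(0.0, width, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    nodes = np.column_stack([np.repeat(xs, ny + 1), np.tile(ys, nx + 1)])
    nid = lambda i, j: i * (ny + 1) + j  # noqa: E731
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    tri = np.concatenate([
        np.column_stack([nid(ii, jj), nid(ii + 1, jj), nid(ii + 1, jj + 1)]),
        np.column_stack([nid(ii, jj), nid(ii + 1, jj + 1), nid(ii, jj + 1)]),
    ])
    mesh = FEMesh(
        nodes=nodes,
        elems=tri,
        region=np.full(len(tri), region, dtype=np.int8),
        thickness=thickness,
        element_size=element_size,
    )
    build_adjacency(mesh)
    edges, owners = mesh._boundary_edges
    xy = nodes
    tol = 1e-9 + 1e-9 * max(width, height)

    def _side(mask):
        return np.rec.fromarrays(
            [owners[mask], edges[mask, 0], edges[mask, 1]],
            names=["elem", "n0", "n1"],
        )

    bottom = (xy[edges[:, 0], 1] < tol) & (xy[edges[:, 1], 1] < tol)
    left = (xy[edges[:, 0], 0] < tol) & (xy[edges[:, 1], 0] < tol)
    mesh.boundary_sets = {
        "SYM_X": _side(bottom),   # symmetry: constrains u_y only
        "SYM_Y": _side(left),     # symmetry: constrains u_x only
        "BOTTOM": _side(bottom),  # full clamp when used as a fixed set
        "LEFT": _side(left),
        "TOP": _side((xy[edges[:, 0], 1] > height - tol) & (xy[edges[:, 1], 1] > height - tol)),
        "RIGHT": _side((xy[edges[:, 0], 0] > width - tol) & (xy[edges[:, 1], 0] > width - tol)),
    }
    return mesh


def extract_anchor_submesh(mesh: FEMesh) -> FEMesh:
    """Extract the anchor + void elements as a standalone ingrowth mesh.

    The INTERFACE boundary set of the submesh is every boundary edge that is
    not a symmetry face — i.e. the (jagged) outer anchor surface where the
    swelling pressure is handed off, including open pore throats.
    """
    keep = mesh.region != BONE
    elem_ids = np.where(keep)[0]
    elems = mesh.elems[keep]
    used = np.unique(elems)
    remap = -np.ones(mesh.n_nodes, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = FEMesh(
        nodes=mesh.nodes[used],
        elems=remap[elems],
        region=mesh.region[keep].copy(),
        thickness=mesh.thickness,
        element_size=mesh.element_size,
        anchor_radius=mesh.anchor_radius,
        outer_radius=mesh.anchor_radius,
        parent_elems=elem_ids,
    )
    build_adjacency(sub)
    edges, owners = sub._boundary_edges
    xy = sub.nodes
    tol = 1e-9 + 1e-6 * sub.element_size
    on_x = (xy[edges[:, 0], 1] < tol) & (xy[edges[:, 1], 1] < tol)
    on_y = (xy[edges[:, 0], 0] < tol) & (xy[edges[:, 1], 0] < tol)
    iface = ~(on_x | on_y)

    def _rec(mask):
        return np.rec.fromarrays(
            [owners[mask], edges[mask, 0], edges[mask, 1]],
            names=["elem", "n0", "n1"],
        )

    sub.boundary_sets = {
        "SYM_X": _rec(on_x), "SYM_Y": _rec(on_y), "INTERFACE": _rec(iface),
    }
    return sub


def interface_elements(mesh: FEMesh, region_filter: int | None = None) -> np.ndarray:
    """Element ids owning an INTERFACE edge, optionally filtered by region."""
    rec = mesh.boundary_sets["INTERFACE"]
    elems = np.unique(rec.elem)
    if region_filter is not None:
        elems = elems[mesh.region[elems] == region_filter]
    return elems


def find_pore_islands(mesh: FEMesh, interface_elems: np.ndarray | None = None) -> list[np.ndarray]:
    """Connected VOID components with no adjacency path to the interface.

    Components of the void subgraph that contain no interface void element
    are pore islands: they can never capture bone ingrowth and only degrade
    the mechanical integrity of the anchor.  Returns a list of element-id
    arrays, one per island (empty list for a fully connected pore network or
    a solid anchor).
    """
    if mesh.adj_indptr is None:
        build_adjacency(mesh)
    void_ids = np.where(mesh.region == VOID)[0]
    if len(void_ids) == 0:
        return []
    if interface_elems is None:
        interface_elems = interface_elements(mesh, region_filter=VOID)
    sub_id = -np.ones(mesh.n_elems, dtype=np.int64)
    sub_id[void_ids] = np.arange(len(void_ids))
    pairs = mesh.adj_pairs
    both_void = (sub_id[pairs[:, 0]] >= 0) & (sub_id[pairs[:, 1]] >= 0)
    vp = pairs[both_void]
    graph = csr_matrix(
        (np.ones(len(vp), dtype=np.int8), (sub_id[vp[:, 0]], sub_id[vp[:, 1]])),
        shape=(len(void_ids), len(void_ids)),
    )
    n_comp, labels = connected_components(graph, directed=False)
    iface_void = interface_elems[mesh.region[interface_elems] == VOID]
    connected_labels = set(labels[sub_id[iface_void]])
    islands = []
    for c in range(n_comp):
        if c not in connected_labels:
            islands.append(void_ids[labels == c])
    return islands
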