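"""Tetrahedral meshing of binary voxel masks.

The brain domain is represented as a simplicial 3-complex built by splitting
every retained voxel cube into 6 tetrahedra (Kuhn subdivision along a fixed
global diagonal).  The resulting mesh is conforming, positively orientable,
and its boundary is a closed genus-zero surface after mask cleanup.

Coordinate conventions
----------------------
Voxel indices are 0-based; cell ``(i, j, k)`` occupies the half-open box
``[i, i+1) x [j, j+1) x [k, k+1)`` in index space.  Physical coordinates are
index coordinates scaled by the per-axis ``spacing``.  After
:func:`normalize_complex` the mesh lives in normalized model units (mass one,
center of mass at the origin); the returned affine recovers physical space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "TetMesh",
    "NormalizeAffine",
    "build_tet_mesh",
    "normalize_complex",
    "dilate_mask",
    "refine_mesh",
    "tet_volumes",
    "boundary_surface_volume",
]

# Kuhn subdivision of the unit cube: 6 tets, each a monotone lattice path
# from corner (0,0,0) to (1,1,1).  Corner ids are bit codes b = x + 2y + 4z.
_KUHN_PATHS = []
for _perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
    _code = 0
    _path = [0]
    for _axis in _perm:
        _code |= 1 << _axis
        _path.append(_code)
    _KUHN_PATHS.append(_path)
_KUHN_PATHS = np.asarray(_KUHN_PATHS, dtype=np.int64)  # (6, 4)

_CORNER_OFFSETS = np.array(
    [[(b >> 0) & 1, (b >> 1) & 1, (b >> 2) & 1] for b in range(8)], dtype=np.int64
)


class MeshTopologyError(ValueError):
    """Raised when the meshed mask violates the genus-zero boundary contract."""


@dataclass
class NormalizeAffine:
    """Affine x_model = (x_physical - shift) * scale."""

    shift: np.ndarray
    scale: float

    def to_model(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.shift) * self.scale

    def to_physical(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) / self.scale + self.shift


@dataclass
class TetMesh:
    """Simplicial 3-complex with a single closed genus-zero boundary.

    ``tets`` are positively oriented.  ``tets_tagged``/``tet_tags`` keep the
    Maubach bisection ordering used by :func:`refine_mesh`; they describe the
    same tetrahedra, possibly with a different vertex order.
    """

    vertices: np.ndarray  # (n, 3) float
    tets: np.ndarray  # (m, 4) int, positively oriented
    spacing: np.ndarray  # (3,) float
    grid_shape: tuple[int, int, int]
    voxel_of_vertex: np.ndarray  # (n, 3) int, owning cell (min-corner rule)
    tets_tagged: np.ndarray = None  # (m, 4) int, bisection ordering
    tet_tags: np.ndarray = None  # (m,) int in {1, 2, 3}
    affine: NormalizeAffine | None = None  # set by normalize_complex
    boundary_faces: np.ndarray = field(default=None)  # (F, 3) outward-oriented
    boundary_vertex_ids: np.ndarray = field(default=None)
    interior_vertex_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.tets_tagged is None:
            self.tets_tagged = self.tets.copy()
            self.tet_tags = np.full(len(self.tets), 3, dtype=np.int8)
        if self.boundary_faces is None:
            self._compute_boundary()

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        return tet_volumes(self.vertices, self.tets)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.boundary_faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(n, axis=1)

    def voxel_of_point(self, points: np.ndarray) -> np.ndarray:
        """Owning voxel cell of physical points (0-based, half-open, clamped)."""
        pts = np.asarray(points, dtype=float)
        if self.affine is not None:
            pts = self.affine.to_physical(pts)
        idx = np.floor(pts / self.spacing).astype(np.int64)
        hi = np.asarray(self.grid_shape, dtype=np.int64) - 1
        return np.clip(idx, 0, hi)

    # -- boundary topology ----------------------------------------------------

    def _compute_boundary(self) -> None:
        faces, counts = _tet_faces_with_counts(self.tets)
        if counts.max(initial=0) > 2:
            raise MeshTopologyError(
                "non-manifold interior face shared by more than 2 tets"
            )
        bnd = faces[counts == 1]
        self.boundary_faces = bnd
        bset = np.unique(bnd)
        self.boundary_vertex_ids = bset
        mask = np.ones(self.n_vertices, dtype=bool)
        mask[bset] = False
        self.interior_vertex_ids = np.nonzero(mask)[0]

    def boundary_euler_characteristic(self) -> int:
        f = self.boundary_faces
        nv = len(np.unique(f))
        edges = np.sort(
            np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
        )
        ne = len(np.unique(edges, axis=0))
        return nv - ne + len(f)

    def check_invariants(self, vol_rtol: float = 1e-9) -> None:
        vols = self.tet_volumes()
        if vols.min(initial=np.inf) <= 0:
            raise MeshTopologyError("tetrahedron with non-positive signed volume")
        f = self.boundary_faces
        edges = np.sort(
            np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
        )
        _, cnt = np.unique(edges, axis=0, return_counts=True)
        if not np.all(cnt == 2):
            raise MeshTopologyError("boundary surface is not closed (open edges)")
        chi = self.boundary_euler_characteristic()
        if chi != 2:
            raise MeshTopologyError(
                f"boundary Euler characteristic is {chi}, expected 2 (genus zero)"
            )
        vdiv = boundary_surface_volume(self.vertices, self.boundary_faces)
        vtot = vols.sum()
        if abs(vdiv - vtot) > vol_rtol * vtot:
            raise MeshTopologyError(
                f"divergence-theorem volume {vdiv} != tet volume sum {vtot}"
            )


def tet_volumes(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra."""
    p = vertices[tets]
    return np.einsum(
        "ij,ij->i",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    ) / 6.0


def boundary_surface_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume from outward-oriented faces (divergence theorem)."""
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    return float(np.einsum("ij,ij->", np.cross(a, b), c) / 6.0)


def _tet_faces_with_counts(tets: np.ndarray):
    faces = np.concatenate(
        [tets[:, [1, 2, 3]], tets[:, [0, 3, 2]], tets[:, [0, 1, 3]], tets[:, [0, 2, 1]]]
    )
    key = np.sort(faces, axis=1)
    _, first, counts = np.unique(
        key, axis=0, return_index=True, return_counts=True
    )
    return faces[first], counts


def _orient_positive(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    vols = tet_volumes(vertices, tets)
    out = tets.copy()
    flip = vols < 0
    out[flip] = out[flip][:, [0, 1, 3, 2]]
    return out


# -- mask cleanup -------------------------------------------------------------

_CRITICAL_PAIRS_2D = [((0, 0), (1, 1)), ((1, 0), (0, 1))]


def _fix_well_composed(mask: np.ndarray, max_passes: int = 50) -> np.ndarray:
    """Add voxels until no 2x2 edge-diagonal or 2x2x2 corner-diagonal
    configuration remains, so the voxel boundary is a 2-manifold."""
    m = mask.copy()
    for _ in range(max_passes):
        changed = False
        # edge-critical: in each axis-aligned 2x2 square, exactly the two
        # diagonal voxels set -> fill one neighbor
        for axis in range(3):
            a = np.moveaxis(m, axis, 0)
            s00 = a[:, :-1, :-1]
            s11 = a[:, 1:, 1:]
            s10 = a[:, 1:, :-1]
            s01 = a[:, :-1, 1:]
            for d0, d1, o0, o1 in ((s00, s11, s10, s01), (s10, s01, s00, s11)):
                bad = d0 & d1 & ~o0 & ~o1
                if bad.any():
                    o0[bad] = True
                    changed = True
        # corner-critical: in a 2x2x2 block only two opposite corners set
        c = m.astype(np.int8)
        blk = (
            c[:-1, :-1, :-1] + c[1:, :-1, :-1] + c[:-1, 1:, :-1] + c[:-1, :-1, 1:]
            + c[1:, 1:, :-1] + c[1:, :-1, 1:] + c[:-1, 1:, 1:] + c[1:, 1:, 1:]
        )
        for d0, d1 in (
            ((0, 0, 0), (1, 1, 1)),
            ((1, 0, 0), (0, 1, 1)),
            ((0, 1, 0), (1, 0, 1)),
            ((0, 0, 1), (1, 1, 0)),
        ):
            sl0 = tuple(slice(o, m.shape[i] - 1 + o) for i, o in enumerate(d0))
            sl1 = tuple(slice(o, m.shape[i] - 1 + o) for i, o in enumerate(d1))
            bad = (blk == 2) & m[sl0] & m[sl1]
            if bad.any():
                slf = tuple(
                    slice(o, m.shape[i] - 1 + o) for i, o in enumerate((d1[0], d0[1], d0[2]))
                )
                m[slf] |= bad
                changed = True
        if not changed:
            return m
    raise MeshTopologyError("mask well-composedness repair did not converge")


def clean_mask(mask: np.ndarray) -> np.ndarray:
    """Largest 26-connected component, cavities filled, manifold-repaired."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    lab, nlab = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if nlab > 1:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, nlab + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    mask = _fix_well_composed(mask)
    mask = ndimage.binary_fill_holes(mask)
    return mask


# -- construction -------------------------------------------------------------

def build_tet_mesh(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> TetMesh:
    """Tetrahedralize a binary voxel mask (6 Kuhn tets per voxel).

    The mask is cleaned first (largest connected component, cavity filling,
    manifold repair); a :class:`MeshTopologyError` is raised if the boundary
    of the result is not a closed genus-zero surface.
    """
    mask = clean_mask(mask)
    spacing = np.asarray(spacing, dtype=float)
    nx, ny, nz = mask.shape
    cells = np.argwhere(mask)  # (c, 3)

    # global corner-grid ids
    gx, gy, gz = nx + 1, ny + 1, nz + 1
    corner = cells[:, None, :] + _CORNER_OFFSETS[None, :, :]  # (c, 8, 3)
    corner_flat = (
        corner[..., 0] * (gy * gz) + corner[..., 1] * gz + corner[..., 2]
    )  # (c, 8)

    tets_global = corner_flat[:, _KUHN_PATHS]  # (c, 6, 4)
    tets_global = tets_global.reshape(-1, 4)

    used, inv = np.unique(tets_global, return_inverse=True)
    tets_tagged = inv.reshape(-1, 4).astype(np.int64)
    ux = used // (gy * gz)
    uy = (used // gz) % gy
    uz = used % gz
    vert_idx = np.stack([ux, uy, uz], axis=1)
    vertices = vert_idx * spacing

    hi = np.array([nx - 1, ny - 1, nz - 1])
    voxel_of_vertex = np.minimum(vert_idx, hi)

    tets = _orient_positive(vertices, tets_tagged)
    mesh = TetMesh(
        vertices=vertices,
        tets=tets,
        spacing=spacing,
        grid_shape=mask.shape,
        voxel_of_vertex=voxel_of_vertex,
        tets_tagged=tets_tagged,
        tet_tags=np.full(len(tets), 3, dtype=np.int8),
    )
    mesh.check_invariants()
    return mesh


# -- normalization ------------------------------------------------------------

def normalize_complex(mesh: TetMesh, rho_vertex: np.ndarray):
    """Center the rho-weighted mass at the origin and rescale to unit mass.

    Returns ``(normalized_mesh, affine)``; the input mesh is unchanged.
    Idempotent: applying it to an already-normalized mesh returns an
    identical mesh.
    """
    rho_vertex = np.asarray(rho_vertex, dtype=float)
    vols = mesh.tet_volumes()
    if vols.sum() <= 0:
        raise ValueError("degenerate mesh: non-positive total volume")
    rho_tet = rho_vertex[mesh.tets].mean(axis=1)
    masses = rho_tet * vols
    total = masses.sum()
    if total <= 0:
        raise ValueError("non-positive total mass")
    centroids = mesh.vertices[mesh.tets].mean(axis=1)
    com = (masses[:, None] * centroids).sum(axis=0) / total
    scale = total ** (-1.0 / 3.0)

    prev = mesh.affine
    if prev is None:
        affine = NormalizeAffine(shift=com.copy(), scale=scale)
    else:  # compose so to_physical still lands in the original frame
        affine = NormalizeAffine(
            shift=prev.shift + com / prev.scale, scale=prev.scale * scale
        )
    new_vertices = (mesh.vertices - com) * scale
    out = TetMesh(
        vertices=new_vertices,
        tets=mesh.tets.copy(),
        spacing=mesh.spacing.copy(),
        grid_shape=mesh.grid_shape,
        voxel_of_vertex=mesh.voxel_of_vertex.copy(),
        tets_tagged=mesh.tets_tagged.copy(),
        tet_tags=mesh.tet_tags.copy(),
        affine=affine,
        boundary_faces=mesh.boundary_faces.copy(),
        boundary_vertex_ids=mesh.boundary_vertex_ids.copy(),
        interior_vertex_ids=mesh.interior_vertex_ids.copy(),
    )
    return out, affine


# -- dilation -----------------------------------------------------------------

def dilate_mask(region: np.ndarray, m: int) -> np.ndarray:
    """Euclidean dilation: voxels within distance ``m`` (voxel units) of the set."""
    if m < 0 or int(m) != m:
        raise ValueError("dilation radius m must be a non-negative integer")
    region = np.asarray(region).astype(bool)
    if m == 0 or not region.any():
        return region.copy()
    dist = ndimage.distance_transform_edt(~region)
    return dist <= m


# -- refinement ---------------------------------------------------------------

def _bisect_batch(verts_list, tagged, tags, edge_mid, which):
    """Bisect tets selected by boolean ``which`` once (Maubach rule).

    Returns new (tagged, tags) arrays; appends midpoints to verts_list.
    """
    keep_t = tagged[~which]
    keep_g = tags[~which]
    sel_t = tagged[which]
    sel_g = tags[which]
    children_t = []
    children_g = []
    for row, k in zip(sel_t, sel_g):
        a, b = int(row[0]), int(row[k])
        key = (a, b) if a < b else (b, a)
        mid = edge_mid.get(key)
        if mid is None:
            mid = len(verts_list)
            verts_list.append(0.5 * (np.asarray(verts_list[a]) + verts_list[b]))
            edge_mid[key] = mid
        c1 = row.copy()
        c1[k] = mid
        c2 = np.empty(4, dtype=np.int64)
        c2[: k] = row[1 : k + 1]
        c2[k] = mid
        c2[k + 1 :] = row[k + 1 :]
        newtag = k - 1 if k > 1 else 3
        children_t.extend([c1, c2])
        children_g.extend([newtag, newtag])
    if children_t:
        tagged = np.concatenate([keep_t, np.asarray(children_t, dtype=np.int64)])
        tags = np.concatenate(
            [keep_g, np.asarray(children_g, dtype=np.int8)]
        )
    else:
        tagged, tags = keep_t, keep_g
    return tagged, tags


def refine_mesh(mesh: TetMesh, region: np.ndarray, max_closure_passes: int = 64) -> TetMesh:
    """Subdivide every tet whose centroid lies in ``region`` into 8 children
    (three levels of tagged bisection), then restore conformity by bisection
    closure on neighbors.  Existing vertices are never moved; total volume is
    conserved exactly.
    """
    region = np.asarray(region).astype(bool)
    if region.shape != mesh.grid_shape:
        raise ValueError("region grid does not match the mesh voxel grid")
    if not region.any():
        return mesh

    centroids = mesh.vertices[mesh.tets_tagged].mean(axis=1)
    cell = mesh.voxel_of_point(centroids)
    marked = region[cell[:, 0], cell[:, 1], cell[:, 2]]
    if not marked.any():
        return mesh

    verts_list = list(mesh.vertices)
    tagged = mesh.tets_tagged.copy()
    tags = mesh.tet_tags.copy()
    edge_mid: dict[tuple[int, int], int] = {}

    # three uniform bisection levels of the marked set (1 -> 8)
    gen = np.zeros(len(tagged), dtype=np.int8)
    gen[marked] = 3
    for _ in range(3):
        which = gen > 0
        if not which.any():
            break
        n_keep = int((~which).sum())
        gen_keep = gen[~which]
        n_child = 2 * int(which.sum())
        child_gen = np.repeat(gen[which] - 1, 2)
        tagged, tags = _bisect_batch(verts_list, tagged, tags, edge_mid, which)
        gen = np.concatenate([gen_keep, child_gen])
        assert len(gen) == n_keep + n_child == len(tagged)

    # conformity closure: bisect any tet that still contains a split edge
    for _ in range(max_closure_passes):
        hang = np.zeros(len(tagged), dtype=bool)
        pairs = np.stack(
            [
                tagged[:, [0, 1]], tagged[:, [0, 2]], tagged[:, [0, 3]],
                tagged[:, [1, 2]], tagged[:, [1, 3]], tagged[:, [2, 3]],
            ],
            axis=1,
        )  # (m, 6, 2)
        lo = pairs.min(axis=2)
        hi = pairs.max(axis=2)
        for e in range(6):
            keys = zip(lo[:, e].tolist(), hi[:, e].tolist())
            hang |= np.fromiter(
                (k in edge_mid for k in keys), dtype=bool, count=len(tagged)
            )
        if not hang.any():
            break
        tagged, tags = _bisect_batch(verts_list, tagged, tags, edge_mid, hang)
    else:
        raise MeshTopologyError("refinement closure did not converge (hanging vertex)")

    vertices = np.asarray(verts_list, dtype=float)
    tets = _orient_positive(vertices, tagged)

    # owning voxels for the new vertices, same min-corner convention
    old_n = mesh.n_vertices
    phys = vertices[old_n:]
    if mesh.affine is not None:
        phys = mesh.affine.to_physical(phys)
    idx = np.floor(phys / mesh.spacing + 1e-9).astype(np.int64)
    hi = np.asarray(mesh.grid_shape, dtype=np.int64) - 1
    idx = np.clip(idx, 0, hi)
    voxel_of_vertex = np.concatenate([mesh.voxel_of_vertex, idx])

    out = TetMesh(
        vertices=vertices,
        tets=tets,
        spacing=mesh.spacing.copy(),
        grid_shape=mesh.grid_shape,
        voxel_of_vertex=voxel_of_vertex,
        tets_tagged=tagged,
        tet_tags=tags,
        affine=mesh.affine,
    )
    vol_in = mesh.tet_volumes().sum()
    vol_out = out.tet_volumes().sum()
    if abs(vol_in - vol_out) > 1e-10 * vol_in:
        raise MeshTopologyError("refinement did not conserve volume")
    return out
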