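"""Area-measure-preserving OMT maps from the brain boundary to the cube surface.

The cubic A-OMT map g*_rho : boundary(M) -> boundary(C^3) is built by
composition: a spherical OMT map h*_rho of the brain boundary and a spherical
OMT map h*_1 of a reference triangulation of the cube surface are computed by
projected gradient descent on the area-weighted stretch energy; then
g*_rho = (h*_1)^{-1} o h*_rho, where the inverse is evaluated by locating each
query direction in a spherical triangle of the reference image and pulling it
back barycentrically onto the cube surface.

The spherical map is defined only up to rotation; the gauge is fixed by
aligning the principal axes of the rho-weighted boundary with the cube axes
before composition, which makes outputs reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .density import DensityField
from .mesh import TetMesh

__all__ = [
    "Surface",
    "PLMap",
    "boundary_surface",
    "reference_cube_surface",
    "stretch_laplacian",
    "stretch_energy",
    "spherical_aomt",
    "invert_reference_sphere_map",
    "cube_boundary_aomt",
]

CUBE_HALF = 0.5  # target cube is [-1/2, 1/2]^3


@dataclass
class Surface:
    """Closed oriented triangle surface (outward faces)."""

    vertices: np.ndarray  # (N, 3)
    faces: np.ndarray  # (F, 3) outward-oriented
    parent_vertex_ids: np.ndarray | None = None  # ids in the parent TetMesh

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)

    def face_areas(self, coords: np.ndarray | None = None) -> np.ndarray:
        v = self.vertices if coords is None else coords
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(n, axis=1)

    def euler_characteristic(self) -> int:
        e = np.sort(
            np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        return len(self.vertices) - len(np.unique(e, axis=0)) + len(self.faces)


@dataclass
class PLMap:
    """Piecewise-linear map given by per-vertex image coordinates.

    ``vertex_ids`` identifies the domain vertices (indices into the parent
    mesh); ``None`` means the map covers every vertex 0..n-1.
    """

    coords: np.ndarray  # (n, 3) image positions
    vertex_ids: np.ndarray | None = None
    report: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.ascontiguousarray(self.coords, dtype=float)


def boundary_surface(mesh: TetMesh) -> Surface:
    """Extract the (outward-oriented) boundary surface of a tetrahedral mesh."""
    ids = mesh.boundary_vertex_ids
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[ids] = np.arange(len(ids))
    return Surface(
        vertices=mesh.vertices[ids],
        faces=remap[mesh.boundary_faces],
        parent_vertex_ids=ids,
    )


def reference_cube_surface(n: int = 33) -> Surface:
    """Regular triangulation of the cube surface with an n x n vertex grid
    per face (shared edges merged), outward-oriented."""
    if n < 2:
        raise ValueError("need at least a 2 x 2 grid per face")
    t = np.linspace(-CUBE_HALF, CUBE_HALF, n)
    verts = []
    faces = []
    for axis in range(3):
        for sign in (-1.0, 1.0):
            u, v = np.meshgrid(t, t, indexing="ij")
            w = np.full_like(u, sign * CUBE_HALF)
            pts = np.zeros((n, n, 3))
            pts[..., axis] = w
            pts[..., (axis + 1) % 3] = u
            pts[..., (axis + 2) % 3] = v
            base = len(verts) * n * n if verts else 0
            idx = base + np.arange(n * n).reshape(n, n)
            i00 = idx[:-1, :-1].ravel()
            i10 = idx[1:, :-1].ravel()
            i01 = idx[:-1, 1:].ravel()
            i11 = idx[1:, 1:].ravel()
            quad = [
                np.stack([i00, i10, i11], axis=1),
                np.stack([i00, i11, i01], axis=1),
            ]
            f = np.concatenate(quad)
            if sign < 0:  # flip to keep normals outward
                f = f[:, [0, 2, 1]]
            verts.append(pts.reshape(-1, 3))
            faces.append(f)
    vertices = np.concatenate(verts)
    faces = np.concatenate(faces)
    # merge duplicated edge/corner vertices
    uniq, inv = np.unique(np.round(vertices, 12), axis=0, return_inverse=True)
    faces = inv[faces]
    surf = Surface(vertices=uniq, faces=faces)
    if surf.euler_characteristic() != 2:
        raise RuntimeError("reference cube surface is not a closed sphere")
    # fix orientation globally: outward means x . n > 0 on a centered cube
    v = surf.vertices
    f = surf.faces
    nrm = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    cent = v[f].mean(axis=1)
    flip = np.einsum("ij,ij->i", nrm, cent) < 0
    surf.faces[flip] = surf.faces[flip][:, [0, 2, 1]]
    return surf


_ref_surface_raw = reference_cube_surface


@lru_cache(maxsize=4)
def _cached_cube_surface(n: int) -> Surface:
    return _ref_surface_raw(n)


# -- stretch energy machinery -------------------------------------------------

def stretch_laplacian(
    g: np.ndarray, surface: Surface, face_mass: np.ndarray
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Area-weighted stretch Laplacian L_S(g) and the per-face stretch
    factors sigma = rho(alpha)|alpha| / |g(alpha)|.

    ``face_mass`` is rho(alpha)|alpha| on the source surface.  The (i, j)
    off-diagonal collects -cot(theta)/2 from the image corner opposite edge
    (i, j) in each adjacent face, divided by that face's sigma; the diagonal
    makes rows sum to zero.
    """
    f = surface.faces
    a, b, c = g[f[:, 0]], g[f[:, 1]], g[f[:, 2]]
    n = np.cross(b - a, c - a)
    dbl_area = np.linalg.norm(n, axis=1)
    if np.any(dbl_area <= 0):
        bad = int(np.argmin(dbl_area))
        raise ValueError(f"collapsed image face {bad}")
    sigma = face_mass / (0.5 * dbl_area)

    # corner cotangents of the image triangles
    cot0 = np.einsum("ij,ij->i", b - a, c - a) / dbl_area
    cot1 = np.einsum("ij,ij->i", a - b, c - b) / dbl_area
    cot2 = np.einsum("ij,ij->i", a - c, b - c) / dbl_area

    m = len(g)
    # edge (1,2) faces corner 0, edge (0,2) corner 1, edge (0,1) corner 2
    rows = np.concatenate([f[:, 1], f[:, 2], f[:, 0], f[:, 2], f[:, 0], f[:, 1]])
    cols = np.concatenate([f[:, 2], f[:, 1], f[:, 2], f[:, 0], f[:, 1], f[:, 0]])
    vals = -0.5 * np.concatenate(
        [cot0 / sigma, cot0 / sigma, cot1 / sigma, cot1 / sigma, cot2 / sigma, cot2 / sigma]
    )
    L = sp.coo_matrix((vals, (rows, cols)), shape=(m, m)).tocsr()
    diag = -np.asarray(L.sum(axis=1)).ravel()
    L = L + sp.diags(diag)
    return L.tocsr(), sigma


def stretch_energy(g: np.ndarray, surface: Surface, face_mass: np.ndarray) -> float:
    L, _ = stretch_laplacian(g, surface, face_mass)
    return 0.5 * float(np.einsum("ij,ij->", g, L @ g))


def _sphere_project(g: np.ndarray) -> np.ndarray:
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def _flipped_fraction(g: np.ndarray, faces: np.ndarray) -> float:
    det = np.einsum(
        "ij,ij->i", np.cross(g[faces[:, 0]], g[faces[:, 1]]), g[faces[:, 2]]
    )
    return float(np.mean(det <= 0))


def _adjacency_mean(surface: Surface) -> sp.csr_matrix:
    f = surface.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 2], f[:, 2], f[:, 0]])
    cols = np.concatenate([f[:, 1], f[:, 0], f[:, 2], f[:, 1], f[:, 0], f[:, 2]])
    m = len(surface.vertices)
    A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m)).tocsr()
    A.data[:] = 1.0
    deg = np.asarray(A.sum(axis=1)).ravel()
    return sp.diags(1.0 / deg) @ A


def spherical_aomt(
    surface: Surface,
    rho: np.ndarray | DensityField | None = None,
    max_iters: int = 400,
    tol: float = 1e-9,
    momentum: float = 0.9,
) -> PLMap:
    """Spherical area-measure-preserving OMT map by projected descent on
    the stretch energy.

    Each iteration steps along the Jacobi-preconditioned gradient
    -diag(L)^{-1} L_S(g) g with heavy-ball momentum, re-projects onto the
    unit sphere, and accepts only energy decreases (dropping the momentum
    term first, then halving the step).  The initial map is the radial
    projection of the centered surface, smoothed on the sphere if it starts
    with more than 5% folded triangles.
    """
    if surface.euler_characteristic() != 2:
        raise ValueError("surface is not a closed genus-zero sphere")
    if rho is None:
        rho_face = np.ones(len(surface.faces))
    elif isinstance(rho, DensityField):
        rho_face = rho.vertex_values[surface.parent_vertex_ids][surface.faces].mean(
            axis=1
        )
    else:
        rho_face = np.asarray(rho, dtype=float)[surface.faces].mean(axis=1)
    face_mass = rho_face * surface.face_areas()

    center = surface.vertices.mean(axis=0)
    g = _sphere_project(surface.vertices - center)
    if _flipped_fraction(g, surface.faces) > 0.05:
        A = _adjacency_mean(surface)
        for _ in range(100):
            g = _sphere_project(A @ g)
            if _flipped_fraction(g, surface.faces) <= 0.05:
                break

    energy = stretch_energy(g, surface, face_mass)
    trace = [energy]
    g_prev = g.copy()
    eta = None
    warned = False
    for _ in range(max_iters):
        L, _ = stretch_laplacian(g, surface, face_mass)
        grad = L @ g
        d = np.asarray(L.diagonal())
        pos = d > 0
        if pos.any():
            d[~pos] = d[pos].min()
            grad = grad / d[:, None]
        if eta is None:
            eta = 0.1 / max(np.abs(grad).max(), 1e-30)
        accepted = False
        mom = momentum
        for _damp in range(40):
            cand = _sphere_project(g - eta * grad + mom * (g - g_prev))
            e_new = stretch_energy(cand, surface, face_mass)
            if e_new < energy:
                accepted = True
                break
            if mom > 0:
                mom = 0.0  # momentum restart before step damping
            else:
                eta *= 0.5
        if not accepted:
            warned = True
            break
        rel = (energy - e_new) / max(abs(energy), 1e-30)
        g_prev, g, energy = g, cand, e_new
        trace.append(energy)
        eta *= 1.3
        if rel < tol:
            break
    return PLMap(
        coords=g,
        vertex_ids=surface.parent_vertex_ids,
        report={
            "energy_trace": trace,
            "flipped_fraction": _flipped_fraction(g, surface.faces),
            "no_descent": warned,
        },
    )


# -- composition --------------------------------------------------------------

def invert_reference_sphere_map(
    h1: np.ndarray,
    cube_surface: Surface,
    queries: np.ndarray,
    tol: float = 1e-12,
) -> np.ndarray:
    """Invert the spherical image of the reference cube surface at unit-norm
    query points.

    Each query is located in a spherical triangle of the image (candidates
    by nearest face centroid, containment by triple-product signs, ties
    broken by lowest face index) and pulled back barycentrically onto the
    cube surface; results are snapped exactly onto the cube face plane.
    """
    faces = cube_surface.faces
    qa = np.asarray(queries, dtype=float)
    qa = qa / np.linalg.norm(qa, axis=1, keepdims=True)
    cents = h1[faces].mean(axis=1)
    cents /= np.linalg.norm(cents, axis=1, keepdims=True)
    tree = cKDTree(cents)

    nq = len(qa)
    found_face = -np.ones(nq, dtype=np.int64)
    pending = np.arange(nq)
    for k, expand in ((8, tol), (64, tol), (len(faces), tol), (len(faces), 1e-7)):
        if len(pending) == 0:
            break
        k = min(k, len(faces))
        _, knn = tree.query(qa[pending], k=k)
        knn = np.atleast_2d(knn)
        cand = faces[knn]  # (p, k, 3)
        q = qa[pending][:, None, :]
        A, B, C = h1[cand[..., 0]], h1[cand[..., 1]], h1[cand[..., 2]]
        s1 = np.einsum("pkj,pkj->pk", np.cross(q, A), B)
        s2 = np.einsum("pkj,pkj->pk", np.cross(q, B), C)
        s3 = np.einsum("pkj,pkj->pk", np.cross(q, C), A)
        inside = (s1 >= -expand) & (s2 >= -expand) & (s3 >= -expand)
        face_idx = np.where(inside, knn, np.iinfo(np.int64).max)
        best = face_idx.min(axis=1)
        hit = best < np.iinfo(np.int64).max
        found_face[pending[hit]] = best[hit]
        pending = pending[~hit]
    if len(pending) > 0:
        raise ValueError(
            f"{len(pending)} query points not covered by any spherical triangle"
        )

    tri = faces[found_face]
    M = np.stack([h1[tri[:, 0]], h1[tri[:, 1]], h1[tri[:, 2]]], axis=2)  # (n,3,3)
    lam = np.linalg.solve(M, qa[..., None])[..., 0]
    lam = np.clip(lam, 0.0, None)
    lam /= lam.sum(axis=1, keepdims=True)
    pts = np.einsum("ni,nij->nj", lam, cube_surface.vertices[tri])
    # snap exactly onto the cube surface: the dominant coordinate is +/- 1/2
    dom = np.argmax(np.abs(pts), axis=1)
    pts[np.arange(len(pts)), dom] = np.sign(pts[np.arange(len(pts)), dom]) * CUBE_HALF
    pts = np.clip(pts, -CUBE_HALF, CUBE_HALF)
    return pts


def _principal_alignment(surface: Surface, weights: np.ndarray) -> np.ndarray:
    """Rotation aligning weighted principal axes with the coordinate axes.

    Returns a proper rotation matrix R (apply as x @ R).  Near-degenerate
    spectra (relative spread < 2%) keep the identity gauge so symmetric
    domains such as the cube itself are not arbitrarily permuted.
    """
    w = weights / weights.sum()
    mu = (w[:, None] * surface.vertices).sum(axis=0)
    d = surface.vertices - mu
    C = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0)
    evals, evecs = np.linalg.eigh(C)
    if evals[-1] <= 0 or (evals[-1] - evals[0]) / evals[-1] < 0.02:
        return np.eye(3)
    order = np.argsort(evals)[::-1]
    E = evecs[:, order]
    for i in range(3):
        j = np.argmax(np.abs(E[:, i]))
        if E[j, i] < 0:
            E[:, i] = -E[:, i]
    if np.linalg.det(E) < 0:
        E[:, 2] = -E[:, 2]
    return E


def cube_boundary_aomt(
    mesh_or_surface,
    rho: DensityField | np.ndarray | None = None,
    ref_resolution: int = 33,
    max_iters: int = 400,
    tol: float = 1e-9,
) -> PLMap:
    """Cubic A-OMT map g*_rho = (h*_1)^{-1} o h*_rho onto the cube surface.

    The boundary density is rescaled so the total rho-weighted boundary area
    equals the cube surface area (6 for the unit cube), which makes the
    per-face area ratios rho(alpha)|alpha| / |g(alpha)| directly comparable
    to 1.  The report carries those ratios and both spherical energy traces.
    """
    if isinstance(mesh_or_surface, TetMesh):
        surface = boundary_surface(mesh_or_surface)
        if rho is None:
            rho_vals = np.ones(len(surface.vertices))
        elif isinstance(rho, DensityField):
            rho_vals = rho.vertex_values[surface.parent_vertex_ids]
        else:
            rho_vals = np.asarray(rho, dtype=float)[surface.parent_vertex_ids]
    else:
        surface = mesh_or_surface
        if rho is None:
            rho_vals = np.ones(len(surface.vertices))
        elif isinstance(rho, DensityField):
            rho_vals = rho.vertex_values
        else:
            rho_vals = np.asarray(rho, dtype=float)

    areas = surface.face_areas()
    face_rho = rho_vals[surface.faces].mean(axis=1)
    total = float((face_rho * areas).sum())
    cube_area = 6.0 * (2 * CUBE_HALF) ** 2
    rho_scaled = rho_vals * (cube_area / total)

    h_rho = spherical_aomt(surface, rho_scaled, max_iters=max_iters, tol=tol)
    R = _principal_alignment(surface, rho_scaled * np.maximum(
        _vertex_area_weights(surface), 1e-300))
    sphere_pts = h_rho.coords @ R

    ref = _cached_cube_surface(ref_resolution)
    h1 = spherical_aomt(ref, None, max_iters=max_iters, tol=tol)
    g = invert_reference_sphere_map(h1.coords, ref, sphere_pts)

    g_areas = Surface(vertices=g, faces=surface.faces).face_areas(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = (rho_scaled[surface.faces].mean(axis=1) * areas) / g_areas
    return PLMap(
        coords=g,
        vertex_ids=surface.parent_vertex_ids,
        report={
            "area_ratios": ratios,
            "median_area_ratio": float(np.nanmedian(ratios)),
            "h_rho": h_rho.report,
            "h_ref": h1.report,
            "alignment": R,
        },
    )


def _vertex_area_weights(surface: Surface) -> np.ndarray:
    areas = surface.face_areas()
    w = np.zeros(len(surface.vertices))
    np.add.at(w, surface.faces.ravel(), np.repeat(areas / 3.0, 3))
    return w
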