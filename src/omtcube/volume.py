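"""Volume-measure-preserving OMT map from the brain mesh to the cube.

Given the cubic boundary map g*_rho, the interior map f*_rho : M -> C^3 is
computed by homotopy continuation: the boundary is moved along the linear
path g_zeta = (1 - zeta) id + zeta g*_rho for zeta on a uniform partition of
[0, 1] with p steps, and at each step the interior vertices solve the
mass-weighted Laplacian system

    [L_V(f_prev)]_II f_I = -[L_V(f_prev)]_IB g_zeta(boundary).

The off-diagonal weight of L_V couples each edge of a tetrahedron through
the areas of the two image faces not containing its endpoints, the dihedral
angle between them, and the source mass rho(tau)|tau|.  Map quality is
reported through the transport cost, the total mass distortion, local mass
ratios and the number of folded (orientation-reversed) image tetrahedra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .density import DensityField, simplex_measures
from .mesh import TetMesh, tet_volumes
from .surface import PLMap

__all__ = [
    "DiagnosticsReport",
    "homotopy_boundary",
    "mass_laplacian",
    "volume_omt",
    "transport_cost",
    "boundary_cost",
    "distortion_diagnostics",
]

_DIRECT_SOLVE_MAX = 10_000  # interior size above which CG replaces factorization
                            # (sparse LU fill-in grows fast for 3D stencils)


@dataclass
class DiagnosticsReport:
    transport_cost: float
    total_mass_distortion: float
    local_ratio_median: float
    local_ratio_mean: float
    local_ratio_sd: float
    local_ratio_sum_median: float
    folding_count: int
    nonfinite_ratio_count: int
    image_volume: float
    homotopy_trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["homotopy_trace"] = list(self.homotopy_trace)
        return d


def homotopy_boundary(gstar: np.ndarray, boundary_coords: np.ndarray, zeta: float):
    """g_zeta(v) = (1 - zeta) v + zeta g*(v) on the boundary vertices."""
    if not 0.0 <= zeta <= 1.0:
        raise ValueError("zeta must lie in [0, 1]")
    return (1.0 - zeta) * boundary_coords + zeta * gstar


def _image_face_normals(p: np.ndarray) -> np.ndarray:
    """Outward normals (|N| = 2 area) of the 4 image faces of each tet,
    N[:, a] opposite local vertex a, for positively oriented source tets."""
    N = np.empty_like(p)
    N[:, 0] = np.cross(p[:, 2] - p[:, 1], p[:, 3] - p[:, 1])
    N[:, 1] = np.cross(p[:, 3] - p[:, 0], p[:, 2] - p[:, 0])
    N[:, 2] = np.cross(p[:, 1] - p[:, 0], p[:, 3] - p[:, 0])
    N[:, 3] = np.cross(p[:, 2] - p[:, 0], p[:, 1] - p[:, 0])
    return N


_TET_EDGES = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def mass_laplacian(
    f: np.ndarray, mesh: TetMesh, rho: DensityField | np.ndarray
) -> sp.csr_matrix:
    """Mass-weighted Laplacian L_V(f): symmetric with zero row sums.

    For each tet and edge (v_i, v_j) with opposite edge (v_l, v_m), the
    off-diagonal weight is

        w_ij -= (1/9) |f([v_i,v_l,v_m])| |f([v_j,v_m,v_l])| cos(theta) / (rho(tau)|tau|)

    with theta the dihedral angle between the two image faces along their
    shared image edge.  With outward image face normals N (|N| = 2 area and
    cos(theta) = -N_oppi.N_oppj / (|N_oppi||N_oppj|)) this collapses to
    w_ij = (N_oppi . N_oppj) / (36 rho(tau)|tau|).  The diagonal is the
    negative row sum.
    """
    rho_tet = rho.on_tets(mesh) if isinstance(rho, DensityField) else np.asarray(rho)
    vols = mesh.tet_volumes()
    mass = rho_tet * vols
    if np.any(mass <= 0):
        raise ValueError("tetrahedron with non-positive mass rho(tau)|tau|")

    t = mesh.tets
    N = _image_face_normals(f[t])
    denom = 36.0 * mass
    rows, cols, vals = [], [], []
    for a, b in _TET_EDGES:
        w = np.einsum("ij,ij->i", N[:, a], N[:, b]) / denom
        rows.extend((t[:, a], t[:, b]))
        cols.extend((t[:, b], t[:, a]))
        vals.extend((w, w))
    n = mesh.n_vertices
    L = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    diag = -np.asarray(L.sum(axis=1)).ravel()
    return (L + sp.diags(diag)).tocsr()


def _solve_interior(L: sp.csr_matrix, I: np.ndarray, B: np.ndarray,
                    g_b: np.ndarray, x0: np.ndarray, rtol: float = 1e-10):
    A = L[I][:, I]
    rhs = -(L[I][:, B] @ g_b)
    if len(I) <= _DIRECT_SOLVE_MAX:
        lu = spla.splu(A.tocsc())
        x = np.column_stack([lu.solve(rhs[:, c]) for c in range(3)])
    else:
        d = A.diagonal()
        M = spla.LinearOperator(A.shape, matvec=lambda v: v / d)
        x = np.empty_like(rhs)
        for c in range(3):
            xc, info = spla.cg(A, rhs[:, c], x0=x0[:, c], M=M,
                               rtol=rtol, maxiter=5000)
            if info != 0:
                raise RuntimeError(f"CG did not converge (info={info})")
            x[:, c] = xc
    res = np.linalg.norm(A @ x - rhs) / max(np.linalg.norm(rhs), 1e-30)
    if res > 1e-8:
        raise RuntimeError(f"interior solve residual {res:.2e} exceeds 1e-8")
    return x


def volume_omt(
    mesh: TetMesh,
    rho: DensityField,
    gstar: PLMap,
    p: int = 11,
) -> tuple[PLMap, DiagnosticsReport]:
    """Cubic V-OMT map f*_rho by homotopy continuation with p uniform steps.

    Boundary vertices are pinned to g_zeta_k at step k; interior vertices
    solve the mass-weighted Laplacian system assembled at the previous
    iterate.  f(0) is the identity; the returned map has its boundary equal
    to g*_rho exactly.  Diagnostics are recorded at every step.
    """
    if p < 1:
        raise ValueError("partition number p must be >= 1")
    B = mesh.boundary_vertex_ids
    I = mesh.interior_vertex_ids
    if gstar.vertex_ids is not None and not np.array_equal(gstar.vertex_ids, B):
        raise ValueError("boundary map vertex ids do not match the mesh boundary")
    boundary0 = mesh.vertices[B]

    f = mesh.vertices.copy()
    trace = []
    for k in range(1, p + 1):
        zeta = k / p
        g_b = homotopy_boundary(gstar.coords, boundary0, zeta)
        if zeta == 1.0:
            g_b = gstar.coords
        L = mass_laplacian(f, mesh, rho)
        f_new = f.copy()
        f_new[B] = g_b
        if len(I) > 0:
            f_new[I] = _solve_interior(L, I, B, g_b, f[I])
        f = f_new
        rep = distortion_diagnostics(f, mesh, rho)
        trace.append(
            {
                "zeta": zeta,
                "transport_cost": transport_cost(f, mesh, rho),
                "total_mass_distortion": rep.total_mass_distortion,
                "folding_count": rep.folding_count,
                "local_ratio_median": rep.local_ratio_median,
            }
        )
    report = distortion_diagnostics(f, mesh, rho)
    report.transport_cost = transport_cost(f, mesh, rho)
    report.homotopy_trace = trace
    return PLMap(coords=f, vertex_ids=None, report={"p": p}), report


def transport_cost(f: np.ndarray | PLMap, mesh: TetMesh, rho: DensityField) -> float:
    """c_rho(f) = sum_v ||v - f(v)||^2 m_rho(v)."""
    coords = f.coords if isinstance(f, PLMap) else np.asarray(f)
    m = simplex_measures(mesh, rho).local_volume
    d2 = np.einsum("ij,ij->i", mesh.vertices - coords, mesh.vertices - coords)
    return float((d2 * m).sum())


def boundary_cost(g: np.ndarray | PLMap, mesh: TetMesh, rho: DensityField) -> float:
    """d_rho(g) = sum_vhat ||vhat - g(vhat)||^2 a_rho(vhat)."""
    coords = g.coords if isinstance(g, PLMap) else np.asarray(g)
    B = mesh.boundary_vertex_ids
    a = simplex_measures(mesh, rho).local_area[B]
    d2 = np.einsum("ij,ij->i", mesh.vertices[B] - coords, mesh.vertices[B] - coords)
    return float((d2 * a).sum())


def distortion_diagnostics(
    f: np.ndarray | PLMap, mesh: TetMesh, rho: DensityField
) -> DiagnosticsReport:
    """Total mass distortion, local mass ratios and folding count.

    d_M(f) sums |rho(tau)|tau| - |f(tau)|| / 4 over the 1-ring of every
    vertex, which counts every tet exactly once.  The local ratio r_f(v) is
    reported as the mean of rho(tau)|tau| / |f(tau)| over the 1-ring (1 under
    exact measure preservation); the raw 1-ring sum is also reported.
    Collapsed image tets yield non-finite ratios, which are excluded from
    the summaries and counted.
    """
    coords = f.coords if isinstance(f, PLMap) else np.asarray(f)
    rho_tet = rho.on_tets(mesh)
    vols = mesh.tet_volumes()
    mass = rho_tet * vols
    sv = tet_volumes(coords, mesh.tets)
    img = np.abs(sv)
    folding = int((sv <= 0).sum())
    d_m = float(np.abs(mass - img).sum())

    with np.errstate(divide="ignore", invalid="ignore"):
        q = mass / img
    finite = np.isfinite(q)
    n = mesh.n_vertices
    ssum = np.zeros(n)
    scount = np.zeros(n)
    np.add.at(ssum, mesh.tets[finite].ravel(), np.repeat(q[finite], 4))
    np.add.at(scount, mesh.tets[finite].ravel(), 1.0)
    ok = scount > 0
    mean_ratio = np.full(n, np.nan)
    mean_ratio[ok] = ssum[ok] / scount[ok]
    sum_ratio = ssum

    return DiagnosticsReport(
        transport_cost=float("nan"),
        total_mass_distortion=d_m,
        local_ratio_median=float(np.nanmedian(mean_ratio)),
        local_ratio_mean=float(np.nanmean(mean_ratio)),
        local_ratio_sd=float(np.nanstd(mean_ratio)),
        local_ratio_sum_median=float(np.median(sum_ratio[ok])) if ok.any() else float("nan"),
        folding_count=folding,
        nonfinite_ratio_count=int((~finite).sum()),
        image_volume=float(img.sum()),
    )
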