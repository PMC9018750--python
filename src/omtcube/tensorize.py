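"""Rasterization of brain volumes into cube tensors and label pullback.

The V-OMT map f carries the brain mesh onto the cube [-1/2, 1/2]^3.  Network
tensors are built by locating the image tetrahedron containing each cube
voxel center c_u, pulling c_u back barycentrically to a point of the brain,
and sampling the source volume at the containing brain voxel (nearest
sampling, so label volumes keep the {0, 1, 2, 4} alphabet).  Predictions are
transferred back by averaging, over each brain voxel, the cube-center
probabilities whose preimages land in it; uncovered brain voxels take the
value of the nearest preimage point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TetMesh, tet_volumes
from .surface import CUBE_HALF, PLMap

__all__ = [
    "CubeSampling",
    "compute_cube_sampling",
    "rasterize_to_cube",
    "pullback_probabilities",
    "PullbackResult",
    "decide_labels",
    "enlarged_ratio",
]

WT_LABELS = (2, 1, 4)
TC_LABELS = (1, 4)
ET_LABELS = (4,)


@dataclass
class CubeSampling:
    """Preimages of the cube voxel centers under the V-OMT map."""

    cube_size: int
    covered: np.ndarray  # (n, n, n) bool
    preimage_physical: np.ndarray  # (n^3, 3), NaN where uncovered
    brain_voxel: np.ndarray  # (n^3, 3) int, -1 where uncovered

    @property
    def coverage(self) -> float:
        return float(self.covered.mean())


def _group_cartesian(q_order, q_cell_counts, t_list, t_cell_starts, t_cell_counts):
    """All (query, tet) pairs grouped by hash cell, fully vectorized."""
    nq = np.repeat(t_cell_counts, q_cell_counts)  # candidates per query (cell order)
    total = int(nq.sum())
    if total == 0:
        return (np.empty(0, np.int64),) * 2
    qi = np.repeat(q_order, nq)
    starts = np.repeat(t_cell_starts, q_cell_counts)
    starts_rep = np.repeat(starts, nq)
    offs = np.arange(total) - np.repeat(np.cumsum(nq) - nq, nq)
    ti = t_list[starts_rep + offs]
    return qi, ti


def compute_cube_sampling(
    f: PLMap | np.ndarray,
    mesh: TetMesh,
    cube_size: int = 128,
    eps: float = 1e-9,
    hash_cells: int = 32,
    chunk_pairs: int = 4_000_000,
) -> CubeSampling:
    """Locate each cube voxel center in the image mesh and pull it back.

    A uniform spatial hash over image-tet bounding boxes provides the
    candidate sets; containment uses barycentric coordinates with an eps
    tolerance.  A point inside several image tets takes a positively
    oriented one if any, then the lowest tet index.
    """
    coords = f.coords if isinstance(f, PLMap) else np.asarray(f)
    n = cube_size
    t = mesh.tets
    P = coords[t]  # (m, 4, 3)
    sv = tet_volumes(coords, t)
    good = np.abs(sv) > 1e-300
    E = np.stack([P[:, 1] - P[:, 0], P[:, 2] - P[:, 0], P[:, 3] - P[:, 0]], axis=2)
    Tinv = np.full((len(t), 3, 3), np.nan)
    Tinv[good] = np.linalg.inv(E[good])

    h = (2 * CUBE_HALF) / hash_cells
    lo = np.clip(np.floor((P.min(axis=1) + CUBE_HALF - 1e-12) / h), 0, hash_cells - 1).astype(np.int64)
    hi = np.clip(np.floor((P.max(axis=1) + CUBE_HALF + 1e-12) / h), 0, hash_cells - 1).astype(np.int64)
    span = hi - lo + 1

    # expand tets into the hash cells overlapped by their AABBs, grouping by
    # span shape so the expansion stays vectorized
    pair_cell = []
    pair_tet = []
    shapes, shape_inv = np.unique(span, axis=0, return_inverse=True)
    tet_ids = np.arange(len(t))
    for si, (sx, sy, sz) in enumerate(shapes):
        sel = (shape_inv == si) & good
        if not sel.any():
            continue
        ox, oy, oz = np.meshgrid(
            np.arange(sx), np.arange(sy), np.arange(sz), indexing="ij"
        )
        offs = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)  # (s, 3)
        cells = lo[sel][:, None, :] + offs[None, :, :]  # (g, s, 3)
        lin = (
            cells[..., 0] * hash_cells * hash_cells
            + cells[..., 1] * hash_cells
            + cells[..., 2]
        ).ravel()
        pair_cell.append(lin)
        pair_tet.append(np.repeat(tet_ids[sel], len(offs)))
    pair_cell = np.concatenate(pair_cell)
    pair_tet = np.concatenate(pair_tet)
    order = np.argsort(pair_cell, kind="stable")
    pair_cell = pair_cell[order]
    t_list = pair_tet[order]
    ncells = hash_cells ** 3
    t_cell_counts = np.bincount(pair_cell, minlength=ncells)
    t_cell_starts = np.concatenate([[0], np.cumsum(t_cell_counts)[:-1]])

    # cube voxel centers and their hash cells
    axis = -CUBE_HALF + (np.arange(n) + 0.5) * (2 * CUBE_HALF) / n
    cx, cy, cz = np.meshgrid(axis, axis, axis, indexing="ij")
    centers = np.stack([cx.ravel(), cy.ravel(), cz.ravel()], axis=1)
    ccell = np.clip(((centers + CUBE_HALF) / h).astype(np.int64), 0, hash_cells - 1)
    qcell = ccell[:, 0] * hash_cells * hash_cells + ccell[:, 1] * hash_cells + ccell[:, 2]
    q_order = np.argsort(qcell, kind="stable")
    q_cell_counts = np.bincount(qcell, minlength=ncells)

    qi_all, ti_all = _group_cartesian(
        q_order, q_cell_counts, t_list, t_cell_starts, t_cell_counts
    )

    BIG = np.iinfo(np.int64).max
    best = np.full(n ** 3, BIG, dtype=np.int64)
    m = len(t)
    for s in range(0, len(qi_all), chunk_pairs):
        qi = qi_all[s : s + chunk_pairs]
        ti = ti_all[s : s + chunk_pairs]
        d = centers[qi] - P[ti, 0]
        lam = np.einsum("nij,nj->ni", Tinv[ti], d)
        inside = (
            (lam[:, 0] >= -eps)
            & (lam[:, 1] >= -eps)
            & (lam[:, 2] >= -eps)
            & (lam.sum(axis=1) <= 1.0 + eps)
        )
        if not inside.any():
            continue
        key = ti[inside] + np.where(sv[ti[inside]] > 0, 0, m)
        np.minimum.at(best, qi[inside], key)

    covered_flat = best < BIG
    tet_hit = np.where(covered_flat, best % m, 0)

    # barycentric pullback to the source mesh and owning brain voxel
    src = mesh.vertices[t[tet_hit]]
    d = centers - coords[t[tet_hit, 0]]
    lam = np.einsum("nij,nj->ni", Tinv[tet_hit], d)
    pts = src[:, 0] + np.einsum(
        "ni,nij->nj",
        lam,
        np.stack(
            [src[:, 1] - src[:, 0], src[:, 2] - src[:, 0], src[:, 3] - src[:, 0]],
            axis=1,
        ),
    )
    if mesh.affine is not None:
        pts = mesh.affine.to_physical(pts)
    pts[~covered_flat] = np.nan
    with np.errstate(invalid="ignore"):
        vox = np.floor(np.nan_to_num(pts) / mesh.spacing).astype(np.int64)
    vox = np.clip(vox, 0, np.asarray(mesh.grid_shape) - 1)
    vox[~covered_flat] = -1

    return CubeSampling(
        cube_size=n,
        covered=covered_flat.reshape(n, n, n),
        preimage_physical=pts,
        brain_voxel=vox,
    )


def rasterize_to_cube(
    f: PLMap | np.ndarray,
    mesh: TetMesh,
    source: np.ndarray,
    mode: str = "grayscale",
    cube_size: int = 128,
    sampling: CubeSampling | None = None,
    max_uncovered: float = 0.05,
) -> tuple[np.ndarray, CubeSampling]:
    """Pull a brain volume into the cube through the inverse OMT map.

    Labels are sampled nearest (containing voxel), never interpolated.
    Cube voxels not covered by any image tet are set to 0; an error is
    raised when more than ``max_uncovered`` of them are uncovered.
    """
    if mode not in ("grayscale", "label"):
        raise ValueError("mode must be 'grayscale' or 'label'")
    if sampling is None:
        sampling = compute_cube_sampling(f, mesh, cube_size)
    n = sampling.cube_size
    if 1.0 - sampling.coverage > max_uncovered:
        raise RuntimeError(
            f"{100 * (1 - sampling.coverage):.1f}% of cube voxels uncovered; "
            "map quality insufficient"
        )
    source = np.asarray(source)
    out = np.zeros(n ** 3, dtype=source.dtype if mode == "label" else float)
    cov = sampling.covered.ravel()
    v = sampling.brain_voxel[cov]
    out[cov] = source[v[:, 0], v[:, 1], v[:, 2]]
    return out.reshape(n, n, n), sampling


@dataclass
class PullbackResult:
    probabilities: dict  # t -> (X, Y, Z) float in [0, 1]
    multiplicity: np.ndarray  # n(j) per brain voxel
    labels: np.ndarray | None = None


def pullback_probabilities(
    f: PLMap | np.ndarray,
    mesh: TetMesh,
    cube_probs: dict,
    brain_mask: np.ndarray,
    sampling: CubeSampling | None = None,
) -> PullbackResult:
    """Transfer cube probabilities to brain voxels (multiplicity-weighted).

    p_j = mean of the cube-center probabilities whose preimages lie in voxel
    j; a brain voxel with no preimage takes the probability of the cube
    center whose preimage is nearest to the voxel center.
    """
    if sampling is None:
        first = next(iter(cube_probs.values()))
        sampling = compute_cube_sampling(f, mesh, first.shape[0])
    brain_mask = np.asarray(brain_mask).astype(bool)
    shape = brain_mask.shape
    nvox = int(np.prod(shape))
    cov = sampling.covered.ravel()
    v = sampling.brain_voxel[cov]
    lin = np.ravel_multi_index((v[:, 0], v[:, 1], v[:, 2]), shape)
    counts = np.bincount(lin, minlength=nvox)

    # nearest-preimage fallback for mask voxels never hit
    miss = brain_mask.ravel() & (counts == 0)
    if miss.any():
        tree = cKDTree(sampling.preimage_physical[cov])
        mi = np.argwhere(miss.reshape(shape))
        qc = (mi + 0.5) * mesh.spacing
        _, nearest = tree.query(qc)
    probs = {}
    for t_key, cube in cube_probs.items():
        cp = np.asarray(cube, dtype=float).ravel()[cov]
        sums = np.bincount(lin, weights=cp, minlength=nvox)
        p = np.zeros(nvox)
        hit = counts > 0
        p[hit] = sums[hit] / counts[hit]
        if miss.any():
            p[miss] = cp[nearest]
        p[~brain_mask.ravel()] = 0.0
        probs[t_key] = p.reshape(shape)
    return PullbackResult(
        probabilities=probs, multiplicity=counts.reshape(shape)
    )


def decide_labels(
    p_wt: np.ndarray, p_tc: np.ndarray, p_et: np.ndarray, brain_mask: np.ndarray
) -> np.ndarray:
    """Hierarchical decision: not WT -> 0; WT but not TC -> 2; TC but not
    ET -> 1; ET -> 4.  Voxels outside the brain stay 0."""
    brain_mask = np.asarray(brain_mask).astype(bool)
    out = np.zeros(brain_mask.shape, dtype=np.int16)
    wt = brain_mask & (p_wt >= 0.5)
    tc = wt & (p_tc >= 0.5)
    et = tc & (p_et >= 0.5)
    out[wt & ~tc] = 2
    out[tc & ~et] = 1
    out[et] = 4
    return out


def enlarged_ratio(
    brain_labels: np.ndarray,
    cube_labels: np.ndarray,
    brain_mask: np.ndarray,
    covered: np.ndarray | None = None,
) -> float:
    """(WT fraction among covered cube voxels) / (WT fraction among brain voxels)."""
    brain_mask = np.asarray(brain_mask).astype(bool)
    wt_brain = np.isin(brain_labels, WT_LABELS) & brain_mask
    n_brain = int(brain_mask.sum())
    if wt_brain.sum() == 0:
        raise ValueError("no WT voxels in the raw labels")
    cube_wt = np.isin(cube_labels, WT_LABELS)
    if covered is None:
        frac_cube = cube_wt.mean()
    else:
        covered = np.asarray(covered).astype(bool)
        frac_cube = cube_wt[covered].sum() / max(covered.sum(), 1)
    frac_brain = wt_brain.sum() / n_brain
    return float(frac_cube / frac_brain)
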