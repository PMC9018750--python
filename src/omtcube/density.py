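"""Grayscale-derived density fields and simplex measures.

The transport maps are driven by a strictly positive per-vertex density
``rho`` built from the FLAIR modality: intensities are Z-scored and
contrast-enhanced by histogram equalization (CEHE) to [0, 1], then
exponentiated, ``rho_gamma(v) = exp(gamma * I(i,j,k))`` with gamma in [1, 2].
Phase II replaces the full-brain density by a step field (exp inside the
dilated tumor region, 1 outside) smoothed with an m^3 mean filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mesh import TetMesh

__all__ = [
    "DensityField",
    "MeasureSet",
    "normalize_intensity",
    "density_phase1",
    "density_phase2",
    "simplex_measures",
]


@dataclass
class DensityField:
    """Strictly positive per-vertex density with barycentric simplex averages."""

    vertex_values: np.ndarray  # (n,) > 0
    gamma: float | None = None

    def __post_init__(self):
        self.vertex_values = np.asarray(self.vertex_values, dtype=float)
        if np.any(self.vertex_values <= 0):
            raise ValueError("density values must be strictly positive")

    def on_tets(self, mesh: TetMesh) -> np.ndarray:
        """rho(tau): mean of the 4 vertex densities."""
        return self.vertex_values[mesh.tets].mean(axis=1)

    def on_faces(self, faces: np.ndarray) -> np.ndarray:
        """rho(alpha): mean of the 3 vertex densities."""
        return self.vertex_values[faces].mean(axis=1)

    @classmethod
    def uniform(cls, mesh: TetMesh) -> "DensityField":
        return cls(np.ones(mesh.n_vertices))


@dataclass
class MeasureSet:
    """Local area/volume measures a_rho(v_hat) and m_rho(v)."""

    face_density: np.ndarray  # rho(alpha) per boundary face
    face_area: np.ndarray  # |alpha|
    tet_density: np.ndarray  # rho(tau)
    tet_volume: np.ndarray  # |tau|
    local_area: np.ndarray  # a_rho per vertex (zero off-boundary)
    local_volume: np.ndarray  # m_rho per vertex

    @property
    def total_mass(self) -> float:
        return float((self.tet_density * self.tet_volume).sum())

    @property
    def total_boundary_mass(self) -> float:
        return float((self.face_density * self.face_area).sum())


def normalize_intensity(volume: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """CEHE: Z-score over mask voxels, clip to +/-3 SD, histogram-equalize
    the mask voxels to [0, 1].  Background is exactly 0.

    The transform is a monotone non-decreasing function of intensity ranks
    inside the mask; a constant image maps every mask voxel to 0.5.
    """
    volume = np.asarray(volume, dtype=float)
    brain_mask = np.asarray(brain_mask).astype(bool)
    if not brain_mask.any():
        raise ValueError("empty brain mask")
    vals = volume[brain_mask]
    sd = vals.std()
    if sd == 0:
        out = np.zeros(volume.shape, dtype=float)
        out[brain_mask] = 0.5
        return out
    z = np.clip((vals - vals.mean()) / sd, -3.0, 3.0)
    levels, inverse, counts = np.unique(z, return_inverse=True, return_counts=True)
    cdf = np.cumsum(counts) / counts.sum()
    out = np.zeros(volume.shape, dtype=float)
    out[brain_mask] = cdf[inverse]
    return out


def _vertex_samples(field: np.ndarray, mesh: TetMesh) -> np.ndarray:
    vox = mesh.voxel_of_vertex
    return field[vox[:, 0], vox[:, 1], vox[:, 2]]


def density_phase1(cehe: np.ndarray, mesh: TetMesh, gamma: float) -> DensityField:
    """Whole-brain density rho_gamma(v) = exp(gamma * I(i,j,k)).

    Each vertex takes the CEHE value of its owning voxel; values lie in
    [1, exp(gamma)].  gamma outside [1, 2] is accepted with a warning.
    """
    if not 1.0 <= gamma <= 2.0:
        warnings.warn(f"gamma={gamma} is outside the recommended interval [1, 2]")
    cehe = np.asarray(cehe, dtype=float)
    if cehe.shape != mesh.grid_shape:
        raise ValueError("CEHE grid does not match the mesh voxel grid")
    return DensityField(np.exp(gamma * _vertex_samples(cehe, mesh)), gamma=gamma)


def density_phase2(
    cehe: np.ndarray,
    region: np.ndarray,
    gamma: float,
    mesh: TetMesh,
    m: int = 5,
) -> DensityField:
    """Step density (exp(gamma*I) inside the dilated tumor region, 1 outside)
    blurred with an m x m x m mean kernel over the full cuboid grid
    (replicate padding at the grid border), sampled at mesh vertices."""
    if m <= 0 or m % 2 == 0:
        raise ValueError("blur kernel size m must be odd and positive")
    cehe = np.asarray(cehe, dtype=float)
    region = np.asarray(region).astype(bool)
    step = np.where(region, np.exp(gamma * cehe), 1.0)
    if m > 1:
        step = ndimage.uniform_filter(step, size=m, mode="nearest")
    return DensityField(_vertex_samples(step, mesh), gamma=gamma)


def simplex_measures(mesh: TetMesh, rho: DensityField) -> MeasureSet:
    """Per-simplex densities and the local mass measures

    a_rho(v_hat) = rho(v_hat)/3 * sum of adjacent boundary face areas,
    m_rho(v)     = rho(v)/4 * sum of adjacent tet volumes.

    Conservation holds algebraically: sum_v m_rho(v) = sum_tau rho(tau)|tau|.
    """
    vols = mesh.tet_volumes()
    areas = mesh.face_areas()
    rv = rho.vertex_values
    tet_density = rv[mesh.tets].mean(axis=1)
    face_density = rv[mesh.boundary_faces].mean(axis=1)

    vol_sum = np.zeros(mesh.n_vertices)
    np.add.at(vol_sum, mesh.tets.ravel(), np.repeat(vols, 4))
    local_volume = 0.25 * rv * vol_sum

    area_sum = np.zeros(mesh.n_vertices)
    np.add.at(area_sum, mesh.boundary_faces.ravel(), np.repeat(areas, 3))
    local_area = (rv * area_sum) / 3.0

    return MeasureSet(
        face_density=face_density,
        face_area=areas,
        tet_density=tet_density,
        tet_volume=vols,
        local_area=local_area,
        local_volume=local_volume,
    )
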