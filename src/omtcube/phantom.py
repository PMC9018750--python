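"""Synthetic BraTS-like subjects and oracle predictors.

The phantom emulates the layout of a multimodal brain MRI study: four
modalities (FLAIR, T1, T1CE, T2) and a label volume on a shared grid, a
brain occupying 12-20% of the cuboid voxels, and nested tumor regions
ET c TC c WT with the usual {4, 1, 2} coding.  FLAIR is hyperintense on WT
and T1CE on ET so the density construction has real signal to work with.
The oracle predictor stands in for a trained network: it emits the cube
label (plus optional clipped Gaussian noise) as a probability grid, which
makes every geometric stage of the pipeline testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "PhantomSubject", "generate_phantom", "oracle_predictor"]

MODALITIES = ("flair", "t1", "t1ce", "t2")

# mean intensity per tissue per modality; tissue order:
# (brain background, WT rim (label 2), TC non-enhancing (1), ET (4))
_DEFAULT_CONTRAST = {
    "flair": (0.35, 0.85, 0.80, 0.75),
    "t1": (0.55, 0.40, 0.35, 0.45),
    "t1ce": (0.45, 0.40, 0.45, 0.90),
    "t2": (0.40, 0.70, 0.75, 0.65),
}


@dataclass
class PhantomSpec:
    seed: int = 0
    grid_shape: tuple[int, int, int] = (96, 96, 64)
    # brain ellipsoid semi-axes as fractions of the grid dimensions; the
    # implied brain fraction (4pi/3 * product) is ~0.17 of the cuboid
    brain_axes_frac: tuple[float, float, float] = (0.40, 0.35, 0.29)
    boundary_noise_amp: float = 0.06  # relative radial perturbation
    boundary_noise_sigma: float = 6.0  # smoothing of the perturbation field
    tumor_center_frac: tuple[float, float, float] = (0.58, 0.44, 0.52)
    # tumor radii as fractions of the smallest brain semi-axis
    wt_radius_frac: float = 0.62
    tc_radius_frac: float = 0.42
    et_radius_frac: float = 0.27
    tumor_noise_amp: float = 0.15
    noise_sd: float = 0.02
    contrast: dict = field(default_factory=lambda: dict(_DEFAULT_CONTRAST))


@dataclass
class PhantomSubject:
    modalities: dict  # name -> float grid
    labels: np.ndarray  # int grid with values {0, 1, 2, 4}
    brain_mask: np.ndarray
    spacing: np.ndarray


def _smooth_noise(rng, shape, sigma):
    g = rng.standard_normal(shape)
    g = ndimage.gaussian_filter(g, sigma)
    sd = g.std()
    return g / sd if sd > 0 else g


def _blob(coords, center, radii, noise):
    d2 = sum(((coords[i] - center[i]) / radii[i]) ** 2 for i in range(3))
    return d2 * (1.0 + noise) < 1.0


def generate_phantom(spec: PhantomSpec | None = None, seed: int | None = None) -> PhantomSubject:
    """Generate one synthetic subject; deterministic for a fixed seed."""
    if spec is None:
        spec = PhantomSpec()
    if seed is not None:
        spec = PhantomSpec(**{**spec.__dict__, "seed": seed})
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    nx, ny, nz = shape
    coords = np.meshgrid(
        np.arange(nx) + 0.5, np.arange(ny) + 0.5, np.arange(nz) + 0.5, indexing="ij"
    )
    center = (nx / 2, ny / 2, nz / 2)
    axes = (
        spec.brain_axes_frac[0] * nx,
        spec.brain_axes_frac[1] * ny,
        spec.brain_axes_frac[2] * nz,
    )
    bnoise = spec.boundary_noise_amp * _smooth_noise(rng, shape, spec.boundary_noise_sigma)
    brain = _blob(coords, center, axes, bnoise)

    tcen = tuple(spec.tumor_center_frac[i] * shape[i] for i in range(3))
    rmin = min(axes)
    tnoise = spec.tumor_noise_amp * _smooth_noise(rng, shape, spec.boundary_noise_sigma / 2)
    wt = _blob(coords, tcen, (spec.wt_radius_frac * rmin,) * 3, tnoise) & brain
    tc = _blob(coords, tcen, (spec.tc_radius_frac * rmin,) * 3, tnoise) & wt
    et = _blob(coords, tcen, (spec.et_radius_frac * rmin,) * 3, tnoise) & tc
    if not (wt.any() and tc.any() and et.any()):
        raise ValueError("infeasible phantom spec: empty tumor region")

    labels = np.zeros(shape, dtype=np.int16)
    labels[wt] = 2
    labels[tc] = 1
    labels[et] = 4

    tissue_masks = (brain & ~wt, wt & ~tc, tc & ~et, et)
    modalities = {}
    for name in MODALITIES:
        means = spec.contrast[name]
        img = np.zeros(shape, dtype=float)
        for mask, mu in zip(tissue_masks, means):
            img[mask] = mu
        img += spec.noise_sd * rng.standard_normal(shape)
        img[~brain] = 0.0
        modalities[name] = img
    return PhantomSubject(
        modalities=modalities,
        labels=labels,
        brain_mask=brain,
        spacing=np.ones(3),
    )


def oracle_predictor(cube_labels: dict, noise_sd: float = 0.0, seed: int = 0) -> dict:
    """Stand-in for the trained networks: per phase t, probability 1 on the
    cube label and 0 elsewhere, plus clipped Gaussian noise.  At zero noise,
    thresholding at 1/2 recovers the cube labels exactly."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = {}
    for t_key, lab in cube_labels.items():
        p = np.asarray(lab, dtype=float)
        if noise_sd > 0:
            p = p + noise_sd * rng.standard_normal(p.shape)
        out[t_key] = np.clip(p, 0.0, 1.0)
    return out
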