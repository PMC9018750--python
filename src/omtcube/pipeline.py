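"""Two-phase OMT pipeline orchestration.

Phase I maps the whole brain to the cube with the FLAIR-derived density and
produces the network tensors for whole-tumor detection.  Phase II dilates
the detected WT region, builds the blurred step density, refines the mesh on
the region and re-maps, magnifying the tumor in the cube.  Validation runs a
plug-in predictor (any callable with the network contract, e.g. the oracle)
over the 5 test-time orientations and up to 3 model slots, ensemble-votes
the 15 probability grids, pulls probabilities back to brain voxels and
applies the hierarchical label decision.

Network training itself is out of scope: the predictor contract
(4-channel cube in, three probability cubes out) is the integration point,
and the recorded training hyperparameters are configuration defaults only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics as emetrics
from .density import DensityField, density_phase1, density_phase2, normalize_intensity
from .mesh import TetMesh, build_tet_mesh, clean_mask, dilate_mask, normalize_complex, refine_mesh
from .phantom import MODALITIES, PhantomSubject
from .surface import cube_boundary_aomt
from .tensorize import (
    ET_LABELS,
    TC_LABELS,
    WT_LABELS,
    compute_cube_sampling,
    decide_labels,
    enlarged_ratio,
    pullback_probabilities,
    rasterize_to_cube,
)
from .volume import volume_omt

__all__ = ["PipelineConfig", "PhaseResult", "run_phase1", "run_phase2", "run_validate"]


@dataclass
class PipelineConfig:
    gammas: tuple = (1.0, 1.5, 1.75, 2.0)  # density exponents for augmentation
    gamma: float = 1.0  # exponent used for a single run
    p: int = 11  # homotopy partition number
    m: int = 5  # dilation radius and blur kernel size (voxels)
    cube_size: int = 128
    ref_resolution: int = 33  # reference cube-surface grid per face
    aomt_max_iters: int = 400
    aomt_tol: float = 1e-9
    refine: bool = True  # mesh refinement on the WT region in Phase II
    # recorded (unused) network training defaults
    training_defaults: dict = field(
        default_factory=lambda: {
            "encoder_depth": 3,
            "initial_learning_rate": 1e-4,
            "learning_rate_drop_factor": 0.95,
            "learning_rate_drop_period": 10,
            "l2_regularization": 1e-4,
            "batch_size": 8,
        }
    )

    def __post_init__(self):
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.m % 2 == 0 or self.m < 0:
            raise ValueError("m must be odd and positive")
        if self.cube_size <= 0 or self.cube_size % 8 != 0:
            raise ValueError("cube resolution must be a positive multiple of 8")


@dataclass
class PhaseResult:
    cubes: dict  # modality name -> grayscale cube
    label_cubes: dict  # t -> binary label cube (training mode only)
    mesh: TetMesh
    fmap: object  # PLMap of the V-OMT
    sampling: object  # CubeSampling
    density: DensityField
    diagnostics: dict
    brain_mask: np.ndarray
    cehe: dict  # modality name -> CEHE volume


def _prepare_subject(subject: PhantomSubject):
    mask = clean_mask(np.asarray(subject.brain_mask))
    cehe = {
        name: normalize_intensity(subject.modalities[name], mask)
        for name in MODALITIES
    }
    return mask, cehe


def _omt_map(mesh, rho, config: PipelineConfig):
    mesh_n, _ = normalize_complex(mesh, rho.vertex_values)
    gstar = cube_boundary_aomt(
        mesh_n,
        rho,
        ref_resolution=config.ref_resolution,
        max_iters=config.aomt_max_iters,
        tol=config.aomt_tol,
    )
    fmap, report = volume_omt(mesh_n, rho, gstar, p=config.p)
    return mesh_n, fmap, gstar, report


def _rasterize_phase(mesh_n, fmap, cehe, labels, label_sets, config):
    sampling = compute_cube_sampling(fmap, mesh_n, config.cube_size)
    cubes = {}
    for name in MODALITIES:
        cubes[name], _ = rasterize_to_cube(
            fmap, mesh_n, cehe[name], "grayscale", sampling=sampling
        )
    label_cubes = {}
    if labels is not None:
        lab_cube, _ = rasterize_to_cube(
            fmap, mesh_n, np.asarray(labels), "label", sampling=sampling
        )
        for t_key, codes in label_sets.items():
            label_cubes[t_key] = np.isin(lab_cube, codes).astype(np.int8)
    return sampling, cubes, label_cubes


def run_phase1(
    subject: PhantomSubject,
    config: PipelineConfig | None = None,
    mode: str = "train",
) -> PhaseResult:
    """Phase I: whole-brain density rho_gamma, V-OMT, cube tensors.

    In training mode a binary WT label cube (codes {2,1,4} -> 1) is emitted
    alongside the 4 grayscale cubes.
    """
    config = config or PipelineConfig()
    mask, cehe = _prepare_subject(subject)
    mesh = build_tet_mesh(mask, subject.spacing)
    rho = density_phase1(cehe["flair"], mesh, config.gamma)
    mesh_n, fmap, gstar, report = _omt_map(mesh, rho, config)
    labels = subject.labels if mode == "train" else None
    sampling, cubes, label_cubes = _rasterize_phase(
        mesh_n, fmap, cehe, labels, {1: WT_LABELS}, config
    )
    return PhaseResult(
        cubes=cubes,
        label_cubes=label_cubes,
        mesh=mesh_n,
        fmap=fmap,
        sampling=sampling,
        density=rho,
        diagnostics={
            "volume": report.to_dict(),
            "boundary_median_area_ratio": gstar.report["median_area_ratio"],
            "coverage": sampling.coverage,
        },
        brain_mask=mask,
        cehe=cehe,
    )


def run_phase2(
    subject: PhantomSubject,
    wt_region: np.ndarray | None = None,
    config: PipelineConfig | None = None,
    mode: str = "train",
) -> PhaseResult:
    """Phase II: dilate the WT region, build the blurred step density,
    refine the mesh on the region, re-map and rasterize.

    ``wt_region`` normally comes from a Phase I prediction; passing ``None``
    in training mode falls back to the ground-truth WT.  Label cubes use the
    one-sets {2,1,4} (t=1), {1,4} (t=2), {4} (t=3).
    """
    config = config or PipelineConfig()
    mask, cehe = _prepare_subject(subject)
    if wt_region is None:
        if subject.labels is None:
            raise ValueError("no WT region and no labels to fall back on")
        wt_region = np.isin(subject.labels, WT_LABELS)
    wt_region = np.asarray(wt_region).astype(bool)
    mesh = build_tet_mesh(mask, subject.spacing)
    if not wt_region.any():
        import warnings

        warnings.warn("empty WT region; falling back to the Phase I density")
        rho_region = None
    else:
        rho_region = dilate_mask(wt_region, config.m) & mask

    if rho_region is None:
        rho = density_phase1(cehe["flair"], mesh, config.gamma)
    else:
        if config.refine:
            mesh = refine_mesh(mesh, rho_region)
        rho = density_phase2(cehe["flair"], rho_region, config.gamma, mesh, m=config.m)
    mesh_n, fmap, gstar, report = _omt_map(mesh, rho, config)
    labels = subject.labels if mode == "train" else None
    sampling, cubes, label_cubes = _rasterize_phase(
        mesh_n,
        fmap,
        cehe,
        labels,
        {1: WT_LABELS, 2: TC_LABELS, 3: ET_LABELS},
        config,
    )
    diag = {
        "volume": report.to_dict(),
        "boundary_median_area_ratio": gstar.report["median_area_ratio"],
        "coverage": sampling.coverage,
    }
    if labels is not None and np.isin(labels, WT_LABELS).any():
        lab_cube, _ = rasterize_to_cube(
            fmap, mesh_n, np.asarray(labels), "label", sampling=sampling
        )
        diag["enlarged_ratio"] = enlarged_ratio(
            np.asarray(labels), lab_cube, mask, sampling.covered
        )
    return PhaseResult(
        cubes=cubes,
        label_cubes=label_cubes,
        mesh=mesh_n,
        fmap=fmap,
        sampling=sampling,
        density=rho,
        diagnostics=diag,
        brain_mask=mask,
        cehe=cehe,
    )


def _call_predictor(predictor, cubes: dict) -> dict:
    stack = np.stack([cubes[name] for name in MODALITIES])
    out = predictor(stack)
    if not isinstance(out, dict) or set(out.keys()) != {1, 2, 3}:
        raise ValueError("predictor must return a dict with keys {1, 2, 3}")
    for t_key, g in out.items():
        g = np.asarray(g)
        if g.shape != cubes[MODALITIES[0]].shape:
            raise ValueError("predictor output shape mismatch")
        if g.min() < 0 or g.max() > 1:
            raise ValueError("predictor probabilities must lie in [0, 1]")
    return out


def run_validate(
    subject: PhantomSubject,
    predictors,
    config: PipelineConfig | None = None,
    wt_region: np.ndarray | None = None,
    ensemble: bool = True,
) -> dict:
    """Full validation: Phase I -> WT region -> Phase II -> orientation
    variants -> predictor(s) -> ensemble vote -> pullback -> label decision
    -> metrics against ground truth when available.

    ``predictors`` is one callable or a list of up to 3 callables mapping a
    (4, n, n, n) grayscale stack to ``{1: p_wt, 2: p_tc, 3: p_et}`` cube
    probability grids.  ``wt_region`` overrides the Phase I detection
    (ground-truth WT is the documented training-time fallback).
    """
    config = config or PipelineConfig()
    if callable(predictors):
        predictors = [predictors]
    predictors = list(predictors)

    if wt_region is None:
        ph1 = run_phase1(subject, config, mode="infer")
        p1 = _call_predictor(predictors[0], ph1.cubes)
        pulled = pullback_probabilities(
            ph1.fmap, ph1.mesh, {1: p1[1]}, ph1.brain_mask, sampling=ph1.sampling
        )
        wt_region = pulled.probabilities[1] >= 0.5

    ph2 = run_phase2(subject, wt_region=wt_region, config=config, mode="infer")

    voted = {}
    if ensemble:
        prob_sets = {1: {}, 2: {}, 3: {}}
        for mu in range(emetrics.N_ORIENTATIONS):
            oriented = {
                name: emetrics.orientation_variants(ph2.cubes[name])[mu]
                for name in MODALITIES
            }
            for nu, pred in enumerate(predictors, start=1):
                out = _call_predictor(pred, oriented)
                for t_key in (1, 2, 3):
                    prob_sets[t_key][(mu, nu)] = emetrics.inverse_orientation(
                        out[t_key], mu
                    )
        for t_key in (1, 2, 3):
            voted[t_key], _ = emetrics.ensemble_vote(prob_sets[t_key])
    else:
        out = _call_predictor(predictors[0], ph2.cubes)
        voted = {t_key: np.asarray(out[t_key], dtype=float) for t_key in (1, 2, 3)}

    pulled = pullback_probabilities(
        ph2.fmap, ph2.mesh, voted, ph2.brain_mask, sampling=ph2.sampling
    )
    labels = decide_labels(
        pulled.probabilities[1],
        pulled.probabilities[2],
        pulled.probabilities[3],
        ph2.brain_mask,
    )
    result = {"labels": labels, "phase2": ph2, "probabilities": pulled.probabilities}
    if subject.labels is not None:
        gt = np.asarray(subject.labels)
        reports = {}
        for name, codes in (("WT", WT_LABELS), ("TC", TC_LABELS), ("ET", ET_LABELS)):
            g = np.isin(gt, codes)
            p = np.isin(labels, codes)
            rep = emetrics.confusion_metrics(g, p)
            if g.any() and p.any():
                rep.hd95 = emetrics.hd95(g, p, subject.spacing)
            reports[name] = rep
        result["metrics"] = reports
    return result
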