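# omtcube

Cubic optimal-mass-transport (OMT) parameterization of 3D brain MRI for
tumor segmentation pipelines.

3D segmentation networks want a dense cubic tensor, but a brain occupies an
irregular ~12-20% of a 240×240×155 MRI cuboid. `omtcube` tetrahedralizes the
brain mask, equips it with an intensity-derived density, and computes a
volume-measure-preserving piecewise-linear map f : M → C³ onto the cube
[-1/2, 1/2]³ that minimizes the quadratic transport cost

    c_ρ(f) = Σ_v ‖v − f(v)‖² m_ρ(v),      m_ρ(v) = ¼ ρ(v) Σ_{τ∋v} |τ|,

subject to local mass preservation ρ(τ)|τ| = |f(τ)|. The map is built in two
stages: a boundary map g*_ρ : ∂M → ∂C³ obtained by minimizing the
area-weighted stretch energy on the sphere and composing two spherical maps
(A-OMT), then a homotopy continuation that moves the boundary from the
identity to g*_ρ in p uniform steps while re-solving a mass-weighted
Laplacian system for the interior (V-OMT).

Because the map preserves local mass ratios, raising the density on a region
magnifies it in the cube. The two-phase pipeline exploits this: Phase I maps
the whole brain with ρ_γ(v) = exp(γ·Ī₁) (Ī₁ the contrast-enhanced,
histogram-equalized FLAIR), Phase II dilates the detected whole-tumor
region, blurs a step density with a 5³ mean kernel, refines the mesh there,
and re-maps — a "magnifying glass" on the tumor for the downstream network.
Predicted cube probabilities are pulled back to brain voxels by
multiplicity-weighted averaging of the inverse-map samples, combined over 5
test-time orientations and up to 3 model slots by Dice-gated ensemble
voting, and converted to labels by a hierarchical WT → TC → ET decision.
Network training itself is out of scope; any callable with the predictor
contract (4-channel cube in, three probability cubes out) plugs in, and an
oracle predictor is included so the whole geometry pipeline is testable
without a GPU.

## Worked example

```python
import numpy as np
from omtcube import (
    PhantomSpec, generate_phantom, oracle_predictor,
    PipelineConfig, run_phase2,
    pullback_probabilities, decide_labels, confusion_metrics,
)

subject = generate_phantom(PhantomSpec(seed=1, grid_shape=(64, 64, 44)))
config = PipelineConfig(gamma=1.0, cube_size=64, ref_resolution=17)
ph2 = run_phase2(subject, None, config, mode="train")  # GT WT region fallback
print("transport cost:", round(ph2.diagnostics["volume"]["transport_cost"], 4))
print("enlarged ratio:", round(ph2.diagnostics["enlarged_ratio"], 3))

probs = oracle_predictor(ph2.label_cubes, noise_sd=0.0)
pulled = pullback_probabilities(ph2.fmap, ph2.mesh, probs,
                                ph2.brain_mask, sampling=ph2.sampling)
labels = decide_labels(pulled.probabilities[1], pulled.probabilities[2],
                       pulled.probabilities[3], ph2.brain_mask)
wt = confusion_metrics(np.isin(subject.labels, (1, 2, 4)),
                       np.isin(labels, (1, 2, 4)))
print("WT Dice:", wt.dice)
```

prints

```
transport cost: 0.0231
enlarged ratio: 1.954
WT Dice: 1.0
```

The transport cost is the residual quadratic displacement of the unit-mass
brain inside the cube; the enlarged ratio is the whole-tumor voxel fraction
in the cube divided by its fraction in the brain (≈2 means the Phase II
density doubled the tumor's share of the tensor); the Dice of 1.0 shows the
cube round trip (rasterize → predict → pull back → decide) is lossless when
the predictor is perfect.

A CLI covers the same steps for NIfTI subject directories in the BraTS
layout:

```sh
omtcube phantom make subj/ --seed 1
omtcube phase1 subj/ out/ --gamma 1.0
omtcube phase2 subj/ out/ --gamma 1.0 --m 5
omtcube validate subj/ out/
omtcube metrics subj/phantom_seg.nii.gz out/prediction_seg.nii.gz
```

## Layout

- `omtcube.mesh` — voxel mask → tetrahedral complex (6-tet Kuhn subdivision),
  normalization, Euclidean dilation, conforming bisection refinement
- `omtcube.density` — CEHE intensity normalization, Phase I/II density
  fields, simplex measures
- `omtcube.surface` — stretch-energy spherical OMT, reference cube surface,
  composed cubic boundary map
- `omtcube.volume` — mass-weighted Laplacian, homotopy V-OMT, transport
  costs and distortion diagnostics
- `omtcube.tensorize` — cube rasterization through the inverse map,
  probability pullback, label decision, enlarged ratio
- `omtcube.metrics` — orientation variants, ensemble voting, Dice /
  sensitivity / specificity / precision, HD95, Dice+CE loss
- `omtcube.phantom` — synthetic BraTS-like subjects and the oracle predictor
- `omtcube.pipeline`, `omtcube.cli`, `omtcube.io` — orchestration, CLI,
  NIfTI I/O
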