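"""NIfTI input/output in the BraTS subject layout.

A subject directory holds ``<name>_flair.nii[.gz]``, ``_t1``, ``_t1ce``,
``_t2`` and optionally ``_seg`` volumes on a shared grid.  Predicted label
volumes are written back with the input's affine/header geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import MODALITIES, PhantomSubject

__all__ = [
    "load_subject",
    "save_subject",
    "save_labels",
    "save_report",
    "export_mesh",
]


def _find(subject_dir: Path, suffix: str) -> Path | None:
    for ext in (".nii.gz", ".nii"):
        hits = sorted(subject_dir.glob(f"*_{suffix}{ext}"))
        if hits:
            return hits[0]
    return None


def load_subject(subject_dir) -> tuple[PhantomSubject, nib.Nifti1Image]:
    """Load a BraTS-layout subject; returns the subject and a reference
    image whose geometry is reused for outputs."""
    subject_dir = Path(subject_dir)
    modalities = {}
    ref = None
    for name in MODALITIES:
        path = _find(subject_dir, name)
        if path is None:
            raise FileNotFoundError(f"missing modality '{name}' in {subject_dir}")
        img = nib.load(str(path))
        modalities[name] = np.asarray(img.dataobj, dtype=float)
        ref = ref or img
    seg_path = _find(subject_dir, "seg")
    labels = None
    if seg_path is not None:
        labels = np.asarray(nib.load(str(seg_path)).dataobj).astype(np.int16)
    spacing = np.asarray(ref.header.get_zooms()[:3], dtype=float)
    mask = np.zeros(modalities["flair"].shape, dtype=bool)
    for vol in modalities.values():
        mask |= vol > 0
    return (
        PhantomSubject(
            modalities=modalities, labels=labels, brain_mask=mask, spacing=spacing
        ),
        ref,
    )


def save_subject(subject: PhantomSubject, subject_dir, name: str = "subject") -> None:
    subject_dir = Path(subject_dir)
    subject_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(subject.spacing) + [1.0])
    for mod in MODALITIES:
        nib.save(
            nib.Nifti1Image(subject.modalities[mod].astype(np.float32), affine),
            str(subject_dir / f"{name}_{mod}.nii.gz"),
        )
    if subject.labels is not None:
        nib.save(
            nib.Nifti1Image(subject.labels.astype(np.int16), affine),
            str(subject_dir / f"{name}_seg.nii.gz"),
        )


def save_labels(labels: np.ndarray, ref: nib.Nifti1Image, path) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(labels).astype(np.int16), ref.affine, ref.header),
        str(path),
    )


def export_mesh(mesh, path, point_data: dict | None = None) -> None:
    """Write the tetrahedral mesh as legacy ASCII VTK (inspection format).

    ``point_data`` maps attribute names to per-vertex scalars (e.g. a
    density field) or per-vertex 3-vectors (e.g. the OMT image coordinates).
    """
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "omtcube tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_vertices} double",
    ]
    lines += [" ".join(f"{x:.17g}" for x in v) for v in mesh.vertices]
    lines.append(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}")
    lines += ["4 " + " ".join(map(str, t)) for t in mesh.tets]
    lines.append(f"CELL_TYPES {mesh.n_tets}")
    lines += ["10"] * mesh.n_tets  # VTK_TETRA
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, values in point_data.items():
            arr = np.asarray(values, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{x:.17g}" for x in arr]
            else:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{x:.17g}" for x in row) for row in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def save_report(report: dict, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        return str(o)

    Path(path).write_text(json.dumps(report, indent=2, default=default))
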