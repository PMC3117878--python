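"""NIfTI-1 and TSV persistence for cohorts, masks, maps and tables.

The synthetic grid uses a diagonal voxel-size affine; all volumes of one
run share it. Cohorts are laid out as one directory with a ``templates/``
subdirectory, per-subject image / lesion / deformation volumes under
``subjects/``, and a two-column subject table (subject_id, group) as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .masks import SearchSpaces
from .simulate import CohortDataset, SubjectRecord, TissueTemplates


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(np.asarray(voxel_size_mm, dtype=float))
    return aff


def save_volume(arr: np.ndarray, path: Path, voxel_size_mm) -> None:
    arr = np.asarray(arr)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int32)
    nib.save(nib.Nifti1Image(arr, _affine(voxel_size_mm)), str(path))


def load_volume(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, voxel_size_mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    voxel_size = np.abs(np.diag(img.affine)[:3])
    return data, voxel_size


def save_cohort(cohort: CohortDataset, outdir: Path) -> None:
    outdir = Path(outdir)
    (outdir / "templates").mkdir(parents=True, exist_ok=True)
    (outdir / "subjects").mkdir(exist_ok=True)
    vs = cohort.templates.voxel_size_mm
    for name in ("brain_mask", "gm_mask", "wm_mask"):
        save_volume(getattr(cohort.templates, name), outdir / "templates" / f"{name}.nii", vs)
    rows = []
    for s in cohort.subjects:
        save_volume(s.image, outdir / "subjects" / f"{s.subject_id}_image.nii", vs)
        save_volume(s.lesion_mask, outdir / "subjects" / f"{s.subject_id}_lesion.nii", vs)
        if s.deformation is not None:
            save_volume(s.deformation, outdir / "subjects" / f"{s.subject_id}_deformation.nii", vs)
        rows.append({"subject_id": s.subject_id, "group": s.group})
    pd.DataFrame(rows).to_csv(outdir / "subjects.tsv", sep="\t", index=False)


def load_cohort(outdir: Path) -> CohortDataset:
    outdir = Path(outdir)
    masks = {}
    vs = None
    for name in ("brain_mask", "gm_mask", "wm_mask"):
        data, vs = load_volume(outdir / "templates" / f"{name}.nii")
        masks[name] = data.astype(bool)
    templates = TissueTemplates(voxel_size_mm=vs, **masks)
    table = pd.read_csv(outdir / "subjects.tsv", sep="\t")
    subjects = []
    for _, row in table.iterrows():
        sid, group = str(row["subject_id"]), str(row["group"])
        image, _ = load_volume(outdir / "subjects" / f"{sid}_image.nii")
        lesion, _ = load_volume(outdir / "subjects" / f"{sid}_lesion.nii")
        dpath = outdir / "subjects" / f"{sid}_deformation.nii"
        deformation = load_volume(dpath)[0] if dpath.exists() else None
        subjects.append(
            SubjectRecord(
                subject_id=sid, group=group, image=image.astype(float),
                lesion_mask=lesion.astype(bool), deformation=deformation,
            )
        )
    n_ms = sum(1 for s in subjects if s.group == "MS")
    return CohortDataset(
        subjects=tuple(subjects), templates=templates,
        n_ms=n_ms, n_hc=len(subjects) - n_ms,
    )


def save_search_spaces(spaces: SearchSpaces, outdir: Path, voxel_size_mm) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("lesion_space", "nagm", "nawm", "nabt"):
        save_volume(getattr(spaces, name), outdir / f"{name}.nii", voxel_size_mm)
    counts = {n: int(getattr(spaces, n).sum()) for n in ("lesion_space", "nagm", "nawm", "nabt")}
    pd.DataFrame([counts]).to_csv(outdir / "mask_summary.tsv", sep="\t", index=False)


def load_search_spaces(outdir: Path) -> SearchSpaces:
    outdir = Path(outdir)
    vols = {
        name: load_volume(outdir / f"{name}.nii")[0].astype(bool)
        for name in ("lesion_space", "nagm", "nawm", "nabt")
    }
    return SearchSpaces(**vols)


def save_4d(stack: np.ndarray, path: Path, voxel_size_mm) -> None:
    """Subject axis last, per convention."""
    save_volume(stack, path, voxel_size_mm)


def write_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_table(df: pd.DataFrame, path: Path) -> None:
    """Deterministic TSV: fixed float formatting so identical runs are
    byte-identical."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
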