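"""Intensity standardization and confound removal.

The chain producing classifier-ready data has three steps, applied in this
order:

1. within-subject intensity standardization — z-scoring each subject's
   image over the brain mask, removing global scale/offset differences
   (e.g. coil loading);
2. (corrected variant only) voxel-wise regression of intensities on the
   local deformation parameters — at every voxel, the N subject intensities
   are replaced by the residuals of an ordinary-least-squares fit on the
   three local displacement components plus an intercept, so that group
   information carried by the spatial-normalization deformations cannot
   leak into the classifier;
3. between-subject z-transformation — every voxel's N-vector is scaled to
   mean 0, SD 1 across subjects.

The variant skipping step 2 is the "uncorrected" data; with step 2 it is the
"corrected" data. Sample standard deviations use the unbiased (N-1)
denominator throughout. The between-subject transform is computed over all
subjects, including the one later used as the leave-one-out test subject,
mirroring the processing order of the original design (the transform
precedes classification); pass ``train_only_z`` to the searchlight engine
for a strictly leakage-free variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .simulate import CohortDataset

logger = logging.getLogger(__name__)

UNCORRECTED = "uncorrected"
CORRECTED = "corrected"


@dataclass(frozen=True)
class PreprocessedCohort:
    """Per-voxel subject-intensity matrix restricted to an analysis mask.

    ``data`` has one row per subject (cohort order) and one column per
    in-mask voxel; ``voxel_index`` maps grid voxels to columns (-1 outside
    the mask) and ``voxel_coords`` is the inverse map. ``provenance``
    records the applied steps in order.
    """

    data: np.ndarray
    mask: np.ndarray
    voxel_index: np.ndarray
    voxel_coords: np.ndarray
    labels: np.ndarray
    subject_ids: tuple[str, ...]
    variant: str
    voxel_size_mm: np.ndarray
    provenance: tuple[str, ...]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def column_of(self, voxel: tuple[int, int, int]) -> int:
        col = int(self.voxel_index[voxel])
        if col < 0:
            raise KeyError(f"voxel {voxel} is outside the analysis mask")
        return col


def standardize_within_subject(image: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Z-score one subject's image over the brain mask; out-of-mask voxels 0.

    Invariant to affine intensity rescaling a·x + b (a > 0) of the input.
    """
    brain_mask = brain_mask.astype(bool)
    vals = image[brain_mask]
    if vals.size < 2:
        raise ValueError("need at least two in-mask voxels")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("constant image inside the brain mask")
    out = np.zeros_like(image, dtype=float)
    out[brain_mask] = (vals - vals.mean()) / sd
    return out


def _index_maps(mask: np.ndarray):
    coords = np.argwhere(mask)
    index = np.full(mask.shape, -1, dtype=np.int64)
    index[tuple(coords.T)] = np.arange(len(coords))
    return index, coords


def _standardized_matrix(cohort: CohortDataset, mask: np.ndarray) -> np.ndarray:
    brain = cohort.templates.brain_mask
    rows = []
    for s in cohort.subjects:
        std = standardize_within_subject(s.image, brain)
        rows.append(std[mask])
    X = np.asarray(rows)
    if not np.isfinite(X).all():
        raise ValueError("non-finite intensities inside the analysis mask")
    return X


def _base(cohort: CohortDataset, mask: np.ndarray, variant: str,
          data: np.ndarray, provenance: tuple[str, ...]) -> PreprocessedCohort:
    index, coords = _index_maps(mask)
    return PreprocessedCohort(
        data=data,
        mask=mask,
        voxel_index=index,
        voxel_coords=coords,
        labels=cohort.labels,
        subject_ids=tuple(s.subject_id for s in cohort.subjects),
        variant=variant,
        voxel_size_mm=cohort.templates.voxel_size_mm,
        provenance=provenance,
    )


def residualize(y: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """OLS residuals of y on [intercept | regressors] across subjects.

    Rank-deficient designs are handled by the minimum-norm least-squares
    solution, whose fitted values (hence residuals) are the projection onto
    the design column space and therefore well defined.
    """
    n = y.shape[0]
    Z = np.column_stack([np.ones(n), regressors])
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ beta, rank < Z.shape[1]


def regress_out_deformation(cohort: CohortDataset, mask: np.ndarray) -> PreprocessedCohort:
    """Standardize, then remove deformation-explained variance per voxel.

    The regressors at each voxel are that voxel's three displacement
    components across subjects. Residuals are exactly orthogonal to every
    regressor column (and to the intercept).
    """
    mask = mask.astype(bool)
    for s in cohort.subjects:
        if s.deformation is None:
            raise ValueError(f"subject {s.subject_id} has no deformation field")
    n = cohort.n_subjects
    if n < 3 + 2:
        raise ValueError("need N >= number of regressors + 2 subjects")
    X = _standardized_matrix(cohort, mask)
    coords = np.argwhere(mask)
    # (N, V, 3) local displacement components
    D = np.stack([s.deformation[tuple(coords.T)] for s in cohort.subjects])
    resid = np.empty_like(X)
    n_deficient = 0
    for j in range(X.shape[1]):
        resid[:, j], deficient = residualize(X[:, j], D[:, j, :])
        n_deficient += bool(deficient)
    if n_deficient:
        logger.warning(
            "rank-deficient deformation regressors at %d voxel(s); "
            "collinear directions dropped", n_deficient,
        )
    return _base(
        cohort, mask, CORRECTED, resid,
        provenance=("standardize_within_subject", "regress_out_deformation"),
    )


def z_transform_between_subjects(pre: PreprocessedCohort) -> PreprocessedCohort:
    """Scale every voxel's subject vector to mean 0, SD 1 (N-1 denominator).

    Zero-variance voxels are set to 0 for all subjects and counted in the
    log. Idempotent up to numerical precision.
    """
    X = pre.data
    if X.shape[0] < 3:
        raise ValueError("need at least three subjects")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        logger.warning("%d zero-variance voxel(s) set to 0", int(zero.sum()))
    safe = np.where(zero, 1.0, sd)
    Z = (X - mean) / safe
    Z[:, zero] = 0.0
    return replace(pre, data=Z, provenance=pre.provenance + ("z_transform_between_subjects",))


def preprocess_cohort(
    cohort: CohortDataset,
    mask: np.ndarray | None = None,
    variant: str = UNCORRECTED,
) -> PreprocessedCohort:
    """Run the full chain for one variant over an analysis mask
    (default: the brain mask)."""
    if variant not in (UNCORRECTED, CORRECTED):
        raise ValueError(f"unknown variant {variant!r}")
    if mask is None:
        mask = cohort.templates.brain_mask
    mask = mask.astype(bool)
    if variant == CORRECTED:
        pre = regress_out_deformation(cohort, mask)
    else:
        X = _standardized_matrix(cohort, mask)
        pre = _base(cohort, mask, UNCORRECTED, X,
                    provenance=("standardize_within_subject",))
    return z_transform_between_subjects(pre)
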