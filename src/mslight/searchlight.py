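"""Searchlight mapping of leave-one-out classification accuracy.

Every voxel of a search space is once the center of a spherical searchlight
(default radius 3 voxels, 123 voxels when untruncated). The searchlight is
intersected with the search space and the grid, so near boundaries it
deviates from the sphere rather than crossing tissue-class borders. For
each center, the subjects' intensity patterns inside the searchlight form
an N x V matrix; leave-one-out cross-validation with a linear soft-margin
SVM predicts every subject's clinical status once, and the balanced
accuracy — the mean of sensitivity and specificity, robust to the unequal
group sizes — is noted at the center voxel.

The classifier is an L2-regularized squared-hinge linear SVM (liblinear)
with fixed cost C = 1; this Newton-SVM-style objective is deterministic
given the data, and decision-value ties are resolved toward the control
class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import LinearSVC

from .preprocess import PreprocessedCohort

#: Liblinear cost parameter (complexity / non-separability tradeoff).
DEFAULT_C = 1.0


@dataclass(frozen=True)
class SearchlightSpec:
    """Radius and precomputed integer offsets of the spherical neighborhood."""

    radius_voxels: int
    offsets: np.ndarray  # (K, 3) int

    @property
    def n_offsets(self) -> int:
        return len(self.offsets)


def sphere_offsets(radius_voxels: int) -> SearchlightSpec:
    """All integer offsets within Euclidean distance ``radius_voxels`` of the
    origin, lexicographically ordered. Radius 3 gives the canonical
    123-voxel searchlight."""
    r = int(radius_voxels)
    if r < 0:
        raise ValueError("radius must be non-negative")
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r**2
    offsets = np.column_stack([dx[keep], dy[keep], dz[keep]])
    return SearchlightSpec(radius_voxels=r, offsets=offsets)


def searchlight_voxels(
    center: tuple[int, int, int],
    spec: SearchlightSpec,
    space_mask: np.ndarray,
) -> np.ndarray:
    """Voxel coordinates of the (possibly truncated) searchlight at a center:
    (center + offsets) ∩ grid ∩ space mask. Always contains the center."""
    space_mask = np.asarray(space_mask, dtype=bool)
    center = np.asarray(center, dtype=int)
    if not space_mask[tuple(center)]:
        raise ValueError(f"center {tuple(center)} is outside the search space")
    pts = center + spec.offsets
    inside = np.all((pts >= 0) & (pts < np.asarray(space_mask.shape)), axis=1)
    pts = pts[inside]
    keep = space_mask[tuple(pts.T)]
    return pts[keep]


def extract_pattern_matrix(data: PreprocessedCohort, voxels: np.ndarray) -> np.ndarray:
    """N x V matrix: one row per subject (cohort order), one column per
    searchlight voxel, in the given voxel order."""
    voxels = np.atleast_2d(np.asarray(voxels, dtype=int))
    if voxels.shape[0] < 1:
        raise ValueError("need at least one voxel")
    cols = data.voxel_index[tuple(voxels.T)]
    if np.any(cols < 0):
        bad = voxels[cols < 0][0]
        raise ValueError(f"voxel {tuple(bad)} is outside the preprocessed mask")
    M = data.data[:, cols]
    if not np.isfinite(M).all():
        i = np.argwhere(~np.isfinite(M))[0]
        raise ValueError(f"non-finite intensity at voxel {tuple(voxels[i[1]])}")
    return M


@dataclass(frozen=True)
class LinearDecisionRule:
    """Linear decision boundary w·x + b; predicts patient (1) for strictly
    positive decision values, control (0) otherwise (ties -> control)."""

    weights: np.ndarray
    bias: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision(X) > 0).astype(int)


def train_linear_classifier(
    train_matrix: np.ndarray, train_labels: np.ndarray, C: float = DEFAULT_C
) -> LinearDecisionRule:
    """Fit the linear soft-margin SVM on a training set containing both
    classes; deterministic given the data."""
    y = np.asarray(train_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    clf = LinearSVC(
        C=C, loss="squared_hinge", dual=True, random_state=0,
        max_iter=20000, tol=1e-4,
    )
    clf.fit(np.asarray(train_matrix, dtype=float), y)
    return LinearDecisionRule(weights=clf.coef_.ravel().copy(), bias=float(clf.intercept_[0]))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion of the cross-validated predictions; patient (MS) is the
    positive class, so tp + fn = N_MS and tn + fp = N_HC."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_ms(self) -> int:
        return self.tp + self.fn

    @property
    def n_hc(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.n_ms + self.n_hc


def balanced_accuracy(c: ConfusionCounts) -> float:
    """Mean of sensitivity and specificity, in percent."""
    if c.n_ms < 1 or c.n_hc < 1:
        raise ValueError("both classes must be represented")
    sens = c.tp / c.n_ms
    spec = c.tn / c.n_hc
    return 100.0 * (sens + spec) / 2.0


def loo_cv(
    matrix: np.ndarray,
    labels: np.ndarray,
    C: float = DEFAULT_C,
    fold_z: bool = False,
) -> ConfusionCounts:
    """Leave-one-out cross-validation: N folds, each training on N-1 rows and
    predicting the held-out subject exactly once.

    ``fold_z=True`` re-standardizes each column from the training rows only
    (strict train-only between-subject transform); feed data that has not
    already been z-transformed across all subjects in that mode.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if n < 4:
        raise ValueError("need at least four subjects")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least two subjects per class")
    tp = fn = tn = fp = 0
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        Xtr, Xte = X[train], X[i]
        if fold_z:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=1)
            sd = np.where(sd == 0, 1.0, sd)
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        try:
            rule = train_linear_classifier(Xtr, y[train], C=C)
        except ValueError as err:
            raise ValueError(f"classifier failure in fold {i}: {err}") from err
        pred = int(rule.predict(Xte)[0])
        if y[i] == 1:
            tp += pred
            fn += 1 - pred
        else:
            tn += 1 - pred
            fp += pred
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


@dataclass(frozen=True)
class AccuracyMap:
    """Per-center balanced accuracy map with its confusion bookkeeping.

    ``accuracy_pct`` is NaN outside searchlight centers; ``n_voxels`` holds
    the searchlight size after boundary truncation; the four count grids
    hold the per-center confusion (-1 outside centers).
    """

    accuracy_pct: np.ndarray
    n_voxels: np.ndarray
    tp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    spec: SearchlightSpec
    variant: str
    space: str
    voxel_size_mm: np.ndarray

    @property
    def center_mask(self) -> np.ndarray:
        return ~np.isnan(self.accuracy_pct)

    @property
    def centers(self) -> np.ndarray:
        return np.argwhere(self.center_mask)

    def confusion_at(self, center: tuple[int, int, int]) -> ConfusionCounts:
        c = tuple(center)
        if not self.center_mask[c]:
            raise KeyError(f"{c} is not a searchlight center")
        return ConfusionCounts(
            tp=int(self.tp[c]), fn=int(self.fn[c]),
            tn=int(self.tn[c]), fp=int(self.fp[c]),
        )


def map_searchlights(
    data: PreprocessedCohort,
    space_mask: np.ndarray,
    spec: SearchlightSpec,
    C: float = DEFAULT_C,
    space: str = "space",
    fold_z: bool = False,
) -> AccuracyMap:
    """Run the LOO searchlight at every voxel of the search space.

    Deterministic given the data; invariant to subject order.
    """
    space_mask = np.asarray(space_mask, dtype=bool)
    if not space_mask.any():
        raise ValueError("search space is empty")
    shape = space_mask.shape
    acc = np.full(shape, np.nan)
    nvox = np.zeros(shape, dtype=np.int64)
    tp = np.full(shape, -1, dtype=np.int64)
    fn = np.full(shape, -1, dtype=np.int64)
    tn = np.full(shape, -1, dtype=np.int64)
    fp = np.full(shape, -1, dtype=np.int64)
    for center in np.argwhere(space_mask):
        voxels = searchlight_voxels(tuple(center), spec, space_mask)
        M = extract_pattern_matrix(data, voxels)
        c = loo_cv(M, data.labels, C=C, fold_z=fold_z)
        t = tuple(center)
        acc[t] = balanced_accuracy(c)
        nvox[t] = len(voxels)
        tp[t], fn[t], tn[t], fp[t] = c.tp, c.fn, c.tn, c.fp
    return AccuracyMap(
        accuracy_pct=acc, n_voxels=nvox, tp=tp, fn=fn, tn=tn, fp=fp,
        spec=spec, variant=data.variant, space=space,
        voxel_size_mm=data.voxel_size_mm,
    )
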