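"""Significance maps, clusters and per-region summaries.

Accuracy maps are converted to p-value maps with a Pearson chi-square test
on each center's 2x2 confusion table (true class x predicted class, 1 df,
upper tail). Family-wise error is controlled by Bonferroni correction over
the searchlight centers of the analyzed space; an optional cluster-size
criterion keeps only connected components of at least k significant
centers. Each surviving cluster is summarized in the style of the original
tables: cluster size CS, peak coordinate (voxel and mm), peak decoding
accuracy DA(%), its p-value, the percentage of underlying voxels with a
significant univariate group difference (Vox*%), and the mean t-value over
those voxels (Mn t, patients minus controls).

The lesion-presence accuracy bound quantifies how much accuracy lesion
presence alone could yield: with controls lesion-free, specificity is 1 and
sensitivity is at most the fraction of patients carrying a lesion, so the
balanced accuracy is bounded by 100 * (n_with_lesion / n_patients + 1) / 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .preprocess import PreprocessedCohort
from .searchlight import AccuracyMap, ConfusionCounts, SearchlightSpec, searchlight_voxels

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignificanceConfig:
    """Thresholds of the significance machinery.

    ``alpha_fwe`` is the Bonferroni family-wise level; ``alpha_fwe_relaxed``
    the relaxed level used for the corrected-data normal-appearing
    analyses; ``alpha_uncorrected_trend`` the per-center trend level;
    ``cluster_k`` the minimum connected-component size where the cluster
    criterion applies; ``connectivity`` one of 6/18/26 neighbor rules.
    """

    alpha_fwe: float = 0.05
    alpha_fwe_relaxed: float = 0.1
    alpha_uncorrected_trend: float = 0.001
    cluster_k: int = 5
    connectivity: int = 26
    alpha_vox: float = 0.001

    def __post_init__(self) -> None:
        for a in (self.alpha_fwe, self.alpha_fwe_relaxed,
                  self.alpha_uncorrected_trend, self.alpha_vox):
            if not 0.0 < a < 1.0:
                raise ValueError("alpha levels must lie in (0, 1)")
        if self.cluster_k < 1:
            raise ValueError("cluster_k must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass(frozen=True)
class ThresholdRegime:
    """How one (space, variant) analysis is thresholded."""

    alpha_fwe: float
    cluster_k: int
    trend: bool  # additionally report p_uncorrected < trend level


def threshold_regime(space: str, variant: str, cfg: SignificanceConfig) -> ThresholdRegime:
    """Per-analysis presets: the lesion/uncorrected analysis uses FWE 0.05
    plus the cluster-size criterion k; the other uncorrected analyses and
    lesion/corrected use FWE 0.05 alone; corrected normal-appearing
    analyses use the relaxed FWE level plus uncorrected-trend reporting."""
    if space == "lesion" and variant == "uncorrected":
        return ThresholdRegime(cfg.alpha_fwe, cfg.cluster_k, trend=False)
    if variant == "uncorrected" or space == "lesion":
        return ThresholdRegime(cfg.alpha_fwe, 1, trend=False)
    return ThresholdRegime(cfg.alpha_fwe_relaxed, 1, trend=True)


def accuracy_pvalue(c: ConfusionCounts) -> float:
    """Upper-tail Pearson chi-square p-value (1 df) of the confusion table.

    Degenerate margins (a class never present or never predicted) give
    p = 1: no evidence of association.
    """
    n = c.n
    r1, r2 = c.n_ms, c.n_hc
    c1, c2 = c.tp + c.fp, c.fn + c.tn
    if min(r1, r2, c1, c2) == 0:
        logger.warning("degenerate confusion margins, p set to 1: %s", c)
        return 1.0
    stat = n * (c.tp * c.tn - c.fp * c.fn) ** 2 / (r1 * r2 * c1 * c2)
    p = float(sps.chi2.sf(stat, df=1))
    return max(p, np.nextafter(0.0, 1.0))


def pvalue_map(acc: AccuracyMap) -> np.ndarray:
    """Per-center chi-square p-values (NaN outside centers)."""
    p = np.full(acc.accuracy_pct.shape, np.nan)
    for center in acc.centers:
        t = tuple(center)
        p[t] = accuracy_pvalue(acc.confusion_at(t))
    return p


def bonferroni(p_map: np.ndarray, alpha: float) -> np.ndarray:
    """Significance mask at family-wise level alpha: center significant iff
    p <= alpha / m, with m the number of defined centers."""
    defined = ~np.isnan(p_map)
    m = int(defined.sum())
    if m < 1:
        raise ValueError("no defined centers")
    sig = np.zeros(p_map.shape, dtype=bool)
    sig[defined] = p_map[defined] <= alpha / m
    return sig


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def cluster_filter(sig_mask: np.ndarray, k: int, connectivity: int = 26) -> list[np.ndarray]:
    """Connected components of the significance mask with at least k
    members, as (n, 3) coordinate arrays, largest first."""
    if k < 1:
        raise ValueError("k must be >= 1")
    labeled, n_lab = ndimage.label(np.asarray(sig_mask, bool), structure=_structure(connectivity))
    clusters = []
    for lab in range(1, n_lab + 1):
        coords = np.argwhere(labeled == lab)
        if len(coords) >= k:
            clusters.append(coords)
    clusters.sort(key=lambda c: (-len(c), tuple(c[0])))
    return clusters


def voxelwise_t_contrast(data: PreprocessedCohort, voxels: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t statistic per voxel, patients minus
    controls, N - 2 degrees of freedom. Zero pooled variance yields NaN."""
    voxels = np.atleast_2d(np.asarray(voxels, dtype=int))
    cols = data.voxel_index[tuple(voxels.T)]
    if np.any(cols < 0):
        raise ValueError("a requested voxel lies outside the preprocessed mask")
    X = data.data[:, cols]
    ms = X[data.labels == 1]
    hc = X[data.labels == 0]
    n1, n2 = len(ms), len(hc)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two subjects per group")
    diff = ms.mean(axis=0) - hc.mean(axis=0)
    sp2 = ((n1 - 1) * ms.var(axis=0, ddof=1) + (n2 - 1) * hc.var(axis=0, ddof=1)) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.nan)
    n_flag = int(np.isnan(t).sum())
    if n_flag:
        logger.warning("t undefined (zero pooled variance) at %d voxel(s)", n_flag)
    return t


def t_contrast_map(data: PreprocessedCohort, mask: np.ndarray) -> np.ndarray:
    """Full-grid t map over an analysis mask (NaN outside)."""
    mask = np.asarray(mask, bool)
    coords = np.argwhere(mask)
    out = np.full(mask.shape, np.nan)
    out[tuple(coords.T)] = voxelwise_t_contrast(data, coords)
    return out


@dataclass(frozen=True)
class ClusterRow:
    """One reported cluster, mirroring the published table layout."""

    space: str
    variant: str
    cs: int
    peak_voxel: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    da_pct: float
    p: float
    vox_star_pct: float
    mean_t: float
    trend: bool = False


def cluster_summary(
    cluster: np.ndarray,
    spec: SearchlightSpec,
    acc: AccuracyMap,
    t_map: np.ndarray,
    alpha_vox: float,
    data_df: int,
    space_mask: np.ndarray | None = None,
    trend: bool = False,
) -> ClusterRow:
    """Summarize one cluster of significant searchlight centers.

    The underlying voxel set is the union of the (truncated) searchlights of
    all cluster centers. Vox*% counts underlying voxels whose two-sided
    pooled-t p-value is below ``alpha_vox``; Mn t averages t over them. The
    peak is the center with maximal accuracy, ties broken toward the
    lexicographically smallest coordinate.
    """
    cluster = np.atleast_2d(np.asarray(cluster, dtype=int))
    if len(cluster) == 0:
        raise ValueError("empty cluster")
    if space_mask is None:
        space_mask = acc.center_mask
    order = np.lexsort(cluster.T[::-1])
    cluster = cluster[order]
    accs = acc.accuracy_pct[tuple(cluster.T)]
    peak = tuple(int(v) for v in cluster[int(np.argmax(accs))])

    underlying = set()
    for center in cluster:
        for v in searchlight_voxels(tuple(center), spec, space_mask):
            underlying.add(tuple(int(i) for i in v))
    under = np.array(sorted(underlying))
    t_vals = t_map[tuple(under.T)]
    finite = np.isfinite(t_vals)
    t_fin = t_vals[finite]
    t_crit = sps.t.ppf(1.0 - alpha_vox / 2.0, df=data_df)
    vox_star = 100.0 * float((np.abs(t_fin) > t_crit).sum()) / len(t_vals) if len(t_vals) else 0.0
    mean_t = float(t_fin.mean()) if len(t_fin) else float("nan")

    return ClusterRow(
        space=acc.space,
        variant=acc.variant,
        cs=int(len(cluster)),
        peak_voxel=peak,
        peak_mm=tuple(float(x) for x in np.asarray(peak) * acc.voxel_size_mm),
        da_pct=float(acc.accuracy_pct[peak]),
        p=accuracy_pvalue(acc.confusion_at(peak)),
        vox_star_pct=vox_star,
        mean_t=mean_t,
        trend=trend,
    )


@dataclass
class SpaceSummary:
    """Thresholding result for one (space, variant) analysis."""

    p_map: np.ndarray
    sig_mask: np.ndarray
    rows: list[ClusterRow] = field(default_factory=list)


def summarize_space(
    acc: AccuracyMap,
    data: PreprocessedCohort,
    cfg: SignificanceConfig,
    space_mask: np.ndarray | None = None,
) -> SpaceSummary:
    """Full significance pipeline for one accuracy map: p-values, Bonferroni
    mask (per-analysis regime), cluster filter, per-cluster summaries, and
    — for regimes with trend reporting — additional uncorrected-trend
    clusters."""
    if space_mask is None:
        space_mask = acc.center_mask
    regime = threshold_regime(acc.space, acc.variant, cfg)
    p = pvalue_map(acc)
    # The chi-square statistic is sign-blind; only above-chance accuracies
    # count as diagnostic information.
    above_chance = np.nan_to_num(acc.accuracy_pct, nan=0.0) > 50.0
    sig = bonferroni(p, regime.alpha_fwe) & above_chance
    t_map = t_contrast_map(data, space_mask)
    df = data.n_subjects - 2
    rows = [
        cluster_summary(cl, acc.spec, acc, t_map, cfg.alpha_vox, df,
                        space_mask=space_mask)
        for cl in cluster_filter(sig, regime.cluster_k, cfg.connectivity)
    ]
    if regime.trend:
        defined = ~np.isnan(p)
        trend_mask = np.zeros(p.shape, bool)
        trend_mask[defined] = p[defined] < cfg.alpha_uncorrected_trend
        trend_mask &= above_chance & ~sig
        rows += [
            cluster_summary(cl, acc.spec, acc, t_map, cfg.alpha_vox, df,
                            space_mask=space_mask, trend=True)
            for cl in cluster_filter(trend_mask, 1, cfg.connectivity)
        ]
    rows.sort(key=lambda r: (r.trend, -r.da_pct, r.peak_voxel))
    return SpaceSummary(p_map=p, sig_mask=sig, rows=rows)


def cluster_table(rows: list[ClusterRow]) -> pd.DataFrame:
    """Tabular view with the published column names (CS, x, y, z, DA(%), p,
    Mn t, Vox*(%)); coordinates in mm."""
    return pd.DataFrame(
        [
            {
                "space": r.space,
                "variant": r.variant,
                "CS": r.cs,
                "x": r.peak_mm[0],
                "y": r.peak_mm[1],
                "z": r.peak_mm[2],
                "DA(%)": round(r.da_pct),
                "p": r.p,
                "Mn t": r.mean_t,
                "Vox*(%)": r.vox_star_pct,
                "trend": r.trend,
            }
            for r in rows
        ],
        columns=["space", "variant", "CS", "x", "y", "z", "DA(%)", "p",
                 "Mn t", "Vox*(%)", "trend"],
    )


def lesion_presence_bound(n_with_lesion: int, n_patients: int) -> float:
    """Maximal balanced accuracy (percent) attainable from lesion presence
    alone, controls being lesion-free."""
    if n_patients < 1:
        raise ValueError("need at least one patient")
    if not 0 <= n_with_lesion <= n_patients:
        raise ValueError("n_with_lesion must lie in [0, n_patients]")
    return 100.0 * (n_with_lesion / n_patients + 1.0) / 2.0
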