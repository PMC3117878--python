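"""Synthetic two-group structural-MRI cohorts.

Generates phantom cohorts with the statistical structure the searchlight
analysis assumes: a nested-ellipsoid brain with a white-matter core and a
grey-matter shell, focal hyperintense white-matter lesions present in only a
subset of patients, subtle distributed hyperintensity in normal-appearing
white matter (NAWM) and hypointensity in normal-appearing grey matter (NAGM)
of patients, and smooth per-subject deformation fields whose statistics may
differ by group. Every generator is a pure function of its parameters and a
seed, so cohorts replay bit-identically.

Intensities are in arbitrary units (white matter 1.0, grey matter 0.8,
background 0 before noise); downstream standardization makes the absolute
scale irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

MS = "MS"
HC = "HC"

#: Study-sized cohort: 41 relapsing-remitting patients, 26 matched controls.
DEFAULT_N_MS = 41
DEFAULT_N_HC = 26

#: Fraction of patients carrying a lesion at the default site (19 of 41).
DEFAULT_LESION_PRESENCE = 19.0 / 41.0


@dataclass(frozen=True)
class TissueTemplates:
    """Binary tissue templates on a common voxel grid.

    Grey and white matter are disjoint and both contained in the brain mask.
    ``voxel_size_mm`` defines the (diagonal) affine used when voxel indices
    are reported as millimetre coordinates.
    """

    brain_mask: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    voxel_size_mm: np.ndarray

    def __post_init__(self) -> None:
        for name in ("brain_mask", "gm_mask", "wm_mask"):
            m = getattr(self, name)
            if m.dtype != bool:
                object.__setattr__(self, name, m.astype(bool))
        object.__setattr__(
            self, "voxel_size_mm", np.asarray(self.voxel_size_mm, dtype=float)
        )
        if not (self.gm_mask.shape == self.wm_mask.shape == self.brain_mask.shape):
            raise ValueError("tissue masks must share one grid shape")
        if np.any(self.gm_mask & self.wm_mask):
            raise ValueError("grey and white matter templates overlap")
        if np.any((self.gm_mask | self.wm_mask) & ~self.brain_mask):
            raise ValueError("tissue templates extend outside the brain mask")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.brain_mask.shape

    @property
    def affine(self) -> np.ndarray:
        """Diagonal voxel-to-mm affine of the synthetic grid."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        return aff


@dataclass(frozen=True)
class LesionSite:
    """A candidate focal lesion: an ellipsoidal blob in mm units.

    ``presence_probability`` is the per-patient Bernoulli probability that
    the site carries a lesion; ``intensity_delta`` is added to the image
    inside the blob when present (hyperintense for positive values).
    """

    center: tuple[int, int, int]
    radius_mm: float
    presence_probability: float
    intensity_delta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.presence_probability <= 1.0:
            raise ValueError("presence_probability must lie in [0, 1]")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


@dataclass(frozen=True)
class EffectConfig:
    """Generative parameters encoding the group differences to plant.

    ``nawm_delta`` (>= 0) is a distributed hyperintensity added to patient
    white matter; ``nagm_delta`` (<= 0) a distributed hypointensity added to
    patient grey matter. ``deformation_group_shift`` offsets the mean of the
    first deformation component inside the white-matter core for patients
    only, so deformation statistics can differ by group.
    """

    lesion_sites: tuple[LesionSite, ...] = ()
    nawm_delta: float = 0.0
    nagm_delta: float = 0.0
    noise_sd: float = 0.2
    deformation_group_shift: float = 0.0
    nawm_region: np.ndarray | None = None
    nagm_region: np.ndarray | None = None
    deformation_sd_mm: float = 0.5
    deformation_smoothness_vox: float = 2.0
    include_deformation: bool = True

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.nawm_delta < 0:
            raise ValueError("nawm_delta must be >= 0 (patient hyperintensity)")
        if self.nagm_delta > 0:
            raise ValueError("nagm_delta must be <= 0 (patient hypointensity)")
        object.__setattr__(self, "lesion_sites", tuple(self.lesion_sites))

    def null(self) -> "EffectConfig":
        """Copy with every group effect removed (lesion sites keep their
        geometry and presence probability but add zero intensity)."""
        sites = tuple(replace(s, intensity_delta=0.0) for s in self.lesion_sites)
        return replace(
            self,
            lesion_sites=sites,
            nawm_delta=0.0,
            nagm_delta=0.0,
            deformation_group_shift=0.0,
        )


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: image volume, lesion mask, group label, optional
    deformation field (3 mm-valued components, stacked on the last axis)."""

    subject_id: str
    group: str
    image: np.ndarray
    lesion_mask: np.ndarray
    deformation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.group not in (MS, HC):
            raise ValueError(f"group must be {MS!r} or {HC!r}, got {self.group!r}")
        if self.group == HC and self.lesion_mask.any():
            raise ValueError("healthy controls must have empty lesion masks")
        if self.image.shape != self.lesion_mask.shape:
            raise ValueError("image and lesion mask grids differ")


@dataclass(frozen=True)
class CohortDataset:
    """Ordered subjects on a shared grid plus the tissue templates."""

    subjects: tuple[SubjectRecord, ...]
    templates: TissueTemplates
    n_ms: int
    n_hc: int
    effect_config: EffectConfig | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        if self.n_ms + self.n_hc != len(self.subjects):
            raise ValueError("n_ms + n_hc must equal the number of subjects")
        for s in self.subjects:
            if s.image.shape != self.templates.grid_shape:
                raise ValueError(f"subject {s.subject_id} is not on the template grid")

    @property
    def labels(self) -> np.ndarray:
        """Integer labels, patients (MS) = 1, controls (HC) = 0."""
        return np.array([1 if s.group == MS else 0 for s in self.subjects])

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    d2 = sum(
        ((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes)
    )
    return d2 <= 1.0


def _sphere_structure(radius: int) -> np.ndarray:
    n = 2 * radius + 1
    c = radius
    idx = np.indices((n, n, n))
    return ((idx - c) ** 2).sum(axis=0) <= radius**2


def make_tissue_templates(
    grid_shape: tuple[int, int, int],
    seed: int,
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> TissueTemplates:
    """Build a nested-ellipsoid phantom: brain envelope, white-matter core,
    grey-matter shell.

    The seed jitters the ellipsoid semi-axes slightly so distinct template
    realizations exist; the layout is deterministic given the seed. Raises
    ``ValueError`` if any axis is shorter than 16 voxels or if the white
    matter core cannot contain a radius-3 searchlight sphere entirely.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3:
        raise ValueError("grid_shape must have three axes")
    if min(grid_shape) < 16:
        raise ValueError("each grid axis must be at least 16 voxels")
    rng = np.random.default_rng(seed)
    shape = np.asarray(grid_shape, dtype=float)
    center = (shape - 1.0) / 2.0
    brain_ax = 0.46 * shape * rng.uniform(0.96, 1.0, size=3)
    wm_ax = 0.55 * brain_ax
    gm_inner = 0.68 * brain_ax
    gm_outer = 0.95 * brain_ax

    brain = _ellipsoid(grid_shape, center, brain_ax)
    wm = _ellipsoid(grid_shape, center, wm_ax)
    gm = _ellipsoid(grid_shape, center, gm_outer) & ~_ellipsoid(
        grid_shape, center, gm_inner
    )

    core = ndimage.binary_erosion(wm, structure=_sphere_structure(3))
    if not core.any():
        raise ValueError(
            "grid too small: white matter cannot contain a radius-3 searchlight"
        )
    return TissueTemplates(
        brain_mask=brain, gm_mask=gm, wm_mask=wm,
        voxel_size_mm=np.asarray(voxel_size_mm, dtype=float),
    )


def default_effect_config(templates: TissueTemplates) -> EffectConfig:
    """Study-condition effects: one white-matter lesion site carried by
    19/41 of patients with a strong hyperintense delta, subtle distributed
    NAWM hyperintensity and NAGM hypointensity, and a group-dependent
    deformation mean shift."""
    site_center = _wm_interior_voxel(templates)
    site = LesionSite(
        center=site_center,
        radius_mm=4.0,
        presence_probability=DEFAULT_LESION_PRESENCE,
        intensity_delta=1.0,
    )
    return EffectConfig(
        lesion_sites=(site,),
        nawm_delta=0.06,
        nagm_delta=-0.06,
        noise_sd=0.2,
        deformation_group_shift=0.5,
    )


def _wm_interior_voxel(templates: TissueTemplates) -> tuple[int, int, int]:
    """A voxel of the white-matter core far enough from its boundary to host
    a radius-3 searchlight (the deepest such voxel)."""
    dist = ndimage.distance_transform_edt(templates.wm_mask)
    idx = np.unravel_index(int(np.argmax(dist)), templates.grid_shape)
    return tuple(int(i) for i in idx)


def lesion_blob(site: LesionSite, templates: TissueTemplates) -> np.ndarray:
    """Binary ellipsoidal blob of the site, radius in mm converted to voxels
    per axis (anisotropic voxels supported)."""
    semi_axes = site.radius_mm / templates.voxel_size_mm
    return _ellipsoid(templates.grid_shape, np.asarray(site.center, float), semi_axes)


def _validate_sites(cfg: EffectConfig, templates: TissueTemplates) -> None:
    for site in cfg.lesion_sites:
        blob = lesion_blob(site, templates)
        if not blob.any():
            raise ValueError(f"lesion site {site.center} produces an empty blob")
        if np.any(blob & ~templates.wm_mask):
            raise ValueError(
                f"lesion site {site.center} extends outside the white matter template"
            )


def _smooth_field(rng: np.random.Generator, shape, smoothness: float, sd: float):
    """Gaussian random field per component: white noise smoothed and rescaled
    to the requested marginal standard deviation."""
    field3 = np.empty(shape + (3,))
    for c in range(3):
        w = rng.standard_normal(shape)
        s = ndimage.gaussian_filter(w, sigma=smoothness)
        s_sd = s.std()
        field3[..., c] = s * (sd / s_sd) if s_sd > 0 else 0.0
    return field3


def simulate_subject(
    templates: TissueTemplates,
    group: str,
    cfg: EffectConfig,
    seed: int,
    subject_id: str | None = None,
) -> SubjectRecord:
    """Draw one subject.

    Baseline intensity is the tissue-class mean (WM 1.0, GM 0.8, background
    0) plus i.i.d. Gaussian noise inside the brain. For patients each lesion
    site is independently present with its presence probability; present
    sites add their intensity delta and mark the lesion mask. Distributed
    NAWM/NAGM deltas apply to patients only. The deformation field is a
    smooth Gaussian random field whose first component acquires a group mean
    offset inside the white-matter core when ``deformation_group_shift`` is
    nonzero.
    """
    if group not in (MS, HC):
        raise ValueError(f"unknown group {group!r}")
    _validate_sites(cfg, templates)
    rng = np.random.default_rng(seed)
    shape = templates.grid_shape

    image = np.zeros(shape)
    image[templates.wm_mask] = 1.0
    image[templates.gm_mask] = 0.8
    noise = rng.normal(0.0, cfg.noise_sd, size=shape)
    image[templates.brain_mask] += noise[templates.brain_mask]

    lesion_mask = np.zeros(shape, dtype=bool)
    if group == MS:
        for site in cfg.lesion_sites:
            if rng.random() < site.presence_probability:
                blob = lesion_blob(site, templates)
                image[blob] += site.intensity_delta
                lesion_mask |= blob
        nawm_region = cfg.nawm_region if cfg.nawm_region is not None else templates.wm_mask
        nagm_region = cfg.nagm_region if cfg.nagm_region is not None else templates.gm_mask
        image[nawm_region] += cfg.nawm_delta
        image[nagm_region] += cfg.nagm_delta

    deformation = None
    if cfg.include_deformation:
        deformation = _smooth_field(
            rng, shape, cfg.deformation_smoothness_vox, cfg.deformation_sd_mm
        )
        if group == MS and cfg.deformation_group_shift != 0.0:
            deformation[..., 0][templates.wm_mask] += cfg.deformation_group_shift

    if subject_id is None:
        subject_id = f"{group}-{seed}"
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        image=image,
        lesion_mask=lesion_mask,
        deformation=deformation,
    )


def simulate_cohort(
    n_ms: int = DEFAULT_N_MS,
    n_hc: int = DEFAULT_N_HC,
    cfg: EffectConfig | None = None,
    seed: int = 0,
    templates: TissueTemplates | None = None,
    grid_shape: tuple[int, int, int] = (24, 24, 24),
) -> CohortDataset:
    """Draw a full two-group cohort (defaults: 41 patients, 26 controls).

    Subject seeds are spawned from the master seed, so the cohort is a pure
    function of ``(parameters, seed)``.
    """
    if n_ms < 2 or n_hc < 2:
        raise ValueError("need at least two subjects per group")
    ss = np.random.SeedSequence(seed)
    template_seed, subject_root = ss.spawn(2)
    if templates is None:
        templates = make_tissue_templates(
            grid_shape, seed=int(template_seed.generate_state(1)[0] % (2**31))
        )
    if cfg is None:
        cfg = default_effect_config(templates)

    child_seeds = subject_root.spawn(n_ms + n_hc)
    subjects = []
    for i in range(n_ms + n_hc):
        group = MS if i < n_ms else HC
        idx = i + 1 if group == MS else i - n_ms + 1
        subjects.append(
            simulate_subject(
                templates,
                group,
                cfg,
                seed=int(child_seeds[i].generate_state(1)[0] % (2**31)),
                subject_id=f"{group}{idx:03d}",
            )
        )
    return CohortDataset(
        subjects=tuple(subjects),
        templates=templates,
        n_ms=n_ms,
        n_hc=n_hc,
        effect_config=cfg,
    )
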