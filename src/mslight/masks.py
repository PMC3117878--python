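"""Group-level search spaces: lesion area, NAGM, NAWM, NABT.

The group lesion mask is the union over subjects of individual lesion masks
(voxels where a lesion occurred in at least one subject), intersected with
the brain mask. Combining it with the grey/white templates yields the
normal-appearing search spaces: NAGM and NAWM are the template voxels that
contained no lesion in any subject, and NABT is their union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import CohortDataset, TissueTemplates


@dataclass(frozen=True)
class SearchSpaces:
    """The three tissue-specific search spaces plus their NABT union.

    Invariants: NAGM and NAWM are disjoint from the lesion space and from
    each other, NAGM lies within the grey template, NAWM within the white
    template, and NABT = NAGM ∪ NAWM.
    """

    lesion_space: np.ndarray
    nagm: np.ndarray
    nawm: np.ndarray
    nabt: np.ndarray

    def __post_init__(self) -> None:
        for name in ("lesion_space", "nagm", "nawm", "nabt"):
            object.__setattr__(self, name, getattr(self, name).astype(bool))
        if np.any(self.nagm & self.lesion_space) or np.any(self.nawm & self.lesion_space):
            raise ValueError("normal-appearing spaces overlap the lesion space")
        if np.any(self.nagm & self.nawm):
            raise ValueError("NAGM and NAWM overlap")
        if np.any(self.nabt != (self.nagm | self.nawm)):
            raise ValueError("NABT must equal NAGM ∪ NAWM")

    def __getitem__(self, name: str) -> np.ndarray:
        key = {"lesion": "lesion_space", "nagm": "nagm", "nawm": "nawm", "nabt": "nabt"}[name]
        return getattr(self, key)


def group_lesion_mask(cohort: CohortDataset) -> np.ndarray:
    """Union of all subjects' lesion masks, restricted to the brain mask."""
    if cohort.n_subjects == 0:
        raise ValueError("cohort is empty")
    shape = cohort.templates.grid_shape
    union = np.zeros(shape, dtype=bool)
    for s in cohort.subjects:
        if s.lesion_mask.shape != shape:
            raise ValueError(f"subject {s.subject_id} lesion mask is not on the grid")
        union |= s.lesion_mask.astype(bool)
    return union & cohort.templates.brain_mask


def tissue_search_spaces(
    group_lesion: np.ndarray, templates: TissueTemplates
) -> SearchSpaces:
    """Carve the normal-appearing spaces out of the tissue templates.

    NAGM/NAWM are template voxels free of lesions across the whole sample;
    lesion voxels outside both templates stay in the lesion space (the
    lesion analysis searches all lesioned tissue, not one tissue class).
    """
    group_lesion = group_lesion.astype(bool)
    if group_lesion.shape != templates.grid_shape:
        raise ValueError("group lesion mask is not on the template grid")
    nagm = templates.gm_mask & ~group_lesion
    nawm = templates.wm_mask & ~group_lesion
    return SearchSpaces(
        lesion_space=group_lesion,
        nagm=nagm,
        nawm=nawm,
        nabt=nagm | nawm,
    )


def mask_summary(spaces: SearchSpaces) -> dict[str, int]:
    """Voxel counts per search space (auditing aid; these sizes set the
    Bonferroni correction factor of each analysis)."""
    return {
        "lesion": int(spaces.lesion_space.sum()),
        "nagm": int(spaces.nagm.sum()),
        "nawm": int(spaces.nawm.sum()),
        "nabt": int(spaces.nabt.sum()),
    }
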