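"""Simulate a two-group phantom cohort and build its search spaces.

The generator plants the study conditions: a focal white-matter lesion site
carried by ~46% of patients (19/41) with a strong hyperintense delta,
subtle distributed NAWM hyperintensity / NAGM hypointensity, and a
group-dependent deformation shift.
"""

import mslight as m

templates = m.make_tissue_templates((24, 24, 24), seed=1)
cfg = m.default_effect_config(templates)
cohort = m.simulate_cohort(20, 13, cfg=cfg, seed=4, templates=templates)

carriers = sum(s.lesion_mask.any() for s in cohort.subjects if s.group == m.MS)
print(f"cohort: {cohort.n_ms} patients, {cohort.n_hc} controls")
print(f"lesion carriers among patients: {carriers}/{cohort.n_ms} "
      f"(site presence probability {cfg.lesion_sites[0].presence_probability:.2f})")

spaces = m.tissue_search_spaces(m.group_lesion_mask(cohort), templates)
print("search-space sizes (voxels):", m.mask_summary(spaces))
# The lesion space is the union of all subjects' lesions; NAGM/NAWM are the
# template voxels no lesion ever touched — the searchlights of each analysis
# stay inside exactly one of these tissue classes.
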