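"""Threshold an accuracy map and summarize significant clusters.

Per-center p-values come from a Pearson chi-square test on the confusion
table; Bonferroni correction over the space's centers controls the
family-wise error, and connected components of at least k significant
centers are reported with peak accuracy DA(%), Vox*(%) (share of
underlying voxels with a significant univariate group difference) and the
mean t-value (patients minus controls).
"""

import mslight as m

templates = m.make_tissue_templates((24, 24, 24), seed=1)
cfg = m.default_effect_config(templates)
cohort = m.simulate_cohort(20, 13, cfg=cfg, seed=4, templates=templates)
spaces = m.tissue_search_spaces(m.group_lesion_mask(cohort), templates)

pre = m.preprocess_cohort(cohort, variant=m.UNCORRECTED)
acc = m.map_searchlights(pre, spaces.lesion_space, m.sphere_offsets(3),
                         space="lesion")

sig_cfg = m.SignificanceConfig()  # FWE 0.05, k=5 for lesion/uncorrected
summary = m.summarize_space(acc, pre, sig_cfg, space_mask=spaces.lesion_space)
print(f"Bonferroni-significant centers: {int(summary.sig_mask.sum())}")
print(m.cluster_table(summary.rows).to_string(index=False))
# CS = cluster size (significant neighboring centers); x,y,z = peak center
# in mm; p = chi-square p of the peak confusion table. High Vox*(%) says the
# separation is carried by strong voxelwise differences; near-zero Vox*(%)
# with high DA(%) indicates distributed multivariate information.
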