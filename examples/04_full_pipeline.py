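"""Run every stage end to end and print the report.

The pipeline simulates a cohort, builds the search spaces, produces both
data variants (uncorrected, and corrected for deformation confounds), maps
all requested spaces, thresholds the maps per the per-analysis regimes and
writes NIfTI maps, TSV cluster tables and a plain-text report into the run
directory. The same config + seed always reproduces the run byte for byte.

Equivalent shell command:  mslight all runs/demo --seed 7
"""

import mslight as m

cfg = m.RunConfig(
    outdir="runs/demo",
    seed=7,
    grid_shape=(16, 16, 16),  # small demo grid; the study grid is 24^3
    n_ms=8,
    n_hc=6,
    spaces=("lesion", "nawm"),
)
rundir = m.run_pipeline(cfg)
print((rundir / "report.txt").read_text())
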