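"""Simulate a full synthetic cohort and run the 2x2 analysis battery.

Generates parcellated timeseries for a reduced-scale cohort (10 PTSD + 10
MDD, 60 nodes, 200 frames) with a large injected group x stress interaction,
writes the cohort to disk, and runs the complete pipeline: connectomes ->
DMN strength -> repeated-measures GLM -> simple effects -> split-half
duration GLMs -> severity correlations.
"""

import tempfile
from pathlib import Path

from netstress import AnalysisConfig, SimConfig, run_analysis, simulate_cohort

out_dir = Path(tempfile.mkdtemp(prefix="netstress_example_"))

cohort = simulate_cohort(SimConfig(dmn_interaction_effect=1.5, seed=7))
data = cohort.write(out_dir / "cohort")

report = run_analysis(AnalysisConfig(
    subjects_csv=str(data / "subjects.csv"),
    timeseries_dir=str(data / "timeseries"),
    atlas_path=str(data / "atlas.tsv"),
    covariates=("age", "sex_male", "motion_pre", "motion_post"),
    split_half=True,
    out_dir=str(out_dir / "report"),
))

print(report.summary())
print(f"full report written to {out_dir / 'report'}")
print("The interaction row is the primary test: a stress-induced DMN-strength")
print("change specific to the PTSD group. Here the generator injected a large")
print("interaction (d = 1.5), so it should be significant; the duration rows")
print("check that within-run time effects do not mimic it.")
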