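"""Simulate a CSF-style qPCR cohort and take the detection census.

Builds a 28-control / 22-case cohort over a 1178-assay panel, counts per
assay in how many samples of each group it is detected (Cq <= 34), and
stratifies the panel into an abundant set A, a less-abundant set B, and
excluded / never-detected assays.
"""

import morscreen as ms

config = ms.SimulationConfig(seed=1)
cq, meta, truth = ms.simulate_cohort(config)
cohort = ms.join_metadata(cq, meta)

census = ms.detection_census(cohort)
s = census.summary
print(f"panel size:        {s.panel_size} assays")
print(f"detected anywhere: {s.n_detected}  ({s.percent_detected}% of panel)")
print(f"set A (abundant):  {s.n_set_a}")
print(f"set B (sparse):    {s.n_set_b}")
print(f"excluded (FOC<3):  {s.n_excluded}")

# The detected percentage reads as "at least X% of the panel is present in
# CSF"; set A assays are detected often enough (19 of 28 controls, 17 of 22
# cases) to support subsampling reliability analysis, set B only a single
# screen.
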