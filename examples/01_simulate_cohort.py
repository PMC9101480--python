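"""Simulate a synthetic eye-tracking cohort and inspect its raw structure.

Generates 64 subjects x 4 Stroop conditions (NWoI, NWI, RWoI, RWI) of
fixation/saccade events over a 4x4 word grid and writes the report files.
"""

import stroopgaze as sg

paths = sg.write_cohort("example_data", sg.calibrate_defaults(), seed=7)
print("report files:", *paths.values(), sep="\n  ")

trials = sg.simulate_trials(seed=7)
print(f"\n{len(trials)} trials (64 subjects x 4 conditions)")
for cond in sg.CONDITIONS:
    n = [t.n_fixations for t in trials if t.condition == cond]
    print(f"  {cond:5s} mean raw fixations/trial: {sum(n) / len(n):5.1f}")
# Naming (N*) trials carry more fixations than Reading (R*), and
# interference (NWI) adds more on top: the effect the analysis must detect.
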