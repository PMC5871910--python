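"""Simulate a ground-truthed single-cell western blot cohort.

Builds the BT474-like preset: 391 occupied lanes, each with loading
controls (actinin, GAPDH), an epithelial marker (panCK) and a
full-length HER2 band; 29 lanes (7.4%) additionally carry a planted
truncated-HER2 band.  Prints the cohort composition from the truth
table the generator emits alongside the profiles.
"""

import scwb

cfg = scwb.bt474_preset(seed=0)
profiles, truth = scwb.generate_cohort(cfg)

n_lanes = len(truth)
n_planted = int((truth["subpop_label"] == "terbb2").sum())
print(f"lanes simulated:        {n_lanes}")
print(f"occupied lanes:         {int(truth['has_cell'].sum())}")
print(f"planted truncated-HER2: {n_planted} ({100 * n_planted / n_lanes:.1f}%)")
print(f"profile table rows:     {len(profiles)} "
      f"({profiles.groupby(['channel', 'round']).ngroups} traces/lane)")

# every planted lane also carries the full-length band (truncated HER2
# co-occurs with full-length HER2)
planted = truth[truth["subpop_label"] == "terbb2"]
print(f"planted lanes with full-length band: {(planted['load_p185'] > 0).sum()}")
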