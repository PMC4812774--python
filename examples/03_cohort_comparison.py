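"""Cohort comparison: microglial activation vs deactivation.

Generates three calibrated bipolar-neuron cohorts (control, LPS-activated
microglia, TGF-beta-deactivated microglia; 40 cells each), runs the full
analysis pipeline per cell, and compares group densities with one-way ANOVA
plus Tukey-Kramer post hoc tests.  Takes about a minute.
"""

import navclamp as nc
from navclamp.cohort import STUDY_FIXTURES

config = nc.SimulatorConfig(seed=1)
results = []
for cond, seed in (("control", 1), ("lps", 2), ("tgfb", 5)):
    fixture = STUDY_FIXTURES[("microglia", "bipolar", cond)]
    results += nc.run_cohort(fixture, config=config, master_seed=seed)

summary = nc.summarize_cohort(results)
for g in summary.groups:
    print(f"{g.label:8s} {g.mean:5.1f} +- {g.se:3.1f} pA/pF  (n = {g.n})")
a = summary.anova
print(f"\nANOVA: F({a.df_between},{a.df_within}) = {a.F:.2f}, p = {a.p:.3g}")
for c in summary.tukey:
    print(f"{c.group_a} vs {c.group_b}: diff = {c.difference:+.1f} pA/pF, "
          f"p = {c.p:.4f} {c.stars}")
# Activated microglia (LPS) raise the Na+ current density above control;
# deactivating residual microglia with TGF-beta lowers it below control.
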