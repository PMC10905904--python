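"""Type-1 SDT estimates and the illusion magnitude (depth - control d').

Simulates the 320-trial same/different task for a cohort, tabulates
confidence counts per subject x background condition, estimates d' and C,
and tests the depth-minus-control drop in d' — the operational measure of
illusion strength (more negative = stronger illusion).
"""

import numpy as np

import ponzometa as pm

trials, manifest = pm.simulate_cohort(pm.CohortSpec(n_subjects=12, seed=1))
tables = pm.tabulate_all(trials)

rows = {}
for (sid, cond), tab in tables.items():
    rows.setdefault(sid, {})[cond.value] = pm.compute_type1(tab)

d_control = np.array([r["control"].d_prime for r in rows.values()])
d_depth = np.array([r["depth"].d_prime for r in rows.values()])

print(f"mean d' control : {d_control.mean():.3f}")
print(f"mean d' depth   : {d_depth.mean():.3f}")
res = pm.paired_diff_t(d_depth, d_control)
print(f"depth - control : t({res.df}) = {res.statistic:.3f}, "
      f"p = {res.p:.2e}, Cohen's d = {res.effect_d:.3f}")
print()
print("Near-ceiling discrimination on the uniform background collapses to")
print("near-chance under pictorial depth cues: the illusion destroys the")
print("physical size signal, and the negative difference quantifies it.")
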