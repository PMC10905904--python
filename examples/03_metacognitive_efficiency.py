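"""Single-subject meta-d' by maximum likelihood.

Simulates one observer whose confidence carries less information than the
type-1 decision (log M-ratio -0.4, i.e. M-ratio ~ 0.67), then refits the
meta-level observer from the 2 x (2 x 4) confidence count table.
"""

import numpy as np

import ponzometa as pm

rng = np.random.default_rng(3)
schedule = pm.build_trial_schedule(3) * 4  # 1,280 trials for a tight fit
trials = pm.exclude_fillers(
    pm.simulate_subject_trials(d_prime=2.0, criterion=0.1, log_m_ratio=-0.4,
                               t2_offsets_s1=[0.5] * 3, t2_offsets_s2=[0.5] * 3,
                               schedule=schedule, rng=rng))
tc = pm.tabulate_counts(trials, "control")
td = pm.tabulate_counts(trials, "depth")
table = pm.ConfidenceCountTable(tc.s1 + td.s1, tc.s2 + td.s2)

t1 = pm.compute_type1(table)
fit = pm.fit_meta_d(table, t1)
print(f"d'            : {t1.d_prime:.3f}   (true 2.0)")
print(f"criterion C   : {t1.criterion_c:+.3f}  (true +0.1)")
print(f"meta-d'       : {fit.meta_d:.3f}")
print(f"M-ratio       : {fit.m_ratio:.3f}   (true {np.exp(-0.4):.3f})")
print(f"log M-ratio   : {fit.log_m_ratio:+.3f}  (true -0.400)")
print()
print("meta-d' below d' (M-ratio < 1) means the confidence ratings use only")
print("part of the perceptual evidence: metacognitive inefficiency.")
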