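import numpy as np
import pytest

import ponzometa as pm


@pytest.fixture(scope="session")
def toy_table():
    """A well-populated 16-cell confidence count table (64 trials/class)."""
    return pm.ConfidenceCountTable([18, 12, 8, 6, 6, 5, 5, 4],
                                   [4, 5, 5, 6, 6, 8, 12, 18])


def make_rating_sheet(subject_id="s000", desirable=0.2, undesirable=-0.2,
                      filler=0.0):
    """Sheet with constant raw scores per item class."""
    items = pm.trait_items()
    scores, classes = {}, {}
    for word, valence in zip(items["word"], items["valence"]):
        cls = pm.ItemClass(valence)
        scores[word] = desirable if cls == pm.ItemClass.DESIRABLE else undesirable
        classes[word] = cls
    for i in range(1, 9):
        scores[f"filler_{i:02d}"] = filler
        classes[f"filler_{i:02d}"] = pm.ItemClass.FILLER
    return pm.RatingSheet(subject_id, scores, classes)


def pooled_subject_table(rng, d, c, logm, offsets=(0.5, 0.5, 0.5)):
    """One subject's 256 analyzed trials pooled over background conditions
    (both conditions simulated at the same d', as in a no-illusion design)."""
    sch = pm.build_trial_schedule(int(rng.integers(2**31)))
    trials = pm.exclude_fillers(
        pm.simulate_subject_trials(d, c, logm, list(offsets), list(offsets),
                                   sch, rng))
    tc = pm.tabulate_counts(trials, "control")
    td = pm.tabulate_counts(trials, "depth")
    return pm.ConfidenceCountTable(tc.s1 + td.s1, tc.s2 + td.s2)


def simulate_flat_cohort(seed, n_subjects, mu=-0.3, sigma=0.2,
                         d_low=0.5, d_high=2.5):
    """Cohort of pooled 256-trial tables with group log M-ratio N(mu, sigma)."""
    rng = np.random.default_rng(seed)
    tabs, t1s, true_logm = [], [], []
    for _ in range(n_subjects):
        d = rng.uniform(d_low, d_high)
        c = rng.normal(0, 0.15)
        logm = rng.normal(mu, sigma)
        tab = pooled_subject_table(rng, d, c, logm)
        tabs.append(tab)
        t1s.append(pm.compute_type1(tab))
        true_logm.append(logm)
    return tabs, t1s, np.array(true_logm)
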