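"""Rating scoring, trial scheduling, count tabulation and CSV round trips."""

import numpy as np
import pytest

import ponzometa as pm
from ponzometa.core_io import ValidationError, reverse_code

from conftest import make_rating_sheet


class TestScoreRatings:
    def test_all_zero_scores_give_zero_summary(self):
        scored = pm.score_ratings(make_rating_sheet(desirable=0.0, undesirable=0.0))
        assert scored.si_score == 0.0
        assert len(scored.values) == 52

    def test_sign_convention_of_reverse_coding(self):
        scored = pm.score_ratings(make_rating_sheet(desirable=0.4, undesirable=0.4))
        items = pm.trait_items()
        valence = dict(zip(items["word"], items["valence"]))
        for word, value in zip(scored.words, scored.values):
            expected = 0.4 if valence[word] == "desirable" else -0.4
            assert value == pytest.approx(expected)

    def test_summary_is_mean_of_scored_values(self):
        # 26 desirable at +0.2 and 26 undesirable at -0.2 raw -> mean +0.2
        scored = pm.score_ratings(make_rating_sheet(desirable=0.2, undesirable=-0.2))
        assert scored.si_score == pytest.approx(0.2)

    def test_filler_items_are_dropped(self):
        scored = pm.score_ratings(make_rating_sheet(filler=0.9))
        assert not any(w.startswith("filler") for w in scored.words)

    def test_off_grid_score_names_the_item(self):
        sheet = make_rating_sheet()
        sheet.scores["warm"] = 0.123
        with pytest.raises(ValidationError, match="warm"):
            pm.score_ratings(sheet)

    def test_wrong_item_counts_rejected(self):
        sheet = make_rating_sheet()
        del sheet.scores["warm"], sheet.classes["warm"]
        with pytest.raises(ValidationError):
            pm.score_ratings(sheet)

    def test_reverse_coding_is_an_involution(self):
        for v in np.arange(-1.0, 1.0001, 0.05):
            assert reverse_code(reverse_code(v)) == pytest.approx(v)


class TestSchedule:
    def test_trial_and_filler_bookkeeping(self):
        sch = pm.build_trial_schedule(0)
        assert len(sch) == 320
        assert len(pm.exclude_fillers(sch)) == 256
        for cond in (pm.Condition.CONTROL, pm.Condition.DEPTH):
            sub = [t for t in sch if t.condition == cond]
            assert len(sub) == 160
            ratios = [t.size_ratio for t in sub]
            assert ratios.count(1.00) == 64 and ratios.count(0.80) == 64
            assert ratios.count(0.95) == 16 and ratios.count(1.05) == 16
            analyzed = [t for t in sub if not t.is_filler]
            same = sum(t.stimulus == pm.Stimulus.SAME for t in analyzed)
            assert same == 64 and len(analyzed) - same == 64

    def test_every_40_trial_block_contains_all_cells(self):
        sch = pm.build_trial_schedule(123)
        cells = {(c, r) for c in pm.Condition for r in (1.0, 0.8, 0.95, 1.05)}
        for start in range(0, 320, 40):
            block = sch[start:start + 40]
            seen = {(t.condition, t.size_ratio) for t in block}
            assert seen == cells

    def test_seed_determinism_and_count_invariance(self):
        a = pm.build_trial_schedule(5)
        b = pm.build_trial_schedule(5)
        c = pm.build_trial_schedule(6)
        assert a == b
        assert a != c
        key = lambda s: sorted((t.condition.value, t.size_ratio) for t in s)
        assert key(a) == key(c)


class TestTabulate:
    def test_degenerate_responder(self):
        trials = [
            pm.TrialRecord("s", pm.Condition.CONTROL, pm.Stimulus.SAME, 1.0,
                           pm.Response.SAME, 4)
            for _ in range(64)
        ]
        tab = pm.tabulate_counts(trials, "control")
        assert tab.s1.tolist() == [64, 0, 0, 0, 0, 0, 0, 0]
        assert tab.s2.sum() == 0

    def test_hand_counted_six_trial_toy(self):
        C, S, D = pm.Condition.CONTROL, pm.Stimulus.SAME, pm.Stimulus.DIFFERENT
        trials = [
            pm.TrialRecord("s", C, S, 1.0, pm.Response.SAME, 4),
            pm.TrialRecord("s", C, S, 1.0, pm.Response.DIFFERENT, 2),
            pm.TrialRecord("s", C, D, 0.8, pm.Response.DIFFERENT, 4),
            pm.TrialRecord("s", C, D, 0.8, pm.Response.SAME, 1),
            pm.TrialRecord("s", C, S, 1.0, pm.Response.SAME, 1),
            pm.TrialRecord("s", C, D, 0.8, pm.Response.DIFFERENT, 1),
        ]
        tab = pm.tabulate_counts(trials, "control")
        assert tab.s1.tolist() == [1, 0, 0, 1, 0, 1, 0, 0]
        assert tab.s2.tolist() == [0, 0, 0, 1, 1, 0, 0, 1]
        assert tab.s1.sum() + tab.s2.sum() == len(trials)

    def test_filler_trial_rejected(self):
        bad = [pm.TrialRecord("s", pm.Condition.CONTROL, pm.Stimulus.DIFFERENT,
                              0.95, pm.Response.SAME, 1, is_filler=True)]
        with pytest.raises(ValidationError):
            pm.tabulate_counts(bad, "control")


class TestRoundTrips:
    def test_trials_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        sch = pm.build_trial_schedule(3)
        trials = pm.simulate_subject_trials(1.5, 0.1, -0.2, [0.5] * 3, [0.5] * 3,
                                            sch, rng)
        path = tmp_path / "trials.csv"
        pm.write_trials(trials, path)
        back = pm.read_trials(path)
        assert back == trials

    def test_ratings_csv_round_trip(self, tmp_path):
        sheet = make_rating_sheet(desirable=0.35, undesirable=-0.15, filler=0.05)
        path = tmp_path / "ratings.csv"
        pm.write_ratings([sheet], path)
        (back,) = pm.read_ratings(path)
        assert back.subject_id == sheet.subject_id
        assert back.scores == sheet.scores
        assert back.classes == sheet.classes

    def test_trial_record_invariants(self):
        with pytest.raises(ValidationError):
            pm.TrialRecord("s", pm.Condition.CONTROL, pm.Stimulus.SAME, 1.0,
                           is_filler=True)
        with pytest.raises(ValidationError):
            pm.TrialRecord("s", pm.Condition.CONTROL, pm.Stimulus.SAME, 1.0,
                           pm.Response.SAME, 5)
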