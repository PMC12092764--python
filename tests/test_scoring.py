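"""Activity scoring, Webster rescoring, non-wear and sleep-period detection."""

from datetime import date, time

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepreg.io import ActigraphySeries
from sleepreg.scoring import (
    MISSING,
    SLEEP,
    WAKE,
    PeriodConfig,
    ScoringConfig,
    SleepWakeSeries,
    apply_webster_rescoring,
    delimit_sleep_periods,
    detect_nonwear,
    score_ucsd,
)

T0 = pd.Timestamp("2024-01-01T00:00:00")


def _series(activity, wear=None, marker=None):
    return ActigraphySeries(
        "t", T0, np.asarray(activity), wear=wear, event_marker=marker
    )


def _states(states, rescored=None):
    return SleepWakeSeries("t", T0, np.asarray(states, dtype=np.int8), rescored=rescored)


class TestScoreUcsd:
    def test_zero_activity_scores_sleep(self):
        out = score_ucsd(_series([0] * 20))
        assert (out.states == SLEEP).all()

    def test_large_constant_activity_scores_wake(self):
        out = score_ucsd(_series([500] * 20))
        assert (out.states == WAKE).all()

    def test_hand_computed_window_scores(self):
        # 3-tap unit-weight window, scale 0.10: D_t = 0.1*(a[t-1]+a[t]+a[t+1])
        cfg = ScoringConfig(weights=[1.0, 1.0, 1.0], center=1)
        activity = [0, 0, 0, 0, 30, 0, 0, 0, 0, 0]
        out = score_ucsd(_series(activity), cfg)
        expected = [SLEEP] * 3 + [WAKE] * 3 + [SLEEP] * 4  # D = 3.0 at t in {3,4,5}
        assert list(out.states) == expected

    def test_missing_epochs_stay_missing_and_contribute_zero(self):
        wear = np.ones(10, dtype=bool)
        wear[4] = False
        cfg = ScoringConfig(weights=[1.0, 1.0, 1.0], center=1)
        out = score_ucsd(_series([0, 0, 0, 0, 30, 0, 0, 0, 0, 0], wear=wear), cfg)
        assert out.states[4] == MISSING
        # the unworn spike is zeroed, so neighbours remain sleep
        assert out.states[3] == SLEEP and out.states[5] == SLEEP

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="no wearable"):
            score_ucsd(_series([1, 2, 3], wear=np.zeros(3, dtype=bool)))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        base=st.lists(st.integers(0, 400), min_size=5, max_size=60),
        bump=st.lists(st.integers(0, 200), min_size=5, max_size=60),
    )
    def test_monotone_in_activity(self, base, bump):
        """Pointwise-increasing activity never turns a wake epoch into sleep."""
        n = min(len(base), len(bump))
        lo = np.array(base[:n])
        hi = lo + np.array(bump[:n])
        s_lo = score_ucsd(_series(lo)).states
        s_hi = score_ucsd(_series(hi)).states
        assert not np.any((s_lo == WAKE) & (s_hi == SLEEP))


class TestWebsterRescoring:
    def test_short_sleep_after_wake_run_rescored(self):
        # 4 min of wake then sleep: the next 1 min (2 epochs) becomes wake
        states = [WAKE] * 8 + [SLEEP] * 6
        out = apply_webster_rescoring(_states(states))
        assert list(out.states[8:10]) == [WAKE, WAKE]
        assert list(out.states[10:14]) == [SLEEP] * 4
        assert out.rescored[8:10].all() and not out.rescored[10:].any()

    def test_stronger_rule_wins_after_long_wake(self):
        # 15 min of wake: 4 min (8 epochs) of following sleep rescored
        states = [WAKE] * 30 + [SLEEP] * 20
        out = apply_webster_rescoring(_states(states))
        assert (out.states[30:38] == WAKE).all()
        assert (out.states[38:] == SLEEP).all()

    def test_sandwiched_short_sleep_rescored(self):
        # 6 min sleep flanked by 20-min wake runs -> wake
        states = [WAKE] * 40 + [SLEEP] * 12 + [WAKE] * 40
        out = apply_webster_rescoring(_states(states))
        assert (out.states == WAKE).all()

    def test_all_sleep_is_fixed_point(self):
        states = [SLEEP] * 50
        out = apply_webster_rescoring(_states(states))
        assert (out.states == SLEEP).all()
        assert not out.rescored.any()

    def test_missing_breaks_trigger_runs(self):
        states = [WAKE] * 4 + [MISSING] * 2 + [WAKE] * 4 + [SLEEP] * 4
        out = apply_webster_rescoring(_states(states))
        # neither wake run reaches 4 min on its own
        assert (out.states[10:] == SLEEP).all()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_idempotent_and_never_creates_sleep(self, seed):
        rng = np.random.default_rng(seed)
        states = rng.choice([SLEEP, WAKE, MISSING], size=2000, p=[0.5, 0.45, 0.05])
        first = apply_webster_rescoring(_states(states))
        second = apply_webster_rescoring(first)
        np.testing.assert_array_equal(first.states, second.states)
        np.testing.assert_array_equal(first.rescored, second.rescored)
        # only sleep -> wake flips
        flipped = first.states != np.asarray(states, dtype=np.int8)
        assert np.all(np.asarray(states)[flipped] == SLEEP)
        assert np.all(first.states[flipped] == WAKE)


class TestDetectNonwear:
    def test_long_zero_run_marked(self):
        activity = [50] * 20 + [0] * 360 + [50] * 20  # 3 h of zeros
        out = detect_nonwear(_series(activity), min_zero_run=90)
        assert not out.wear[20:380].any()
        assert out.wear[:20].all() and out.wear[380:].all()
        np.testing.assert_array_equal(out.activity, activity)

    def test_short_zero_run_untouched(self):
        activity = [50] * 20 + [0] * 40 + [50] * 20  # 20 min of zeros
        out = detect_nonwear(_series(activity), min_zero_run=90)
        assert out.wear.all()

    def test_injected_gaps_recovered(self, small_cohort):
        """Injected non-wear gaps are recovered with high sensitivity."""
        found = 0
        total = 0
        for series, _, truth in small_cohort.participants:
            if not truth.nonwear.any():
                continue
            detected = ~detect_nonwear(series, min_zero_run=5).wear
            total += int(truth.nonwear.sum())
            found += int((detected & truth.nonwear).sum())
        assert total > 0
        assert found / total >= 0.95


class TestDelimitSleepPeriods:
    def _scored_night(self):
        # one full day + night: sleep exactly 23:10 - 06:50
        n = 2880 * 2
        states = np.full(n, WAKE, dtype=np.int8)
        onset = (23 * 60 + 10) * 2
        offset = (24 * 60 * 1 + 6 * 60 + 50) * 2
        states[onset:offset] = SLEEP
        return _states(states), onset, offset

    def test_diary_window_contains_run(self):
        states, onset, offset = self._scored_night()
        from sleepreg.io import SleepDiary

        diary = SleepDiary(
            "t",
            pd.DataFrame(
                [{"date": date(2024, 1, 1), "attempted_sleep": time(23, 0),
                  "final_wake": time(7, 0)}]
            ),
        )
        periods = delimit_sleep_periods(states, diary)
        night = [p for p in periods if p.night_date == date(2024, 1, 1)]
        assert len(night) == 1
        assert night[0].onset == onset
        assert night[0].offset == offset - 1
        assert night[0].source == "diary"

    def test_marker_fallback_when_no_diary(self):
        states, onset, offset = self._scored_night()
        marker = np.zeros(states.n_epochs, dtype=bool)
        marker[(22 * 60 + 30) * 2] = True  # 22:30
        marker[(24 * 60 + 6 * 60 + 30) * 2] = True  # 06:30 next day
        series = _series(np.zeros(states.n_epochs), marker=marker)
        periods = delimit_sleep_periods(states, None, series)
        night = [p for p in periods if p.night_date == date(2024, 1, 1)]
        assert len(night) == 1
        assert night[0].source == "markers"
        assert night[0].onset == onset

    def test_fallback_window_without_diary_or_markers(self):
        states, onset, offset = self._scored_night()
        periods = delimit_sleep_periods(states)
        night = [p for p in periods if p.night_date == date(2024, 1, 1)]
        assert len(night) == 1
        assert night[0].source == "fallback"

    def test_synthetic_onsets_close_to_truth(self, small_cohort, small_spec):
        """With noise-free diaries, detected onsets track ground truth."""
        close = 0
        total = 0
        for series, diary, truth in small_cohort.participants:
            scored = apply_webster_rescoring(score_ucsd(series))
            periods = delimit_sleep_periods(scored, diary, series)
            epm = 60.0 / small_spec.epoch_length
            for p in periods:
                night_idx = (p.night_date - small_spec.start_date).days
                # ground-truth onsets are indexed from night -1
                k = night_idx + 1
                if k < 1 or k >= len(truth.onsets):
                    continue
                true_onset_epoch = truth.onsets[k] * epm
                if true_onset_epoch < 0 or true_onset_epoch > scored.n_epochs:
                    continue
                total += 1
                if abs(p.onset - true_onset_epoch) <= 10 * epm:
                    close += 1
        assert total >= 50
        assert close / total >= 0.95
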