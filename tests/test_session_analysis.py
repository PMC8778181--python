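"""The four session-analysis tools, each checked against a brute-force oracle."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facelattice.errors import InputError, StateError
from facelattice.session_analysis import (
    MODALITIES,
    Attempt,
    EventRecord,
    Frame,
    StateSeries,
    detect_events,
    filter_complete,
    merge_tallies,
    mine_patterns,
    modality_histogram,
    pattern_modality_profile,
    state_timeseries,
    total_transitions,
    transitions,
)


def make_frame(i, animation="None", sound="no", leds="no", speaking="no", complete=True, state=None):
    return Frame(
        timestamp=f"2021-01-01 10:00:{i:02d}",
        animation=animation,
        sound=sound,
        leds=leds,
        speaking=speaking,
        landmarks=np.zeros((68, 2)) if complete else None,
        state=state,
    )


class TestFilterComplete:
    def test_no_landmarks_means_ineligible(self):
        a = Attempt("a", [make_frame(i, complete=False) for i in range(5)])
        assert filter_complete(a) == []
        assert not a.eligible

    def test_partial_detection_counts(self):
        frames = [make_frame(i, complete=(i % 3 == 0)) for i in range(10)]
        a = Attempt("a", frames)
        assert len(filter_complete(a)) == 4
        assert a.eligible

    def test_conservation(self, rng):
        frames = [make_frame(i, complete=bool(rng.random() < 0.6)) for i in range(200)]
        a = Attempt("a", frames)
        complete = filter_complete(a)
        discarded = [f for f in a.frames if not f.complete]
        assert len(complete) + len(discarded) == len(frames)


class TestModalityHistogram:
    def test_all_active_in_front(self):
        frames = [make_frame(i, sound="yes", state=0) for i in range(7)]
        h = modality_histogram(frames, "Sound")
        assert h.probabilities[0] == 1.0 and h.probabilities[1:].sum() == 0.0

    def test_no_active_frames_flagged_not_nan(self):
        frames = [make_frame(i, state=3) for i in range(5)]
        h = modality_histogram(frames, "LEDs")
        assert h.empty
        assert np.all(np.isfinite(h.probabilities)) and h.probabilities.sum() == 0.0

    def test_normalization(self, rng):
        frames = [
            make_frame(i, speaking="yes" if rng.random() < 0.5 else "no", state=int(rng.integers(9)))
            for i in range(300)
        ]
        h = modality_histogram(frames, "Speaking")
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_recovers_generator_probabilities(self):
        from facelattice.synthetic_data import generate_conditional_frames

        p = np.array([0.4, 0.05, 0.05, 0.05, 0.1, 0.05, 0.1, 0.05, 0.15])
        n = 4000
        frames = generate_conditional_frames(p, n, modality="Sound", seed=9)
        h = modality_histogram(frames, "Sound")
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(h.probabilities - p) <= 3 * se + 1e-12)

    def test_animation_active_is_any_value_but_none(self):
        frames = [
            make_frame(0, animation="None", state=1),
            make_frame(1, animation="Stand", state=2),
            make_frame(2, animation="Default", state=2),
        ]
        h = modality_histogram(frames, "Animation")
        assert h.n_active == 2 and h.counts[2] == 2

    def test_unknown_modality_and_missing_state_rejected(self):
        with pytest.raises(InputError):
            modality_histogram([], "Gaze")
        with pytest.raises(StateError):
            modality_histogram([make_frame(0, sound="yes", state=None)], "Sound")


class TestDetectEvents:
    def test_single_sound_onset(self):
        frames = [make_frame(i, sound=s) for i, s in enumerate(["no", "no", "yes", "yes"])]
        events = detect_events(frames)
        assert events == [EventRecord(k=3, modality="Sound", value="yes")]

    def test_constant_activity_yields_no_events(self):
        frames = [make_frame(i, leds="yes") for i in range(6)]
        assert detect_events(frames) == []

    def test_simultaneous_onsets_give_one_record_per_modality(self):
        frames = [make_frame(0), make_frame(1, sound="yes", animation="Stand")]
        events = detect_events(frames)
        assert {e.modality for e in events} == {"Sound", "Animation"}
        assert all(e.k == 2 for e in events)

    def test_matches_brute_force_adjacent_scan(self, rng):
        frames = []
        for i in range(300):
            frames.append(
                make_frame(
                    i,
                    animation=str(rng.choice(["None", "Default", "Stand"])),
                    sound=str(rng.choice(["no", "yes"])),
                    leds=str(rng.choice(["no", "yes"])),
                    speaking=str(rng.choice(["no", "yes"])),
                )
            )
        got = detect_events(frames)
        # independent adjacent-pair scan
        want = []
        from facelattice.session_analysis import is_active

        for i in range(1, len(frames)):
            for m in MODALITIES:
                if is_active(frames[i], m) and not is_active(frames[i - 1], m):
                    want.append((i + 1, m))
        assert [(e.k, e.modality) for e in got] == want


class TestTransitions:
    def test_worked_transition_six_to_zero(self):
        series = StateSeries([6, 6, 0, 0, 0])
        events = [EventRecord(k=3, modality="Animation", value="Default")]
        t = transitions(series, events, lag=1)
        assert t["Animation"].transitions == Counter({"60": 1})
        assert t["Animation"].yes == 1 and t["Animation"].no == 0

    def test_no_transition_when_state_unchanged(self):
        series = StateSeries([0, 0, 0])
        events = [EventRecord(k=2, modality="Sound", value="yes")]
        t = transitions(series, events, lag=1)
        assert t["Sound"].yes == 0 and t["Sound"].no == 1

    def test_out_of_bounds_events_skipped(self):
        series = StateSeries([1, 2, 3])
        events = [EventRecord(k=1, modality="Sound", value="yes"),
                  EventRecord(k=3, modality="Sound", value="yes")]
        t = transitions(series, events, lag=1)
        assert t["Sound"].yes + t["Sound"].no == 0

    def test_invalid_lag_rejected(self):
        with pytest.raises(InputError):
            transitions(StateSeries([0, 1]), [], lag=4)

    @pytest.mark.parametrize("lag", [1, 2, 3])
    def test_matches_brute_force_recount(self, lag, rng):
        n = 500
        states = rng.integers(0, 9, n)
        series = StateSeries(states)
        events = [
            EventRecord(k=int(k), modality=str(rng.choice(MODALITIES)), value="yes")
            for k in rng.integers(1, n + 1, 80)
        ]
        got = transitions(series, events, lag)
        want_yes = {m: 0 for m in MODALITIES}
        want_no = {m: 0 for m in MODALITIES}
        want_pairs = {m: Counter() for m in MODALITIES}
        for ev in events:
            if ev.k - 1 >= 1 and ev.k + lag <= n:
                a, b = states[ev.k - 2], states[ev.k + lag - 1]
                if a != b:
                    want_yes[ev.modality] += 1
                    want_pairs[ev.modality][f"{a}{b}"] += 1
                else:
                    want_no[ev.modality] += 1
        for m in MODALITIES:
            assert got[m].yes == want_yes[m]
            assert got[m].no == want_no[m]
            assert got[m].transitions == want_pairs[m]
        # yes + no equals the number of in-bounds events per modality
        in_bounds = Counter(ev.modality for ev in events if 2 <= ev.k <= n - lag)
        for m in MODALITIES:
            assert got[m].yes + got[m].no == in_bounds[m]

    def test_merge_and_total(self):
        s1 = StateSeries([6, 6, 0, 0])
        s2 = StateSeries([1, 1, 2, 2])
        ev = [EventRecord(k=3, modality="Sound", value="yes")]
        pooled = merge_tallies([transitions(s1, ev, 1), transitions(s2, ev, 1)])
        assert pooled["Sound"].yes == 2
        assert total_transitions(pooled) == 2


class TestStateTimeseries:
    def test_all_complete_has_no_gaps(self):
        a = Attempt("a", [make_frame(i, state=i % 9) for i in range(9)])
        ts = state_timeseries(a)
        assert not ts["state"].isna().any()

    def test_alternating_gaps(self):
        frames = [make_frame(i, complete=(i % 2 == 0), state=0 if i % 2 == 0 else None)
                  for i in range(10)]
        ts = state_timeseries(Attempt("a", frames))
        assert list(ts["state"].isna()) == [i % 2 == 1 for i in range(10)]

    def test_csv_round_trip_lossless(self, tmp_path):
        frames = [make_frame(i, complete=(i % 3 != 0), state=(i % 9 if i % 3 != 0 else None))
                  for i in range(20)]
        ts = state_timeseries(Attempt("a", frames))
        path = tmp_path / "ts.csv"
        ts.to_csv(path, index=False)
        back = pd.read_csv(path, dtype={"timestamp": str}).astype({"state": "Int64"})
        pd.testing.assert_frame_equal(ts, back)

    def test_plot_renders_file(self, tmp_path):
        from facelattice.session_analysis import plot_state_timeseries

        frames = [make_frame(i, complete=(i % 4 != 0), state=(i % 9 if i % 4 != 0 else None))
                  for i in range(30)]
        ts = state_timeseries(Attempt("a", frames))
        out = tmp_path / "ts.png"
        plot_state_timeseries(ts, out)
        assert out.exists() and out.stat().st_size > 0


def brute_force_patterns(states, min_distinct=3, max_run=3):
    """Independent enumerator: test every substring against the definition."""
    s = "".join(str(x) for x in states)
    n = len(s)
    found = []
    for i in range(n):
        for j in range(i + 1, n + 1):
            sub = s[i:j]
            # must start and end on maximal-run boundaries of the full string
            if i > 0 and s[i - 1] == s[i]:
                continue
            if j < n and s[j] == s[j - 1]:
                continue
            # collapse to runs
            runs = []
            for ch in sub:
                if runs and runs[-1][0] == ch:
                    runs[-1][1] += 1
                else:
                    runs.append([ch, 1])
            if len(runs) != min_distinct:
                continue
            if any(l > max_run for _, l in runs):
                continue
            if len({ch for ch, _ in runs}) != min_distinct:
                continue
            found.append((i, j - 1, "".join(ch for ch, _ in runs), sub))
    return sorted(found)


class TestMinePatterns:
    def test_worked_equivalents_collapse_to_806(self):
        for variant in ("806", "8066", "8806", "80006"):
            reps = mine_patterns([variant])
            assert list(reps) == ["806"]
            assert reps["806"].variant_counts == Counter({variant: 1})

    def test_run_longer_than_three_is_excluded(self):
        assert mine_patterns(["800006"]) == {}

    def test_occurrence_spans_and_classes(self):
        reps = mine_patterns([StateSeries([8, 8, 0, 6, 6, 6], attempt_id="a1")])
        occ = reps["806"].occurrences[0]
        assert (occ.start, occ.end) == (0, 5)
        assert occ.variant == "880666"
        assert occ.spanned_frames == 6
        assert occ.attempt_id == "a1"

    def test_repeated_symbol_window_rejected(self):
        # runs 8,0,8 have only two distinct states
        assert mine_patterns(["808"]) == {}
        # but a window with three distinct run symbols in the same string counts
        assert set(mine_patterns(["8086"])) == {"086"}

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(st.lists(st.integers(0, 8), min_size=0, max_size=30))
    def test_matches_brute_force_enumerator(self, states):
        reps = mine_patterns([StateSeries(states)] if states else [])
        got = sorted(
            (occ.start, occ.end, cls, occ.variant)
            for cls, rep in reps.items()
            for occ in rep.occurrences
        )
        assert got == brute_force_patterns(states)

    def test_class_total_equals_sum_of_variant_counts(self, rng):
        series = [StateSeries(rng.integers(0, 4, 40), attempt_id=str(i)) for i in range(10)]
        for rep in mine_patterns(series).values():
            assert rep.total == sum(rep.variant_counts.values())

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(InputError):
            mine_patterns([[0, 9, 1]])


class TestPatternModalityProfile:
    def test_speaking_counts_over_one_occurrence(self):
        frames = [make_frame(i, speaking="yes") for i in range(3)]
        occ = [next(iter(mine_patterns([StateSeries([8, 0, 6])]).values())).occurrences[0]]
        profile = pattern_modality_profile(occ, frames)
        assert profile["Speaking"] == Counter({"yes": 3})
        assert profile["Sound"] == Counter({"no": 3})

    def test_per_modality_totals_all_equal_spanned_frames(self, rng):
        states = rng.integers(0, 5, 60)
        frames = [
            make_frame(
                i,
                animation=str(rng.choice(["None", "Default"])),
                sound=str(rng.choice(["no", "yes"])),
                speaking=str(rng.choice(["no", "yes"])),
            )
            for i in range(60)
        ]
        reps = mine_patterns([StateSeries(states, attempt_id="a")])
        for rep in reps.values():
            profile = pattern_modality_profile(rep.occurrences, {"a": frames})
            totals = {m: sum(c.values()) for m, c in profile.items()}
            assert len(set(totals.values())) == 1

    def test_counts_match_brute_force_tally(self, rng):
        states = [8, 0, 6, 6, 2, 8, 8, 0, 6]
        frames = [make_frame(i, sound="yes" if i % 2 else "no") for i in range(len(states))]
        reps = mine_patterns([StateSeries(states, attempt_id="a")])
        rep = reps["806"]
        profile = pattern_modality_profile(rep.occurrences, {"a": frames})
        spanned = set()
        for occ in rep.occurrences:
            spanned |= set(range(occ.start, occ.end + 1))
        want = Counter(frames[i].sound for i in spanned)
        assert profile["Sound"] == want
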