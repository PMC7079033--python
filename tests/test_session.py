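"""Bias-event detection, adjustment classes, repeats, candidate sets, log I/O."""

import numpy as np
import pytest

from scanbias.errors import DataError, InputError
from scanbias.gaze import AOI, Fixation
from scanbias.session import (
    AWAY,
    TOWARD,
    UNBIASED,
    UNCHANGED,
    BiasEvent,
    MeasurementEpisode,
    ScanSession,
    candidate_values,
    classify_adjustment,
    count_repeats,
    detect_bias_events,
    group_repeats,
    read_sessions,
    write_event_log,
    write_metadata_csv,
)

from conftest import make_linear_standard

LINEAR = make_linear_standard()  # measurement(mm) = 2 * GA(days)


def episode(plane="HC", t0=0.0, t_save=5000.0, traj=None):
    traj = traj if traj is not None else [(t0, 400.0)]
    return MeasurementEpisode(
        plane=plane,
        box_aoi=AOI(left=0, top=0, right=100, bottom=50, t_start=t0, t_end=t_save),
        trajectory=tuple(traj),
        t_save=t_save,
    )


def session(episodes, scan_id="s1", expected_ga=200.0):
    return ScanSession(
        scan_id=scan_id,
        operator_id="op1",
        expected_ga_days=expected_ga,
        maternal_bmi=25.0,
        operator_experience_years=5.0,
        episodes=tuple(episodes),
    )


def make_event(d_before, d_after, expected_ga=200.0, plane="HC"):
    """BiasEvent with chosen observed-minus-expected deviations (linear curve)."""
    o_b, o_a = expected_ga + d_before, expected_ga + d_after
    return BiasEvent(
        scan_id="s1",
        episode_index=0,
        plane=plane,
        t_first_look=1000.0,
        value_at_first_look=2.0 * o_b,
        saved_value=2.0 * o_a,
        observed_ga_at_first_look=o_b,
        observed_ga_saved=o_a,
        first_look_oor=False,
        saved_oor=False,
        n_looks=1,
    )


class TestEpisodeModel:
    def test_value_at_is_a_step_function(self):
        ep = episode(traj=[(0.0, 300.0), (2000.0, 310.0), (4000.0, 320.0)])
        assert ep.value_at(-10.0) == 300.0
        assert ep.value_at(1999.9) == 300.0
        assert ep.value_at(2000.0) == 310.0
        assert ep.value_at(4500.0) == 320.0
        assert ep.saved_value == 320.0
        assert ep.initial_value == 300.0

    def test_empty_trajectory_rejected(self):
        with pytest.raises(DataError):
            episode(traj=[])

    def test_trajectory_outside_window_rejected(self):
        with pytest.raises(DataError):
            episode(t0=100.0, traj=[(0.0, 300.0)])


class TestDetectBiasEvents:
    def test_no_fixations_means_unbiased(self):
        s = session([episode()])
        assert detect_bias_events(s, [[]], LINEAR) == []

    def test_first_look_value_lookup(self):
        # value is 310 mm when the fixation starts at 2500 ms
        ep = episode(traj=[(0.0, 310.0), (3000.0, 330.0)])
        s = session([ep])
        [ev] = detect_bias_events(s, [[Fixation(2500.0, 2700.0)]], LINEAR)
        assert ev.value_at_first_look == 310.0
        assert ev.saved_value == 330.0
        assert ev.observed_ga_at_first_look == pytest.approx(155.0)
        assert ev.n_looks == 1

    def test_fixation_at_or_after_save_does_not_qualify(self):
        ep = episode(t_save=5000.0)
        s = session([ep])
        assert detect_bias_events(s, [[Fixation(5000.0, 5200.0)]], LINEAR) == []

    def test_fixation_straddling_box_appearance_counts_from_t_box(self):
        ep = episode(t0=1000.0, t_save=5000.0, traj=[(1000.0, 400.0)])
        s = session([ep])
        [ev] = detect_bias_events(s, [[Fixation(500.0, 1500.0)]], LINEAR)
        assert ev.t_first_look == 1000.0

    def test_mismatched_fixation_list_length(self):
        s = session([episode()])
        with pytest.raises(InputError):
            detect_bias_events(s, [[], []], LINEAR)

    @pytest.mark.parametrize("seed", range(8))
    def test_incidence_matches_per_episode_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        eps, fixes = [], []
        t = 0.0
        for _ in range(rng.integers(3, 10)):
            t_save = t + rng.uniform(2000, 6000)
            eps.append(episode(t0=t, t_save=t_save))
            fx = []
            for _ in range(rng.integers(0, 3)):
                a = t + rng.uniform(-500, (t_save - t) + 500)
                fx.append(Fixation(a, a + rng.uniform(100, 400)))
            fixes.append(fx)
            t = t_save + 1000.0
        s = session(eps)
        events = detect_bias_events(s, fixes, LINEAR)
        # brute force: an episode is biased iff some fixation overlaps
        # [t_box, t_save) and starts before the save
        expected = sum(
            any(f.t_end > ep.t_box_appear and f.t_start < ep.t_save for f in fx)
            for ep, fx in zip(eps, fixes)
        )
        assert len(events) == expected


class TestClassifyAdjustment:
    def test_toward(self):
        res = classify_adjustment(make_event(-10.0, -4.0), 200.0, LINEAR)
        assert res.adjustment_class == TOWARD
        assert res.adjustment_days == pytest.approx(6.0)

    def test_away(self):
        res = classify_adjustment(make_event(3.0, 8.0), 200.0, LINEAR)
        assert res.adjustment_class == AWAY
        assert res.adjustment_days == pytest.approx(-5.0)

    def test_unchanged_within_tolerance(self):
        res = classify_adjustment(make_event(5.0, 5.0), 200.0, LINEAR)
        assert res.adjustment_class == UNCHANGED
        assert res.adjustment_days == pytest.approx(0.0)
        # sign flip with equal magnitude is also "unchanged"
        res = classify_adjustment(make_event(5.0, -5.1), 200.0, LINEAR)
        assert res.adjustment_class == UNCHANGED

    def test_unbiased_needs_saved_value(self):
        res = classify_adjustment(None, 200.0, LINEAR, saved_value=420.0, plane="HC")
        assert res.adjustment_class == UNBIASED
        assert res.d_before is None
        assert res.d_after == pytest.approx(10.0)
        with pytest.raises(DataError):
            classify_adjustment(None, 200.0, LINEAR)


class TestRepeats:
    def test_ac_saved_three_times_gives_two_repeats(self):
        eps = [
            episode("AC", t0=0, t_save=1000),
            episode("AC", t0=2000, t_save=3000),
            episode("AC", t0=4000, t_save=5000),
        ]
        assert group_repeats(session(eps)) == [False, True, True]
        assert count_repeats(session(eps)) == 2

    def test_one_of_each_plane_no_repeats(self):
        eps = [
            episode("HC", t0=0, t_save=1000),
            episode("AC", t0=2000, t_save=3000),
            episode("FL", t0=4000, t_save=5000),
        ]
        assert count_repeats(session(eps)) == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_counting_identity(self, seed):
        rng = np.random.default_rng(seed)
        planes = [("HC", "AC", "FL")[i] for i in rng.integers(0, 3, size=rng.integers(1, 12))]
        eps = [episode(p, t0=2000.0 * i, t_save=2000.0 * i + 1000) for i, p in enumerate(planes)]
        s = session(eps)
        want = sum(max(0, planes.count(p) - 1) for p in set(planes))
        assert count_repeats(s) == want


class TestCandidateValues:
    def test_biased_episode_contributes_both_values(self):
        ep = episode(traj=[(0.0, 300.0), (3000.0, 310.0)])
        s = session([ep])
        events = detect_bias_events(s, [[Fixation(1000.0, 1200.0)]], LINEAR)
        assert candidate_values(s, "HC", events) == (300.0, 310.0)

    def test_unbiased_episode_contributes_saved_only(self):
        s = session([episode(traj=[(0.0, 310.0)])])
        assert candidate_values(s, "HC", []) == (310.0, 310.0)

    def test_missing_plane_raises(self):
        s = session([episode("HC")])
        with pytest.raises(DataError):
            candidate_values(s, "FL", [])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle_and_brackets_saved(self, seed):
        rng = np.random.default_rng(seed)
        eps, fixes = [], []
        t = 0.0
        for _ in range(rng.integers(1, 6)):
            v0, v1 = rng.uniform(250, 350, size=2)
            eps.append(episode("AC", t0=t, t_save=t + 4000, traj=[(t, v0), (t + 2000, v1)]))
            fixes.append([Fixation(t + 500, t + 700)] if rng.random() < 0.6 else [])
            t += 5000.0
        s = session(eps)
        events = detect_bias_events(s, fixes, LINEAR)
        lo, hi = candidate_values(s, "AC", events)
        pool = []
        for ep, fx in zip(eps, fixes):
            pool.append(ep.saved_value)
            if fx:
                pool.append(ep.trajectory[0][1])  # value in force at the look
        assert (lo, hi) == (min(pool), max(pool))
        for ep in eps:
            assert lo <= ep.saved_value <= hi


class TestPartitionInvariant:
    def test_every_measurement_gets_exactly_one_class(self):
        rng = np.random.default_rng(7)
        eps, fixes = [], []
        t = 0.0
        for i in range(10):
            plane = ("HC", "AC", "FL")[i % 3]
            v0, v1 = rng.uniform(250, 350, size=2)
            eps.append(episode(plane, t0=t, t_save=t + 4000, traj=[(t, v0), (t + 2000, v1)]))
            fixes.append([Fixation(t + 500, t + 700)] if i % 2 else [])
            t += 5000.0
        s = session(eps)
        events = {ev.episode_index: ev for ev in detect_bias_events(s, fixes, LINEAR)}
        classes = [
            classify_adjustment(
                events.get(i), s.expected_ga_days, LINEAR,
                saved_value=ep.saved_value, plane=ep.plane,
            ).adjustment_class
            for i, ep in enumerate(s.episodes)
        ]
        assert len(classes) == len(s.episodes)
        assert set(classes) <= {TOWARD, AWAY, UNCHANGED, UNBIASED}
        n_unbiased = sum(c == UNBIASED for c in classes)
        assert n_unbiased == len(s.episodes) - len(events)


class TestSessionIO:
    def _cohort(self):
        eps1 = [
            episode("HC", t0=0, t_save=4000, traj=[(0.0, 300.0), (2000.0, 310.0)]),
            episode("AC", t0=5000, t_save=9000, traj=[(5000.0, 320.0)]),
        ]
        eps2 = [episode("FL", t0=0, t_save=3000, traj=[(0.0, 60.0)])]
        return [
            session(eps1, scan_id="a", expected_ga=210.0),
            session(eps2, scan_id="b", expected_ga=250.0),
        ]

    def test_roundtrip(self, tmp_path):
        cohort = self._cohort()
        write_event_log(cohort, tmp_path / "events.jsonl")
        write_metadata_csv(cohort, tmp_path / "meta.csv")
        back = read_sessions(tmp_path / "events.jsonl", tmp_path / "meta.csv")
        assert [s.scan_id for s in back] == ["a", "b"]
        assert back[0].episodes == cohort[0].episodes
        assert back[1].expected_ga_days == 250.0

    def test_malformed_line_names_line_number(self, tmp_path):
        cohort = self._cohort()
        write_event_log(cohort, tmp_path / "events.jsonl")
        write_metadata_csv(cohort, tmp_path / "meta.csv")
        lines = (tmp_path / "events.jsonl").read_text().splitlines()
        lines[1] = '{"scan_id": "a", "plane": "AC"}'  # missing aoi/trajectory
        (tmp_path / "events.jsonl").write_text("\n".join(lines) + "\n")
        with pytest.raises(InputError, match="line 2"):
            read_sessions(tmp_path / "events.jsonl", tmp_path / "meta.csv")

    def test_ga_window_validation(self):
        s = session([episode()], expected_ga=100.0)
        with pytest.raises(DataError):
            s.validate_ga_window()
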