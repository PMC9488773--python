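"""Appearance clustering, disappearance detection, attribution and summaries."""

from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from sentinelcam.events import (
    Appearance,
    AttributionTieError,
    attribute_predation,
    cluster_appearances,
    detect_disappearances,
    extract_events,
    fit_hour_glm,
    hourly_profile,
    PredationEvent,
    share_percent,
    summarize_study,
    UNSEEN,
)
from tests.conftest import annotation_rows


def _event(hour=20, minute=0, predator="S. murinus", session="s1", slot=1, index=0):
    return PredationEvent(
        session_id=session,
        plot_id="P1",
        disappearance_index=index,
        event_time=datetime(2020, 9, 15, hour, minute, 0),
        predator=predator,
        weevil_slot=slot,
    )


class TestClusterAppearances:
    def test_consecutive_frames_form_one_appearance(self):
        df = annotation_rows("s1", [(10, "shrew", False, 2), (11, "shrew", False, 2), (12, "shrew", False, 2)])
        apps = cluster_appearances(df)
        assert len(apps) == 1
        assert (apps[0].start_index, apps[0].end_index) == (10, 12)

    def test_gap_splits_appearances(self):
        df = annotation_rows("s1", [(10, "shrew", False, 2), (11, "shrew", False, 2),
                                    (14, "shrew", False, 2), (15, "shrew", False, 2)])
        apps = cluster_appearances(df)
        assert [(a.start_index, a.end_index) for a in apps] == [(10, 11), (14, 15)]

    def test_empty_table_gives_empty_list(self):
        df = annotation_rows("s1", [])
        df = df.reindex(columns=["session_id", "frame_index", "timestamp", "species",
                                 "feeding_on_weevil", "weevils_visible"])
        assert cluster_appearances(df) == []

    def test_duplicate_rows_rejected(self):
        df = annotation_rows("s1", [(10, "shrew", False, 2), (10, "shrew", False, 2)])
        with pytest.raises(ValueError, match="duplicate"):
            cluster_appearances(df)

    def test_species_and_sessions_cluster_independently(self):
        rows_a = [(5, "shrew", False, 2), (6, "mouse", False, 2), (6, "shrew", False, 2)]
        df = pd.concat(
            [annotation_rows("s1", rows_a), annotation_rows("s2", [(5, "shrew", False, 2)])],
            ignore_index=True,
        )
        apps = cluster_appearances(df)
        assert len(apps) == 3


class TestDetectDisappearances:
    def test_two_separate_unit_drops(self):
        df = annotation_rows("s1", [(i, "", False, c) for i, c in enumerate([2, 2, 1, 1, 0])])
        assert detect_disappearances(df) == [(2, 1), (4, 2)]

    def test_both_weevils_in_one_frame(self):
        df = annotation_rows("s1", [(0, "", False, 2), (1, "", False, 0)])
        assert detect_disappearances(df) == [(1, 1), (1, 2)]

    def test_constant_count_yields_nothing(self):
        df = annotation_rows("s1", [(i, "", False, 2) for i in range(3)])
        assert detect_disappearances(df) == []

    def test_reappearance_is_an_annotation_error(self):
        df = annotation_rows("s1", [(0, "", False, 1), (1, "", False, 2)])
        with pytest.raises(ValueError, match="cannot reappear"):
            detect_disappearances(df)

    def test_drop_at_first_annotated_frame_counts_from_deployment(self):
        df = annotation_rows("s1", [(40, "", False, 1)])
        assert detect_disappearances(df) == [(40, 1)]


class TestAttribution:
    def test_appearance_just_before_disappearance_wins(self):
        df = annotation_rows("s1", [(i, "shrew", False, 2) for i in (97, 98, 99)] + [(100, "", False, 1)])
        apps = cluster_appearances(df)
        events = attribute_predation([(100, 1)], apps, annotations=df, session_id="s1")
        assert events[0].predator == "shrew"
        assert apps[0].involved_in_predation

    def test_appearance_outside_window_is_unseen(self):
        df = annotation_rows("s1", [(i, "shrew", False, 2) for i in (488, 489, 490)] + [(500, "", False, 1)])
        apps = cluster_appearances(df)
        events = attribute_predation([(500, 1)], apps, annotations=df, session_id="s1")
        assert events[0].predator == UNSEEN
        assert not apps[0].involved_in_predation

    def test_double_take_attributed_to_one_spanning_appearance(self):
        df = annotation_rows(
            "s1",
            [(298, "shrew", False, 2), (299, "shrew", False, 2),
             (300, "shrew", True, 0), (301, "shrew", False, 0)],
        )
        apps = cluster_appearances(df)
        events = attribute_predation([(300, 1), (300, 2)], apps, annotations=df, session_id="s1")
        assert [e.predator for e in events] == ["shrew", "shrew"]
        assert [e.weevil_slot for e in events] == [1, 2]

    def test_feeding_flag_beats_distance(self):
        df = annotation_rows(
            "s1",
            [(99, "lizard", False, 2), (100, "shrew", True, 1), (101, "", False, 1)],
        )
        apps = cluster_appearances(df)
        events = attribute_predation([(100, 1)], apps, annotations=df, session_id="s1")
        assert events[0].predator == "shrew"

    def test_exact_distance_tie_requires_adjudication(self):
        df = annotation_rows(
            "s1", [(98, "lizard", False, 2), (102, "shrew", False, 1)]
        )
        apps = cluster_appearances(df)
        with pytest.raises(AttributionTieError, match="lizard"):
            attribute_predation([(100, 1)], apps, annotations=df, session_id="s1")

    def test_event_time_is_the_disappearance_timestamp(self):
        df = annotation_rows("s1", [(99, "shrew", False, 2), (100, "", False, 1)])
        apps = cluster_appearances(df)
        events = attribute_predation([(100, 1)], apps, annotations=df, session_id="s1")
        assert events[0].event_time == df[df.frame_index == 100].timestamp.iloc[0]


class TestSummarize:
    def _study(self, make=None):
        sessions = pd.DataFrame(
            {"session_id": ["s1", "s2", "s3"], "plot_id": ["P1", "P1", "P2"], "prey_deployed": 2}
        )
        events = [
            _event(predator="shrew", session="s1", slot=1),
            _event(predator="shrew", session="s1", slot=2),
            _event(predator=UNSEEN, session="s2", slot=1),
        ]
        apps = [
            Appearance("s1", "shrew", 10, 12, involved_in_predation=True),
            Appearance("s1", "shrew", 50, 52, involved_in_predation=True),
            Appearance("s2", "shrew", 30, 31),
            Appearance("s3", "lizard", 7, 9),
        ]
        return events, apps, sessions

    def test_counts_rates_and_accounting(self):
        events, apps, sessions = self._study()
        s = summarize_study(events, apps, sessions)
        assert s.events_total == 3
        assert s.events_by_species == {"shrew": 2, UNSEEN: 1}
        assert s.prey_deployed == 6
        assert s.predation_rate == pytest.approx(0.5)
        assert s.predation_rate_by_plot == {"P1": 0.75, "P2": 0.0}
        assert 2 * s.sessions_both + s.sessions_one == s.events_total
        assert s.identified_events == 2

    def test_predation_frequency_counts_involved_appearances(self):
        events, apps, sessions = self._study()
        s = summarize_study(events, apps, sessions)
        assert s.predation_frequency["shrew"] == pytest.approx(2 / 3)
        assert s.predation_frequency["lizard"] == 0.0

    def test_species_with_events_but_no_appearances_has_undefined_frequency(self):
        sessions = pd.DataFrame({"session_id": ["s1"], "plot_id": ["P1"], "prey_deployed": 2})
        s = summarize_study([_event(predator="toad")], [], sessions)
        assert s.predation_frequency["toad"] is None

    def test_zero_events_is_a_valid_summary(self):
        sessions = pd.DataFrame({"session_id": ["s1"], "plot_id": ["P1"], "prey_deployed": 2})
        s = summarize_study([], [], sessions)
        assert s.events_total == 0
        assert s.predation_rate == 0.0
        assert s.percent_by_species == {}

    def test_more_events_than_prey_rejected(self):
        sessions = pd.DataFrame({"session_id": ["s1"], "plot_id": ["P1"], "prey_deployed": 2})
        events = [_event(slot=i) for i in (1, 2, 1)]
        with pytest.raises(ValueError, match="more events than prey"):
            summarize_study(events, [], sessions)

    def test_share_percent_truncates_at_one_decimal(self):
        assert share_percent(55, 82) == 67.0
        assert share_percent(18, 82) == 21.9
        assert share_percent(1, 3) == 33.3
        with pytest.raises(ZeroDivisionError):
            share_percent(1, 0)


class TestHourlyProfile:
    def test_events_in_same_hour_share_a_bin(self):
        events = [_event(hour=19, minute=27), _event(hour=19, minute=59)]
        profile = hourly_profile(events)
        assert profile[19] == 2 and profile.sum() == 2

    def test_empty_events_give_zero_vector(self):
        assert not hourly_profile([]).any()

    def test_profile_sums_to_total_without_filter(self):
        rng = np.random.default_rng(0)
        events = [_event(hour=int(h), predator=p)
                  for h, p in zip(rng.integers(0, 24, 40), rng.choice(["a", "b"], 40))]
        assert hourly_profile(events).sum() == 40
        assert hourly_profile(events, "a").sum() + hourly_profile(events, "b").sum() == 40


class TestHourGlm:
    def test_uniform_counts_give_null_fit(self):
        fit = fit_hour_glm(np.full(24, 5.0))
        assert abs(fit.params[1]) < 1e-6 and abs(fit.params[2]) < 1e-6
        assert fit.p_value == pytest.approx(1.0, abs=1e-6)

    def test_night_peak_recovered_within_three_se(self):
        # counts from lambda(h) = exp(1 + 1.5*cos(2*pi*(h-22)/24)), 200 events
        from sentinelcam.synth import generate_event_table

        lam = np.exp(1 + 1.5 * np.cos(2 * np.pi * (np.arange(24) - 22) / 24))
        table = generate_event_table(lam, 200, seed=5)
        hours = [datetime.fromisoformat(t).hour for t in table.event_time]
        counts = np.bincount(hours, minlength=24).astype(float)
        fit = fit_hour_glm(counts)
        assert abs(fit.amplitude - 1.5) < 3 * fit.amplitude_se
        assert min(abs(fit.peak_hour - 22), 24 - abs(fit.peak_hour - 22)) <= 1.0
        assert fit.p_value < 1e-6

    def test_night_concentration_is_detected_reliably(self):
        lam = np.exp(1 + 1.5 * np.cos(2 * np.pi * (np.arange(24) - 22) / 24))
        rng = np.random.default_rng(123)
        rejections = 0
        for _ in range(200):
            hours = rng.choice(24, size=60, p=lam / lam.sum())
            counts = np.bincount(hours, minlength=24).astype(float)
            rejections += fit_hour_glm(counts).p_value < 0.01
        assert rejections / 200 >= 0.95

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            fit_hour_glm(np.zeros(24))

    def test_single_hour_concentration_flags_degenerate_fit(self):
        counts = np.zeros(24)
        counts[3] = 30
        with pytest.warns(RuntimeWarning, match="single hour"):
            fit = fit_hour_glm(counts)
        assert not fit.converged


class TestExtractEvents:
    def test_multi_session_extraction_respects_plots(self, sessions_meta):
        df = pd.concat(
            [
                annotation_rows("s1", [(99, "shrew", False, 2), (100, "shrew", True, 1)]),
                annotation_rows("s2", [(10, "lizard", False, 2)]),
            ],
            ignore_index=True,
        )
        meta = sessions_meta(["s1", "s2"], plot_ids=["P1", "P2"])
        events, apps = extract_events(df, meta)
        assert len(events) == 1
        assert events[0].plot_id == "P1"
        assert len(apps) == 2

    def test_unknown_session_rejected(self, sessions_meta):
        df = annotation_rows("ghost", [(1, "", False, 2)])
        with pytest.raises(ValueError, match="unknown session"):
            extract_events(df, sessions_meta(["s1"]))
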