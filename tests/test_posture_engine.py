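"""Hysteresis comparators, posture state, and reminder throttling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import posturekit as pk
from posturekit.errors import ConfigurationError, DegenerateBandError
from posturekit.posture_engine import Polarity, posture_message


def brute_force_hysteresis(values, href, lref, triggers_above, out0=0):
    """Independent oracle: explicit two-threshold replay."""
    outs, out = [], out0
    for v in values:
        if triggers_above:
            out = 1 if v > href else (0 if v < lref else out)
        else:
            out = 1 if v < href else (0 if v > lref else out)
        outs.append(out)
    return outs


def step_all(comp, values):
    outs = []
    for v in values:
        comp = pk.comparator_step(comp, v)
        outs.append(comp.out)
    return outs


class TestComparator:
    def test_left_comparator_trips_above_trigger(self):
        comp = pk.ComparatorState(href=0.02834, lref=0.02441,
                                  polarity=Polarity.TRIGGERS_ABOVE, out=0)
        assert pk.comparator_step(comp, 0.030).out == 1

    def test_value_inside_band_retains_output(self):
        comp = pk.ComparatorState(href=0.02834, lref=0.02441,
                                  polarity=Polarity.TRIGGERS_ABOVE, out=1)
        assert pk.comparator_step(comp, 0.026).out == 1

    def test_forward_comparator_releases_above_lref(self):
        comp = pk.ComparatorState(href=0.98841, lref=0.99146,
                                  polarity=Polarity.TRIGGERS_BELOW, out=1)
        assert pk.comparator_step(comp, 0.995).out == 0

    def test_degenerate_band_rejected(self):
        with pytest.raises(DegenerateBandError):
            pk.ComparatorState(href=0.5, lref=0.5, polarity=Polarity.TRIGGERS_ABOVE)

    @pytest.mark.parametrize("triggers_above", [True, False])
    def test_matches_bruteforce_oracle_on_random_walk(self, triggers_above):
        rng = np.random.default_rng(7 if triggers_above else 8)
        values = np.cumsum(rng.normal(0, 0.01, 10_000))
        href, lref = (0.02, -0.02) if triggers_above else (-0.02, 0.02)
        pol = Polarity.TRIGGERS_ABOVE if triggers_above else Polarity.TRIGGERS_BELOW
        comp = pk.ComparatorState(href=href, lref=lref, polarity=pol)
        assert step_all(comp, values) == brute_force_hysteresis(
            values, href, lref, triggers_above
        )

    @given(st.lists(st.floats(-0.0284, 0.0244,  # open band of the left comparator
                              exclude_min=True, exclude_max=True,
                              allow_nan=False), min_size=1, max_size=100),
           st.integers(0, 1))
    def test_no_chattering_inside_band(self, values, out0):
        comp = pk.ComparatorState(href=0.0244, lref=-0.0284,
                                  polarity=Polarity.TRIGGERS_ABOVE, out=out0)
        assert step_all(comp, values) == [out0] * len(values)

    @given(st.lists(st.floats(-1, 1, allow_nan=False), max_size=50))
    def test_monotone_trigger_regardless_of_history(self, history):
        comp = pk.ComparatorState(href=0.02834, lref=0.02441,
                                  polarity=Polarity.TRIGGERS_ABOVE)
        for v in history:
            comp = pk.comparator_step(comp, v)
        assert pk.comparator_step(comp, 0.5).out == 1


class TestThresholdSet:
    def test_default_forward_thresholds(self):
        th = pk.build_threshold_set(1.0, 0.0)
        assert th.Href_x == pytest.approx(0.98841)
        assert th.Lref_x == pytest.approx(0.99146)

    def test_default_lateral_thresholds(self):
        th = pk.build_threshold_set(1.0, 0.0)
        assert th.Href_yl == pytest.approx(0.02834)
        assert th.Href_yr == pytest.approx(-0.02834)
        assert th.Lref_yl == pytest.approx(0.02441)
        assert th.Lref_yr == pytest.approx(-0.02441)

    @pytest.mark.parametrize("slider", ["a", "b", "c", "d"])
    @pytest.mark.parametrize("value", [0, 301, -5])
    def test_slider_out_of_range_rejected(self, slider, value):
        with pytest.raises(ConfigurationError):
            pk.ThresholdSet(s_x_base=1.0, s_y_base=0.0, **{slider: value})

    def test_dict_round_trip_preserves_thresholds(self):
        th = pk.apply_sliders(pk.build_threshold_set(0.99288, -0.06689),
                              a=160, b=80, c=140, d=210)
        back = pk.ThresholdSet.from_dict(th.to_dict())
        for f in ("S_x", "S_y", "Href_x", "Lref_x", "Href_yl",
                  "Lref_yl", "Href_yr", "Lref_yr"):
            assert getattr(back, f) == pytest.approx(getattr(th, f))

    def test_json_file_round_trip(self, tmp_path):
        th = pk.build_threshold_set(1.0, 0.1)
        p = tmp_path / "th.json"
        th.save(p)
        back = pk.ThresholdSet.load(p)
        assert back.to_dict() == pytest.approx(th.to_dict())


class TestBuildComparators:
    def test_polarities_follow_threshold_ordering(self, default_thresholds):
        bank = pk.build_comparators(default_thresholds)
        assert bank.forward.polarity is Polarity.TRIGGERS_BELOW
        assert bank.left.polarity is Polarity.TRIGGERS_ABOVE
        assert bank.right.polarity is Polarity.TRIGGERS_BELOW

    def test_all_outputs_start_correct(self, default_thresholds):
        bank = pk.build_comparators(default_thresholds)
        assert (bank.forward.out, bank.left.out, bank.right.out) == (0, 0, 0)

    def test_forward_thresholds_wired_through(self, default_thresholds):
        bank = pk.build_comparators(default_thresholds)
        assert bank.forward.href == pytest.approx(0.98841)
        assert bank.forward.lref == pytest.approx(0.99146)
        assert bank.left.href == pytest.approx(0.02834)
        assert bank.right.href == pytest.approx(-0.02834)


class TestPostureState:
    @pytest.mark.parametrize(
        "flags,led",
        [
            (set(), {"middle"}),
            ({"forward"}, {"top"}),
            ({"left"}, {"left"}),
            ({"right"}, {"right"}),
            ({"forward", "left"}, {"top", "left"}),
            ({"forward", "right"}, {"top", "right"}),
        ],
    )
    def test_led_mapping(self, flags, led):
        state = pk.PostureState(flags=frozenset(flags))
        assert state.led == frozenset(led)
        assert ("middle" in state.led) == (not flags)

    def test_left_and_right_mutually_exclusive(self):
        with pytest.raises(ConfigurationError):
            pk.PostureState(flags=frozenset({"left", "right"}))

    @pytest.mark.parametrize(
        "flags,message",
        [
            (set(), None),
            ({"forward"}, "Too Forward!!"),
            ({"right"}, "Too Right!!"),
            ({"forward", "left"}, "Too Forward & Left!!"),
            ({"forward", "right"}, "Too Forward & Right!!"),
        ],
    )
    def test_messages(self, flags, message):
        assert posture_message(frozenset(flags)) == message


class TestAssess:
    def test_forward_tilt_flags_forward(self, default_thresholds):
        bank = pk.build_comparators(default_thresholds)
        fv = pk.FilteredValue(t=0.0, A_x=0.985, A_y=0.0, window_fill=10)
        _, state = pk.assess(fv, bank)
        assert state.flags == frozenset({"forward"})
        assert state.led == frozenset({"top"})

    def test_standard_posture_is_clean(self, default_thresholds):
        bank = pk.build_comparators(default_thresholds)
        fv = pk.FilteredValue(t=0.0, A_x=1.0, A_y=0.0, window_fill=10)
        _, state = pk.assess(fv, bank)
        assert state.flags == frozenset()
        assert state.message is None

    def test_lateral_exclusivity_resolved_by_deviation_side(self):
        # pathological overlapping bands so both lateral comparators trip
        bank = pk.ComparatorBank(
            forward=pk.ComparatorState(href=0.9, lref=0.95,
                                       polarity=Polarity.TRIGGERS_BELOW),
            left=pk.ComparatorState(href=0.01, lref=0.005,
                                    polarity=Polarity.TRIGGERS_ABOVE),
            right=pk.ComparatorState(href=0.02, lref=0.025,
                                     polarity=Polarity.TRIGGERS_BELOW),
            s_y=0.0,
        )
        fv = pk.FilteredValue(t=0.0, A_x=1.0, A_y=0.015, window_fill=10)
        _, state = pk.assess(fv, bank)
        assert state.flags == frozenset({"left"})


class TestEmitReminders:
    @staticmethod
    def held_stream(flags, duration, dt=0.1):
        state = pk.PostureState(flags=frozenset(flags))
        return [(k * dt, state) for k in range(int(duration / dt))]

    def test_thirty_seconds_poor_posture_yields_three_events(self):
        events = pk.emit_reminders(self.held_stream({"forward"}, 30.0),
                                   warning_time=1)
        assert len(events) == 3
        assert [e.t for e in events] == pytest.approx([0.0, 10.0, 20.0])

    def test_higher_warning_time_raises_frequency(self):
        events = pk.emit_reminders(self.held_stream({"forward"}, 30.0),
                                   warning_time=2)
        assert len(events) == 6

    def test_no_flags_no_events(self):
        assert pk.emit_reminders(self.held_stream(set(), 30.0), 1) == []

    def test_single_right_sample_emits_once(self):
        stream = [(0.0, pk.PostureState(flags=frozenset({"right"})))]
        (event,) = pk.emit_reminders(stream, warning_time=1)
        assert event.message == "Too Right!!"
        assert event.flags == frozenset({"right"})

    def test_flag_change_emits_immediately(self):
        stream = self.held_stream({"forward"}, 5.0)
        stream += [(t + 5.0, pk.PostureState(flags=frozenset({"forward", "left"})))
                   for t, _ in self.held_stream({"forward"}, 5.0)]
        events = pk.emit_reminders(stream, warning_time=1)
        assert [e.message for e in events] == ["Too Forward!!", "Too Forward & Left!!"]
        assert events[1].t == pytest.approx(5.0)

    def test_throttle_interval_respected(self):
        events = pk.emit_reminders(self.held_stream({"left"}, 60.0), warning_time=3)
        gaps = np.diff([e.t for e in events])
        assert (gaps >= 10.0 / 3 - 1e-9).all()

    def test_invalid_warning_time_rejected(self):
        with pytest.raises(ConfigurationError):
            pk.emit_reminders([], warning_time=0)
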