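"""Strategy validation and the adherence/deviation engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccw.trial_spec import (
    COMPLETION_OF_PREVIOUS,
    LAST_OCCURRENCE,
    TRIGGER_EVENT,
    AdherenceStatus,
    ComponentRule,
    ExcusalRule,
    History,
    StrategyError,
    StrategySpec,
    TimeGrid,
    adherence_status,
    first_deviation_time,
    validate_strategy,
)


def initiation(component="surgery", window=(0, 182), id="arm_a"):
    return StrategySpec(
        id=id, kind="initiation",
        components=(ComponentRule(component, "require", window),),
    )


def abstention(component="surgery", window=(0, 182), id="arm_b"):
    return StrategySpec(
        id=id, kind="abstention",
        components=(ComponentRule(component, "forbid", window),),
    )


class TestValidation:
    def test_valid_initiation_spec_passes(self):
        spec = initiation()
        assert validate_strategy(spec, {"surgery"}) is spec

    def test_unknown_component_rejected(self):
        with pytest.raises(StrategyError, match="unknown component"):
            validate_strategy(initiation(component="proton_beam"), {"surgery"})

    def test_inverted_window_rejected_at_construction(self):
        with pytest.raises(StrategyError, match="inverted window"):
            ComponentRule("surgery", "require", (100, 5))

    def test_negative_window_rejected(self):
        with pytest.raises(StrategyError, match="negative window"):
            ComponentRule("surgery", "require", (-3, 5))

    def test_contradictory_require_and_forbid_rejected(self):
        spec = StrategySpec(
            id="bad", kind="initiation",
            components=(
                ComponentRule("surgery", "require", (0, 100)),
                ComponentRule("surgery", "forbid", (50, 150)),
            ),
        )
        with pytest.raises(StrategyError, match="intersecting"):
            validate_strategy(spec, {"surgery"})

    def test_sequential_chain_validates(self):
        spec = StrategySpec(
            id="seq", kind="sequential",
            components=(
                ComponentRule("radiation", "require", (0, 7)),
                ComponentRule("surgery", "require", (0, 182), anchor=COMPLETION_OF_PREVIOUS),
            ),
        )
        assert validate_strategy(spec, {"radiation", "surgery"}) is spec

    def test_completion_anchor_outside_sequential_rejected(self):
        spec = StrategySpec(
            id="x", kind="initiation",
            components=(
                ComponentRule("surgery", "require", (0, 10), anchor=COMPLETION_OF_PREVIOUS),
            ),
        )
        with pytest.raises(StrategyError, match="sequential"):
            validate_strategy(spec, {"surgery"})

    def test_timegrid_invariants(self):
        with pytest.raises(StrategyError):
            TimeGrid(horizon=0)
        with pytest.raises(StrategyError):
            TimeGrid(horizon=10, interval_length=0)
        assert TimeGrid(horizon=10, interval_length=3).has_short_final_interval


class TestAdherenceStatus:
    def test_forbidden_event_deviates_at_occurrence(self):
        h = History({"surgery": [90]}, followup_end=300, event=1)
        st_ = adherence_status(h, abstention(), 90)
        assert st_ == AdherenceStatus("deviated", 90)

    def test_open_grace_window_still_consistent(self):
        h = History({}, followup_end=365)
        assert adherence_status(h, initiation(), 181).state == "consistent"

    def test_unmet_requirement_deviates_at_window_end(self):
        h = History({}, followup_end=365)
        st_ = adherence_status(h, initiation(), 182)
        assert st_ == AdherenceStatus("deviated", 182)

    def test_negative_time_rejected(self):
        with pytest.raises(StrategyError):
            adherence_status(History({}), initiation(), -1)

    def test_future_data_rejected(self):
        h = History({"surgery": [200]}, followup_end=365)
        with pytest.raises(StrategyError, match="extends beyond"):
            adherence_status(h, initiation(), 100)

    def test_excusal_before_violation_wins(self):
        spec = StrategySpec(
            id="a", kind="initiation",
            components=(ComponentRule("surgery", "require", (0, 182)),),
            excusals=(ExcusalRule("contraindication"),),
        )
        h = History({}, {"contraindication": [(50, 1)]}, followup_end=365)
        assert adherence_status(h, spec, 200).state == "excused"


class TestFirstDeviation:
    def test_death_during_grace_preempts_deadline(self):
        h = History({}, followup_end=112, event=1)
        assert first_deviation_time(h, initiation(), 365) is None

    def test_late_component_is_consistent_with_abstention(self):
        h = History({"surgery": [250]}, followup_end=365)
        assert first_deviation_time(h, abstention(), 365) is None

    def test_late_component_fails_requirement_at_window_end(self):
        h = History({"surgery": [250]}, followup_end=365)
        assert first_deviation_time(h, initiation(), 365) == 182

    def test_death_on_deadline_day_preempts(self):
        h = History({}, followup_end=182, event=1)
        assert first_deviation_time(h, initiation(), 365) is None

    def test_forbidden_event_on_death_day_is_retained(self):
        # tie-breaking (event over artificial) happens in censor_clones
        h = History({"surgery": [112]}, followup_end=112, event=1)
        assert first_deviation_time(h, abstention(), 365) == 112

    def test_component_on_window_end_day_counts_as_within(self):
        h = History({"surgery": [182]}, followup_end=365)
        assert first_deviation_time(h, initiation(), 365) is None
        assert first_deviation_time(h, abstention(), 365) == 182

    def test_horizon_truncates_detection(self):
        h = History({}, followup_end=365)
        assert first_deviation_time(h, initiation(), 100) is None


class TestRecurringSchedule:
    spec = StrategySpec(
        id="annual", kind="schedule",
        components=(ComponentRule("screen", "require", (0, 14), anchor=LAST_OCCURRENCE),),
        excusals=(ExcusalRule("incident_cancer"),),
    )

    def test_gap_beyond_limit_deviates_at_deadline(self):
        h = History({"screen": [0, 12]}, followup_end=36)
        assert first_deviation_time(h, self.spec, 96) == 26

    def test_excusal_suspends_further_requirements(self):
        h = History({"screen": [0, 12]}, {"incident_cancer": [(20, 1)]}, followup_end=36)
        assert first_deviation_time(h, self.spec, 96) is None

    def test_adherent_then_stops(self):
        h = History({"screen": [0, 13, 27, 41]}, followup_end=96)
        assert first_deviation_time(h, self.spec, 96) == 55


class TestDynamicStrategy:
    deferred = StrategySpec(
        id="deferred", kind="dynamic",
        components=(
            ComponentRule("adt", "forbid", (0, 729), lift_on_trigger="progression"),
            ComponentRule("adt", "require", (0, 91), anchor=TRIGGER_EVENT,
                          trigger="progression"),
        ),
    )

    def test_early_initiation_without_progression_deviates(self):
        h = History({"adt": [300]}, followup_end=1000)
        assert first_deviation_time(h, self.deferred, 1825) == 300

    def test_initiation_after_progression_is_consistent(self):
        h = History({"adt": [250]}, {"progression": [(200, 1)]}, followup_end=1000)
        assert first_deviation_time(h, self.deferred, 1825) is None

    def test_missing_initiation_after_progression_deviates(self):
        h = History({}, {"progression": [(200, 1)]}, followup_end=1000)
        assert first_deviation_time(h, self.deferred, 1825) == 291

    def test_initiation_after_two_years_is_consistent(self):
        h = History({"adt": [800]}, followup_end=1000)
        assert first_deviation_time(h, self.deferred, 1825) is None


@st.composite
def _history_and_t(draw):
    occ = draw(st.lists(st.integers(1, 400), max_size=4))
    fu = draw(st.integers(1, 400))
    occ = sorted(d for d in occ if d <= fu)
    t1 = draw(st.integers(0, 400))
    t2 = draw(st.integers(0, 400))
    return History({"surgery": occ}, followup_end=fu), min(t1, t2), max(t1, t2)


class TestProperties:
    @settings(max_examples=200, derandomize=True)
    @given(_history_and_t())
    def test_deviation_is_absorbing(self, case):
        """Once deviated at t, deviated (same as_of) at every later t'."""
        h, t_lo, t_hi = case

        def upto(t):
            return History(
                {"surgery": [d for d in h.occurrences("surgery") if d <= t]},
                followup_end=h.followup_end,
            )

        for spec in (initiation(), abstention()):
            s_lo = adherence_status(upto(t_lo), spec, t_lo)
            s_hi = adherence_status(upto(t_hi), spec, t_hi)
            if s_lo.state == "deviated":
                assert s_hi.state == "deviated"
                assert s_hi.as_of == s_lo.as_of

    @settings(max_examples=200, derandomize=True)
    @given(_history_and_t())
    def test_detection_never_inside_open_grace_window(self, case):
        """A require deviation is dated at a window end; a forbid deviation
        at a component occurrence."""
        h, _, _ = case
        fd = first_deviation_time(h, initiation(), 365)
        if fd is not None:
            assert fd == 182
        fd = first_deviation_time(h, abstention(), 365)
        if fd is not None:
            assert fd in h.occurrences("surgery")

    @settings(max_examples=200, derandomize=True)
    @given(_history_and_t())
    def test_two_arm_partition_after_grace(self, case):
        """A patient surviving uncensored past the window end deviates from
        exactly one of an initiation/abstention pair over the same window."""
        h, _, _ = case
        if h.followup_end <= 182:
            return
        fa = first_deviation_time(h, initiation(), 365)
        fb = first_deviation_time(h, abstention(), 365)
        in_window = [d for d in h.occurrences("surgery") if d <= 182]
        if in_window:
            assert fa is None and fb is not None
        else:
            assert fa is not None and fb is None
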