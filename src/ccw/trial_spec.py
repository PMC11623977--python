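"""Treatment-strategy protocols and adherence evaluation.

A target-trial emulation compares *treatment strategies* — protocol rules such
as "undergo surgery within 182 days of diagnosis" or "repeat screening within
14 months of the last screen".  This module declares those rules
(:class:`StrategySpec`) and evaluates a patient's observed history against
them: whether the patient is still consistent with a strategy at a time ``t``
(:func:`adherence_status`) and when, if ever, the data first reveal a protocol
deviation (:func:`first_deviation_time`).

Timing conventions (kept consistent package-wide):

* grace windows are closed on both ends in integer time units — a component
  occurring on day ``window_end`` still counts;
* an unmet *require* rule deviates at ``window_end`` itself (the earliest time
  the deviation is apparent in the data), but a death or classic censoring at
  or before ``window_end`` preempts the deviation;
* a *forbid* rule deviates at the day the forbidden component occurs;
* deviation is absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TIME_ZERO",
    "COMPLETION_OF_PREVIOUS",
    "LAST_OCCURRENCE",
    "TRIGGER_EVENT",
    "TimeGrid",
    "ComponentRule",
    "ExcusalRule",
    "StrategySpec",
    "AdherenceStatus",
    "History",
    "StrategyError",
    "validate_strategy",
    "adherence_status",
    "first_deviation_time",
    "censor_risk_open",
]

TIME_ZERO = "time-zero"
COMPLETION_OF_PREVIOUS = "completion-of-previous-component"
LAST_OCCURRENCE = "last-occurrence-of-component"
TRIGGER_EVENT = "trigger-event"

_ANCHORS = {TIME_ZERO, COMPLETION_OF_PREVIOUS, LAST_OCCURRENCE, TRIGGER_EVENT}
_KINDS = {"initiation", "abstention", "sequential", "schedule", "dynamic"}


class StrategyError(ValueError):
    """Invalid strategy specification or misuse of the adherence engine."""


@dataclass(frozen=True)
class TimeGrid:
    """Discrete follow-up grid: unit label, horizon, and interval width."""

    horizon: int
    interval_length: int = 1
    unit: str = "day"

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise StrategyError(f"horizon must be positive, got {self.horizon}")
        if self.interval_length < 1:
            raise StrategyError(
                f"interval_length must be >= 1, got {self.interval_length}"
            )

    @property
    def n_intervals(self) -> int:
        """Number of intervals covering (0, horizon]; the last may be short."""
        return -(-self.horizon // self.interval_length)

    @property
    def has_short_final_interval(self) -> bool:
        return self.horizon % self.interval_length != 0

    def interval_of(self, day: int) -> int:
        """Index of the interval (k*L, (k+1)*L] containing ``day`` (day >= 1)."""
        if day <= 0:
            return 0
        return (day - 1) // self.interval_length


@dataclass(frozen=True)
class ComponentRule:
    """One protocol rule about a treatment component.

    ``mode='require'``: the component must occur inside
    ``[anchor+window_start, anchor+window_end]``; failing to do so is a
    deviation detected at the window end.  ``mode='forbid'``: an occurrence
    inside the window is a deviation at the occurrence day.

    ``anchor`` chooses the window's origin: absolute time zero, the day the
    previous rule in a sequential strategy was satisfied, the last occurrence
    of this same component (recurring schedules such as repeat screening), or
    the first day a named time-varying covariate becomes truthy (dynamic
    strategies).  ``lift_on_trigger`` voids a forbid rule from the trigger's
    first truthy day onward (e.g., deferred therapy that becomes required once
    disease progression occurs).
    """

    component: str
    mode: str
    window: tuple[int, int]
    anchor: str = TIME_ZERO
    trigger: str | None = None
    lift_on_trigger: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("require", "forbid"):
            raise StrategyError(f"unknown rule mode {self.mode!r}")
        if self.anchor not in _ANCHORS:
            raise StrategyError(f"unknown anchor {self.anchor!r}")
        ws, we = self.window
        if ws < 0 or we < 0:
            raise StrategyError(f"negative window {self.window} for {self.component!r}")
        if we < ws:
            raise StrategyError(
                f"inverted window {self.window} for component {self.component!r}"
            )
        if self.anchor == TRIGGER_EVENT and not self.trigger:
            raise StrategyError("trigger-event anchor needs a trigger covariate name")


@dataclass(frozen=True)
class ExcusalRule:
    """A condition that suspends protocol requirements from its onset onward."""

    condition: str


@dataclass(frozen=True)
class StrategySpec:
    id: str
    kind: str
    components: tuple[ComponentRule, ...]
    excusals: tuple[ExcusalRule, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise StrategyError(f"unknown strategy kind {self.kind!r}")
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "excusals", tuple(self.excusals))


@dataclass(frozen=True)
class AdherenceStatus:
    state: str  # 'consistent' | 'deviated' | 'excused'
    as_of: int


class History:
    """One patient's observed data: treatment occurrences and covariate steps.

    Covariates are step functions: a sparse log of (day, value) records with
    the value carried forward between records.
    """

    def __init__(
        self,
        treatments: Mapping[str, Sequence[int]] | None = None,
        covariates: Mapping[str, Sequence[tuple[int, float]]] | None = None,
        followup_end: int | None = None,
        event: int = 0,
    ) -> None:
        self.treatments = {
            k: tuple(sorted(int(d) for d in v)) for k, v in (treatments or {}).items()
        }
        self.covariates = {
            k: tuple(sorted((int(d), v) for d, v in recs))
            for k, recs in (covariates or {}).items()
        }
        self.followup_end = followup_end
        self.event = int(event)

    def occurrences(self, component: str) -> tuple[int, ...]:
        return self.treatments.get(component, ())

    def covariate_at(self, name: str, day: int):
        """Last observed value at or before ``day`` (None if none yet)."""
        val = None
        for d, v in self.covariates.get(name, ()):
            if d > day:
                break
            val = v
        return val

    def first_truthy(self, name: str) -> int | None:
        """First day the named covariate is recorded with a truthy value."""
        for d, v in self.covariates.get(name, ()):
            if v:
                return d
        return None

    def max_observed_day(self) -> int:
        days = [d for occ in self.treatments.values() for d in occ]
        days += [d for recs in self.covariates.values() for d, _ in recs]
        return max(days, default=0)


def validate_strategy(
    spec: StrategySpec, known_components: Iterable[str]
) -> StrategySpec:
    """Check a strategy's internal consistency against the known component set."""
    known = set(known_components)
    for rule in spec.components:
        if rule.component not in known:
            raise StrategyError(
                f"strategy {spec.id!r}: unknown component {rule.component!r} "
                f"(known: {sorted(known)})"
            )
        if rule.anchor == COMPLETION_OF_PREVIOUS and spec.kind != "sequential":
            raise StrategyError(
                f"strategy {spec.id!r}: completion-of-previous anchor is only "
                "valid for sequential strategies"
            )
    if spec.kind == "sequential" and len(spec.components) < 2:
        raise StrategyError(f"sequential strategy {spec.id!r} needs >= 2 components")
    # contradictory require/forbid of one component over intersecting
    # absolute windows (only decidable for time-zero anchors)
    absolute = [r for r in spec.components if r.anchor == TIME_ZERO]
    for i, a in enumerate(absolute):
        for b in absolute[i + 1 :]:
            if a.component == b.component and a.mode != b.mode:
                if a.window[0] <= b.window[1] and b.window[0] <= a.window[1]:
                    if b.lift_on_trigger is None and a.lift_on_trigger is None:
                        raise StrategyError(
                            f"strategy {spec.id!r}: require and forbid of "
                            f"{a.component!r} over intersecting windows"
                        )
    return spec


@dataclass
class _Violation:
    time: int
    kind: str  # 'deadline' (unmet require) | 'occurrence' (forbidden event)
    rule: ComponentRule


def _rule_violations(
    history: History, spec: StrategySpec, upto: int | None
) -> list[_Violation]:
    """All rule violations detectable in data observed through ``upto``.

    ``upto=None`` means the full observed history.  Sequential chaining:
    a rule anchored to completion-of-previous is dormant until the previous
    rule has been satisfied.
    """
    out: list[_Violation] = []
    prev_satisfied_at: int | None = 0  # time zero anchors the first rule
    for rule in spec.components:
        anchor = _anchor_time(rule, history, prev_satisfied_at)
        satisfied_at: int | None = None
        if anchor is None:
            # dormant (trigger never fires / previous rule unsatisfied)
            if rule.anchor != COMPLETION_OF_PREVIOUS:
                prev_satisfied_at = None
            continue
        occ = history.occurrences(rule.component)
        if rule.anchor == LAST_OCCURRENCE:
            out.extend(_recurring_violations(rule, occ, history, upto))
            prev_satisfied_at = None
            continue
        ws, we = anchor + rule.window[0], anchor + rule.window[1]
        if rule.mode == "require":
            if rule.anchor == TRIGGER_EVENT:
                qualifying = [d for d in occ if d <= we]
            else:
                qualifying = [d for d in occ if ws <= d <= we]
            if upto is not None:
                qualifying = [d for d in qualifying if d <= upto]
            if qualifying:
                satisfied_at = qualifying[0]
            elif upto is None or we <= upto:
                out.append(_Violation(we, "deadline", rule))
        else:  # forbid
            lift = (
                history.first_truthy(rule.lift_on_trigger)
                if rule.lift_on_trigger
                else None
            )
            bad = [
                d
                for d in occ
                if ws <= d <= we
                and (lift is None or d < lift)
                and (upto is None or d <= upto)
            ]
            if bad:
                out.append(_Violation(bad[0], "occurrence", rule))
        prev_satisfied_at = satisfied_at
    return out


def _anchor_time(
    rule: ComponentRule, history: History, prev_satisfied_at: int | None
) -> int | None:
    if rule.anchor == TIME_ZERO:
        return 0
    if rule.anchor == COMPLETION_OF_PREVIOUS:
        return prev_satisfied_at
    if rule.anchor == TRIGGER_EVENT:
        return history.first_truthy(rule.trigger)
    return 0  # LAST_OCCURRENCE handled separately; nominal anchor


def _recurring_violations(
    rule: ComponentRule,
    occ: Sequence[int],
    history: History,
    upto: int | None,
) -> list[_Violation]:
    """Repeat-within-``window_end``-of-last-occurrence rule (e.g., screening).

    Anchors are time zero and every occurrence; the next occurrence must come
    within ``window_end`` units of the current anchor, else deviation at
    ``anchor + window_end``.
    """
    if rule.mode != "require":
        raise StrategyError("last-occurrence anchor only supports require rules")
    we = rule.window[1]
    anchor = 0
    for day in occ:
        if upto is not None and day > upto:
            break
        if day > anchor + we:
            return [_Violation(anchor + we, "deadline", rule)]
        anchor = max(anchor, day)
    deadline = anchor + we
    if upto is None or deadline <= upto:
        return [_Violation(deadline, "deadline", rule)]
    return []


def _excusal_time(history: History, spec: StrategySpec) -> int | None:
    times = [
        t
        for t in (history.first_truthy(e.condition) for e in spec.excusals)
        if t is not None
    ]
    return min(times, default=None)


def adherence_status(history: History, spec: StrategySpec, t: int) -> AdherenceStatus:
    """Adherence state implied by data observed on ``[0, t]``.

    An unmet require rule only counts once its window has fully elapsed
    (deviation dated and detected at the window end); a forbidden occurrence
    counts at its own day.  An excusal condition at or before the first
    violation suspends it.
    """
    if t < 0:
        raise StrategyError(f"t must be >= 0, got {t}")
    if history.max_observed_day() > t:
        raise StrategyError(
            "history extends beyond t: caller passed future data to adherence_status"
        )
    violations = _rule_violations(history, spec, upto=t)
    excusal = _excusal_time(history, spec)
    if excusal is not None and excusal > t:
        excusal = None
    first = min((v.time for v in violations), default=None)
    if excusal is not None and (first is None or excusal <= first):
        return AdherenceStatus("excused", excusal)
    if first is not None:
        return AdherenceStatus("deviated", first)
    return AdherenceStatus("consistent", t)


def first_deviation_time(
    history: History, spec: StrategySpec, horizon: int
) -> int | None:
    """Earliest time the observed data reveal a deviation, or None.

    Deviations are truncated at the patient's own end of follow-up: a
    require-rule deadline is preempted by death/classic censoring at or
    before it, and a forbidden occurrence on the last follow-up day is
    retained (downstream tie-breaking lets the outcome event win).
    """
    end = horizon
    if history.followup_end is not None:
        end = min(end, history.followup_end)
    excusal = _excusal_time(history, spec)
    candidates = []
    for v in _rule_violations(history, spec, upto=None):
        if excusal is not None and v.time >= excusal:
            continue  # requirements suspended from the excusal onward
        if v.kind == "deadline":
            if v.time < end:
                candidates.append(v.time)
        else:
            if v.time <= end:
                candidates.append(v.time)
    return min(candidates, default=None)


def censor_risk_open(
    history: History, spec: StrategySpec, t: int, horizon: int
) -> bool:
    """Could this strategy still artificially censor *someone* with this
    trigger/excusal history at time ``t``?

    This defines the risk set of the censoring weight model.  It is
    deliberately a function of the protocol windows and the covariate
    (trigger/excusal) history only — never of the patient's own treatment
    occurrences — so that, e.g., initiation-arm clones that already received
    treatment remain in the risk set throughout the grace window and are
    upweighted relative to grace-period-expiry censorings (they are the
    uncensored "successes" the model must see).  After the window closes the
    censoring hazard is structurally zero and rows contribute probability 1.
    """
    excusal = _excusal_time(history, spec)
    if excusal is not None and excusal <= t:
        return False
    prev_known = True
    for rule in spec.components:
        if rule.anchor == LAST_OCCURRENCE:
            return True  # recurring deadline always pending
        if rule.anchor == COMPLETION_OF_PREVIOUS:
            # conservatively at risk while the chain could still bind
            if prev_known and t < horizon:
                return True
            continue
        if rule.anchor == TRIGGER_EVENT:
            a = history.first_truthy(rule.trigger)
            if a is None:
                continue  # dormant: imposes nothing yet
        else:
            a = 0
        we = a + rule.window[1]
        if rule.mode == "forbid" and rule.lift_on_trigger:
            lift = history.first_truthy(rule.lift_on_trigger)
            if lift is not None:
                we = min(we, lift - 1)
        if t < we:
            return True
    return False
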