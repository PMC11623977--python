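"""Cloning, artificial censoring, and person-time expansion.

Every eligible patient is duplicated into one clone per treatment strategy at
time zero (using baseline data only, so baseline covariates are identical
across arms by construction).  Each clone is then followed until the earliest
of: the patient's outcome event, classic censoring (loss to follow-up or
administrative end of study), or *artificial censoring* — the first time the
observed data reveal that the patient's conduct deviates from the clone's
assigned strategy.  Ties on the same day resolve as
event > classic censoring > artificial censoring, which maximizes event
capture (a death on the deviation-detection day is counted as a death in that
arm — the property that removes immortal time bias).

The censored clones are finally expanded into an interval-level person-time
table (one row per clone per interval), the substrate for weight estimation
and weighted survival analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortBundle
from .trial_spec import (
    StrategySpec,
    TimeGrid,
    censor_risk_open,
    first_deviation_time,
    validate_strategy,
)

__all__ = [
    "Clone",
    "FlowReport",
    "make_clones",
    "censor_clones",
    "expand_person_time",
    "attrition_counts",
]


@dataclass
class Clone:
    """A (patient, strategy) pair with its resolved end of follow-up."""

    patient_id: object
    strategy_id: str
    followup_end: int
    event: int
    classic_censor_reason: str | None
    artificial_censor_time: int | None = None
    end_time: int | None = None
    end_reason: str | None = None  # 'event' | 'artificial' | 'lost' | 'administrative'


def make_clones(
    bundle: CohortBundle, strategies: list[StrategySpec]
) -> list[Clone]:
    """One clone per patient per strategy, assigned at time zero.

    Cloning uses no post-baseline information: every clone of a patient is an
    identical copy at baseline, so measured confounders are exactly balanced
    across arms at time zero.
    """
    if len(strategies) < 2:
        raise ValueError("need at least 2 strategies to emulate a trial")
    ids = [s.id for s in strategies]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate strategy ids: {ids}")
    known = bundle.component_names | {
        r.component for s in strategies for r in s.components
    }
    for s in strategies:
        validate_strategy(s, known)
    clones = []
    for row in bundle.patients.itertuples(index=False):
        for s in strategies:
            clones.append(
                Clone(
                    patient_id=row.id,
                    strategy_id=s.id,
                    followup_end=int(row.followup_end),
                    event=int(row.event),
                    classic_censor_reason=getattr(row, "classic_censor_reason", None),
                )
            )
    return clones


def censor_clones(
    clones: list[Clone],
    bundle: CohortBundle,
    strategies: list[StrategySpec],
) -> list[Clone]:
    """Set each clone's artificial-censoring time and resolved end of follow-up."""
    specs = {s.id: s for s in strategies}
    histories = bundle.histories()
    horizon = bundle.grid.horizon
    out = []
    for c in clones:
        hist = histories[c.patient_id]
        fd = first_deviation_time(hist, specs[c.strategy_id], horizon)
        c = Clone(**{**c.__dict__})
        c.artificial_censor_time = fd
        if fd is not None and fd < c.followup_end:
            c.end_time, c.end_reason = fd, "artificial"
        else:
            c.end_time = c.followup_end
            if c.event:
                c.end_reason = "event"
            else:
                c.end_reason = c.classic_censor_reason or "administrative"
        out.append(c)
    return out


PERSON_TIME_COLUMNS = [
    "patient_id",
    "strategy_id",
    "interval_index",
    "interval_start",
    "interval_end",
    "at_risk",
    "event_this_interval",
    "artificial_censor_this_interval",
    "classic_censor_this_interval",
    "at_censor_risk",
    "weight",
]


def expand_person_time(
    clones: list[Clone],
    bundle: CohortBundle,
    grid: TimeGrid | None = None,
    strategies: list[StrategySpec] | None = None,
    tv_covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Expand censored clones into one row per clone per interval.

    Intervals are ``(k*L, (k+1)*L]``; the final interval of a clone ends at
    its ``end_time`` (a short final interval is allowed).  Terminal indicators
    are placed only in the final row; all weights start at 1.  Baseline
    covariates are merged onto every row; time-varying covariates are merged
    by last observation carried forward, evaluated at each interval's start
    (falling back to a same-named baseline column before the first record).

    ``at_censor_risk`` marks rows inside the assigned strategy's
    censoring-risk window — the risk set for the artificial-censoring weight
    model (see :func:`ccw.trial_spec.censor_risk_open`).
    """
    grid = grid or bundle.grid
    L = grid.interval_length
    specs = {s.id: s for s in strategies} if strategies else {}
    histories = bundle.histories() if strategies or tv_covariates else {}

    n_rows = []
    for c in clones:
        n_rows.append(max(1, -(-c.end_time // L)))
    n_rows = np.asarray(n_rows, dtype=int)
    total = int(n_rows.sum())

    idx = np.concatenate([np.arange(k) for k in n_rows]) if total else np.array([], int)
    clone_ix = np.repeat(np.arange(len(clones)), n_rows)
    ends = np.asarray([c.end_time for c in clones], dtype=int)
    starts = idx * L
    stops = np.minimum((idx + 1) * L, ends[clone_ix])
    final = idx == (n_rows[clone_ix] - 1)

    reasons = np.asarray([c.end_reason for c in clones], dtype=object)
    df = pd.DataFrame(
        {
            "patient_id": np.asarray([c.patient_id for c in clones], object)[clone_ix],
            "strategy_id": np.asarray([c.strategy_id for c in clones], object)[clone_ix],
            "interval_index": idx,
            "interval_start": starts,
            "interval_end": stops,
            "at_risk": 1,
            "event_this_interval": (final & (reasons[clone_ix] == "event")).astype(int),
            "artificial_censor_this_interval": (
                final & (reasons[clone_ix] == "artificial")
            ).astype(int),
            "classic_censor_this_interval": (
                final & np.isin(reasons[clone_ix], ["lost", "administrative"])
            ).astype(int),
            "end_reason": reasons[clone_ix],
        }
    )

    # baseline covariates onto every row
    base = bundle.patients.set_index("id")[bundle.baseline_covariate_names]
    for col in base.columns:
        df[col] = df["patient_id"].map(base[col]).to_numpy()

    # time-varying covariates by LOCF at interval start
    tv = tv_covariates if tv_covariates is not None else sorted(bundle.tv_covariate_names)
    for name in tv:
        values = np.full(total, np.nan, dtype=float)
        baseline_fallback = name in base.columns
        cov = bundle.covariates[bundle.covariates["name"] == name]
        recs = {pid: (grp["day"].to_numpy(), grp["value"].to_numpy(float))
                for pid, grp in cov.groupby("id")}
        for ci, c in enumerate(clones):
            mask = clone_ix == ci
            row_starts = starts[mask]
            days, vals = recs.get(c.patient_id, (np.array([], int), np.array([])))
            pos = np.searchsorted(days, row_starts, side="right") - 1
            v = np.where(pos >= 0, vals[np.clip(pos, 0, None)], np.nan)
            if baseline_fallback:
                v = np.where(pos >= 0, v, float(base.loc[c.patient_id, name]))
            values[mask] = v
        if np.isnan(values).any() and not baseline_fallback:
            raise ValueError(
                f"time-varying covariate {name!r} has intervals before its first "
                "record and no baseline fallback column"
            )
        df[name] = values

    # censoring-risk window of the weight model
    if specs:
        risk = np.zeros(total, dtype=bool)
        # evaluate per clone from its trigger/excusal history and strategy windows
        offset = 0
        for ci, c in enumerate(clones):
            k = n_rows[ci]
            hist = histories[c.patient_id]
            spec = specs[c.strategy_id]
            for j in range(k):
                risk[offset + j] = censor_risk_open(
                    hist, spec, int(starts[offset + j]), grid.horizon
                )
            offset += k
        df["at_censor_risk"] = risk.astype(int)
    else:
        df["at_censor_risk"] = 1
    df["weight"] = 1.0
    return df


@dataclass
class FlowReport:
    """Figure-style study flow: screening, exclusions, cloning, censoring, events."""

    screened: int
    excluded: dict[str, int]
    eligible: int
    arms: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "screened": self.screened,
                "excluded_per_criterion": self.excluded,
                "eligible": self.eligible,
                "arms": self.arms,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def to_text(self) -> str:
        lines = [f"Screened: {self.screened}"]
        for crit, n in self.excluded.items():
            lines.append(f"  excluded ({crit}): {n}")
        lines.append(f"Eligible: {self.eligible}")
        for arm, counts in self.arms.items():
            lines.append(f"Arm {arm}:")
            for key, n in counts.items():
                lines.append(f"  {key}: {n}")
        return "\n".join(lines)


def attrition_counts(
    clones: list[Clone],
    exclusion_log: dict[str, int] | None = None,
    screened: int | None = None,
    bundle: CohortBundle | None = None,
) -> FlowReport:
    """Per-arm attrition: clones, artificial censorings by reason, events.

    Artificial censorings are split into forbidden-event censorings (detected
    at the day a forbidden component occurred) and grace-period-expiry
    censorings (a required component never came; detected at a window end).
    The split needs the treatment log, so it is reported only when ``bundle``
    is given: a censoring whose day coincides with one of the patient's own
    treatment occurrences is classified as forbidden-event.
    """
    exclusion_log = exclusion_log or {}
    patient_ids = {c.patient_id for c in clones}
    eligible = len(patient_ids)
    report = FlowReport(
        screened=screened if screened is not None else eligible + sum(exclusion_log.values()),
        excluded=dict(exclusion_log),
        eligible=eligible,
    )
    occ_days: dict = {}
    if bundle is not None and len(bundle.treatments):
        for pid, grp in bundle.treatments.groupby("id")["day"]:
            occ_days[pid] = set(int(d) for d in grp)
    arms = sorted({c.strategy_id for c in clones})
    for arm in arms:
        sub = [c for c in clones if c.strategy_id == arm]
        art = [c for c in sub if c.end_reason == "artificial"]
        counts = {
            "clones": len(sub),
            "artificially_censored": len(art),
            "events": sum(c.event for c in sub if c.end_reason == "event"),
            "lost": sum(1 for c in sub if c.end_reason == "lost"),
            "administrative": sum(1 for c in sub if c.end_reason == "administrative"),
        }
        if bundle is not None:
            forb = sum(
                1 for c in art if c.end_time in occ_days.get(c.patient_id, ())
            )
            counts["censored_forbidden_event"] = forb
            counts["censored_grace_expiry"] = len(art) - forb
        report.arms[arm] = counts
    return report
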