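"""Weighted survival estimation and per-protocol contrasts.

Per-arm survival is estimated by a weighted Kaplan–Meier product-limit
estimator on the weighted person-time table:

    S(t) = prod_{u <= t} (1 - dw(u) / nw(u))

with weighted event mass ``dw`` and weighted risk set ``nw`` per interval
(events are processed before same-interval censorings; artificially censored
rows carry weight 0 and leave the risk set at their censoring interval).
Alternatively, a weighted discrete-time (pooled logistic) outcome model with
arm, time, and arm-by-time terms yields smoothed cumulative incidence; with
saturated interval time and no covariates its predictions coincide exactly
with 1 minus the weighted Kaplan–Meier curve.

Contrasts (risk difference, survival difference, restricted-mean-survival-time
difference) are computed from the curves, with percentile bootstrap
confidence intervals that resample *patients* — not clones — and re-run the
entire clone/censor/weight/estimate pipeline per replicate, preserving the
correlation between clones of the same person.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortBundle
from .trial_spec import StrategySpec

__all__ = [
    "SurvivalCurve",
    "ContrastEstimate",
    "weighted_km",
    "fit_outcome_model",
    "contrast",
    "bootstrap_ci",
    "per_interval_risk_check",
]


@dataclass
class SurvivalCurve:
    """A per-arm weighted survival step function over interval end times."""

    strategy_id: str
    times: np.ndarray  # increasing interval end times (excluding 0)
    survival: np.ndarray  # S at each time; S(0) = 1 implicitly
    weighted_risk_set: np.ndarray
    weighted_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function evaluation: S at the last jump time <= t."""
        if t < 0:
            raise ValueError("t must be >= 0")
        ix = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if ix < 0 else float(self.survival[ix])

    def rmst(self, horizon: float) -> float:
        """Restricted mean survival time: exact area under the step function."""
        edges = np.concatenate([[0.0], self.times])
        values = np.concatenate([[1.0], self.survival])
        total = 0.0
        for i in range(len(edges)):
            left = edges[i]
            right = edges[i + 1] if i + 1 < len(edges) else np.inf
            if left >= horizon:
                break
            total += values[i] * (min(right, horizon) - left)
        return total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy_id": self.strategy_id,
                "time": self.times,
                "survival": self.survival,
                "weighted_risk_set": self.weighted_risk_set,
                "weighted_events": self.weighted_events,
            }
        )


@dataclass
class ContrastEstimate:
    estimand: str
    horizon: float
    point: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    ci_method: str | None = None
    replicates: int | None = None
    failed_replicates: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "estimand": self.estimand,
            "horizon": self.horizon,
            "point": self.point,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "ci_method": self.ci_method,
            "replicates": self.replicates,
            "failed_replicates": self.failed_replicates,
            "seed": self.seed,
        }


def weighted_km(table: pd.DataFrame, arm: str) -> SurvivalCurve:
    """Weighted Kaplan–Meier survival for one arm of a weighted table.

    Risk set at an interval = total weight of that interval's rows with
    positive weight (clones artificially censored in the interval carry
    weight 0 and are excluded; clones ending by event or classic censoring
    contribute their weight and leave afterwards).
    """
    rows = table[table["strategy_id"] == arm]
    if rows.empty:
        raise ValueError(f"no rows for arm {arm!r}")
    pos = rows[rows["weight"] > 0].copy()
    pos["_ev_w"] = pos["weight"] * pos["event_this_interval"]
    grp = pos.groupby("interval_index", sort=True)
    nw = grp["weight"].sum()
    dw = grp["_ev_w"].sum()
    ends = grp["interval_end"].max()
    order = nw.index.to_numpy()
    nw_v = nw.to_numpy(float)
    dw_v = dw.reindex(order).to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        factors = 1.0 - np.divide(dw_v, nw_v, out=np.zeros_like(dw_v), where=nw_v > 0)
    dead = nw_v <= 0
    if dead.any() and dw_v[np.argmax(dead):].sum() > 0:
        warnings.warn(
            f"arm {arm!r}: weighted risk set empty before the last event; "
            "curve truncated",
            stacklevel=2,
        )
    surv = np.cumprod(factors)
    return SurvivalCurve(
        strategy_id=arm,
        times=ends.reindex(order).to_numpy(float),
        survival=surv,
        weighted_risk_set=nw_v,
        weighted_events=dw_v,
    )


@dataclass
class OutcomeModelFit:
    """Weighted discrete-time outcome model: per-arm cumulative incidence."""

    arms: list[str]
    times: dict[str, np.ndarray]
    cumulative_incidence: dict[str, np.ndarray]
    hazards: dict[str, np.ndarray]
    time_form: str
    coefficients: dict | None = None

    def incidence_at(self, arm: str, t: float) -> float:
        ix = np.searchsorted(self.times[arm], t, side="right") - 1
        return 0.0 if ix < 0 else float(self.cumulative_incidence[arm][ix])

    def survival_curve(self, arm: str) -> SurvivalCurve:
        ci = self.cumulative_incidence[arm]
        return SurvivalCurve(
            strategy_id=arm,
            times=self.times[arm],
            survival=1.0 - ci,
            weighted_risk_set=np.full(len(ci), np.nan),
            weighted_events=np.full(len(ci), np.nan),
        )


def fit_outcome_model(
    table: pd.DataFrame, time_form: str = "categorical"
) -> OutcomeModelFit:
    """Weighted pooled logistic outcome model over all arms.

    Hazard of the event per interval given strategy, time, and their
    interaction; cumulative incidence per arm is the complement of the
    cumulative product of (1 - hazard).  With ``time_form='categorical'`` the
    model is saturated in (arm, interval): its maximum-likelihood hazards are
    the weighted per-cell event proportions, computed in closed form, and the
    predicted cumulative incidence reproduces 1 minus the weighted
    Kaplan–Meier curve exactly.  Smooth time forms (``spline:<df>``,
    ``polynomial:<deg>``) are fitted by weighted GLM.
    """
    pos = table[table["weight"] > 0]
    arms = sorted(pos["strategy_id"].unique())
    times: dict[str, np.ndarray] = {}
    cuminc: dict[str, np.ndarray] = {}
    hazards: dict[str, np.ndarray] = {}
    coefficients = None
    if time_form == "categorical":
        for arm in arms:
            curve = weighted_km(pos, arm)
            h = np.divide(
                curve.weighted_events,
                curve.weighted_risk_set,
                out=np.zeros_like(curve.weighted_events),
                where=curve.weighted_risk_set > 0,
            )
            times[arm] = curve.times
            hazards[arm] = h
            cuminc[arm] = 1.0 - np.cumprod(1.0 - h)
    else:
        from .weights import _time_columns  # shared basis construction

        y = pos["event_this_interval"].to_numpy(int)
        w = pos["weight"].to_numpy(float)
        t = pos["interval_index"].to_numpy()
        levels = np.unique(t)
        tm, tnames = _time_columns(time_form, t, levels)
        parts = [np.ones((len(pos), 1)), tm]
        names = ["intercept"] + tnames
        arm_codes = pd.Categorical(pos["strategy_id"], categories=arms)
        for k, arm in enumerate(arms[1:], start=1):
            a = (arm_codes.codes == k).astype(float)
            parts.append(a[:, None])
            names.append(f"arm[{arm}]")
            parts.append(tm * a[:, None])
            names.extend([f"arm[{arm}]:{n}" for n in tnames])
        X = np.column_stack(parts)
        glm = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = glm.fit(maxiter=200)
        if not res.converged:
            raise RuntimeError("weighted outcome model did not converge")
        coefficients = dict(zip(names, np.asarray(res.params, float)))
        ends = pos.groupby("interval_index")["interval_end"].max()
        for arm in arms:
            tm_g, _ = _time_columns(time_form, levels, levels)
            parts = [np.ones((len(levels), 1)), tm_g]
            for other in arms[1:]:
                a = 1.0 if other == arm else 0.0
                parts.append(np.full((len(levels), 1), a))
                parts.append(tm_g * a)
            Xg = np.column_stack(parts)
            h = np.asarray(res.predict(Xg), float)
            times[arm] = ends.reindex(levels).to_numpy(float)
            hazards[arm] = h
            cuminc[arm] = 1.0 - np.cumprod(1.0 - h)
    return OutcomeModelFit(
        arms=arms,
        times=times,
        cumulative_incidence=cuminc,
        hazards=hazards,
        time_form=time_form,
        coefficients=coefficients,
    )


_ESTIMANDS = ("risk_difference", "survival_difference", "rmst_difference")


def contrast(
    curves: dict[str, SurvivalCurve],
    estimand: str,
    horizon: float,
    arms: tuple[str, str] | None = None,
) -> ContrastEstimate:
    """Point contrast between two arms at a horizon.

    ``risk_difference`` = (1-S_A(h)) - (1-S_B(h)); ``survival_difference`` =
    S_A(h) - S_B(h); ``rmst_difference`` integrates the step functions
    exactly.  A is the first named arm, B the second.
    """
    if estimand not in _ESTIMANDS:
        raise ValueError(f"unknown estimand {estimand!r}")
    if arms is None:
        if len(curves) != 2:
            raise ValueError("specify arms= when more than two curves are present")
        arms = tuple(curves)  # insertion order
    a, b = arms
    for arm in (a, b):
        if arm not in curves:
            raise ValueError(f"no curve for arm {arm!r}")
        if horizon > 0 and len(curves[arm].times) and horizon > curves[arm].times[-1]:
            # beyond support the step function is flat; allowed, but the
            # horizon must not exceed the study horizon upstream
            pass
    if estimand == "risk_difference":
        point = (1 - curves[a].survival_at(horizon)) - (1 - curves[b].survival_at(horizon))
    elif estimand == "survival_difference":
        point = curves[a].survival_at(horizon) - curves[b].survival_at(horizon)
    else:
        point = curves[a].rmst(horizon) - curves[b].rmst(horizon)
    return ContrastEstimate(estimand=estimand, horizon=horizon, point=float(point))


def per_interval_risk_check(
    table: pd.DataFrame, threshold: float = 0.10
) -> list[str]:
    """Warn where weighted per-interval event risk reaches the threshold.

    Discrete-time (pooled logistic) hazard coefficients approximate hazard
    ratios only when per-interval risk is small; intervals at or above the
    threshold make that interpretation unsafe.
    """
    if table.empty:
        return []
    out = []
    for arm in sorted(table["strategy_id"].unique()):
        curve = weighted_km(table, arm)
        with np.errstate(invalid="ignore", divide="ignore"):
            risk = np.divide(
                curve.weighted_events,
                curve.weighted_risk_set,
                out=np.zeros_like(curve.weighted_events),
                where=curve.weighted_risk_set > 0,
            )
        for t, r in zip(curve.times, risk):
            if r >= threshold:
                out.append(
                    f"arm {arm!r}, interval ending {t:g}: weighted event risk "
                    f"{r:.3f} >= {threshold:g}; pooled-logistic coefficients "
                    "should not be read as hazard ratios"
                )
    return out


def bootstrap_ci(
    bundle: CohortBundle,
    strategies: list[StrategySpec],
    estimand: str,
    horizon: float,
    weight_spec=None,
    B: int = 500,
    seed: int = 0,
    arms: tuple[str, str] | None = None,
    engine: str = "auto",
) -> ContrastEstimate:
    """Percentile bootstrap CI for a contrast, resampling patients.

    Each replicate draws n patients with replacement, re-clones, re-censors,
    re-estimates the weights, and re-computes the weighted Kaplan–Meier
    contrast, so the clone-of-the-same-person correlation is preserved.
    Replicates that fail (e.g., an arm empties) are excluded and counted.

    ``engine='auto'`` uses an aggregated count-based evaluation of the
    identical pipeline algebra when the configuration allows it (two-arm
    initiation/abstention, empirical weights on discrete baseline strata) and
    the row-level pipeline otherwise.
    """
    from .pipeline import estimate_once  # avoids an import cycle
    from . import _fast

    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    n = bundle.n_patients

    fast_data = None
    if engine in ("auto", "aggregate"):
        fast_data = _fast.prepare(bundle, strategies, weight_spec, arms=arms)
        if fast_data is None and engine == "aggregate":
            raise ValueError("aggregate engine not applicable to this configuration")
    if fast_data is not None:
        point = _fast.estimate(fast_data, np.arange(n), estimand, horizon)
    else:
        point = estimate_once(bundle, strategies, weight_spec, estimand, horizon, arms)

    estimates = []
    failed = 0
    if fast_data is not None:
        for _ in range(B):
            idx = rng.integers(0, n, size=n)
            try:
                estimates.append(_fast.estimate(fast_data, idx, estimand, horizon))
            except (ZeroDivisionError, FloatingPointError, ValueError):
                failed += 1
    else:
        ids = bundle.patients["id"].to_numpy()
        for _ in range(B):
            idx = rng.integers(0, n, size=n)
            try:
                rb = _resample_bundle(bundle, idx)
                estimates.append(
                    estimate_once(rb, strategies, weight_spec, estimand, horizon, arms)
                )
            except Exception:
                failed += 1
    if not estimates:
        raise RuntimeError("all bootstrap replicates failed")
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return ContrastEstimate(
        estimand=estimand,
        horizon=horizon,
        point=float(point),
        ci_lower=float(lo),
        ci_upper=float(hi),
        ci_method="bootstrap_percentile",
        replicates=len(estimates),
        failed_replicates=failed,
        seed=seed,
    )


def _resample_bundle(bundle: CohortBundle, idx: np.ndarray) -> CohortBundle:
    """Patient-level resample with fresh unique ids per drawn copy."""
    pts = bundle.patients.iloc[idx].reset_index(drop=True).copy()
    old_ids = pts["id"].to_numpy(object).copy()
    new_ids = np.array([f"{pid}#{k}" for k, pid in enumerate(old_ids)], object)
    pts["id"] = new_ids
    parts_t, parts_c = [], []
    trt_by_id = dict(tuple(bundle.treatments.groupby("id"))) if len(bundle.treatments) else {}
    cov_by_id = dict(tuple(bundle.covariates.groupby("id"))) if len(bundle.covariates) else {}
    for k, pid in enumerate(old_ids):
        t = trt_by_id.get(pid)
        if t is not None:
            t = t.copy()
            t["id"] = new_ids[k]
            parts_t.append(t)
        c = cov_by_id.get(pid)
        if c is not None:
            c = c.copy()
            c["id"] = new_ids[k]
            parts_c.append(c)
    trt = pd.concat(parts_t, ignore_index=True) if parts_t else bundle.treatments.iloc[:0]
    cov = pd.concat(parts_c, ignore_index=True) if parts_c else bundle.covariates.iloc[:0]
    return CohortBundle(pts, trt, cov, bundle.grid)
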