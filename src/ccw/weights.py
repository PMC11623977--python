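"""Inverse-probability weights for artificial (and classic) censoring.

After cloning and censoring, the artificial censoring is informative: it is
driven by the same covariates that drive treatment uptake and the outcome.
Uncensored person-time is therefore reweighted by the inverse of the
estimated probability of remaining artificially uncensored, so that in the
weighted population measured covariates no longer predict censoring.

Two implementations are provided, following the two families in the applied
literature:

* **IPCW** — a discrete-time model of artificial censoring fitted per arm on
  the cloned-censored person-time (pooled logistic, or exact empirical
  stratum proportions);
* **IPTW** — a discrete-time model of treatment initiation fitted on the
  *original* (uncloned) cohort person-time, mapped onto each clone as the
  inverse probability of remaining compatible with its assigned strategy.
  Implemented for initiation/abstention strategy pairs over a single grace
  window (the configuration for which the literature describes it).

Weights accumulate multiplicatively over intervals
(``w_k = prod_{j<=k} num_j / den_j``), may be stabilized by a baseline-only
numerator model, truncated at a percentile, and multiplied with classic
loss-to-follow-up censoring weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline

from .cohort import CohortBundle
from .trial_spec import StrategySpec, TimeGrid, TIME_ZERO

__all__ = [
    "WeightModelSpec",
    "FittedWeightModel",
    "PositivityError",
    "PositivityWarning",
    "fit_uncensored_model",
    "fit_classic_model",
    "compute_ipcw",
    "compute_iptw",
    "truncate_weights",
    "combine_classic_weights",
]

POSITIVITY_FLOOR = 1e-6


class PositivityError(RuntimeError):
    """Structural positivity violation: an arm's weighted risk set is empty."""


class PositivityWarning(UserWarning):
    """Fitted uncensored-probability below the positivity floor."""


@dataclass(frozen=True)
class WeightModelSpec:
    """How the censoring/treatment probabilities are estimated.

    ``implementation``: ``ipcw`` | ``iptw`` | ``nonparametric`` (an alias for
    IPCW with exact empirical stratum proportions).  ``estimator``:
    ``pooled-logistic`` | ``empirical``.  ``time_form``: ``categorical`` |
    ``spline:<df>`` | ``polynomial:<degree>``; ``default`` picks categorical
    interval time when the grid has <= 20 intervals, else a cubic B-spline
    with 4 df.  ``numerator_covariates`` non-empty (or ``stabilized=True``)
    turns on stabilization: the numerator model conditions on those baseline
    covariates plus time only.
    """

    implementation: str = "ipcw"
    denominator_covariates: tuple[str, ...] = ()
    numerator_covariates: tuple[str, ...] = ()
    stabilized: bool = False
    estimator: str | None = None
    time_form: str = "default"
    truncation_percentile: float | None = None

    def __post_init__(self) -> None:
        if self.implementation not in ("ipcw", "iptw", "nonparametric"):
            raise ValueError(f"unknown implementation {self.implementation!r}")
        object.__setattr__(
            self, "denominator_covariates", tuple(self.denominator_covariates)
        )
        object.__setattr__(
            self, "numerator_covariates", tuple(self.numerator_covariates)
        )
        extra = set(self.numerator_covariates) - set(self.denominator_covariates)
        if extra:
            raise ValueError(
                f"numerator covariates {sorted(extra)} not in the denominator set"
            )
        if self.truncation_percentile is not None and not (
            0 < self.truncation_percentile <= 100
        ):
            raise ValueError("truncation_percentile must lie in (0, 100]")

    @property
    def is_stabilized(self) -> bool:
        return self.stabilized or len(self.numerator_covariates) > 0

    def resolved_estimator(self) -> str:
        if self.implementation == "nonparametric":
            return "empirical"
        return self.estimator or "pooled-logistic"

    def resolved_time_form(self, n_intervals: int) -> str:
        if self.time_form != "default":
            return self.time_form
        return "categorical" if n_intervals <= 20 else "spline:4"


def _bspline_basis(x: np.ndarray, df: int, degree: int = 3) -> np.ndarray:
    """Cubic B-spline basis with interior knots at quantiles (df columns)."""
    x = np.asarray(x, float)
    n_interior = max(df - degree, 0)
    if n_interior:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.array([])
    lo, hi = x.min(), x.max() + 1e-9
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    n_basis = len(knots) - degree - 1
    basis = np.empty((len(x), n_basis))
    for i in range(n_basis):
        coefs = np.zeros(n_basis)
        coefs[i] = 1.0
        basis[:, i] = BSpline(knots, coefs, degree, extrapolate=True)(x)
    return basis[:, : max(df, 1)]


def _time_columns(time_form: str, interval_index: np.ndarray, levels: np.ndarray):
    """Time portion of a design matrix; returns (matrix, names)."""
    t = np.asarray(interval_index, float)
    if time_form == "categorical":
        cols = [(t == lev).astype(float) for lev in levels[1:]]
        names = [f"t[{int(lev)}]" for lev in levels[1:]]
        if not cols:
            return np.empty((len(t), 0)), []
        return np.column_stack(cols), names
    if time_form.startswith("spline"):
        df = int(time_form.split(":")[1]) if ":" in time_form else 4
        if df < 2:
            raise ValueError("spline df must be >= 2")
        return _bspline_basis(t, df), [f"bs(t){i}" for i in range(df)]
    if time_form.startswith("polynomial"):
        deg = int(time_form.split(":")[1]) if ":" in time_form else 2
        scale = max(t.max(), 1.0)
        cols = np.column_stack([(t / scale) ** k for k in range(1, deg + 1)])
        return cols, [f"t^{k}" for k in range(1, deg + 1)]
    raise ValueError(f"unknown time_form {time_form!r}")


def _design(
    rows: pd.DataFrame,
    covariates: Sequence[str],
    time_form: str,
    time_levels: np.ndarray,
):
    parts = [np.ones((len(rows), 1))]
    names = ["intercept"]
    for cov in covariates:
        col = rows[cov]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            parts.append(dummies.to_numpy())
            names.extend(dummies.columns.tolist())
        else:
            parts.append(col.to_numpy(float)[:, None])
            names.append(cov)
    tm, tn = _time_columns(time_form, rows["interval_index"].to_numpy(), time_levels)
    parts.append(tm)
    names.extend(tn)
    return np.column_stack(parts), names


@dataclass
class FittedWeightModel:
    """A fitted per-arm discrete-time censoring (or initiation) model."""

    arm: str
    response: str
    estimator: str
    covariates: tuple[str, ...]
    time_form: str | None = None
    coefficients: dict | None = None
    strata_probs: pd.DataFrame | None = None  # empirical: per (strata, interval)
    converged: bool = True
    n_rows: int = 0
    n_events: int = 0
    _glm_result: object = field(default=None, repr=False)
    _time_levels: np.ndarray | None = field(default=None, repr=False)

    def predict_event_probability(self, rows: pd.DataFrame) -> np.ndarray:
        """P(censoring/initiation event in interval | covariates, time)."""
        if self.estimator == "empirical":
            key_cols = list(self.covariates) + ["interval_index"]
            keyed = rows[key_cols].astype(object)
            merged = keyed.merge(self.strata_probs, how="left", on=key_cols)
            p = merged["p_event"].to_numpy(float)
            return np.where(np.isnan(p), 0.0, p)
        X, _ = _design(rows, self.covariates, self.time_form, self._time_levels)
        return self._glm_result.predict(X)

    def summary(self) -> dict:
        out = {
            "arm": self.arm,
            "response": self.response,
            "estimator": self.estimator,
            "covariates": list(self.covariates),
            "time_form": self.time_form,
            "converged": self.converged,
            "n_rows": self.n_rows,
            "n_events": self.n_events,
        }
        if self.coefficients is not None:
            out["coefficients"] = self.coefficients
        return out


def _fit_discrete_hazard(
    rows: pd.DataFrame,
    response: str,
    covariates: Sequence[str],
    estimator: str,
    time_form: str,
    arm: str,
) -> FittedWeightModel:
    if rows.empty:
        raise PositivityError(f"arm {arm!r}: zero at-risk rows for {response} model")
    y = rows[response].to_numpy(int)
    if estimator == "empirical":
        key_cols = list(covariates) + ["interval_index"]
        grp = (
            rows.assign(_y=y)
            .groupby(key_cols, dropna=False, observed=True)["_y"]
            .mean()
            .rename("p_event")
            .reset_index()
        )
        grp[key_cols] = grp[key_cols].astype(object)
        return FittedWeightModel(
            arm=arm,
            response=response,
            estimator="empirical",
            covariates=tuple(covariates),
            strata_probs=grp,
            n_rows=len(rows),
            n_events=int(y.sum()),
        )
    levels = np.unique(rows["interval_index"].to_numpy())
    X, names = _design(rows, covariates, time_form, levels)
    if y.sum() == 0:
        # no censoring events at all: hazard identically zero
        model = FittedWeightModel(
            arm=arm, response=response, estimator="zero",
            covariates=tuple(covariates), time_form=time_form,
            n_rows=len(rows), n_events=0,
        )
        model.predict_event_probability = lambda r: np.zeros(len(r))  # type: ignore
        return model
    glm = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = glm.fit(maxiter=200)
    if not res.converged:
        raise RuntimeError(
            f"arm {arm!r}: pooled logistic {response} model did not converge "
            "(possible separation); consider the empirical estimator or fewer strata"
        )
    return FittedWeightModel(
        arm=arm,
        response=response,
        estimator="pooled-logistic",
        covariates=tuple(covariates),
        time_form=time_form,
        coefficients=dict(zip(names, np.asarray(res.params, float))),
        converged=bool(res.converged),
        n_rows=len(rows),
        n_events=int(y.sum()),
        _glm_result=res,
        _time_levels=levels,
    )


def fit_uncensored_model(
    table: pd.DataFrame,
    spec: WeightModelSpec,
    arm: str,
    grid: TimeGrid | None = None,
    numerator: bool = False,
) -> FittedWeightModel:
    """Discrete-time model of artificial censoring for one arm.

    The risk set is the rows flagged ``at_censor_risk`` — person-time inside
    the strategy's censoring-risk window.  Rows outside the window have
    structurally zero censoring hazard and contribute probability 1 downstream.
    """
    rows = table[(table["strategy_id"] == arm) & (table["at_censor_risk"] == 1)]
    covs = spec.numerator_covariates if numerator else spec.denominator_covariates
    n_intervals = (
        grid.n_intervals if grid is not None else int(table["interval_index"].max()) + 1
    )
    return _fit_discrete_hazard(
        rows,
        "artificial_censor_this_interval",
        covs,
        spec.resolved_estimator(),
        spec.resolved_time_form(n_intervals),
        arm,
    )


def fit_classic_model(
    table: pd.DataFrame,
    spec: WeightModelSpec,
    arm: str,
    grid: TimeGrid | None = None,
) -> FittedWeightModel:
    """Discrete-time model of loss to follow-up ('classic' censoring).

    Only informative loss (``end_reason == 'lost'``) counts as the event;
    administrative end of study is treated as non-informative.
    """
    rows = table[table["strategy_id"] == arm].copy()
    rows["_lost"] = (
        (rows["classic_censor_this_interval"] == 1) & (rows["end_reason"] == "lost")
    ).astype(int)
    n_intervals = (
        grid.n_intervals if grid is not None else int(table["interval_index"].max()) + 1
    )
    return _fit_discrete_hazard(
        rows,
        "_lost",
        spec.denominator_covariates,
        spec.resolved_estimator(),
        spec.resolved_time_form(n_intervals),
        arm,
    )


def _positivity_check(p_unc: np.ndarray, rows: pd.DataFrame, arm: str, covs) -> None:
    bad = p_unc < POSITIVITY_FLOOR
    if bad.any():
        strata = (
            rows.loc[bad, list(covs) + ["interval_index"]].drop_duplicates()
            if covs
            else rows.loc[bad, ["interval_index"]].drop_duplicates()
        )
        warnings.warn(
            f"arm {arm!r}: fitted uncensored-probability below {POSITIVITY_FLOOR} in "
            f"{len(strata)} stratum/interval cell(s) — near-positivity violation:\n"
            f"{strata.to_string(index=False)}",
            PositivityWarning,
            stacklevel=3,
        )


def _accumulate(table: pd.DataFrame, ratio: np.ndarray) -> pd.DataFrame:
    """Cumulative-product weights per clone; censored final rows get weight 0."""
    out = table.copy()
    out["_ratio"] = ratio
    out = out.sort_values(
        ["strategy_id", "patient_id", "interval_index"], kind="stable"
    ).reset_index(drop=True)
    out["weight"] = out.groupby(
        ["strategy_id", "patient_id"], sort=False
    )["_ratio"].cumprod()
    out.loc[out["artificial_censor_this_interval"] == 1, "weight"] = 0.0
    out = out.drop(columns="_ratio")
    return out


def compute_ipcw(
    table: pd.DataFrame,
    models: dict[str, FittedWeightModel],
    spec: WeightModelSpec,
    numerator_models: dict[str, FittedWeightModel] | None = None,
) -> pd.DataFrame:
    """Attach inverse-probability-of-censoring weights to the person-time table.

    ``w_k = prod_{j<=k} num_j / den_j`` per clone, where ``den_j`` is the
    fitted probability of remaining uncensored in interval ``j`` (1 outside
    the censoring-risk window) and the numerator is 1 (unstabilized) or the
    baseline-covariate stabilization model's probability.  The final row of
    an artificially censored clone gets weight 0.
    """
    den = np.ones(len(table))
    num = np.ones(len(table))
    for arm, model in models.items():
        mask = (table["strategy_id"] == arm) & (table["at_censor_risk"] == 1)
        rows = table[mask]
        if rows.empty:
            continue
        p_unc = 1.0 - np.asarray(model.predict_event_probability(rows), float)
        _positivity_check(p_unc, rows, arm, spec.denominator_covariates)
        den[mask.to_numpy()] = p_unc
        if spec.is_stabilized:
            if not numerator_models or arm not in numerator_models:
                raise ValueError("stabilization requested but no numerator model given")
            p_num = 1.0 - np.asarray(
                numerator_models[arm].predict_event_probability(rows), float
            )
            num[mask.to_numpy()] = p_num
    if (den <= 0).any():
        keep = den > 0
        # probability 0 can only be predicted for rows that are themselves
        # censored in that cell; their weight is 0 regardless
        offending = table[~keep & (table["artificial_censor_this_interval"] != 1)]
        if len(offending):
            raise PositivityError(
                "fitted uncensored-probability is 0 for surviving person-time "
                f"({len(offending)} row(s)) — structural positivity violation"
            )
        den = np.where(keep, den, 1.0)
    out = _accumulate(table, num / den)
    for arm in models:
        if not (out.loc[out["strategy_id"] == arm, "weight"] > 0).any():
            raise PositivityError(f"arm {arm!r} has no positive-weight person-time")
    return out


def truncate_weights(
    table: pd.DataFrame, percentile: float
) -> tuple[pd.DataFrame, int]:
    """Cap weights at the given percentile of the positive-weight distribution.

    The percentile is the inverted-CDF sample percentile (the smallest
    observed weight with cumulative frequency >= p), so truncation maps
    weights onto an observed value.  Returns the capped table and the number
    of rows affected.
    """
    if not (0 < percentile <= 100):
        raise ValueError("percentile must lie in (0, 100]")
    out = table.copy()
    pos = out.loc[out["weight"] > 0, "weight"].to_numpy()
    if len(pos) == 0:
        return out, 0
    cap = float(np.percentile(pos, percentile, method="inverted_cdf"))
    n_truncated = int((out["weight"] > cap).sum())
    out.loc[out["weight"] > cap, "weight"] = cap
    return out, n_truncated


def combine_classic_weights(
    table: pd.DataFrame,
    classic_models: dict[str, FittedWeightModel],
) -> pd.DataFrame:
    """Multiply artificial-censoring weights with classic-censoring weights.

    The classic model predicts remaining free of loss to follow-up; its
    inverse-probability weight accumulates per clone exactly like the
    artificial weight, and the two multiply row-wise.
    """
    den = np.ones(len(table))
    for arm, model in classic_models.items():
        mask = table["strategy_id"] == arm
        rows = table[mask]
        if rows.empty:
            continue
        p_free = 1.0 - np.asarray(model.predict_event_probability(rows), float)
        _positivity_check(p_free, rows, arm, model.covariates)
        den[mask.to_numpy()] = p_free
    if (den <= 0).any():
        lost_here = (table["classic_censor_this_interval"] == 1) & (
            table["end_reason"] == "lost"
        )
        if ((den <= 0) & ~lost_here.to_numpy()).any():
            raise PositivityError(
                "fitted loss-free probability is 0 for retained person-time"
            )
        den = np.where(den > 0, den, 1.0)
    out = table.sort_values(
        ["strategy_id", "patient_id", "interval_index"], kind="stable"
    ).reset_index(drop=True)
    order = table.sort_values(
        ["strategy_id", "patient_id", "interval_index"], kind="stable"
    ).index.to_numpy()
    classic_w = pd.Series(1.0 / den[order]).groupby(
        [out["strategy_id"], out["patient_id"]], sort=False
    ).cumprod()
    lost_final = (out["classic_censor_this_interval"] == 1) & (
        out["end_reason"] == "lost"
    )
    classic_w[lost_final] = 0.0
    out["weight"] = out["weight"].to_numpy() * classic_w.to_numpy()
    return out


def _initiation_pair(strategies: list[StrategySpec]):
    """Identify (require_arm, forbid_arm, component, grace_end) or raise."""
    req = forb = None
    for s in strategies:
        if len(s.components) != 1:
            raise NotImplementedError(
                "IPTW implementation covers single-component initiation/abstention "
                "pairs; use IPCW for other strategy kinds"
            )
        r = s.components[0]
        if r.anchor != TIME_ZERO:
            raise NotImplementedError("IPTW needs time-zero-anchored windows")
        if r.mode == "require":
            req = (s.id, r)
        else:
            forb = (s.id, r)
    if req is None or forb is None or len(strategies) != 2:
        raise NotImplementedError(
            "IPTW needs exactly one require-arm and one forbid-arm"
        )
    if req[1].component != forb[1].component or req[1].window != forb[1].window:
        raise NotImplementedError(
            "IPTW needs the two arms to reference the same component and window"
        )
    return req[0], forb[0], req[1].component, req[1].window[1]


def _iptw_factors(
    bundle: CohortBundle,
    table: pd.DataFrame,
    covs: list[str],
    estimator: str,
    time_form: str,
    require_arm: str,
    forbid_arm: str,
    component: str,
    grace_end: int,
    grid: TimeGrid,
) -> np.ndarray:
    """Per-row compatibility-probability factors from the original cohort."""
    pts = bundle.patients
    first_trt = (
        bundle.treatments[bundle.treatments["component"] == component]
        .groupby("id")["day"]
        .min()
    )
    t_init = pts["id"].map(first_trt).to_numpy(float)  # NaN = never
    fu_end = pts["followup_end"].to_numpy(int)
    J_g = grid.interval_of(grace_end)
    L = grid.interval_length

    # per-patient: interval of own follow-up end, initiation interval (if any
    # at or before the grace end and strictly before follow-up end — the same
    # definition as the abstention arm's artificial censoring)
    end_iv = np.array([grid.interval_of(e) for e in fu_end])
    init_ok = (~np.isnan(t_init)) & (t_init <= grace_end) & (t_init < fu_end)
    init_iv = np.where(init_ok, [grid.interval_of(int(t)) if not np.isnan(t) else -1
                                 for t in t_init], -1)

    strata_vals = (
        pts[covs].astype(object).apply(tuple, axis=1).to_numpy()
        if covs
        else np.array([()] * len(pts), dtype=object)
    )
    strata_levels = sorted(set(strata_vals))
    pt_codes = np.array([strata_levels.index(t) for t in strata_vals])

    lam: dict[tuple, np.ndarray] = {}
    p_by_g: dict[tuple, float] = {}
    if estimator == "empirical":
        for zi, z in enumerate(strata_levels):
            zmask = pt_codes == zi
            lam_z = np.zeros(J_g + 1)
            for j in range(J_g + 1):
                at_risk = zmask & (end_iv >= j) & ((init_iv == -1) | (init_iv >= j))
                n = int(at_risk.sum())
                c = int((at_risk & (init_iv == j)).sum())
                lam_z[j] = c / n if n else 0.0
            lam[z] = lam_z
            present = zmask & (end_iv >= J_g)
            n = int(present.sum())
            # a censoring at the grace end needs: untreated within the window
            # AND own follow-up continuing strictly beyond it
            censored = int((present & ~init_ok & (fu_end > grace_end)).sum())
            p_by_g[z] = 1.0 - censored / n if n else np.nan
    else:
        # pooled logistic on original person-time (untreated at-risk rows)
        rows = []
        for i in range(len(pts)):
            last = min(end_iv[i], init_iv[i] if init_iv[i] >= 0 else end_iv[i], J_g)
            for j in range(last + 1):
                rows.append((strata_vals[i], j, int(init_iv[i] == j)))
        orig = pd.DataFrame(rows, columns=["_z", "interval_index", "_init"])
        for k, cov in enumerate(covs):
            orig[cov] = [z[k] for z in orig["_z"]]
        model = _fit_discrete_hazard(
            orig, "_init", covs, "pooled-logistic", time_form, "original-cohort",
        )
        pred_grid = pd.DataFrame(
            [(z, j) for z in strata_levels for j in range(J_g + 1)],
            columns=["_z", "interval_index"],
        )
        for k, cov in enumerate(covs):
            pred_grid[cov] = [z[k] for z in pred_grid["_z"]]
        lam_flat = np.asarray(model.predict_event_probability(pred_grid), float)
        for zi, z in enumerate(strata_levels):
            lam[z] = lam_flat[zi * (J_g + 1) : (zi + 1) * (J_g + 1)]
            p_by_g[z] = 1.0 - float(np.prod(1.0 - lam[z]))

    # map per-interval compatibility factors onto the clone table
    code_of = {z: k for k, z in enumerate(strata_levels)}
    if covs:
        row_codes = np.array(
            [code_of[t] for t in table[covs].astype(object).apply(tuple, axis=1)]
        )
    else:
        row_codes = np.zeros(len(table), int)
    iv = table["interval_index"].to_numpy()
    arm = table["strategy_id"].to_numpy()
    den = np.ones(len(table))
    for z in strata_levels:
        zmask = row_codes == code_of[z]
        m = zmask & (arm == forbid_arm) & (iv <= J_g)
        den[m] = 1.0 - lam[z][iv[m]]
        m = zmask & (arm == require_arm) & (iv == J_g)
        den[m] = p_by_g[z]
    if np.isnan(den).any():
        raise PositivityError("empty stratum at the grace-window end (IPTW)")
    return den


def compute_iptw(
    bundle: CohortBundle,
    table: pd.DataFrame,
    spec: WeightModelSpec,
    strategies: list[StrategySpec],
    grid: TimeGrid | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Inverse-probability-of-treatment weights mapped onto the cloned rows.

    A discrete-time treatment-initiation model is estimated in the original
    eligible population (before cloning and censoring): empirical stratum
    proportions, or pooled logistic on the original person-time.  Each
    clone-interval then receives the inverse probability of having remained
    *compatible* with its assigned strategy: per-interval non-initiation
    factors for the abstention arm, and the probability of initiation within
    the grace window (applied at the window-end interval) for the initiation
    arm.  Stabilization and truncation follow the same contract as IPCW.
    Covariates must be baseline.
    """
    grid = grid or bundle.grid
    require_arm, forbid_arm, component, grace_end = _initiation_pair(strategies)
    covs = list(spec.denominator_covariates)
    bad = [c for c in covs if c not in bundle.patients.columns]
    if bad:
        raise NotImplementedError(
            f"IPTW supports baseline covariates only; not in patient table: {bad}"
        )
    estimator = spec.resolved_estimator()
    time_form = spec.resolved_time_form(grid.n_intervals)
    den = _iptw_factors(
        bundle, table, covs, estimator, time_form,
        require_arm, forbid_arm, component, grace_end, grid,
    )
    _positivity_check(den, table, "both", covs)
    if (den <= 0).any():
        keep = den > 0
        if (~keep & (table["artificial_censor_this_interval"] != 1).to_numpy()).any():
            raise PositivityError(
                "treatment-course probability 0 for surviving person-time — "
                "structural positivity violation (e.g., everyone initiated at once)"
            )
        den = np.where(keep, den, 1.0)
    num = np.ones(len(table))
    if spec.is_stabilized:
        num = _iptw_factors(
            bundle, table, list(spec.numerator_covariates), estimator, time_form,
            require_arm, forbid_arm, component, grace_end, grid,
        )
    result = _accumulate(table, num / den)
    info = {
        "implementation": "iptw",
        "estimator": estimator,
        "require_arm": require_arm,
        "forbid_arm": forbid_arm,
        "component": component,
        "grace_end": grace_end,
    }
    for a in (require_arm, forbid_arm):
        if not (result.loc[result["strategy_id"] == a, "weight"] > 0).any():
            raise PositivityError(f"arm {a!r} has no positive-weight person-time")
    return result, info
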