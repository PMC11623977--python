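"""Aggregated count-based evaluation of the clone-censor-weight pipeline.

For two-arm designs whose rules are all anchored at time zero (no excusals or
trigger-lifted windows) and whose weights are unstabilized empirical IPCW on
discrete baseline strata, the entire pipeline — cloning, artificial
censoring, stratum-by-interval empirical censoring probabilities, cumulative
inverse-probability weights, and the weighted Kaplan–Meier contrast — is a
function of per-(stratum, interval) counts.  This module precomputes each
patient's per-arm clone outcome once (using the same strategy engine as the
row-level pipeline) and then evaluates any patient-multiset (in particular,
bootstrap resamples) with a handful of ``bincount`` operations.

``tests`` assert that this engine and the row-level pipeline agree to float
precision; it exists so that patient-level bootstrap studies remain cheap.
"""

from __future__ import annotations

import numpy as np

from .clone_censor import censor_clones, make_clones
from .cohort import CohortBundle
from .trial_spec import TIME_ZERO

__all__ = ["prepare", "estimate"]

_REASON = {"event": 0, "artificial": 1, "lost": 2, "administrative": 2}


def _eligible(strategies, weight_spec, bundle) -> bool:
    if len(strategies) != 2:
        return False
    for s in strategies:
        if s.excusals:
            return False
        for r in s.components:
            if r.anchor != TIME_ZERO or r.lift_on_trigger or r.trigger:
                return False
    if weight_spec is None:
        return False
    if weight_spec.implementation not in ("ipcw", "nonparametric"):
        return False
    if weight_spec.resolved_estimator() != "empirical":
        return False
    if weight_spec.is_stabilized or weight_spec.truncation_percentile is not None:
        return False
    base = set(bundle.patients.columns)
    return all(c in base for c in weight_spec.denominator_covariates)


def prepare(bundle: CohortBundle, strategies, weight_spec, arms=None):
    """Precompute per-patient clone outcomes; None if not applicable."""
    if not _eligible(strategies, weight_spec, bundle):
        return None
    grid = bundle.grid
    J = grid.n_intervals
    clones = censor_clones(make_clones(bundle, strategies), bundle, strategies)
    order = {pid: i for i, pid in enumerate(bundle.patients["id"])}
    n = len(order)
    arm_ids = list(arms) if arms else [s.id for s in strategies]
    f = {a: np.zeros(n, int) for a in arm_ids}  # clone final interval
    r = {a: np.zeros(n, int) for a in arm_ids}  # clone end reason code
    for c in clones:
        i = order[c.patient_id]
        f[c.strategy_id][i] = grid.interval_of(max(c.end_time, 1))
        r[c.strategy_id][i] = _REASON[c.end_reason]
    covs = list(weight_spec.denominator_covariates)
    if covs:
        strata = bundle.patients[covs].astype(object).apply(tuple, axis=1)
        codes, _ = strata.factorize()
    else:
        codes = np.zeros(n, int)
    n_strata = int(codes.max()) + 1
    # outside the censoring-risk windows every empirical cell has zero
    # censorings, so its probability is 1 automatically; no window bookkeeping
    # is needed here
    ends = np.minimum((np.arange(J) + 1) * grid.interval_length, grid.horizon).astype(
        float
    )
    return {
        "arms": arm_ids,
        "J": J,
        "ends": ends,
        "z": codes.astype(int),
        "n_strata": n_strata,
        "f": f,
        "reason": r,
        "n": n,
    }


def _arm_curve(data, idx, arm):
    J, nz = data["J"], data["n_strata"]
    z = data["z"][idx]
    f = data["f"][arm][idx]
    reason = data["reason"][arm][idx]
    key = z * J + f
    minlength = nz * J
    exits = np.bincount(key, minlength=minlength).reshape(nz, J)
    cens = np.bincount(key[reason == 1], minlength=minlength).reshape(nz, J)
    evts = np.bincount(key[reason == 0], minlength=minlength).reshape(nz, J)
    # at-risk (entering) per stratum/interval: reverse cumulative sum of exits
    at_risk = exits[:, ::-1].cumsum(axis=1)[:, ::-1].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_unc = np.where(at_risk > 0, 1.0 - cens / np.where(at_risk > 0, at_risk, 1), 1.0)
    if (p_unc <= 0).any():
        # a cell where everyone at risk is censored: weight mass vanishes there
        p_unc = np.where(p_unc <= 0, np.nan, p_unc)
    W = np.cumprod(1.0 / p_unc, axis=1)
    W = np.where(np.isnan(W), 0.0, W)
    nw = ((at_risk - cens) * W).sum(axis=0)
    dw = (evts * W).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - np.divide(dw, nw, out=np.zeros_like(dw), where=nw > 0)
    surv = np.cumprod(factors)
    if not (nw > 0).any():
        raise ValueError(f"arm {arm!r}: empty weighted risk set")
    return surv


def _surv_at(ends, surv, t):
    ix = np.searchsorted(ends, t, side="right") - 1
    return 1.0 if ix < 0 else float(surv[ix])


def _rmst(ends, surv, horizon):
    edges = np.concatenate([[0.0], ends])
    values = np.concatenate([[1.0], surv])
    total = 0.0
    for i in range(len(edges)):
        left = edges[i]
        right = edges[i + 1] if i + 1 < len(edges) else np.inf
        if left >= horizon:
            break
        total += values[i] * (min(right, horizon) - left)
    return total


def estimate(data, idx, estimand: str, horizon: float) -> float:
    """Contrast estimate (arm A minus arm B conventions of ``contrast``)."""
    a, b = data["arms"]
    ends = data["ends"]
    sa = _arm_curve(data, idx, a)
    sb = _arm_curve(data, idx, b)
    if estimand == "risk_difference":
        return (1 - _surv_at(ends, sa, horizon)) - (1 - _surv_at(ends, sb, horizon))
    if estimand == "survival_difference":
        return _surv_at(ends, sa, horizon) - _surv_at(ends, sb, horizon)
    if estimand == "rmst_difference":
        return _rmst(ends, sa, horizon) - _rmst(ends, sb, horizon)
    raise ValueError(f"unknown estimand {estimand!r}")
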