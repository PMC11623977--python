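"""Balance and weight diagnostics for the clone-censor-weight pipeline.

Weighting is supposed to restore the covariate balance that artificial
censoring destroys; whether it did is an empirical question.  The standard
check is the standardized mean difference (SMD) between arms among clones
still at risk at a reference time — by convention the end of the grace
period, where the selection induced by censoring is fully expressed.  Clones
whose event occurred before the reference time are necessarily absent from
the at-risk set, a known blind spot of the snapshot recorded in the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BalanceReport",
    "weighted_smd",
    "weight_summary",
    "check_risk_set_conservation",
]

AT_RISK_NOTE = (
    "At-risk set: clones with a person-time row in the interval containing the "
    "reference time and positive weight (at reference time 0: all clones, "
    "unweighted). Clones whose event or censoring precedes the reference time "
    "are not represented in these balance metrics."
)


@dataclass
class BalanceReport:
    reference_time: float
    table: pd.DataFrame  # covariate, unweighted_smd, weighted_smd, flagged
    threshold: float
    note: str = AT_RISK_NOTE

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _wmean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    m = float(np.average(x, weights=w))
    binary = set(np.unique(x)) <= {0.0, 1.0}
    if binary:
        return m, m * (1.0 - m)
    v = float(np.average((x - m) ** 2, weights=w))
    return m, v


def _smd(xa, wa, xb, wb) -> float:
    ma, va = _wmean_var(xa, wa)
    mb, vb = _wmean_var(xb, wb)
    denom = np.sqrt((va + vb) / 2.0)
    if denom == 0:
        return 0.0 if ma == mb else np.inf
    return (ma - mb) / denom


def weighted_smd(
    table: pd.DataFrame,
    time: float,
    covariates: list[str],
    arms: tuple[str, str] | None = None,
    threshold: float = 0.1,
) -> BalanceReport:
    """Unweighted and weighted SMD between two arms at a reference time.

    SMD = (m_A - m_B) / sqrt((v_A + v_B) / 2), with proportion variance
    p(1-p) for binary covariates; categorical covariates are expanded to
    indicator levels.  At reference time 0 all clones are present and
    identical across arms, so every SMD is exactly 0 (the cloning identity).
    """
    if arms is None:
        uniq = sorted(table["strategy_id"].unique())
        if len(uniq) != 2:
            raise ValueError("specify arms= when the table has more than two arms")
        arms = (uniq[0], uniq[1])
    if time <= 0:
        rows = table[table["interval_index"] == 0].copy()
        rows["weight"] = 1.0
        at_risk = rows
    else:
        at_risk = table[
            (table["interval_start"] < time)
            & (time <= table["interval_end"])
            & (table["weight"] > 0)
        ]
    if at_risk.empty:
        raise ValueError(f"no at-risk rows at reference time {time}")
    records = []
    for cov in covariates:
        col = at_risk[cov]
        if col.dtype == object or str(col.dtype) == "category":
            expanded = pd.get_dummies(col, prefix=cov, dtype=float)
        else:
            expanded = pd.DataFrame({cov: col.astype(float)})
        for name in expanded.columns:
            x = expanded[name].to_numpy(float)
            w = at_risk["weight"].to_numpy(float)
            in_a = (at_risk["strategy_id"] == arms[0]).to_numpy()
            in_b = (at_risk["strategy_id"] == arms[1]).to_numpy()
            if not in_a.any() or not in_b.any():
                raise ValueError(f"an arm has no at-risk rows at time {time}")
            smd_w = _smd(x[in_a], w[in_a], x[in_b], w[in_b])
            smd_u = _smd(x[in_a], np.ones(in_a.sum()), x[in_b], np.ones(in_b.sum()))
            records.append(
                {
                    "covariate": name,
                    "unweighted_smd": smd_u,
                    "weighted_smd": smd_w,
                    "flagged": abs(smd_w) > threshold,
                }
            )
    return BalanceReport(
        reference_time=time,
        table=pd.DataFrame(records),
        threshold=threshold,
    )


def weight_summary(table: pd.DataFrame) -> dict:
    """Per-arm summary of positive row weights (mean, median, tails, max)."""
    out = {}
    for arm, grp in table.groupby("strategy_id"):
        w = grp.loc[grp["weight"] > 0, "weight"].to_numpy(float)
        if len(w) == 0:
            out[str(arm)] = {"n_rows": 0}
            continue
        out[str(arm)] = {
            "n_rows": int(len(w)),
            "mean": float(w.mean()),
            "median": float(np.median(w)),
            "p1": float(np.percentile(w, 1)),
            "p99": float(np.percentile(w, 99)),
            "max": float(w.max()),
            "n_zero_weight_rows": int((grp["weight"] == 0).sum()),
        }
    return out


def check_risk_set_conservation(
    table: pd.DataFrame, strata: list[str] | None = None
) -> pd.DataFrame:
    """Within-interval risk-set conservation of inverse-probability weighting.

    For stratum-empirical (saturated) unstabilized IPCW weights, reweighting
    exactly restores, in every (arm, interval, stratum) cell, the at-risk
    mass present immediately before that interval's artificial censoring:

        sum of post-update weights over rows remaining uncensored
          ==  sum of entering weights over all rows of the interval.

    (The comparison is against the table's own entering weights rather than
    the fully uncensored clone table: clones may die *after* their artificial
    censoring, so the two tables' risk sets diverge over time in any finite
    sample and no weighting can reproduce the latter exactly.)

    Cells where *every* at-risk clone is censored in the same interval are a
    structural positivity failure: the post-censoring risk set is empty, the
    stratum's weight mass vanishes, and no reweighting can restore it.  Such
    cells are flagged ``exhausted`` (compute_ipcw has already warned about
    them); conservation holds exactly on all other cells.

    Returns a frame with both sides per cell; equality off the exhausted
    cells is the diagnostic.
    """
    df = table.sort_values(
        ["strategy_id", "patient_id", "interval_index"], kind="stable"
    ).copy()
    grp = df.groupby(["strategy_id", "patient_id"], sort=False)["weight"]
    entering = grp.shift(1)
    # a clone's first interval enters with weight 1; a censored row's own
    # weight is 0, but it entered with its previous cumulative weight
    df["_entering"] = entering.fillna(1.0)
    keys = ["strategy_id", "interval_index"] + (strata or [])
    df["_uncensored"] = (df["artificial_censor_this_interval"] != 1).astype(int)
    agg = df.groupby(keys, observed=True).agg(
        weighted_at_risk_before=("_entering", "sum"),
        weighted_at_risk_after=("weight", "sum"),
        n_uncensored=("_uncensored", "sum"),
    )
    agg["exhausted"] = (agg["n_uncensored"] == 0) & (
        agg["weighted_at_risk_before"] > 0
    )
    agg["abs_difference"] = (
        agg["weighted_at_risk_after"] - agg["weighted_at_risk_before"]
    ).abs()
    return agg.reset_index()
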