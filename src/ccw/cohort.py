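"""Cohort input tables: reading, validation, eligibility filtering.

Three delimited tables describe the observational cohort, all times being
non-negative integer units since each patient's own time zero (calendar dates
are converted on read):

* ``patients`` — one row per subject: ``id``, ``time_zero`` (optional ISO date
  or integer anchor), ``followup_end``, ``event`` (1 = outcome event at
  ``followup_end``), ``classic_censor_reason`` (``lost``/``administrative``,
  empty when event=1), plus any baseline covariate columns;
* ``treatments`` — ``id``, ``day``, ``component``: one row per treatment
  component occurrence;
* ``covariates`` — ``id``, ``day``, ``name``, ``value``: sparse time-varying
  covariate log, value carried forward between records.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .trial_spec import History, TimeGrid

__all__ = [
    "CohortBundle",
    "CohortError",
    "read_cohort",
    "write_cohort",
    "apply_eligibility",
    "make_bundle",
]

PATIENT_REQUIRED = ("id", "followup_end", "event")
TREATMENT_REQUIRED = ("id", "day", "component")
COVARIATE_REQUIRED = ("id", "day", "name", "value")
RESERVED = {"id", "time_zero", "followup_end", "event", "classic_censor_reason"}


class CohortError(ValueError):
    pass


@dataclass
class CohortBundle:
    """Validated cohort: patient, treatment and covariate tables plus grid."""

    patients: pd.DataFrame
    treatments: pd.DataFrame
    covariates: pd.DataFrame
    grid: TimeGrid

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def baseline_covariate_names(self) -> list[str]:
        return [c for c in self.patients.columns if c not in RESERVED]

    @property
    def component_names(self) -> set[str]:
        return set(self.treatments["component"].unique())

    @property
    def tv_covariate_names(self) -> set[str]:
        return set(self.covariates["name"].unique())

    def history(self, patient_id) -> History:
        """Assemble one patient's History (treatments + covariate steps)."""
        row = self.patients.loc[self.patients["id"] == patient_id]
        if row.empty:
            raise CohortError(f"unknown patient id {patient_id!r}")
        trt = self.treatments[self.treatments["id"] == patient_id]
        cov = self.covariates[self.covariates["id"] == patient_id]
        treatments: dict[str, list[int]] = {}
        for comp, days in trt.groupby("component")["day"]:
            treatments[comp] = list(days)
        covs: dict[str, list[tuple[int, float]]] = {}
        for name, grp in cov.groupby("name"):
            covs[name] = list(zip(grp["day"], grp["value"]))
        return History(
            treatments,
            covs,
            followup_end=int(row["followup_end"].iloc[0]),
            event=int(row["event"].iloc[0]),
        )

    def histories(self) -> dict:
        """All patient histories keyed by id (one pass over the tables)."""
        treatments: dict = {pid: {} for pid in self.patients["id"]}
        for pid, comp, day in zip(
            self.treatments["id"], self.treatments["component"], self.treatments["day"]
        ):
            treatments[pid].setdefault(comp, []).append(int(day))
        covs: dict = {pid: {} for pid in self.patients["id"]}
        for pid, name, day, value in zip(
            self.covariates["id"],
            self.covariates["name"],
            self.covariates["day"],
            self.covariates["value"],
        ):
            covs[pid].setdefault(name, []).append((int(day), value))
        out = {}
        for row in self.patients.itertuples(index=False):
            out[row.id] = History(
                treatments[row.id],
                covs[row.id],
                followup_end=int(row.followup_end),
                event=int(row.event),
            )
        return out


def _empty_treatments() -> pd.DataFrame:
    return pd.DataFrame({"id": pd.Series(dtype=object), "day": pd.Series(dtype=int),
                         "component": pd.Series(dtype=object)})


def _empty_covariates() -> pd.DataFrame:
    return pd.DataFrame({"id": pd.Series(dtype=object), "day": pd.Series(dtype=int),
                         "name": pd.Series(dtype=object),
                         "value": pd.Series(dtype=float)})


def make_bundle(
    patients: pd.DataFrame,
    treatments: pd.DataFrame | None,
    covariates: pd.DataFrame | None,
    grid: TimeGrid,
) -> CohortBundle:
    """Validate frames and administratively truncate follow-up at the horizon."""
    patients = patients.copy()
    for col in PATIENT_REQUIRED:
        if col not in patients.columns:
            raise CohortError(f"patient table missing required column {col!r}")
    if patients["id"].duplicated().any():
        dupes = patients.loc[patients["id"].duplicated(), "id"].tolist()
        raise CohortError(f"duplicate patient id(s): {dupes}")
    if "classic_censor_reason" not in patients.columns:
        patients["classic_censor_reason"] = None
    patients["classic_censor_reason"] = patients["classic_censor_reason"].where(
        patients["classic_censor_reason"].notna()
        & (patients["classic_censor_reason"] != ""),
        None,
    )
    patients["followup_end"] = patients["followup_end"].astype(int)
    patients["event"] = patients["event"].astype(int)
    if (patients["followup_end"] < 0).any():
        raise CohortError("negative followup_end")
    bad = (patients["event"] == 1) & patients["classic_censor_reason"].notna()
    if bad.any():
        raise CohortError(
            "event=1 rows must not carry a classic_censor_reason: "
            f"{patients.loc[bad, 'id'].tolist()}"
        )
    # administrative truncation at the horizon
    over = patients["followup_end"] > grid.horizon
    if over.any():
        patients.loc[over, "followup_end"] = grid.horizon
        patients.loc[over, "event"] = 0
        patients.loc[over, "classic_censor_reason"] = "administrative"
    at_end = (
        (patients["followup_end"] == grid.horizon)
        & (patients["event"] == 0)
        & patients["classic_censor_reason"].isna()
    )
    patients.loc[at_end, "classic_censor_reason"] = "administrative"
    no_reason = (patients["event"] == 0) & patients["classic_censor_reason"].isna()
    if no_reason.any():
        raise CohortError(
            "censored patients before the horizon need a classic_censor_reason: "
            f"{patients.loc[no_reason, 'id'].tolist()}"
        )

    treatments = (
        treatments.copy() if treatments is not None and len(treatments)
        else _empty_treatments()
    )
    covariates = (
        covariates.copy() if covariates is not None and len(covariates)
        else _empty_covariates()
    )
    for col in TREATMENT_REQUIRED:
        if col not in treatments.columns:
            raise CohortError(f"treatment table missing required column {col!r}")
    for col in COVARIATE_REQUIRED:
        if col not in covariates.columns:
            raise CohortError(f"covariate table missing required column {col!r}")
    known = set(patients["id"])
    for label, tbl in (("treatment", treatments), ("covariate", covariates)):
        if len(tbl):
            tbl["day"] = tbl["day"].astype(int)
            if (tbl["day"] < 0).any():
                raise CohortError(f"negative day in {label} table")
            unknown = set(tbl["id"]) - known
            if unknown:
                raise CohortError(f"{label} rows for unknown id(s): {sorted(unknown)}")
    if len(treatments):
        end = patients.set_index("id")["followup_end"]
        over_end = treatments["day"] > treatments["id"].map(end)
        treatments = treatments[~over_end]  # dropped by horizon truncation
        treatments = treatments.sort_values(["id", "day"], kind="stable")
    if len(covariates):
        dup = covariates.duplicated(subset=["id", "day", "name"])
        if dup.any():
            raise CohortError("duplicate (id, day, name) in covariate table")
        end = patients.set_index("id")["followup_end"]
        covariates = covariates[covariates["day"] <= covariates["id"].map(end)]
        covariates = covariates.sort_values(["id", "day"], kind="stable")
    return CohortBundle(
        patients.reset_index(drop=True),
        treatments.reset_index(drop=True),
        covariates.reset_index(drop=True),
        grid,
    )


def read_cohort(
    patient_path,
    grid: TimeGrid,
    treatment_path=None,
    covariate_path=None,
) -> CohortBundle:
    """Read the delimited cohort tables into a validated bundle.

    ``time_zero`` may be an ISO-8601 date (then treatment/covariate ``day``
    columns may also be dates, converted to offsets) or an integer anchor.
    Follow-up is administratively truncated at ``grid.horizon``.
    """
    patients = pd.read_csv(patient_path)
    treatments = pd.read_csv(treatment_path) if treatment_path else None
    covariates = pd.read_csv(covariate_path) if covariate_path else None

    if "time_zero" in patients.columns and patients["time_zero"].dtype == object:
        t0 = pd.to_datetime(patients["time_zero"], format="ISO8601")
        anchor = dict(zip(patients["id"], t0))
        for tbl in (treatments, covariates):
            if tbl is not None and len(tbl) and tbl["day"].dtype == object:
                days = pd.to_datetime(tbl["day"], format="ISO8601")
                tbl["day"] = (
                    days - tbl["id"].map(anchor)
                ).dt.days.astype(int)
        if patients["followup_end"].dtype == object:
            fe = pd.to_datetime(patients["followup_end"], format="ISO8601")
            patients["followup_end"] = (fe - t0).dt.days.astype(int)
    return make_bundle(patients, treatments, covariates, grid)


def write_cohort(bundle: CohortBundle, out_dir) -> dict[str, Path]:
    """Write the three tables as UTF-8 comma-delimited CSV; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("patients", bundle.patients),
        ("treatments", bundle.treatments),
        ("covariates", bundle.covariates),
    ):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def _predicate(crit: Mapping) -> Callable[[pd.Series], pd.Series]:
    """Compile a criterion dict into a vectorized baseline predicate."""
    op = crit.get("op", "between")
    value = crit.get("value")
    if op == "between":
        lo, hi = value
        return lambda s: (s >= lo) & (s <= hi)
    if op in ("==", "eq"):
        return lambda s: s == value
    if op in ("!=", "ne"):
        return lambda s: s != value
    if op in ("<=", "le"):
        return lambda s: s <= value
    if op in (">=", "ge"):
        return lambda s: s >= value
    if op == "in":
        allowed = set(value)
        return lambda s: s.isin(allowed)
    raise CohortError(f"unknown eligibility op {op!r}")


def apply_eligibility(
    bundle: CohortBundle, criteria: Sequence[Mapping]
) -> tuple[CohortBundle, dict[str, int]]:
    """Filter patients by baseline criteria, in order; log exclusions per criterion.

    Each criterion is ``{"covariate": name, "op": ..., "value": ...}`` and may
    reference baseline covariate columns only — eligibility must be decidable
    at time zero so that eligibility, assignment and follow-up stay aligned.
    """
    patients = bundle.patients
    keep = pd.Series(True, index=patients.index)
    log: dict[str, int] = {}
    for crit in criteria:
        name = crit["covariate"]
        if name in RESERVED or name not in patients.columns:
            raise CohortError(
                f"eligibility criterion references unknown or post-baseline "
                f"covariate {name!r}"
            )
        col = patients[name]
        if col.isna().any():
            missing = patients.loc[col.isna() & keep, "id"].tolist()
            if missing:
                raise CohortError(
                    f"missing baseline covariate {name!r} for patients {missing}"
                )
        ok = _predicate(crit)(col)
        label = crit.get("label", f"{name} {crit.get('op', 'between')} {crit.get('value')}")
        log[label] = int((keep & ~ok).sum())
        keep &= ok
    kept_ids = set(patients.loc[keep, "id"])
    sub = CohortBundle(
        patients[keep].reset_index(drop=True),
        bundle.treatments[bundle.treatments["id"].isin(kept_ids)].reset_index(drop=True),
        bundle.covariates[bundle.covariates["id"].isin(kept_ids)].reset_index(drop=True),
        bundle.grid,
    )
    return sub, log
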