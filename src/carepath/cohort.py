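"""Cohort construction: inclusion/exclusion, PPD labeling, trimester
assignment, per-patient event sequences, and descriptive summaries.

Times are integer days relative to delivery (delivery = day 0, negative =
antepartum).  Pregnancy start is delivery minus 7 * gestational_week days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "PatientSequence",
    "apply_inclusion_exclusion",
    "label_ppd",
    "assign_trimester",
    "build_sequences",
    "cohort_summary",
    "CohortSummary",
]

AGE_MIN, AGE_MAX = 18.0, 45.0
PPD_WINDOW_DAYS = 365  # "within 1 year after childbirth", day 365 inclusive


class SchemaError(ValueError):
    """An input table is missing required columns."""


def _require(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns {missing}")


def apply_inclusion_exclusion(
    patients: pd.DataFrame, events: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Apply the study's inclusion/exclusion rules.

    Retains patients with 18 <= age <= 45, at least one recorded event from
    1 year before pregnancy start to 1 year after delivery, and a
    non-missing home location.  Returns the filtered patient and event
    tables plus a tally of exclusions per criterion (a patient failing
    several criteria is tallied under each).
    """
    _require(patients, ["patient_id", "age", "gestational_week", "home_x", "home_y"], "patients")
    _require(events, ["patient_id", "t"], "events")

    age_ok = (patients["age"] >= AGE_MIN) & (patients["age"] <= AGE_MAX)
    home_ok = patients["home_x"].notna() & patients["home_y"].notna()

    start = -7.0 * patients["gestational_week"].to_numpy(dtype=float)
    lo = pd.Series(start - 365.0, index=patients.index)
    window_lo = dict(zip(patients["patient_id"], lo))
    ev = events[["patient_id", "t"]]
    lo_per_event = ev["patient_id"].map(window_lo)
    in_window = (ev["t"] >= lo_per_event) & (ev["t"] <= 365)
    has_event = patients["patient_id"].isin(ev.loc[in_window, "patient_id"].unique())

    keep = age_ok & home_ok & has_event
    tally = {
        "age": int((~age_ok).sum()),
        "no_encounter_in_window": int((~has_event).sum()),
        "missing_home": int((~home_ok).sum()),
        "excluded_total": int((~keep).sum()),
    }
    kept = patients.loc[keep].reset_index(drop=True)
    kept_events = events[events["patient_id"].isin(kept["patient_id"])].reset_index(drop=True)
    return kept, kept_events, tally


def label_ppd(events: pd.DataFrame, ppd_code_set: set[str] | list[str]) -> pd.Series:
    """True iff the patient has a diagnosis with a code in ``ppd_code_set``
    at 0 < t <= 365 (postpartum year, day 365 inclusive)."""
    codes = set(ppd_code_set)
    if not codes:
        raise ValueError("ppd_code_set must be non-empty")
    _require(events, ["patient_id", "t", "event_type", "code"], "events")
    hit = (
        (events["event_type"] == "diagnosis")
        & events["code"].isin(codes)
        & (events["t"] > 0)
        & (events["t"] <= PPD_WINDOW_DAYS)
    )
    pos = set(events.loc[hit, "patient_id"])
    out = events["patient_id"].drop_duplicates().reset_index(drop=True)
    return pd.Series([p in pos for p in out], index=out, name="ppd")


def assign_trimester(t, gestational_week):
    """Map event day(s) ``t`` (relative to delivery) to a pregnancy period.

    Pregnancy start = -7 * gestational_week.  The first 13 weeks from start
    are T1, weeks 14-27 are T2, week 28 through delivery is T3; events
    before start are 'pre-pregnancy' and events after delivery (t > 0) are
    'postpartum'.  Accepts scalars or arrays.
    """
    gw = np.asarray(gestational_week, dtype=float)
    if np.any(gw <= 0):
        raise ValueError("gestational_week must be positive")
    t = np.asarray(t, dtype=float)
    start = -7.0 * gw
    week = np.floor((t - start) / 7.0) + 1  # 1-indexed week of pregnancy
    out = np.where(
        t > 0,
        "postpartum",
        np.where(
            t < start,
            "pre-pregnancy",
            np.where(week <= 13, "T1", np.where(week <= 27, "T2", "T3")),
        ),
    )
    return out.item() if out.ndim == 0 else out


@dataclass
class PatientSequence:
    patient_id: str
    tokens: list[str]
    times: list[int]


def build_sequences(
    events: pd.DataFrame, vocabulary_filter: set[str] | list[str]
) -> tuple[dict[str, PatientSequence], int]:
    """Build ordered prenatal token sequences per patient.

    Events are restricted to the prenatal window (t <= 0) and to the
    configured token allow-list, ordered by time with same-day ties broken
    by (event_type, code); duplicate same-day tokens collapse to one.
    Patients left with no allowed tokens are dropped; their count is
    returned alongside the sequences.
    """
    vocab = set(vocabulary_filter)
    if not vocab:
        raise ValueError("vocabulary_filter must be non-empty")
    _require(events, ["patient_id", "t", "event_type", "code"], "events")
    pre = events[(events["t"] <= 0) & events["code"].isin(vocab)]
    pre = pre.sort_values(["patient_id", "t", "event_type", "code"], kind="mergesort")
    sequences: dict[str, PatientSequence] = {}
    for pid, grp in pre.groupby("patient_id", sort=True):
        # collapse duplicate (day, token) pairs, keeping first occurrence
        seen: set[tuple[int, str]] = set()
        ctoks: list[str] = []
        ctimes: list[int] = []
        for tt, tok in zip(grp["t"].astype(int), grp["code"]):
            if (tt, tok) in seen:
                continue
            seen.add((tt, tok))
            ctoks.append(tok)
            ctimes.append(int(tt))
        sequences[str(pid)] = PatientSequence(str(pid), ctoks, ctimes)
    n_total = events["patient_id"].nunique()
    return sequences, n_total - len(sequences)


@dataclass
class CohortSummary:
    """Table-style descriptive summary: mean (SD) for continuous variables,
    N (%) for categorical levels."""

    n: int
    continuous: pd.DataFrame  # index variable, columns mean/sd
    categorical: pd.DataFrame  # columns variable, level, n, pct
    extras: dict[str, float] = field(default_factory=dict)

    def percent(self, variable: str, level) -> float:
        m = self.categorical
        row = m[(m["variable"] == variable) & (m["level"] == level)]
        return float(row["pct"].iloc[0]) if len(row) else float("nan")


def _sd(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def cohort_summary(
    patients: pd.DataFrame,
    events: pd.DataFrame | None = None,
    continuous: list[str] = ("age", "bmi", "gestational_week"),
    categorical: list[str] = ("race", "marital", "insurance", "ppd"),
) -> CohortSummary:
    """Descriptive statistics of the labeled cohort.

    Percentages use non-missing denominators; the SD of a singleton group
    is reported as 0.  When an event table is supplied, the share of
    patients with at least one pre-/post-delivery emergency-department
    visit is added to ``extras``.
    """
    n = len(patients)
    cont_rows = {}
    for var in continuous:
        if var not in patients.columns:
            continue
        x = patients[var].to_numpy(dtype=float)
        valid = x[~np.isnan(x)]
        cont_rows[var] = {"mean": float(np.mean(valid)) if len(valid) else float("nan"), "sd": _sd(x)}
    cat_rows = []
    for var in categorical:
        if var not in patients.columns:
            continue
        col = patients[var].dropna()
        denom = len(col)
        for level, cnt in col.value_counts().sort_index().items():
            cat_rows.append(
                {"variable": var, "level": level, "n": int(cnt), "pct": 100.0 * cnt / denom if denom else float("nan")}
            )
    extras: dict[str, float] = {}
    if events is not None and n > 0 and "code" in events.columns:
        ed = events[events["code"] == "ENC_ED"]
        pre = set(ed.loc[ed["t"] <= 0, "patient_id"])
        post = set(ed.loc[ed["t"] > 0, "patient_id"])
        pids = set(patients["patient_id"])
        extras["ed_pre_pct"] = 100.0 * len(pre & pids) / n
        extras["ed_post_pct"] = 100.0 * len(post & pids) / n
    return CohortSummary(
        n=n,
        continuous=pd.DataFrame(cont_rows).T.rename_axis("variable") if cont_rows else pd.DataFrame(columns=["mean", "sd"]),
        categorical=pd.DataFrame(cat_rows, columns=["variable", "level", "n", "pct"]),
        extras=extras,
    )
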