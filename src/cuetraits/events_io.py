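"""CSV data model for behavioral phenotyping sessions.

Two table families are defined:

* **Event tables** — long-format, one row per timestamped behavioral event
  (lever deflection, food-cup entry, nosepoke, CS onset/offset, pellet
  delivery) within a subject-session, for the Pavlovian conditioned approach
  (``pavca``) and conditioned reinforcement (``crf``) tasks.
* **Summary tables** — one row per session for the cocaine conditioned cue
  preference (``ccp``) and cocaine contextual conditioning (``ccc``)
  paradigms, carrying derived measures (time on floor, distance travelled,
  headwave bouts) produced upstream by video tracking.

The event dialect is UTF-8 CSV with columns exactly
``subject_id, cohort, sex, task, session, trial, event, time_s``; ``time_s``
is seconds from session start at millisecond precision, trials are 1-based
and trial 0 is reserved for inter-trial-interval events.  CS windows are
half-open ``[cs_onset, cs_offset)``: an entry at exactly ``cs_offset`` is ITI.

All readers validate invariants up front and raise :class:`ValidationError`
naming the offending file row; malformed input is rejected, never silently
coerced.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1"

EVENT_COLUMNS = [
    "subject_id", "cohort", "sex", "task", "session", "trial", "event", "time_s",
]
CCP_COLUMNS = [
    "subject_id", "cohort", "sex", "phase", "trial", "drug", "floor",
    "time_on_grid_s", "time_on_hole_s", "distance_mm",
]
CCC_COLUMNS = [
    "subject_id", "cohort", "sex", "day", "injection", "distance_mm", "headwave_bouts",
]

SEXES = ("female", "male")
COHORTS = ("A", "B")
TASKS = ("pavca", "crf")
PAVCA_EVENTS = ("cs_onset", "cs_offset", "lever_deflection", "foodcup_entry",
                "pellet_delivery")
CRF_EVENTS = ("poke_active", "poke_inactive", "lever_presentation",
              "lever_deflection")
CCP_PHASES = ("habituation", "pretest", "conditioning", "posttest")
CCP_FLOORS = ("grid", "hole", "both", "smooth")
CCP_DRUGS = ("saline", "cocaine", "none")
#: Injection schedule of the 8-day contextual-conditioning procedure:
#: day 1 habituation (no injection), day 2 saline baseline, days 3-7 cocaine
#: conditioning, day 8 drug-free (saline) conditioned-locomotion probe.
CCC_INJECTION_SCHEDULE = {
    1: "none", 2: "saline", 3: "cocaine", 4: "cocaine", 5: "cocaine",
    6: "cocaine", 7: "cocaine", 8: "saline",
}

CS_WIDTH_TOL_S = 1e-6


class ValidationError(ValueError):
    """Malformed table content.  ``row`` is the 1-based file line (header = line 1)."""

    def __init__(self, message: str, row=None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


def _check_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {missing}")


def _fail_where(mask, df: pd.DataFrame, message: str) -> None:
    mask = np.asarray(mask, dtype=bool)
    if mask.any():
        row = df.index[int(np.flatnonzero(mask)[0])]
        raise ValidationError(message, row=row)


def _as_int(df: pd.DataFrame, col: str) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    _fail_where(vals.isna() | (vals != np.floor(vals)), df,
                f"non-integer value in column '{col}'")
    return vals.astype(int)


# ---------------------------------------------------------------------------
# Event tables


def empty_event_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in EVENT_COLUMNS})


def validate_event_table(df: pd.DataFrame, task: str | None = None,
                         cs_duration_s: float = 8.0) -> pd.DataFrame:
    """Validate an event table and return it time-sorted within sessions.

    Enforces the full event-record invariant set: typed columns, non-negative
    millisecond timestamps, task-consistent event names, exactly one
    ``cs_onset``/``cs_offset`` per PavCA trial with the configured CS width,
    and CS-period contact events falling inside their half-open trial window.
    The returned frame preserves the caller's row index (file line numbers
    when coming from :func:`read_event_table`).
    """
    _check_columns(df, EVENT_COLUMNS, "event table")
    df = df.copy()
    if df.empty:
        return df[EVENT_COLUMNS]

    sid = df["subject_id"].astype(str)
    _fail_where(df["subject_id"].isna() | (sid.str.len() == 0), df,
                "missing subject_id")
    df["subject_id"] = sid
    _fail_where(~df["sex"].isin(SEXES), df,
                f"sex must be one of {SEXES}")
    _fail_where(~df["task"].isin(TASKS), df, f"task must be one of {TASKS}")
    if task is not None:
        _fail_where(df["task"] != task, df, f"expected task '{task}'")

    df["session"] = _as_int(df, "session")
    df["trial"] = _as_int(df, "trial")
    _fail_where(df["session"] < 1, df, "session must be >= 1")
    _fail_where(df["trial"] < 0, df, "trial must be >= 0")

    time = pd.to_numeric(df["time_s"], errors="coerce")
    _fail_where(time.isna() | ~np.isfinite(time), df,
                "unsortable timestamp (missing or non-numeric time_s)")
    _fail_where(time < 0, df, "time_s must be >= 0")
    df["time_s"] = time.astype(float)

    for t, allowed in (("pavca", PAVCA_EVENTS), ("crf", CRF_EVENTS)):
        _fail_where((df["task"] == t) & ~df["event"].isin(allowed), df,
                    f"event not valid for task '{t}'")

    # subject metadata must be single-valued per subject
    meta = df.groupby("subject_id")[["cohort", "sex"]].nunique()
    bad = meta[(meta > 1).any(axis=1)]
    if len(bad):
        offender = bad.index[0]
        _fail_where(df["subject_id"] == offender, df,
                    f"inconsistent cohort/sex for subject '{offender}'")

    df = df.sort_values(["subject_id", "task", "session", "time_s"],
                        kind="mergesort")

    pav = df[df["task"] == "pavca"]
    if len(pav):
        _check_cs_windows(pav, cs_duration_s)
    return df


def _check_cs_windows(pav: pd.DataFrame, cs_duration_s: float) -> None:
    trials = pav[pav["trial"] > 0]
    if trials.empty:
        return
    key = ["subject_id", "session", "trial"]
    on = trials[trials["event"] == "cs_onset"]
    off = trials[trials["event"] == "cs_offset"]

    counts = (trials[key].drop_duplicates()
              .merge(on.groupby(key).size().rename("n_on"), on=key, how="left")
              .merge(off.groupby(key).size().rename("n_off"), on=key, how="left")
              .fillna(0))
    bad = counts[(counts["n_on"] != 1) | (counts["n_off"] != 1)]
    if len(bad):
        b = bad.iloc[0]
        grp = trials[(trials["subject_id"] == b["subject_id"])
                     & (trials["session"] == b["session"])
                     & (trials["trial"] == b["trial"])]
        row = grp.index[0] if len(grp) else None
        raise ValidationError(
            f"trial {int(b['trial'])} of subject '{b['subject_id']}' session "
            f"{int(b['session'])} must have exactly one cs_onset and one "
            f"cs_offset (found {int(b['n_on'])}/{int(b['n_off'])})", row=row)

    windows = (on[key + ["time_s"]].rename(columns={"time_s": "_onset"})
               .merge(off[key + ["time_s"]].rename(columns={"time_s": "_offset"}),
                      on=key))
    off_idx = off.reset_index().rename(columns={"index": "_row"})
    windows = windows.merge(off_idx[key + ["_row"]], on=key)
    width_bad = (windows["_offset"] - windows["_onset"]
                 - cs_duration_s).abs() > CS_WIDTH_TOL_S
    if width_bad.any():
        b = windows[width_bad].iloc[0]
        raise ValidationError(
            f"CS window width {b['_offset'] - b['_onset']:.6f} s != "
            f"{cs_duration_s} s", row=b["_row"])

    contacts = trials[trials["event"].isin(("lever_deflection", "foodcup_entry"))]
    if len(contacts):
        c = contacts.reset_index().rename(columns={"index": "_row"})
        c = c.merge(windows[key + ["_onset", "_offset"]], on=key, how="left")
        outside = (c["_onset"].isna() | (c["time_s"] < c["_onset"])
                   | (c["time_s"] >= c["_offset"]))
        if outside.any():
            b = c[outside].iloc[0]
            raise ValidationError(
                f"{b['event']} at {b['time_s']:.3f} s outside the CS window "
                f"of trial {int(b['trial'])}", row=b["_row"])


def read_event_table(path, task: str | None = None,
                     cs_duration_s: float = 8.0) -> pd.DataFrame:
    """Read and validate an event CSV; index holds 1-based file line numbers."""
    df = pd.read_csv(path, dtype={"subject_id": str, "cohort": str, "sex": str,
                                  "task": str, "event": str})
    df.index = pd.RangeIndex(2, len(df) + 2)
    return validate_event_table(df, task=task, cs_duration_s=cs_duration_s)


def write_event_table(df: pd.DataFrame, path,
                      cs_duration_s: float = 8.0) -> None:
    """Write a validated event table in the canonical byte-stable form.

    Rows are sorted (subject, task, session, time) and ``time_s`` is printed
    with exactly three decimals, so ``read_event_table(write_event_table(x))``
    reproduces ``x`` field-for-field and repeated writes are byte-identical.
    """
    df = validate_event_table(df, cs_duration_s=cs_duration_s)
    out = df[EVENT_COLUMNS].copy()
    if len(out):
        out["time_s"] = out["time_s"].map(lambda t: f"{t:.3f}")
    out.to_csv(path, index=False, lineterminator="\n")


def derive_trial_windows(events: pd.DataFrame) -> pd.DataFrame:
    """CS windows per (subject, session, trial) from a validated PavCA table."""
    pav = events[(events["task"] == "pavca") & (events["trial"] > 0)]
    key = ["subject_id", "session", "trial"]
    on = pav[pav["event"] == "cs_onset"][key + ["time_s"]]
    off = pav[pav["event"] == "cs_offset"][key + ["time_s"]]
    w = on.rename(columns={"time_s": "onset_s"}).merge(
        off.rename(columns={"time_s": "offset_s"}), on=key)
    return w.sort_values(key).reset_index(drop=True)


def iter_sessions(events: pd.DataFrame):
    """Yield ((subject_id, session), frame) for each subject-session group."""
    for key, grp in events.groupby(["subject_id", "session"], sort=True):
        yield key, grp


# ---------------------------------------------------------------------------
# Summary tables (CCP / CCC)


def validate_ccp_table(df: pd.DataFrame, test_duration_s: float = 1800.0,
                       n_trials: int = 4) -> pd.DataFrame:
    _check_columns(df, CCP_COLUMNS, "CCP table")
    df = df.copy()
    if df.empty:
        return df[CCP_COLUMNS]
    _fail_where(~df["phase"].isin(CCP_PHASES), df,
                f"phase must be one of {CCP_PHASES}")
    _fail_where(~df["floor"].isin(CCP_FLOORS), df,
                f"floor must be one of {CCP_FLOORS}")
    _fail_where(~df["drug"].isin(CCP_DRUGS), df,
                f"drug must be one of {CCP_DRUGS}")
    dist = pd.to_numeric(df["distance_mm"], errors="coerce")
    _fail_where(dist.isna() | (dist < 0), df,
                "distance_mm must be non-negative")
    df["distance_mm"] = dist.astype(float)
    df["trial"] = pd.to_numeric(df["trial"], errors="coerce").fillna(0).astype(int)

    cond = df["phase"] == "conditioning"
    _fail_where(cond & ~df["floor"].isin(("grid", "hole")), df,
                "conditioning rows must use exactly one floor in {grid, hole}")
    _fail_where(cond & ~df["drug"].isin(("saline", "cocaine")), df,
                "conditioning rows must have drug saline or cocaine")
    _fail_where(cond & ((df["trial"] < 1) | (df["trial"] > n_trials)), df,
                f"conditioning trial must be in 1..{n_trials}")

    tests = df["phase"].isin(("pretest", "posttest"))
    _fail_where(tests & (df["floor"] != "both"), df,
                "pretest/posttest rows must have floor 'both'")
    for col in ("time_on_grid_s", "time_on_hole_s"):
        vals = pd.to_numeric(df[col], errors="coerce")
        _fail_where(tests & (vals.isna() | (vals < 0)), df,
                    f"{col} must be non-negative on test rows")
        df[col] = vals.astype(float)
    total = df["time_on_grid_s"] + df["time_on_hole_s"]
    _fail_where(tests & (total > test_duration_s + 1e-6), df,
                f"time_on_grid_s + time_on_hole_s exceeds the "
                f"{test_duration_s:.0f}-s session")
    return df


def validate_ccc_table(df: pd.DataFrame) -> pd.DataFrame:
    _check_columns(df, CCC_COLUMNS, "CCC table")
    df = df.copy()
    if df.empty:
        return df[CCC_COLUMNS]
    df["day"] = _as_int(df, "day")
    _fail_where((df["day"] < 1) | (df["day"] > 8), df, "day must be in 1..8")
    expected = df["day"].map(CCC_INJECTION_SCHEDULE)
    _fail_where(df["injection"] != expected, df,
                "injection violates the day schedule "
                "(day 1 none, days 2/8 saline, days 3-7 cocaine)")
    dist = pd.to_numeric(df["distance_mm"], errors="coerce")
    _fail_where(dist.isna() | (dist < 0), df, "distance_mm must be non-negative")
    df["distance_mm"] = dist.astype(float)
    hw = pd.to_numeric(df["headwave_bouts"], errors="coerce")
    _fail_where(hw.isna() | (hw < 0) | (hw != np.floor(hw)), df,
                "headwave_bouts must be a non-negative integer")
    df["headwave_bouts"] = hw.astype(int)
    dup = df.duplicated(subset=["subject_id", "day"], keep=False)
    _fail_where(dup & df.duplicated(subset=["subject_id", "day"]), df,
                "duplicate (subject_id, day) row")
    return df


def ccp_incomplete_subjects(df: pd.DataFrame, n_trials: int = 4) -> list:
    """Subjects missing either test or any of the 2 x n_trials conditioning rows."""
    incomplete = []
    for sid, grp in df.groupby("subject_id"):
        ok = ("pretest" in grp["phase"].values
              and "posttest" in grp["phase"].values)
        cond = grp[grp["phase"] == "conditioning"]
        cells = set(zip(cond["drug"], cond["trial"]))
        need = {(d, t) for d in ("cocaine", "saline")
                for t in range(1, n_trials + 1)}
        if not ok or not need <= cells:
            incomplete.append(sid)
    return sorted(incomplete)


def ccc_incomplete_subjects(df: pd.DataFrame, days=range(1, 9)) -> list:
    """Subjects missing any of the required days (flagged, excluded casewise)."""
    need = set(days)
    have = df.groupby("subject_id")["day"].agg(set)
    return sorted(str(s) for s in have.index[~have.map(need.issubset)])


def read_summary_table(path, kind: str, **kwargs) -> pd.DataFrame:
    """Read and validate a CCP or CCC session-summary CSV."""
    df = pd.read_csv(path, dtype={"subject_id": str, "cohort": str, "sex": str})
    df.index = pd.RangeIndex(2, len(df) + 2)
    if kind == "ccp":
        return validate_ccp_table(df, **kwargs)
    if kind == "ccc":
        return validate_ccc_table(df, **kwargs)
    raise ValueError(f"unknown summary-table kind '{kind}'")


def write_summary_table(df: pd.DataFrame, kind: str, path) -> None:
    cols = {"ccp": CCP_COLUMNS, "ccc": CCC_COLUMNS}[kind]
    df = validate_ccp_table(df) if kind == "ccp" else validate_ccc_table(df)
    df[cols].to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Manifest


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, files: dict, **extra) -> dict:
    """Record schema version, per-file sha256 checksums and extra metadata."""
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "files": {name: {"path": str(Path(p).name), "sha256": file_checksum(p)}
                  for name, p in files.items()},
    }
    manifest.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
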