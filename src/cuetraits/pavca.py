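"""Pavlovian conditioned approach (PavCA) scoring.

During PavCA an 8-s insertion of a backlit lever (the conditioned stimulus,
CS) precedes response-independent delivery of a food pellet, 25 trials per
session over 5 sessions.  Some animals come to approach the lever itself
(sign-trackers, ST), others the food cup (goal-trackers, GT).  The PavCA
index summarizes that tendency per session as the mean of three components,
each bounded in [-1, 1]:

* probability differential — P(lever contact on a trial) - P(food-cup
  contact on a trial);
* response bias — (lever contacts - food-cup contacts) /
  (lever contacts + food-cup contacts), 0 when both are 0;
* latency score — (food-cup latency - lever latency) / CS duration, where
  per-trial first-contact latencies are censored at the CS duration on
  trials with no contact.

The terminal index is the mean of sessions 4 and 5; subjects are classed GT
for terminal index <= -0.5, ST for >= +0.5, intermediate (IN) otherwise
(the boundary itself belongs to the extreme phenotypes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

CS_DURATION_S = 8.0
TERMINAL_SESSIONS = (4, 5)
GT_THRESHOLD = -0.5
ST_THRESHOLD = 0.5
PHENOTYPES = ("GT", "IN", "ST")

_RANGE_TOL = 1e-9


class MissingSessionError(ValueError):
    """A terminal session (4 or 5) is absent; subject is excluded casewise."""


@dataclass(frozen=True)
class SessionSummary:
    """CS-period and ITI aggregates for one subject-session."""

    subject_id: str
    session: int
    n_trials: int
    lever_contact_prob: float
    foodcup_contact_prob: float
    lever_deflections: int
    foodcup_entries_cs: int
    lever_latency_s: float
    foodcup_latency_s: float
    iti_foodcup_entries: int


@dataclass(frozen=True)
class PavCAComponents:
    prob_diff: float
    response_bias: float
    latency_score: float


def _component_arrays(lever_prob, food_prob, lever_n, food_n,
                      lever_lat, food_lat, cs_duration_s):
    lever_n = np.asarray(lever_n, dtype=float)
    food_n = np.asarray(food_n, dtype=float)
    prob_diff = np.asarray(lever_prob, dtype=float) - np.asarray(food_prob, dtype=float)
    total = lever_n + food_n
    bias = np.divide(lever_n - food_n, np.where(total > 0, total, 1.0),
                     out=np.zeros_like(total), where=True)
    bias = np.where(total > 0, bias, 0.0)
    lat = (np.asarray(food_lat, dtype=float)
           - np.asarray(lever_lat, dtype=float)) / cs_duration_s
    return prob_diff, bias, lat


def prob_differential(s: SessionSummary) -> float:
    """Lever-contact probability minus food-cup-contact probability."""
    return float(s.lever_contact_prob - s.foodcup_contact_prob)


def response_bias(s: SessionSummary) -> float:
    """(lever - food-cup counts) / (lever + food-cup counts); 0 for 0/0."""
    total = s.lever_deflections + s.foodcup_entries_cs
    if total == 0:
        return 0.0
    return float((s.lever_deflections - s.foodcup_entries_cs) / total)


def latency_score(s: SessionSummary, cs_duration_s: float = CS_DURATION_S) -> float:
    """(food-cup latency - lever latency) / CS duration."""
    return float((s.foodcup_latency_s - s.lever_latency_s) / cs_duration_s)


def components(s: SessionSummary,
               cs_duration_s: float = CS_DURATION_S) -> PavCAComponents:
    return PavCAComponents(prob_differential(s), response_bias(s),
                           latency_score(s, cs_duration_s))


def pavca_index(c: PavCAComponents) -> float:
    """Arithmetic mean of the three components; guaranteed in [-1, 1]."""
    for v in (c.prob_diff, c.response_bias, c.latency_score):
        if not -1.0 - _RANGE_TOL <= v <= 1.0 + _RANGE_TOL:
            raise ValueError(f"component {v} outside [-1, 1]")
    return float((c.prob_diff + c.response_bias + c.latency_score) / 3.0)


def session_index(s: SessionSummary,
                  cs_duration_s: float = CS_DURATION_S) -> float:
    return pavca_index(components(s, cs_duration_s))


def terminal_index(per_session: Mapping[int, float]) -> float:
    """Mean index of sessions 4 and 5 only; earlier sessions are ignored."""
    missing = [s for s in TERMINAL_SESSIONS if s not in per_session]
    if missing:
        raise MissingSessionError(
            f"missing terminal session(s) {missing}; subject excluded casewise")
    return float(np.mean([per_session[s] for s in TERMINAL_SESSIONS]))


def classify_phenotype(terminal: float) -> str:
    """GT for terminal <= -0.5, ST for >= +0.5, IN otherwise."""
    if not np.isfinite(terminal) or not -1.0 - _RANGE_TOL <= terminal <= 1.0 + _RANGE_TOL:
        raise ValueError(f"terminal index {terminal} outside [-1, 1]")
    if terminal <= GT_THRESHOLD:
        return "GT"
    if terminal >= ST_THRESHOLD:
        return "ST"
    return "IN"


# ---------------------------------------------------------------------------
# Table-level scoring


def score_pavca_events(events: pd.DataFrame,
                       cs_duration_s: float = CS_DURATION_S) -> pd.DataFrame:
    """Score all PavCA subject-sessions of a validated event table.

    Returns one row per subject-session with the six raw measures, the three
    index components and the per-session index.  Vectorized; suitable for
    cohort-scale event tables (millions of rows).
    """
    ev = events[events["task"] == "pavca"]
    key = ["subject_id", "session", "trial"]
    onsets = ev.loc[ev["event"] == "cs_onset",
                    ["subject_id", "cohort", "sex", "session", "trial", "time_s"]]
    onsets = onsets.rename(columns={"time_s": "_onset"})
    if onsets.empty:
        raise ValueError("no PavCA trials in event table")

    def _per_trial(event_name, prefix):
        sub = ev[(ev["event"] == event_name) & (ev["trial"] > 0)]
        agg = (sub.groupby(key)["time_s"].agg(["size", "min"])
               .rename(columns={"size": f"{prefix}_n", "min": f"{prefix}_first"}))
        return agg.reset_index()

    trial = onsets.merge(_per_trial("lever_deflection", "lev"), on=key, how="left")
    trial = trial.merge(_per_trial("foodcup_entry", "food"), on=key, how="left")
    for p in ("lev", "food"):
        trial[f"{p}_n"] = trial[f"{p}_n"].fillna(0).astype(int)
        lat = (trial[f"{p}_first"] - trial["_onset"]).clip(0.0, cs_duration_s)
        trial[f"{p}_lat"] = lat.fillna(cs_duration_s)
        trial[f"{p}_contact"] = (trial[f"{p}_n"] > 0).astype(float)

    grp = trial.groupby(["subject_id", "session"], sort=True)
    out = grp.agg(
        cohort=("cohort", "first"),
        sex=("sex", "first"),
        n_trials=("trial", "size"),
        lever_contact_prob=("lev_contact", "mean"),
        foodcup_contact_prob=("food_contact", "mean"),
        lever_deflections=("lev_n", "sum"),
        foodcup_entries_cs=("food_n", "sum"),
        lever_latency_s=("lev_lat", "mean"),
        foodcup_latency_s=("food_lat", "mean"),
    ).reset_index()

    iti = (ev[(ev["event"] == "foodcup_entry") & (ev["trial"] == 0)]
           .groupby(["subject_id", "session"]).size().rename("iti_foodcup_entries")
           .reset_index())
    out = out.merge(iti, on=["subject_id", "session"], how="left")
    out["iti_foodcup_entries"] = out["iti_foodcup_entries"].fillna(0).astype(int)

    pd_, bias, lat = _component_arrays(
        out["lever_contact_prob"], out["foodcup_contact_prob"],
        out["lever_deflections"], out["foodcup_entries_cs"],
        out["lever_latency_s"], out["foodcup_latency_s"], cs_duration_s)
    out["prob_diff"] = pd_
    out["response_bias"] = bias
    out["latency_score"] = lat
    out["pavca_index"] = (pd_ + bias + lat) / 3.0
    return out


def summarize_session(events: pd.DataFrame,
                      cs_duration_s: float = CS_DURATION_S) -> SessionSummary:
    """Aggregate a single validated subject-session into a :class:`SessionSummary`."""
    ev = events[events["task"] == "pavca"]
    if ev["subject_id"].nunique() != 1 or ev["session"].nunique() != 1:
        raise ValueError("summarize_session expects exactly one subject-session")
    if (ev["event"] == "cs_onset").sum() == 0:
        raise ValueError("session has zero trials")
    row = score_pavca_events(ev, cs_duration_s).iloc[0]
    return SessionSummary(
        subject_id=row["subject_id"], session=int(row["session"]),
        n_trials=int(row["n_trials"]),
        lever_contact_prob=float(row["lever_contact_prob"]),
        foodcup_contact_prob=float(row["foodcup_contact_prob"]),
        lever_deflections=int(row["lever_deflections"]),
        foodcup_entries_cs=int(row["foodcup_entries_cs"]),
        lever_latency_s=float(row["lever_latency_s"]),
        foodcup_latency_s=float(row["foodcup_latency_s"]),
        iti_foodcup_entries=int(row["iti_foodcup_entries"]))


def subject_table(session_scores: pd.DataFrame):
    """Terminal index and phenotype per subject from per-session scores.

    Subjects missing session 4 or 5 get NaN terminal index and a null
    phenotype and are returned in the excluded list (casewise exclusion).
    """
    wide = session_scores.pivot(index="subject_id", columns="session",
                                values="pavca_index")
    meta = session_scores.groupby("subject_id")[["cohort", "sex"]].first()
    have = [s for s in TERMINAL_SESSIONS if s in wide.columns]
    if len(have) == len(TERMINAL_SESSIONS):
        terminal = wide[list(TERMINAL_SESSIONS)].mean(axis=1, skipna=False)
    else:
        terminal = pd.Series(np.nan, index=wide.index)
    out = meta.copy()
    out["terminal_index"] = terminal
    out["phenotype"] = [classify_phenotype(t) if np.isfinite(t) else None
                        for t in terminal]
    out = out.reset_index()
    excluded = sorted(out.loc[out["terminal_index"].isna(), "subject_id"])
    return out, excluded
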