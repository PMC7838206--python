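"""Conditioned reinforcement (CRF) test scoring.

After Pavlovian training the food cup is removed and nosepokes into an
active port earn 3-s presentations of the lever-CS (an FR-1 schedule with a
lockout: pokes during an ongoing presentation are counted but do not queue
further presentations).  Pokes into the inactive port have no consequence.
Primary measures are active/inactive pokes, earned lever presentations,
lever deflections, lever presses per earned reinforcer, and the composite
Incentive Value Index, (active - inactive pokes) + lever deflections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SESSION_DURATION_MIN = 40.0
PRESENTATION_S = 3.0


@dataclass(frozen=True)
class CRFSummary:
    subject_id: str
    active_pokes: int
    inactive_pokes: int
    earned_reinforcers: int
    lever_deflections: int

    @property
    def presses_per_reinforcer(self) -> float:
        return presses_per_reinforcer(self)

    @property
    def incentive_value_index(self) -> int:
        return incentive_value_index(self)


def presses_per_reinforcer(s: CRFSummary) -> float:
    """Lever deflections per earned reinforcer; NaN (missing) when none earned.

    Subjects with zero earned reinforcers are excluded casewise from analyses
    of this measure.
    """
    if s.earned_reinforcers == 0:
        return float("nan")
    return float(s.lever_deflections / s.earned_reinforcers)


def incentive_value_index(s: CRFSummary) -> int:
    """(active pokes - inactive pokes) + lever deflections; may be negative."""
    return int(s.active_pokes - s.inactive_pokes + s.lever_deflections)


def crf_summary(events: pd.DataFrame) -> CRFSummary:
    """Tally one subject's CRF session from a validated event table."""
    ev = events[events["task"] == "crf"]
    subjects = ev["subject_id"].unique()
    if len(subjects) > 1:
        raise ValueError("crf_summary expects a single subject")
    sid = subjects[0] if len(subjects) else ""
    n = ev["event"].value_counts()
    return CRFSummary(
        subject_id=str(sid),
        active_pokes=int(n.get("poke_active", 0)),
        inactive_pokes=int(n.get("poke_inactive", 0)),
        earned_reinforcers=int(n.get("lever_presentation", 0)),
        lever_deflections=int(n.get("lever_deflection", 0)))


def score_crf_events(events: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: the four counts plus derived incentive measures."""
    ev = events[events["task"] == "crf"]
    meta = ev.groupby("subject_id")[["cohort", "sex"]].first()
    counts = (ev.groupby(["subject_id", "event"]).size().unstack(fill_value=0)
              .reindex(columns=["poke_active", "poke_inactive",
                                "lever_presentation", "lever_deflection"],
                       fill_value=0))
    counts.columns = ["active_pokes", "inactive_pokes",
                      "earned_reinforcers", "lever_deflections"]
    out = meta.join(counts).reset_index()
    earned = out["earned_reinforcers"].to_numpy(dtype=float)
    defl = out["lever_deflections"].to_numpy(dtype=float)
    out["presses_per_reinforcer"] = np.where(earned > 0, defl / np.where(earned > 0, earned, 1.0), np.nan)
    out["incentive_value_index"] = (out["active_pokes"] - out["inactive_pokes"]
                                    + out["lever_deflections"])
    return out


def replay_earned_presentations(poke_times, presentation_s: float = PRESENTATION_S):
    """Presentation onset times implied by active pokes under the 3-s lockout.

    A poke earns a presentation only if no presentation is ongoing; pokes
    inside the window are counted as pokes but earn nothing, so
    earned <= active pokes always.
    """
    onsets = []
    busy_until = -np.inf
    for t in np.sort(np.asarray(poke_times, dtype=float)):
        if t >= busy_until:
            onsets.append(t)
            busy_until = t + presentation_s
    return np.asarray(onsets)
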