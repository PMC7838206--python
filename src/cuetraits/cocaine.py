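"""Scoring of the two cocaine-conditioning paradigms.

Conditioned cue preference (CCP): after a pre-test on the combined
grid/hole floor, cocaine (10 mg/kg i.p.) is paired with the *less* preferred
floor (counter-conditioning) over 4 cocaine/saline trial pairs, followed by a
drug-free post-test.  Scores per subject: the assigned cocaine floor, change
in time on that floor (post - pre; positive = increased preference),
per-trial cocaine/saline locomotion, and locomotor sensitization
(cocaine trial 4 - trial 1).

Contextual conditioning (CCC): an 8-day schedule (day 1 habituation, day 2
saline baseline, days 3-7 cocaine at 15 mg/kg, day 8 drug-free probe)
yields three contrasts for distance and for headwave bouts, all signed
later-day minus earlier-day: acute activation (day 3 - day 2), sensitization
(day 7 - day 3, typically negative for locomotion as stereotypy replaces
forward movement), and conditioned locomotion (day 8 - day 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FLOORS = ("grid", "hole")

#: (later day, earlier day) per contrast; signs are later - earlier.
CCC_CONTRAST_DAYS = {"acute": (3, 2), "sensitization": (7, 3),
                     "conditioned": (8, 2)}
CCC_REQUIRED_DAYS = tuple(range(1, 9))


@dataclass(frozen=True)
class CCPResult:
    subject_id: str
    cocaine_floor: str
    pre_time_cocaine_floor_s: float
    post_time_cocaine_floor_s: float
    delta_preference_s: float
    cocaine_distance_by_trial: tuple
    saline_distance_by_trial: tuple
    locomotor_sensitization_mm: float
    posttest_locomotion_mm: float


@dataclass(frozen=True)
class CCCResult:
    subject_id: str
    acute_locomotion_mm: float
    sensitization_locomotion_mm: float
    conditioned_locomotion_mm: float
    acute_headwaves: float
    sensitized_headwaves: float
    conditioned_headwaves: float


def assign_cocaine_floor(time_on_grid_s: float, time_on_hole_s: float,
                         rng=None) -> str:
    """Counter-conditioning: the less-preferred pre-test floor gets cocaine.

    An exact tie is broken by a seeded uniform choice (``rng`` required then),
    so assignment is reproducible under the same seed.
    """
    tg, th = float(time_on_grid_s), float(time_on_hole_s)
    if not (np.isfinite(tg) and np.isfinite(th)):
        raise ValueError("missing pre-test floor time")
    if tg < th:
        return "grid"
    if th < tg:
        return "hole"
    if rng is None:
        raise ValueError("exact floor-time tie: provide rng for the seeded tie-break")
    return str(rng.choice(FLOORS))


def ccp_preference_change(pre_time_s: float, post_time_s: float) -> float:
    """Post-test minus pre-test time on the cocaine floor (positive = increase)."""
    return float(post_time_s - pre_time_s)


def ccp_locomotor_measures(conditioning: pd.DataFrame, n_trials: int = 4) -> dict:
    """Per-trial cocaine/saline distances and sensitization for one subject."""
    out = {}
    for drug in ("cocaine", "saline"):
        rows = conditioning[conditioning["drug"] == drug]
        by_trial = rows.set_index("trial")["distance_mm"]
        if sorted(by_trial.index) != list(range(1, n_trials + 1)):
            raise ValueError(f"incomplete {drug} conditioning trials; "
                             "subject excluded casewise")
        out[drug] = tuple(float(by_trial[t]) for t in range(1, n_trials + 1))
    out["sensitization_mm"] = out["cocaine"][-1] - out["cocaine"][0]
    return out


def ccc_contrasts(rows: pd.DataFrame) -> CCCResult:
    """Signed day contrasts for one subject's 8-day contextual conditioning."""
    sid = str(rows["subject_id"].iloc[0])
    dist = rows.set_index("day")["distance_mm"]
    hw = rows.set_index("day")["headwave_bouts"]
    needed = {d for pair in CCC_CONTRAST_DAYS.values() for d in pair}
    if not needed <= set(dist.index):
        raise ValueError(f"subject {sid} missing required day(s); excluded casewise")
    vals = {}
    for name, (late, early) in CCC_CONTRAST_DAYS.items():
        vals[name] = (float(dist[late] - dist[early]),
                      float(hw[late] - hw[early]))
    return CCCResult(
        subject_id=sid,
        acute_locomotion_mm=vals["acute"][0],
        sensitization_locomotion_mm=vals["sensitization"][0],
        conditioned_locomotion_mm=vals["conditioned"][0],
        acute_headwaves=vals["acute"][1],
        sensitized_headwaves=vals["sensitization"][1],
        conditioned_headwaves=vals["conditioned"][1])


# ---------------------------------------------------------------------------
# Table-level scoring


def score_ccp(ccp: pd.DataFrame, rng=None, n_trials: int = 4):
    """Score a validated CCP table; returns (per-subject frame, exclusion log).

    Subjects missing a test session or any conditioning cell are excluded
    casewise; exact pre-test ties are tie-broken with ``rng`` and logged.
    """
    log = {"excluded": [], "ties": []}
    meta = ccp.groupby("subject_id")[["cohort", "sex"]].first()

    def _test(phase):
        t = ccp[ccp["phase"] == phase].set_index("subject_id")
        return t[~t.index.duplicated()]

    pre, post = _test("pretest"), _test("posttest")
    cond = ccp[ccp["phase"] == "conditioning"]
    dist = cond.pivot_table(index="subject_id", columns=["drug", "trial"],
                            values="distance_mm", aggfunc="first")
    need = pd.MultiIndex.from_product(
        [["cocaine", "saline"], range(1, n_trials + 1)])
    dist = dist.reindex(columns=need)
    posttest_dist = post["distance_mm"] if "distance_mm" in post else pd.Series(dtype=float)

    rows = []
    for sid in meta.index:
        ok = (sid in pre.index and sid in post.index
              and sid in dist.index and not dist.loc[sid].isna().any())
        if not ok:
            log["excluded"].append(sid)
            continue
        tg, th = pre.loc[sid, "time_on_grid_s"], pre.loc[sid, "time_on_hole_s"]
        if tg == th:
            log["ties"].append(sid)
        floor = assign_cocaine_floor(tg, th, rng=rng)
        pre_t = tg if floor == "grid" else th
        post_t = (post.loc[sid, "time_on_grid_s"] if floor == "grid"
                  else post.loc[sid, "time_on_hole_s"])
        coc = [dist.loc[sid, ("cocaine", t)] for t in range(1, n_trials + 1)]
        sal = [dist.loc[sid, ("saline", t)] for t in range(1, n_trials + 1)]
        row = {
            "subject_id": sid,
            "cohort": meta.loc[sid, "cohort"], "sex": meta.loc[sid, "sex"],
            "cocaine_floor": floor,
            "pre_time_cocaine_floor_s": float(pre_t),
            "post_time_cocaine_floor_s": float(post_t),
            "delta_preference_s": ccp_preference_change(pre_t, post_t),
            "ccp_sensitization_mm": float(coc[-1] - coc[0]),
            "posttest_locomotion_mm": float(posttest_dist.get(sid, np.nan)),
        }
        for t in range(n_trials):
            row[f"cocaine_dist_t{t + 1}_mm"] = float(coc[t])
            row[f"saline_dist_t{t + 1}_mm"] = float(sal[t])
        rows.append(row)
    out = pd.DataFrame(rows)
    log["excluded"] = sorted(log["excluded"])
    return out, log


def score_ccc(ccc: pd.DataFrame, required_days=CCC_REQUIRED_DAYS):
    """Score a validated CCC table; returns (per-subject frame, excluded list).

    Subjects missing any required day are flagged incomplete and excluded
    casewise from all contrasts.
    """
    meta = ccc.groupby("subject_id")[["cohort", "sex"]].first()
    have = ccc.groupby("subject_id")["day"].agg(set)
    need = set(required_days)
    excluded = sorted(str(s) for s in have.index[~have.map(need.issubset)])
    keep = [s for s in meta.index if s not in set(excluded)]

    dist = ccc.pivot_table(index="subject_id", columns="day",
                           values="distance_mm", aggfunc="first")
    hw = ccc.pivot_table(index="subject_id", columns="day",
                         values="headwave_bouts", aggfunc="first")
    rows = []
    for sid in keep:
        d, h = dist.loc[sid], hw.loc[sid]
        row = {"subject_id": sid, "cohort": meta.loc[sid, "cohort"],
               "sex": meta.loc[sid, "sex"]}
        for name, (late, early) in CCC_CONTRAST_DAYS.items():
            row[f"ccc_{name}_locomotion_mm"] = float(d[late] - d[early])
            row[f"ccc_{name}_headwaves"] = float(h[late] - h[early])
        row["ccc_day2_distance_mm"] = float(d[2])
        row["ccc_day3_distance_mm"] = float(d[3])
        row["ccc_day7_distance_mm"] = float(d[7])
        row["ccc_day8_distance_mm"] = float(d[8])
        rows.append(row)
    return pd.DataFrame(rows), excluded
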