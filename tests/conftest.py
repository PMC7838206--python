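"""Shared fixtures: event-table builders and independent scoring oracles.

The oracles deliberately avoid the package's vectorized code paths: they
re-derive every quantity with explicit per-trial / per-cell loops so that
agreement is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Event builders


def build_pavca_session(subject_id, session, trial_specs, cs=8.0,
                        iti=60.0, cohort="A", sex="male", iti_entries=()):
    """Build one valid PavCA subject-session from per-trial contact offsets.

    ``trial_specs`` is a list of ``(lever_offsets, food_offsets)`` with
    offsets in [0, cs) seconds relative to CS onset.  ``iti_entries`` are
    absolute times of trial-0 food-cup entries.
    """
    rows = []
    t = 0.0
    for i, (lever, food) in enumerate(trial_specs, start=1):
        t += iti
        onset = round(t, 3)
        offset = onset + cs

        def _row(trial, event, time):
            rows.append(dict(subject_id=subject_id, cohort=cohort, sex=sex,
                             task="pavca", session=session, trial=trial,
                             event=event, time_s=round(time, 3)))

        _row(i, "cs_onset", onset)
        for dt in lever:
            _row(i, "lever_deflection", onset + dt)
        for dt in food:
            _row(i, "foodcup_entry", onset + dt)
        _row(i, "cs_offset", offset)
        _row(i, "pellet_delivery", offset)
        t = offset
    for at in iti_entries:
        rows.append(dict(subject_id=subject_id, cohort=cohort, sex=sex,
                         task="pavca", session=session, trial=0,
                         event="foodcup_entry", time_s=round(at, 3)))
    return pd.DataFrame(rows)


def build_crf_session(subject_id, counts, cohort="A", sex="male",
                      duration_s=2400.0):
    """CRF event table for one subject from raw per-event counts."""
    rows = []
    t = 1.0
    for event, n in counts.items():
        for _ in range(n):
            rows.append(dict(subject_id=subject_id, cohort=cohort, sex=sex,
                             task="crf", session=1, trial=0, event=event,
                             time_s=round(min(t, duration_s - 1.0), 3)))
            t += 0.731
    if not rows:
        from cuetraits.events_io import empty_event_table
        return empty_event_table()
    return pd.DataFrame(rows)


def random_pavca_session(rng, subject_id="R1", session=1, n_trials=25, cs=8.0):
    """Random but valid session: random contacts, counts and latencies."""
    specs = []
    for _ in range(n_trials):
        lever, food = [], []
        if rng.random() < 0.6:
            n = rng.integers(1, 6)
            lever = sorted(np.round(rng.uniform(0, cs - 1e-3, n), 3))
        if rng.random() < 0.6:
            n = rng.integers(1, 5)
            food = sorted(np.round(rng.uniform(0, cs - 1e-3, n), 3))
        specs.append((lever, food))
    iti_entries = np.round(rng.uniform(1, 50, rng.integers(0, 5)), 3)
    return build_pavca_session(subject_id, session, specs, cs=cs,
                               iti=float(rng.uniform(30, 150)),
                               iti_entries=iti_entries)


@pytest.fixture
def make_pavca_session():
    return build_pavca_session


@pytest.fixture
def make_crf_session():
    return build_crf_session


@pytest.fixture
def make_random_session():
    return random_pavca_session


# ---------------------------------------------------------------------------
# Independent oracles


def pavca_index_oracle(events, cs=8.0):
    """PavCA session index recomputed by an explicit per-trial line scan.

    Works directly from raw events — no SessionSummary intermediate — using
    plain Python dicts and loops.
    """
    onsets, lever, food = {}, {}, {}
    for _, row in events.iterrows():
        tr = int(row["trial"])
        if row["event"] == "cs_onset":
            onsets[tr] = float(row["time_s"])
        elif row["event"] == "lever_deflection" and tr > 0:
            lever.setdefault(tr, []).append(float(row["time_s"]))
        elif row["event"] == "foodcup_entry" and tr > 0:
            food.setdefault(tr, []).append(float(row["time_s"]))
    trials = sorted(onsets)
    n = len(trials)
    lever_hits = sum(1 for t in trials if lever.get(t))
    food_hits = sum(1 for t in trials if food.get(t))
    n_lever = sum(len(lever.get(t, [])) for t in trials)
    n_food = sum(len(food.get(t, [])) for t in trials)
    lat_l = sum(min(lever[t]) - onsets[t] if lever.get(t) else cs
                for t in trials) / n
    lat_f = sum(min(food[t]) - onsets[t] if food.get(t) else cs
                for t in trials) / n
    prob_diff = lever_hits / n - food_hits / n
    bias = 0.0 if n_lever + n_food == 0 else \
        (n_lever - n_food) / (n_lever + n_food)
    lat_score = (lat_f - lat_l) / cs
    return (prob_diff + bias + lat_score) / 3.0


def anova_oracle_mixed(y):
    """Brute-force SS decomposition for a balanced one-between one-within design.

    ``y[g][s][w]`` indexes group, subject-within-group, within-level.
    Returns dict of (ss, df) per term using explicit summation only.
    """
    y = np.asarray(y, dtype=float)
    a, n, w = y.shape
    grand = y.mean()
    m_g = y.mean(axis=(1, 2))
    m_s = y.mean(axis=2)
    m_w = y.mean(axis=(0, 1))
    m_gw = y.mean(axis=1)
    ss_a = sum(n * w * (m_g[g] - grand) ** 2 for g in range(a))
    ss_subj = sum(w * (m_s[g, s] - m_g[g]) ** 2
                  for g in range(a) for s in range(n))
    ss_w = sum(a * n * (m_w[k] - grand) ** 2 for k in range(w))
    ss_aw = sum(n * (m_gw[g, k] - m_g[g] - m_w[k] + grand) ** 2
                for g in range(a) for k in range(w))
    ss_err = sum((y[g, s, k] - m_s[g, s] - m_gw[g, k] + m_g[g]) ** 2
                 for g in range(a) for s in range(n) for k in range(w))
    return {
        "between": (ss_a, a - 1),
        "subjects": (ss_subj, a * (n - 1)),
        "within": (ss_w, w - 1),
        "interaction": (ss_aw, (a - 1) * (w - 1)),
        "error": (ss_err, a * (n - 1) * (w - 1)),
        "total": (float(((y - grand) ** 2).sum()), a * n * w - 1),
    }


def anova_oracle_two_between(y):
    """Explicit two-way between-only decomposition, balanced ``y[a][b][rep]``."""
    y = np.asarray(y, dtype=float)
    a, b, n = y.shape
    grand = y.mean()
    m_a = y.mean(axis=(1, 2))
    m_b = y.mean(axis=(0, 2))
    m_ab = y.mean(axis=2)
    ss_a = sum(b * n * (m_a[i] - grand) ** 2 for i in range(a))
    ss_b = sum(a * n * (m_b[j] - grand) ** 2 for j in range(b))
    ss_ab = sum(n * (m_ab[i, j] - m_a[i] - m_b[j] + grand) ** 2
                for i in range(a) for j in range(b))
    ss_err = sum((y[i, j, r] - m_ab[i, j]) ** 2
                 for i in range(a) for j in range(b) for r in range(n))
    return {"A": (ss_a, a - 1), "B": (ss_b, b - 1),
            "AB": (ss_ab, (a - 1) * (b - 1)),
            "error": (ss_err, a * b * (n - 1)),
            "total": (float(((y - grand) ** 2).sum()), a * b * n - 1)}


@pytest.fixture
def index_oracle():
    return pavca_index_oracle


@pytest.fixture
def mixed_anova_oracle():
    return anova_oracle_mixed


@pytest.fixture
def between_anova_oracle():
    return anova_oracle_two_between


# ---------------------------------------------------------------------------
# Small simulated cohort shared across tests (session scope: built once)


@pytest.fixture(scope="session")
def small_cohort():
    from cuetraits.simulate import CohortConfig, simulate_cohort
    return simulate_cohort(CohortConfig(n_subjects=40, master_seed=11))


@pytest.fixture(scope="session")
def small_score(small_cohort):
    from cuetraits.pipeline import run_score
    return run_score(pavca_events=small_cohort.pavca_events,
                     crf_events=small_cohort.crf_events,
                     ccp=small_cohort.ccp, ccc=small_cohort.ccc)
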