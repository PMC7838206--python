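"""PavCA index components, terminal average, phenotype classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cuetraits import pavca
from cuetraits.pavca import (MissingSessionError, PavCAComponents,
                             SessionSummary, classify_phenotype, components,
                             latency_score, pavca_index, prob_differential,
                             response_bias, score_pavca_events, session_index,
                             subject_table, summarize_session, terminal_index)


def _summary(lp=0.0, fp=0.0, ln=0, fn=0, ll=8.0, fl=8.0):
    return SessionSummary("S", 1, 25, lp, fp, ln, fn, ll, fl, 0)


# --- worked fixture from a spreadsheet-style recomputation ------------------

def test_session_summary_matches_per_trial_recomputation(make_pavca_session):
    # 25 trials: lever contact on 20 (4 deflections each, first at 2.0 s),
    # food cup on 10 (3 entries each, first at 5.0 s)
    specs = []
    for i in range(25):
        lever = [2.0, 3.0, 4.0, 5.0] if i < 20 else []
        food = [5.0, 6.0, 7.0] if i < 10 else []
        specs.append((lever, food))
    events = make_pavca_session("S1", 4, specs)
    s = summarize_session(events)
    assert s.n_trials == 25
    assert s.lever_contact_prob == pytest.approx(0.80)
    assert s.foodcup_contact_prob == pytest.approx(0.40)
    assert s.lever_deflections == 80
    assert s.foodcup_entries_cs == 30
    # censored means: (20*2.0 + 5*8)/25 and (10*5.0 + 15*8)/25
    assert s.lever_latency_s == pytest.approx(3.2)
    assert s.foodcup_latency_s == pytest.approx(6.8)
    c = components(s)
    assert c.prob_diff == pytest.approx(0.40)
    assert c.response_bias == pytest.approx(50 / 110)
    assert c.latency_score == pytest.approx(0.45)
    assert pavca_index(c) == pytest.approx((0.40 + 50 / 110 + 0.45) / 3)
    assert pavca_index(c) == pytest.approx(0.4348, abs=5e-4)


def test_all_lever_no_food_session(make_pavca_session):
    events = make_pavca_session("S1", 1, [([1.0], []) for _ in range(25)])
    s = summarize_session(events)
    assert (s.lever_contact_prob, s.foodcup_contact_prob) == (1.0, 0.0)
    assert s.lever_latency_s == pytest.approx(1.0)
    assert s.foodcup_latency_s == pytest.approx(8.0)  # censored


def test_empty_session_censors_both_latencies(make_pavca_session):
    events = make_pavca_session("S1", 1, [([], []) for _ in range(10)])
    s = summarize_session(events)
    assert s.lever_contact_prob == 0.0 and s.foodcup_contact_prob == 0.0
    assert s.lever_latency_s == 8.0 and s.foodcup_latency_s == 8.0
    assert session_index(s) == 0.0


def test_zero_trials_is_an_error(make_pavca_session):
    events = make_pavca_session("S1", 1, [([1.0], [])])
    with pytest.raises(ValueError, match="zero trials"):
        summarize_session(events[events["event"] == "pellet_delivery"])


# --- component arithmetic ---------------------------------------------------

@pytest.mark.parametrize("lp,fp,expect", [(1.0, 0.0, 1.0), (0.80, 0.40, 0.40),
                                          (0.5, 0.5, 0.0)])
def test_probability_differential(lp, fp, expect):
    assert prob_differential(_summary(lp=lp, fp=fp)) == pytest.approx(expect)


@pytest.mark.parametrize("ln,fn,expect", [(80, 30, 50 / 110), (0, 0, 0.0),
                                          (0, 40, -1.0)])
def test_response_bias_including_degenerate_zero(ln, fn, expect):
    assert response_bias(_summary(ln=ln, fn=fn)) == pytest.approx(expect)


@pytest.mark.parametrize("fl,ll,expect", [(8.0, 0.0, 1.0), (6.8, 3.2, 0.45),
                                          (4.4, 4.4, 0.0)])
def test_latency_score_divides_the_whole_difference(fl, ll, expect):
    assert latency_score(_summary(ll=ll, fl=fl)) == pytest.approx(expect)


@pytest.mark.parametrize("c,expect", [
    ((1.0, 1.0, 1.0), 1.0),        # pure sign-tracker attains the upper bound
    ((-1.0, -1.0, -1.0), -1.0),    # pure goal-tracker attains the lower bound
    ((0.40, 50 / 110, 0.45), (0.40 + 50 / 110 + 0.45) / 3),
])
def test_index_is_mean_of_components(c, expect):
    assert pavca_index(PavCAComponents(*c)) == pytest.approx(expect)


def test_index_rejects_out_of_range_components():
    with pytest.raises(ValueError):
        pavca_index(PavCAComponents(1.5, 0.0, 0.0))


# --- terminal index and classification --------------------------------------

def test_terminal_uses_sessions_4_and_5_only():
    assert terminal_index({4: 0.2, 5: 0.4}) == pytest.approx(0.3)
    assert terminal_index({1: 0.9, 2: 0.9, 3: 0.9, 4: -0.6, 5: -0.6}) \
        == pytest.approx(-0.6)
    with pytest.raises(MissingSessionError):
        terminal_index({1: 0.1, 2: 0.1, 3: 0.1, 4: 0.1})


@pytest.mark.parametrize("t,label", [(-0.75, "GT"), (0.0, "IN"), (0.5, "ST"),
                                     (-0.5, "GT"), (0.49999, "IN"),
                                     (1.0, "ST"), (-1.0, "GT")])
def test_classification_thresholds_and_boundaries(t, label):
    assert classify_phenotype(t) == label


def test_classification_is_total_and_partitions_the_range():
    grid = np.linspace(-1, 1, 4001)
    labels = [classify_phenotype(t) for t in grid]
    assert set(labels) == {"GT", "IN", "ST"}
    # exactly one label per value, stable under re-application of thresholds
    for t, lab in zip(grid, labels):
        assert classify_phenotype(t) == lab
    with pytest.raises(ValueError):
        classify_phenotype(1.2)
    with pytest.raises(ValueError):
        classify_phenotype(float("nan"))


# --- properties -------------------------------------------------------------

@given(lp=st.floats(0, 1), fp=st.floats(0, 1),
       ln=st.integers(0, 500), fn=st.integers(0, 500),
       ll=st.floats(0, 8), fl=st.floats(0, 8))
def test_components_and_index_always_bounded(lp, fp, ln, fn, ll, fl):
    s = _summary(lp, fp, ln, fn, ll, fl)
    c = components(s)
    for v in (c.prob_diff, c.response_bias, c.latency_score):
        assert -1.0 <= v <= 1.0
    assert -1.0 <= pavca_index(c) <= 1.0


@pytest.mark.parametrize("seed", range(8))
def test_adding_lever_contact_never_decreases_index(seed, make_random_session,
                                                    index_oracle):
    rng = np.random.default_rng(seed)
    events = make_random_session(rng)
    base = index_oracle(events)
    onsets = events[events["event"] == "cs_onset"]
    row = onsets.sample(1, random_state=seed).iloc[0]
    t_new = float(row["time_s"]) + float(rng.uniform(0, 7.99))
    for event, direction in (("lever_deflection", 1), ("foodcup_entry", -1)):
        extra = pd.DataFrame([{**row.to_dict(), "event": event,
                               "time_s": round(t_new, 3)}])
        bumped = index_oracle(pd.concat([events, extra], ignore_index=True))
        mod = summarize_session(
            pd.concat([events, extra], ignore_index=True))
        assert session_index(mod) == pytest.approx(bumped, abs=1e-12)
        if direction > 0:
            assert bumped >= base - 1e-12
        else:
            assert bumped <= base + 1e-12


def test_index_matches_event_level_oracle_on_100_random_fixtures(
        make_random_session, index_oracle):
    rng = np.random.default_rng(123)
    for i in range(100):
        events = make_random_session(rng, subject_id=f"S{i}",
                                     n_trials=int(rng.integers(5, 30)))
        expect = index_oracle(events)
        got = session_index(summarize_session(events))
        assert got == pytest.approx(expect, abs=1e-12)


# --- table-level scoring -----------------------------------------------------

def test_score_table_and_subject_terminal(make_pavca_session):
    frames = []
    for sess in range(1, 6):
        spec = [([0.5], [])] * 25 if sess >= 4 else [([], [1.0])] * 25
        frames.append(make_pavca_session("S1", sess, spec))
    # subject missing session 5 entirely
    frames.append(make_pavca_session("S2", 4, [([0.5], [])] * 25))
    events = pd.concat(frames, ignore_index=True)
    scores = score_pavca_events(events)
    assert len(scores) == 6
    subj, excluded = subject_table(scores)
    s1 = subj[subj["subject_id"] == "S1"].iloc[0]
    # sessions 1-3 are pure goal-tracking, ignored by the terminal average
    assert s1["terminal_index"] == pytest.approx(
        (1 + 1 + (8 - 0.5) / 8) / 3)
    assert s1["phenotype"] == "ST"
    assert excluded == ["S2"]
    assert subj[subj["subject_id"] == "S2"]["phenotype"].isna().all()


def test_iti_entries_reported_but_excluded_from_index(make_pavca_session):
    specs = [([1.0], []) for _ in range(5)]
    plain = make_pavca_session("S1", 1, specs)
    with_iti = make_pavca_session("S1", 1, specs, iti_entries=[10.0, 20.0])
    a, b = summarize_session(plain), summarize_session(with_iti)
    assert b.iti_foodcup_entries == 2 and a.iti_foodcup_entries == 0
    assert session_index(a) == session_index(b)
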