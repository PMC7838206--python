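"""Synthetic cohort generator.

Generates complete cohorts — trial-level PavCA and CRF event streams plus
session-level CCP/CCC tables — from a two-trait latent model:

* ``theta_is`` (incentive salience): drives lever- vs food-cup-directed
  behavior during PavCA and, through the realized terminal index, the
  conditioned reinforcing value of the lever during CRF;
* ``theta_cr`` (cocaine responsivity): drives cocaine-induced locomotion,
  stereotypy and conditioned responses during CCP and CCC.

The two standardized traits are bivariate normal with configurable
correlation ``trait_correlation_rho`` (default 0, the independence null).
Females get an upward shift of ``theta_is`` (more lever-directed behavior)
and a multiplicative boost of cocaine locomotion.  Task schedules follow the
study design: 5 PavCA sessions x 25 trials with an 8-s CS and VI-90
(uniform 30-150 s) ITIs, a 40-min CRF session with 3-s lever presentations
under an FR-1 lockout, 4-trial CCP at 10 mg/kg with counter-conditioned
floor assignment, and 8-day CCC at 15 mg/kg.

All outputs use the :mod:`cuetraits.events_io` dialects, so simulated and
real data are interchangeable, and generation is fully deterministic under
``master_seed`` (independent child streams per component).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import crf as _crf
from . import pavca as _pavca


@dataclass
class CohortConfig:
    """Study-design schedule, latent-trait structure and generator knobs."""

    # cohort composition
    n_subjects: int = 200
    sex_ratio: float = 0.5          # fraction female
    cohort: str = "A"
    master_seed: int = 0

    # PavCA schedule
    n_sessions: int = 5
    trials_per_session: int = 25
    cs_duration_s: float = 8.0
    iti_range_s: tuple = (30.0, 150.0)   # VI-90

    # CRF schedule
    crf_duration_min: float = 40.0
    crf_presentation_s: float = 3.0

    # CCP / CCC schedule
    ccp_trials: int = 4
    ccp_test_duration_s: float = 1800.0
    ccp_dose_mg_kg: float = 10.0
    ccc_days: int = 8
    ccc_dose_mg_kg: float = 15.0

    # latent-trait structure
    trait_correlation_rho: float = 0.0
    sex_index_shift: float = 0.4         # theta_is shift for females (SD units)
    sex_locomotion_multiplier: float = 1.35
    crf_coupling: float = 0.43           # target r^2, index vs presses/reinforcer

    # PavCA acquisition dynamics (session ramp makes session 1 near-indifferent
    # and sessions 4-5 trait-saturated)
    acq_intercept: float = -0.2
    acq_slope: float = 2.5
    latency_scale_s: float = 2.5
    latency_slope: float = 0.8
    count_rate: float = 2.0
    count_slope: float = 0.5
    iti_entry_rate_per_min: float = 1.0
    iti_entry_female_multiplier: float = 1.5

    # CRF response generation
    crf_active_log_rate: float = 3.2
    crf_active_slope: float = 0.3
    crf_inactive_log_rate: float = 2.3
    crf_inactive_slope: float = -0.1
    crf_ppr_mean: float = 2.5
    crf_ppr_sd: float = 0.8

    # locomotion / CCP generation
    loco_log_baseline: float = 9.6       # log mm per 30-min session (~15 m)
    loco_log_baseline_sd: float = 0.35
    loco_noise_sd: float = 0.25
    ccp_cocaine_multiplier: float = 2.2
    ccp_theta_slope: float = 0.35
    ccp_sensitization_per_trial: float = 0.08
    ccp_bias_base_s: float = 60.0
    ccp_bias_gt_s: float = 110.0
    ccp_bias_slope: float = 1.2
    ccp_bias_retention: float = 0.55
    ccp_gain_s: float = 90.0
    ccp_gain_theta: float = 0.20
    ccp_pref_noise_s: float = 55.0
    ccp_posttest_conditioned: float = 0.10

    # CCC generation
    ccc_cocaine_multiplier: float = 2.5
    ccc_theta_slope: float = 0.35
    ccc_decay_male: float = 0.86         # per-day locomotion decay, days 3-7
    ccc_decay_female: float = 0.78
    ccc_headwave_base: float = 4.0
    ccc_headwave_growth: float = 1.9
    ccc_headwave_female: float = 1.6
    ccc_headwave_theta: float = 0.3
    ccc_baseline_headwaves: float = 2.0
    ccc_day8_headwaves: float = 4.0
    ccc_conditioned_loco: float = 0.45
    ccc_conditioned_theta: float = 0.30
    ccc_novelty_boost: float = 0.15
    n_incomplete_ccc: int = 0            # subjects with one day dropped

    def __post_init__(self):
        self.iti_range_s = tuple(float(v) for v in self.iti_range_s)
        if not -1.0 <= self.trait_correlation_rho <= 1.0:
            raise ValueError("trait_correlation_rho must lie in [-1, 1]")
        for name in ("n_subjects", "n_sessions", "trials_per_session",
                     "ccp_trials", "ccc_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.iti_range_s[0] <= 0 or self.iti_range_s[1] < self.iti_range_s[0]:
            raise ValueError("iti_range_s must be a positive increasing pair")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["iti_range_s"] = list(d["iti_range_s"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class SimulatedCohort:
    config: CohortConfig
    traits: pd.DataFrame        # subject_id, cohort, sex, theta_is, theta_cr
    pavca_events: pd.DataFrame
    crf_events: pd.DataFrame
    ccp: pd.DataFrame
    ccc: pd.DataFrame
    terminal_index: pd.Series = field(default=None)   # realized, per subject


def _round_ms(x):
    return np.round(np.asarray(x, dtype=float), 3)


def draw_traits(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-subject latent traits: bivariate normal, female theta_is shift."""
    n = config.n_subjects
    rho = config.trait_correlation_rho
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    theta_is = z1
    theta_cr = rho * z1 + np.sqrt(max(0.0, 1.0 - rho ** 2)) * z2
    n_female = int(round(n * config.sex_ratio))
    sex = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(sex)
    theta_is = theta_is + np.where(sex == "female", config.sex_index_shift, 0.0)
    ids = [f"{config.cohort}{i + 1:05d}" for i in range(n)]
    return pd.DataFrame({"subject_id": ids, "cohort": config.cohort,
                         "sex": sex, "theta_is": theta_is,
                         "theta_cr": theta_cr})


def _truncated_exp(rng, scale, upper):
    """Exponential with per-draw scale, truncated to [0, upper)."""
    u = rng.random(np.shape(scale))
    return -scale * np.log1p(-u * (1.0 - np.exp(-upper / scale)))


def simulate_pavca(traits: pd.DataFrame, config: CohortConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Event streams for all PavCA sessions (vectorized over the cohort).

    Per trial, contact with the lever (mirror: food cup) is Bernoulli with a
    logistic link in session-scaled theta_is (-theta_is), deflection/entry
    counts are 1 + Poisson conditional on contact, first-contact latencies
    are truncated-exponential on [0, CS), and ITI food-cup entries are
    Poisson with a female-elevated rate.  ITIs are uniform on the VI range,
    so the expected cumulative ITI time per session is
    ``trials * mean(ITI)`` (37.5 min under the default VI-90 x 25 trials).
    """
    n = len(traits)
    S, T = config.n_sessions, config.trials_per_session
    cs = config.cs_duration_s
    lo, hi = config.iti_range_s
    N = n * S * T

    subj = np.repeat(np.arange(n), S * T)
    sess = np.tile(np.repeat(np.arange(1, S + 1), T), n)
    trial = np.tile(np.arange(1, T + 1), n * S)
    theta = traits["theta_is"].to_numpy()[subj]
    female = (traits["sex"].to_numpy() == "female")[subj]
    g = sess / S

    itis = rng.uniform(lo, hi, N)
    cum = itis.reshape(n * S, T).cumsum(axis=1).reshape(N)
    onset = _round_ms(cum + cs * (trial - 1))
    offset = onset + cs
    t_max = cs - 1e-3   # keep rounded events strictly inside the window

    drive = np.clip(config.acq_slope * g * theta, -30.0, 30.0)
    out = {k: [] for k in ("subj", "sess", "trial", "event", "time")}

    def _emit(idx, event, times):
        out["subj"].append(subj[idx])
        out["sess"].append(sess[idx])
        out["trial"].append(trial[idx] if event != "iti_entry" else
                            np.zeros(len(idx), dtype=int))
        out["event"].append(np.full(len(idx), "foodcup_entry" if
                                    event == "iti_entry" else event))
        out["time"].append(times)

    all_idx = np.arange(N)
    _emit(all_idx, "cs_onset", onset)
    _emit(all_idx, "cs_offset", offset)
    _emit(all_idx, "pellet_delivery", offset)

    for sign, event in ((1.0, "lever_deflection"), (-1.0, "foodcup_entry")):
        p = expit(config.acq_intercept + sign * drive)
        contact = rng.random(N) < p
        scale = config.latency_scale_s * np.exp(
            np.clip(-config.latency_slope * sign * g * theta, -8.0, 8.0))
        lat = np.minimum(_round_ms(_truncated_exp(rng, scale, cs)), t_max)
        rate = config.count_rate * np.exp(
            np.clip(config.count_slope * sign * g * theta, -8.0, 3.5))
        extra = rng.poisson(rate)
        idx = all_idx[contact]
        _emit(idx, event, onset[idx] + lat[idx])
        rep = np.repeat(idx, extra[contact])
        if len(rep):
            u = rng.uniform(lat[rep], t_max)
            _emit(rep, event, onset[rep] + np.clip(_round_ms(u), 0.0, t_max))

    iti_rate = (itis / 60.0) * config.iti_entry_rate_per_min \
        * np.where(female, config.iti_entry_female_multiplier, 1.0)
    n_iti = rng.poisson(iti_rate)
    rep = np.repeat(all_idx, n_iti)
    if len(rep):
        u = rng.uniform(1e-3, np.maximum(itis[rep] - 1e-3, 2e-3))
        _emit(rep, "iti_entry", np.maximum(_round_ms(onset[rep] - u), 0.0))

    ids = traits["subject_id"].to_numpy()
    events = pd.DataFrame({
        "subject_id": ids[np.concatenate(out["subj"])],
        "session": np.concatenate(out["sess"]),
        "trial": np.concatenate(out["trial"]),
        "event": np.concatenate(out["event"]),
        "time_s": np.concatenate(out["time"]),
    })
    events["cohort"] = config.cohort
    events["sex"] = traits.set_index("subject_id")["sex"] \
        .reindex(events["subject_id"]).to_numpy()
    events["task"] = "pavca"
    events = events.sort_values(["subject_id", "session", "time_s", "trial"],
                                kind="mergesort").reset_index(drop=True)
    from .events_io import EVENT_COLUMNS
    return events[EVENT_COLUMNS]


def simulate_crf(traits: pd.DataFrame, terminal_index: pd.Series,
                 config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """CRF event streams coupled to the realized terminal PavCA index.

    Lever presses per earned reinforcer track the cohort-standardized
    terminal index with target variance explained ``crf_coupling``; active
    pokes are generated as a Poisson process over the session and earned
    presentations honor the 3-s lockout (earned <= active pokes).
    """
    dur = config.crf_duration_min * 60.0
    z = terminal_index.reindex(traits["subject_id"]).to_numpy(dtype=float)
    z = (z - np.nanmean(z)) / max(np.nanstd(z), 1e-12)
    c = config.crf_coupling
    latent = np.sqrt(c) * z + np.sqrt(1.0 - c) * rng.standard_normal(len(z))
    ppr = np.clip(config.crf_ppr_mean + config.crf_ppr_sd * latent, 0.05, None)

    n_act = rng.poisson(np.exp(np.clip(
        config.crf_active_log_rate + config.crf_active_slope * z, 0.0, 6.0)))
    n_inact = rng.poisson(np.exp(np.clip(
        config.crf_inactive_log_rate + config.crf_inactive_slope * z, 0.0, 6.0)))

    rows = {k: [] for k in ("sid", "event", "time")}
    for i, sid in enumerate(traits["subject_id"]):
        act = np.sort(rng.uniform(0.0, dur, n_act[i]))
        act = _round_ms(act)
        pres = _crf.replay_earned_presentations(act, config.crf_presentation_s)
        inact = _round_ms(rng.uniform(0.0, dur, n_inact[i]))
        n_defl = int(round(ppr[i] * len(pres))) if len(pres) else 0
        if n_defl:
            which = rng.integers(0, len(pres), n_defl)
            d_times = _round_ms(pres[which] + rng.uniform(
                0.0, config.crf_presentation_s - 1e-3, n_defl))
        else:
            d_times = np.empty(0)
        for ev, times in (("poke_active", act), ("poke_inactive", inact),
                          ("lever_presentation", pres),
                          ("lever_deflection", d_times)):
            rows["sid"].append(np.full(len(times), sid))
            rows["event"].append(np.full(len(times), ev))
            rows["time"].append(times)
    events = pd.DataFrame({
        "subject_id": np.concatenate(rows["sid"]),
        "event": np.concatenate(rows["event"]),
        "time_s": np.concatenate(rows["time"]),
    })
    events["cohort"] = config.cohort
    events["sex"] = traits.set_index("subject_id")["sex"] \
        .reindex(events["subject_id"]).to_numpy()
    events["task"] = "crf"
    events["session"] = 1
    events["trial"] = 0
    events = events.sort_values(["subject_id", "time_s"],
                                kind="mergesort").reset_index(drop=True)
    from .events_io import EVENT_COLUMNS
    return events[EVENT_COLUMNS]


def simulate_ccp(traits: pd.DataFrame, config: CohortConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Session-summary table for conditioned cue preference.

    Pre-test floor bias is centered on 50/50 with a magnitude that grows as
    theta_is falls (goal-trackers bias harder against what becomes the
    cocaine floor — the counter-conditioning artifact); the post-test keeps
    a fraction of that bias (regression to the mean) plus a conditioned gain
    scaled by theta_cr.  Cocaine-trial locomotion is baseline x sex
    multiplier x trial sensitization x exp(slope * theta_cr).
    """
    n = len(traits)
    theta_is = traits["theta_is"].to_numpy()
    theta_cr = traits["theta_cr"].to_numpy()
    female = traits["sex"].to_numpy() == "female"
    half = config.ccp_test_duration_s / 2.0

    base = np.exp(config.loco_log_baseline
                  + config.loco_log_baseline_sd * rng.standard_normal(n))
    sexmult = np.where(female, config.sex_locomotion_multiplier, 1.0)

    mag = np.abs(rng.standard_normal(n)) * (
        config.ccp_bias_base_s
        + config.ccp_bias_gt_s * expit(-config.ccp_bias_slope * theta_is))
    mag = np.clip(mag, 0.0, half - 100.0)
    coc_is_grid = rng.random(n) < 0.5      # which physical floor is less preferred
    pre_coc = half - mag
    post_coc = np.clip(
        half - config.ccp_bias_retention * mag
        + config.ccp_gain_s * (1.0 + config.ccp_gain_theta * theta_cr)
        + config.ccp_pref_noise_s * rng.standard_normal(n),
        0.0, config.ccp_test_duration_s)

    def _noise():
        return np.exp(config.loco_noise_sd * rng.standard_normal(n))

    rows = []
    ids = traits["subject_id"].to_numpy()
    coh = traits["cohort"].to_numpy()
    sex = traits["sex"].to_numpy()

    def _add(phase, trial, drug, floor, tg, th, dist):
        for i in range(n):
            rows.append({
                "subject_id": ids[i], "cohort": coh[i], "sex": sex[i],
                "phase": phase, "trial": trial, "drug": drug,
                "floor": floor[i] if isinstance(floor, np.ndarray) else floor,
                "time_on_grid_s": np.nan if tg is None else round(float(tg[i]), 1),
                "time_on_hole_s": np.nan if th is None else round(float(th[i]), 1),
                "distance_mm": round(float(dist[i]), 1),
            })

    _add("habituation", 0, "saline", "smooth", None, None, base * _noise())
    tg_pre = np.where(coc_is_grid, pre_coc, config.ccp_test_duration_s - pre_coc)
    th_pre = config.ccp_test_duration_s - tg_pre
    _add("pretest", 0, "saline", "both", tg_pre, th_pre, base * _noise())

    coc_floor = np.where(coc_is_grid, "grid", "hole")
    sal_floor = np.where(coc_is_grid, "hole", "grid")
    for t in range(1, config.ccp_trials + 1):
        coc_dist = (base * sexmult * config.ccp_cocaine_multiplier
                    * (1.0 + config.ccp_sensitization_per_trial * (t - 1))
                    * np.exp(config.ccp_theta_slope * theta_cr) * _noise())
        _add("conditioning", t, "cocaine", coc_floor, None, None, coc_dist)
        _add("conditioning", t, "saline", sal_floor, None, None, base * _noise())

    tg_post = np.where(coc_is_grid, post_coc, config.ccp_test_duration_s - post_coc)
    th_post = config.ccp_test_duration_s - tg_post
    post_dist = base * np.exp(config.ccp_posttest_conditioned
                              * (1.0 + 0.5 * theta_cr)) * _noise()
    _add("posttest", 0, "saline", "both", tg_post, th_post, post_dist)
    return pd.DataFrame(rows)


def simulate_ccc(traits: pd.DataFrame, config: CohortConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Session-summary table for 8-day cocaine contextual conditioning.

    Days 3-7 show acute activation (scaled by theta_cr and sex) that decays
    across days while headwave bouts grow (the locomotion-to-stereotypy
    trade-off, steeper in females); day 8 (saline) exceeds day 2 by a
    conditioned-locomotion term scaled by theta_cr.
    """
    n = len(traits)
    theta_cr = traits["theta_cr"].to_numpy()
    female = traits["sex"].to_numpy() == "female"
    base = np.exp(config.loco_log_baseline
                  + config.loco_log_baseline_sd * rng.standard_normal(n))
    sexmult = np.where(female, config.sex_locomotion_multiplier, 1.0)
    decay = np.where(female, config.ccc_decay_female, config.ccc_decay_male)
    hw_sex = np.where(female, config.ccc_headwave_female, 1.0)

    def _noise():
        return np.exp(config.loco_noise_sd * rng.standard_normal(n))

    dist_by_day, hw_by_day = {}, {}
    dist_by_day[1] = base * np.exp(config.ccc_novelty_boost) * _noise()
    dist_by_day[2] = base * _noise()
    hw_by_day[1] = rng.poisson(config.ccc_baseline_headwaves, n)
    hw_by_day[2] = rng.poisson(config.ccc_baseline_headwaves, n)
    for d in range(3, 8):
        amp = (base * sexmult * config.ccc_cocaine_multiplier
               * decay ** (d - 3)
               * np.exp(config.ccc_theta_slope * theta_cr))
        dist_by_day[d] = amp * _noise()
        hw_rate = (config.ccc_headwave_base * config.ccc_headwave_growth ** (d - 3)
                   * hw_sex * np.exp(config.ccc_headwave_theta * theta_cr))
        hw_by_day[d] = rng.poisson(hw_rate)
    dist_by_day[8] = base * np.exp(
        config.ccc_conditioned_loco
        + config.ccc_conditioned_theta * theta_cr) * _noise()
    hw_by_day[8] = rng.poisson(config.ccc_day8_headwaves * hw_sex)

    from .events_io import CCC_INJECTION_SCHEDULE
    frames = []
    for d in range(1, config.ccc_days + 1):
        frames.append(pd.DataFrame({
            "subject_id": traits["subject_id"],
            "cohort": traits["cohort"], "sex": traits["sex"],
            "day": d, "injection": CCC_INJECTION_SCHEDULE[d],
            "distance_mm": np.round(dist_by_day[d], 1),
            "headwave_bouts": hw_by_day[d],
        }))
    ccc = pd.concat(frames, ignore_index=True)

    if config.n_incomplete_ccc:
        k = min(config.n_incomplete_ccc, n)
        victims = rng.choice(traits["subject_id"].to_numpy(), size=k,
                             replace=False)
        drop_day = rng.integers(1, config.ccc_days + 1, size=k)
        mask = pd.Series(False, index=ccc.index)
        for sid, day in zip(victims, drop_day):
            mask |= (ccc["subject_id"] == sid) & (ccc["day"] == day)
        ccc = ccc[~mask].reset_index(drop=True)
    return ccc.sort_values(["subject_id", "day"], kind="mergesort") \
        .reset_index(drop=True)


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate a full cohort: traits, PavCA + CRF events, CCP + CCC tables.

    Deterministic under ``master_seed``: each component draws from an
    independent child stream of the master seed sequence.
    """
    ss = np.random.SeedSequence(config.master_seed)
    r_traits, r_pavca, r_crf, r_ccp, r_ccc = \
        (np.random.default_rng(c) for c in ss.spawn(5))
    traits = draw_traits(config, r_traits)
    pav = simulate_pavca(traits, config, r_pavca)
    scores = _pavca.score_pavca_events(pav, config.cs_duration_s)
    subj, _ = _pavca.subject_table(scores)
    terminal = subj.set_index("subject_id")["terminal_index"]
    crf_ev = simulate_crf(traits, terminal, config, r_crf)
    ccp = simulate_ccp(traits, config, r_ccp)
    ccc = simulate_ccc(traits, config, r_ccc)
    return SimulatedCohort(config=config, traits=traits, pavca_events=pav,
                           crf_events=crf_ev, ccp=ccp, ccc=ccc,
                           terminal_index=terminal)
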