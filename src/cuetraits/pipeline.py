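"""Simulate -> score -> stats -> report orchestration.

``run_score`` joins the task-level scorers into one row per subject;
``run_stats`` executes the analysis battery (mixed RM-ANOVAs per task with
Tukey probes of phenotype effects, per-sex correlation panels between the
PavCA index and every cocaine measure, raw-measure correlation checks, and
the varimax PCA of incentive + cocaine measures); ``run_report`` produces
phenotype x sex descriptive tables and a machine-readable results bundle.
Casewise exclusions are logged at every stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cocaine as _cocaine
from . import crf as _crf
from . import pavca as _pavca
from .events_io import SCHEMA_VERSION, write_manifest
from .stats import mixed_rm_anova, pca_varimax, pearson_with_r2, tukey_hsd

__version__ = "0.1.0"


@dataclass
class ScoreResult:
    sessions: pd.DataFrame          # per subject-session PavCA measures
    traits: pd.DataFrame            # one row per subject, all tasks joined
    exclusions: dict = field(default_factory=dict)

    @property
    def exclusion_counts(self) -> dict:
        return {k: len(v) for k, v in self.exclusions.items()}


def run_score(pavca_events=None, crf_events=None, ccp=None, ccc=None,
              cs_duration_s: float = 8.0, seed: int = 0) -> ScoreResult:
    """Score all supplied tasks and join them per subject.

    Subjects present in one task but not another are retained with missing
    fields; each analysis downstream excludes incomplete cases itself.
    ``seed`` only feeds the (rare) pre-test floor-time tie-break.
    """
    exclusions = {}
    sessions = pd.DataFrame()
    parts = []
    if pavca_events is not None and len(pavca_events):
        sessions = _pavca.score_pavca_events(pavca_events, cs_duration_s)
        subj, excl = _pavca.subject_table(sessions)
        exclusions["pavca_missing_terminal_session"] = excl
        term = sessions[sessions["session"].isin(_pavca.TERMINAL_SESSIONS)]
        raw45 = term.groupby("subject_id")[
            ["lever_deflections", "foodcup_entries_cs"]].mean()
        raw45.columns = ["lever_deflections_s45", "foodcup_entries_s45"]
        parts.append(subj.merge(raw45.reset_index(), on="subject_id", how="left"))
    if crf_events is not None and len(crf_events):
        crf_tab = _crf.score_crf_events(crf_events)
        exclusions["crf_zero_reinforcers"] = sorted(
            crf_tab.loc[crf_tab["earned_reinforcers"] == 0, "subject_id"])
        crf_tab = crf_tab.rename(columns={
            "lever_deflections": "crf_lever_deflections"})
        crf_tab["active_minus_inactive"] = (crf_tab["active_pokes"]
                                            - crf_tab["inactive_pokes"])
        parts.append(crf_tab)
    if ccp is not None and len(ccp):
        rng = np.random.default_rng(seed)
        ccp_tab, log = _cocaine.score_ccp(ccp, rng=rng)
        exclusions["ccp_incomplete"] = log["excluded"]
        if log["ties"]:
            exclusions["ccp_floor_ties"] = log["ties"]
        parts.append(ccp_tab)
    if ccc is not None and len(ccc):
        ccc_tab, excl = _cocaine.score_ccc(ccc)
        exclusions["ccc_incomplete"] = excl
        parts.append(ccc_tab)

    if not parts:
        return ScoreResult(sessions=sessions,
                           traits=pd.DataFrame(columns=["subject_id"]),
                           exclusions=exclusions)
    traits = parts[0]
    for p in parts[1:]:
        overlap = [c for c in p.columns
                   if c in traits.columns and c != "subject_id"]
        traits = traits.merge(p.drop(columns=overlap), on="subject_id",
                              how="outer")
    return ScoreResult(sessions=sessions, traits=traits, exclusions=exclusions)


# ---------------------------------------------------------------------------
# Stats battery


#: dependent variable -> (within reshape spec) for the per-task RM-ANOVAs
_PAVCA_MEASURES = ["lever_contact_prob", "lever_deflections", "lever_latency_s",
                   "foodcup_contact_prob", "foodcup_entries_cs",
                   "foodcup_latency_s"]

PCA_VARIABLES_CCP = ["terminal_index", "presses_per_reinforcer",
                     "cocaine_dist_t1_mm", "cocaine_dist_t4_mm",
                     "delta_preference_s"]
PCA_VARIABLES_CCC = ["terminal_index", "incentive_value_index",
                     "ccc_acute_locomotion_mm", "ccc_sensitization_headwaves",
                     "ccc_conditioned_locomotion_mm"]


def _try(bundle_skipped, name, fn):
    try:
        return fn()
    except (ValueError, KeyError) as exc:
        bundle_skipped[name] = str(exc)
        return None


def run_stats(score: ScoreResult, alpha: float = 0.05) -> dict:
    """Execute the analysis battery on scored data.

    Returns a bundle with keys ``anova`` (name -> AnovaResult), ``tukey``,
    ``correlations`` (tidy frame), ``pca`` (name -> PCAResult) and
    ``skipped`` (model -> reason) for analyses with insufficient data.
    """
    traits = score.traits
    sessions = score.sessions
    bundle = {"anova": {}, "tukey": {}, "correlations": None, "pca": {},
              "skipped": {}, "exclusion_counts": score.exclusion_counts}
    sk = bundle["skipped"]

    has_pheno = "phenotype" in traits.columns
    sess_aug = pd.DataFrame()
    if len(sessions) and has_pheno:
        sess_aug = sessions.merge(
            traits[["subject_id", "phenotype"]], on="subject_id", how="left")
        sess_aug = sess_aug[sess_aug["phenotype"].notna()]

    # --- PavCA: Session (within) x Sex, and six measures x Phenotype x Sex
    if len(sess_aug):
        idx_long = sess_aug.rename(columns={"pavca_index": "value"})
        bundle["anova"]["pavca_index"] = _try(sk, "pavca_index", lambda: mixed_rm_anova(
            idx_long, dv="value", subject="subject_id",
            between=["sex"], within=["session"]))
        for m in _PAVCA_MEASURES:
            bundle["anova"][f"pavca_{m}"] = _try(sk, f"pavca_{m}", lambda m=m: mixed_rm_anova(
                sess_aug, dv=m, subject="subject_id",
                between=["sex", "phenotype"], within=["session"]))

    # --- CRF: Port (within) x Sex x Phenotype; ppr between-only
    if has_pheno and {"active_pokes", "inactive_pokes"} <= set(traits.columns):
        crf_long = traits.melt(
            id_vars=["subject_id", "sex", "phenotype"],
            value_vars=["active_pokes", "inactive_pokes"],
            var_name="port", value_name="pokes")
        crf_long["port"] = crf_long["port"].str.replace("_pokes", "")
        bundle["anova"]["crf_pokes"] = _try(sk, "crf_pokes", lambda: mixed_rm_anova(
            crf_long, dv="pokes", subject="subject_id",
            between=["sex", "phenotype"], within=["port"]))
        for m in ("earned_reinforcers", "presses_per_reinforcer"):
            if m in traits.columns:
                bundle["anova"][f"crf_{m}"] = _try(sk, f"crf_{m}", lambda m=m: mixed_rm_anova(
                    traits[traits[m].notna()], dv=m, subject="subject_id",
                    between=["sex", "phenotype"]))

    # --- CCP: Drug x Trial (within) x Sex; preference Test (within) x Sex x Pheno
    coc_cols = [c for c in traits.columns if c.startswith("cocaine_dist_t")]
    if has_pheno and coc_cols:
        loco = traits.melt(
            id_vars=["subject_id", "sex", "phenotype"],
            value_vars=[c for c in traits.columns
                        if c.startswith(("cocaine_dist_t", "saline_dist_t"))],
            var_name="cell", value_name="distance_mm").dropna()
        loco["drug"] = loco["cell"].str.split("_").str[0]
        loco["trial"] = loco["cell"].str.extract(r"t(\d)").astype(int)
        bundle["anova"]["ccp_locomotion"] = _try(sk, "ccp_locomotion", lambda: mixed_rm_anova(
            loco, dv="distance_mm", subject="subject_id",
            between=["sex"], within=["drug", "trial"]))
        pref = traits.melt(
            id_vars=["subject_id", "sex", "phenotype"],
            value_vars=["pre_time_cocaine_floor_s", "post_time_cocaine_floor_s"],
            var_name="test", value_name="time_s").dropna()
        pref["test"] = pref["test"].str.split("_").str[0]
        bundle["anova"]["ccp_preference"] = _try(sk, "ccp_preference", lambda: mixed_rm_anova(
            pref, dv="time_s", subject="subject_id",
            between=["sex", "phenotype"], within=["test"]))

    # --- CCC: each contrast as a 2-level within factor x Sex x Phenotype
    if has_pheno and "ccc_acute_locomotion_mm" in traits.columns:
        day_cols = {2: "ccc_day2_distance_mm", 3: "ccc_day3_distance_mm",
                    7: "ccc_day7_distance_mm", 8: "ccc_day8_distance_mm"}
        if set(day_cols.values()) <= set(traits.columns):
            for name, (late, early) in _cocaine.CCC_CONTRAST_DAYS.items():
                long = traits.melt(
                    id_vars=["subject_id", "sex", "phenotype"],
                    value_vars=[day_cols[early], day_cols[late]],
                    var_name="day", value_name="distance_mm").dropna()
                bundle["anova"][f"ccc_{name}_locomotion"] = _try(
                    sk, f"ccc_{name}_locomotion", lambda long=long: mixed_rm_anova(
                        long, dv="distance_mm", subject="subject_id",
                        between=["sex", "phenotype"], within=["day"]))

    # --- Tukey probes of phenotype main effects
    for name, dv in (("crf_presses_per_reinforcer", "presses_per_reinforcer"),
                     ("ccp_delta_preference", "delta_preference_s")):
        if not has_pheno or dv not in traits.columns:
            continue
        sub = traits[traits[dv].notna() & traits["phenotype"].notna()]
        if sub["phenotype"].nunique() < 2 or (sub.groupby("phenotype")[dv]
                                              .size() < 2).any():
            sk[f"tukey_{name}"] = "fewer than 2 observations in a phenotype group"
            continue
        groups = sub.groupby("phenotype")[dv]
        means, ns = groups.mean(), groups.size()
        sse = float(((sub[dv] - sub.groupby("phenotype")[dv]
                      .transform("mean")) ** 2).sum())
        dfe = float(len(sub) - sub["phenotype"].nunique())
        bundle["tukey"][name] = tukey_hsd(
            means.to_numpy(), ns.to_numpy(), sse / dfe, dfe,
            labels=list(means.index), alpha=alpha)

    # --- Correlation panels (per sex, as in the primary analyses)
    rows = []

    def _corr(panel, xcol, ycol, frame):
        for sex, sub in frame.groupby("sex"):
            sub = sub[[xcol, ycol]].dropna()
            if len(sub) < 3:
                continue
            try:
                res = pearson_with_r2(sub[xcol], sub[ycol])
            except ValueError:
                continue
            rows.append({"panel": panel, "sex": sex, "x": xcol, "y": ycol,
                         "r": res.r, "r_squared": res.r_squared,
                         "n": res.n, "p": res.p})

    crf_targets = ["presses_per_reinforcer", "earned_reinforcers",
                   "active_minus_inactive", "incentive_value_index"]
    cocaine_targets = ["cocaine_dist_t1_mm", "cocaine_dist_t4_mm",
                       "delta_preference_s", "posttest_locomotion_mm",
                       "ccc_acute_locomotion_mm", "ccc_conditioned_locomotion_mm"]
    if "terminal_index" in traits.columns:
        for y in crf_targets:
            if y in traits.columns:
                _corr("index_vs_crf", "terminal_index", y, traits)
        for y in cocaine_targets:
            if y in traits.columns:
                _corr("index_vs_cocaine", "terminal_index", y, traits)
    for x in ("lever_deflections_s45", "foodcup_entries_s45"):
        if x in traits.columns:
            for y in ("delta_preference_s", "cocaine_dist_t4_mm"):
                if y in traits.columns:
                    _corr("raw_measures", x, y, traits)
    bundle["correlations"] = pd.DataFrame(rows)

    # --- PCA per cohort-style measure set
    for name, cols in (("incentive_ccp", PCA_VARIABLES_CCP),
                       ("incentive_ccc", PCA_VARIABLES_CCC)):
        avail = [c for c in cols if c in traits.columns]
        if len(avail) < 2:
            continue
        bundle["pca"][name] = _try(sk, f"pca_{name}", lambda a=avail: pca_varimax(
            traits, columns=a))
    return bundle


# ---------------------------------------------------------------------------
# Report


def descriptive_table(df: pd.DataFrame, value: str,
                      by=("phenotype", "sex")) -> pd.DataFrame:
    """Mean/SEM/median/IQR and notch half-width per group.

    Quartiles use linear interpolation; the notch half-width is the box-plot
    convention 1.58 * IQR / sqrt(n) behind a 95% CI on the median.  SEM is
    undefined (NaN) for n < 2 groups and flagged.
    """
    rows = []
    for key, grp in df.groupby(list(by), dropna=False, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        v = grp[value].dropna().to_numpy(dtype=float)
        n = len(v)
        if n == 0:
            continue
        q1, med, q3 = (np.percentile(v, [25, 50, 75])
                       if n else (np.nan,) * 3)
        iqr = q3 - q1
        rows.append({
            **dict(zip(by, key)), "measure": value, "n": n,
            "mean": float(v.mean()),
            "sem": float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "sem_undefined": n < 2,
            "median": float(med), "q1": float(q1), "q3": float(q3),
            "iqr": float(iqr),
            "notch_halfwidth": float(1.58 * iqr / np.sqrt(n)),
        })
    return pd.DataFrame(rows)


_REPORT_MEASURES = [
    "terminal_index", "presses_per_reinforcer", "incentive_value_index",
    "earned_reinforcers", "delta_preference_s", "cocaine_dist_t1_mm",
    "cocaine_dist_t4_mm", "ccp_sensitization_mm", "ccc_acute_locomotion_mm",
    "ccc_sensitization_locomotion_mm", "ccc_conditioned_locomotion_mm",
]


def run_report(score: ScoreResult, stats_bundle: dict | None = None) -> dict:
    """Descriptive tables plus JSON-able summaries of every computed analysis."""
    traits = score.traits
    descriptives = pd.concat(
        [descriptive_table(traits, m) for m in _REPORT_MEASURES
         if m in traits.columns],
        ignore_index=True) if len(traits) else pd.DataFrame()
    report = {"descriptives": descriptives,
              "exclusion_counts": score.exclusion_counts}
    if stats_bundle is not None:
        report["stats"] = stats_bundle
    return report


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if hasattr(obj, "__dataclass_fields__"):
        return {f: _jsonable(getattr(obj, f)) for f in obj.__dataclass_fields__}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results_bundle(outdir, score: ScoreResult, stats_bundle: dict,
                         report: dict, seed: int = 0,
                         config_snapshot: dict | None = None) -> Path:
    """Write CSV tables plus a stable-key-order ``results.json`` and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    def _csv(name, df):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, lineterminator="\n")
        files[name] = p

    _csv("traits", score.traits)
    if len(score.sessions):
        _csv("pavca_sessions", score.sessions)
    for name, res in stats_bundle.get("anova", {}).items():
        if res is not None:
            _csv(f"anova_{name}", res.table)
    if stats_bundle.get("correlations") is not None:
        _csv("correlations", stats_bundle["correlations"])
    for name, res in stats_bundle.get("pca", {}).items():
        if res is not None:
            _csv(f"pca_{name}_loadings", res.loadings.reset_index(names="variable"))
    if isinstance(report.get("descriptives"), pd.DataFrame):
        _csv("descriptives", report["descriptives"])

    results = {
        "version": __version__, "schema_version": SCHEMA_VERSION, "seed": seed,
        "exclusion_counts": _jsonable(score.exclusion_counts),
        "exclusions": _jsonable(score.exclusions),
        "correlations": _jsonable(stats_bundle.get("correlations")),
        "anova": {k: _jsonable(v.table) for k, v in
                  stats_bundle.get("anova", {}).items() if v is not None},
        "tukey": {k: _jsonable(v) for k, v in
                  stats_bundle.get("tukey", {}).items()},
        "pca": {k: {"loadings": _jsonable(
                        v.loadings.reset_index(names="variable")),
                    "eigenvalues": _jsonable(v.eigenvalues),
                    "n_retained": v.n_retained,
                    "proportion": _jsonable(v.proportion)}
                for k, v in stats_bundle.get("pca", {}).items()
                if v is not None},
        "skipped": _jsonable(stats_bundle.get("skipped", {})),
    }
    if config_snapshot:
        results["config"] = _jsonable(config_snapshot)
    rp = outdir / "results.json"
    with open(rp, "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, allow_nan=False,
                  default=str)
        fh.write("\n")
    files["results"] = rp
    write_manifest(outdir / "manifest.json", files, seed=seed,
                   version=__version__)
    return rp
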