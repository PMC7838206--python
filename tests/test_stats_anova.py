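"""Mixed RM-ANOVA against brute-force summation oracles and design checks."""

import numpy as np
import pandas as pd
import pytest

from cuetraits.stats import mixed_rm_anova


def _long_mixed(y):
    """y[g][s][w] -> long frame with group/subject/within columns."""
    a, n, w = np.asarray(y).shape
    rows = []
    for g in range(a):
        for s in range(n):
            for k in range(w):
                rows.append(dict(subject=f"g{g}s{s}", group=f"G{g}",
                                 time=f"t{k}", y=float(y[g][s][k])))
    return pd.DataFrame(rows)


@pytest.mark.parametrize("seed", range(20))
def test_mixed_design_matches_brute_force_oracle(seed, mixed_anova_oracle):
    rng = np.random.default_rng(seed)
    a = int(rng.integers(2, 4))
    n = int(rng.integers(3, 7))
    w = int(rng.integers(2, 4))
    y = rng.normal(rng.normal(0, 1, (a, 1, 1)), 1.0, (a, n, w))
    oracle = mixed_anova_oracle(y)
    res = mixed_rm_anova(_long_mixed(y), dv="y", subject="subject",
                         between=["group"], within=["time"])

    t_between = res.term("group")
    t_within = res.term("time")
    t_inter = res.term("time × group")
    err = res.errors.set_index("stratum")

    for got_ss, got_df, key in [
            (t_between["ss"], t_between["df_num"], "between"),
            (t_within["ss"], t_within["df_num"], "within"),
            (t_inter["ss"], t_inter["df_num"], "interaction"),
            (err.loc["Between", "ss"], err.loc["Between", "df"], "subjects"),
            (err.loc["time", "ss"], err.loc["time", "df"], "error")]:
        exp_ss, exp_df = oracle[key]
        assert got_ss == pytest.approx(exp_ss, abs=1e-8)
        assert got_df == exp_df
    # F statistics recomputed from oracle SS
    ms_subj = oracle["subjects"][0] / oracle["subjects"][1]
    ms_err = oracle["error"][0] / oracle["error"][1]
    assert t_between["F"] == pytest.approx(
        (oracle["between"][0] / oracle["between"][1]) / ms_subj, rel=1e-10)
    assert t_within["F"] == pytest.approx(
        (oracle["within"][0] / oracle["within"][1]) / ms_err, rel=1e-10)
    # full decomposition adds up on balanced designs
    parts = res.table["ss"].sum() + res.errors["ss"].sum()
    assert parts == pytest.approx(res.ss_total, abs=1e-8)


@pytest.mark.parametrize("seed", range(5))
def test_two_between_factors_match_oracle(seed, between_anova_oracle):
    rng = np.random.default_rng(100 + seed)
    a, b, n = 2, 3, 5
    y = rng.normal(0, 1, (a, b, n)) + rng.normal(0, 1, (a, b, 1))
    rows = []
    for i in range(a):
        for j in range(b):
            for r in range(n):
                rows.append(dict(subject=f"{i}{j}{r}", A=f"a{i}", B=f"b{j}",
                                 y=float(y[i, j, r])))
    res = mixed_rm_anova(pd.DataFrame(rows), dv="y", subject="subject",
                         between=["A", "B"])
    oracle = between_anova_oracle(y)
    for term, key in (("A", "A"), ("B", "B"), ("A × B", "AB")):
        assert res.term(term)["ss"] == pytest.approx(oracle[key][0], abs=1e-8)
        assert res.term(term)["df_num"] == oracle[key][1]
    err = res.errors.iloc[0]
    assert err["ss"] == pytest.approx(oracle["error"][0], abs=1e-8)
    assert err["df"] == oracle["error"][1]


def test_null_between_design_gives_zero_f():
    # identical residuals in every cell: cell means equal, F exactly 0
    resid = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
    rows = []
    for i, A in enumerate(["a1", "a2"]):
        for j, B in enumerate(["b1", "b2"]):
            for r, e in enumerate(resid):
                rows.append(dict(subject=f"{A}{B}{r}", A=A, B=B, y=3.0 + e))
    res = mixed_rm_anova(pd.DataFrame(rows), dv="y", subject="subject",
                         between=["A", "B"])
    for term in ("A", "B", "A × B"):
        assert res.term(term)["F"] == pytest.approx(0.0, abs=1e-12)
        assert res.term(term)["p"] == pytest.approx(1.0)


def test_between_only_df_arithmetic():
    rng = np.random.default_rng(0)
    rows = [dict(subject=f"s{i}", group=f"g{i % 3}", y=float(rng.normal()))
            for i in range(30)]
    res = mixed_rm_anova(pd.DataFrame(rows), dv="y", subject="subject",
                         between=["group"])
    t = res.term("group")
    assert (t["df_num"], t["df_den"]) == (2, 27)


def test_study_style_error_df():
    # 2 x 3 between cells, 5-level within: within error df = (S - 6) * 4
    rng = np.random.default_rng(1)
    rows = []
    for i in range(36):
        sex = "f" if i % 2 else "m"
        ph = ["GT", "IN", "ST"][i % 3]
        for sess in range(1, 6):
            rows.append(dict(subject=f"s{i}", sex=sex, pheno=ph,
                             session=sess, y=float(rng.normal())))
    res = mixed_rm_anova(pd.DataFrame(rows), dv="y", subject="subject",
                         between=["sex", "pheno"], within=["session"])
    assert res.term("session")["df_den"] == (36 - 6) * 4
    assert res.term("session × sex × pheno")["df_num"] == 4 * 1 * 2


def test_eta_squared_bounded_and_uses_total_ss():
    rng = np.random.default_rng(2)
    y = rng.normal(0, 1, (3, 6, 2)) + np.arange(3).reshape(3, 1, 1)
    res = mixed_rm_anova(_long_mixed(y), dv="y", subject="subject",
                         between=["group"], within=["time"])
    assert ((res.table["eta_squared"] >= 0)
            & (res.table["eta_squared"] <= 1)).all()
    assert res.table["eta_squared"].sum() <= 1.0 + 1e-12
    t = res.term("group")
    assert t["eta_squared"] == pytest.approx(t["ss"] / res.ss_total)


def test_f_invariant_under_level_relabeling():
    rng = np.random.default_rng(3)
    y = rng.normal(0, 1, (3, 5, 3))
    base = mixed_rm_anova(_long_mixed(y), dv="y", subject="subject",
                          between=["group"], within=["time"])
    relabeled = _long_mixed(y)
    relabeled["group"] = relabeled["group"].map(
        {"G0": "zebra", "G1": "ant", "G2": "mole"})
    perm = mixed_rm_anova(relabeled, dv="y", subject="subject",
                          between=["group"], within=["time"])
    for term in ("group", "time", "time × group"):
        assert perm.term(term)["F"] == pytest.approx(base.term(term)["F"],
                                                     rel=1e-10)


def test_subject_with_missing_within_cell_excluded_and_logged():
    rng = np.random.default_rng(4)
    df = _long_mixed(rng.normal(0, 1, (2, 5, 3)))
    df = df[~((df["subject"] == "g0s0") & (df["time"] == "t2"))]
    res = mixed_rm_anova(df, dv="y", subject="subject",
                         between=["group"], within=["time"])
    assert res.excluded_subjects == ["g0s0"]
    assert res.n_excluded == 1
    assert res.n_subjects == 9


def test_unbalanced_groups_handled_with_type_iii():
    rng = np.random.default_rng(5)
    rows = []
    sizes = {"GT": 4, "IN": 12, "ST": 6}
    for ph, n in sizes.items():
        for i in range(n):
            for t in ("t0", "t1"):
                rows.append(dict(subject=f"{ph}{i}", pheno=ph, time=t,
                                 y=float(rng.normal())))
    res = mixed_rm_anova(pd.DataFrame(rows), dv="y", subject="subject",
                         between=["pheno"], within=["time"])
    assert res.term("pheno")["df_den"] == sum(sizes.values()) - 3
    assert np.isfinite(res.term("time × pheno")["F"])


def test_two_within_factors_match_statsmodels_anovarm():
    # independent oracle for the fully-within two-factor decomposition
    from statsmodels.stats.anova import AnovaRM
    rng = np.random.default_rng(6)
    rows = []
    for s in range(10):
        for i, a in enumerate(("a1", "a2")):
            for j, b in enumerate(("b1", "b2", "b3")):
                rows.append(dict(subject=f"s{s}", A=a, B=b,
                                 y=float(rng.normal() + 0.5 * i - 0.2 * j)))
    df = pd.DataFrame(rows)
    ours = mixed_rm_anova(df, dv="y", subject="subject", within=["A", "B"])
    ref = AnovaRM(df, depvar="y", subject="subject",
                  within=["A", "B"]).fit().anova_table
    for ours_term, ref_term in (("A", "A"), ("B", "B"), ("A × B", "A:B")):
        assert ours.term(ours_term)["F"] == pytest.approx(
            ref.loc[ref_term, "F Value"], rel=1e-8)
        assert ours.term(ours_term)["df_num"] == ref.loc[ref_term, "Num DF"]
        assert ours.term(ours_term)["df_den"] == ref.loc[ref_term, "Den DF"]


def test_singular_design_raises():
    rows = [dict(subject=f"s{i}", A="a1" if i < 4 else "a2",
                 B="b1" if i < 4 else "b2", y=float(i)) for i in range(8)]
    with pytest.raises(ValueError, match="singular|empty"):
        mixed_rm_anova(pd.DataFrame(rows), dv="y", subject="subject",
                       between=["A", "B"])


def test_duplicate_observation_raises():
    df = pd.DataFrame([dict(subject="s1", time="t0", y=1.0),
                       dict(subject="s1", time="t0", y=2.0),
                       dict(subject="s2", time="t0", y=1.5)])
    with pytest.raises(ValueError, match="duplicate"):
        mixed_rm_anova(df, dv="y", subject="subject", within=["time"])
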