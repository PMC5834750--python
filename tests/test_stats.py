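from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from fcnet import stats as st

import oracles as orc


def _three_groups(rng, means=(0.0, 0.3, 0.8), sds=(1.0, 1.4, 0.7), ns=(12, 15, 10)):
    return {
        g: rng.normal(m, s, size=n)
        for g, m, s, n in zip(("NC", "SIVCIND", "SIVaD"), means, sds, ns)
    }


# ---------------------------------------------------------------------------
# normality


def test_ks_normality_calibration_lite():
    """Null samples should reject at roughly the nominal 5% rate."""
    rng = np.random.default_rng(0)
    rejections = sum(
        st.ks_normality(rng.standard_normal(20)).pvalue < 0.05 for _ in range(200)
    )
    assert 1 <= rejections <= 25  # binomial(200, 0.05) well within bounds


def test_ks_normality_detects_gross_nonnormality():
    rng = np.random.default_rng(1)
    x = rng.exponential(size=200) ** 2
    assert st.ks_normality(x).pvalue < 0.01


def test_ks_normality_contract():
    with pytest.raises(ValueError):
        st.ks_normality([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        st.ks_normality([2.0] * 10)


def test_ks_normality_deterministic():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(15)
    r1 = st.ks_normality(x)
    r2 = st.ks_normality(x)
    assert r1.statistic == r2.statistic and r1.pvalue == r2.pvalue


# ---------------------------------------------------------------------------
# Levene


def test_levene_identical_variances():
    rng = np.random.default_rng(3)
    g = _three_groups(rng, sds=(1.0, 1.0, 1.0), ns=(40, 40, 40))
    assert st.levene_test(g).pvalue > 0.01


def test_levene_detects_heteroscedasticity():
    rng = np.random.default_rng(4)
    g = _three_groups(rng, sds=(0.2, 1.0, 5.0), ns=(30, 30, 30))
    assert st.levene_test(g).pvalue < 1e-6


def test_levene_matches_oracles():
    rng = np.random.default_rng(5)
    g = _three_groups(rng)
    res = st.levene_test(g)
    w_bf = orc.bf_levene(g)
    assert res.statistic == pytest.approx(w_bf, abs=1e-10)
    w_sp, p_sp = sps.levene(*g.values(), center="mean")
    assert res.statistic == pytest.approx(w_sp, abs=1e-12)
    assert res.pvalue == pytest.approx(p_sp, abs=1e-12)


def test_levene_contract():
    with pytest.raises(ValueError):
        st.levene_test({"A": [1.0, 2.0]})
    with pytest.raises(ValueError):
        st.levene_test({"A": [1.0, 2.0], "B": [3.0]})


# ---------------------------------------------------------------------------
# Welch ANOVA


def test_welch_anova_matches_definition():
    rng = np.random.default_rng(6)
    for _ in range(20):
        g = _three_groups(rng, ns=(8, 11, 9))
        res = st.welch_anova(g)
        f_o, df1_o, df2_o = orc.bf_welch_anova(g)
        assert res.statistic == pytest.approx(f_o, abs=1e-10)
        assert res.df[0] == pytest.approx(df1_o, abs=1e-10)
        assert res.df[1] == pytest.approx(df2_o, abs=1e-10)
        assert res.pvalue == pytest.approx(sps.f.sf(f_o, df1_o, df2_o), abs=1e-12)


def test_welch_anova_matches_pingouin():
    rng = np.random.default_rng(7)
    g = _three_groups(rng)
    res = st.welch_anova(g)
    frame = pd.DataFrame(
        {
            "y": np.concatenate(list(g.values())),
            "g": np.repeat(list(g), [len(v) for v in g.values()]),
        }
    )
    pr = pg.welch_anova(data=frame, dv="y", between="g")
    assert res.statistic == pytest.approx(float(pr["F"].iloc[0]), rel=1e-9)
    assert res.df[1] == pytest.approx(float(pr["ddof2"].iloc[0]), rel=1e-9)
    assert res.pvalue == pytest.approx(float(pr["p_unc"].iloc[0]), abs=1e-9)


def test_welch_anova_two_groups_equals_welch_t_squared():
    rng = np.random.default_rng(8)
    a, b = rng.normal(0, 1, 14), rng.normal(0.5, 2, 9)
    res = st.welch_anova({"A": a, "B": b})
    t = sps.ttest_ind(a, b, equal_var=False)
    assert res.statistic == pytest.approx(t.statistic**2, abs=1e-10)
    assert res.df[1] == pytest.approx(t.df, abs=1e-10)
    assert res.pvalue == pytest.approx(t.pvalue, abs=1e-12)


def test_welch_anova_null_calibration():
    rng = np.random.default_rng(9)
    ps = [
        st.welch_anova(_three_groups(rng, means=(0, 0, 0), ns=(15, 15, 15))).pvalue
        for _ in range(200)
    ]
    assert 1 <= sum(p < 0.05 for p in ps) <= 25


def test_welch_anova_zero_variance_error():
    with pytest.raises(ValueError, match="zero variance"):
        st.welch_anova({"A": [1.0, 1.0, 1.0], "B": [2.0, 3.0, 4.0]})


# ---------------------------------------------------------------------------
# Games-Howell


def test_games_howell_matches_definition():
    rng = np.random.default_rng(10)
    g = _three_groups(rng)
    res = st.games_howell(g)
    assert len(res) == 3
    for r in res:
        a, b = r.extra["pair"]
        t_o, df_o, q_o = orc.bf_games_howell(g[a], g[b])
        assert r.statistic == pytest.approx(t_o, abs=1e-10)
        assert r.df == pytest.approx(df_o, abs=1e-10)
        p_o = sps.studentized_range.sf(q_o, 3, df_o)
        assert r.pvalue == pytest.approx(p_o, abs=1e-10)


def test_games_howell_matches_pingouin():
    rng = np.random.default_rng(11)
    g = _three_groups(rng)
    res = {r.extra["pair"]: r for r in st.games_howell(g)}
    frame = pd.DataFrame(
        {
            "y": np.concatenate(list(g.values())),
            "g": np.repeat(list(g), [len(v) for v in g.values()]),
        }
    )
    pr = pg.pairwise_gameshowell(data=frame, dv="y", between="g")
    for _, row in pr.iterrows():
        key = (row["A"], row["B"]) if (row["A"], row["B"]) in res else (row["B"], row["A"])
        r = res[key]
        assert abs(r.statistic) == pytest.approx(abs(float(row["T"])), rel=1e-9)
        assert r.df == pytest.approx(float(row["df"]), rel=1e-9)
        assert r.pvalue == pytest.approx(float(row["pval"]), abs=1e-6)


def test_games_howell_identical_groups_nonsignificant():
    rng = np.random.default_rng(12)
    base = rng.normal(size=15)
    g = {"A": base, "B": base + rng.normal(0, 1e-3, 15), "C": base + rng.normal(0, 1e-3, 15)}
    for r in st.games_howell(g):
        assert r.pvalue > 0.5


def test_games_howell_flags_separated_pair():
    rng = np.random.default_rng(13)
    g = _three_groups(rng, means=(0.0, 0.1, 3.0), sds=(1, 1, 1), ns=(20, 20, 20))
    res = {r.extra["pair"]: r for r in st.games_howell(g)}
    assert res[("NC", "SIVaD")].pvalue < 1e-4
    assert res[("SIVCIND", "SIVaD")].pvalue < 1e-4
    assert res[("NC", "SIVCIND")].pvalue > 0.05
    assert res[("NC", "SIVaD")].extra["mean_diff"] < 0


def test_games_howell_two_groups_q_is_t_root2():
    rng = np.random.default_rng(14)
    a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
    (r,) = st.games_howell({"A": a, "B": b})
    t_o, df_o, q_o = orc.bf_games_howell(a, b)
    assert q_o == pytest.approx(abs(t_o) * np.sqrt(2.0), abs=1e-12)
    assert r.pvalue == pytest.approx(sps.studentized_range.sf(q_o, 2, df_o), abs=1e-10)


# ---------------------------------------------------------------------------
# BH-FDR


def test_fdr_bh_worked_example():
    adj = st.fdr_bh([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)


def test_fdr_bh_single_and_empty():
    assert st.fdr_bh([0.2]) == pytest.approx([0.2])
    assert st.fdr_bh([]).size == 0


def test_fdr_bh_matches_definition():
    rng = np.random.default_rng(15)
    for _ in range(20):
        p = rng.random(9)
        adj = st.fdr_bh(p)
        assert np.allclose(adj, orc.bf_bh(p), atol=1e-12)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)


def test_fdr_bh_order_invariance():
    p = np.array([0.04, 0.001, 0.3, 0.02, 0.9])
    adj = st.fdr_bh(p)
    order = np.argsort(p)
    assert np.allclose(np.sort(adj), st.fdr_bh(p[order]), atol=1e-15)


def test_fdr_bh_contract():
    with pytest.raises(ValueError):
        st.fdr_bh([0.5, 1.2])
    with pytest.raises(ValueError):
        st.fdr_bh([0.5, np.nan])


# ---------------------------------------------------------------------------
# chi-squared and t


def test_chisq_worked_examples():
    res = st.chisq_test(np.array([[10, 10], [10, 10]]))
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.pvalue == pytest.approx(1.0)
    res = st.chisq_test(np.array([[10, 0], [0, 10]]))
    assert res.statistic == pytest.approx(20.0, abs=1e-10)
    assert res.df == 1


def test_chisq_matches_definition():
    table = np.array([[12, 7, 9], [5, 14, 10]])
    res = st.chisq_test(table)
    chi2_o, dof_o = orc.bf_chisq(table)
    assert res.statistic == pytest.approx(chi2_o, abs=1e-10)
    assert res.df == dof_o
    assert res.pvalue == pytest.approx(sps.chi2.sf(chi2_o, dof_o), abs=1e-12)


def test_chisq_contract():
    with pytest.raises(ValueError):
        st.chisq_test(np.array([[1.5, 2.0], [3.0, 4.0]]))
    with pytest.raises(ValueError):
        st.chisq_test(np.array([[0, 0], [3, 4]]))


def test_two_sample_t():
    rng = np.random.default_rng(16)
    a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
    res = st.two_sample_t(a, b)
    ref = sps.ttest_ind(a, b)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
    assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-12)
    degenerate = st.two_sample_t([2.0, 2.0], [2.0, 2.0])
    assert degenerate.statistic == 0.0 and degenerate.pvalue == 1.0
    with pytest.raises(ValueError):
        st.two_sample_t([1.0], [2.0, 3.0])


# ---------------------------------------------------------------------------
# Spearman


def _auc_meta(n_pat=12, rho_perfect=True, seed=17):
    rng = np.random.default_rng(seed)
    n = n_pat + 4
    groups = ["NC"] * 4 + ["SIVCIND"] * (n_pat // 2) + ["SIVaD"] * (n_pat - n_pat // 2)
    auc = pd.DataFrame(
        {f"AUC_{m}": rng.random(n) for m in ("Cp", "Lp", "Eg", "Eloc")}
    )
    meta = pd.DataFrame({"group": groups})
    meta["MMSE"] = rng.normal(20, 4, n)
    meta["MoCA"] = rng.normal(18, 4, n)
    if rho_perfect:
        # make MMSE a strictly increasing function of AUC_Eg for patients
        pat = meta["group"] != "NC"
        meta.loc[pat, "MMSE"] = np.exp(auc.loc[pat.to_numpy(), "AUC_Eg"].to_numpy())
    return auc, meta


def test_spearman_monotone_gives_rho_one():
    auc, meta = _auc_meta()
    res = st.spearman_scores(auc, meta)
    hit = [r for r in res if r.metric_name == "Eg" and r.score_name == "MMSE"]
    assert len(hit) == 1 and hit[0].rho == pytest.approx(1.0)
    assert hit[0].n == 12
    assert len(res) == 8  # 4 metrics x 2 scores, one BH family
    assert all(r.adjusted_p is not None for r in res)


def test_spearman_matches_definition_with_ties():
    auc, meta = _auc_meta(rho_perfect=False, seed=18)
    pat = (meta["group"] != "NC").to_numpy()
    meta.loc[pat, "MMSE"] = np.round(meta.loc[pat, "MMSE"])  # induce ties
    res = st.spearman_scores(auc, meta)
    for r in res:
        score = meta.loc[pat, r.score_name].to_numpy(dtype=float)
        x = auc.loc[pat, f"AUC_{r.metric_name}"].to_numpy()
        assert r.rho == pytest.approx(orc.bf_spearman(x, score), abs=1e-10)


def test_spearman_zscore_invariance():
    auc, meta = _auc_meta(rho_perfect=False, seed=19)
    res = st.spearman_scores(auc, meta)
    pat = (meta["group"] != "NC").to_numpy()
    for r in res:
        raw = sps.spearmanr(
            auc.loc[pat, f"AUC_{r.metric_name}"], meta.loc[pat, r.score_name]
        ).statistic
        assert r.rho == pytest.approx(raw, abs=1e-12)


def test_spearman_contract():
    auc, meta = _auc_meta()
    meta_small = meta.iloc[:6]  # only 2 patients
    with pytest.raises(ValueError):
        st.spearman_scores(auc.iloc[:6], meta_small)
    meta_const = meta.copy()
    meta_const["MMSE"] = 20.0
    with pytest.raises(ValueError, match="MMSE"):
        st.spearman_scores(auc, meta_const)


# ---------------------------------------------------------------------------
# compare_groups


def _cohort_tables(seed=20, sep=1.5):
    rng = np.random.default_rng(seed)
    groups = ["NC"] * 15 + ["SIVCIND"] * 15 + ["SIVaD"] * 15
    shift = np.repeat([2 * sep, sep, 0.0], 15)
    auc = pd.DataFrame(
        {
            f"AUC_{m}": shift + rng.normal(0, 1, 45)
            for m in ("Cp", "Lp", "Eg", "Eloc")
        }
    )
    nodal = {
        "Enodal_glob": pd.DataFrame(
            {f"R{i:03d}": shift + rng.normal(0, 1, 45) for i in range(1, 6)}
        )
    }
    return auc, groups, nodal


def test_compare_groups_gated():
    auc, groups, nodal = _cohort_tables()
    out = st.compare_groups(auc, groups, nodal=nodal)
    g = out["global"]
    assert set(g["metric"]) == {"Cp", "Lp", "Eg", "Eloc"}
    assert {
        "welch_F", "welch_p", "welch_p_adj", "levene_W", "levene_p",
        "ks_min_p", "mean_NC", "sd_NC", "mean_SIVaD",
    } <= set(g.columns)
    assert (g["welch_p_adj"] >= g["welch_p"] - 1e-15).all()
    # strong separation: every omnibus significant, so post hocs run
    assert (g["welch_p_adj"] < 0.05).all()
    ph = out["posthoc"]
    assert len(ph) == 12  # 4 metrics x 3 pairs
    nc_ad = ph[(ph["group_a"] == "NC") & (ph["group_b"] == "SIVaD")]
    assert (nc_ad["p"] < 0.01).all()
    nd = out["nodal"]
    assert len(nd) == 5
    assert (nd["welch_p_adj"] < 0.05).all()


def test_compare_groups_gating_blocks_null_metrics():
    auc, groups, _ = _cohort_tables(sep=0.0, seed=21)
    out = st.compare_groups(auc, groups)
    sig = set(out["global"].loc[out["global"]["welch_p_adj"] < 0.05, "metric"])
    ran = set(out["posthoc"]["metric"]) if len(out["posthoc"]) else set()
    assert ran == sig
    out_all = st.compare_groups(auc, groups, gh_mode="exploratory")
    assert len(out_all["posthoc"]) == 12
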