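"""Group-level statistics on AUC metrics and brain-behavior correlation.

The comparison workflow mirrors the field's standard practice for
three-group connectome studies: assess normality (Lilliefors-type
Kolmogorov-Smirnov with estimated parameters), test variance
homogeneity (Levene), run a variance-robust omnibus test (Welch
ANOVA) on every metric, follow significant omnibus tests with
Games-Howell pairwise comparisons, and control the false discovery
rate with Benjamini-Hochberg within each test family.  Cognitive
scores are related to network metrics with Spearman rank correlation
in the pooled patient sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class StatTestResult:
    test_name: str
    statistic: float
    df: float | tuple[float, float]
    pvalue: float
    group_summaries: dict = field(default_factory=dict)
    adjusted_p: float | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class CorrelationResult:
    metric_name: str
    score_name: str
    rho: float
    pvalue: float
    n: int
    adjusted_p: float | None = None


def _summaries(groups: Mapping[str, np.ndarray]) -> dict:
    return {
        g: {"n": len(v), "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))}
        for g, v in groups.items()
    }


# ---------------------------------------------------------------------------
# normality

_LILLIEFORS_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _lilliefors_stat(x: np.ndarray) -> float:
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = sps.norm.cdf(z)
    up = np.arange(1, n + 1) / n - cdf
    down = cdf - np.arange(0, n) / n
    return float(max(up.max(), down.max()))


def _lilliefors_null(n: int, n_mc: int, seed: int) -> np.ndarray:
    key = (n, n_mc, seed)
    if key not in _LILLIEFORS_CACHE:
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((n_mc, n))
        draws = (draws - draws.mean(axis=1, keepdims=True)) / draws.std(
            axis=1, ddof=1, keepdims=True
        )
        draws.sort(axis=1)
        cdf = sps.norm.cdf(draws)
        grid_hi = np.arange(1, n + 1) / n
        grid_lo = np.arange(0, n) / n
        d = np.maximum((grid_hi - cdf).max(axis=1), (cdf - grid_lo).max(axis=1))
        _LILLIEFORS_CACHE[key] = np.sort(d)
    return _LILLIEFORS_CACHE[key]


def ks_normality(
    values: Sequence[float], n_mc: int = 2000, seed: int = 1234
) -> StatTestResult:
    """Kolmogorov-Smirnov test of normality with estimated parameters.

    The null distribution of the statistic (mean and SD estimated from
    the sample, i.e. the Lilliefors correction) is obtained by seeded
    Monte-Carlo simulation, cached per sample size.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("normality test needs at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for constant input")
    d = _lilliefors_stat(x)
    null = _lilliefors_null(len(x), n_mc, seed)
    p = (1 + int((null >= d).sum())) / (n_mc + 1)
    return StatTestResult("ks_normality", d, float(len(x)), float(p))


# ---------------------------------------------------------------------------
# variance homogeneity and omnibus tests


def levene_test(groups: Mapping[str, Sequence[float]]) -> StatTestResult:
    """Levene's test (mean-centered) for homogeneity of variances."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    w, p = sps.levene(*arrays, center="mean")
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    return StatTestResult(
        "levene", float(w), (k - 1, n - k), float(p), _summaries(dict(groups))
    )


def welch_anova(groups: Mapping[str, Sequence[float]]) -> StatTestResult:
    """Welch's heteroscedastic one-way ANOVA.

    F* = [sum_j w_j (m_j - m_w)^2 / (k-1)] / [1 + 2(k-2)/(k^2-1) * A],
    with w_j = n_j / s_j^2, m_w the weighted grand mean, and
    A = sum_j (1 - w_j/W)^2 / (n_j - 1); the denominator degrees of
    freedom are (k^2 - 1) / (3 A).
    """
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    k = len(arrays)
    if k < 2 or any(len(a) < 2 for a in arrays.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n = np.array([len(a) for a in arrays.values()], dtype=float)
    m = np.array([a.mean() for a in arrays.values()])
    s2 = np.array([a.var(ddof=1) for a in arrays.values()])
    if np.any(s2 == 0):
        zero = [g for g, a in arrays.items() if a.var(ddof=1) == 0]
        raise ValueError(f"zero variance in group(s) {zero}; Welch ANOVA undefined")
    w = n / s2
    ww = w.sum()
    mw = (w * m).sum() / ww
    a = ((1 - w / ww) ** 2 / (n - 1)).sum()
    num = (w * (m - mw) ** 2).sum() / (k - 1)
    den = 1 + 2 * (k - 2) / (k**2 - 1) * a
    f = num / den
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * a)
    p = float(sps.f.sf(f, df1, df2))
    return StatTestResult("welch_anova", float(f), (float(df1), float(df2)), p, _summaries(arrays))


def games_howell(groups: Mapping[str, Sequence[float]]) -> list[StatTestResult]:
    """Games-Howell pairwise comparisons (unequal variances).

    Each pair uses the Welch standard error and degrees of freedom;
    the p-value comes from the studentized range distribution with k
    groups (q = |t| * sqrt(2))."""
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    k = len(arrays)
    if k < 2 or any(len(a) < 2 for a in arrays.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    names = list(arrays)
    out = []
    for ai in range(k):
        for bi in range(ai + 1, k):
            a, b = arrays[names[ai]], arrays[names[bi]]
            na, nb = len(a), len(b)
            va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
            se = np.sqrt(va + vb)
            diff = a.mean() - b.mean()
            t = diff / se
            df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
            q = abs(t) * np.sqrt(2.0)
            p = float(sps.studentized_range.sf(q, k, df))
            out.append(
                StatTestResult(
                    "games_howell",
                    float(t),
                    float(df),
                    min(max(p, 0.0), 1.0),
                    _summaries({names[ai]: a, names[bi]: b}),
                    extra={"pair": (names[ai], names[bi]), "mean_diff": float(diff)},
                )
            )
    return out


def fdr_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# demographics


def chisq_test(counts: np.ndarray) -> StatTestResult:
    """Pearson chi-squared test of independence on a contingency table."""
    table = np.asarray(counts, dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return StatTestResult("chi_squared", float(chi2), float(dof), float(p))


def two_sample_t(
    group_a: Sequence[float], group_b: Sequence[float], equal_var: bool = True
) -> StatTestResult:
    """Two-sided two-sample t-test (Student or Welch)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        df = len(a) + len(b) - 2
        return StatTestResult("two_sample_t", 0.0, float(df), 1.0)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return StatTestResult(
        "two_sample_t", float(res.statistic), float(res.df), float(res.pvalue),
        _summaries({"A": a, "B": b}),
    )


# ---------------------------------------------------------------------------
# brain-behavior correlation


def spearman_scores(
    auc_table: pd.DataFrame,
    meta: pd.DataFrame,
    metrics: Sequence[str] = ("Cp", "Lp", "Eg", "Eloc"),
    scores: Sequence[str] = ("MMSE", "MoCA"),
    patient_groups: Sequence[str] = ("SIVCIND", "SIVaD"),
) -> list[CorrelationResult]:
    """Spearman correlation between metric AUCs and cognitive scores.

    Computed in the pooled patient sample; scores are z-scored within
    that pool first (a monotone transform, so rho is unchanged — kept
    for scale comparability of reported values).  All metric x score
    tests are BH-adjusted as one family.
    """
    mask = meta["group"].isin(patient_groups).to_numpy()
    if mask.sum() < 5:
        raise ValueError("need at least 5 patients for correlation")
    results = []
    for score in scores:
        vals = meta.loc[mask, score].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            raise ValueError(f"score {score!r} is constant in the patient pool")
        zvals = (vals - vals.mean()) / vals.std(ddof=1)
        for metric in metrics:
            col = f"AUC_{metric}" if f"AUC_{metric}" in auc_table.columns else metric
            x = auc_table.loc[mask, col].to_numpy(dtype=float)
            rho, p = sps.spearmanr(x, zvals)
            results.append(CorrelationResult(metric, score, float(rho), float(p), int(mask.sum())))
    adj = fdr_bh([r.pvalue for r in results])
    for r, ap in zip(results, adj):
        r.adjusted_p = float(ap)
    return results


# ---------------------------------------------------------------------------
# assembled group comparison


def _split(values: np.ndarray, groups: np.ndarray) -> dict[str, np.ndarray]:
    names = list(dict.fromkeys(groups.tolist()))
    return {g: values[groups == g] for g in names}


def compare_groups(
    auc_table: pd.DataFrame,
    groups: Sequence[str],
    nodal: Mapping[str, pd.DataFrame] | None = None,
    metrics: Sequence[str] = ("Cp", "Lp", "Eg", "Eloc"),
    alpha: float = 0.05,
    gh_mode: str = "gated",
    seed: int = 1234,
) -> dict[str, pd.DataFrame]:
    """Full group comparison of global and nodal AUC metrics.

    Global metrics form one BH family (4 tests); each nodal metric's
    regions form their own family.  Games-Howell runs only where the
    omnibus Welch ANOVA is significant (``gh_mode='gated'``, default)
    or everywhere (``'exploratory'``).

    Returns tidy tables under keys ``'global'``, ``'posthoc'`` and
    ``'nodal'``.
    """
    glabels = np.asarray(groups)
    global_rows = []
    posthoc_rows = []
    welch_results = []
    for metric in metrics:
        col = f"AUC_{metric}" if f"AUC_{metric}" in auc_table.columns else metric
        vals = auc_table[col].to_numpy(dtype=float)
        by_group = _split(vals, glabels)
        ks_p = min(
            ks_normality(v, seed=seed).pvalue for v in by_group.values() if len(v) >= 4
        )
        lev = levene_test(by_group)
        wa = welch_anova(by_group)
        welch_results.append(wa)
        row = {
            "metric": metric,
            "ks_min_p": ks_p,
            "levene_W": lev.statistic,
            "levene_p": lev.pvalue,
            "welch_F": wa.statistic,
            "welch_df1": wa.df[0],
            "welch_df2": wa.df[1],
            "welch_p": wa.pvalue,
        }
        for g, s in wa.group_summaries.items():
            row[f"mean_{g}"] = s["mean"]
            row[f"sd_{g}"] = s["sd"]
        global_rows.append(row)
    adj = fdr_bh([w.pvalue for w in welch_results])
    for row, w, ap in zip(global_rows, welch_results, adj):
        row["welch_p_adj"] = float(ap)
        w.adjusted_p = float(ap)
    for metric, w in zip(metrics, welch_results):
        run_gh = gh_mode == "exploratory" or w.adjusted_p < alpha
        if not run_gh:
            continue
        col = f"AUC_{metric}" if f"AUC_{metric}" in auc_table.columns else metric
        by_group = _split(auc_table[col].to_numpy(dtype=float), glabels)
        for res in games_howell(by_group):
            a, b = res.extra["pair"]
            posthoc_rows.append(
                {
                    "metric": metric,
                    "group_a": a,
                    "group_b": b,
                    "mean_diff": res.extra["mean_diff"],
                    "t": res.statistic,
                    "df": res.df,
                    "p": res.pvalue,
                }
            )
    nodal_rows = []
    if nodal:
        for metric, table in nodal.items():
            pvals = []
            rows_here = []
            for region in table.columns:
                vals = table[region].to_numpy(dtype=float)
                by_group = _split(vals, glabels)
                try:
                    wa = welch_anova(by_group)
                except ValueError:
                    continue
                rows_here.append(
                    {
                        "metric": metric,
                        "region": region,
                        "welch_F": wa.statistic,
                        "welch_p": wa.pvalue,
                    }
                )
                pvals.append(wa.pvalue)
            adj_n = fdr_bh(pvals)
            for r, ap in zip(rows_here, adj_n):
                r["welch_p_adj"] = float(ap)
            nodal_rows.extend(rows_here)
    return {
        "global": pd.DataFrame(global_rows),
        "posthoc": pd.DataFrame(posthoc_rows),
        "nodal": pd.DataFrame(nodal_rows),
    }
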