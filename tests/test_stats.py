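import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psycop import simulate
from psycop.datatypes import BehaviorTable, ValidationError
from psycop.stats import (
    TERMS,
    etest_mvn,
    fit_factorial,
    interaction_followup,
    manova_table,
    manova_wilks,
    run_factorial_stats,
    significance_stars,
    univariate_followups,
    whiten,
    _expected_norm_standard_pair,
    _expected_norm_to_points,
)

from conftest import null_spec


def random_table(seed, sizes=(7, 9, 8, 10), p=3, effects=None):
    variables = [f"v{i + 1}" for i in range(p)]
    eff = pd.DataFrame(0.0, index=variables, columns=["G", "E", "GxE"])
    if effects:
        for (var, term), val in effects.items():
            eff.loc[var, term] = val
    spec = simulate.CohortSpec(group_sizes=sizes, effects=eff, missing_prob=0.0)
    table, _ = simulate.simulate_cohort(spec, seed=seed)
    return table


# ---------------------------------------------------------------------------
# model fit / Type-II cross-products
# ---------------------------------------------------------------------------

def explicit_type2_H(table):
    """Oracle: H per term as differences of residual cross-products of
    explicitly refitted nested models."""
    codes = table.design_codes().to_numpy()
    Y = table.data.to_numpy()
    n = len(Y)
    one = np.ones((n, 1))
    g, e, ge = codes[:, [0]], codes[:, [1]], codes[:, [2]]

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        r = Y - X @ beta
        return r.T @ r

    main = rss(np.hstack([one, g, e]))
    return {
        "G": rss(np.hstack([one, e])) - main,
        "E": rss(np.hstack([one, g])) - main,
        "GxE": main - rss(np.hstack([one, g, e, ge])),
    }


def test_type2_H_equals_explicit_nested_refits():
    table = random_table(0, sizes=(6, 9, 11, 8), p=4)
    model = fit_factorial(table)
    oracle = explicit_type2_H(table)
    for term in TERMS:
        assert np.abs(model.H[term] - oracle[term]).max() < 1e-8


def test_type2_invariant_to_factor_order():
    """Swapping the roles of the two factors maps SS(G)<->SS(E) exactly."""
    table = random_table(1, sizes=(5, 12, 9, 6), p=3)
    swapped = BehaviorTable(
        data=table.data.copy(),
        factors=pd.DataFrame(
            {
                "genotype": table.factors["environment"].map({"ns": "wt", "sd": "tg"}),
                "environment": table.factors["genotype"].map({"wt": "ns", "tg": "sd"}),
            },
            index=table.animals,
        ),
    )
    m1, m2 = fit_factorial(table), fit_factorial(swapped)
    assert np.abs(m1.H["G"] - m2.H["E"]).max() < 1e-8
    assert np.abs(m1.H["E"] - m2.H["G"]).max() < 1e-8
    assert np.abs(m1.H["GxE"] - m2.H["GxE"]).max() < 1e-8


def test_balanced_type2_equals_sequential():
    """In a balanced design the factors are orthogonal, so Type-II SS equal
    sequential (Type-I) SS."""
    table = random_table(2, sizes=(8, 8, 8, 8), p=1)
    model = fit_factorial(table)
    codes = table.design_codes().to_numpy()
    Y = table.data.to_numpy()
    n = len(Y)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        r = Y - X @ beta
        return float((r.T @ r)[0, 0])

    one = np.ones((n, 1))
    seq = []
    X = one
    for j in range(3):
        X2 = np.hstack([X, codes[:, [j]]])
        seq.append(rss(X) - rss(X2))
        X = X2
    for term, ss in zip(TERMS, seq):
        assert model.H[term][0, 0] == pytest.approx(ss, abs=1e-8)


def test_residual_df_is_n_minus_four(cohort):
    table, _ = cohort
    model = fit_factorial(table)
    assert model.df_error == model.n - 4
    assert model.n + model.n_excluded == 64


def test_empty_cell_is_hard_error():
    table = random_table(3, sizes=(5, 5, 5, 5), p=2)
    # delete one full cell's worth of one variable -> those animals incomplete
    mask = table.groups == "tg-sd"
    table.data.loc[mask, "v1"] = np.nan
    with pytest.raises(ValidationError, match="tg-sd"):
        fit_factorial(table)


# ---------------------------------------------------------------------------
# MANOVA
# ---------------------------------------------------------------------------

def test_one_response_manova_equals_univariate_anova():
    table = random_table(4, p=1, effects={("v1", "G"): 0.6, ("v1", "GxE"): 0.4})
    model = fit_factorial(table)
    man = manova_table(manova_wilks(model))
    uni = univariate_followups(model)
    for term in TERMS:
        assert man.loc[term, "F"] == pytest.approx(uni.loc[("v1", term), "F"], abs=1e-10)
        assert man.loc[term, "p"] == pytest.approx(uni.loc[("v1", term), "p"], abs=1e-10)


def test_manova_matches_statsmodels_on_balanced_design():
    import statsmodels.api  # noqa: F401  (ensure availability)
    from statsmodels.multivariate.manova import MANOVA

    table = random_table(5, sizes=(8, 8, 8, 8), p=3, effects={("v2", "E"): 1.0})
    model = fit_factorial(table)
    mine = manova_table(manova_wilks(model))
    df = table.to_frame().reset_index()
    res = MANOVA.from_formula(
        "v1 + v2 + v3 ~ C(genotype, Sum) * C(environment, Sum)", data=df
    ).mv_test()
    pairs = {
        "G": "C(genotype, Sum)",
        "E": "C(environment, Sum)",
        "GxE": "C(genotype, Sum):C(environment, Sum)",
    }
    for term, sm_term in pairs.items():
        stat = res.results[sm_term]["stat"].loc["Wilks' lambda"]
        assert mine.loc[term, "wilks_lambda"] == pytest.approx(stat["Value"], abs=1e-8)
        assert mine.loc[term, "F"] == pytest.approx(stat["F Value"], abs=1e-8)
        assert mine.loc[term, "df2"] == pytest.approx(stat["Den DF"], abs=1e-8)


def test_manova_singular_error_message():
    table = random_table(6, sizes=(3, 3, 3, 3), p=11)  # p >= df_error
    model = fit_factorial(table)
    with pytest.raises(ValidationError, match="singular|reduce"):
        manova_wilks(model)


def test_wilks_lambda_in_unit_interval(cohort):
    table, _ = cohort
    for t in manova_wilks(fit_factorial(table)):
        assert 0 < t.statistic <= 1


# ---------------------------------------------------------------------------
# FDR follow-ups
# ---------------------------------------------------------------------------

def bh_oracle(pvals):
    """Hand-computed Benjamini-Hochberg step-up."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank
        prev = min(prev, p[idx] * m / i)
        adj[idx] = prev
    return adj


def test_bh_adjustment_printed_vectors():
    assert bh_oracle([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_oracle([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)


def test_followup_adjustment_matches_bh_oracle(cohort):
    table, _ = cohort
    uni = univariate_followups(fit_factorial(table), fdr_scope="all")
    assert uni["p_adj"].to_numpy() == pytest.approx(bh_oracle(uni["p"]), abs=1e-12)
    assert (uni["p_adj"] >= uni["p"] - 1e-15).all()
    per = univariate_followups(fit_factorial(table), fdr_scope="per_term")
    for term in TERMS:
        sub = per.xs(term, level="term")
        assert sub["p_adj"].to_numpy() == pytest.approx(bh_oracle(sub["p"]), abs=1e-12)


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
@settings(deadline=None, max_examples=100)
def test_bh_oracle_is_monotone_and_bounded(pvals):
    from statsmodels.stats.multitest import multipletests

    adj = bh_oracle(pvals)
    assert np.all(adj >= np.asarray(pvals) - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    order = np.argsort(pvals)
    assert np.all(np.diff(adj[order]) >= -1e-12)
    assert adj == pytest.approx(multipletests(pvals, method="fdr_bh")[1], abs=1e-12)


def test_significance_star_convention():
    assert significance_stars(0.0043) == "**"
    assert significance_stars(0.034) == "*"
    assert significance_stars(4.47e-5) == "***"
    assert significance_stars(0.0674) == "n.s."


# ---------------------------------------------------------------------------
# interaction follow-up
# ---------------------------------------------------------------------------

def test_interaction_followup_identical_means_gives_zero_F():
    table = random_table(7, p=1)
    table.data["v1"] = np.tile([1.0, 2.0], len(table.animals) // 2 + 1)[: len(table.animals)]
    # force identical env-level means within each genotype
    for gt in ("wt", "tg"):
        for lv in ("ns", "sd"):
            m = (table.factors["genotype"] == gt) & (table.factors["environment"] == lv)
            vals = table.data.loc[m, "v1"].to_numpy()
            table.data.loc[m, "v1"] = vals - vals.mean()
    res = interaction_followup(table, "v1")
    assert res.loc["wtE", "F"] == pytest.approx(0.0, abs=1e-20)
    assert res.loc["tgE", "F"] == pytest.approx(0.0, abs=1e-20)


def test_interaction_followup_detects_tg_only_environment_effect():
    # environment shifts tg animals only: tgE small p, wtE large p
    variables = ["v1"]
    eff = pd.DataFrame(0.0, index=variables, columns=["G", "E", "GxE"])
    eff.loc["v1", "E"] = 1.5
    eff.loc["v1", "GxE"] = 1.5  # E effect 2*1.5 in tg, 0 in wt
    spec = simulate.CohortSpec(group_sizes=(16,) * 4, effects=eff, missing_prob=0.0)
    table, _ = simulate.simulate_cohort(spec, seed=8)
    res = interaction_followup(table, "v1")
    assert res.loc["tgE", "p"] < 0.001
    assert res.loc["wtE", "p"] > 0.05
    assert res.loc["tgE", "df2"] == 30


def test_run_factorial_stats_gates_followups_on_adjusted_interaction():
    eff = pd.DataFrame(0.0, index=[f"v{i}" for i in range(4)], columns=["G", "E", "GxE"])
    eff.iloc[0] = [0.0, 1.5, 2.5]
    spec = simulate.CohortSpec(group_sizes=(16,) * 4, effects=eff, missing_prob=0.0)
    table, _ = simulate.simulate_cohort(spec, seed=9)
    report = run_factorial_stats(table, run_etest=False)
    sig = report.univariate.xs("GxE", level="term")["significant"]
    assert set(report.interactions) == set(sig.index[sig])
    assert "v0" in report.interactions


# ---------------------------------------------------------------------------
# E-test of multivariate normality
# ---------------------------------------------------------------------------

def test_expected_norm_closed_forms():
    # E|0 - Z| in 1-D
    assert _expected_norm_to_points(np.zeros((1, 1)))[0] == pytest.approx(
        math.sqrt(2 / math.pi), abs=1e-12
    )
    # E|Z - Z'| in 1-D is 2/sqrt(pi)
    assert _expected_norm_standard_pair(1) == pytest.approx(2 / math.sqrt(math.pi), abs=1e-12)
    # 1-D closed form 2*phi(a) + a*(2*Phi(a) - 1) at a = 1.3
    from scipy.stats import norm

    a = 1.3
    expected = 2 * norm.pdf(a) + a * (2 * norm.cdf(a) - 1)
    assert _expected_norm_to_points(np.array([[a]]))[0] == pytest.approx(expected, abs=1e-10)


def test_expected_norm_matches_monte_carlo_in_5d():
    rng = np.random.default_rng(0)
    a = np.array([[0.5, -1.0, 0.3, 0.0, 2.0]])
    z = rng.standard_normal((400_000, 5))
    mc = np.linalg.norm(a - z, axis=1).mean()
    assert _expected_norm_to_points(a)[0] == pytest.approx(mc, abs=5e-3)
    mc_pair = np.linalg.norm(
        rng.standard_normal((400_000, 5)) - rng.standard_normal((400_000, 5)), axis=1
    ).mean()
    assert _expected_norm_standard_pair(5) == pytest.approx(mc_pair, abs=5e-3)


def test_whiten_gives_identity_sample_covariance():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((60, 4)) @ np.diag([1, 3, 0.5, 2]) + 5
    y = whiten(x)
    cov = np.cov(y.T)
    assert np.abs(cov - np.eye(4)).max() < 1e-10
    assert np.abs(y.mean(axis=0)).max() < 1e-12


def test_etest_accepts_normal_and_rejects_heavy_tails():
    rng = np.random.default_rng(2)
    normal = rng.standard_normal((60, 4))
    res = etest_mvn(normal, n_boot=199, seed=3)
    assert res.p > 0.05
    heavy = rng.standard_t(df=1.5, size=(60, 4))
    res2 = etest_mvn(heavy, n_boot=199, seed=4)
    assert res2.p < 0.05
    assert res2.statistic > res.statistic


def test_etest_input_validation():
    rng = np.random.default_rng(3)
    with pytest.raises(ValidationError):
        etest_mvn(rng.standard_normal((2, 3)))
    with pytest.raises(ValidationError):
        etest_mvn(rng.standard_normal((30, 3)), n_boot=50)


def test_null_effect_cohorts_rarely_reject(cohort):
    """Null synthetic cohorts: each MANOVA term non-significant in >= 90%
    of seeds at alpha = 0.05."""
    spec = null_spec(n_variables=5, n_per_group=12)
    nonsig = {t: 0 for t in TERMS}
    n_seeds = 20
    for seed in range(n_seeds):
        table, _ = simulate.simulate_cohort(spec, seed=seed)
        man = manova_table(manova_wilks(fit_factorial(table)))
        for t in TERMS:
            nonsig[t] += int(man.loc[t, "p"] >= 0.05)
    for t, count in nonsig.items():
        assert count >= int(0.9 * n_seeds), (t, count)
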