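import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from psycop import simulate
from psycop.datatypes import BehaviorTable, ValidationError
from psycop.dimred import (
    cda,
    nipals_impute,
    per_term_cda,
    standardize,
    term_coefficient_matrix,
)
from psycop.stats import fit_factorial


def frame(X, prefix="v"):
    return pd.DataFrame(
        X,
        index=[f"a{i}" for i in range(len(X))],
        columns=[f"{prefix}{j}" for j in range(X.shape[1])],
    )


# ---------------------------------------------------------------------------
# NIPALS
# ---------------------------------------------------------------------------

def test_nipals_on_complete_data_equals_svd():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((24, 6))
    nip = nipals_impute(frame(X), k=5, tol=1e-13, max_iter=20_000)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = np.sum(s**2)
    for j in range(5):
        p = nip.loadings.iloc[:, j].to_numpy()
        err = min(np.abs(Vt[j] - p).max(), np.abs(Vt[j] + p).max())
        assert err < 1e-8
        assert nip.explained_variance[j] == pytest.approx(s[j] ** 2 / total, abs=1e-8)
        t = nip.scores.iloc[:, j].to_numpy()
        assert np.abs(np.abs(t) - np.abs(Xc @ Vt[j])).max() < 1e-8


def test_nipals_loadings_unit_norm_and_orthogonal():
    rng = np.random.default_rng(1)
    nip = nipals_impute(frame(rng.standard_normal((30, 5))), k=4, tol=1e-12, max_iter=10_000)
    P = nip.loadings.to_numpy()
    assert np.abs(np.linalg.norm(P, axis=0) - 1).max() < 1e-9
    # deflation orthogonality of scores
    T = nip.scores.to_numpy()
    G = T.T @ T
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 1e-6 * np.abs(np.diag(G)).max()


def test_nipals_rank1_matrix_recovers_deleted_cell():
    rng = np.random.default_rng(2)
    M = np.outer(rng.standard_normal(15), rng.standard_normal(5))
    df = frame(M.copy())
    df.iat[3, 2] = np.nan
    nip = nipals_impute(df, k=1, tol=1e-13, max_iter=20_000)
    assert abs(nip.reconstituted.iat[3, 2] - M[3, 2]) < 1e-6


def test_nipals_observed_cells_never_overwritten():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((20, 6))
    df = frame(X)
    mask = rng.random(X.shape) < 0.1
    df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))
    nip = nipals_impute(df, k=3)
    obs = ~df.isna()
    assert np.array_equal(
        nip.reconstituted.to_numpy()[obs.to_numpy()], df.to_numpy()[obs.to_numpy()]
    )
    assert not nip.reconstituted.isna().any().any()


def test_nipals_constant_column_excluded():
    rng = np.random.default_rng(4)
    X = rng.standard_normal((15, 4))
    df = frame(X)
    df["v0"] = 3.0
    nip = nipals_impute(df, k=2)
    assert nip.dropped_columns == ["v0"]
    assert "v0" not in nip.loadings.index
    # reconstituted keeps the constant column as-is
    assert (nip.reconstituted["v0"] == 3.0).all()


def test_nipals_sparse_rows_or_columns_error():
    rng = np.random.default_rng(5)
    df = frame(rng.standard_normal((10, 4)))
    df.iloc[0, :3] = np.nan  # animal observed in fewer than 3 variables
    with pytest.raises(ValidationError, match="animals observed"):
        nipals_impute(df)
    df2 = frame(rng.standard_normal((10, 4)))
    df2.iloc[2:, 1] = np.nan  # variable observed in fewer than 3 animals
    with pytest.raises(ValidationError, match="variables observed"):
        nipals_impute(df2)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def test_standardize_moments_and_inverse():
    rng = np.random.default_rng(6)
    df = frame(rng.standard_normal((40, 4)) * [1, 5, 0.2, 9] + [0, 3, -2, 10])
    z = standardize(df)
    assert np.abs(z.mean()).max() < 1e-12
    assert np.abs(z.std(ddof=1) - 1).max() < 1e-12
    back = z * df.std(ddof=1) + df.mean()
    assert np.abs(back - df).max().max() < 1e-10


def test_standardize_duplicated_animals_get_identical_rows():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((10, 3))
    X[1] = X[0]
    z = standardize(frame(X))
    assert np.allclose(z.iloc[0], z.iloc[1])


def test_standardize_rejects_missing_and_drops_constant():
    df = frame(np.random.default_rng(8).standard_normal((10, 3)))
    withna = df.copy()
    withna.iat[0, 0] = np.nan
    with pytest.raises(ValidationError):
        standardize(withna)
    df["v1"] = 7.0
    z = standardize(df)
    assert "v1" not in z.columns


# ---------------------------------------------------------------------------
# CDA
# ---------------------------------------------------------------------------

def two_group_data(seed, n=30, p=4, shift=1.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X[n // 2:, 0] += shift
    X[n // 2:, 2] -= 0.5 * shift
    groups = pd.Series(
        ["a"] * (n // 2) + ["b"] * (n - n // 2), index=[f"a{i}" for i in range(n)]
    )
    return frame(X), groups


def test_cda_two_groups_equals_fisher_lda():
    z, groups = two_group_data(0)
    res = cda(z, groups)
    X = z.to_numpy()
    m1 = X[(groups == "a").to_numpy()].mean(axis=0)
    m2 = X[(groups == "b").to_numpy()].mean(axis=0)
    W = np.zeros((4, 4))
    for lab in ("a", "b"):
        Xg = X[(groups == lab).to_numpy()]
        W += (Xg - Xg.mean(0)).T @ (Xg - Xg.mean(0))
    lda = np.linalg.solve(W / (len(X) - 2), m2 - m1)
    c = res.coefficients.iloc[:, 0].to_numpy()
    cos = abs(lda @ c) / np.linalg.norm(lda) / np.linalg.norm(c)
    assert cos > 1 - 1e-10


def test_cda_matches_generalized_eigen_oracle():
    rng = np.random.default_rng(1)
    for p in (3, 6):
        n = 40
        X = rng.standard_normal((n, p))
        X[10:20] += 0.8
        X[20:30, -1] -= 1.2
        groups = pd.Series(
            np.repeat(["g1", "g2", "g3", "g4"], 10), index=[f"a{i}" for i in range(n)]
        )
        res = cda(frame(X), groups)
        W = np.zeros((p, p))
        B = np.zeros((p, p))
        gm = X.mean(axis=0)
        for lab in ("g1", "g2", "g3", "g4"):
            Xg = X[(groups == lab).to_numpy()]
            m = Xg.mean(axis=0)
            W += (Xg - m).T @ (Xg - m)
            B += len(Xg) * np.outer(m - gm, m - gm)
        vals, vecs = linalg.eigh(B, W)
        idx = np.argsort(vals)[::-1][:3]
        for j in range(3):
            c_o = vecs[:, idx[j]]
            c_m = res.coefficients.iloc[:, j].to_numpy()
            cos = abs(c_o @ c_m) / np.linalg.norm(c_o) / np.linalg.norm(c_m)
            assert cos > 1 - 1e-6
            assert res.percent[j] == pytest.approx(
                100 * vals[idx[j]] / vals[idx].sum(), abs=1e-6
            )


def test_cda_scores_have_identity_pooled_within_covariance(complete_cohort):
    table, _ = complete_cohort
    z = standardize(table.data)
    res = cda(z, table.groups)
    S = res.scores.to_numpy()
    k = S.shape[1]
    W = np.zeros((k, k))
    for lab in table.groups.unique():
        Sg = S[(table.groups == lab).to_numpy()]
        W += (Sg - Sg.mean(0)).T @ (Sg - Sg.mean(0))
    W /= len(S) - 4
    assert np.abs(W - np.eye(k)).max() < 1e-6
    assert res.percent.sum() == pytest.approx(100.0, abs=1e-9)


def test_cda_identical_group_means_gives_zero_singular_values():
    rng = np.random.default_rng(2)
    base = rng.standard_normal((10, 3))
    X = np.vstack([base + 0 for _ in range(4)])  # identical group clouds
    groups = pd.Series(np.repeat(list("abcd"), 10), index=[f"a{i}" for i in range(40)])
    res = cda(frame(X), groups)
    assert np.abs(res.singular_values).max() < 1e-10


def test_cda_effect_on_single_variable_dominates_can1():
    eff = pd.DataFrame(0.0, index=[f"v{i + 1}" for i in range(6)], columns=["G", "E", "GxE"])
    eff.loc["v1", "E"] = 3.0
    spec = simulate.CohortSpec(
        group_sizes=(16,) * 4, effects=eff, correlation=0.0, missing_prob=0.0
    )
    table, _ = simulate.simulate_cohort(spec, seed=3)
    res = cda(standardize(table.data), table.groups)
    c1 = res.coefficients["Can1"].abs()
    assert c1.idxmax() == "v1"


def test_cda_singular_within_covariance_errors():
    rng = np.random.default_rng(4)
    X = rng.standard_normal((12, 3))
    X = np.hstack([X, X[:, [0]]])  # duplicated variable
    groups = pd.Series(np.repeat(list("abcd"), 3), index=[f"a{i}" for i in range(12)])
    with pytest.raises(ValidationError, match="singular|ridge"):
        cda(frame(X), groups)


# ---------------------------------------------------------------------------
# per-term CDA
# ---------------------------------------------------------------------------

def test_per_term_scores_unit_within_variance(complete_cohort):
    table, _ = complete_cohort
    z = standardize(table.data)
    model = fit_factorial(BehaviorTable(z, table.factors))
    terms = per_term_cda(model)
    for term, r in terms.items():
        c = r.coefficients.to_numpy()
        within_var = float(c @ (model.R / model.df_error) @ c)
        assert within_var == pytest.approx(1.0, abs=1e-9)
        assert 0 <= r.canonical_correlation < 1
        # sign convention: largest-magnitude coefficient positive
        assert c[np.argmax(np.abs(c))] > 0


def test_per_term_single_response_reduces_to_scalar():
    eff = pd.DataFrame({"G": [1.0], "E": [0.0], "GxE": [0.0]}, index=["v1"])
    spec = simulate.CohortSpec(group_sizes=(10,) * 4, effects=eff, missing_prob=0.0)
    table, _ = simulate.simulate_cohort(spec, seed=5)
    z = standardize(table.data)
    model = fit_factorial(BehaviorTable(z, table.factors))
    terms = per_term_cda(model)
    for r in terms.values():
        # one variable: the normalized coefficient is 1/residual-sd
        resid_sd = np.sqrt(model.R[0, 0] / model.df_error)
        assert abs(r.coefficients.iloc[0]) == pytest.approx(1.0 / resid_sd, abs=1e-9)


def test_per_term_pure_E_effect_aligns_with_planted_direction():
    variables = [f"v{i + 1}" for i in range(5)]
    eff = pd.DataFrame(0.0, index=variables, columns=["G", "E", "GxE"])
    eff.loc["v2", "E"] = 3.0
    spec = simulate.CohortSpec(
        group_sizes=(16,) * 4, effects=eff, correlation=0.0, missing_prob=0.0
    )
    cosines = []
    for seed in range(5):
        table, _ = simulate.simulate_cohort(spec, seed=seed)
        z = standardize(table.data)
        model = fit_factorial(BehaviorTable(z, table.factors))
        c = per_term_cda(model)["E"].coefficients.to_numpy()
        e2 = np.zeros(5)
        e2[1] = 1.0
        cosines.append(abs(c @ e2) / np.linalg.norm(c))
    assert np.mean(cosines) > 0.95


def test_term_coefficient_matrix_shape(complete_cohort):
    table, _ = complete_cohort
    z = standardize(table.data)
    model = fit_factorial(BehaviorTable(z, table.factors))
    mat = term_coefficient_matrix(per_term_cda(model))
    assert list(mat.columns) == ["G", "E", "GxE"]
    assert list(mat.index) == list(z.columns)
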