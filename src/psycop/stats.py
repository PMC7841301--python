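"""Factorial statistics for 2x2 genotype-by-environment cohorts.

The pipeline fits one multivariate bifactorial linear model to the listwise
complete measure matrix under sum-to-zero (-1/+1) factor coding and derives
from its cross-product matrices:

* a MANOVA per term (G, E, GxE) with Wilks' lambda converted to an F value
  by Rao's approximation (exact for the 1-df hypotheses of a 2x2 design);
* per-variable Type-II two-way ANOVAs, Benjamini-Hochberg adjusted within
  one family (all variables x all terms by default);
* one-way follow-up ANOVAs of environment within each genotype level,
  for variables whose adjusted interaction p-value is significant;
* an energy-statistic goodness-of-fit test of multivariate normality on the
  whitened residuals, calibrated by parametric bootstrap;
* a split-plot repeated-measures ANOVA (two between factors x one within
  factor) with Mauchly's sphericity test and the Huynh-Feldt correction.

Hypothesis cross-products are Type-II: each main effect is adjusted for the
other main effect (not the interaction), and the interaction for both main
effects — the standard choice for unbalanced factorial designs that respects
marginality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .datatypes import BehaviorTable, ValidationError

TERMS = ("G", "E", "GxE")


def significance_stars(p: float) -> str:
    """Figure-legend convention: * <0.05, ** <0.01, *** <0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


# ---------------------------------------------------------------------------
# model fit
# ---------------------------------------------------------------------------

@dataclass
class FactorialModel:
    """Fitted 2x2 multivariate linear model with Type-II cross-products."""

    Y: pd.DataFrame                    # complete-case responses (n x p)
    X: np.ndarray                      # n x 4 design: 1, g, e, g*e
    factors: pd.DataFrame              # genotype/environment of complete cases
    H: dict[str, np.ndarray]           # per-term hypothesis cross-products
    R: np.ndarray                      # error cross-products (full model)
    residuals: np.ndarray              # n x p full-model residuals
    df_error: int
    n_excluded: int                    # animals dropped by listwise deletion

    @property
    def variables(self) -> list[str]:
        return list(self.Y.columns)

    @property
    def n(self) -> int:
        return len(self.Y)


def _rss_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual cross-product matrix of the least-squares fit of Y on X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid.T @ resid


def fit_factorial(table: BehaviorTable) -> FactorialModel:
    """Fit the bifactorial linear model to the untransformed complete cases.

    Listwise deletion is applied first (the imputed matrix is used only by
    dimension reduction, never here). Requires at least 2 complete animals
    per factor cell.
    """
    complete = table.complete_cases()
    sizes = complete.group_sizes()
    empty = sizes[sizes < 2]
    if len(empty):
        raise ValidationError(
            f"factor cell(s) with fewer than 2 complete cases: {dict(empty)}"
        )
    codes = complete.design_codes().to_numpy()
    n = len(complete.animals)
    ones = np.ones((n, 1))
    g, e, ge = codes[:, [0]], codes[:, [1]], codes[:, [2]]
    X_full = np.hstack([ones, g, e, ge])
    Y = complete.data.to_numpy(dtype=float)

    rss_full_main = _rss_matrix(np.hstack([ones, g, e]), Y)
    H = {
        "G": _rss_matrix(np.hstack([ones, e]), Y) - rss_full_main,
        "E": _rss_matrix(np.hstack([ones, g]), Y) - rss_full_main,
        "GxE": rss_full_main - _rss_matrix(X_full, Y),
    }
    beta, *_ = np.linalg.lstsq(X_full, Y, rcond=None)
    resid = Y - X_full @ beta
    return FactorialModel(
        Y=complete.data,
        X=X_full,
        factors=complete.factors,
        H=H,
        R=resid.T @ resid,
        residuals=resid,
        df_error=n - 4,
        n_excluded=len(table.animals) - n,
    )


# ---------------------------------------------------------------------------
# MANOVA (Wilks' lambda, Rao's F approximation)
# ---------------------------------------------------------------------------

@dataclass
class TermTest:
    term: str
    statistic: float          # Wilks' lambda (MANOVA) or F numerator context
    F: float
    df1: float
    df2: float
    p: float
    p_adjusted: float = math.nan
    variable: str | None = None

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted if np.isfinite(self.p_adjusted) else self.p)


def wilks_lambda(H: np.ndarray, R: np.ndarray) -> float:
    """Lambda = det(R) / det(R + H), via slogdet for stability."""
    s1, ld1 = np.linalg.slogdet(R)
    s2, ld2 = np.linalg.slogdet(R + H)
    if s1 <= 0 or s2 <= 0:
        raise ValidationError("error cross-product matrix is singular; reduce variables")
    return float(np.exp(ld1 - ld2))


def rao_f(lmbda: float, p: int, q: int, df_error: int) -> tuple[float, float, float, float]:
    """Rao's F approximation for Wilks' lambda.

    Exact whenever ``min(p, q) <= 2`` — in particular for every 1-df term of
    a 2x2 design. Returns (F, df1, df2, p-value).
    """
    if p * p + q * q - 5 > 0:
        t = math.sqrt((p * p * q * q - 4) / (p * p + q * q - 5))
    else:
        t = 1.0
    w = df_error + q - (p + q + 1) / 2
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2
    if df2 <= 0:
        raise ValidationError("not enough error degrees of freedom for the MANOVA")
    lam_t = lmbda ** (1.0 / t)
    F = (1 - lam_t) / lam_t * df2 / df1
    pval = float(stats.f.sf(F, df1, df2))
    return float(F), float(df1), float(df2), pval


def manova_wilks(model: FactorialModel) -> list[TermTest]:
    """Wilks' lambda MANOVA of G, E and GxE on the fitted model."""
    p = len(model.variables)
    if p >= model.df_error:
        raise ValidationError(
            f"{p} response variables with only {model.df_error} error df: "
            "error matrix singular; reduce variables"
        )
    out = []
    for term in TERMS:
        lmbda = wilks_lambda(model.H[term], model.R)
        F, df1, df2, pval = rao_f(lmbda, p, 1, model.df_error)
        out.append(TermTest(term=term, statistic=lmbda, F=F, df1=df1, df2=df2, p=pval))
    return out


def manova_table(tests: list[TermTest]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [t.term for t in tests],
            "wilks_lambda": [t.statistic for t in tests],
            "F": [t.F for t in tests],
            "df1": [t.df1 for t in tests],
            "df2": [t.df2 for t in tests],
            "p": [t.p for t in tests],
        }
    ).set_index("term")


# ---------------------------------------------------------------------------
# univariate follow-ups with FDR
# ---------------------------------------------------------------------------

def univariate_followups(
    model: FactorialModel,
    fdr_scope: str = "all",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable Type-II two-way ANOVAs derived from the same model.

    ``fdr_scope='all'`` applies Benjamini-Hochberg across all variables and
    all three terms jointly (one family per run); ``'per_term'`` adjusts
    within each term. Rows are flagged significant at ``alpha`` on the
    adjusted p-value.
    """
    if fdr_scope not in ("all", "per_term"):
        raise ValidationError("fdr_scope must be 'all' or 'per_term'")
    rows = []
    dfe = model.df_error
    for j, var in enumerate(model.variables):
        mse = model.R[j, j] / dfe
        for term in TERMS:
            ss = model.H[term][j, j]
            F = ss / mse if mse > 0 else math.inf
            rows.append(
                {
                    "variable": var,
                    "term": term,
                    "ss": ss,
                    "F": F,
                    "df1": 1,
                    "df2": dfe,
                    "p": float(stats.f.sf(F, 1, dfe)),
                }
            )
    out = pd.DataFrame(rows)
    if fdr_scope == "all":
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = np.nan
        for term in TERMS:
            m = out["term"] == term
            out.loc[m, "p_adj"] = multipletests(out.loc[m, "p"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    out["stars"] = [significance_stars(p) for p in out["p_adj"]]
    return out.set_index(["variable", "term"])


def interaction_followup(table: BehaviorTable, variable: str) -> pd.DataFrame:
    """One-way ANOVA of environment within each genotype level.

    Invoked for variables whose adjusted GxE p-value is significant: it
    tests for an environment effect free of any genotype influence.
    p-values are reported unadjusted, labeled ``wtE`` / ``tgE``.
    """
    if variable not in table.variables:
        raise ValidationError(f"unknown variable {variable!r}")
    rows = []
    for gt in ("wt", "tg"):
        sub = table.data.loc[table.factors["genotype"] == gt, variable].dropna()
        env = table.factors.loc[sub.index, "environment"]
        groups = [sub[env == lv].to_numpy() for lv in ("ns", "sd")]
        if any(len(grp) < 2 for grp in groups):
            raise ValidationError(
                f"genotype {gt!r}: an environment level has fewer than 2 animals"
            )
        F, p = stats.f_oneway(*groups)
        rows.append(
            {
                "label": f"{gt}E",
                "F": float(F),
                "df1": 1,
                "df2": int(len(sub) - 2),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("label")


# ---------------------------------------------------------------------------
# E-test of multivariate normality (energy statistic, parametric bootstrap)
# ---------------------------------------------------------------------------

def _expected_norm_standard_pair(d: int) -> float:
    """E||Z - Z'|| for independent standard d-variate normals."""
    return float(2.0 * math.exp(special.gammaln((d + 1) / 2) - special.gammaln(d / 2)))


def _expected_norm_to_points(y: np.ndarray) -> np.ndarray:
    """E||y_i - Z|| for each row y_i against a standard d-variate normal.

    Closed form via the confluent hypergeometric function:
    ``sqrt(2) * Gamma((d+1)/2) / Gamma(d/2) * 1F1(-1/2; d/2; -||y||^2 / 2)``.
    """
    y = np.atleast_2d(y)
    d = y.shape[1]
    c = math.sqrt(2.0) * math.exp(special.gammaln((d + 1) / 2) - special.gammaln(d / 2))
    sq = np.sum(y * y, axis=1)
    return c * special.hyp1f1(-0.5, d / 2.0, -sq / 2.0)


def energy_statistic(y: np.ndarray) -> float:
    """Székely-Rizzo energy statistic of y against the standard normal.

    ``E = n * (2 mean_i E||y_i - Z|| - E||Z - Z'|| - mean_ij ||y_i - y_j||)``.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n, d = y.shape
    term1 = float(np.mean(_expected_norm_to_points(y)))
    term2 = _expected_norm_standard_pair(d)
    if n > 1:
        term3 = float(2.0 * pdist(y).sum() / (n * n))
    else:
        term3 = 0.0
    return n * (2.0 * term1 - term2 - term3)


def whiten(x: np.ndarray) -> np.ndarray:
    """Center and whiten rows by the inverse Cholesky factor of the sample covariance."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (len(x) - 1)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValidationError("sample covariance is singular; cannot whiten") from None
    return linalg.solve_triangular(L, xc.T, lower=True).T


@dataclass(frozen=True)
class ETestResult:
    statistic: float
    p: float
    n_boot: int


def etest_mvn(
    residuals: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    standardize: bool = True,
) -> ETestResult:
    """E-test of multivariate normality, calibrated by parametric bootstrap.

    The observed rows are whitened to identity sample covariance; each
    bootstrap replicate draws standard-normal samples of the same shape and
    whitens them identically, so the reference distribution is the
    conditional null. ``p = (1 + #{boot >= observed}) / (n_boot + 1)``.
    """
    x = np.atleast_2d(np.asarray(residuals, dtype=float))
    n, d = x.shape
    if d == 0 or n < 3:
        raise ValidationError("E-test needs at least 3 observations and 1 variable")
    if n_boot < 99:
        raise ValidationError("use at least 99 bootstrap replicates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = whiten(x) if standardize else x
    observed = energy_statistic(y)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        z = rng.standard_normal((n, d))
        boots[b] = energy_statistic(whiten(z) if standardize else z)
    p = (1.0 + np.sum(boots >= observed)) / (n_boot + 1.0)
    return ETestResult(statistic=float(observed), p=float(p), n_boot=n_boot)


# ---------------------------------------------------------------------------
# repeated-measures (split-plot) ANOVA
# ---------------------------------------------------------------------------

@dataclass
class RMResult:
    """Split-plot ANOVA with sphericity diagnostics.

    ``table`` has one row per term (G, E, GxE, the within factor, and its
    interactions with the between terms) with F, df and raw p; within-involving
    rows additionally carry a Huynh-Feldt-corrected p, applied only when
    Mauchly's test is significant at 0.05.
    """

    table: pd.DataFrame
    mauchly_w: float
    mauchly_p: float
    epsilon_gg: float
    epsilon_hf: float
    correction_applied: bool
    within: str = "within"


def _type2_rss_scan(designs: dict[str, np.ndarray], y: np.ndarray) -> dict[str, float]:
    return {k: float(_rss_matrix(X, y[:, None])[0, 0]) for k, X in designs.items()}


def rm_anova(
    long: pd.DataFrame,
    dv: str,
    within: str,
    subject: str = "animal_id",
    alpha_sphericity: float = 0.05,
) -> RMResult:
    """Two-between x one-within split-plot ANOVA.

    ``long`` must contain ``subject``, ``genotype``, ``environment``,
    ``within`` and ``dv`` columns, with every subject measured at every
    within level. Between-subject terms are tested against the
    subjects-within-groups error; within-involving terms against the
    subject-by-within residual, with Huynh-Feldt df correction when
    Mauchly's test rejects sphericity.
    """
    wide = long.pivot_table(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValidationError(f"animals missing within levels: {bad}")
    fac = (
        long[[subject, "genotype", "environment"]]
        .drop_duplicates()
        .set_index(subject)
        .loc[wide.index]
    )
    g = fac["genotype"].map({"wt": -1.0, "tg": 1.0}).to_numpy()
    e = fac["environment"].map({"ns": -1.0, "sd": 1.0}).to_numpy()
    ge = g * e
    Y = wide.to_numpy(dtype=float)
    n, T = Y.shape
    k = T - 1
    if n <= 4:
        raise ValidationError("need more than 4 subjects")

    # ---- between-subject stratum: Type-II ANOVA on subject means, x T
    m = Y.mean(axis=1)
    ones = np.ones((n, 1))
    cols = {"g": g[:, None], "e": e[:, None], "ge": ge[:, None]}
    full_main = np.hstack([ones, cols["g"], cols["e"]])
    full = np.hstack([full_main, cols["ge"]])
    rss = _type2_rss_scan(
        {
            "full": full,
            "main": full_main,
            "no_g": np.hstack([ones, cols["e"]]),
            "no_e": np.hstack([ones, cols["g"]]),
        },
        m,
    )
    ss_between = {
        "G": T * (rss["no_g"] - rss["main"]),
        "E": T * (rss["no_e"] - rss["main"]),
        "GxE": T * (rss["main"] - rss["full"]),
    }
    ss_err_between = T * rss["full"]
    df_err_between = n - 4

    # ---- within-subject stratum on subject-centered data
    W = (Y - m[:, None]).ravel()  # row-major: subject-by-time
    D = np.kron(np.ones((n, 1)), np.eye(T)[:, :k] - np.eye(T)[:, [T - 1]][:, [0] * k])
    # D: deviation-coded time dummies replicated per subject
    Dg = D * np.repeat(g, T)[:, None]
    De = D * np.repeat(e, T)[:, None]
    Dge = D * np.repeat(ge, T)[:, None]
    full_w = np.hstack([D, Dg, De, Dge])
    rss_w = _type2_rss_scan(
        {
            "null": np.zeros((n * T, 0)),
            "t": D,
            "t_te": np.hstack([D, De]),
            "t_tg": np.hstack([D, Dg]),
            "t_tg_te": np.hstack([D, Dg, De]),
            "full": full_w,
        },
        W,
    )
    ss_within = {
        within: rss_w["null"] - rss_w["t"],
        f"Gx{within}": rss_w["t_te"] - rss_w["t_tg_te"],
        f"Ex{within}": rss_w["t_tg"] - rss_w["t_tg_te"],
        f"GxEx{within}": rss_w["t_tg_te"] - rss_w["full"],
    }
    ss_err_within = rss_w["full"]
    df_err_within = (n - 4) * k

    # ---- Mauchly + epsilons on cell-mean residual contrast covariance
    cell = {}
    for code in set(zip(g, e)):
        mask = (g == code[0]) & (e == code[1])
        cell[code] = Y[mask].mean(axis=0)
    E_resid = Y - np.array([cell[(gi, ei)] for gi, ei in zip(g, e)])
    C = _orthonormal_contrasts(T)
    V = E_resid @ C
    S = V.T @ V / df_err_between
    eig = np.linalg.eigvalsh(S)
    eig = np.clip(eig, 1e-300, None)
    w_stat = float(np.exp(np.sum(np.log(eig)) - k * math.log(np.mean(eig))))
    if k >= 2:
        d_corr = 1.0 - (2 * k * k + k + 2) / (6.0 * k * df_err_between)
        chi2 = -df_err_between * d_corr * math.log(max(w_stat, 1e-300))
        df_m = k * (k + 1) / 2 - 1
        mauchly_p = float(stats.chi2.sf(chi2, df_m))
    else:
        mauchly_p = 1.0  # two within levels: sphericity holds trivially
    tr = float(np.trace(S))
    eps_gg = tr * tr / (k * float(np.sum(S * S))) if k >= 2 else 1.0
    eps_hf = _huynh_feldt(eps_gg, n=n, n_groups=4, k=k) if k >= 2 else 1.0
    apply_corr = bool(mauchly_p < alpha_sphericity) and k >= 2
    eps_use = eps_hf if apply_corr else 1.0

    rows = []
    for term, ss in ss_between.items():
        F = (ss / 1) / (ss_err_between / df_err_between)
        rows.append(
            {"term": term, "ss": ss, "df1": 1.0, "df2": float(df_err_between),
             "F": F, "p": float(stats.f.sf(F, 1, df_err_between)),
             "p_corrected": float(stats.f.sf(F, 1, df_err_between))}
        )
    for term, ss in ss_within.items():
        F = (ss / k) / (ss_err_within / df_err_within)
        p_raw = float(stats.f.sf(F, k, df_err_within))
        p_corr = float(stats.f.sf(F, k * eps_use, df_err_within * eps_use))
        rows.append(
            {"term": term, "ss": ss, "df1": float(k), "df2": float(df_err_within),
             "F": F, "p": p_raw, "p_corrected": p_corr}
        )
    return RMResult(
        table=pd.DataFrame(rows).set_index("term"),
        mauchly_w=w_stat,
        mauchly_p=mauchly_p,
        epsilon_gg=float(eps_gg),
        epsilon_hf=float(min(eps_hf, 1.0)),
        correction_applied=apply_corr,
        within=within,
    )


def _orthonormal_contrasts(T: int) -> np.ndarray:
    """T x (T-1) orthonormal contrast matrix (columns orthogonal to the mean)."""
    H = np.linalg.qr(np.hstack([np.ones((T, 1)) / math.sqrt(T), np.eye(T)[:, : T - 1]]))[0]
    return H[:, 1:]


def _huynh_feldt(eps_gg: float, n: int, n_groups: int, k: int) -> float:
    """Huynh-Feldt epsilon for a grouped design, truncated to [1/k, 1]."""
    num = (n - n_groups + 1) * k * eps_gg - 2
    den = k * (n - n_groups - k * eps_gg)
    eps = num / den if den != 0 else 1.0
    return float(min(max(eps, 1.0 / k), 1.0))


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class FactorialStatsReport:
    """Everything the statistics stage produces for one cohort."""

    model: FactorialModel
    manova: pd.DataFrame
    univariate: pd.DataFrame
    interactions: dict[str, pd.DataFrame] = field(default_factory=dict)
    etest: ETestResult | None = None


def run_factorial_stats(
    table: BehaviorTable,
    fdr_scope: str = "all",
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    run_etest: bool = True,
) -> FactorialStatsReport:
    """Fit the model and run MANOVA, follow-ups and the normality E-test."""
    model = fit_factorial(table)
    manova = manova_table(manova_wilks(model))
    uni = univariate_followups(model, fdr_scope=fdr_scope, alpha=alpha)
    interactions = {}
    sig_gxe = uni.xs("GxE", level="term")
    for var in sig_gxe.index[sig_gxe["significant"]]:
        interactions[var] = interaction_followup(table, var)
    etest = None
    if run_etest:
        etest = etest_mvn(model.residuals, n_boot=n_boot, seed=seed)
    return FactorialStatsReport(
        model=model, manova=manova, univariate=uni,
        interactions=interactions, etest=etest,
    )
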