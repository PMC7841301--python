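"""NIPALS-based PCA with missing-value imputation and canonical discriminant
analysis (CDA).

The profiling pipeline never fills missing measurements in the statistics
stage; instead, dimension reduction and visualization consume a
*reconstituted* matrix: NIPALS components are extracted while skipping
missing cells, missing entries are filled from the low-rank reconstruction,
observed entries are kept untouched, and the result is z-standardized.

CDA finds the linear combinations of variables that maximally separate the
four factor groups relative to the pooled within-group covariance, in four
steps: (1) whiten by the pooled within-group covariance so it becomes the
identity; (2) compute group means of the transformed variables; (3) take a
singular value decomposition of the grand-mean-centered group means,
weighted by group sample size; (4) back-transform the singular vectors to
the original variable space as canonical coefficients. The per-term variant
applies the same idea to each hypothesis cross-product of the fitted 2x2
model, yielding one canonical direction per 1-df term.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .datatypes import BehaviorTable, ValidationError
from .stats import TERMS, FactorialModel

log = logging.getLogger("psycop")


# ---------------------------------------------------------------------------
# NIPALS
# ---------------------------------------------------------------------------

@dataclass
class NipalsResult:
    scores: pd.DataFrame            # animals x k
    loadings: pd.DataFrame          # variables x k (unit norm per component)
    explained_variance: np.ndarray  # fraction of total (centered) variance
    reconstituted: pd.DataFrame     # observed cells unchanged, missing filled
    column_means: pd.Series
    converged: np.ndarray           # per-component convergence flags
    dropped_columns: list[str] = field(default_factory=list)


def _fix_sign(p: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sign each loading so its largest-magnitude entry is positive."""
    j = int(np.argmax(np.abs(p)))
    if p[j] < 0:
        return -p, -t
    return p, t


def _nipals_core(
    X: np.ndarray,
    mask: np.ndarray,
    k_max: int,
    tol: float,
    max_iter: int,
    variance_cap: float | None,
):
    """Sequential NIPALS components of a centered matrix, skipping masked cells.

    Returns (scores, loadings, explained-variance fractions, convergence
    flags). ``variance_cap`` (when given) stops extraction once that
    fraction of the total observed sum of squares is explained.
    """
    R = np.where(mask, X, 0.0)
    total_ss = float(np.sum(R**2))
    T_list, P_list, ev, conv = [], [], [], []
    for _ in range(k_max):
        if float(np.sum(R * R)) <= 1e-20 * max(total_ss, 1.0):
            break  # residual numerically exhausted
        j0 = int(np.argmax(np.sum(R * R, axis=0)))
        t = R[:, j0].copy()
        if np.allclose(t, 0):
            break
        converged = False
        for _ in range(max_iter):
            denom_p = mask.T.astype(float) @ (t * t)
            pvec = (R.T @ t) / np.where(denom_p > 0, denom_p, 1.0)
            norm = np.linalg.norm(pvec)
            if norm == 0:
                break
            pvec /= norm
            denom_t = mask.astype(float) @ (pvec * pvec)
            t_new = (R @ pvec) / np.where(denom_t > 0, denom_t, 1.0)
            if np.linalg.norm(t_new - t) < tol * max(np.linalg.norm(t_new), 1.0):
                t = t_new
                converged = True
                break
            t = t_new
        pvec, t = _fix_sign(pvec, t)
        R = R - np.where(mask, np.outer(t, pvec), 0.0)
        T_list.append(t)
        P_list.append(pvec)
        conv.append(converged)
        ev.append(float(t @ t) / total_ss if total_ss > 0 else 0.0)
        if variance_cap is not None and sum(ev) >= variance_cap:
            break
    n, p = X.shape
    T = np.column_stack(T_list) if T_list else np.zeros((n, 0))
    P = np.column_stack(P_list) if P_list else np.zeros((p, 0))
    return T, P, np.asarray(ev), np.asarray(conv, dtype=bool)


def nipals_impute(
    table: BehaviorTable | pd.DataFrame,
    k: int | None = 2,
    tol: float = 1e-9,
    max_iter: int = 1000,
    variance_cap: float = 0.999,
    max_refine: int = 200,
) -> NipalsResult:
    """NIPALS PCA tolerating missing cells, with low-rank imputation.

    Components are extracted one at a time by alternating score/loading
    regressions over observed cells only, deflating after convergence.
    The default rank for imputation is ``k = 2``: behavioral batteries have
    low intrinsic dimension (at most 3 between-group dimensions in a 2x2
    design), and higher ranks interpolate measurement noise into the filled
    cells. When ``k`` is None, components are extracted up to ``min(n, p)``
    but stop once ``variance_cap`` of the total variance is explained.

    Missing cells are then filled from the rank-k reconstruction and the
    decomposition is re-run on the completed matrix until the fills
    stabilize (an expectation-maximization refinement; for exactly low-rank
    data this converges to the exact completion). Observed cells are
    returned unchanged in the reconstituted matrix.
    """
    df = table.data if isinstance(table, BehaviorTable) else table
    X_raw = df.to_numpy(dtype=float)
    obs = ~np.isnan(X_raw)
    if (obs.sum(axis=0) < 3).any():
        bad = [c for c, m in zip(df.columns, obs.sum(axis=0)) if m < 3]
        raise ValidationError(f"variables observed in fewer than 3 animals: {bad}")
    if (obs.sum(axis=1) < 3).any():
        bad = [a for a, m in zip(df.index, obs.sum(axis=1)) if m < 3]
        raise ValidationError(f"animals observed in fewer than 3 variables: {bad}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_var = np.nanvar(X_raw, axis=0, ddof=1)
    dropped = [c for c, v in zip(df.columns, col_var) if not v > 0]
    if dropped:
        log.warning("NIPALS: excluding zero-variance columns: %s", dropped)
    keep = [c for c in df.columns if c not in dropped]
    kept_idx = [df.columns.get_loc(c) for c in keep]
    mask = obs[:, kept_idx]
    n, p = mask.shape
    k_max = min(n, p) if k is None else min(k, n, p)

    # first pass: skip missing cells
    col_means = np.nanmean(X_raw[:, kept_idx], axis=0)
    T, P, ev, conv = _nipals_core(
        X_raw[:, kept_idx] - col_means, mask, k_max,
        tol, max_iter, variance_cap if k is None else None,
    )
    k_eff = T.shape[1]

    # EM refinement: refill missing cells from the reconstruction, re-extract
    if not mask.all() and k_eff:
        full = np.ones_like(mask)
        filled = np.where(mask, X_raw[:, kept_idx], T @ P.T + col_means)
        for _ in range(max_refine):
            col_means = filled.mean(axis=0)
            T, P, ev, conv = _nipals_core(
                filled - col_means, full, k_eff, tol, max_iter, None
            )
            new_fill = T @ P.T + col_means
            delta = float(np.abs((new_fill - filled))[~mask].max(initial=0.0))
            filled = np.where(mask, filled, new_fill)
            scale = max(float(np.abs(filled).max()), 1.0)
            if delta < 1e-8 * scale:
                break

    if not conv.all():
        log.warning(
            "NIPALS: %d component(s) hit the iteration cap; using last iterates",
            int((~conv).sum()),
        )
    recon_kept = T @ P.T + col_means
    all_means = np.nanmean(X_raw, axis=0)
    recon = np.tile(all_means, (len(df), 1)).astype(float)
    recon[:, kept_idx] = recon_kept
    filled_out = np.where(obs, X_raw, recon)

    comp_names = [f"PC{i + 1}" for i in range(k_eff)]
    return NipalsResult(
        scores=pd.DataFrame(T, index=df.index, columns=comp_names),
        loadings=pd.DataFrame(P, index=keep, columns=comp_names),
        explained_variance=ev,
        reconstituted=pd.DataFrame(filled_out, index=df.index, columns=df.columns),
        column_means=pd.Series(np.nanmean(X_raw, axis=0), index=df.columns),
        converged=conv,
        dropped_columns=dropped,
    )


# ---------------------------------------------------------------------------
# z-standardization
# ---------------------------------------------------------------------------

def standardize(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-transform (mean 0, sample sd 1 over the full cohort).

    Zero-variance columns are dropped with a warning. The input must have
    no missing cells (run imputation first).
    """
    if df.isna().any().any():
        raise ValidationError("standardize expects a complete matrix; impute first")
    sd = df.std(ddof=1)
    zero = sd[~(sd > 0)].index.tolist()
    if zero:
        log.warning("standardize: dropping zero-variance columns: %s", zero)
        df = df.drop(columns=zero)
        sd = sd.drop(zero)
    return (df - df.mean()) / sd


# ---------------------------------------------------------------------------
# CDA
# ---------------------------------------------------------------------------

@dataclass
class CDAResult:
    coefficients: pd.DataFrame      # variables x components (z-score units)
    scores: pd.DataFrame            # animals x components
    singular_values: np.ndarray
    percent: np.ndarray             # percent of total canonical correlation
    group_means: pd.DataFrame       # groups x components


def _inv_sqrt_psd(S: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    if vals.min() < rcond * vals.max():
        raise ValidationError(
            "pooled within-group covariance is singular; reduce the number of "
            "variables or enable a ridge"
        )
    return vecs @ np.diag(vals**-0.5) @ vecs.T


def cda(z: pd.DataFrame, groups: pd.Series, ridge: float = 0.0) -> CDAResult:
    """Canonical discriminant analysis of a standardized matrix.

    Steps: whiten by the pooled within-group covariance (denominator
    ``n - n_groups``), compute group means of the whitened variables, take
    the SVD of the sample-size-weighted, grand-mean-centered means, and
    back-transform the right singular vectors to canonical coefficients.
    Canonical scores then have identity pooled within-group covariance, and
    each component's share of the total canonical correlation is its squared
    singular value over the total.
    """
    groups = groups.loc[z.index]
    labels = [g for g in pd.unique(groups)]
    if len(labels) < 2:
        raise ValidationError("CDA needs at least 2 groups")
    X = z.to_numpy(dtype=float)
    n, p = X.shape

    # pooled within-group covariance
    Wc = np.zeros((p, p))
    means, sizes = {}, {}
    for gname in labels:
        Xg = X[(groups == gname).to_numpy()]
        mg = Xg.mean(axis=0)
        means[gname] = mg
        sizes[gname] = len(Xg)
        Xc = Xg - mg
        Wc += Xc.T @ Xc
    W = Wc / (n - len(labels))
    if ridge > 0:
        W = W + ridge * np.eye(p)
    Wisqrt = _inv_sqrt_psd(W)

    ws = np.array([sizes[g] for g in labels], dtype=float)
    M = np.array([means[g] for g in labels]) @ Wisqrt       # whitened group means
    grand = ws @ M / ws.sum()
    D = np.sqrt(ws)[:, None] * (M - grand)
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    k = min(len(labels) - 1, p)
    s = s[:k]
    V = Vt[:k].T

    raw = Wisqrt @ V                                        # coefficients, z units
    for j in range(k):
        i = int(np.argmax(np.abs(raw[:, j])))
        if raw[i, j] < 0:
            raw[:, j] = -raw[:, j]

    center = ws @ np.array([means[g] for g in labels]) / ws.sum()
    scores = (X - center) @ raw
    comp = [f"Can{i + 1}" for i in range(k)]
    gm = pd.DataFrame(
        [(means[g] - center) @ raw for g in labels], index=labels, columns=comp
    )
    total = float(np.sum(s**2))
    percent = 100.0 * s**2 / total if total > 0 else np.zeros(k)
    return CDAResult(
        coefficients=pd.DataFrame(raw, index=z.columns, columns=comp),
        scores=pd.DataFrame(scores, index=z.index, columns=comp),
        singular_values=s,
        percent=percent,
        group_means=gm,
    )


# ---------------------------------------------------------------------------
# per-term CDA
# ---------------------------------------------------------------------------

@dataclass
class TermCDA:
    term: str
    coefficients: pd.Series        # one canonical direction (1-df term)
    scores: pd.Series
    canonical_correlation: float   # squared canonical correlation in [0, 1)


def per_term_cda(model: FactorialModel) -> dict[str, TermCDA]:
    """One canonical direction per model term (G, E, GxE).

    For a 1-df term the generalized eigenproblem ``H c = lambda R c`` has a
    single non-trivial solution; the coefficient vector is scaled to unit
    pooled within-group variance of the scores and signed so its
    largest-magnitude entry is positive. ``lambda / (1 + lambda)`` is the
    squared canonical correlation of the term.
    """
    out = {}
    X = model.Y.to_numpy(dtype=float)
    for term in TERMS:
        H, R = model.H[term], model.R
        vals, vecs = linalg.eigh(H, R)
        c = vecs[:, -1]
        lam = float(vals[-1])
        scale = float(np.sqrt(c @ (R / model.df_error) @ c))
        c = c / scale if scale > 0 else c
        i = int(np.argmax(np.abs(c)))
        if c[i] < 0:
            c = -c
        scores = (X - X.mean(axis=0)) @ c
        out[term] = TermCDA(
            term=term,
            coefficients=pd.Series(c, index=model.variables),
            scores=pd.Series(scores, index=model.Y.index),
            canonical_correlation=lam / (1.0 + lam),
        )
    return out


def term_coefficient_matrix(terms: dict[str, TermCDA]) -> pd.DataFrame:
    """Variables x terms matrix of canonical coefficients (heatmap input)."""
    return pd.DataFrame({t: terms[t].coefficients for t in TERMS if t in terms})
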