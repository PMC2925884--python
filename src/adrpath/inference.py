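"""Two-phase logistic-regression engine for pathway–ADR association mining.

Phase I screens, for each binary ADR column y, the drug×pathway feature
matrix X with an L1-penalized logistic regression at a penalty expressed
relative to λ_max — the smallest penalty at which every coefficient is
exactly zero.  Pathways receiving nonzero weight are candidates.  Phase II
refits each ADR's candidate set without penalty, prunes it by a
both-direction stepwise search under AIC, and assigns Wald p-values to the
surviving coefficients.  All surviving p-values are pooled across ADRs and
subjected to Benjamini–Hochberg control at the configured FDR.

The penalized objective is

    (1/n) Σ_i log(1 + exp(−(2y_i − 1)(β₀ + x_iᵀβ))) + λ Σ_j |β_j|

with an unpenalized intercept; features are standardized (mean 0, unit
population sd) per fit so λ is comparable across pathways.  Optimality of a
returned fit is certified by the KKT subgradient residual, computed here
independently of the solver.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

logger = logging.getLogger(__name__)

_SEPARATION_COEF = 1e3   # |coefficient| beyond this on standardized features ⇒ separation


# ---------------------------------------------------------------------------
# Standardization and λ_max

def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale columns to mean 0, population sd 1.

    Returns (Z, mask) where mask flags columns with nonzero variance;
    zero-variance columns are left centered (all-zero) and excluded from
    penalized fitting by the caller.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    mask = sd > 0
    Z = X - mu
    Z[:, mask] /= sd[mask]
    return Z, mask


def compute_lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty yielding an all-zero coefficient vector.

    At the intercept-only optimum the per-feature score gradient is
    (1/n)·X_jᵀ(ȳ − y); the all-zero solution is KKT-stationary iff λ bounds
    every |gradient|, so λ_max = (1/n)·max_j |X_jᵀ(y − ȳ)|.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("y must contain both classes")
    n = len(y)
    return float(np.abs(X.T @ (y - y.mean())).max() / n)


# ---------------------------------------------------------------------------
# L1 fit

@dataclass
class L1Fit:
    intercept: float
    weights: np.ndarray
    lam: float
    converged: bool
    kkt_residual: float
    n_iter: int = 0

    def nonzero(self) -> np.ndarray:
        return np.flatnonzero(self.weights)


def _kkt_residual(X: np.ndarray, y: np.ndarray, b0: float, beta: np.ndarray, lam: float) -> float:
    """Max violation of the subgradient stationarity conditions."""
    n = len(y)
    resid = expit(b0 + X @ beta) - y
    g = X.T @ resid / n
    per_coef = np.where(
        beta == 0.0,
        np.maximum(np.abs(g) - lam, 0.0),
        np.abs(g + lam * np.sign(beta)),
    )
    g0 = abs(resid.mean())
    return float(max(per_coef.max(initial=0.0), g0))


def _polish_intercept(X: np.ndarray, y: np.ndarray, b0: float, beta: np.ndarray) -> float:
    """Newton steps on the intercept alone (the solver's stopping rule can
    leave it slack when all slopes are zero)."""
    eta = X @ beta
    for _ in range(50):
        p = expit(b0 + eta)
        g = (p - y).mean()
        h = (p * (1 - p)).mean()
        if h <= 0 or abs(g) < 1e-14:
            break
        b0 -= g / h
    return b0


def fit_l1_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> L1Fit:
    """Solve the L1-penalized logistic regression at penalty ``lam``.

    ``X`` is expected standardized; the intercept is unpenalized.  The fit
    is labelled converged when the independently computed KKT residual is
    within ``tol``; non-convergence returns the best fit found rather than
    raising.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    n = len(y)
    if lam == 0.0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-12, max_iter=max_iter)
    else:
        clf = LogisticRegression(
            C=1.0 / (n * lam), l1_ratio=1.0, solver="saga",
            tol=1e-12, max_iter=max_iter, random_state=0,
        )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="The max_iter was reached")
        warnings.filterwarnings("ignore", message=".*lbfgs failed to converge.*")
        clf.fit(X, y)
    beta = clf.coef_[0].copy()
    beta[np.abs(beta) < 1e-10] = 0.0   # snap solver round-off at the path boundary
    b0 = _polish_intercept(X, y, float(clf.intercept_[0]), beta)
    kkt = _kkt_residual(X, y, b0, beta, lam)
    n_iter = int(np.ravel(clf.n_iter_)[0])
    fit = L1Fit(
        intercept=b0, weights=beta, lam=lam,
        converged=bool(kkt <= tol), kkt_residual=kkt, n_iter=n_iter,
    )
    if not fit.converged:
        logger.warning("fit_l1_logistic: KKT residual %.2e > tol %.0e at lam=%.3g", kkt, tol, lam)
    return fit


# ---------------------------------------------------------------------------
# Phase I

def phase1_select(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    rel_lambda: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> pd.DataFrame:
    """L1 screen of every ADR column at penalty rel_lambda·λ_max.

    Returns tidy rows (adr_group, pathway_id, phase1_weight) for every
    nonzero coefficient; ADR columns that are single-class (or for which
    every feature is orthogonal to the label) are skipped with a log note.
    Coefficients are on the standardized feature scale.
    """
    if not 0 < rel_lambda <= 1:
        raise ValueError("rel_lambda must be in (0, 1]")
    Z, mask = standardize(X.to_numpy(dtype=float))
    Zm = Z[:, mask]
    cols = X.columns[mask]
    rows = []
    for adr in Y.columns:
        y = Y[adr].to_numpy(dtype=float)
        if y.min() == y.max():
            logger.info("phase1_select: ADR %s has a single class; skipped", adr)
            continue
        lam_max = compute_lambda_max(Zm, y)
        if lam_max == 0.0:
            logger.info("phase1_select: ADR %s orthogonal to all features; skipped", adr)
            continue
        fit = fit_l1_logistic(Zm, y, rel_lambda * lam_max, tol=tol, max_iter=max_iter)
        for j in fit.nonzero():
            rows.append((adr, cols[j], float(fit.weights[j])))
    return pd.DataFrame(rows, columns=["adr_group", "pathway_id", "phase1_weight"])


# ---------------------------------------------------------------------------
# Phase II: stepwise AIC

@dataclass
class StepwiseFit:
    selected: list[str]
    coefficients: dict[str, float]
    aic: float
    wald_p: dict[str, float]
    separated: set[str] = field(default_factory=set)


def _logit_fit(Z: np.ndarray, y: np.ndarray, cols: Sequence[int]):
    """Fit an unpenalized logistic model on the given columns.

    Returns (result, aic, separated).  Any failure to produce a finite,
    converged maximum-likelihood fit — including perfect separation — is
    reported as separated with infinite AIC so the stepwise search never
    walks into it.
    """
    design = sm.add_constant(Z[:, list(cols)], has_constant="add")
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.filterwarnings("ignore", message="Maximum Likelihood optimization failed")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False) or np.abs(res.params).max() > _SEPARATION_COEF:
            separated = True
    except Exception:  # includes PerfectSeparationWarning raised as an error
        return None, np.inf, True
    if separated or not np.all(np.isfinite(res.params)):
        return res, np.inf, True
    return res, float(res.aic), False


def stepwise_aic(X_cand: pd.DataFrame, y: np.ndarray | pd.Series) -> StepwiseFit:
    """Both-direction stepwise search under AIC over the candidate columns.

    Starts from the full candidate model and, at each step, evaluates every
    single-feature removal and re-addition, taking the move that most
    decreases AIC; stops when no move strictly improves.  Candidate columns
    are standardized before fitting; reported coefficients and Wald
    p-values are on that scale.  Features whose fit exhibits perfect
    separation are flagged, given p = 1, and excluded from significance
    downstream.
    """
    y = np.asarray(y, dtype=float)
    names = list(X_cand.columns)
    if names:
        Z, mask = standardize(X_cand.to_numpy(dtype=float))
        names = [n for n, m in zip(names, mask) if m]
        Z = Z[:, mask]
    else:
        Z = np.empty((len(y), 0))
    idx = {n: i for i, n in enumerate(names)}

    current = list(names)
    res, aic, sep = _logit_fit(Z, y, [idx[n] for n in current])
    # a separated/unfittable full model falls back to backward pruning from
    # the best fittable subset: drop features until the fit stabilizes
    while sep and current:
        best = (np.inf, None, None)
        for n in current:
            trial = [m for m in current if m != n]
            r2, a2, s2 = _logit_fit(Z, y, [idx[m] for m in trial])
            score = a2 if not s2 else np.inf
            if score < best[0]:
                best = (score, trial, r2)
        if best[1] is None:
            # nothing fittable: drop arbitrarily-chosen last feature
            current = current[:-1]
            res, aic, sep = _logit_fit(Z, y, [idx[n] for n in current])
        else:
            aic, current, res = best
            sep = False

    improved = True
    while improved:
        improved = False
        best_move: tuple[float, list[str]] | None = None
        for n in current:
            trial = [m for m in current if m != n]
            _, a2, s2 = _logit_fit(Z, y, [idx[m] for m in trial])
            if not s2 and a2 < aic and (best_move is None or a2 < best_move[0]):
                best_move = (a2, trial)
        for n in names:
            if n in current:
                continue
            trial = current + [n]
            _, a2, s2 = _logit_fit(Z, y, [idx[m] for m in trial])
            if not s2 and a2 < aic and (best_move is None or a2 < best_move[0]):
                best_move = (a2, trial)
        if best_move is not None:
            aic, current = best_move
            improved = True
    res, aic, sep = _logit_fit(Z, y, [idx[n] for n in current])

    coefficients: dict[str, float] = {}
    wald_p: dict[str, float] = {}
    separated: set[str] = set()
    if res is not None and not sep:
        params = res.params[1:]           # drop intercept
        pvals = res.pvalues[1:]
        for n, b, p in zip(current, params, pvals):
            coefficients[n] = float(b)
            wald_p[n] = float(p)
    else:
        for n in current:
            separated.add(n)
            coefficients[n] = float("nan")
            wald_p[n] = 1.0
        aic = float("inf")
    return StepwiseFit(selected=current, coefficients=coefficients, aic=aic,
                       wald_p=wald_p, separated=separated)


# ---------------------------------------------------------------------------
# Multiple testing

def bh_adjust(p_values: Sequence[float], fdr: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (q-values, reject flags) at level ``fdr``."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return q, reject


# ---------------------------------------------------------------------------
# End-to-end inference

def candidate_universe(pathways: Sequence[str], adr_groups: Sequence[str]) -> Iterator[tuple[str, str]]:
    """Every (ADR group, pathway) pair the model could in principle report."""
    return itertools.product(adr_groups, pathways)


def infer_associations(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    rel_lambda: float = 0.1,
    fdr: float = 0.02,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> pd.DataFrame:
    """Run the full two-phase screen and return every phase-I candidate.

    Rows: adr_group, pathway_id, phase1_weight, phase2_coefficient,
    p_value, q_value, significant.  Phase-II fields are NA for candidates
    the stepwise search dropped.  Wald p-values of stepwise survivors are
    pooled across all ADRs for a single BH correction at ``fdr``;
    separation-flagged coefficients carry p = 1 and are never significant.
    The procedure is deterministic.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    if not X.index.equals(Y.index):
        raise ValueError("X and Y must share the same drug ordering")
    cands = phase1_select(X, Y, rel_lambda=rel_lambda, tol=tol, max_iter=max_iter)
    records: list[dict] = []
    tested: list[tuple[int, float]] = []   # (record index, p) entering BH
    for adr, sub in cands.groupby("adr_group", sort=True):
        pathways = list(sub.pathway_id)
        fit = stepwise_aic(X[pathways], Y[adr].to_numpy(dtype=float))
        for row in sub.itertuples(index=False):
            rec = {
                "adr_group": adr,
                "pathway_id": row.pathway_id,
                "phase1_weight": row.phase1_weight,
                "phase2_coefficient": np.nan,
                "p_value": np.nan,
                "q_value": np.nan,
                "significant": False,
            }
            if row.pathway_id in fit.selected:
                rec["phase2_coefficient"] = fit.coefficients[row.pathway_id]
                rec["p_value"] = fit.wald_p[row.pathway_id]
                if row.pathway_id not in fit.separated:
                    tested.append((len(records), rec["p_value"]))
            records.append(rec)
    if tested:
        q, reject = bh_adjust([max(p, np.finfo(float).tiny) for _, p in tested], fdr=fdr)
        for (i, _), qi, ri in zip(tested, q, reject):
            records[i]["q_value"] = qi
            records[i]["significant"] = bool(ri)
    out = pd.DataFrame.from_records(
        records,
        columns=["adr_group", "pathway_id", "phase1_weight", "phase2_coefficient",
                 "p_value", "q_value", "significant"],
    )
    return out.sort_values(
        ["q_value", "p_value", "adr_group", "pathway_id"], na_position="last"
    ).reset_index(drop=True)
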