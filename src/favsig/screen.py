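"""Genome-wide univariate proportional-hazards screening and confounder filters.

The screen fits, for every gene independently, a single-covariate Cox model
of progression-free survival on (standardized) expression and keeps genes
with p < alpha. No multiple-testing correction is applied at this stage —
the retained list is a raw p < 0.05 screen, and the output table says so in
its metadata. Hits are then filtered against clinical/genetic confounders:
a hit is dropped if its expression differs between the levels of any listed
binary covariate (two-sided Wilcoxon rank-sum) or correlates with any
listed ordinal/continuous covariate (Spearman), each at a per-test alpha.

The per-gene fits are a vectorized Newton-Raphson on the Efron-tie-corrected
partial likelihood, solving all genes simultaneously; the implementation is
validated against lifelines in the test suite. Wald p-values are reported
by default, likelihood-ratio p-values by option.

Sign convention, asserted everywhere: direction = favorable iff the fitted
log-hazard coefficient < 0 (high expression, lower hazard, better
prognosis) iff hazard ratio < 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, align_samples

__all__ = [
    "ScreenResult",
    "cox_univariate",
    "cox_screen_batch",
    "screen_genes",
    "filter_confounders",
]

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """Per-gene result of the univariate proportional-hazards screen."""

    gene_id: str
    coefficient: float
    hazard_ratio: float
    p_value: float
    direction: str  # 'favorable' iff coefficient < 0
    converged: bool = True
    flagged: bool = False

    def __post_init__(self) -> None:
        assert (self.direction == "favorable") == (self.coefficient < 0)


def _efron_prepare(time, event):
    """Sort by time and precompute tie-group bookkeeping."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order]
    ev_times = np.unique(t[d])
    starts = np.searchsorted(t, ev_times, side="left")
    groups = [np.flatnonzero(d & (t == et)) for et in ev_times]
    return order, t, d, starts, groups


def _efron_quantities(X, beta, starts, groups, sum_xD):
    """Log partial likelihood, score and information for all genes at beta.

    X: (G, n) sorted by ascending time. beta: (G,). Returns (ll, U, I).
    """
    eta = beta[:, None] * X
    r = np.exp(eta)
    xr = X * r
    xxr = X * xr
    R = np.cumsum(r[:, ::-1], axis=1)[:, ::-1]
    Rx = np.cumsum(xr[:, ::-1], axis=1)[:, ::-1]
    Rxx = np.cumsum(xxr[:, ::-1], axis=1)[:, ::-1]
    ll = beta * sum_xD
    U = sum_xD.copy()
    I = np.zeros_like(beta)
    for s, g in zip(starts, groups):
        S, Sx, Sxx = R[:, s], Rx[:, s], Rxx[:, s]
        d = len(g)
        if d == 1:
            phi, px, pxx = S, Sx, Sxx
            ll = ll - np.log(phi)
            U -= px / phi
            I += pxx / phi - (px / phi) ** 2
        else:
            SD = r[:, g].sum(axis=1)
            SxD = xr[:, g].sum(axis=1)
            SxxD = xxr[:, g].sum(axis=1)
            for l in range(d):
                f = l / d
                phi = S - f * SD
                px = Sx - f * SxD
                pxx = Sxx - f * SxxD
                ll = ll - np.log(phi)
                U -= px / phi
                I += pxx / phi - (px / phi) ** 2
    return ll, U, I


def cox_screen_batch(
    X,
    time,
    event,
    max_iter: int = 30,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Fit one univariate Cox model per row of ``X`` (genes x samples).

    Returns a DataFrame with columns ``coefficient``, ``se``, ``p_wald``,
    ``p_lr``, ``loglik``, ``converged``, ``constant``. Constant rows are not
    fit (coefficient 0, p 1, flagged).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if X.shape[1] != time.shape[0]:
        raise ValueError("X columns must match number of samples")
    if event.sum() < 2:
        raise ValueError("need at least 2 events")

    order, t, d, starts, groups = _efron_prepare(time, event)
    Xs = X[:, order]
    constant = np.ptp(X, axis=1) == 0
    G = X.shape[0]

    sum_xD = np.zeros(G)
    for g in groups:
        sum_xD += Xs[:, g].sum(axis=1)

    beta = np.zeros(G)
    ll0, _, _ = _efron_quantities(Xs, beta, starts, groups, sum_xD)
    converged = np.zeros(G, dtype=bool)
    ll, U, I = ll0, None, None
    for _ in range(max_iter):
        ll, U, I = _efron_quantities(Xs, beta, starts, groups, sum_xD)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(I > 0, U / np.maximum(I, 1e-300), 0.0)
        step = np.clip(step, -5.0, 5.0)
        step[constant] = 0.0
        beta = beta + step
        converged = np.abs(step) < tol
        if converged.all():
            break
    ll, U, I = _efron_quantities(Xs, beta, starts, groups, sum_xD)

    with np.errstate(divide="ignore"):
        se = np.where(I > 0, 1.0 / np.sqrt(np.maximum(I, 1e-300)), np.inf)
    z = np.where(np.isfinite(se), beta / se, 0.0)
    p_wald = 2.0 * stats.norm.sf(np.abs(z))
    lr = np.maximum(2.0 * (ll - ll0), 0.0)
    p_lr = stats.chi2.sf(lr, df=1)
    p_wald[constant] = 1.0
    p_lr[constant] = 1.0
    beta[constant] = 0.0
    converged[constant] = True
    return pd.DataFrame(
        {
            "coefficient": beta,
            "se": se,
            "p_wald": p_wald,
            "p_lr": p_lr,
            "loglik": ll,
            "converged": converged,
            "constant": constant,
        }
    )


def cox_univariate(expr, surv: pd.DataFrame, p_kind: str = "wald") -> ScreenResult:
    """Univariate Cox fit of survival on one expression vector.

    ``expr`` may be a pandas Series (aligned on the survival index) or an
    array in survival-table order. Constant expression is flagged with
    p = 1 rather than raising.
    """
    if isinstance(expr, pd.Series):
        gene_id = str(expr.name) if expr.name is not None else "gene"
        x = expr.loc[surv.index].to_numpy(dtype=float)
    else:
        gene_id = "gene"
        x = np.asarray(expr, dtype=float)
    fit = cox_screen_batch(x[None, :], surv["time"], surv["event"]).iloc[0]
    p = fit["p_wald"] if p_kind == "wald" else fit["p_lr"]
    flagged = bool(fit["constant"]) or not bool(fit["converged"])
    coef = float(fit["coefficient"])
    return ScreenResult(
        gene_id=gene_id,
        coefficient=coef,
        hazard_ratio=float(np.exp(coef)),
        p_value=float(p),
        direction="favorable" if coef < 0 else "unfavorable",
        converged=bool(fit["converged"]),
        flagged=flagged,
    )


def screen_genes(
    m: ExpressionMatrix,
    surv: pd.DataFrame,
    alpha: float = 0.05,
    standardize: bool = True,
    p_kind: str = "wald",
) -> pd.DataFrame:
    """Screen every gene for association with survival.

    Returns the full per-gene table (indexed by gene id) with columns
    ``coefficient``, ``hazard_ratio``, ``p_value``, ``direction``,
    ``converged``, ``hit``. ``hit`` is True iff p < alpha and the fit
    converged. Expression is standardized per gene (unit SD) before fitting
    by default, so coefficients are per-SD log-hazard.

    No multiple-testing correction is applied; ``result.attrs`` records
    that the hit list is a raw p < alpha screen.
    """
    if m.scale != "log2":
        raise ValueError("screen_genes expects log-scale expression")
    if p_kind not in ("wald", "lr"):
        raise ValueError("p_kind must be 'wald' or 'lr'")
    m, surv = align_samples(m, surv)
    X = m.values.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=1, ddof=1, keepdims=True)
        mean = X.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            X = np.where(sd > 0, (X - mean) / np.where(sd == 0, 1, sd), 0.0)
    fits = cox_screen_batch(X, surv["time"], surv["event"])
    fits.index = m.gene_ids
    p = fits["p_wald"] if p_kind == "wald" else fits["p_lr"]
    n_bad = int((~fits["converged"]).sum())
    if n_bad:
        logger.warning("%d genes did not converge; excluded from hits", n_bad)
    out = pd.DataFrame(
        {
            "coefficient": fits["coefficient"],
            "hazard_ratio": np.exp(fits["coefficient"]),
            "p_value": p,
            "direction": np.where(fits["coefficient"] < 0, "favorable", "unfavorable"),
            "converged": fits["converged"],
        }
    )
    out["hit"] = (out["p_value"] < alpha) & out["converged"] & ~fits["constant"]
    out.attrs["alpha"] = alpha
    out.attrs["p_kind"] = p_kind
    out.attrs["multiple_testing"] = (
        "NONE — hits are a raw p < alpha screen with no FDR control"
    )
    return out


def _spearman_p_vectorized(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Spearman correlation p for each row of X against y."""
    n = y.shape[0]
    rx = stats.rankdata(X, axis=1)
    ry = stats.rankdata(y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (rx * ry).sum(axis=1) / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)


def filter_confounders(
    hits: pd.DataFrame,
    m: ExpressionMatrix,
    surv: pd.DataFrame,
    binary_covariates=(),
    ordinal_or_continuous_covariates=(),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Remove screen hits associated with clinical/genetic covariates.

    A hit is removed when, for any listed binary covariate, the two-group
    Wilcoxon rank-sum test on its expression has p < alpha, or for any
    listed ordinal/continuous covariate the Spearman correlation test has
    p < alpha. The returned table is the surviving subset of ``hits``
    (rows unchanged) with one added boolean column ``assoc_<covariate>``
    per test recording the removals; covariates with a single observed
    level are skipped with a warning.
    """
    if hits.empty:
        return hits.copy()
    for cov in list(binary_covariates) + list(ordinal_or_continuous_covariates):
        if cov not in surv.columns:
            raise ValueError(f"covariate {cov!r} not in survival table")
    m, surv = align_samples(m.subset_genes(hits.index), surv)
    X = m.values.to_numpy(dtype=float)
    out = hits.copy()
    removed = np.zeros(len(hits), dtype=bool)
    for cov in binary_covariates:
        vals = surv[cov].to_numpy()
        levels = pd.unique(vals[~pd.isna(vals)])
        if len(levels) < 2:
            logger.warning("covariate %r has a single level; skipped", cov)
            continue
        a, b = X[:, vals == levels[0]], X[:, vals == levels[1]]
        p = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided").pvalue
        out[f"assoc_{cov}"] = p < alpha
        removed |= p < alpha
    for cov in ordinal_or_continuous_covariates:
        vals = surv[cov].to_numpy(dtype=float)
        if len(pd.unique(vals[~np.isnan(vals)])) < 2:
            logger.warning("covariate %r has a single level; skipped", cov)
            continue
        p = _spearman_p_vectorized(X, vals)
        out[f"assoc_{cov}"] = p < alpha
        removed |= p < alpha
    return out.loc[~removed]
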