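"""Subgroup stratification, survival comparison, cross-validation, cutpoints.

The favorability matrix is clustered into response subgroups by k-means on
its rows (k = 2 by default: a favorable-signature and an unfavorable-
signature group, named by mean favorability score). Subgroup survival is
compared with a single binary-covariate Cox model (likelihood-ratio p;
the hazard ratio is always reported with the unfavorable-vs-favorable
orientation). Cross-validation re-derives everything — screen, confounder
filter, thresholds, gene directions, cluster centroids — on training folds
only and assigns held-out samples to the nearest training centroid.

The single-gene baseline is the optimal-cutpoint procedure: scan every
admissible observed expression value as a cut, maximize the two-sample
log-rank statistic, then compare the resulting low/high groups. The
maximally selected statistic is anti-conservative as a test (no correction
is applied, by design); the comparison p-value is descriptive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.model_selection import KFold

from .containers import ExpressionMatrix, align_samples
from .favorability import FavorabilityMatrix, score_matrix, expression_thresholds
from .screen import screen_genes, filter_confounders

__all__ = [
    "SubgroupAssignment",
    "SubgroupComparison",
    "cluster_subgroups",
    "compare_subgroup_survival",
    "compare_subgroup_ic50",
    "cross_validate",
    "CVResult",
    "optimal_cutpoint",
]

logger = logging.getLogger(__name__)

FAVORABLE, UNFAVORABLE = "favorable_group", "unfavorable_group"


@dataclass
class SubgroupAssignment:
    """Sample-to-subgroup labels plus the fitted k-means geometry."""

    labels: pd.Series  # values: FAVORABLE / UNFAVORABLE (or group_<r> for k>2)
    mean_favorability: dict
    centroids: np.ndarray  # (k, n_genes), ordered like centroid_labels
    centroid_labels: list
    gene_ids: pd.Index
    separable: bool = True

    def group(self, name) -> pd.Index:
        return self.labels.index[self.labels == name]


@dataclass
class SubgroupComparison:
    """Outcome difference between the two subgroups."""

    p_value: float
    hazard_ratio: float  # unfavorable vs favorable; NaN for rank-sum tests
    n_per_group: dict
    statistic_kind: str  # 'cox_lr', 'cox_wald' or 'wilcoxon'
    stable: bool = True
    median_diff: Optional[float] = None  # unfavorable - favorable (IC-50 tests)
    km_curves: Optional[pd.DataFrame] = None


def cluster_subgroups(
    F: FavorabilityMatrix,
    k: int = 2,
    n_restarts: int = 50,
    seed: int = 0,
) -> SubgroupAssignment:
    """k-means on the rows of the favorability matrix.

    The integer scores are treated as reals under Euclidean distance; the
    best of ``n_restarts`` initializations by within-cluster sum of squares
    is kept. Groups are named by decreasing mean favorability score: with
    k = 2 the higher-mean group is the favorable group; with other k the
    names are ``group_1`` (most favorable) .. ``group_k``.
    """
    X = F.scores.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2 * k:
        raise ValueError(f"need at least {2*k} samples for k={k}")
    distinct = np.unique(X, axis=0).shape[0]
    separable = distinct >= k
    if not separable:
        logger.warning(
            "favorability matrix has %d distinct rows < k=%d; "
            "clustering is degenerate", distinct, k)
        half = n // 2
        raw = np.zeros(n, dtype=int)
        raw[half:] = 1 if k > 1 else 0
    else:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        raw = km.fit_predict(X)
    means = {c: float(X[raw == c].mean()) if (raw == c).any() else -np.inf
             for c in range(k)}
    ranked = sorted(means, key=means.get, reverse=True)
    if k == 2:
        names = {ranked[0]: FAVORABLE, ranked[1]: UNFAVORABLE}
    else:
        names = {c: f"group_{r + 1}" for r, c in enumerate(ranked)}
    labels = pd.Series([names[c] for c in raw], index=F.sample_ids)
    if separable:
        cents = np.vstack([X[raw == c].mean(axis=0) for c in ranked])
    else:
        cents = np.vstack([X.mean(axis=0)] * k)
    return SubgroupAssignment(
        labels=labels,
        mean_favorability={names[c]: means[c] for c in ranked},
        centroids=cents,
        centroid_labels=[names[c] for c in ranked],
        gene_ids=F.gene_ids,
        separable=separable,
    )


def assign_nearest_centroid(
    F: FavorabilityMatrix, groups: SubgroupAssignment
) -> pd.Series:
    """Assign new samples to the nearest existing subgroup centroid."""
    X = F.scores[groups.gene_ids].to_numpy(dtype=float)
    d2 = ((X[:, None, :] - groups.centroids[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)
    return pd.Series([groups.centroid_labels[i] for i in idx], index=F.sample_ids)


def _fit_binary_cox(df: pd.DataFrame, col: str) -> tuple[float, float, bool]:
    """Single binary-covariate Cox fit; returns (log HR, LR p, stable).

    Complete separation between the groups can stall the unpenalized
    Newton solver; in that case the fit is retried with a small ridge
    penalty and flagged.
    """
    try:
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        stable = True
    except Exception:
        logger.warning("unpenalized Cox fit failed (separation?); "
                       "retrying with a small ridge penalty")
        cph = CoxPHFitter(penalizer=0.01)
        cph.fit(df, duration_col="time", event_col="event")
        stable = False
    return (float(cph.params_[col]),
            float(cph.log_likelihood_ratio_test().p_value), stable)


def _km_coordinates(surv: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    frames = []
    for name, ids in labels.groupby(labels).groups.items():
        kmf = KaplanMeierFitter()
        sub = surv.loc[ids]
        kmf.fit(sub["time"], sub["event"], label=str(name))
        sf = kmf.survival_function_
        frames.append(pd.DataFrame({
            "time": sf.index.to_numpy(),
            "survival": sf.iloc[:, 0].to_numpy(),
            "group": str(name),
        }))
    return pd.concat(frames, ignore_index=True)


def compare_subgroup_survival(
    groups, surv: pd.DataFrame, with_km: bool = True
) -> SubgroupComparison:
    """Cox comparison of progression-free survival between two subgroups.

    ``groups`` may be a :class:`SubgroupAssignment` or a two-level label
    Series. Fits a single binary-covariate proportional-hazards model
    (indicator = unfavorable group) and reports the likelihood-ratio p and
    the hazard ratio of the unfavorable vs the favorable group.
    """
    labels = groups.labels if isinstance(groups, SubgroupAssignment) else groups
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    # orientation: indicator 1 = unfavorable group if named, else 2nd level
    unfav = UNFAVORABLE if UNFAVORABLE in levels else levels[1]
    surv = surv.loc[labels.index]
    ind = (labels == unfav).astype(int)
    df = pd.DataFrame({
        "time": surv["time"].to_numpy(dtype=float),
        "event": surv["event"].to_numpy(dtype=int),
        "unfavorable": ind.to_numpy(),
    })
    events_per = df.groupby("unfavorable")["event"].sum()
    stable = bool((events_per > 0).all()) and len(events_per) == 2
    if not stable:
        logger.warning("a subgroup has zero events; comparison flagged unstable")
    coef, p, fit_ok = _fit_binary_cox(df, "unfavorable")
    hr = float(np.exp(coef))
    stable = stable and fit_ok
    return SubgroupComparison(
        p_value=p,
        hazard_ratio=hr,
        n_per_group={lvl: int((labels == lvl).sum()) for lvl in levels},
        statistic_kind="cox_lr",
        stable=stable,
        km_curves=_km_coordinates(surv, labels) if with_km else None,
    )


def compare_subgroup_ic50(groups, ic50) -> SubgroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of log IC-50 between groups."""
    labels = groups.labels if isinstance(groups, SubgroupAssignment) else groups
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    unfav = UNFAVORABLE if UNFAVORABLE in levels else levels[1]
    fav = [lvl for lvl in levels if lvl != unfav][0]
    x = pd.Series(ic50).astype(float)
    a = np.log(x.loc[labels.index[labels == unfav]].dropna().to_numpy())
    b = np.log(x.loc[labels.index[labels == fav]].dropna().to_numpy())
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 lines with IC-50")
    if np.ptp(np.concatenate([a, b])) == 0:
        logger.warning("all IC-50 values tied; p = 1")
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return SubgroupComparison(
        p_value=p,
        hazard_ratio=float("nan"),
        n_per_group={unfav: len(a), fav: len(b)},
        statistic_kind="wilcoxon",
        median_diff=float(np.median(a) - np.median(b)),
    )


@dataclass
class CVResult:
    """Per-fold and summary cross-validation statistics."""

    folds: pd.DataFrame  # fold, n_signature_genes, train_p, test_p
    median_train_p: float
    median_test_p: float
    sd_train_p: float
    sd_test_p: float

    def summary(self) -> dict:
        return {
            "median_train_p": self.median_train_p,
            "median_test_p": self.median_test_p,
            "sd_train_p": self.sd_train_p,
            "sd_test_p": self.sd_test_p,
        }


def cross_validate(
    m: ExpressionMatrix,
    surv: pd.DataFrame,
    n_folds: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    binary_covariates=(),
    ordinal_or_continuous_covariates=(),
    mode: str = "gene_direction",
    n_restarts: int = 50,
) -> CVResult:
    """k-fold cross-validation of the whole stratification procedure.

    For each fold, the screen, confounder filter, per-gene thresholds and
    directions, and the k-means centroids are estimated on the training
    samples only; held-out samples are scored with the frozen thresholds
    and directions and assigned to the nearest training centroid. The
    train-fold and test-fold subgroup Cox likelihood-ratio p-values are
    recorded per fold.
    """
    m, surv = align_samples(m, surv)
    if m.n_samples < n_folds:
        raise ValueError("fewer samples than folds")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    samples = np.asarray(m.sample_ids)
    for fold, (tr, te) in enumerate(kf.split(samples)):
        tr_ids, te_ids = samples[tr], samples[te]
        m_tr, s_tr = m.subset_samples(tr_ids), surv.loc[tr_ids]
        m_te, s_te = m.subset_samples(te_ids), surv.loc[te_ids]
        if s_tr["event"].sum() < 2 or s_te["event"].sum() < 1:
            logger.warning("fold %d has too few events; skipped", fold)
            rows.append({"fold": fold, "n_signature_genes": 0,
                         "train_p": np.nan, "test_p": np.nan})
            continue
        tab = screen_genes(m_tr, s_tr, alpha=alpha)
        hits = tab[tab["hit"]]
        if binary_covariates or ordinal_or_continuous_covariates:
            hits = filter_confounders(
                hits, m_tr, s_tr,
                binary_covariates=binary_covariates,
                ordinal_or_continuous_covariates=ordinal_or_continuous_covariates,
                alpha=alpha,
            )
        if len(hits) < 2:
            logger.warning("fold %d signature has < 2 genes; skipped", fold)
            rows.append({"fold": fold, "n_signature_genes": len(hits),
                         "train_p": np.nan, "test_p": np.nan})
            continue
        m_tr_sig = m_tr.subset_genes(hits.index)
        thr = expression_thresholds(m_tr_sig)
        F_tr = score_matrix(m_tr_sig, mode=mode, screen=hits,
                            classing=None, thresholds=thr)
        groups = cluster_subgroups(F_tr, k=2, n_restarts=n_restarts, seed=seed)
        try:
            train_cmp = compare_subgroup_survival(groups, s_tr, with_km=False)
            train_p = train_cmp.p_value
        except ValueError:
            train_p = np.nan
        F_te = score_matrix(m_te.subset_genes(hits.index), mode=mode,
                            screen=hits, thresholds=thr)
        te_labels = assign_nearest_centroid(F_te, groups)
        try:
            test_cmp = compare_subgroup_survival(te_labels, s_te, with_km=False)
            test_p = test_cmp.p_value
        except ValueError:
            test_p = np.nan
        rows.append({"fold": fold, "n_signature_genes": len(hits),
                     "train_p": train_p, "test_p": test_p})
    folds = pd.DataFrame(rows)
    return CVResult(
        folds=folds,
        median_train_p=float(folds["train_p"].median()),
        median_test_p=float(folds["test_p"].median()),
        sd_train_p=float(folds["train_p"].std()),
        sd_test_p=float(folds["test_p"].std()),
    )


def optimal_cutpoint(
    expr, surv: pd.DataFrame, min_group_frac: float = 0.1
) -> tuple[float, SubgroupComparison]:
    """Best survival cutpoint on a continuous expression vector.

    Scans every distinct observed value as a candidate cut (low group:
    expression <= cut) that leaves at least ``min_group_frac`` of samples
    on each side, and returns the cut maximizing the two-sample log-rank
    statistic together with the low-vs-high Cox comparison (hazard ratio of
    the high group vs the low group). The maximally selected statistic is
    anti-conservative; no multiplicity adjustment is applied.
    """
    if isinstance(expr, pd.Series):
        x = expr.loc[surv.index].to_numpy(dtype=float)
    else:
        x = np.asarray(expr, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples")
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    min_n = max(1, int(np.ceil(min_group_frac * n)))
    cands = [c for c in np.unique(x) if min_n <= (x <= c).sum() <= n - min_n]
    if not cands:
        raise ValueError("no admissible cutpoint under min_group_frac")
    best_c, best_stat = None, -np.inf
    for c in cands:
        low = x <= c
        res = logrank_test(time[low], time[~low], event[low], event[~low])
        if res.test_statistic > best_stat:
            best_stat, best_c = float(res.test_statistic), float(c)
    low = x <= best_c
    labels = pd.Series(np.where(low, "low", "high"), index=surv.index)
    df = pd.DataFrame({"time": time, "event": event, "high": (~low).astype(int)})
    coef, p, fit_ok = _fit_binary_cox(df, "high")
    cmp = SubgroupComparison(
        p_value=p,
        hazard_ratio=float(np.exp(coef)),
        n_per_group={"low": int(low.sum()), "high": int((~low).sum())},
        statistic_kind="cox_lr",
        stable=fit_ok,
        km_curves=_km_coordinates(surv.loc[labels.index], labels),
    )
    return best_c, cmp
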