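"""Scikit-learn style estimators for favorability-signature stratification.

Two estimators wrap the method end to end, following sklearn conventions
(``fit``/``predict``/``transform``, ``get_params``/``set_params``, fitted
attributes with a trailing underscore):

* :class:`FavorabilityStratifier` — tumor branch. ``fit(X, y)`` takes a
  samples x genes expression DataFrame (log scale) and a survival table
  ``y`` (``time``/``event`` plus covariates, indexed like ``X``); it runs
  the genome-wide Cox screen, the confounder filter, favorability
  discretization and k-means subgrouping. ``predict`` assigns new samples
  to the nearest training subgroup centroid using the frozen thresholds
  and gene directions — exactly the test-fold rule of the cross-validation
  procedure. ``transform`` returns the favorability scores.
* :class:`CellLineStratifier` — cell-line branch, anchored on a drug's
  IC-50 vector instead of survival.

Both compose with sklearn model selection; :func:`favsig.stratify.cross_validate`
is the purpose-built CV driver that also records per-fold train/test
subgroup p-values.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix
from .favorability import expression_thresholds, score_matrix, class_lines_sensitivity
from .preprocess import filter_low_cv
from .screen import screen_genes, filter_confounders
from .cellline import screen_genes_ic50
from .stratify import (assign_nearest_centroid, cluster_subgroups,
                       compare_subgroup_survival, compare_subgroup_ic50)

__all__ = ["FavorabilityStratifier", "CellLineStratifier"]


def _as_expression(X, scale="log2") -> ExpressionMatrix:
    """Samples x genes DataFrame (sklearn orientation) -> ExpressionMatrix."""
    if isinstance(X, ExpressionMatrix):
        return X
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a samples x genes DataFrame with ids")
    return ExpressionMatrix(X.T, scale=scale)


class FavorabilityStratifier(BaseEstimator):
    """Survival-anchored favorability-signature subgrouping.

    Parameters
    ----------
    alpha : per-gene screen significance threshold (raw p, no FDR).
    mode : 'gene_direction' (per-gene Cox direction signs the scores) or
        'patient_class' (per-sample outcome class signs them).
    binary_covariates, ordinal_or_continuous_covariates : covariate columns
        of ``y`` used by the confounder filter (rank-sum / Spearman).
    gene_subset : optional gene list to restrict the signature to after
        filtering (e.g. a metabolic gene panel).
    k, n_restarts, random_state : k-means subgrouping controls.

    Attributes (after fit)
    ----------------------
    screen_table_ : full per-gene screen table.
    signature_ : index of genes in the final signature.
    thresholds_ : per-gene med + SD/2 cutoffs (training data).
    favorability_ : training FavorabilityMatrix.
    groups_ : SubgroupAssignment with k-means centroids.
    labels_ : training subgroup labels.
    comparison_ : training subgroup survival comparison.
    funnel_ : gene counts at each filtering stage.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        mode: str = "gene_direction",
        binary_covariates: Sequence[str] = (),
        ordinal_or_continuous_covariates: Sequence[str] = (),
        confounder_alpha: float = 0.05,
        gene_subset: Optional[Sequence[str]] = None,
        k: int = 2,
        n_restarts: int = 50,
        random_state: int = 0,
        standardize: bool = True,
        p_kind: str = "wald",
    ):
        self.alpha = alpha
        self.mode = mode
        self.binary_covariates = binary_covariates
        self.ordinal_or_continuous_covariates = ordinal_or_continuous_covariates
        self.confounder_alpha = confounder_alpha
        self.gene_subset = gene_subset
        self.k = k
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.standardize = standardize
        self.p_kind = p_kind

    def fit(self, X, y):
        m = _as_expression(X)
        surv = y
        tab = screen_genes(m, surv, alpha=self.alpha,
                           standardize=self.standardize, p_kind=self.p_kind)
        hits = tab[tab["hit"]]
        funnel = {"input_genes": m.n_genes, "screen_hits": len(hits)}
        if self.binary_covariates or self.ordinal_or_continuous_covariates:
            hits = filter_confounders(
                hits, m, surv,
                binary_covariates=self.binary_covariates,
                ordinal_or_continuous_covariates=self.ordinal_or_continuous_covariates,
                alpha=self.confounder_alpha,
            )
        funnel["after_confounder_filter"] = len(hits)
        if self.gene_subset is not None:
            hits = hits.loc[hits.index.intersection(list(self.gene_subset))]
        funnel["signature_genes"] = len(hits)
        if len(hits) < 2:
            raise ValueError(
                f"signature has {len(hits)} gene(s); cannot stratify")
        m_sig = m.subset_genes(hits.index)
        thr = expression_thresholds(m_sig)
        classing = None
        if self.mode == "patient_class":
            from .favorability import class_samples_survival
            classing = class_samples_survival(surv.loc[m.sample_ids])
        F = score_matrix(m_sig, mode=self.mode, screen=hits,
                         classing=classing, thresholds=thr)
        groups = cluster_subgroups(F, k=self.k, n_restarts=self.n_restarts,
                                   seed=self.random_state)
        self.screen_table_ = tab
        self.hits_ = hits
        self.signature_ = hits.index
        self.thresholds_ = thr
        self.favorability_ = F
        self.groups_ = groups
        self.labels_ = groups.labels
        self.funnel_ = funnel
        if self.k == 2:
            self.comparison_ = compare_subgroup_survival(groups, surv)
        else:
            self.comparison_ = None
        return self

    def _check_can_score_new(self) -> None:
        # per-sample outcome classes do not exist for unseen samples
        if self.mode != "gene_direction":
            raise NotImplementedError(
                "scoring new samples requires mode='gene_direction'; "
                "patient_class signs depend on each sample's own outcome")

    def transform(self, X) -> pd.DataFrame:
        """Favorability scores of new samples under the frozen signature."""
        self._check_can_score_new()
        m = _as_expression(X).subset_genes(self.signature_)
        F = score_matrix(m, mode=self.mode, screen=self.hits_,
                         thresholds=self.thresholds_)
        return F.scores

    def predict(self, X) -> pd.Series:
        """Nearest-centroid subgroup assignment for new samples."""
        self._check_can_score_new()
        m = _as_expression(X).subset_genes(self.signature_)
        F = score_matrix(m, mode=self.mode, screen=self.hits_,
                         thresholds=self.thresholds_)
        return assign_nearest_centroid(F, self.groups_)

    def fit_predict(self, X, y) -> pd.Series:
        return self.fit(X, y).labels_


class CellLineStratifier(BaseEstimator):
    """IC-50-anchored favorability-signature subgrouping of cell lines.

    ``fit(X, y)`` takes a lines x genes expression DataFrame and the per-line
    IC-50 Series of one drug; the screen is the Kendall-tau correlation
    filter (|tau| > min_tau, p <= max_p) after removing low-CV genes.
    """

    def __init__(
        self,
        min_cv: float = 0.05,
        min_tau: float = 0.2,
        max_p: float = 0.01,
        mode: str = "gene_direction",
        lower_q: float = 0.25,
        upper_q: float = 0.75,
        k: int = 2,
        n_restarts: int = 50,
        random_state: int = 0,
    ):
        self.min_cv = min_cv
        self.min_tau = min_tau
        self.max_p = max_p
        self.mode = mode
        self.lower_q = lower_q
        self.upper_q = upper_q
        self.k = k
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y):
        m = _as_expression(X)
        ic50 = pd.Series(y, index=m.sample_ids) if not isinstance(y, pd.Series) else y
        m_cv = filter_low_cv(m, min_cv=self.min_cv)
        tab = screen_genes_ic50(m_cv, ic50, min_tau=self.min_tau, max_p=self.max_p)
        hits = tab[tab["hit"]]
        self.funnel_ = {"input_genes": m.n_genes,
                        "after_cv_filter": m_cv.n_genes,
                        "signature_genes": len(hits)}
        if len(hits) < 2:
            raise ValueError(f"signature has {len(hits)} gene(s); cannot stratify")
        m_sig = m_cv.subset_genes(hits.index)
        thr = expression_thresholds(m_sig)
        classing = class_lines_sensitivity(
            ic50.loc[m_sig.sample_ids], lower_q=self.lower_q, upper_q=self.upper_q)
        F = score_matrix(m_sig, mode=self.mode, screen=hits, classing=classing,
                         anchor="sensitivity", thresholds=thr)
        groups = cluster_subgroups(F, k=self.k, n_restarts=self.n_restarts,
                                   seed=self.random_state)
        self.screen_table_ = tab
        self.hits_ = hits
        self.signature_ = hits.index
        self.thresholds_ = thr
        self.favorability_ = F
        self.groups_ = groups
        self.labels_ = groups.labels
        self.comparison_ = compare_subgroup_ic50(groups, ic50) if self.k == 2 else None
        return self

    def predict(self, X) -> pd.Series:
        if self.mode != "gene_direction":
            raise NotImplementedError(
                "scoring new lines requires mode='gene_direction'; "
                "patient_class signs depend on each line's own IC-50 class")
        m = _as_expression(X).subset_genes(self.signature_)
        F = score_matrix(m, mode=self.mode, screen=self.hits_,
                         anchor="sensitivity", thresholds=self.thresholds_)
        return assign_nearest_centroid(F, self.groups_)

    def fit_predict(self, X, y) -> pd.Series:
        return self.fit(X, y).labels_
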