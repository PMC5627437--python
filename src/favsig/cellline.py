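"""Cell-line analogue of the survival screen: expression vs IC-50.

Gene selection correlates each gene's expression with the IC-50 of one drug
across the panel using Kendall's tau (tau-b, tie-corrected); genes with
|tau| > 0.2 and p <= 0.01 pass. The tau sign is the direction: a negative
tau (high expression, low IC-50) marks a *favorable* sensitivity gene, a
positive tau a resistance (*unfavorable*) gene.

:func:`run_cellline_pipeline` composes the whole branch: CV filter ->
tau screen -> IC-50 extreme classing -> favorability scoring -> k-means
subgroups -> Wilcoxon IC-50 comparison between the subgroups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DoseResponsePanel, ExpressionMatrix
from .favorability import (FavorabilityMatrix, class_lines_sensitivity,
                           score_matrix)
from .preprocess import filter_low_cv
from .stratify import (SubgroupAssignment, SubgroupComparison,
                       cluster_subgroups, compare_subgroup_ic50)

__all__ = [
    "kendall_tau",
    "screen_genes_ic50",
    "run_cellline_pipeline",
    "CellLinePipelineResult",
]

logger = logging.getLogger(__name__)


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall's tau-b between two paired vectors with a two-sided p.

    Uses exact enumeration of the null distribution when n <= 8 and the
    data are tie-free, the normal approximation otherwise. Pairs with a
    missing value are dropped; raises if a vector is constant (tau
    undefined) or fewer than 5 complete pairs remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 5:
        raise ValueError("need at least 5 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: tau undefined")
    no_ties = (np.unique(x).size == x.size) and (np.unique(y).size == y.size)
    method = "exact" if (x.size <= 8 and no_ties) else "asymptotic"
    res = stats.kendalltau(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def screen_genes_ic50(
    m: ExpressionMatrix,
    ic50,
    min_tau: float = 0.2,
    max_p: float = 0.01,
) -> pd.DataFrame:
    """Screen genes for rank correlation with a drug's IC-50.

    Returns the full per-gene table (index = gene id) with columns ``tau``,
    ``p_value``, ``direction`` and ``hit``; a gene is a hit iff
    |tau| > min_tau and p <= max_p. Direction: ``favorable`` for tau < 0
    (high expression tracks sensitivity), ``unfavorable`` for tau > 0.
    Constant genes are skipped (tau NaN, not a hit).
    """
    y = pd.Series(ic50).astype(float)
    common = m.sample_ids.intersection(y.index) if hasattr(y, "index") else m.sample_ids
    if len(common) < 5:
        raise ValueError("need at least 5 lines shared between matrix and IC-50")
    m = m.subset_samples(common)
    yv = y.loc[common].to_numpy()
    rows = []
    for gene in m.gene_ids:
        xv = m.values.loc[gene].to_numpy(dtype=float)
        try:
            tau, p = kendall_tau(xv, yv)
        except ValueError:
            rows.append((gene, np.nan, np.nan))
            continue
        rows.append((gene, tau, p))
    out = pd.DataFrame(rows, columns=["gene_id", "tau", "p_value"]).set_index("gene_id")
    out["direction"] = np.where(out["tau"] < 0, "favorable", "unfavorable")
    out["hit"] = (out["tau"].abs() > min_tau) & (out["p_value"] <= max_p)
    out.loc[out["tau"].isna(), "hit"] = False
    n_skip = int(out["tau"].isna().sum())
    if n_skip:
        logger.warning("%d constant genes skipped in IC-50 screen", n_skip)
    return out


@dataclass
class CellLinePipelineResult:
    """All intermediate and final artifacts of the cell-line branch."""

    screen: pd.DataFrame
    favorability: Optional[FavorabilityMatrix]
    groups: Optional[SubgroupAssignment]
    comparison: Optional[SubgroupComparison]
    counts: dict = field(default_factory=dict)


def run_cellline_pipeline(
    m: ExpressionMatrix,
    panel: DoseResponsePanel,
    drug: str,
    min_cv: float = 0.05,
    min_tau: float = 0.2,
    max_p: float = 0.01,
    mode: str = "gene_direction",
    lower_q: float = 0.25,
    upper_q: float = 0.75,
    k: int = 2,
    n_restarts: int = 50,
    seed: int = 0,
) -> CellLinePipelineResult:
    """End-to-end cell-line sensitivity branch for one drug.

    Stage funnel: CV filter -> Kendall-tau screen -> favorability scoring
    (IC-50 extremes classing in ``patient_class`` mode, tau directions in
    ``gene_direction`` mode) -> k-means subgroups -> Wilcoxon IC-50
    comparison. Gene counts at every stage are recorded in ``counts``.
    If no gene passes the screen the pipeline stops gracefully with a
    zero-gene signature.
    """
    if drug not in panel.drug_ids:
        raise ValueError(f"drug {drug!r} not in panel")
    ic50 = panel.ic50[drug]
    counts = {"input_genes": m.n_genes}
    m_cv = filter_low_cv(m, min_cv=min_cv)
    counts["after_cv_filter"] = m_cv.n_genes
    tab = screen_genes_ic50(m_cv, ic50, min_tau=min_tau, max_p=max_p)
    hits = tab[tab["hit"]]
    counts["after_tau_screen"] = len(hits)
    if len(hits) < 2:
        logger.warning("zero/one-gene signature for %s; stopping", drug)
        return CellLinePipelineResult(tab, None, None, None, counts)
    m_sig = m_cv.subset_genes(hits.index)
    classing = class_lines_sensitivity(ic50.loc[m_sig.sample_ids],
                                       lower_q=lower_q, upper_q=upper_q)
    F = score_matrix(m_sig, mode=mode, screen=hits, classing=classing,
                     anchor="sensitivity")
    groups = cluster_subgroups(F, k=k, n_restarts=n_restarts, seed=seed)
    comparison = compare_subgroup_ic50(groups, ic50)
    counts["signature_genes"] = F.scores.shape[1]
    return CellLinePipelineResult(tab, F, groups, comparison, counts)
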