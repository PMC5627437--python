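"""Phenotype correlates of drug sensitivity across a cell-line panel.

Sensitivity is ``-log10(IC-50)`` (rank-based correlations make the log base
immaterial). Spearman correlations are computed per drug between the
sensitivity and a per-line trait — proliferation rate ``kp``, cell volume,
the volume-corrected growth rate ``kg = V0 * kp / ln 2`` (volume per day),
or any CORE metabolite exchange-rate column — with Benjamini-Hochberg
q-values across the drug family for that trait and a significance flag at
q < 0.05.

The growth-rate identity comes from linear volume growth between divisions:
``V1 = V0 + T1 * kg`` and division at the doubling volume ``2 V0`` after
``Td = ln 2 / kp`` gives ``V0 = Td * kg``, hence ``kg = V0 * kp / ln 2``.

:func:`drug_similarity` builds the pairwise Pearson correlation matrix of
IC-50 profiles over drugs (pairwise-complete observations) and clusters it
hierarchically on distance 1 - r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .containers import DoseResponsePanel

__all__ = [
    "growth_rate",
    "correlate_sensitivity",
    "core_vs_sensitivity",
    "drug_similarity",
    "DrugSimilarity",
]

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


def growth_rate(V0, kp):
    """Volume-corrected growth rate kg = V0 * kp / ln 2.

    ``V0`` is the post-division cell volume (fL) and ``kp`` the
    proliferation rate constant (1/day, doubling time ln 2 / kp); the
    result is in volume per day. Accepts scalars or arrays; all inputs
    must be positive and finite.
    """
    V0 = np.asarray(V0, dtype=float)
    kp = np.asarray(kp, dtype=float)
    if not (np.isfinite(V0).all() and np.isfinite(kp).all()):
        raise ValueError("V0 and kp must be finite")
    if (V0 <= 0).any() or (kp <= 0).any():
        raise ValueError("V0 and kp must be > 0")
    out = V0 * kp / LN2
    return float(out) if out.ndim == 0 else out


def _trait_values(panel: DoseResponsePanel, trait: str) -> pd.Series:
    if panel.phenotypes is None:
        raise ValueError("panel has no phenotype table")
    ph = panel.phenotypes
    if trait == "kg":
        if not {"volume", "kp"}.issubset(ph.columns):
            raise ValueError("kg requires 'volume' and 'kp' phenotype columns")
        return pd.Series(growth_rate(ph["volume"], ph["kp"]), index=ph.index,
                         name="kg")
    if trait not in ph.columns:
        raise ValueError(f"trait {trait!r} not in phenotype table")
    return ph[trait]


def _spearman_per_drug(panel, values: pd.Series, trait: str,
                       min_pairs: int = 10) -> pd.DataFrame:
    rows = []
    for drug in panel.drug_ids:
        sens = -np.log10(panel.ic50[drug])
        both = pd.concat([values, sens], axis=1).dropna()
        if len(both) < min_pairs:
            logger.warning("drug %s: only %d complete pairs; skipped",
                           drug, len(both))
            continue
        rho, p = stats.spearmanr(both.iloc[:, 0], both.iloc[:, 1])
        rows.append({"trait": trait, "drug": drug, "rho": float(rho),
                     "p_value": float(p), "n": len(both)})
    return pd.DataFrame(rows)


def _add_q(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    if df.empty:
        df["q_value"] = []
        df["significant"] = []
        return df
    df = df.copy()
    df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["q_value"] < alpha
    return df


def correlate_sensitivity(
    panel: DoseResponsePanel,
    trait: str,
    transform: str = "neg_log_ic50",
    alpha: float = 0.05,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Spearman correlation between a per-line trait and drug sensitivity.

    One row per drug with at least ``min_pairs`` complete (trait, IC-50)
    pairs: columns ``trait``, ``drug``, ``rho``, ``p_value``, ``n``,
    ``q_value`` (BH across this trait's drug family) and ``significant``
    (q < alpha).
    """
    if transform != "neg_log_ic50":
        raise ValueError("only the neg_log_ic50 sensitivity transform is defined")
    values = _trait_values(panel, trait)
    return _add_q(_spearman_per_drug(panel, values, trait, min_pairs), alpha)


def core_vs_sensitivity(
    panel: DoseResponsePanel,
    alpha: float = 0.05,
    min_pairs: int = 10,
    fdr_scope: str = "global",
) -> pd.DataFrame:
    """Correlate every CORE metabolite exchange rate with every drug.

    CORE values are positive when the metabolite is released and negative
    when consumed, so a metabolite whose release tracks resistance shows a
    negative rho against -log10(IC-50). BH correction spans all
    (metabolite, drug) pairs (``fdr_scope='global'``) or each metabolite's
    drug family (``'per_metabolite'``).
    """
    cores = panel.core_columns()
    if not cores:
        raise ValueError("panel has no CORE_* phenotype columns")
    frames = []
    for col in cores:
        vals = panel.phenotypes[col]
        if vals.dropna().nunique() <= 1:
            logger.warning("metabolite %s constant across lines; skipped", col)
            continue
        frames.append(_spearman_per_drug(panel, vals, col, min_pairs))
    allp = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["trait", "drug", "rho", "p_value", "n"])
    if fdr_scope == "global":
        return _add_q(allp, alpha)
    if fdr_scope == "per_metabolite":
        return pd.concat(
            [_add_q(g, alpha) for _, g in allp.groupby("trait", sort=False)],
            ignore_index=True,
        )
    raise ValueError("fdr_scope must be 'global' or 'per_metabolite'")


@dataclass
class DrugSimilarity:
    """Pairwise Pearson similarity of drug IC-50 profiles plus clustering."""

    similarity: pd.DataFrame  # drugs x drugs, unit diagonal
    linkage_matrix: np.ndarray  # scipy hierarchical linkage on 1 - r
    leaf_order: list

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels from cutting the tree into k clusters."""
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.similarity.index)

    def to_newick(self) -> str:
        """Newick string of the dendrogram (branch lengths = merge heights)."""
        tree = hierarchy.to_tree(self.linkage_matrix)
        names = list(self.similarity.index)

        def rec(node, parent_dist):
            bl = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{names[node.id]}:{bl:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{bl:.6g}"

        return rec(tree, tree.dist) + ";"


def drug_similarity(
    panel: DoseResponsePanel,
    linkage: str = "average",
    min_pairs: int = 10,
) -> DrugSimilarity:
    """Pearson similarity matrix over drugs and its hierarchical clustering.

    Correlations use pairwise-complete observations with at least
    ``min_pairs`` shared lines; zero-variance drugs are excluded with a
    warning. Clustering is on distance 1 - r with the given linkage.
    """
    ic50 = panel.ic50
    if ic50.shape[1] < 3:
        raise ValueError("need at least 3 drugs")
    var = ic50.var(ddof=1)
    zero = var[var == 0].index
    if len(zero):
        logger.warning("excluding zero-variance drugs: %s", list(zero))
        ic50 = ic50.drop(columns=zero)
    sim = ic50.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(sim.values, 1.0)
    dist = 1.0 - sim.to_numpy()
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = hierarchy.linkage(condensed, method=linkage)
    order = hierarchy.dendrogram(Z, no_plot=True)["leaves"]
    return DrugSimilarity(
        similarity=sim,
        linkage_matrix=Z,
        leaf_order=[sim.index[i] for i in order],
    )
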