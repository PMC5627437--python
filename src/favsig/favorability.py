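"""Discretizing expression into favorability scores F in {-1, 0, +1}.

A gene/sample cell is non-zero only when expression is high — at or above
the gene's ``median + SD/2`` threshold — and is then signed by the anchor:

* tumor branch (anchor = survival): +1 when high expression co-occurs with
  good prognosis, -1 with poor prognosis;
* cell-line branch (anchor = sensitivity): +1 when high expression
  co-occurs with drug sensitivity (low IC-50), -1 with resistance.

"Co-occurs with good prognosis" is ambiguous between two readings, both
implemented behind ``mode``:

* ``gene_direction`` (default) — the sign comes from the per-gene
  univariate Cox (or Kendall-tau) direction: every high cell of a favorable
  gene scores +1. This produces the column-coherent favorable/unfavorable
  gene blocks seen in clustered heatmaps and avoids scoring samples by
  labels derived directly from their own survival.
* ``patient_class`` — the sign comes from a per-sample outcome class
  (good / poor survival, or sensitive / resistant line), matching the
  displayed definition literally.

Thresholds can be frozen (computed on a training cohort) and applied to new
samples, which is how cross-validation avoids leakage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "SampleClassing",
    "FavorabilityMatrix",
    "expression_threshold",
    "expression_thresholds",
    "class_samples_survival",
    "class_lines_sensitivity",
    "score_matrix",
]

logger = logging.getLogger(__name__)

_ANCHOR_LABELS = {
    "survival": ("good", "poor"),
    "sensitivity": ("sensitive", "resistant"),
}


@dataclass
class SampleClassing:
    """Per-sample outcome class: positive / negative / neutral."""

    labels: pd.Series  # values: anchor-specific labels or 'neutral'
    anchor: str = "survival"

    def __post_init__(self) -> None:
        if self.anchor not in _ANCHOR_LABELS:
            raise ValueError(f"unknown anchor {self.anchor!r}")
        pos, neg = _ANCHOR_LABELS[self.anchor]
        bad = set(self.labels.unique()) - {pos, neg, "neutral"}
        if bad:
            raise ValueError(f"unexpected class labels {bad} for anchor {self.anchor}")

    def signs(self) -> pd.Series:
        """+1 for the positive class, -1 negative, 0 neutral."""
        pos, neg = _ANCHOR_LABELS[self.anchor]
        return self.labels.map({pos: 1, neg: -1, "neutral": 0}).astype(np.int8)


@dataclass
class FavorabilityMatrix:
    """Samples x genes matrix of favorability scores in {-1, 0, +1}."""

    scores: pd.DataFrame  # int8, rows = samples, columns = genes
    anchor: str
    mode: str
    thresholds: pd.Series  # per gene: the med + s/2 cutoff applied
    classing: Optional[SampleClassing] = None

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy()
        if not np.isin(vals, [-1, 0, 1]).all():
            raise ValueError("favorability scores must be in {-1, 0, 1}")
        if not np.isfinite(self.thresholds.to_numpy(dtype=float)).all():
            raise ValueError("thresholds must be finite")

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.scores.columns

    def to_tsv(self, path, sidecar_path=None) -> None:
        out = self.scores.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")
        if sidecar_path is not None:
            meta = {
                "anchor": self.anchor,
                "mode": self.mode,
                "thresholds": {str(k): float(v) for k, v in self.thresholds.items()},
                "classing": None if self.classing is None
                else self.classing.labels.to_dict(),
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=1)


def expression_threshold(expr) -> float:
    """High-expression cutoff for one gene: median + SD/2 (n-1 SD)."""
    x = np.asarray(expr, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 finite values")
    return float(np.median(x) + np.std(x, ddof=1) / 2.0)


def expression_thresholds(m: ExpressionMatrix) -> pd.Series:
    """Per-gene med + SD/2 thresholds for a whole matrix."""
    vals = m.values
    med = vals.median(axis=1, skipna=True)
    sd = vals.std(axis=1, ddof=1, skipna=True)
    if vals.notna().sum(axis=1).min() < 2:
        raise ValueError("every gene needs at least 2 finite values")
    return med + sd / 2.0


def class_samples_survival(
    surv: pd.DataFrame, mode: str = "patient_class"
) -> Optional[SampleClassing]:
    """Class samples by outcome relative to the median event time.

    ``patient_class``: a sample is *poor* if it had an event before the
    cohort's median event time; *good* if it remained event-free up to that
    median (whether its final status is censored or an event); *neutral* if
    censored before the median (insufficient follow-up).

    ``gene_direction``: classing is deferred to the per-gene screen
    direction (see :func:`score_matrix`); returns None.
    """
    if mode == "gene_direction":
        return None
    if mode != "patient_class":
        raise ValueError(f"unknown mode {mode!r}")
    event = surv["event"].to_numpy().astype(bool)
    time = surv["time"].to_numpy(dtype=float)
    if event.sum() < 2:
        raise ValueError("need at least 2 events to class samples")
    med_t = float(np.median(time[event]))
    labels = np.where(
        event & (time < med_t), "poor",
        np.where(time >= med_t, "good", "neutral"),
    )
    out = SampleClassing(pd.Series(labels, index=surv.index), anchor="survival")
    pos, neg = _ANCHOR_LABELS["survival"]
    if (out.labels == pos).sum() == 0 or (out.labels == neg).sum() == 0:
        logger.warning("degenerate survival classing: an outcome class is empty")
    return out


def class_lines_sensitivity(
    ic50, lower_q: float = 0.25, upper_q: float = 0.75
) -> SampleClassing:
    """Class cell lines by the extremes of the IC-50 distribution.

    Lines at or below the ``lower_q`` quantile are *sensitive*, at or above
    the ``upper_q`` quantile *resistant*, in between *neutral*. Quantiles
    use linear (type-7) interpolation. Classing depends on IC-50 only
    through ranks, so any monotone transform gives the same result.
    """
    x = pd.Series(ic50).astype(float)
    obs = x.dropna()
    if len(obs) < 5:
        raise ValueError("need at least 5 lines with IC-50 values")
    if obs.nunique() == 1:
        logger.warning("constant IC-50: all lines neutral")
        return SampleClassing(
            pd.Series("neutral", index=x.index), anchor="sensitivity")
    lo = float(np.quantile(obs, lower_q))
    hi = float(np.quantile(obs, upper_q))
    labels = pd.Series("neutral", index=x.index, dtype=object)
    labels[x <= lo] = "sensitive"
    labels[x >= hi] = "resistant"
    labels[x.isna()] = "neutral"
    return SampleClassing(labels, anchor="sensitivity")


def score_matrix(
    m: ExpressionMatrix,
    mode: str = "gene_direction",
    screen: Optional[pd.DataFrame] = None,
    classing: Optional[SampleClassing] = None,
    anchor: Optional[str] = None,
    thresholds: Optional[pd.Series] = None,
) -> FavorabilityMatrix:
    """Build the samples x genes favorability matrix.

    ``F[j, i] = +1`` iff expression of gene i in sample j is at or above the
    gene's threshold *and* the anchor condition is favorable; ``-1`` for the
    unfavorable counterpart; ``0`` otherwise (including every below-threshold
    cell).

    In ``gene_direction`` mode the anchor condition is the per-gene
    ``direction`` column of ``screen`` (restrict ``m`` to screen survivors
    beforehand or pass the hit table; only genes present in both are
    scored). In ``patient_class`` mode it is the per-sample class of
    ``classing``; neutral samples score 0 everywhere.

    ``thresholds`` overrides the per-gene cutoffs (used to apply
    training-derived thresholds to held-out samples).
    """
    if mode == "gene_direction":
        if screen is None:
            raise ValueError("gene_direction mode requires a screen table")
        genes = m.gene_ids.intersection(screen.index)
        m = m.subset_genes(genes)
        gene_sign = (
            screen.loc[genes, "direction"].map({"favorable": 1, "unfavorable": -1})
            .astype(np.int8)
        )
        anchor = anchor or "survival"
    elif mode == "patient_class":
        if classing is None:
            raise ValueError("patient_class mode requires a sample classing")
        anchor = anchor or classing.anchor
    else:
        raise ValueError(f"unknown mode {mode!r}")

    thr = expression_thresholds(m) if thresholds is None else thresholds.loc[m.gene_ids]
    E = m.values.T  # samples x genes
    high = (E >= thr.to_numpy()[None, :]).to_numpy()

    if mode == "gene_direction":
        F = high.astype(np.int8) * gene_sign.to_numpy()[None, :]
    else:
        s = classing.signs().loc[E.index].to_numpy()
        F = high.astype(np.int8) * s[:, None]
    scores = pd.DataFrame(F, index=E.index, columns=E.columns, dtype=np.int8)
    return FavorabilityMatrix(
        scores=scores, anchor=anchor, mode=mode, thresholds=thr,
        classing=classing if mode == "patient_class" else None,
    )
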