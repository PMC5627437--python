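"""Expression-matrix normalization and gene filters.

Three operations, applied in this order for the tumor branch:
``filter_low_count`` (raw counts) -> ``log2_normalize`` -> screening; the
cell-line branch instead uses ``filter_low_cv`` on (already normalized)
microarray-style values.

Conventions pinned down here: the log transform is ``log2(x + 1)``
(pseudocount 1 keeps zeros at zero); a gene is low-count when its count is
<= ``max_count`` in strictly more than ``frac`` of samples; the coefficient
of variation uses the n-1 sample SD and genes with CV <= ``min_cv`` are
removed. Missing values are excluded pairwise from per-gene statistics and
genes missing in more than 20% of samples are dropped with a warning.
Filters never reorder surviving genes or samples and are idempotent.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = ["log2_normalize", "filter_low_count", "filter_low_cv"]

logger = logging.getLogger(__name__)

MAX_MISSING_FRAC = 0.2


def log2_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform of a raw-count matrix."""
    if m.scale != "raw_count":
        raise ValueError("log2_normalize expects a raw_count matrix")
    vals = m.values.to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        raise ValueError("raw counts must be non-negative")
    out = pd.DataFrame(np.log2(vals + 1.0), index=m.gene_ids, columns=m.sample_ids)
    return ExpressionMatrix(out, scale="log2")


def _drop_high_missing(m: ExpressionMatrix) -> ExpressionMatrix:
    miss = m.values.isna().mean(axis=1)
    bad = miss > MAX_MISSING_FRAC
    if bad.any():
        logger.warning("dropping %d genes with > %.0f%% missing values",
                       int(bad.sum()), 100 * MAX_MISSING_FRAC)
        m = ExpressionMatrix(m.values.loc[~bad], scale=m.scale)
    return m


def filter_low_count(
    m: ExpressionMatrix, max_count: int = 2, frac: float = 0.8
) -> ExpressionMatrix:
    """Remove genes with count <= ``max_count`` in over ``frac`` of samples.

    The inequality on the sample fraction is strict: a gene low in exactly
    80% of samples is kept under the default ``frac=0.8``.
    """
    if m.scale != "raw_count":
        raise ValueError("filter_low_count applies to raw counts, before log transform")
    m = _drop_high_missing(m)
    low = (m.values <= max_count)
    low_frac = low.sum(axis=1) / m.values.notna().sum(axis=1).clip(lower=1)
    keep = low_frac <= frac
    if not keep.any():
        logger.warning("filter_low_count removed every gene")
    return ExpressionMatrix(m.values.loc[keep], scale=m.scale)


def filter_low_cv(m: ExpressionMatrix, min_cv: float = 0.05) -> ExpressionMatrix:
    """Remove genes whose coefficient of variation (SD/|mean|) is <= ``min_cv``.

    Zero-mean genes have an undefined CV and are removed with a warning.
    """
    m = _drop_high_missing(m)
    mean = m.values.mean(axis=1, skipna=True)
    sd = m.values.std(axis=1, ddof=1, skipna=True)
    zero_mean = mean == 0
    if zero_mean.any():
        logger.warning("removing %d zero-mean genes (CV undefined)", int(zero_mean.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean.abs()
    keep = (~zero_mean) & (cv > min_cv)
    if not keep.any():
        logger.warning("filter_low_cv removed every gene")
    return ExpressionMatrix(m.values.loc[keep], scale=m.scale)
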