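"""Core data containers.

All tabular data rides on pandas. The containers here are thin, validated
wrappers that pin down orientation and units once, so downstream modules can
assume them:

* :class:`ExpressionMatrix` — genes x samples, with an explicit ``scale``
  flag (``raw_count`` or ``log2``) that is carried by config, never guessed
  from the data.
* Survival tables are plain DataFrames indexed by sample id with ``time``
  (days) and ``event`` (1 = progression or death) columns plus clinical
  covariates; :func:`check_survival` enforces the schema.
* :class:`DoseResponsePanel` — lines x drugs IC-50 matrix (original
  concentration units, > 0) plus optional per-line phenotype columns
  (``volume`` in fL, ``kp`` in 1/day, and ``CORE_<metabolite>`` columns in
  fmol/cell/h, positive = released into the medium).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DoseResponsePanel",
    "check_survival",
    "read_survival_tsv",
    "write_survival_tsv",
    "align_samples",
]

_SCALES = ("raw_count", "log2")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale flag."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        vals = self.values.to_numpy(dtype=float, copy=False)
        if np.isinf(vals).any():
            raise ValueError("expression values must be finite (NaN allowed for missing)")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], scale=self.scale)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], scale=self.scale)

    def to_tsv(self, path) -> None:
        """Write as TSV: first column gene id, header row = sample ids."""
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, scale: str) -> "ExpressionMatrix":
        """Read a TSV written by :meth:`to_tsv`.

        ``scale`` must be supplied by the caller's configuration; it is never
        inferred from the data.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, scale=scale)


def check_survival(surv: pd.DataFrame) -> pd.DataFrame:
    """Validate a survival table (index = sample ids, time/event columns)."""
    if "time" not in surv.columns or "event" not in surv.columns:
        raise ValueError("survival table needs 'time' and 'event' columns")
    if surv.index.duplicated().any():
        raise ValueError("duplicate sample ids in survival table")
    t = surv["time"].to_numpy(dtype=float)
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValueError("time must be finite and >= 0")
    e = surv["event"].to_numpy()
    if not np.isin(e, [0, 1]).all():
        raise ValueError("event must be binary 0/1")
    return surv


def read_survival_tsv(path) -> pd.DataFrame:
    surv = pd.read_csv(path, sep="\t", index_col=0)
    return check_survival(surv)


def write_survival_tsv(surv: pd.DataFrame, path) -> None:
    out = check_survival(surv).copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def align_samples(m: ExpressionMatrix, surv: pd.DataFrame) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Align expression columns with survival rows; error on mismatch.

    The survival table may be a superset of the expression samples; the
    reverse is an error and the offending ids are reported.
    """
    check_survival(surv)
    missing = m.sample_ids.difference(surv.index)
    if len(missing) > 0:
        raise ValueError(
            f"{len(missing)} expression samples missing from survival table: "
            f"{list(missing[:5])}"
        )
    return m, surv.loc[m.sample_ids]


@dataclass
class DoseResponsePanel:
    """Per-(cell line, drug) IC-50 values plus optional per-line phenotypes.

    ``ic50`` is lines x drugs in original concentration units (strictly
    positive where present; NaN = missing). ``phenotypes`` is indexed by the
    same line ids; recognised columns are ``volume`` (fL), ``kp`` (1/day) and
    any number of ``CORE_*`` metabolite exchange-rate columns (fmol/cell/h,
    positive = released, negative = consumed).
    """

    ic50: pd.DataFrame
    phenotypes: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.ic50.index.duplicated().any():
            raise ValueError("duplicate cell line ids")
        if self.ic50.columns.duplicated().any():
            raise ValueError("duplicate drug ids")
        vals = self.ic50.to_numpy(dtype=float)
        if np.isfinite(vals).any() and np.nanmin(vals) <= 0:
            raise ValueError("IC-50 values must be > 0 where present")
        if self.phenotypes is not None:
            extra = self.phenotypes.index.difference(self.ic50.index)
            if len(extra) > 0:
                raise ValueError(f"phenotype lines not in panel: {list(extra[:5])}")

    @property
    def line_ids(self) -> pd.Index:
        return self.ic50.index

    @property
    def drug_ids(self) -> pd.Index:
        return self.ic50.columns

    def core_columns(self) -> list[str]:
        if self.phenotypes is None:
            return []
        return [c for c in self.phenotypes.columns if c.startswith("CORE_")]

    def to_tsv(self, ic50_path, phenotype_path=None) -> None:
        out = self.ic50.copy()
        out.index.name = "line_id"
        out.to_csv(ic50_path, sep="\t")
        if phenotype_path is not None and self.phenotypes is not None:
            ph = self.phenotypes.copy()
            ph.index.name = "line_id"
            ph.to_csv(phenotype_path, sep="\t")

    @classmethod
    def from_tsv(cls, ic50_path, phenotype_path=None) -> "DoseResponsePanel":
        ic50 = pd.read_csv(ic50_path, sep="\t", index_col=0)
        ph = None
        if phenotype_path is not None and Path(phenotype_path).exists():
            ph = pd.read_csv(phenotype_path, sep="\t", index_col=0)
        return cls(ic50, ph)
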