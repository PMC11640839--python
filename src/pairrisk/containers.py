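"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "validate_clinical", "CLINICAL_VOCAB"]

CLINICAL_VOCAB = {
    "regimen": ("CHOP", "R-CHOP", "other"),
    "ipi_group": ("low", "intermediate", "high"),
    "coo": ("GCB", "ABC", "UNC", "MHG"),
    "myc": ("normal", "double-hit"),
}


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples log-scale expression.

    ``batch`` is either a single label applying to all samples, a
    per-sample mapping (pandas Series indexed by sample id), or None.
    """

    values: pd.DataFrame
    batch: str | pd.Series | None = None

    def __post_init__(self):
        df = self.values
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if not np.isfinite(df.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if isinstance(self.batch, pd.Series):
            if not self.batch.index.equals(df.columns):
                raise ValueError("batch series must be indexed by the sample ids")

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

    def batch_series(self) -> pd.Series | None:
        """Per-sample batch labels, expanding a scalar label if needed."""
        if self.batch is None:
            return None
        if isinstance(self.batch, pd.Series):
            return self.batch
        return pd.Series(self.batch, index=self.values.columns)


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Check a clinical table: required columns, ranges, vocabularies.

    Required columns: sample_id, os_time (> 0), os_event (0/1).
    Optional categorical columns must draw from their vocabularies
    (missing values allowed).  Returns the validated frame.
    """
    for col in ("sample_id", "os_time", "os_event"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dup}")
    os_time = pd.to_numeric(df["os_time"], errors="coerce")
    if os_time.isna().any() or (os_time <= 0).any():
        bad = df.index[os_time.isna() | (os_time <= 0)].tolist()
        raise ValueError(f"os_time must be positive and numeric (rows {bad})")
    if not df["os_event"].isin((0, 1)).all():
        bad = df.index[~df["os_event"].isin((0, 1))].tolist()
        raise ValueError(f"os_event must be 0/1 (rows {bad})")
    for col, vocab in CLINICAL_VOCAB.items():
        if col in df.columns:
            vals = df[col].dropna()
            bad = sorted(set(vals) - set(vocab))
            if bad:
                raise ValueError(
                    f"unknown {col} values {bad}; allowed: {list(vocab)}"
                )
    return df
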