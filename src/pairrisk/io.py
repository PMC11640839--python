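"""Readers and writers for the pipeline's tab-delimited formats.

The canonical dialect is TSV (UTF-8, '.' decimal); CSV is accepted on
read.  Floats are written with 17 significant digits so write/read
round-trips are exact to well below 1e-12.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_clinical
from .evaluate import CoefficientSignature
from .survstats import KmCurve

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_batch_map",
    "read_drug_responses",
    "read_coefficient_signatures",
    "write_km_curve",
    "write_table",
]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_expression(path) -> ExpressionMatrix:
    """Load a gene x sample table (first column gene id, header = samples).

    Duplicate gene ids are rejected with their row numbers; missing
    values are imputed with the gene median (logged); non-numeric cells
    are an error naming the coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression table")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()]
        rows = [int(i) + 2 for i in np.flatnonzero(df.index.duplicated())]
        raise ValueError(
            f"{path}: duplicate gene ids {dup.unique().tolist()} (rows {rows})"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}: {df.iloc[g, s]!r}"
        )
    if numeric.isna().any().any():
        n_missing = int(numeric.isna().sum().sum())
        log.warning("%s: imputing %d missing value(s) with gene medians",
                    path, n_missing)
        med = numeric.median(axis=1)
        numeric = numeric.apply(lambda row: row.fillna(med[row.name]), axis=1)
    return ExpressionMatrix(values=numeric)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    path = Path(path)
    matrix.values.to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FMT,
                         index_label="gene_id")


def read_clinical(path) -> pd.DataFrame:
    """Load and validate a clinical table (sample_id, os_time, os_event, ...)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return validate_clinical(df)


def write_clinical(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FMT, index=False)


def read_batch_map(path) -> pd.Series:
    """Two-column (sample_id, batch) map as a Series indexed by sample."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if list(df.columns[:2]) != ["sample_id", "batch"]:
        raise ValueError(f"{path}: expected columns sample_id, batch")
    return df.set_index("sample_id")["batch"]


def read_drug_responses(path) -> pd.DataFrame:
    """Long-format (cell_line, drug, ln_ic50) TSV to a lines x drugs frame."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("cell_line", "drug", "ln_ic50"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df.pivot_table(index="cell_line", columns="drug", values="ln_ic50",
                          aggfunc="first")


def read_coefficient_signatures(path) -> dict[str, CoefficientSignature]:
    """(signature, gene, coefficient) TSV to named coefficient signatures."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("signature", "gene", "coefficient"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out = {}
    for name, sub in df.groupby("signature"):
        terms = tuple(
            (str(r.gene), float(r.coefficient)) for r in sub.itertuples()
        )
        out[str(name)] = CoefficientSignature(name=str(name), terms=terms)
    return out


def write_km_curve(curve: KmCurve, path) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "time": curve.event_times,
            "survival": curve.survival,
            "at_risk": curve.at_risk,
        }
    ).to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FMT, index=False)


def write_table(df: pd.DataFrame, path, *, index: bool = False) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FMT, index=index)
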