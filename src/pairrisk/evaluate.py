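"""Survival evaluation of risk scores and cross-signature comparison.

Covers Kaplan-Meier stratification by risk level, clinical-subgroup
(IPI / cell-of-origin / Myc) stratified analyses, time-dependent AUCs
averaged over 1-3 year horizons, linear coefficient-based signatures
used as comparators, and the ranked-AUC table that summarises which
signature discriminates best across datasets (rank 1 = highest mean
AUC within a dataset; tied signatures share the minimum rank).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix
from . import survstats
from .survstats import KmCurve, SurvivalData

__all__ = [
    "CoefficientSignature",
    "km_by_risk",
    "stratified_eval",
    "linear_score",
    "signature_auc",
    "rank_signatures",
    "mean_ranks",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoefficientSignature:
    """A published-style linear signature: score = sum(coef * expression)."""

    name: str
    terms: tuple[tuple[str, float], ...]

    def __post_init__(self):
        genes = [g for g, _ in self.terms]
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate genes in signature {self.name!r}")


def _aligned_survival(scores: pd.DataFrame, clinical: pd.DataFrame):
    clin = clinical.set_index("sample_id").loc[scores.index]
    return (
        clin["os_time"].to_numpy(dtype=float),
        clin["os_event"].to_numpy(),
    )


def km_by_risk(
    scores: pd.DataFrame, clinical: pd.DataFrame
) -> tuple[dict[int, KmCurve], float]:
    """One KM curve per risk level plus a multi-group log-rank p.

    ``scores`` is the frame from ``score_samples`` (indexed by sample
    id, with a ``score`` column).
    """
    times, events = _aligned_survival(scores, clinical)
    levels = np.sort(scores["score"].unique())
    if levels.shape[0] < 2:
        raise ValueError("risk score has a single level; nothing to compare")
    curves = {}
    for lev in levels:
        mask = (scores["score"] == lev).to_numpy()
        curves[int(lev)] = survstats.km_estimate(
            SurvivalData(times=times[mask], events=events[mask])
        )
    _, p, _ = survstats.multigroup_logrank(times, events, scores["score"].to_numpy())
    return curves, p


def stratified_eval(
    scores: pd.DataFrame, clinical: pd.DataFrame, stratum_field: str
) -> dict[str, dict]:
    """Low-vs-high comparison repeated within each clinical stratum.

    Returns per-stratum dicts with keys ``evaluable``, ``p_logrank``,
    ``curves`` (low/high KM) or ``reason`` when a stratum lacks both
    risk groups.
    """
    if stratum_field not in clinical.columns:
        raise ValueError(f"unknown stratum field {stratum_field!r}")
    clin = clinical.set_index("sample_id").loc[scores.index]
    out: dict[str, dict] = {}
    for stratum, sub in clin.groupby(stratum_field, observed=True):
        sub_scores = scores.loc[sub.index]
        groups = sub_scores["group"].unique()
        if len(groups) < 2:
            out[str(stratum)] = {
                "evaluable": False,
                "reason": f"only {groups.tolist()} risk group(s) present",
            }
            continue
        times = sub["os_time"].to_numpy(dtype=float)
        events = sub["os_event"].to_numpy()
        z = (sub_scores["group"] == "high").to_numpy()
        data = SurvivalData(times=times, events=events, group=z.astype(np.int8))
        chi2, p = survstats.logrank(data)
        curves = {
            label: survstats.km_estimate(
                SurvivalData(times=times[z == flag], events=events[z == flag])
            )
            for label, flag in (("low", False), ("high", True))
        }
        out[str(stratum)] = {
            "evaluable": True,
            "chi2": chi2,
            "p_logrank": p,
            "curves": curves,
        }
    return out


def linear_score(sig: CoefficientSignature, expr: ExpressionMatrix) -> pd.Series:
    """Coefficient-weighted sum of expression over the signature genes.

    Genes absent from the matrix are dropped (the retained coverage
    fraction is logged); with no genes present there is no score.
    """
    present = [(g, c) for g, c in sig.terms if g in expr.gene_ids]
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} is present")
    if len(present) < len(sig.terms):
        log.warning("signature %s: %d/%d genes present", sig.name,
                    len(present), len(sig.terms))
    genes = [g for g, _ in present]
    coefs = np.array([c for _, c in present])
    vals = expr.values.loc[genes].to_numpy(dtype=float)
    return pd.Series(coefs @ vals, index=expr.sample_ids, name=sig.name)


def signature_auc(
    marker, clinical: pd.DataFrame, horizons=(1.0, 2.0, 3.0)
) -> tuple[dict[float, float], float]:
    """Time-dependent AUC at each horizon and their arithmetic mean.

    Horizons where cases or controls are degenerate are excluded from
    the mean (with a warning).
    """
    marker = pd.Series(marker)
    clin = clinical.set_index("sample_id").loc[marker.index]
    data = SurvivalData(
        times=clin["os_time"].to_numpy(dtype=float),
        events=clin["os_event"].to_numpy(),
    )
    per_h: dict[float, float] = {}
    for h in horizons:
        try:
            per_h[float(h)] = survstats.td_roc(marker.to_numpy(), data, h).auc
        except ValueError as exc:
            warnings.warn(f"horizon {h}: {exc}; excluded from the mean")
    if not per_h:
        raise ValueError("no evaluable horizon")
    return per_h, float(np.mean(list(per_h.values())))


def rank_signatures(auc: pd.DataFrame) -> pd.DataFrame:
    """Per-dataset ranks of a signatures x datasets AUC table.

    Rank 1 is the highest mean AUC within a dataset; ties share the
    minimum rank.  Adds a ``mean_rank`` column (two decimals).
    """
    if auc.isna().any().any():
        raise ValueError("AUC table has missing cells")
    ranks = pd.DataFrame(
        np.column_stack([rankdata(-auc[c].to_numpy(), method="min") for c in auc]),
        index=auc.index,
        columns=auc.columns,
    ).astype(int)
    out = ranks.copy()
    out["mean_rank"] = mean_ranks(ranks)
    return out


def mean_ranks(ranks: pd.DataFrame) -> pd.Series:
    """Row means of a per-dataset rank table, reported to two decimals."""
    return ranks.mean(axis=1).round(2)
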