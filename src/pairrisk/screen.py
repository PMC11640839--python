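"""Per-gene prognostic screening by median dichotomisation.

Each gene is dichotomised at the cohort median expression (ties at the
median go to the low group) and the high-vs-low contrast is tested with
a univariable Cox model plus log-rank and Gehan-Wilcoxon tests.  Genes
with hazard ratio below 1 and both rank-test p-values under the
threshold are favorable prognostic genes (FPG); hazard ratio above 1
with the same gates, unfavorable (UPG).  The Cox Wald p is recorded but
not gated on.  No multiple-testing correction is applied at this stage
— the screen is deliberately a raw two-gate filter whose false-positive
behaviour is characterised by the calibration tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_clinical
from . import survstats

__all__ = ["ScreenConfig", "filter_regimen", "median_split", "screen_genes",
           "intersect_gene_sets"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds shared across the screening and evaluation stages.

    p_threshold gates the gene screen's log-rank and Wilcoxon tests;
    pair_hr_threshold gates the pair screen's hazard ratio;
    high_risk_min_score is the low/high cut on the k=4 score; horizons
    (years) are where time-dependent AUCs are evaluated.
    """

    p_threshold: float = 0.01
    pair_hr_threshold: float = 1.8
    high_risk_min_score: int = 3
    eval_horizons: tuple[float, ...] = (1.0, 2.0, 3.0)
    time_unit: str = "years"

    def __post_init__(self):
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.pair_hr_threshold <= 1.0:
            raise ValueError("pair_hr_threshold must exceed 1")
        if self.time_unit not in ("days", "months", "years"):
            raise ValueError("time_unit must be days, months or years")


def filter_regimen(
    clinical: pd.DataFrame, keep: set[str] = frozenset({"CHOP", "R-CHOP"})
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition patients by treatment regimen.

    Patients on a regimen in ``keep`` stay in the training set; the rest
    become the internal test set.  Returns (kept, internal_test).
    """
    if not keep:
        raise ValueError("keep set must be non-empty")
    if "regimen" not in clinical.columns:
        raise ValueError("clinical table has no regimen column")
    mask = clinical["regimen"].isin(keep)
    return clinical[mask].copy(), clinical[~mask].copy()


def median_split(values) -> np.ndarray:
    """High/low indicator at the median: 1 iff strictly above the median.

    Samples tied with the median land in the low group, which keeps the
    split deterministic.  A constant vector has no split and is an error.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 4:
        raise ValueError("need at least 4 values to split")
    if np.ptp(values) == 0:
        raise ValueError("constant vector: no median split exists")
    return (values > np.median(values)).astype(np.int8)


def screen_genes(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Median-split Cox/log-rank/Wilcoxon screen of every gene.

    ``clinical`` should already be regimen-filtered.  Returns a frame:
    gene_id, hr, p_logrank, p_wilcoxon, p_wald, class (FPG/UPG/none),
    reason for unscreenable genes.
    """
    validate_clinical(clinical)
    order = clinical["sample_id"].to_numpy()
    missing = set(order) - set(expr.sample_ids)
    if missing:
        raise ValueError(f"samples missing from expression: {sorted(missing)}")
    vals = expr.values.loc[:, order].to_numpy(dtype=float)
    times = clinical["os_time"].to_numpy(dtype=float)
    events = clinical["os_event"].to_numpy()
    genes = expr.gene_ids

    n = vals.shape[1]
    med = np.median(vals, axis=1)
    Z = (vals > med[:, None]).astype(np.int8)
    # a usable split needs both groups present
    n_high = Z.sum(axis=1)
    usable = (n_high > 0) & (n_high < n) & (np.ptp(vals, axis=1) > 0)
    if (~usable).any():
        log.warning("gene screen: %d gene(s) had no median split", int((~usable).sum()))

    hr = np.full(len(genes), np.nan)
    p_lr = np.full(len(genes), np.nan)
    p_wx = np.full(len(genes), np.nan)
    p_wald = np.full(len(genes), np.nan)
    if usable.any():
        Zu = Z[usable]
        fit = survstats.cox_binary_many(times, events, Zu)
        hr[usable] = fit["hr"]
        p_wald[usable] = fit["p_wald"]
        _, p = survstats.logrank_many(times, events, Zu)
        p_lr[usable] = p
        _, p = survstats.gehan_wilcoxon_many(times, events, Zu)
        p_wx[usable] = p

    gates = usable & (p_lr < config.p_threshold) & (p_wx < config.p_threshold)
    cls = np.where(gates & (hr < 1.0), "FPG",
                   np.where(gates & (hr > 1.0), "UPG", "none"))
    return pd.DataFrame(
        {
            "gene_id": genes,
            "hr": hr,
            "p_logrank": p_lr,
            "p_wilcoxon": p_wx,
            "p_wald": p_wald,
            "class": cls,
            "reason": np.where(usable, "", "no median split"),
        }
    )


def intersect_gene_sets(a: pd.DataFrame, b: pd.DataFrame):
    """Genes given the same class in both cohorts' screens.

    Returns (fpg_ids, upg_ids), each sorted.  A gene classified FPG in
    one cohort and UPG in the other is excluded from both sets.
    """
    cls_a = a.set_index("gene_id")["class"]
    cls_b = b.set_index("gene_id")["class"]
    common = cls_a.index.intersection(cls_b.index)
    same = cls_a.loc[common] == cls_b.loc[common]
    agreed = cls_a.loc[common][same]
    fpg = sorted(agreed.index[agreed == "FPG"])
    upg = sorted(agreed.index[agreed == "UPG"])
    return fpg, upg
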