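"""Risk stratification of cell-line panels and drug-sensitivity comparison.

Cell lines are scored with the gene-pair signature exactly like patient
samples, split into low (< cut-off) and high (>= cut-off) risk groups,
and each drug's log-IC50 is compared between the groups with Welch's
t-test.  Higher LN_IC50 means more resistant, so a positive high-minus-
low difference reads as "high-risk lines are more resistant".  Raw
p-values are reported by default — the drugs are screened, not
confirmed — with optional Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .signature import PairSignature, score_samples
from .simulate import DrugPanel
from .survstats import welch_t

__all__ = ["stratify_panel", "compare_drugs"]


def stratify_panel(
    expr: ExpressionMatrix,
    signature: PairSignature,
    responses: pd.DataFrame,
    *,
    high_risk_min_score: int = 3,
) -> DrugPanel:
    """Score cell lines and attach risk groups to a response table.

    ``responses`` is lines x drugs LN_IC50 (NaN = not measured).  Lines
    must be shared between expression and responses; either group being
    empty is an error (the threshold needs changing).
    """
    lines = [s for s in expr.sample_ids if s in responses.index]
    if not lines:
        raise ValueError("no cell lines shared between expression and responses")
    sub = ExpressionMatrix(values=expr.values.loc[:, lines])
    scored = score_samples(signature, sub, high_risk_min_score=high_risk_min_score)
    group = scored["group"]
    for label in ("low", "high"):
        if (group == label).sum() == 0:
            raise ValueError(
                f"{label}-risk group is empty at cut-off {high_risk_min_score}; "
                "adjust the threshold"
            )
    return DrugPanel(
        expression=sub,
        ln_ic50=responses.loc[lines],
        risk_score=scored["score"],
        group=group,
        true_effect=pd.Series(dtype=float),
    )


def compare_drugs(panel: DrugPanel, *, bh_adjust: bool = False) -> pd.DataFrame:
    """Welch's t per drug between low- and high-risk lines.

    Returns a frame sorted ascending by p: drug, n_low, n_high,
    mean_low, mean_high, diff (high - low), resistant_in_high, t, p
    (and q when ``bh_adjust``).  Drugs with fewer than two measured
    lines in either group are reported not-evaluable (p = NaN).
    """
    low_mask = (panel.group == "low").to_numpy()
    high_mask = (panel.group == "high").to_numpy()
    rows = []
    for drug in panel.ln_ic50.columns:
        col = panel.ln_ic50[drug].to_numpy(dtype=float)
        x = col[high_mask]
        y = col[low_mask]
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        row = {
            "drug": drug,
            "n_low": y.shape[0],
            "n_high": x.shape[0],
            "mean_low": np.mean(y) if y.shape[0] else np.nan,
            "mean_high": np.mean(x) if x.shape[0] else np.nan,
        }
        if x.shape[0] < 2 or y.shape[0] < 2:
            row.update(diff=np.nan, resistant_in_high=pd.NA, t=np.nan, p=np.nan,
                       evaluable=False)
        else:
            t, _, p = welch_t(x, y)
            diff = float(np.mean(x) - np.mean(y))
            row.update(diff=diff, resistant_in_high=diff > 0, t=t, p=p,
                       evaluable=True)
        rows.append(row)
    out = pd.DataFrame(rows)
    if bh_adjust:
        out["q"] = _bh(out["p"].to_numpy())
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, NaN-tolerant."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    ps = p[ok]
    m = ps.shape[0]
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.clip(ranked, 0.0, 1.0)
    q[ok] = adj
    return q
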