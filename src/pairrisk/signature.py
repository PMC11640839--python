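"""The binary gene-pair risk score.

A signature is an ordered list of (unfavorable gene, favorable gene)
pairs.  Per sample, each pair contributes an indicator s = 1 when the
unfavorable gene's within-cohort percentile rank is greater than or
equal to the favorable gene's, and the risk score is the plain integer
sum R = sum(s) — no coefficients.  Because both the per-gene quantile
transform and the pair comparison are rank-based, the score is
invariant under any per-gene strictly monotone transform of raw
expression, which is what makes it portable across platforms.

The quantile transform is always fit on the cohort being scored (each
dataset is scored independently), and — deliberately — the pair
comparison happens *after* the transform: it compares percentile ranks,
not raw intensities.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix
from . import survstats

__all__ = [
    "GenePair",
    "PairSignature",
    "quantile_uniform",
    "enumerate_pairs",
    "binarize",
    "screen_pairs",
    "intersect_pairs",
    "score_samples",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class GenePair:
    """Ordered (unfavorable, favorable) gene pair."""

    upg_id: str
    fpg_id: str

    def __post_init__(self):
        if self.upg_id == self.fpg_id:
            raise ValueError("a pair must consist of two distinct genes")


@dataclass(frozen=True)
class PairSignature:
    """A k-pair signature; the score is the sum of the pair indicators."""

    pairs: tuple[GenePair, ...]
    name: str = "pair-signature"
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs in signature")
        object.__setattr__(self, "pairs", tuple(self.pairs))

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.pairs:
            seen.setdefault(p.upg_id)
            seen.setdefault(p.fpg_id)
        return tuple(seen)

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "pairs": [{"upg": p.upg_id, "fpg": p.fpg_id} for p in self.pairs],
                "provenance": self.provenance,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PairSignature":
        obj = json.loads(text)
        pairs = tuple(GenePair(p["upg"], p["fpg"]) for p in obj["pairs"])
        return cls(pairs=pairs, name=obj.get("name", "pair-signature"),
                   provenance=obj.get("provenance", {}))


def quantile_uniform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Map each gene independently to its empirical quantiles in [0, 1].

    Rank-based: value -> (average rank - 1) / (n - 1); ties share the
    mean of their rank positions.  Matches a uniform-output quantile
    transform fit per gene on the same samples.  A constant gene maps
    every sample to 0.5 (logged).
    """
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples for a quantile transform")
    vals = expr.values.to_numpy(dtype=float)
    n = vals.shape[1]
    out = np.empty_like(vals)
    const = np.ptp(vals, axis=1) == 0
    if const.any():
        log.warning("quantile transform: %d constant gene(s) mapped to 0.5",
                    int(const.sum()))
        out[const] = 0.5
    if (~const).any():
        ranks = rankdata(vals[~const], method="average", axis=1)
        out[~const] = (ranks - 1.0) / (n - 1.0)
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=expr.gene_ids, columns=expr.sample_ids),
        batch=expr.batch,
    )


def enumerate_pairs(fpg_ids, upg_ids) -> list[GenePair]:
    """Full Cartesian product UPG x FPG in deterministic (lexicographic) order."""
    fpg = sorted(fpg_ids)
    upg = sorted(upg_ids)
    if not fpg or not upg:
        raise ValueError("both gene sets must be non-empty")
    shared = sorted(set(fpg) & set(upg))
    if shared:
        raise ValueError(f"gene sets overlap: {shared}")
    return [GenePair(u, f) for u, f in itertools.product(upg, fpg)]


def binarize(pair: GenePair, qexpr: ExpressionMatrix) -> np.ndarray:
    """Per-sample indicator: 1 iff UPG quantile >= FPG quantile."""
    for g in (pair.upg_id, pair.fpg_id):
        if g not in qexpr.gene_ids:
            raise KeyError(
                f"gene {g!r} absent from the matrix; use score_samples for "
                "missing-gene handling"
            )
    u = qexpr.values.loc[pair.upg_id].to_numpy(dtype=float)
    f = qexpr.values.loc[pair.fpg_id].to_numpy(dtype=float)
    return (u >= f).astype(np.int8)


def screen_pairs(
    pairs,
    qexpr: ExpressionMatrix,
    clinical: pd.DataFrame,
    *,
    pair_hr_threshold: float = 1.8,
) -> pd.DataFrame:
    """Univariable Cox screen of pair indicators.

    Each pair's binary vector is fit as a single Cox covariate; a pair
    is selected when its hazard ratio exceeds ``pair_hr_threshold``.
    Pairs with a constant indicator are skipped (reason recorded).
    Returns a frame: upg_id, fpg_id, hr, p_wald, selected, reason.
    """
    if pair_hr_threshold <= 1.0:
        raise ValueError("pair_hr_threshold must exceed 1")
    order = clinical["sample_id"].to_numpy()
    missing = set(order) - set(qexpr.sample_ids)
    if missing:
        raise ValueError(f"samples missing from expression: {sorted(missing)}")
    vals = qexpr.values.loc[:, order]
    times = clinical["os_time"].to_numpy(dtype=float)
    events = clinical["os_event"].to_numpy()

    pairs = list(pairs)
    gi = {g: i for i, g in enumerate(vals.index)}
    arr = vals.to_numpy(dtype=float)
    Z = np.empty((len(pairs), arr.shape[1]), dtype=np.int8)
    for i, p in enumerate(pairs):
        Z[i] = arr[gi[p.upg_id]] >= arr[gi[p.fpg_id]]
    usable = ~((Z == Z[:, :1]).all(axis=1))

    hr = np.full(len(pairs), np.nan)
    p_wald = np.full(len(pairs), np.nan)
    if usable.any():
        fit = survstats.cox_binary_many(times, events, Z[usable])
        hr[usable] = fit["hr"]
        p_wald[usable] = fit["p_wald"]
    selected = usable & (hr > pair_hr_threshold)
    return pd.DataFrame(
        {
            "upg_id": [p.upg_id for p in pairs],
            "fpg_id": [p.fpg_id for p in pairs],
            "hr": hr,
            "p_wald": p_wald,
            "selected": selected,
            "reason": np.where(usable, "", "constant indicator"),
        }
    )


def intersect_pairs(a: pd.DataFrame, b: pd.DataFrame,
                    name: str = "pair-signature") -> PairSignature:
    """Pairs selected in both cohorts, as a signature (lexicographic order)."""
    sel_a = {
        (r.upg_id, r.fpg_id) for r in a.itertuples() if r.selected
    }
    sel_b = {
        (r.upg_id, r.fpg_id) for r in b.itertuples() if r.selected
    }
    common = sorted(sel_a & sel_b)
    if not common:
        log.warning("pair intersection is empty")
    pairs = tuple(GenePair(u, f) for u, f in common)
    sig = PairSignature(pairs=pairs, name=name,
                        provenance={"n_cohort_a": len(sel_a),
                                    "n_cohort_b": len(sel_b)})
    return sig


def score_samples(
    signature: PairSignature,
    expr: ExpressionMatrix,
    *,
    high_risk_min_score: int = 3,
) -> pd.DataFrame:
    """Risk scores for every sample of a cohort.

    The expression matrix is restricted to the signature genes that are
    present, quantile-transformed on this cohort alone, and the score is
    the sum of the available pair indicators.  When some signature genes
    are missing, only pairs with both genes present contribute
    (``k_available``) and the high-risk cut-off is rescaled to
    ``ceil(high_risk_min_score * k_available / k)``.

    Returns a frame indexed by sample_id: score, k_available, group.
    """
    present = [g for g in signature.genes if g in expr.gene_ids]
    avail = [
        p for p in signature.pairs
        if p.upg_id in expr.gene_ids and p.fpg_id in expr.gene_ids
    ]
    if not avail:
        raise ValueError("no signature pair has both genes in the matrix")
    if len(avail) < signature.k:
        log.warning("scoring with %d of %d pairs (missing genes)",
                    len(avail), signature.k)
    sub = ExpressionMatrix(values=expr.values.loc[present])
    qexpr = quantile_uniform(sub)
    score = np.zeros(expr.n_samples, dtype=int)
    for p in avail:
        score += binarize(p, qexpr)
    k_avail = len(avail)
    # rescale the cut for reduced pair counts, clamped so the high group
    # stays attainable for signatures smaller than the reference k=4
    cut = min(math.ceil(high_risk_min_score * k_avail / signature.k), k_avail)
    group = np.where(score >= cut, "high", "low")
    return pd.DataFrame(
        {"score": score, "k_available": k_avail, "group": group},
        index=pd.Index(expr.sample_ids, name="sample_id"),
    )
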