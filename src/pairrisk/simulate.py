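"""Synthetic multi-batch DLBCL-like cohorts with planted prognostic signal.

The generator emulates the structure the scoring method was designed
for: several same-platform expression batches with per-gene additive and
multiplicative batch effects, overall survival driven by a proportional
hazards model on median-dichotomised planted genes plus optional
gene-pair indicator effects, independent uniform censoring tuned to a
target censor fraction, chemotherapy regimen labels, and a small
cell-line panel whose drug response shifts with risk group.

Expression is emitted on a log-like continuous scale; the downstream
scoring is rank-based, so no attempt is made to mimic platform-specific
probe behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import ExpressionMatrix
from .signature import PairSignature, score_samples

__all__ = ["SimConfig", "GroundTruth", "DrugPanel", "simulate_cohort",
           "simulate_two_cohorts", "simulate_drug_panel"]

REGIMENS = ("CHOP", "R-CHOP", "other")
IPI_GROUPS = ("low", "intermediate", "high")
COO_CLASSES = ("GCB", "ABC", "UNC", "MHG")
MYC_CLASSES = ("normal", "double-hit")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults describe the reference conditions used throughout the test
    suite: two batches of 200 patients, 200 genes, one favorable and one
    unfavorable prognostic gene at |log HR| ln(2.0) joined by one
    planted pair at log HR ln(2.2), exponential baseline hazard 0.12
    events/year and a 30% censoring target.  Only the pair's own genes
    carry gene-level effects by default: additional planted prognostic
    genes make every cross-combination of them genuinely prognostic
    (their pair indicators inherit hazard from both parents), leaving no
    unambiguously "false" pairs for recovery experiments to count.
    """

    n_genes: int = 200
    n_samples_per_batch: tuple[int, ...] = (200, 200)
    n_fpg_planted: int = 1
    n_upg_planted: int = 1
    gene_log_hr: float = math.log(2.0)
    planted_pairs: tuple[tuple[int, int], ...] = ((0, 0),)  # (upg slot, fpg slot)
    pair_log_hr: float = math.log(2.2)
    baseline_hazard: float = 0.12
    censor_rate_target: float = 0.30
    batch_shift_sd: float = 0.5
    batch_scale_sd: float = 0.2
    noise_sd: float = 1.0
    regimen_mix: tuple[float, float, float] = (0.2, 0.7, 0.1)
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if any(n < 2 for n in self.n_samples_per_batch):
            raise ValueError("each batch needs at least 2 samples")
        if self.n_fpg_planted < 0 or self.n_upg_planted < 0:
            raise ValueError("planted counts must be non-negative")
        if self.n_fpg_planted + self.n_upg_planted > self.n_genes:
            raise ValueError("more planted genes than genes")
        if not (0.0 <= self.censor_rate_target < 1.0):
            raise ValueError("censor_rate_target must be in [0, 1)")
        if self.baseline_hazard <= 0 or self.noise_sd <= 0:
            raise ValueError("baseline_hazard and noise_sd must be positive")
        if self.batch_shift_sd < 0 or self.batch_scale_sd < 0:
            raise ValueError("batch effect sds must be non-negative")
        if abs(sum(self.regimen_mix) - 1.0) > 1e-9 or any(
            f < 0 for f in self.regimen_mix
        ):
            raise ValueError("regimen_mix must be non-negative and sum to 1")
        for u, f in self.planted_pairs:
            if not (0 <= u < self.n_upg_planted) or not (0 <= f < self.n_fpg_planted):
                raise ValueError("planted pair slots must index planted UPGs/FPGs")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, for recovery experiments."""

    planted_fpg_ids: tuple[str, ...]
    planted_upg_ids: tuple[str, ...]
    planted_pair_ids: tuple[tuple[str, str], ...]  # (upg id, fpg id)
    linear_predictor: pd.Series = field(repr=False)


@dataclass(frozen=True)
class DrugPanel:
    """Cell line x drug log-IC50 panel with risk-group labels."""

    expression: ExpressionMatrix
    ln_ic50: pd.DataFrame  # lines x drugs
    risk_score: pd.Series
    group: pd.Series  # 'low' / 'high'
    true_effect: pd.Series  # per-drug planted high-vs-low shift


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _median_indicator(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    return (values > med).astype(np.int8)


def _solve_censor_scale(hazards: np.ndarray, target: float) -> float:
    """Upper bound c of Uniform(0, c) censoring hitting the target fraction.

    With T ~ Exp(h) and C ~ U(0, c) independent, P(censored) averaged
    over subjects is mean over h of (1 - exp(-h c)) / (h c); solve for c
    by bracketed root finding (the function is decreasing in c).
    """

    def frac(c: float) -> float:
        hc = hazards * c
        return float(np.mean((1.0 - np.exp(-hc)) / hc))

    lo, hi = 1e-9, 1.0
    while frac(hi) > target and hi < 1e12:
        hi *= 4.0
    if frac(hi) > target:  # pragma: no cover - unreachable for target < 1
        raise ValueError("cannot reach censoring target")
    return float(optimize.brentq(lambda c: frac(c) - target, lo, hi, xtol=1e-10))


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[ExpressionMatrix], pd.DataFrame, GroundTruth]:
    """Simulate one multi-batch cohort.

    Expression of gene g in sample j of batch b is
    ``mu_g + gamma_gb + delta_gb * eps`` with ``eps ~ N(0, noise_sd)``,
    ``gamma ~ N(0, batch_shift_sd)`` and ``delta = exp(N(0, batch_scale_sd))``.
    The hazard of sample j is
    ``baseline * exp(sum_g beta_g z_gj + sum_p pair_log_hr * s_pj)`` where z
    dichotomises expression at the cohort median and s is the pair
    relative-rank indicator.  Survival is exponential; censoring is
    Uniform(0, c) with c solved so the expected censored fraction equals
    the target.

    Returns per-batch expression matrices, a clinical table (sample_id,
    os_time, os_event, regimen, ipi_group, coo, myc, batch) and the
    planted ground truth.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n_total = int(sum(config.n_samples_per_batch))
    sample_ids = [f"S{j:05d}" for j in range(n_total)]

    mu = rng.normal(6.0, 1.0, size=config.n_genes)
    blocks = []
    batch_of = np.empty(n_total, dtype=object)
    start = 0
    for b, nb in enumerate(config.n_samples_per_batch):
        gamma = rng.normal(0.0, config.batch_shift_sd, size=config.n_genes)
        delta = np.exp(rng.normal(0.0, config.batch_scale_sd, size=config.n_genes))
        eps = rng.normal(0.0, config.noise_sd, size=(config.n_genes, nb))
        blocks.append(mu[:, None] + gamma[:, None] + delta[:, None] * eps)
        batch_of[start : start + nb] = f"batch{b + 1}"
        start += nb
    values = np.concatenate(blocks, axis=1)

    fpg_idx = np.arange(config.n_fpg_planted)
    upg_idx = np.arange(config.n_fpg_planted, config.n_fpg_planted + config.n_upg_planted)
    fpg_ids = tuple(genes[i] for i in fpg_idx)
    upg_ids = tuple(genes[i] for i in upg_idx)

    # hazard model on cohort-median dichotomised planted genes
    lp = np.zeros(n_total)
    for i in fpg_idx:
        lp -= config.gene_log_hr * _median_indicator(values[i])
    for i in upg_idx:
        lp += config.gene_log_hr * _median_indicator(values[i])

    # pair indicators compare within-cohort percentile ranks
    from scipy.stats import rankdata

    pair_ids = []
    for u_slot, f_slot in config.planted_pairs:
        u, f = upg_idx[u_slot], fpg_idx[f_slot]
        qu = rankdata(values[u], method="average")
        qf = rankdata(values[f], method="average")
        s = (qu >= qf).astype(np.int8)
        lp += config.pair_log_hr * s
        pair_ids.append((genes[u], genes[f]))

    hazards = config.baseline_hazard * np.exp(lp)
    death = rng.exponential(1.0 / hazards)
    if config.censor_rate_target == 0.0:
        os_time = death
        os_event = np.ones(n_total, dtype=np.int8)
    else:
        c = _solve_censor_scale(hazards, config.censor_rate_target)
        censor = rng.uniform(0.0, c, size=n_total)
        os_time = np.minimum(death, censor)
        os_event = (death <= censor).astype(np.int8)
    os_time = np.maximum(os_time, 1e-6)

    regimen = rng.choice(REGIMENS, size=n_total, p=config.regimen_mix)
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "os_time": os_time,
            "os_event": os_event,
            "regimen": regimen,
            "ipi_group": rng.choice(IPI_GROUPS, size=n_total, p=(0.35, 0.4, 0.25)),
            "coo": rng.choice(COO_CLASSES, size=n_total, p=(0.45, 0.3, 0.15, 0.1)),
            "myc": rng.choice(MYC_CLASSES, size=n_total, p=(0.9, 0.1)),
            "batch": batch_of,
        }
    )

    matrices = []
    start = 0
    for b, nb in enumerate(config.n_samples_per_batch):
        df = pd.DataFrame(
            values[:, start : start + nb],
            index=genes,
            columns=sample_ids[start : start + nb],
        )
        matrices.append(ExpressionMatrix(values=df, batch=f"batch{b + 1}"))
        start += nb

    truth = GroundTruth(
        planted_fpg_ids=fpg_ids,
        planted_upg_ids=upg_ids,
        planted_pair_ids=tuple(pair_ids),
        linear_predictor=pd.Series(lp, index=sample_ids),
    )
    return matrices, clinical, truth


def simulate_two_cohorts(config: SimConfig):
    """Two independent cohorts sharing gene identity and planted truth.

    The planted gene/pair ids are positional, so cohorts simulated from
    the same config (with decorrelated seeds) agree on what was planted
    — the setting the cross-cohort intersection steps expect.
    """
    c1 = simulate_cohort(replace(config, seed=config.seed * 2 + 1))
    c2 = simulate_cohort(replace(config, seed=config.seed * 2 + 2))
    return c1, c2


# ---------------------------------------------------------------------------
# drug panel


def simulate_drug_panel(
    n_lines: int,
    signature: PairSignature,
    effect: float,
    seed: int,
    *,
    n_drugs: int = 260,
    n_responsive: int | None = None,
    noise_sd: float = 1.0,
    high_risk_min_score: int = 3,
) -> DrugPanel:
    """Cell-line panel whose drug response shifts with risk group.

    Line expression over the signature's genes is constructed so the
    risk scores span 0..k (lines cycle through target scores; per pair,
    lines meant to score that pair get the top expression ranks of the
    unfavorable gene and the bottom ranks of the favorable gene).  For
    the first ``n_responsive`` drugs LN_IC50 = base + effect * 1[high
    risk] + N(0, noise_sd); the remaining drugs are neutral.  If pairs
    share genes the realised scores (always recomputed through the real
    scoring path) may not span the full range.
    """
    if n_lines < 4:
        raise ValueError("need at least 4 cell lines")
    if n_responsive is None:
        n_responsive = min(26, n_drugs)  # one in ten, as in a 260-drug panel
    if not (0 <= n_responsive <= n_drugs):
        raise ValueError("n_responsive must be within n_drugs")
    rng = np.random.default_rng(seed)
    k = len(signature.pairs)
    line_ids = [f"CL{i:03d}" for i in range(n_lines)]
    # one line per score level, the rest alternating between the extremes so
    # the low/high split at the usual ceil(3k/4) cut-off stays near-balanced
    # (17 lines, k=4 -> 9 low vs 8 high)
    base = list(range(min(k + 1, n_lines)))
    extra = [(k if i % 2 == 0 else 0) for i in range(n_lines - len(base))]
    targets = rng.permutation(np.array(base + extra))

    gene_values: dict[str, np.ndarray] = {}
    for p_idx, pair in enumerate(signature.pairs):
        hit = targets > p_idx  # lines whose target score covers this pair
        m = int(hit.sum())
        u_rank = np.empty(n_lines)
        f_rank = np.empty(n_lines)
        u_rank[hit] = np.arange(n_lines - m + 1, n_lines + 1)
        f_rank[hit] = np.arange(1, m + 1)
        u_rank[~hit] = np.arange(1, n_lines - m + 1)
        f_rank[~hit] = np.arange(m + 1, n_lines + 1)
        gene_values.setdefault(pair.upg_id, 4.0 + u_rank / 10.0)
        gene_values.setdefault(pair.fpg_id, 4.0 + f_rank / 10.0)
    expr = ExpressionMatrix(
        values=pd.DataFrame(gene_values, index=line_ids).T
    )

    scored = score_samples(signature, expr, high_risk_min_score=high_risk_min_score)
    risk = scored["score"]
    group = scored["group"]
    high = (group == "high").to_numpy()

    drug_ids = [f"drug{d:03d}" for d in range(n_drugs)]
    base = rng.normal(0.0, 2.0, size=n_drugs)
    effects = np.zeros(n_drugs)
    effects[:n_responsive] = effect
    noise = (
        rng.normal(0.0, noise_sd, size=(n_lines, n_drugs)) if noise_sd > 0 else 0.0
    )
    ln_ic50 = base[None, :] + effects[None, :] * high[:, None] + noise
    return DrugPanel(
        expression=expr,
        ln_ic50=pd.DataFrame(ln_ic50, index=line_ids, columns=drug_ids),
        risk_score=risk,
        group=group,
        true_effect=pd.Series(effects, index=drug_ids),
    )
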