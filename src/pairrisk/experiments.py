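"""Repeatable simulation experiments: calibration, recovery, batch removal.

These are the package's standard self-checks — null-calibration of the
survival tests and the two-gate gene screen, end-to-end recovery of a
planted gene pair across two cohorts, and moment-removal quality of the
batch adjustment — parameterised by a single seed so they can be rerun
reproducibly from the analysis scripts and the test suite alike.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from . import survstats
from .batch import combat_adjust, merge_common_genes
from .containers import ExpressionMatrix
from .screen import ScreenConfig, filter_regimen, intersect_gene_sets, screen_genes
from .signature import (enumerate_pairs, intersect_pairs, quantile_uniform,
                        screen_pairs)
from .simulate import SimConfig, simulate_two_cohorts

__all__ = [
    "survival_test_type1_error",
    "welch_type1_error",
    "null_screen_classified_fraction",
    "pair_recovery_experiment",
    "batch_moment_experiment",
]


def survival_test_type1_error(
    *, n: int = 200, reps: int = 1000, alpha: float = 0.05, seed: int = 0
) -> dict[str, float]:
    """Empirical type-I error of log-rank and Gehan-Wilcoxon under the null.

    Survival is exponential with independent uniform censoring (~30%);
    the group label is an independent fair coin, so every rejection is a
    false positive.
    """
    rng = np.random.default_rng(seed)
    rej_lr = 0
    rej_wx = 0
    for _ in range(reps):
        times = rng.exponential(5.0, n)
        censor = rng.uniform(0, 15.0, n)
        obs = np.minimum(times, censor)
        events = (times <= censor).astype(int)
        z = rng.integers(0, 2, n)[None, :]
        _, p = survstats.logrank_many(obs, events, z)
        rej_lr += p[0] < alpha
        _, p = survstats.gehan_wilcoxon_many(obs, events, z)
        rej_wx += p[0] < alpha
    return {"logrank": rej_lr / reps, "gehan_wilcoxon": rej_wx / reps}


def welch_type1_error(
    *, n: int = 200, reps: int = 1000, alpha: float = 0.05, seed: int = 0
) -> float:
    """Empirical type-I error of Welch's t on equal-mean normal samples."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, (reps, n // 2))
    y = rng.normal(0, 1.5, (reps, n // 2))
    res = stats.ttest_ind(x, y, axis=1, equal_var=False)
    return float(np.mean(res.pvalue < alpha))


def null_screen_classified_fraction(
    *, reps: int = 20, n_genes: int = 2000, n: int = 300, seed: int = 0
) -> float:
    """Fraction of pure-null genes the two-gate 0.01 screen classifies.

    Each replicate draws a fresh null cohort (no planted effects) and
    screens ``n_genes`` independent genes; the returned fraction pools
    all replicates.
    """
    classified = 0
    total = 0
    for r in range(reps):
        cfg = SimConfig(
            n_genes=n_genes, n_samples_per_batch=(n,), n_fpg_planted=0,
            n_upg_planted=0, planted_pairs=(), seed=seed * 1000 + r,
        )
        from .simulate import simulate_cohort

        ms, clinical, _ = simulate_cohort(cfg)
        res = screen_genes(ms[0], clinical)
        classified += int((res["class"] != "none").sum())
        total += len(res)
    return classified / total


def pair_recovery_experiment(
    *, n_seeds: int = 20, seed: int = 0, config: SimConfig | None = None,
    screen_cfg: ScreenConfig = ScreenConfig(),
) -> dict[str, float]:
    """Full two-cohort derivation repeated over seeds.

    Simulate two cohorts under the reference conditions, adjust batches,
    filter to CHOP/R-CHOP, screen genes, intersect, enumerate and screen
    pairs, intersect — then compare the final signature against the
    planted truth.  Returns the mean recovered fraction of planted pairs
    and the mean number of non-planted pairs in the signature.
    """
    base = config if config is not None else SimConfig()
    rec, false = [], []
    for s in range(n_seeds):
        cfg = dataclasses.replace(base, seed=seed * 1000 + s)
        (m1, c1, t1), (m2, c2, _) = simulate_two_cohorts(cfg)
        screens, cohorts = [], []
        for ms, clin in ((m1, c1), (m2, c2)):
            merged = combat_adjust(merge_common_genes(ms))
            kept, _ = filter_regimen(clin)
            cohorts.append((merged, kept))
            screens.append(screen_genes(merged, kept, screen_cfg))
        fpg, upg = intersect_gene_sets(screens[0], screens[1])
        planted = set(t1.planted_pair_ids)
        if not fpg or not upg:
            rec.append(0.0)
            false.append(0)
            continue
        pairs = enumerate_pairs(fpg, upg)
        pair_screens = []
        for merged, kept in cohorts:
            sub = ExpressionMatrix(values=merged.values.loc[fpg + upg])
            pair_screens.append(
                screen_pairs(pairs, quantile_uniform(sub), kept,
                             pair_hr_threshold=screen_cfg.pair_hr_threshold)
            )
        sig = intersect_pairs(pair_screens[0], pair_screens[1])
        found = {(p.upg_id, p.fpg_id) for p in sig.pairs}
        rec.append(len(found & planted) / len(planted))
        false.append(len(found - planted))
    return {
        "recovery_fraction": float(np.mean(rec)),
        "mean_false_pairs": float(np.mean(false)),
        "n_seeds": n_seeds,
    }


def batch_moment_experiment(
    *, n_genes: int = 400, n_per_batch: int = 800, shift_sd: float = 2.0,
    scale_sd: float = 0.5, seed: int = 0,
) -> dict[str, float]:
    """Adjust a two-batch cohort with strong planted batch effects.

    Returns the fraction of genes whose between-batch mean difference
    falls under 0.1 and whose variance ratio lands in (0.8, 1.25) after
    adjustment, plus the median mean-difference before adjustment.
    """
    from .simulate import simulate_cohort

    cfg = SimConfig(
        n_genes=n_genes, n_samples_per_batch=(n_per_batch, n_per_batch),
        batch_shift_sd=shift_sd, batch_scale_sd=scale_sd,
        n_fpg_planted=0, n_upg_planted=0, planted_pairs=(), seed=seed,
    )
    ms, _, _ = simulate_cohort(cfg)
    merged = merge_common_genes(ms)
    adj = combat_adjust(merged)
    bt = adj.batch_series()
    m1 = bt == "batch1"
    raw_diff = (merged.values.loc[:, m1].mean(axis=1)
                - merged.values.loc[:, ~m1].mean(axis=1)).abs()
    g1 = adj.values.loc[:, m1]
    g2 = adj.values.loc[:, ~m1]
    mean_diff = (g1.mean(axis=1) - g2.mean(axis=1)).abs()
    var_ratio = g1.var(axis=1) / g2.var(axis=1)
    return {
        "frac_mean_diff_under_0.1": float((mean_diff < 0.1).mean()),
        "frac_var_ratio_in_band": float(
            ((var_ratio > 0.8) & (var_ratio < 1.25)).mean()
        ),
        "median_raw_mean_diff": float(raw_diff.median()),
    }
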