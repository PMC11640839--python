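"""End-to-end driver: integrate, screen, build the pair signature, score.

``run_pipeline`` executes the whole derivation on two training cohorts:
merge batches on common genes -> empirical-Bayes batch adjustment ->
regimen filter (CHOP / R-CHOP kept, the rest set aside as internal
test data) -> per-cohort gene screen -> cross-cohort gene intersection
-> pair enumeration and Cox pair screen on quantile-transformed data ->
cross-cohort pair intersection -> risk scores and survival evaluation.
All intermediate tables are written to the artifact directory together
with a run log (config echo, versions, seed); a stage failure aborts
with the stage name while keeping the intermediates already written.

Cohorts come either from a simulation block in the config or from
expression/clinical/batch files on disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .batch import combat_adjust, merge_common_genes
from .containers import ExpressionMatrix
from .evaluate import km_by_risk, signature_auc
from .screen import ScreenConfig, filter_regimen, intersect_gene_sets, screen_genes
from .signature import (PairSignature, enumerate_pairs, intersect_pairs,
                        quantile_uniform, score_samples, screen_pairs)
from .simulate import SimConfig, simulate_two_cohorts

__all__ = ["run_pipeline", "derive_signature"]

log = logging.getLogger(__name__)


def _screen_config(cfg: dict) -> ScreenConfig:
    fields = {f.name for f in dataclasses.fields(ScreenConfig)}
    kwargs = {k: v for k, v in cfg.get("thresholds", {}).items() if k in fields}
    if "eval_horizons" in kwargs:
        kwargs["eval_horizons"] = tuple(kwargs["eval_horizons"])
    return ScreenConfig(**kwargs)


def _load_cohorts(cfg: dict):
    """Cohorts from the simulation block or from files; two are required."""
    if "simulation" in cfg:
        sim = dict(cfg["simulation"])
        sim.setdefault("seed", cfg.get("seed", 0))
        for key in ("n_samples_per_batch", "regimen_mix"):
            if key in sim:
                sim[key] = tuple(sim[key])
        if "planted_pairs" in sim:
            sim["planted_pairs"] = tuple(tuple(p) for p in sim["planted_pairs"])
        config = SimConfig(**sim)
        (m1, c1, t1), (m2, c2, t2) = simulate_two_cohorts(config)
        return [(m1, c1), (m2, c2)], (t1, t2)
    cohorts = cfg.get("cohorts", [])
    if len(cohorts) < 2:
        raise ValueError("config must name at least two training cohorts "
                         "(or a simulation block)")
    loaded = []
    for c in cohorts:
        matrices = [io.read_expression(p) for p in c["expression"]]
        clinical = io.read_clinical(c["clinical"])
        loaded.append((matrices, clinical))
    return loaded, None


def derive_signature(
    cohorts,
    screen_cfg: ScreenConfig = ScreenConfig(),
    *,
    outdir: Path | None = None,
):
    """Run the derivation on [(batch matrices, clinical), ...] x 2.

    Returns a dict with the merged/adjusted cohorts, the per-cohort
    screen tables, the intersected gene sets, the pair screen tables and
    the final signature.  When ``outdir`` is given every table is also
    written there as TSV.
    """

    def save(name, df, **kw):
        if outdir is not None:
            io.write_table(df, Path(outdir) / name, **kw)

    merged, kept_clin, screens = [], [], []
    for i, (matrices, clinical) in enumerate(cohorts, start=1):
        stage = f"integrate cohort {i}"
        try:
            m = merge_common_genes(matrices) if len(matrices) > 1 else matrices[0]
            adj = combat_adjust(m) if m.batch_series() is not None else m
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        kept, internal = filter_regimen(clinical)
        save(f"cohort{i}_internal_test.tsv", internal)
        merged.append(adj)
        kept_clin.append(kept)
        stage = f"gene screen cohort {i}"
        try:
            res = screen_genes(adj, kept, screen_cfg)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        screens.append(res)
        save(f"cohort{i}_gene_screen.tsv", res)

    fpg, upg = intersect_gene_sets(screens[0], screens[1])
    save("gene_sets.tsv", pd.DataFrame(
        {"gene_id": fpg + upg, "class": ["FPG"] * len(fpg) + ["UPG"] * len(upg)}
    ))
    if not fpg or not upg:
        raise RuntimeError("stage 'gene intersection' failed: one of the "
                           "FPG/UPG sets is empty")
    pairs = enumerate_pairs(fpg, upg)

    pair_screens = []
    for i, (adj, kept) in enumerate(zip(merged, kept_clin), start=1):
        stage = f"pair screen cohort {i}"
        try:
            sub = ExpressionMatrix(values=adj.values.loc[fpg + upg],
                                   batch=adj.batch)
            qexpr = quantile_uniform(sub)
            res = screen_pairs(pairs, qexpr, kept,
                               pair_hr_threshold=screen_cfg.pair_hr_threshold)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        pair_screens.append(res)
        save(f"cohort{i}_pair_screen.tsv", res)

    sig = intersect_pairs(pair_screens[0], pair_screens[1])
    return {
        "cohorts": merged,
        "clinical": kept_clin,
        "gene_screens": screens,
        "fpg_ids": fpg,
        "upg_ids": upg,
        "pair_screens": pair_screens,
        "signature": sig,
    }


def run_pipeline(config_path) -> Path:
    """Execute the full workflow described by a YAML config file.

    Returns the artifact directory.  Deterministic under a fixed seed.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    outdir = Path(cfg.get("outdir", config_path.with_suffix("")))
    outdir.mkdir(parents=True, exist_ok=True)
    screen_cfg = _screen_config(cfg)

    cohorts, truth = _load_cohorts(cfg)
    result = derive_signature(cohorts, screen_cfg, outdir=outdir)
    sig: PairSignature = result["signature"]
    (outdir / "signature.json").write_text(sig.to_json() + "\n")

    evaluation = {}
    if sig.k >= 1:
        for i, (adj, kept) in enumerate(
            zip(result["cohorts"], result["clinical"]), start=1
        ):
            training = ExpressionMatrix(
                values=adj.values.loc[:, kept["sample_id"]]
            )
            scores = score_samples(
                sig, training, high_risk_min_score=screen_cfg.high_risk_min_score
            )
            io.write_table(scores.reset_index(), outdir / f"cohort{i}_scores.tsv")
            entry = {}
            if scores["score"].nunique() >= 2:
                curves, p = km_by_risk(scores, kept)
                entry["km_logrank_p"] = p
                for lev, curve in curves.items():
                    io.write_km_curve(curve, outdir / f"cohort{i}_km_score{lev}.tsv")
            try:
                _, mean_auc = signature_auc(
                    scores["score"], kept, screen_cfg.eval_horizons
                )
                entry["mean_auc_1to3"] = mean_auc
            except ValueError as exc:
                entry["mean_auc_1to3"] = None
                log.warning("cohort %d AUC skipped: %s", i, exc)
            evaluation[f"cohort{i}"] = entry

    run_log = {
        "config": cfg,
        "seed": cfg.get("seed", 0),
        "signature": {"k": sig.k, "genes": list(sig.genes)},
        "n_fpg": len(result["fpg_ids"]),
        "n_upg": len(result["upg_ids"]),
        "evaluation": evaluation,
        "versions": {
            "python": sys.version.split()[0],
            "platform": platform.platform(),
            "pairrisk": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if truth is not None:
        planted = {tuple(p) for t in truth for p in t.planted_pair_ids}
        found = {(p.upg_id, p.fpg_id) for p in sig.pairs}
        run_log["recovery"] = {
            "planted_pairs": sorted(planted),
            "recovered": sorted(planted & found),
            "false_pairs": sorted(found - planted),
        }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")
    return outdir
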