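"""Tests of the quantile transform, pair enumeration/screening and scoring."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import expr_from_array
from pairrisk.batch import combat_adjust, merge_common_genes
from pairrisk.containers import ExpressionMatrix
from pairrisk.screen import filter_regimen
from pairrisk.signature import (GenePair, PairSignature, binarize,
                                enumerate_pairs, intersect_pairs,
                                quantile_uniform, score_samples, screen_pairs)
from pairrisk.simulate import SimConfig, simulate_cohort


class TestQuantileUniform:
    def test_equally_spaced_ranks(self):
        q = quantile_uniform(expr_from_array([[10, 20, 30, 40]]))
        assert np.allclose(q.values.iloc[0], [0, 1 / 3, 2 / 3, 1])

    def test_ties_share_transformed_value(self):
        q = quantile_uniform(expr_from_array([[5, 5, 9]]))
        v = q.values.iloc[0]
        assert v.iloc[0] == v.iloc[1] < v.iloc[2]

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (5, 30))
        q1 = quantile_uniform(expr_from_array(x))
        q2 = quantile_uniform(expr_from_array(np.exp(x) + 3))
        pd.testing.assert_frame_equal(q1.values, q2.values)

    def test_constant_gene_maps_to_half(self):
        q = quantile_uniform(expr_from_array([[4, 4, 4], [1, 2, 3]]))
        assert (q.values.iloc[0] == 0.5).all()

    def test_matches_sklearn_quantile_transformer(self):
        from sklearn.preprocessing import QuantileTransformer

        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (4, 25))
        x[1, :5] = x[1, 5]  # inject ties
        q = quantile_uniform(expr_from_array(x))
        qt = QuantileTransformer(n_quantiles=25, output_distribution="uniform")
        ref = qt.fit_transform(x.T).T
        assert np.allclose(q.values.to_numpy(), ref, atol=1e-12)


class TestEnumeratePairs:
    def test_full_product_count(self):
        fpg = [f"F{i}" for i in range(204)]
        upg = [f"U{i}" for i in range(204)]
        assert len(enumerate_pairs(fpg, upg)) == 41616

    def test_small_products(self):
        assert len(enumerate_pairs(["F"], ["U"])) == 1
        pairs = enumerate_pairs([f"F{i}" for i in range(5)],
                                [f"U{i}" for i in range(3)])
        assert len(pairs) == 15 and len(set(pairs)) == 15

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="X"):
            enumerate_pairs(["X", "F"], ["X", "U"])


class TestBinarize:
    def test_tie_scores_one(self):
        q = quantile_uniform(expr_from_array([[1, 2, 3], [1, 3, 2]],
                                             genes=["U", "F"]))
        s = binarize(GenePair("U", "F"), q)
        assert s[0] == 1  # equal quantiles -> 1

    def test_upg_always_below_gives_zero(self):
        expr = expr_from_array([[1, 2, 3], [4, 5, 6]], genes=["U", "F"])
        # same ranks per gene -> quantiles tie -> >= rule gives ones;
        # flip order in every sample instead
        expr = expr_from_array([[1, 3, 2], [2, 1, 3]], genes=["U", "F"])
        q = quantile_uniform(expr)
        s = binarize(GenePair("U", "F"), q)
        t = binarize(GenePair("F", "U"), q)
        ties = q.values.loc["U"].to_numpy() == q.values.loc["F"].to_numpy()
        assert np.all((s + t)[~ties] == 1)  # swap complements off ties
        assert np.all((s + t)[ties] == 2)

    def test_missing_gene_raises(self):
        q = quantile_uniform(expr_from_array([[1, 2, 3]], genes=["U"]))
        with pytest.raises(KeyError, match="missing-gene"):
            binarize(GenePair("U", "F"), q)


def _cohort_frames(seed=0, **kw):
    cfg = dataclasses.replace(SimConfig(seed=seed), **kw)
    ms, clinical, truth = simulate_cohort(cfg)
    merged = merge_common_genes(ms) if len(ms) > 1 else ms[0]
    kept, _ = filter_regimen(clinical)
    return merged, kept, truth


class TestScreenPairs:
    def test_planted_pair_selected_almost_always(self):
        hits = 0
        for seed in range(20):
            merged, kept, truth = _cohort_frames(seed=seed)
            u, f = truth.planted_pair_ids[0]
            sub = ExpressionMatrix(values=merged.values.loc[[u, f]])
            res = screen_pairs([GenePair(u, f)], quantile_uniform(sub), kept)
            hits += bool(res["selected"].iloc[0])
        assert hits >= 18

    def test_null_selection_decreases_with_threshold(self):
        merged, kept, _ = _cohort_frames(
            seed=30, n_genes=40, n_fpg_planted=0, n_upg_planted=0,
            planted_pairs=(), n_samples_per_batch=(200,),
        )
        genes = list(merged.gene_ids)
        pairs = enumerate_pairs(genes[:20], genes[20:])
        q = quantile_uniform(merged)
        fracs = []
        for thr in (1.4, 1.8, 2.2):
            res = screen_pairs(pairs, q, kept, pair_hr_threshold=thr)
            fracs.append(res["selected"].mean())
        assert fracs[0] >= fracs[1] >= fracs[2]
        assert fracs[1] < 0.05

    def test_constant_indicator_skipped(self):
        expr = expr_from_array(
            [[5, 6, 7, 8], [1, 2, 3, 4]], genes=["U", "F"],
        )
        q = quantile_uniform(expr)  # identical ranks -> indicator all 1
        clinical = pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(4)],
            "os_time": [1.0, 2.0, 3.0, 4.0],
            "os_event": [1, 1, 1, 1],
        })
        res = screen_pairs([GenePair("U", "F")], q, clinical)
        assert not res["selected"].iloc[0]
        assert res["reason"].iloc[0] == "constant indicator"


class TestIntersectPairs:
    def as_frame(self, pairs):
        return pd.DataFrame({
            "upg_id": [u for u, _ in pairs],
            "fpg_id": [f for _, f in pairs],
            "selected": True,
        })

    def test_common_pairs_only(self):
        a = self.as_frame([("U1", "F1"), ("U2", "F2")])
        b = self.as_frame([("U2", "F2"), ("U3", "F3")])
        sig = intersect_pairs(a, b)
        assert sig.pairs == (GenePair("U2", "F2"),)

    def test_disjoint_gives_empty_signature(self):
        a = self.as_frame([("U1", "F1")])
        b = self.as_frame([("U2", "F2")])
        assert intersect_pairs(a, b).k == 0

    def test_shared_gene_yields_seven_unique_genes(self):
        pairs = [("U1", "F1"), ("U2", "F2"), ("U3", "F3"), ("U3", "F4")]
        sig = intersect_pairs(self.as_frame(pairs), self.as_frame(pairs))
        assert sig.k == 4
        assert len(sig.genes) == 7


class TestScoreSamples:
    def combo_expr(self):
        """16 samples realising every 4-pair indicator combination."""
        genes = {}
        combos = list(itertools.product([0, 1], repeat=4))
        n = len(combos)
        for p in range(4):
            hit = np.array([c[p] for c in combos], dtype=bool)
            m = int(hit.sum())
            u = np.empty(n)
            f = np.empty(n)
            u[hit] = np.arange(n - m + 1, n + 1)
            f[hit] = np.arange(1, m + 1)
            u[~hit] = np.arange(1, n - m + 1)
            f[~hit] = np.arange(m + 1, n + 1)
            genes[f"U{p}"] = u
            genes[f"F{p}"] = f
        return ExpressionMatrix(values=pd.DataFrame(
            genes, index=[f"s{i}" for i in range(n)]).T), combos

    def test_score_support_is_five_levels(self, four_pair_signature):
        expr, combos = self.combo_expr()
        scores = score_samples(four_pair_signature, expr)
        assert sorted(set(scores["score"])) == [0, 1, 2, 3, 4]
        assert (scores["score"].to_numpy()
                == np.array([sum(c) for c in combos])).all()
        assert ((scores["group"] == "high")
                == (scores["score"] >= 3)).all()

    def test_reduced_pair_count_limits_support(self, four_pair_signature):
        expr, _ = self.combo_expr()
        reduced = ExpressionMatrix(
            values=expr.values.drop(index=["U2", "U3"]))
        scores = score_samples(four_pair_signature, reduced)
        assert (scores["k_available"] == 2).all()
        assert set(scores["score"]) <= {0, 1, 2}
        # rescaled high-risk cut: ceil(3 * 2 / 4) = 2
        assert ((scores["group"] == "high") == (scores["score"] >= 2)).all()

    def test_no_available_pair_is_an_error(self, four_pair_signature):
        expr = expr_from_array([[1, 2], [3, 4]], genes=["U0", "U1"])
        with pytest.raises(ValueError, match="no signature pair"):
            score_samples(four_pair_signature, expr)

    def test_monotone_transform_leaves_scores_identical(self, four_pair_signature):
        expr, _ = self.combo_expr()
        rng = np.random.default_rng(6)
        warped = expr.values.copy()
        for g in warped.index:  # a different strictly monotone map per gene
            a, b = rng.uniform(0.5, 2.0), rng.uniform(-3, 3)
            warped.loc[g] = np.exp(a * warped.loc[g] / 16.0) + b
        s1 = score_samples(four_pair_signature, expr)
        s2 = score_samples(four_pair_signature,
                           ExpressionMatrix(values=warped))
        pd.testing.assert_frame_equal(s1, s2)

    def test_single_batch_adjustment_leaves_scores_identical(
        self, four_pair_signature
    ):
        expr, _ = self.combo_expr()
        labelled = ExpressionMatrix(values=expr.values, batch="one")
        adjusted = combat_adjust(labelled)
        s1 = score_samples(four_pair_signature, expr)
        s2 = score_samples(four_pair_signature, adjusted)
        pd.testing.assert_frame_equal(s1, s2)


class TestSignatureContainer:
    def test_json_roundtrip(self, four_pair_signature):
        text = four_pair_signature.to_json()
        back = PairSignature.from_json(text)
        assert back.pairs == four_pair_signature.pairs

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError):
            PairSignature(pairs=(GenePair("U", "F"), GenePair("U", "F")))

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            GenePair("X", "X")
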