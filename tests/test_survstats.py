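"""Unit and property tests for the first-principles survival statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from pairrisk import survstats as ss
from pairrisk.survstats import SurvivalData


def sdata(times, events, group=None):
    return SurvivalData(
        times=np.asarray(times, dtype=float),
        events=np.asarray(events, dtype=int),
        group=None if group is None else np.asarray(group, dtype=int),
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = ss.km_estimate(sdata([1, 2, 3], [1, 1, 1]))
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_is_constant_one(self):
        curve = ss.km_estimate(sdata([1, 2, 3], [0, 0, 0]))
        assert curve.event_times.size == 0
        assert ss.km_survival_at(curve, 99.0) == 1.0

    def test_censored_subject_counted_at_risk(self):
        # times (1, 2+, 3): S(1) = 2/3, S(3) = 0
        curve = ss.km_estimate(sdata([1, 2, 3], [1, 0, 1]))
        assert ss.km_survival_at(curve, 1.0) == pytest.approx(2 / 3)
        assert ss.km_survival_at(curve, 3.0) == pytest.approx(0.0)

    def test_matches_product_limit_oracle(self, tied_survival):
        times, events, _ = tied_survival
        curve = ss.km_estimate(sdata(times, events))
        expect = oracles.km_oracle(times, events)
        for t, s in expect.items():
            assert ss.km_survival_at(curve, t) == pytest.approx(s, abs=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.integers(1, 8), min_size=3, max_size=15))
    def test_uncensored_km_is_empirical(self, raw):
        times = np.array(raw, dtype=float)
        curve = ss.km_estimate(sdata(times, np.ones_like(times)))
        for t in np.unique(times):
            assert ss.km_survival_at(curve, t) == pytest.approx(
                np.mean(times > t), abs=1e-12
            )


# ---------------------------------------------------------------------------
# rank tests


class TestRankTests:
    def test_identical_groups_are_null(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 0, 1, 1, 1, 0, 1, 1]
        group = [0, 0, 0, 0, 1, 1, 1, 1]
        chi2, p = ss.logrank(sdata(times, events, group))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        chi2w, pw = ss.gehan_wilcoxon(sdata(times, events, group))
        assert chi2w == pytest.approx(0.0, abs=1e-12)
        assert pw == pytest.approx(1.0)

    def test_four_subject_logrank_matches_oracle(self):
        times, events, z = [1, 2, 3, 4], [1, 1, 1, 1], [0, 0, 1, 1]
        chi2, _ = ss.logrank(sdata(times, events, z))
        assert chi2 == pytest.approx(
            oracles.weighted_logrank_oracle(times, events, z), abs=1e-10
        )

    def test_logrank_matches_oracle_with_ties(self, tied_survival):
        times, events, z = tied_survival
        chi2, _ = ss.logrank(sdata(times, events, z))
        assert chi2 == pytest.approx(
            oracles.weighted_logrank_oracle(times, events, z), abs=1e-10
        )

    def test_gehan_matches_weighted_oracle(self):
        times = [1, 1, 2, 3, 4, 5]
        events = [1, 0, 1, 1, 0, 1]
        z = [1, 0, 1, 0, 1, 0]
        chi2, _ = ss.gehan_wilcoxon(sdata(times, events, z))
        assert chi2 == pytest.approx(
            oracles.weighted_logrank_oracle(times, events, z, gehan=True), abs=1e-10
        )

    def test_single_event_time_gehan_equals_logrank_p(self):
        times = [1, 1, 1, 1, 2, 2]
        events = [1, 1, 0, 0, 0, 0]
        z = [1, 0, 1, 0, 1, 0]
        _, p_lr = ss.logrank(sdata(times, events, z))
        _, p_wx = ss.gehan_wilcoxon(sdata(times, events, z))
        assert p_wx == pytest.approx(p_lr, abs=1e-12)

    def test_matches_lifelines(self, tied_survival):
        from lifelines.statistics import logrank_test

        times, events, z = tied_survival
        chi2, p = ss.logrank(sdata(times, events, z))
        ref = logrank_test(times[z == 0], times[z == 1], events[z == 0], events[z == 1])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-10)
        assert p == pytest.approx(ref.p_value, rel=1e-10)

    def test_multigroup_matches_lifelines(self, tied_survival):
        from lifelines.statistics import multivariate_logrank_test

        times, events, _ = tied_survival
        labels = np.arange(len(times)) % 3
        chi2, p, df = ss.multigroup_logrank(times, events, labels)
        ref = multivariate_logrank_test(times, labels, events)
        assert df == 2
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_single_group_is_degenerate(self):
        with pytest.raises(ValueError):
            ss.logrank(sdata([1, 2], [1, 1], [1, 1]))

    def test_time_transform_invariance(self, tied_survival):
        times, events, z = tied_survival
        chi2, _ = ss.logrank(sdata(times, events, z))
        chi2w, _ = ss.gehan_wilcoxon(sdata(times, events, z))
        warped = np.exp(times / 3.0)  # strictly monotone warp
        chi2_t, _ = ss.logrank(sdata(warped, events, z))
        chi2w_t, _ = ss.gehan_wilcoxon(sdata(warped, events, z))
        assert chi2_t == pytest.approx(chi2, rel=1e-12)
        assert chi2w_t == pytest.approx(chi2w, rel=1e-12)


# ---------------------------------------------------------------------------
# Cox (binary covariate, Efron ties)


class TestCoxBinary:
    def test_twelve_subject_tied_fixture_matches_grid_oracle(self):
        times = [1, 1, 2, 2, 2, 3, 4, 4, 5, 6, 7, 8]
        events = [1, 1, 1, 0, 1, 1, 1, 0, 1, 1, 0, 1]
        z = [1, 0, 1, 1, 0, 1, 0, 0, 1, 0, 1, 0]
        fit = ss.cox_binary(sdata(times, events, z))
        ref = oracles.efron_grid_argmax(np.array(times, float), np.array(events),
                                        np.array(z))
        assert fit.beta == pytest.approx(ref, abs=1e-4)
        assert fit.hr == pytest.approx(np.exp(fit.beta))

    def test_matches_lifelines_efron(self, tied_survival):
        from lifelines import CoxPHFitter

        times, events, z = tied_survival
        fit = ss.cox_binary(sdata(times, events, z))
        cph = CoxPHFitter()
        cph.fit(pd.DataFrame({"T": times, "E": events, "z": z}), "T", "E")
        assert fit.beta == pytest.approx(cph.params_["z"], abs=1e-6)
        assert fit.se == pytest.approx(cph.standard_errors_["z"], abs=1e-6)
        assert fit.p_wald == pytest.approx(cph.summary.loc["z", "p"], abs=1e-6)

    def test_null_labels_give_unit_hazard_ratio(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(5, 800)
        events = rng.integers(0, 2, 800)
        z = rng.integers(0, 2, 800)
        fit = ss.cox_binary(sdata(times, events, z))
        assert abs(fit.beta) < 3 * fit.se

    def test_recovers_known_log_hazard_ratio(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = rng.integers(0, 2, 2000)
            times = rng.exponential(1.0 / np.exp(np.log(2.0) * z))
            fit = ss.cox_binary(sdata(times, np.ones(2000, int), z))
            hits += 1.8 < fit.hr < 2.2
        assert hits >= 18

    def test_separation_is_capped_and_flagged(self):
        # group-1 deaths all strictly precede every group-0 event
        times = [1, 2, 3, 10, 11, 12]
        events = [1, 1, 1, 1, 1, 1]
        z = [1, 1, 1, 0, 0, 0]
        fit = ss.cox_binary(sdata(times, events, z))
        assert not fit.converged
        assert abs(fit.beta) <= 20.0

    def test_no_events_is_an_error(self):
        with pytest.raises(ValueError, match="events"):
            ss.cox_binary(sdata([1, 2, 3, 4], [0, 0, 0, 0], [0, 1, 0, 1]))

    def test_sign_agrees_with_km_ordering(self):
        rng = np.random.default_rng(9)
        z = rng.integers(0, 2, 400)
        times = rng.exponential(1.0 / np.exp(0.9 * z))
        data = sdata(times, np.ones(400, int), z)
        fit = ss.cox_binary(data)
        km1 = ss.km_estimate(sdata(times[z == 1], np.ones((z == 1).sum(), int)))
        km0 = ss.km_estimate(sdata(times[z == 0], np.ones((z == 0).sum(), int)))
        t = np.median(times)
        below = ss.km_survival_at(km1, t) < ss.km_survival_at(km0, t)
        assert (fit.beta > 0) == below


# ---------------------------------------------------------------------------
# time-dependent ROC


class TestTdRoc:
    def test_perfect_marker_has_unit_auc(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.exponential(5, 50)) + 0.1
        marker = -times  # perfectly ordered with event time
        curve = ss.td_roc(marker, sdata(times, np.ones(50, int)), np.median(times))
        assert curve.auc == pytest.approx(1.0, abs=1e-9)

    def test_constant_marker_is_diagonal(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(5, 40) + 0.1
        curve = ss.td_roc(np.ones(40), sdata(times, np.ones(40, int)),
                          np.median(times))
        assert curve.auc == pytest.approx(0.5, abs=1e-12)

    def test_uncensored_auc_equals_mann_whitney(self):
        rng = np.random.default_rng(12)
        times = rng.exponential(5, 18) + 0.1
        marker = -times + rng.normal(0, 3, 18)
        tau = float(np.median(times))
        curve = ss.td_roc(marker, sdata(times, np.ones(18, int)), tau)
        ref = oracles.mw_auc(marker[times <= tau], marker[times > tau])
        assert curve.auc == pytest.approx(ref, abs=1e-4)

    def test_monotone_marker_transform_invariance(self):
        rng = np.random.default_rng(13)
        times = rng.exponential(5, 60) + 0.1
        events = rng.integers(0, 2, 60)
        events[:10] = 1
        marker = rng.normal(0, 1, 60)
        d = sdata(times, events)
        tau = float(np.median(times))
        a1 = ss.td_roc(marker, d, tau).auc
        a2 = ss.td_roc(np.exp(2 * marker) + 5, d, tau).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_no_cases_or_controls_raises(self):
        with pytest.raises(ValueError, match="cases"):
            ss.td_roc([1, 2, 3], sdata([5, 6, 7], [1, 1, 1]), 1.0)
        with pytest.raises(ValueError, match="controls"):
            ss.td_roc([1, 2, 3], sdata([1, 2, 3], [1, 1, 1]), 10.0)

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(14)
        times = rng.exponential(5, 80) + 0.1
        events = rng.integers(0, 2, 80)
        events[:10] = 1
        curve = ss.td_roc(rng.normal(0, 1, 80), sdata(times, events),
                          float(np.median(times)))
        assert np.all(np.diff(curve.sensitivity) >= 0)
        assert np.all(np.diff(curve.one_minus_specificity) >= 0)


# ---------------------------------------------------------------------------
# t tests


class TestTTests:
    def test_welch_identical_samples(self):
        t, _, p = ss.welch_t([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert t == 0.0 and p == 1.0

    def test_welch_five_vs_five_matches_formulas(self):
        x = [4.1, 5.2, 6.3, 4.8, 5.5]
        y = [3.0, 3.9, 4.4, 3.1, 3.8]
        t, df, p = ss.welch_t(x, y)
        t_ref, df_ref = oracles.welch_oracle(x, y)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert df == pytest.approx(df_ref, abs=1e-10)
        assert 0 < p < 1

    def test_welch_degenerate_zero_variance(self):
        t, _, p = ss.welch_t([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0

    def test_paired_identity_and_shift(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert ss.paired_t(x, x) == (0.0, 1.0)
        t, p = ss.paired_t(x + 2.0, x)
        assert t == pytest.approx(1e6) and p == pytest.approx(0.0)

    def test_paired_eight_pairs_matches_formula(self):
        rng = np.random.default_rng(21)
        x = rng.normal(1, 1, 8)
        y = rng.normal(0, 1, 8)
        t, p = ss.paired_t(x, y)
        assert t == pytest.approx(oracles.paired_oracle(x, y), abs=1e-10)
        assert 0 < p <= 1


@settings(deadline=None, max_examples=30)
@given(
    st.lists(st.integers(1, 6), min_size=6, max_size=16),
    st.randoms(use_true_random=False),
)
def test_all_pvalues_in_unit_interval(raw, rnd):
    """Every test emits p in (0, 1] on arbitrary small censored samples."""
    times = np.array(raw, dtype=float)
    n = len(times)
    events = np.array([rnd.randint(0, 1) for _ in range(n)])
    z = np.array([i % 2 for i in range(n)])
    events[0] = 1
    data = sdata(times, events, z)
    for p in (ss.logrank(data)[1], ss.gehan_wilcoxon(data)[1],
              ss.cox_binary(data).p_wald):
        assert 0 < p <= 1
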