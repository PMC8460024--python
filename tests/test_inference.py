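"""Statistics and permutation engines: conventions, exact small-sample
behaviour, recovery on noiseless fixtures, and reproducibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import proxinet as px
from proxinet.matrices import DyadicMatrix, DayStratifiedNetwork, \
    masked_for_presence
from proxinet.records import HourlyCoforagingTable


class TestPValue:
    def test_no_exceedances_gives_smallest_attainable_p(self):
        null = np.zeros(4999)
        assert px.p_value(null, 1.0, "greater") == pytest.approx(1 / 5000)

    def test_all_exceedances_give_one(self):
        null = np.ones(100) * 5
        assert px.p_value(null, 1.0, "greater") == 1.0

    def test_two_sided_doubles_smaller_tail_capped(self):
        null = np.arange(10)          # draws 0..9
        # observed 9: greater tail (1+1)/11, doubled
        assert px.p_value(null, 9, "two_sided") == pytest.approx(4 / 11)
        assert px.p_value(null, 4.5, "two_sided") == 1.0

    def test_matches_hand_enumeration_on_ten_draws(self):
        null = np.array([3, 1, 4, 1, 5, 9, 2, 6, 5, 3])
        # greater: draws >= 4 are {4,5,9,6,5} -> (1+5)/11
        assert px.p_value(null, 4, "greater") == pytest.approx(6 / 11)
        # less: draws <= 4 are {3,1,4,1,2,3} -> (1+6)/11
        assert px.p_value(null, 4, "less") == pytest.approx(7 / 11)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=50),
           st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_always_in_unit_interval_and_never_zero(self, null, obs):
        for tail in ("greater", "less", "two_sided"):
            p = px.p_value(np.array(null), obs, tail)
            assert 0 < p <= 1


class TestCvStatistic:
    def test_no_variation_gives_zero(self):
        assert px.cv_statistic([2, 2, 2]) == 0.0

    def test_printed_example_with_sample_sd(self):
        # sd([0,0,6], ddof=1) = sqrt(12), mean = 2
        assert px.cv_statistic([0, 0, 6]) == pytest.approx(np.sqrt(12) / 2)
        assert px.cv_statistic([0, 0, 6]) == pytest.approx(1.732, abs=1e-3)

    @given(st.floats(0.01, 100))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        base = np.array([0.0, 1.0, 3.0, 7.0])
        assert px.cv_statistic(base * c) == pytest.approx(
            px.cv_statistic(base))

    def test_zero_mean_signalled_distinctly(self):
        with pytest.raises(px.UndefinedStatisticError):
            px.cv_statistic([0, 0, 0])


class TestICC:
    def test_pure_between_variance_gives_one(self):
        y = [1, 1, 1, 5, 5, 5]
        g = ["a", "a", "a", "b", "b", "b"]
        assert px.icc_unadjusted(y, g).icc == 1.0

    def test_identical_group_means_give_zero(self):
        y = [0, 2, 0, 2, 0, 2]
        g = ["a", "a", "b", "b", "c", "c"]
        assert px.icc_unadjusted(y, g).icc == 0.0

    def test_matches_pingouin_one_way_icc(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        k, n = 12, 6
        y = (np.repeat(rng.normal(0, 2, k), n)
             + rng.normal(0, 1, k * n))
        g = np.repeat(np.arange(k), n)
        df = pd.DataFrame({"targets": g, "raters": np.tile(np.arange(n), k),
                           "ratings": y})
        ref = pingouin.intraclass_corr(df, targets="targets",
                                       raters="raters", ratings="ratings")
        one_way = ref[ref["Type"].isin(["ICC1", "ICC(1,1)"])]
        icc1 = float(one_way["ICC"].iloc[0])
        assert px.icc_unadjusted(y, g).icc == pytest.approx(icc1, abs=1e-9)

    def test_degenerate_groupings_rejected(self):
        with pytest.raises(px.UndefinedStatisticError):
            px.icc_unadjusted([1, 2], ["a", "a"])
        with pytest.raises(px.UndefinedStatisticError):
            px.icc_unadjusted([1, 2, 3], ["a", "b", "c"])


def _random_dyadic(n, seed, role="rate"):
    rng = np.random.default_rng(seed)
    m = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    m[iu, ju] = rng.gamma(2.0, 1.0, iu.size)
    return DyadicMatrix([f"b{i}" for i in range(n)], m + m.T, role=role)


class TestMantel:
    def test_self_correlation_is_one(self):
        a = _random_dyadic(6, 0)
        res = px.mantel_test(a, a, n_perm=99, seed=1)
        assert res.observed_stat == pytest.approx(1.0)
        assert res.p_value <= 2 * (1 / 100) * 2

    def test_r_matches_pearson_on_printed_toy(self):
        a = DyadicMatrix(list("wxyz"), np.array(
            [[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0]],
            dtype=float), role="count")
        b = DyadicMatrix(list("wxyz"), np.array(
            [[0, 2, 1, 4], [2, 0, 3, 7], [1, 3, 0, 5], [4, 7, 5, 0]],
            dtype=float), role="count")
        res = px.mantel_test(a, b, n_perm=49, seed=0)
        r_ref, _ = stats.pearsonr([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 7, 5])
        assert res.observed_stat == pytest.approx(r_ref)

    def test_p_roughly_uniform_under_shuffled_matrices(self):
        rng = np.random.default_rng(9)
        ps = []
        for s in range(60):
            a = _random_dyadic(8, 100 + s)
            perm = rng.permutation(8)
            b = DyadicMatrix(a.ids, a.values[np.ix_(perm, perm)], role="rate")
            ps.append(px.mantel_test(a, b, n_perm=99, seed=s,
                                     tail="greater").p_value)
        assert 0.35 < np.mean(ps) < 0.65


class TestQAP:
    def _noiseless(self, n=8, periods=2, beta=2.0, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"b{i}" for i in range(n)]
        layers, presence = {}, {}
        pred = np.zeros((n, n))
        iu, ju = np.triu_indices(n, 1)
        pred[iu, ju] = rng.uniform(0, 1, iu.size)
        pred = pred + pred.T
        per_layer = pred * (beta / periods)
        for p in range(periods):
            layers[f"n{p}"] = DyadicMatrix(ids, per_layer, role="seconds")
            presence[f"n{p}"] = set(ids)
        resp = DayStratifiedNetwork(periods=list(layers), layers=layers,
                                    presence=presence)
        return resp, DyadicMatrix(ids, pred, role="rate")

    def test_noiseless_recovery_beta_exact_p_at_floor(self):
        resp, pred = self._noiseless(beta=2.0)
        res = px.qap_regression(resp, {"x": pred}, n_perm=199, seed=1)
        assert res.coefficients["x"] == pytest.approx(2.0, abs=1e-10)
        assert res.p_values["x"] == pytest.approx(2 / 200)  # two-sided floor

    def test_dsp_recovers_two_noiseless_betas(self):
        rng = np.random.default_rng(5)
        ids = [f"b{i}" for i in range(9)]
        iu, ju = np.triu_indices(9, 1)
        x1 = np.zeros((9, 9)); x1[iu, ju] = rng.uniform(0, 1, iu.size)
        x2 = np.zeros((9, 9)); x2[iu, ju] = rng.uniform(0, 1, iu.size)
        x1, x2 = x1 + x1.T, x2 + x2.T
        y = 2.0 * x1 + 1.0 * x2
        res = px.qap_regression(
            DyadicMatrix(ids, y, role="seconds"),
            {"x1": DyadicMatrix(ids, x1, role="rate"),
             "x2": DyadicMatrix(ids, x2, role="rate")},
            n_perm=99, seed=2, mode="dsp")
        assert res.coefficients["x1"] == pytest.approx(2.0, abs=1e-10)
        assert res.coefficients["x2"] == pytest.approx(1.0, abs=1e-10)

    def test_collinear_predictors_guarded(self):
        resp, pred = self._noiseless()
        pred2 = DyadicMatrix(pred.ids, pred.values * 2.0, role="rate")
        with pytest.raises(ValueError, match="collinear"):
            px.qap_regression(resp, {"a": pred, "b": pred2}, n_perm=9, seed=0)

    def test_constrained_draws_never_move_absent_bats(self):
        # response with one bat absent in period 2: its dyads must stay
        # missing under every constrained relabelling, so every null fit
        # uses the same dyad count
        ids = [f"b{i}" for i in range(6)]
        rng = np.random.default_rng(0)
        iu, ju = np.triu_indices(6, 1)
        full = np.zeros((6, 6)); full[iu, ju] = rng.uniform(0, 1, iu.size)
        full = full + full.T
        lay1 = DyadicMatrix(ids, full, role="seconds")
        lay2 = masked_for_presence(ids, full, set(ids[:-1]), "seconds")
        resp = DayStratifiedNetwork(
            periods=["a", "b"], layers={"a": lay1, "b": lay2},
            presence={"a": set(ids), "b": set(ids[:-1])})
        pred = _random_dyadic(6, 3)
        res = px.qap_regression(resp, {"x": pred}, n_perm=200, seed=4)
        assert np.isfinite(list(res.null_draws.values())[0]).all()

    def test_identical_seed_identical_nulls(self):
        resp, pred = self._noiseless(seed=3)
        r1 = px.qap_regression(resp, {"x": pred}, n_perm=50, seed=11)
        r2 = px.qap_regression(resp, {"x": pred}, n_perm=50, seed=11)
        assert np.array_equal(r1.null_draws["x"], r2.null_draws["x"])
        assert r1.p_values == r2.p_values


class TestDifferentiation:
    def test_no_freedom_stratum_keeps_records_fixed(self):
        # only two bats outside: every permutation reproduces the data
        records = pd.DataFrame([(1, 13, "a", "b")],
                               columns=["night", "hour", "bat_a", "bat_b"])
        outside = {(1, 13): np.array(["a", "b"]),
                   (1, 14): np.array(["a", "b", "c"])}
        table = HourlyCoforagingTable(ids=["a", "b", "c"], records=records,
                                      outside=outside)
        res = px.differentiation_test(table, n_perm=100, seed=0)
        assert (res.null_draws == res.observed_stat).all()
        assert res.p_value == 1.0

    def test_identical_seed_identical_result(self, true_foraging_table):
        r1 = px.differentiation_test(true_foraging_table, n_perm=100, seed=9)
        r2 = px.differentiation_test(true_foraging_table, n_perm=100, seed=9)
        assert np.array_equal(r1.null_draws, r2.null_draws)
        assert r1.p_value == r2.p_value

    def test_reports_raw_and_centered_statistics(self, true_foraging_table):
        res = px.differentiation_test(true_foraging_table, n_perm=200, seed=1)
        assert res.centered_stat == pytest.approx(
            res.observed_stat - np.median(res.null_draws))


class TestWithinHourPermutation:
    def test_two_bat_hour_is_a_fixed_point(self):
        events = pd.DataFrame([(1, 0, "a", "b")] * 3,
                              columns=["night", "hour", "bat_a", "bat_b"])
        att = pd.DataFrame([(1, 0, "a"), (1, 0, "b")],
                           columns=["night", "hour", "bat"])
        nulls = px.within_hour_identity_permutation(events, att,
                                                    ["a", "b", "c"],
                                                    n_perm=50, seed=0)
        assert (nulls[:, 0, 1] == 3).all()
        assert nulls[:, 0, 2].sum() == 0

    def test_event_participation_marginals_conserved(self):
        events = pd.DataFrame([(1, 0, "a", "b"), (1, 0, "a", "c")],
                              columns=["night", "hour", "bat_a", "bat_b"])
        att = pd.DataFrame([(1, 0, b) for b in "abcd"],
                           columns=["night", "hour", "bat"])
        nulls = px.within_hour_identity_permutation(events, att,
                                                    list("abcd"),
                                                    n_perm=200, seed=1)
        # each event contributes one symmetric pair of entries per draw
        assert (nulls.sum(axis=(1, 2)) == 4).all()

    def test_event_naming_unseen_bat_rejected(self):
        events = pd.DataFrame([(1, 0, "a", "z")],
                              columns=["night", "hour", "bat_a", "bat_b"])
        att = pd.DataFrame([(1, 0, "a"), (1, 0, "b")],
                           columns=["night", "hour", "bat"])
        with pytest.raises(ValueError, match="not seen"):
            px.within_hour_identity_permutation(events, att, ["a", "b", "z"],
                                                n_perm=5, seed=0)


class TestDoublePermutation:
    def test_self_predictor_correlates_perfectly(self, small_truth):
        feed = px.simulate_captive_feeding(small_truth, n_nights=30,
                                           hours_per_night=8)
        cap = small_truth.captive_ids()
        # run once to obtain the adjusted matrix, then use it as predictor
        adj, _ = px.double_permutation_test(
            feed.events, feed.attendance,
            DyadicMatrix.zeros(cap, role="rate").__class__(
                cap, small_truth.relationship.subset(cap).values,
                role="rate"),
            n_perm=99, seed=7)
        adj2, res = px.double_permutation_test(
            feed.events, feed.attendance,
            DyadicMatrix(cap, adj.values, role="adjusted"),
            n_perm=99, seed=7)
        assert res.observed_stat == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_constant_predictor_rejected(self, small_truth):
        feed = px.simulate_captive_feeding(small_truth, n_nights=10,
                                           hours_per_night=5)
        cap = small_truth.captive_ids()
        ones = np.ones((len(cap), len(cap))) - np.eye(len(cap))
        with pytest.raises(px.UndefinedStatisticError):
            px.double_permutation_test(feed.events, feed.attendance,
                                       DyadicMatrix(cap, ones, role="rate"),
                                       n_perm=20, seed=0)


class TestCentralityConsistency:
    def test_identical_centralities_slope_one_p_floor(self):
        bats = [f"b{i}" for i in range(8)]
        rng = np.random.default_rng(2)
        x = pd.Series(rng.uniform(1, 5, 8), index=bats)
        rows = [(b, f"n{t}", x[b]) for b in bats for t in range(3)]
        prof = pd.DataFrame(rows, columns=["bat", "period", "degree"])
        res = px.centrality_consistency_test(x, prof, n_perm=199, seed=5)
        assert res.observed_stat == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_reports_center_of_null(self):
        bats = [f"b{i}" for i in range(6)]
        rng = np.random.default_rng(4)
        x = pd.Series(rng.uniform(0, 1, 6), index=bats)
        rows = [(b, f"n{t}", rng.uniform(0, 3)) for b in bats
                for t in range(2)]
        prof = pd.DataFrame(rows, columns=["bat", "period", "degree"])
        res = px.centrality_consistency_test(x, prof, n_perm=99, seed=1)
        assert res.centered_stat == pytest.approx(
            res.observed_stat - np.median(res.null_draws))

    def test_all_missing_rejected(self):
        x = pd.Series([1.0, 2.0], index=["a", "b"])
        prof = pd.DataFrame({"bat": ["a"], "period": ["n1"],
                             "degree": [np.nan]})
        with pytest.raises(px.UndefinedStatisticError):
            px.centrality_consistency_test(x, prof, n_perm=10, seed=0)


class TestDayNightPairedQAP:
    def _nets(self, slopes, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"b{i}" for i in range(8)]
        iu, ju = np.triu_indices(8, 1)
        days, nights = {}, {}
        dp, np_ = [], []
        for d, c in enumerate(slopes):
            x = np.zeros((8, 8)); x[iu, ju] = rng.uniform(0, 1, iu.size)
            x = x + x.T
            days[f"day{d}"] = DyadicMatrix(ids, x, role="rate")
            nights[f"night{d}"] = DyadicMatrix(ids, c * x, role="seconds")
            dp.append(f"day{d}"); np_.append(f"night{d}")
        roost = DayStratifiedNetwork(periods=dp, layers=days,
                                     presence={p: set(ids) for p in dp})
        forage = DayStratifiedNetwork(periods=np_, layers=nights,
                                      presence={p: set(ids) for p in np_})
        return roost, forage

    def test_equal_noiseless_slopes_collapse_ci(self):
        roost, forage = self._nets([0.5, 0.5, 0.5])
        out = px.daynight_paired_qap(roost, forage, n_perm=49, seed=3,
                                     n_boot=500)
        assert np.allclose(out["slopes"], 0.5)
        assert out["ci"] == (pytest.approx(0.5), pytest.approx(0.5))

    def test_bootstrap_ci_matches_enumeration_on_three_days(self):
        roost, forage = self._nets([0.2, 0.5, 0.9])
        out = px.daynight_paired_qap(roost, forage, n_perm=49, seed=1,
                                     n_boot=40_000)
        s = out["slopes"]
        exact = np.array([(s[i] + s[j] + s[k]) / 3
                          for i in range(3) for j in range(3)
                          for k in range(3)])
        lo, hi = np.quantile(exact, [0.025, 0.975])
        # the exact bootstrap distribution has 27 atoms; the MC quantiles
        # must land on (or adjacent to) the exact ones
        atoms = np.unique(np.round(exact, 12))
        gap = np.diff(atoms).max()
        assert abs(out["ci"][0] - lo) <= gap + 1e-9
        assert abs(out["ci"][1] - hi) <= gap + 1e-9

    def test_needs_two_layers(self):
        roost, forage = self._nets([0.5])
        with pytest.raises(ValueError):
            px.daynight_paired_qap(roost, forage, n_perm=9, seed=0)
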