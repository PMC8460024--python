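"""Edge definitions: rates over co-presence, foraging seconds/nights,
hourly co-foraging bins, bout overlap and missing-if-absent degree."""

import numpy as np
import pandas as pd
import pytest

import proxinet as px
from proxinet.matrices import DyadicMatrix, masked_for_presence
from proxinet.networks import (_overlap_seconds, _roost_intervals_by_day)
from proxinet.records import EVENT_COLS, STATION_COLS


def _rate_fixture():
    """Two bats co-present 36,000 s on day 1 with 3,600 s in association."""
    stations = pd.DataFrame([
        ("a", "roost", 0, 36000),
        ("b", "roost", 0, 36000),
    ], columns=STATION_COLS)
    events = pd.DataFrame([
        ("a", "b", 100, 3600, 30.0),
    ], columns=EVENT_COLS)
    return events, stations


class TestRoostingNetwork:
    TH = {"assoc_min_signal": 25.0, "close_min_signal": 50.0}

    def test_rate_is_association_seconds_over_copresence(self):
        events, stations = _rate_fixture()
        net = px.roosting_network(events, stations, ["a", "b"],
                                  n_days=1, thresholds=self.TH)
        assert net.values[0, 1] == pytest.approx(3600 / 36000)

    def test_never_copresent_dyad_is_missing_not_zero(self):
        events, stations = _rate_fixture()
        net = px.roosting_network(events, stations, ["a", "b", "c"],
                                  n_days=1, thresholds=self.TH)
        assert net.missing[0, 2] and net.missing[1, 2]
        assert not net.missing[0, 1]

    def test_close_contact_rates_nested_below_association(self, small_truth,
                                                          full_streams):
        events, stations, _ = full_streams
        ids = small_truth.ids
        assoc = px.roosting_network(events, stations, ids, n_days=5)
        close = px.roosting_network(events, stations, ids,
                                    level="close_contact", n_days=5)
        obs = ~assoc.missing
        assert (close.values[obs] <= assoc.values[obs] + 1e-12).all()

    def test_aggregate_is_copresence_weighted_mean_of_daily_rates(
            self, small_truth, full_streams):
        events, stations, _ = full_streams
        ids = small_truth.ids
        daily = px.roosting_network(events, stations, ids, window="per_day",
                                    n_days=5)
        agg = px.roosting_network(events, stations, ids, window="aggregate",
                                  n_days=5)
        # recompute the co-presence denominators per day
        idx = {b: i for i, b in enumerate(ids)}
        num = np.zeros((len(ids), len(ids)))
        den = np.zeros((len(ids), len(ids)))
        for d in range(1, 6):
            iv = _roost_intervals_by_day(stations, d, 43200)
            lay = daily.layers[f"day{d}"]
            for a in ids:
                for b in ids:
                    if a >= b or a not in iv or b not in iv:
                        continue
                    w = _overlap_seconds(iv[a], iv[b])
                    i, j = idx[a], idx[b]
                    if not lay.missing[i, j]:
                        num[i, j] += w * lay.values[i, j]
                        den[i, j] += w
        obs = den > 0
        assert np.allclose(agg.values[np.triu_indices_from(num, 1)][
            obs[np.triu_indices_from(num, 1)]],
            (num / np.maximum(den, 1))[obs], atol=1e-9)

    def test_unknown_level_rejected(self, full_streams):
        events, stations, _ = full_streams
        with pytest.raises(ValueError):
            px.roosting_network(events, stations, ["a"], level="cuddle")


class TestForagingNetworks:
    EV = pd.DataFrame([
        ("a", "b", 50_000, 1, 30.0),
        ("a", "b", 60_000, 9, 30.0),
        ("a", "c", 86_400 + 50_000, 4, 30.0),
        ("a", "b", 8 * 86_400 + 50_000, 2, 30.0),
    ], columns=EVENT_COLS)

    def test_seconds_are_summed_per_dyad(self):
        net = px.foraging_seconds_network(self.EV, ["a", "b", "c"])
        assert net.values[0, 1] == 12
        assert net.values[0, 2] == 4
        assert net.values[1, 2] == 0

    def test_nights_count_distinct_nights_only(self):
        net = px.foraging_nights_network(self.EV, ["a", "b", "c"], 9)
        assert net.values[0, 1] == 2      # nights 1 and 9
        assert net.values[0, 2] == 1
        assert net.vectorize().max() <= 9

    def test_empty_stream_gives_zero_matrices(self):
        empty = self.EV.iloc[:0]
        assert px.foraging_seconds_network(empty, ["a", "b"]).values.sum() == 0
        assert px.foraging_nights_network(empty, ["a", "b"], 9).values.sum() == 0

    def test_matches_brute_force_tally(self, small_truth, night_streams):
        ev, _, _ = night_streams
        fe = ev[ev["true_context"] == "foraging"]
        net = px.foraging_seconds_network(fe, small_truth.ids)
        idx = {b: i for i, b in enumerate(small_truth.ids)}
        brute = np.zeros_like(net.values)
        for _, r in fe.iterrows():
            i, j = idx[r["bat_a"]], idx[r["bat_b"]]
            brute[i, j] += r["duration_s"]
            brute[j, i] += r["duration_s"]
        assert np.array_equal(net.values, brute)


class TestHourlyCoforaging:
    BOUTS = pd.DataFrame([
        ("a", 1, 50_000, 60_000, False),
        ("b", 1, 50_400, 59_000, False),
    ], columns=["bat", "night", "depart_s", "return_s", "censored"])

    def test_two_meetings_in_one_hour_count_once(self):
        ev = pd.DataFrame([
            ("a", "b", 50_700, 1, 30.0),    # hour 14 (50400-54000)
            ("a", "b", 52_000, 1, 30.0),    # same hour
        ], columns=EVENT_COLS)
        table = px.hourly_coforaging(ev, self.BOUTS)
        assert len(table.records) == 1
        assert table.dyad_totals().loc[("a", "b")] == 1

    def test_hour_boundary_splits_bins(self):
        ev = pd.DataFrame([
            ("a", "b", 53_999, 1, 30.0),
            ("a", "b", 54_001, 1, 30.0),
        ], columns=EVENT_COLS)
        table = px.hourly_coforaging(ev, self.BOUTS)
        assert len(table.records) == 2

    def test_totals_bounded_by_shared_outside_hours(self, night_streams):
        ev, _, bouts = night_streams
        fe = ev[ev["true_context"] == "foraging"]
        table = px.hourly_coforaging(fe, bouts)
        totals = table.dyad_totals()
        shared = table.shared_outside_hours()
        assert (totals <= shared.reindex(totals.index)).all()

    def test_marked_dyads_require_both_outside(self):
        # encounter in an hour (13:00-14:00) that b's bout never overlaps
        ev = pd.DataFrame([("a", "b", 49_000, 1, 30.0)], columns=EVENT_COLS)
        with pytest.raises(ValueError, match="not both outside"):
            px.hourly_coforaging(ev, self.BOUTS)


class TestBoutOverlap:
    def test_identical_and_disjoint_bouts(self):
        bouts = pd.DataFrame([
            ("a", 1, 0, 3600, False),
            ("b", 1, 0, 3600, False),
            ("c", 1, 10_000, 12_000, False),
        ], columns=["bat", "night", "depart_s", "return_s", "censored"])
        m = px.bout_overlap(bouts, ["a", "b", "c"])
        assert m.values[0, 1] == 3600
        assert m.values[0, 2] == 0

    def test_matches_per_second_tally_on_random_bouts(self):
        rng = np.random.default_rng(7)
        rows = []
        for night in (1, 2):
            for b in "abcd":
                d = int(rng.integers(0, 500))
                rows.append((b, night, night * 10_000 + d,
                             night * 10_000 + d + int(rng.integers(1, 800)),
                             False))
        bouts = pd.DataFrame(rows, columns=["bat", "night", "depart_s",
                                            "return_s", "censored"])
        m = px.bout_overlap(bouts, list("abcd"))
        # brute force: per-second outside indicators
        t = np.arange(0, 40_000)
        out = {b: np.zeros(40_000, bool) for b in "abcd"}
        for _, r in bouts.iterrows():
            out[r["bat"]][r["depart_s"]:r["return_s"]] = True
        for i, a in enumerate("abcd"):
            for j, b in enumerate("abcd"):
                if i < j:
                    assert m.values[i, j] == (out[a] & out[b]).sum()


class TestDegreeCentrality:
    def _net(self):
        ids = ["a", "b", "c", "d"]
        l1 = np.zeros((4, 4))
        l1[0, 1] = l1[1, 0] = 5.0
        l1[0, 2] = l1[2, 0] = 1.0
        l2 = np.zeros((4, 4))
        l2[1, 2] = l2[2, 1] = 2.0
        layers = {
            "n1": masked_for_presence(ids, l1, {"a", "b", "c"}, "seconds"),
            "n2": masked_for_presence(ids, l2, {"a", "b", "c", "d"},
                                      "seconds"),
        }
        return px.DayStratifiedNetwork(
            periods=["n1", "n2"], layers=layers,
            presence={"n1": {"a", "b", "c"}, "n2": {"a", "b", "c", "d"}})

    def test_degree_counts_distinct_partners(self):
        prof, mean = px.degree_centrality_profiles(self._net())
        p = prof.set_index(["bat", "period"])["degree"]
        assert p[("a", "n1")] == 2
        assert p[("b", "n1")] == 1

    def test_no_encounters_is_missing_never_zero(self):
        prof, mean = px.degree_centrality_profiles(self._net())
        p = prof.set_index(["bat", "period"])["degree"]
        assert np.isnan(p[("a", "n2")])     # present but no partners
        assert np.isnan(p[("d", "n1")])     # absent that period
        assert np.isnan(mean["d"]) or mean["d"] == 0  # d: only missing
        assert mean["a"] == 2.0             # mean over non-missing = {2}

    def test_mean_skips_missing_periods(self):
        prof, mean = px.degree_centrality_profiles(self._net())
        assert mean["b"] == pytest.approx(1.0)  # degrees {1, 1}
        assert mean["c"] == pytest.approx(1.0)


class TestDyadicMatrix:
    def test_symmetry_and_diagonal_enforced(self):
        with pytest.raises(ValueError):
            DyadicMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DyadicMatrix(["a", "b"], np.array([[1.0, 2.0], [2.0, 0.0]]))

    def test_negative_values_only_for_adjusted_role(self):
        vals = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError):
            DyadicMatrix(["a", "b"], vals, role="count")
        m = DyadicMatrix(["a", "b"], vals, role="adjusted")
        assert m.values[0, 1] == -1.0

    def test_cofeeding_network_symmetric_and_tallies(self):
        ev = pd.DataFrame([(1, 0, "a", "b"), (1, 1, "a", "b"),
                           (2, 0, "b", "c")],
                          columns=["night", "hour", "bat_a", "bat_b"])
        m = px.cofeeding_network(ev, ["a", "b", "c"])
        assert m.values[0, 1] == 2
        assert m.values[1, 2] == 1
        assert np.array_equal(m.values, m.values.T)
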