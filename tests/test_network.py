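"""Social network module: filtering, tallying, adjusted SRI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micetrans import network
from micetrans.network import (AliveWindows, AssociationTally, adjusted_sri,
                               build_network, filter_detections, tally_pair)

from conftest import scripted_detections


def det(ind, logger, ts):
    return (ind, logger, ts)


class TestFilterDetections:
    def test_noon_record_dropped(self):
        df = scripted_detections([det("A", "L1", "2019-03-01 12:00:00")])
        assert len(filter_detections(df)) == 0

    def test_unique_minute_dedup(self):
        df = scripted_detections([
            det("A", "L1", "2019-03-01 23:10:05"),
            det("A", "L1", "2019-03-01 23:10:40"),
        ])
        assert len(filter_detections(df)) == 1

    def test_night_index_after_midnight(self):
        df = scripted_detections([det("A", "L1", "2019-03-02 02:00:00")])
        out = filter_detections(df)
        assert out["night"].iloc[0] == pd.Timestamp("2019-03-01")

    def test_window_boundaries(self):
        df = scripted_detections([
            det("A", "L1", "2019-03-01 16:00:00"),  # kept: start inclusive
            det("B", "L1", "2019-03-01 08:00:00"),  # dropped: end exclusive
            det("C", "L1", "2019-03-01 07:59:59"),  # kept
        ])
        out = filter_detections(df)
        assert set(out["individual"]) == {"A", "C"}

    def test_unparseable_timestamp_reports_row(self):
        df = pd.DataFrame({"individual": ["A", "B"], "logger": ["L1", "L1"],
                           "timestamp": ["2019-03-01 20:00:00", "not-a-date"]})
        with pytest.raises(network.DetectionParseError) as exc:
            filter_detections(df)
        assert exc.value.row == 1

    def test_different_loggers_not_deduplicated(self):
        df = scripted_detections([
            det("A", "L1", "2019-03-01 23:10:05"),
            det("A", "L2", "2019-03-01 23:10:40"),
        ])
        assert len(filter_detections(df)) == 2


class TestAdjustedSri:
    def test_zero_x(self):
        assert adjusted_sri(AssociationTally(0, 0, 2, 3)) == 0.0

    def test_always_together(self):
        assert adjusted_sri(AssociationTally(5, 0, 0, 0)) == 1.0

    def test_arithmetic(self):
        assert adjusted_sri(AssociationTally(2, 1, 3, 2)) == 0.25

    def test_empty_denominator(self):
        assert adjusted_sri(AssociationTally(0, 0, 0, 0)) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            AssociationTally(-1, 0, 0, 0)

    @given(x=st.integers(0, 50), y_ab=st.integers(0, 50),
           y_a=st.integers(0, 50), y_b=st.integers(0, 50))
    def test_range_and_monotonicity(self, x, y_ab, y_a, y_b):
        s = adjusted_sri(AssociationTally(x, y_ab, y_a, y_b))
        assert 0.0 <= s <= 1.0
        s_up = adjusted_sri(AssociationTally(x + 1, y_ab, y_a, y_b))
        assert s_up >= s
        s_down = adjusted_sri(AssociationTally(x, y_ab + 1, y_a, y_b))
        if x > 0:
            assert s_down < s


class TestTallyPair:
    def alive(self, *inds, first="2019-03-01", last="2019-03-10"):
        return AliveWindows({i: (pd.Timestamp(first), pd.Timestamp(last))
                             for i in inds})

    def test_same_logger_one_hour_apart(self):
        df = filter_detections(scripted_detections([
            det("A", "L1", "2019-03-01 20:00:00"),
            det("B", "L1", "2019-03-01 21:00:00"),
        ]))
        alive = self.alive("A", "B", last="2019-03-01")
        t = tally_pair(df, alive, "A", "B")
        assert (t.x, t.y_ab, t.y_a, t.y_b) == (1, 0, 0, 0)

    def test_different_loggers_broad_mode(self):
        # D1: both observed, never same-logger => y_AB in broad mode
        df = filter_detections(scripted_detections([
            det("A", "L1", "2019-03-01 18:00:00"),
            det("B", "L2", "2019-03-01 18:00:00"),
        ]))
        alive = self.alive("A", "B", last="2019-03-01")
        t = tally_pair(df, alive, "A", "B")
        assert (t.x, t.y_ab) == (0, 1)
        t_narrow = tally_pair(df, alive, "A", "B", mode="narrow")
        assert (t_narrow.x, t_narrow.y_ab) == (0, 0)

    def test_only_a_observed(self):
        rows = [det("A", "L1", f"2019-03-{d:02d} 20:00:00") for d in (1, 2, 3)]
        df = filter_detections(scripted_detections(rows))
        alive = self.alive("A", "B", last="2019-03-03")
        t = tally_pair(df, alive, "A", "B")
        assert (t.x, t.y_ab, t.y_a, t.y_b) == (0, 0, 3, 0)

    def test_disjoint_alive_windows_zero(self):
        df = filter_detections(scripted_detections([
            det("A", "L1", "2019-03-01 20:00:00"),
            det("B", "L1", "2019-03-05 20:00:00"),
        ]))
        alive = AliveWindows({"A": (pd.Timestamp("2019-03-01"),) * 2,
                              "B": (pd.Timestamp("2019-03-05"),) * 2})
        t = tally_pair(df, alive, "A", "B")
        assert (t.x, t.y_ab, t.y_a, t.y_b) == (0, 0, 0, 0)

    def test_over_12h_same_logger_not_associated(self):
        df = filter_detections(scripted_detections([
            det("A", "L1", "2019-03-01 16:30:00"),
            det("B", "L1", "2019-03-02 07:30:00"),  # same night, 15 h apart
        ]))
        alive = self.alive("A", "B", last="2019-03-02")
        t = tally_pair(df, alive, "A", "B")
        assert t.x == 0
        assert t.y_ab == 1


def brute_force_network(filtered, alive, window_h=12.0):
    """Independent oracle: enumerate every night and classify it per pair."""
    ids = sorted(alive.individuals)
    nights = pd.date_range(min(w[0] for w in alive.windows.values()),
                           max(w[1] for w in alive.windows.values()), freq="D")
    n = len(ids)
    sri = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ids[i], ids[j]
            x = y_ab = y_a = y_b = 0
            for night in nights:
                if not (alive.alive_on(a, night) and alive.alive_on(b, night)):
                    continue
                da = filtered[(filtered["individual"] == a) & (filtered["night"] == night)]
                db = filtered[(filtered["individual"] == b) & (filtered["night"] == night)]
                if len(da) and len(db):
                    assoc = any(
                        ra["logger"] == rb["logger"]
                        and abs((ra["timestamp"] - rb["timestamp"]).total_seconds())
                        <= window_h * 3600
                        for _, ra in da.iterrows() for _, rb in db.iterrows())
                    if assoc:
                        x += 1
                    else:
                        y_ab += 1
                elif len(da):
                    y_a += 1
                elif len(db):
                    y_b += 1
            denom = x + y_ab + y_a + y_b
            sri[i, j] = sri[j, i] = x / denom if denom else 0.0
    return ids, sri


class TestBuildNetwork:
    def test_single_mouse(self):
        df = filter_detections(scripted_detections(
            [det("A", "L1", "2019-03-01 20:00:00")]))
        net = build_network(df)
        assert net.ids == ["A"]
        assert net.sri.shape == (1, 1) and net.sri[0, 0] == 0.0

    def test_empty_table_warns(self, caplog):
        net = build_network(pd.DataFrame(
            columns=["individual", "logger", "timestamp", "night"]))
        assert net.sri.shape == (0, 0)

    def test_codetected_every_night(self):
        rows = []
        for d in range(1, 6):
            rows += [det("A", "L1", f"2019-03-{d:02d} 20:00:00"),
                     det("B", "L1", f"2019-03-{d:02d} 20:30:00")]
        df = filter_detections(scripted_detections(rows))
        net = build_network(df)
        assert net.value("A", "B") == 1.0

    def test_matches_bruteforce_oracle_scripted(self, rng):
        ids, sri = self._random_case(rng, n_mice=5, n_nights=8)

    def _random_case(self, rng, n_mice=5, n_nights=8, n_loggers=3):
        mice = [f"m{k}" for k in range(n_mice)]
        rows = []
        for night in range(n_nights):
            date = pd.Timestamp("2019-03-01") + pd.Timedelta(days=night)
            for m in mice:
                for _ in range(rng.poisson(1.2)):
                    lg = f"L{rng.integers(n_loggers)}"
                    secs = float(rng.uniform(0, 16 * 3600))
                    ts = date + pd.Timedelta(hours=16) + pd.Timedelta(seconds=secs)
                    rows.append((m, lg, str(ts)))
        if not rows:
            return None, None
        df = filter_detections(scripted_detections(rows))
        alive = AliveWindows({m: (pd.Timestamp("2019-03-01"),
                                  pd.Timestamp("2019-03-01") + pd.Timedelta(days=n_nights - 1))
                              for m in mice})
        net = build_network(df, alive)
        oids, osri = brute_force_network(df, alive)
        assert net.ids == oids
        np.testing.assert_allclose(net.sri, osri, atol=1e-12)
        return oids, osri

    def test_dead_nights_do_not_change_sri(self, rng):
        # appending detections outside both alive windows leaves SRI unchanged
        rows = [det("A", "L1", "2019-03-01 20:00:00"),
                det("B", "L1", "2019-03-01 21:00:00"),
                det("A", "L1", "2019-03-02 20:00:00")]
        alive = AliveWindows({"A": (pd.Timestamp("2019-03-01"), pd.Timestamp("2019-03-02")),
                              "B": (pd.Timestamp("2019-03-01"), pd.Timestamp("2019-03-02"))})
        base = build_network(filter_detections(scripted_detections(rows)), alive)
        rows_extra = rows + [det("A", "L1", "2019-03-20 20:00:00"),
                             det("B", "L1", "2019-03-20 20:10:00")]
        extra = build_network(filter_detections(scripted_detections(rows_extra)), alive)
        assert base.value("A", "B") == extra.value("A", "B")

    def test_shared_lifetime_equals_classic_sri(self, rng):
        # with one common alive window the adjusted SRI equals the classic
        # simple ratio index X / (X + yAB + yA + yB) from naive counting
        for _ in range(3):
            self._random_case(rng)

    def test_seasonal_split_halves(self):
        rows = [det("A", "L1", f"2019-{m:02d}-10 20:00:00") for m in (2, 5, 8, 11)]
        df = filter_detections(scripted_detections(rows))
        wins = network.season_windows(df)
        assert wins["spring"][0] == df["night"].min()
        assert wins["autumn"][1] == df["night"].max()
        assert wins["spring"][1] < wins["autumn"][0]


class TestAliveWindows:
    def test_from_detections(self):
        df = filter_detections(scripted_detections([
            det("A", "L1", "2019-03-01 20:00:00"),
            det("A", "L1", "2019-03-05 20:00:00")]))
        aw = AliveWindows.from_detections(df)
        assert aw.windows["A"] == (pd.Timestamp("2019-03-01"), pd.Timestamp("2019-03-05"))

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            AliveWindows({"A": (pd.Timestamp("2019-03-05"), pd.Timestamp("2019-03-01"))})
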