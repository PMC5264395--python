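"""Survey-table ingestion, the 30-min independence filter, occasion binning,
effort and encounter-array construction."""

import warnings
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carnidens.survey import (EncounterData, TelemetryData, bin_occasions,
                              build_behavior_matrix, build_effort,
                              build_encounter_data, filter_independent_events,
                              n_events, read_device_table, read_event_table,
                              read_marks_table)
from conftest import make_events


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadDeviceTable:
    def test_two_row_tt_covariate(self, tmp_path):
        p = _write(tmp_path, "devices.csv",
                   "device_id,x,y,class,active_from,active_to\n"
                   "c1,0,0,camera,2013-01-15,2013-02-11\n"
                   "t1,100,0,trap,2013-01-15,2013-02-11\n")
        dev = read_device_table(p)
        assert list(dev.tt) == [1.0, 0.0]
        assert dev.n_days == 28

    def test_downtime_ranges(self, tmp_path):
        p = _write(tmp_path, "devices.csv",
                   "device_id,x,y,class,active_from,active_to,downtime_ranges\n"
                   "c1,0,0,camera,2013-01-15,2013-01-28,"
                   "2013-01-18:2013-01-20\n")
        dev = read_device_table(p)
        assert dev.operation.sum() == 14 - 3
        assert not dev.operation[0, 3:6].any()

    def test_duplicate_device_id(self, tmp_path):
        p = _write(tmp_path, "devices.csv",
                   "device_id,x,y,class,active_from,active_to\n"
                   "c1,0,0,camera,2013-01-15,2013-01-20\n"
                   "c1,5,5,trap,2013-01-15,2013-01-20\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_device_table(p)

    def test_empty_file(self, tmp_path):
        with pytest.raises(ValueError, match="no devices"):
            read_device_table(_write(tmp_path, "d.csv", ""))

    def test_bad_coordinates_and_class(self, tmp_path):
        p = _write(tmp_path, "devices.csv",
                   "device_id,x,y,class,active_from,active_to\n"
                   "c1,abc,0,camera,2013-01-15,2013-01-20\n")
        with pytest.raises(ValueError, match="coordinates"):
            read_device_table(p)
        p = _write(tmp_path, "devices2.csv",
                   "device_id,x,y,class,active_from,active_to\n"
                   "c1,0,0,drone,2013-01-15,2013-01-20\n")
        with pytest.raises(ValueError, match="device_class"):
            read_device_table(p)


class TestIndependenceFilter:
    def test_single_picture(self):
        ev = make_events([("c1", "2013-01-16 10:00", "fox", "f1", True, 1)])
        assert len(filter_independent_events(ev)) == 1

    def test_thirty_minute_window_keep_first(self):
        ev = make_events([
            ("c1", "2013-01-16 10:00", "fox", None, False, 1),
            ("c1", "2013-01-16 10:15", "fox", None, False, 1),
            ("c1", "2013-01-16 10:45", "fox", None, False, 1),
        ])
        out = filter_independent_events(ev)
        # 10:15 is within 30 min of 10:00; 10:45 is 45 min after it
        assert list(out["timestamp"].dt.strftime("%H:%M")) == ["10:00", "10:45"]

    def test_exactly_thirty_minutes_is_dropped(self):
        ev = make_events([
            ("c1", "2013-01-16 10:00", "fox", None, False, 1),
            ("c1", "2013-01-16 10:30", "fox", None, False, 1),
        ])
        assert len(filter_independent_events(ev)) == 1

    def test_multi_animal_picture_counts_two_events(self):
        ev = make_events([("c1", "2013-01-16 10:00", "fox", None, False, 2)])
        out = filter_independent_events(ev)
        assert n_events(out) == 2

    def test_streams_are_independent(self):
        # same device+time: different individuals and species do not collide
        ev = make_events([
            ("c1", "2013-01-16 10:00", "fox", "f1", True, 1),
            ("c1", "2013-01-16 10:10", "fox", "f2", True, 1),
            ("c1", "2013-01-16 10:12", "genet", None, False, 1),
            ("c2", "2013-01-16 10:14", "fox", "f1", True, 1),
        ])
        assert len(filter_independent_events(ev)) == 4

    def test_empty_input(self):
        ev = make_events([])
        assert filter_independent_events(ev).empty

    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 1),
                              st.integers(0, 5000)), max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_idempotent(self, raw):
        rows = [(f"c{d}", pd.Timestamp("2013-01-16") + pd.Timedelta(minutes=m),
                 "fox", f"f{i}" if i else None, bool(i), 1)
                for d, i, m in raw]
        ev = make_events(rows)
        once = filter_independent_events(ev)
        twice = filter_independent_events(once)
        pd.testing.assert_frame_equal(once, twice)


class TestOccasionGrid:
    @pytest.mark.parametrize("days,length,expected",
                             [(98, 7, 14), (7, 7, 1), (10, 7, 2), (1, 7, 1)])
    def test_binning(self, days, length, expected):
        assert bin_occasions(days, length).n_occasions == expected

    def test_short_final_occasion(self):
        grid = bin_occasions(10, 7)
        assert len(grid.occasion_days(1)) == 3

    @pytest.mark.parametrize("days,length", [(0, 7), (10, 0), (-5, 7)])
    def test_invalid(self, days, length):
        with pytest.raises(ValueError):
            bin_occasions(days, length)

    def test_occasion_of_day(self):
        grid = bin_occasions(98, 7)
        assert grid.occasion_of_day(0) == 0
        assert grid.occasion_of_day(97) == 13
        with pytest.raises(ValueError):
            grid.occasion_of_day(98)

    def test_t_covariate_standardised(self):
        t = bin_occasions(98, 7).t_covariate
        assert t.mean() == pytest.approx(0.0, abs=1e-12)
        assert t.std() == pytest.approx(1.0, abs=1e-12)


class TestEffort:
    def test_always_on_device(self, mini_devices, mini_grid):
        e = build_effort(mini_devices, mini_grid).e
        assert e.shape == (4, 4)
        assert (e == 7).all()

    def test_downtime_counted(self, mini_devices, mini_grid):
        mini_devices.operation[0, 0:3] = False     # off days 1-3 of occasion 1
        e = build_effort(mini_devices, mini_grid).e
        assert e[0, 0] == 4
        assert e[0, 1:].sum() == 21

    def test_all_off_device_warns(self, mini_devices, mini_grid):
        mini_devices.operation[3, :] = False
        with pytest.warns(UserWarning, match="never operative"):
            e = build_effort(mini_devices, mini_grid).e
        assert (e[3] == 0).all()


class TestEncounterData:
    def test_marked_counts_accumulate(self, mini_devices, mini_grid):
        ev = make_events([
            ("trap0", "2013-01-23 08:00", "fox", "f1", True, 1),
            ("trap0", "2013-01-24 09:00", "fox", "f1", True, 1),
            ("cam1", "2013-02-05 01:00", "fox", None, False, 5),
        ])
        marks = pd.DataFrame({"individual_id": ["f1"], "species": ["fox"],
                              "mark_date": [date(2013, 1, 15)],
                              "removal_date": [pd.NaT]})
        enc = build_encounter_data(ev, mini_devices, mini_grid, marks, "SMR")
        assert enc.y[0, 2, 1] == 2          # f1 at trap0 in occasion 2
        assert enc.n[1, 3] == 5             # 5 unmarked events at cam1
        assert enc.total_events() == 7

    def test_removal_convention(self, mini_devices, mini_grid, tmp_path):
        # removal on day 17 (occasion 3 of 4, 0-based k=2): at risk through
        # k=2, dead from k=3 on
        marks = _write(tmp_path, "marks.csv",
                       "individual_id,species,mark_date,removal_date\n"
                       "f1,fox,2013-01-15,2013-01-31\n")
        ev = make_events([("trap0", "2013-01-31 07:00", "fox", "f1", True, 1)])
        enc = build_encounter_data(ev, mini_devices, mini_grid,
                                   read_marks_table(marks), "SMR")
        assert list(enc.dead[0]) == [0, 0, 0, 1]
        assert enc.y[0, 2, 2] == 1

    def test_event_after_removal_is_error(self, mini_devices, mini_grid,
                                          tmp_path):
        marks = _write(tmp_path, "marks.csv",
                       "individual_id,species,mark_date,removal_date\n"
                       "f1,fox,2013-01-15,2013-01-31\n")
        ev = make_events([("cam0", "2013-02-08 07:00", "fox", "f1", True, 1)])
        with pytest.raises(ValueError, match="after removal"):
            build_encounter_data(ev, mini_devices, mini_grid,
                                 read_marks_table(marks), "SMR")

    def test_unlisted_device_is_error(self, mini_devices, mini_grid):
        ev = make_events([("nope", "2013-01-16 07:00", "fox", None, False, 1)])
        with pytest.raises(ValueError, match="unlisted device"):
            build_encounter_data(ev, mini_devices, mini_grid, None, "SC")

    def test_sc_collapses_identity(self, mini_devices, mini_grid):
        ev = make_events([
            ("cam0", "2013-01-16 07:00", "mongoose", "m1", True, 1),
            ("cam0", "2013-01-16 09:00", "mongoose", None, False, 1),
        ])
        enc = build_encounter_data(ev, mini_devices, mini_grid, None, "SC")
        assert enc.n_identified == 0
        assert enc.n.sum() == 2

    def test_counts_on_zero_effort_rejected(self, mini_devices, mini_grid):
        y = np.zeros((1, 4, 4), np.int64)
        y[0, 0, 0] = 1
        eff = np.full((4, 4), 7.0)
        eff[0, 0] = 0.0
        with pytest.raises(ValueError, match="effort is zero"):
            EncounterData(model_class="SCR", y=y,
                          n=np.zeros((4, 4), np.int64),
                          dead=np.zeros((1, 4), np.int8),
                          Lb=np.zeros((1, 4), np.int8),
                          tt=mini_devices.tt, t=mini_grid.t_covariate,
                          effort=eff, device_xy=mini_devices.xy,
                          individual_ids=["f1"])

    def test_event_table_reader_validates_window(self, mini_devices, tmp_path):
        p = _write(tmp_path, "events.csv",
                   "device_id,timestamp,species,individual_id,marked,n_animals\n"
                   "cam0,2014-06-01T10:00:00,fox,,False,1\n")
        with pytest.raises(ValueError, match="outside survey window"):
            read_event_table(p, mini_devices)


class TestBehaviorMatrix:
    def _enc(self, y, mini_devices, mini_grid):
        m = y.shape[0]
        return EncounterData(model_class="SCR", y=y,
                             n=np.zeros((4, 4), np.int64),
                             dead=np.zeros((m, 4), np.int8),
                             Lb=np.zeros((m, 4), np.int8),
                             tt=mini_devices.tt, t=mini_grid.t_covariate,
                             effort=np.full((4, 4), 7.0),
                             device_xy=mini_devices.xy,
                             individual_ids=[f"i{r}" for r in range(m)])

    def test_first_capture_in_second_occasion(self, mini_devices, mini_grid):
        y = np.zeros((2, 4, 4), np.int64)
        y[0, 1, 1] = 1                          # first capture at k=1
        Lb = build_behavior_matrix(self._enc(y, mini_devices, mini_grid))
        assert list(Lb[0]) == [0, 0, 1, 1]
        assert list(Lb[1]) == [0, 0, 0, 0]      # never captured

    def test_no_prior_session_on_first_occasion(self, mini_devices, mini_grid):
        y = np.zeros((3, 4, 4), np.int64)
        y[:, 0, 0] = 2
        Lb = build_behavior_matrix(self._enc(y, mini_devices, mini_grid))
        assert (Lb[:, 0] == 0).all()

    def test_monotone_along_occasions(self, mini_devices, mini_grid):
        rng = np.random.default_rng(3)
        y = rng.poisson(0.3, size=(5, 4, 4)).astype(np.int64)
        Lb = build_behavior_matrix(self._enc(y, mini_devices, mini_grid))
        assert (np.diff(Lb.astype(int), axis=1) >= 0).all()

    def test_sc_is_error(self, mini_devices, mini_grid):
        enc = EncounterData(model_class="SC",
                            y=np.zeros((0, 4, 4), np.int64),
                            n=np.zeros((4, 4), np.int64),
                            dead=np.zeros((0, 4), np.int8),
                            Lb=np.zeros((0, 4), np.int8),
                            tt=mini_devices.tt, t=mini_grid.t_covariate,
                            effort=np.full((4, 4), 7.0),
                            device_xy=mini_devices.xy)
        with pytest.raises(ValueError, match="identified individuals"):
            build_behavior_matrix(enc)


class TestTelemetryData:
    def test_warns_below_25_locations(self):
        with pytest.warns(UserWarning, match="25"):
            TelemetryData("b1", np.zeros((5, 2)))

    def test_quiet_at_25(self):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            TelemetryData("b1", np.zeros((25, 2)))
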