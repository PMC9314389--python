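import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import quollscr as q
from quollscr.exceptions import RowError, SchemaError

from conftest import make_nonid, make_record


class TestDetectionTable:
    def test_well_formed_file_reads_in_station_time_order(self, tmp_path):
        recs = [
            make_record(station="c2", ts="2020-07-01 20:00:00"),
            make_record(station="c1", ts="2020-07-02 20:00:00", individual="q2"),
            make_record(station="c1", ts="2020-07-01 20:00:00", individual="q2"),
        ]
        path = q.write_detection_table(recs, tmp_path / "d.csv")
        out = q.read_detection_table(path)
        assert len(out) == 3
        keys = [(r.station_id, r.timestamp) for r in out]
        assert keys == sorted(keys)

    def test_misnamed_column_raises_schema_error(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "station_id,individ,timestamp,profile_class\n"
            "c1,q1,2020-07-01T20:00:00,complete\n"
        )
        with pytest.raises(SchemaError, match="individual_id"):
            q.read_detection_table(p)

    def test_bad_timestamp_reports_line_number(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "station_id,individual_id,timestamp,profile_class\n"
            "c1,q1,2020-07-01T20:00:00,complete\n"
            "c1,q1,not-a-time,complete\n"
        )
        with pytest.raises(RowError, match="line 3"):
            q.read_detection_table(p)

    def test_exact_duplicate_rows_collapsed_with_warning(self, tmp_path):
        row = "c1,q1,2020-07-01T20:00:00,10,complete\n"
        p = tmp_path / "d.csv"
        p.write_text(
            "station_id,individual_id,timestamp,n_images,profile_class\n" + row * 3
        )
        with pytest.warns(UserWarning, match="duplicate"):
            out = q.read_detection_table(p)
        assert len(out) == 1

    def test_simulator_output_round_trips(self, tmp_path):
        cfg = q.SimulationConfig(seed=11, non_identifiable_fraction=0.1,
                                 semi_profile_fraction=0.2)
        det_csv, lay_csv = q.simulate_raw_stream(cfg, tmp_path)
        recs = q.read_detection_table(det_csv)
        assert recs  # non-empty at the default design
        path2 = q.write_detection_table(recs, tmp_path / "again.csv")
        assert q.read_detection_table(path2) == recs
        layout = q.read_detector_layout(lay_csv)
        assert layout.station_ids == cfg.detectors.station_ids
        np.testing.assert_allclose(layout.xy, cfg.detectors.xy)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        rows=st.lists(
            st.tuples(
                st.sampled_from(["s1", "s2", "s3"]),
                st.integers(min_value=0, max_value=10_000),
                st.sampled_from(["complete", "semi_left", "semi_right", None]),
                st.integers(min_value=1, max_value=30),
            ),
            min_size=1, max_size=30, unique=True,
        )
    )
    def test_round_trip_preserves_all_fields(self, tmp_path_factory, rows):
        base = pd.Timestamp("2020-07-01 12:00:00")
        recs = []
        for station, secs, profile, n_img in rows:
            if profile is None:
                recs.append(q.DetectionRecord(station, None, base + pd.Timedelta(seconds=secs),
                                              "non_identifiable", n_img))
            else:
                recs.append(q.DetectionRecord(station, f"q{secs % 7}",
                                              base + pd.Timedelta(seconds=secs),
                                              profile, n_img))
        tmp = tmp_path_factory.mktemp("rt") / "d.csv"
        q.write_detection_table(recs, tmp)
        out = q.read_detection_table(tmp)
        key = lambda r: (r.station_id, r.timestamp, str(r.individual_id),
                         r.profile_class, r.n_images)
        assert sorted(out, key=key) == sorted(recs, key=key)


class TestDetectorLayout:
    def test_grid_layout(self, tmp_path, grid25):
        p = q.write_detector_layout(grid25, tmp_path / "lay.csv")
        arr = q.read_detector_layout(p)
        assert arr.n == 25
        assert arr.nearest_neighbour_distances().min() == pytest.approx(500.0)

    def test_single_station_is_valid(self, tmp_path):
        p = tmp_path / "lay.csv"
        p.write_text("station_id,x,y\nc1,0,0\n")
        assert q.read_detector_layout(p).n == 1

    def test_duplicate_station_id_rejected(self, tmp_path):
        p = tmp_path / "lay.csv"
        p.write_text("station_id,x,y\nC07,0,0\nC07,500,0\n")
        with pytest.raises(SchemaError, match="C07"):
            q.read_detector_layout(p)

    def test_non_numeric_coordinate_rejected(self, tmp_path):
        p = tmp_path / "lay.csv"
        p.write_text("station_id,x,y\nc1,east,0\n")
        with pytest.raises(RowError):
            q.read_detector_layout(p)


class TestCaptureFile:
    def test_single_detection_row(self, tmp_path, pair_detectors):
        inc = np.zeros((1, 5, 2), dtype=int)
        inc[0, 2, 0] = 1  # occasion 3 at detector "a"
        ch = q.CaptHist(["q1"], ["a", "b"], inc)
        p = q.export_capture_file(ch, pair_detectors, tmp_path / "cap.txt")
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert lines == ["1 q1 3 a"]

    def test_round_trip_preserves_incidence(self, tmp_path, grid25):
        ch, _ = q.simulate_capthist(q.SimulationConfig(seed=3))
        p = q.export_capture_file(ch, grid25, tmp_path / "cap.txt")
        back = q.import_capture_file(p, n_occasions=ch.n_occasions)
        assert back == q.CaptHist(ch.individuals, ch.detector_ids, ch.incidence)

    def test_empty_capthist_writes_header_only(self, tmp_path, pair_detectors):
        ch = q.CaptHist([], ["a", "b"], np.zeros((0, 3, 2), dtype=int))
        with pytest.warns(UserWarning, match="zero individuals"):
            p = q.export_capture_file(ch, pair_detectors, tmp_path / "cap.txt")
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")
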