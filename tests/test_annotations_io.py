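import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from howlloc.annotations_io import (
    Recorder,
    build_howl_observations,
    group_events,
    parse_recording_start,
    parse_timestamp,
    read_deployment,
    read_raven_selection_table,
    read_salient_points,
    write_deployment,
)
from conftest import recorder_at


class TestFilenameTimestamps:
    def test_default_token_parses(self):
        t = parse_recording_start("CAR01_20210902_223835.wav")
        assert t == parse_timestamp("2021-09-02T22:38:35")

    def test_offset_added_to_start(self):
        start = parse_recording_start("CAR01_20210902_223835.wav")
        assert start + 12.34 == pytest.approx(
            parse_timestamp("2021-09-02T22:38:35") + 12.34
        )

    def test_unparseable_filename_names_pattern(self):
        with pytest.raises(ValueError, match="20210902_223835"):
            parse_recording_start("notes.txt")

    def test_custom_pattern(self):
        t = parse_recording_start(
            "rec-20210831-202905.flac", pattern=r"(?P<date>\d{8})-(?P<time>\d{6})"
        )
        assert t == parse_timestamp("2021-08-31T20:29:05")


@pytest.fixture
def deployment_csv(tmp_path):
    path = tmp_path / "dep.csv"
    path.write_text(
        textwrap.dedent(
            """\
            site_id,lat,lon,active_from,active_to
            11,46.1440,21.1950,2021-08-31T00:00:00,2021-09-07T00:00:00
            13,46.1500,21.1900,2021-08-31T00:00:00,2021-09-07T00:00:00
            14,46.1460,21.1840,2021-08-31T00:00:00,2021-09-07T00:00:00
            """
        )
    )
    return path


class TestDeploymentIO:
    def test_read_deployment(self, deployment_csv):
        recs = read_deployment(deployment_csv)
        assert [r.site_id for r in recs] == ["11", "13", "14"]
        assert recs[0].position.lat == 46.1440
        assert recs[0].active_at(parse_timestamp("2021-09-02T22:00:00"))
        assert not recs[0].active_at(parse_timestamp("2021-09-08T00:00:00"))

    def test_duplicate_site_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "site_id,lat,lon,active_from,active_to\n"
            "1,46.1,21.1,2021-08-31T00:00:00,2021-09-07T00:00:00\n"
            "1,46.2,21.2,2021-08-31T00:00:00,2021-09-07T00:00:00\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_deployment(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("site_id,lat\n1,46.1\n")
        with pytest.raises(ValueError, match="lon"):
            read_deployment(p)

    def test_write_read_round_trip(self, tmp_path, deployment_csv):
        recs = read_deployment(deployment_csv)
        out = tmp_path / "out.csv"
        write_deployment(recs, out)
        again = read_deployment(out)
        assert again == recs

    def test_inverted_interval_rejected(self):
        from howlloc.geodesy import GeoPoint

        with pytest.raises(ValueError, match="active_from"):
            Recorder("x", GeoPoint(46.1, 21.1), 100.0, 50.0)


class TestSalientPointIO:
    def test_absolute_time_layout(self, tmp_path, deployment_csv):
        p = tmp_path / "sal.csv"
        p.write_text(
            "event_id,howl_id,site_id,arrival_time_iso\n"
            "e1,h1,11,2021-09-02T22:38:35.100000\n"
            "e1,h1,13,2021-09-02T22:38:36.500000\n"
            "e1,h1,14,2021-09-02T22:38:37.000000\n"
        )
        pts = read_salient_points(p, read_deployment(deployment_csv))
        assert len(pts) == 3
        assert {q.site_id for q in pts} == {"11", "13", "14"}
        assert pts[1].arrival_time - pts[0].arrival_time == pytest.approx(1.4)

    def test_file_offset_layout(self, tmp_path):
        p = tmp_path / "sal.csv"
        p.write_text(
            "event_id,howl_id,site_id,file,begin_time_s\n"
            "e1,h1,11,CAR11_20210902_223800.wav,5.00\n"
        )
        (pt,) = read_salient_points(p)
        assert pt.arrival_time == parse_timestamp("2021-09-02T22:38:00") + 5.0

    def test_unknown_site_rejected(self, tmp_path, deployment_csv):
        p = tmp_path / "sal.csv"
        p.write_text(
            "event_id,howl_id,site_id,arrival_time_iso\n"
            "e1,h1,99,2021-09-02T22:38:35\n"
        )
        with pytest.raises(ValueError, match="99"):
            read_salient_points(p, read_deployment(deployment_csv))

    def test_duplicate_howl_site_rejected(self, tmp_path):
        p = tmp_path / "sal.csv"
        p.write_text(
            "event_id,howl_id,site_id,arrival_time_iso\n"
            "e1,h1,11,2021-09-02T22:38:35\n"
            "e1,h1,11,2021-09-02T22:38:36\n"
        )
        with pytest.raises(ValueError, match=r"\(h1, 11\)"):
            read_salient_points(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "sal.csv"
        p.write_text("event_id,howl_id,site_id\ne1,h1,11\n")
        with pytest.raises(ValueError, match="arrival_time_iso"):
            read_salient_points(p)

    def test_arrival_outside_active_interval_rejected(self, tmp_path, deployment_csv):
        p = tmp_path / "sal.csv"
        p.write_text(
            "event_id,howl_id,site_id,arrival_time_iso\n"
            "e1,h1,11,2021-10-01T00:00:00\n"
        )
        with pytest.raises(ValueError, match="active interval"):
            read_salient_points(p, read_deployment(deployment_csv))

    def test_raven_dialect(self, tmp_path):
        p = tmp_path / "sel.txt"
        p.write_text(
            "Selection\tBegin Time (s)\tEnd Time (s)\tAnnotation\n"
            "1\t5.00\t8.20\th1\n"
            "2\t61.35\t66.00\th2\n"
        )
        pts = read_raven_selection_table(
            p, site_id="11", recording_file="CAR11_20210902_223800.wav"
        )
        start = parse_timestamp("2021-09-02T22:38:00")
        assert [q.arrival_time for q in pts] == [start + 5.0, start + 61.35]
        assert [q.howl_id for q in pts] == ["h1", "h2"]

    def test_raven_missing_column_named(self, tmp_path):
        p = tmp_path / "sel.txt"
        p.write_text("Selection\tAnnotation\n1\th1\n")
        with pytest.raises(ValueError, match="Begin Time"):
            read_raven_selection_table(p, site_id="11", recording_file="x_20210902_223800.wav")


class TestHowlObservations:
    def test_split_by_recorder_count(self, tmp_path):
        p = tmp_path / "sal.csv"
        p.write_text(
            "event_id,howl_id,site_id,arrival_time_iso\n"
            "e1,h1,11,2021-09-02T22:38:35.0\n"
            "e1,h1,13,2021-09-02T22:38:36.0\n"
            "e1,h1,14,2021-09-02T22:38:37.0\n"
            "e1,h2,11,2021-09-02T22:39:35.0\n"
            "e1,h2,13,2021-09-02T22:39:36.0\n"
        )
        ok, rejected = build_howl_observations(read_salient_points(p))
        assert [o.howl_id for o in ok] == ["h1"]
        assert [o.howl_id for o in rejected] == ["h2"]

    def test_wide_spread_rejected(self, tmp_path):
        p = tmp_path / "sal.csv"
        p.write_text(
            "event_id,howl_id,site_id,arrival_time_iso\n"
            "e1,h1,11,2021-09-02T22:38:35.0\n"
            "e1,h1,13,2021-09-02T22:38:36.0\n"
            "e1,h1,14,2021-09-02T22:39:35.0\n"  # 60 s after the first
        )
        ok, rejected = build_howl_observations(read_salient_points(p))
        assert ok == [] and [o.howl_id for o in rejected] == ["h1"]


class TestEventGrouping:
    def test_long_silence_splits(self):
        howls = [("a", 0.0), ("b", 30.0), ("c", 50.0), ("d", 200.0)]
        ev = group_events(howls)
        assert ev["a"] == ev["b"] == ev["c"]
        assert ev["d"] != ev["a"]

    def test_sub_minute_gaps_merge(self):
        howls = [(f"h{i}", i * 59.0) for i in range(4)]
        assert len(set(group_events(howls).values())) == 1

    def test_four_close_howls_one_event(self):
        # four distinct howls separated by less than a minute of silence
        howls = [("h1", 0.0), ("h2", 12.0), ("h3", 40.0), ("h4", 95.0)]
        ev = group_events(howls)
        assert len(set(ev.values())) == 1

    def test_exact_gap_starts_new_event(self):
        ev = group_events([("a", 0.0), ("b", 60.0)])
        assert ev["a"] != ev["b"]

    def test_empty_input(self):
        assert group_events([]) == {}

    def test_nonpositive_gap_rejected(self):
        with pytest.raises(ValueError):
            group_events([("a", 0.0)], gap_s=0.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        times=st.lists(st.floats(0.0, 3600.0), min_size=1, max_size=25, unique=True),
        seed=st.integers(0, 2**16),
    )
    def test_order_independent_and_gap_invariant(self, times, seed):
        import random

        howls = [(f"h{i}", t) for i, t in enumerate(times)]
        shuffled = howls[:]
        random.Random(seed).shuffle(shuffled)
        ev_sorted = group_events(sorted(howls, key=lambda ht: ht[1]))
        ev_shuffled = group_events(shuffled)
        assert ev_sorted == ev_shuffled
        # within an event adjacent gaps < 60; across boundaries >= 60
        ordered = sorted(howls, key=lambda ht: ht[1])
        for (h1, t1), (h2, t2) in zip(ordered, ordered[1:]):
            if ev_sorted[h1] == ev_sorted[h2]:
                assert t2 - t1 < 60.0
            else:
                assert t2 - t1 >= 60.0


def test_results_round_trip(tmp_path, square_array):
    """Write→read of localisation results preserves every reported field."""
    import pandas as pd

    from howlloc.annotations_io import write_results_csv, write_results_geojson
    from howlloc.geodesy import GeoPoint
    from howlloc.localisation import LocalisationResult

    results = [
        LocalisationResult(
            howl_id="h1",
            event_id="e1",
            position=GeoPoint(46.147001, 21.190002),
            rms_residual_s=0.001,
            n_recorders=4,
            recorder_subset=("1", "2", "3", "4"),
            in_local_hull=True,
            converged=True,
        )
    ]
    csv_path = tmp_path / "res.csv"
    write_results_csv(results, csv_path)
    df = pd.read_csv(csv_path, dtype={"howl_id": str})
    assert df.loc[0, "lat"] == 46.147001
    assert df.loc[0, "recorder_subset"] == "1;2;3;4"
    assert bool(df.loc[0, "in_local_hull"]) is True

    gj_path = tmp_path / "res.geojson"
    write_results_geojson(results, gj_path)
    import json

    fc = json.loads(gj_path.read_text())
    assert fc["type"] == "FeatureCollection"
    (feat,) = fc["features"]
    # GeoJSON is lon-lat
    assert feat["geometry"]["coordinates"] == [21.190002, 46.147001]
    assert feat["properties"]["howl_id"] == "h1"
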