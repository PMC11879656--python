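"""Deployment and salient-point table I/O, filename timestamps, event grouping.

Arrival times of the same howl at GPS-synchronised recorders are measured by
marking *salient points* — distinctive instants of the sound visible on the
spectrograms of several recorders.  This module reads deployment tables and
salient-point annotations (plain CSV or Raven-style tab-separated selection
tables), converts within-file offsets to absolute UTC times using the
timestamp embedded in each recording's filename, groups howls into events
separated by ≥ 1 min of silence, and writes localisation results as CSV and
GeoJSON.

All timestamps are UTC epoch seconds internally (GPS time is UTC); ISO 8601
strings appear only at the file boundary.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .geodesy import GeoPoint

__all__ = [
    "Recorder",
    "SalientPoint",
    "HowlObservation",
    "parse_recording_start",
    "parse_timestamp",
    "read_deployment",
    "read_salient_points",
    "read_raven_selection_table",
    "build_howl_observations",
    "group_events",
    "write_results_csv",
    "write_results_geojson",
]

#: Default filename timestamp token: YYYYMMDD_HHMMSS, e.g. CAR01_20210902_223835.wav
DEFAULT_FILENAME_PATTERN = r"(?P<date>\d{8})_(?P<time>\d{6})"

#: Maximum plausible arrival-time spread of one howl across an array (s).
#: ~5 km of path difference at 343 m/s; larger spreads indicate mismatched
#: salient points joined under one howl id.
MAX_TDOA_WINDOW_S = 15.0


@dataclass(frozen=True)
class Recorder:
    """A deployed recording unit: site label, position, active interval."""

    site_id: str
    position: GeoPoint
    active_from: float  # UTC epoch seconds
    active_to: float

    def __post_init__(self) -> None:
        if not self.active_from < self.active_to:
            raise ValueError(
                f"recorder {self.site_id}: active_from must precede active_to"
            )

    def active_at(self, t: float) -> bool:
        return self.active_from <= t <= self.active_to


@dataclass(frozen=True)
class SalientPoint:
    """One marked arrival of one howl at one recorder."""

    event_id: str
    howl_id: str
    site_id: str
    arrival_time: float  # UTC epoch seconds


@dataclass
class HowlObservation:
    """All salient points of one howl, keyed by recorder site."""

    howl_id: str
    event_id: str
    points: dict[str, SalientPoint] = field(default_factory=dict)

    @property
    def n_recorders(self) -> int:
        return len(self.points)

    @property
    def spread_s(self) -> float:
        times = [p.arrival_time for p in self.points.values()]
        return max(times) - min(times) if times else 0.0


def parse_timestamp(text: str) -> float:
    """Parse an ISO 8601 timestamp (naive = UTC) to epoch seconds."""
    dt = datetime.fromisoformat(text)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


def _epoch_to_iso(t: float) -> str:
    return datetime.fromtimestamp(t, tz=timezone.utc).strftime("%Y-%m-%dT%H:%M:%S")


def parse_recording_start(
    filename: str, pattern: str = DEFAULT_FILENAME_PATTERN
) -> float:
    """Extract the recording start time embedded in a filename.

    GPS-synchronised recorders stamp each file with its UTC start time; the
    default token is ``YYYYMMDD_HHMMSS``.  Salient-point offsets within the
    file are added to this to obtain absolute arrival times.

    Raises ``ValueError`` naming the expected pattern if no token matches.
    """
    m = re.search(pattern, Path(filename).name)
    if m is None:
        raise ValueError(
            f"could not parse a recording start time from {filename!r}; "
            f"expected a token matching {pattern!r} (e.g. 20210902_223835)"
        )
    try:
        date, time = m.group("date"), m.group("time")
    except (IndexError, re.error):
        date, time = m.group(1), m.group(2)
    dt = datetime.strptime(date + time, "%Y%m%d%H%M%S").replace(tzinfo=timezone.utc)
    return dt.timestamp()


def read_deployment(path: str | Path) -> list[Recorder]:
    """Read a deployment CSV: site_id, lat, lon, active_from, active_to."""
    df = pd.read_csv(path, dtype={"site_id": str})
    required = {"site_id", "lat", "lon", "active_from", "active_to"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"deployment table {path} missing columns: {sorted(missing)}")
    if df["site_id"].duplicated().any():
        dupes = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicate site_id(s) in deployment: {dupes}")
    return [
        Recorder(
            site_id=row.site_id,
            position=GeoPoint(lat=row.lat, lon=row.lon),
            active_from=parse_timestamp(str(row.active_from)),
            active_to=parse_timestamp(str(row.active_to)),
        )
        for row in df.itertuples()
    ]


def write_deployment(recorders: Sequence[Recorder], path: str | Path) -> None:
    pd.DataFrame(
        {
            "site_id": [r.site_id for r in recorders],
            "lat": [r.position.lat for r in recorders],
            "lon": [r.position.lon for r in recorders],
            "active_from": [_epoch_to_iso(r.active_from) for r in recorders],
            "active_to": [_epoch_to_iso(r.active_to) for r in recorders],
        }
    ).to_csv(path, index=False)


def read_salient_points(
    path: str | Path,
    deployment: Sequence[Recorder] | None = None,
    *,
    filename_pattern: str = DEFAULT_FILENAME_PATTERN,
) -> list[SalientPoint]:
    """Read a salient-point CSV into absolute-time annotations.

    Two column layouts are accepted:

    * ``event_id, howl_id, site_id, arrival_time_iso`` — absolute times; or
    * ``event_id, howl_id, site_id, file, begin_time_s`` — a recording
      filename (with embedded start timestamp) plus an offset in seconds.

    If ``deployment`` is given, rows referencing unknown sites are rejected
    and arrival times are checked against each recorder's active interval.
    Duplicate (howl_id, site_id) pairs are an error: the marking protocol
    allows exactly one salient point per howl per recorder.
    """
    df = pd.read_csv(path, dtype={"site_id": str, "howl_id": str, "event_id": str})
    base = {"event_id", "howl_id", "site_id"}
    missing = base - set(df.columns)
    if missing:
        raise ValueError(f"salient-point table {path} missing columns: {sorted(missing)}")

    if "arrival_time_iso" in df.columns:
        arrivals = [parse_timestamp(str(v)) for v in df["arrival_time_iso"]]
    elif {"file", "begin_time_s"} <= set(df.columns):
        arrivals = [
            parse_recording_start(str(f), filename_pattern) + float(off)
            for f, off in zip(df["file"], df["begin_time_s"])
        ]
    else:
        raise ValueError(
            f"salient-point table {path} needs either an 'arrival_time_iso' column "
            "or 'file' + 'begin_time_s' columns"
        )
    df = df.assign(arrival_time=arrivals)

    dup = df.duplicated(subset=["howl_id", "site_id"])
    if dup.any():
        pairs = df.loc[dup, ["howl_id", "site_id"]].itertuples(index=False)
        raise ValueError(
            "duplicate salient point(s) for (howl_id, site_id): "
            + ", ".join(f"({h}, {s})" for h, s in pairs)
        )

    if deployment is not None:
        by_site = {r.site_id: r for r in deployment}
        unknown = sorted(set(df["site_id"]) - set(by_site))
        if unknown:
            raise ValueError(f"salient points reference unknown site_id(s): {unknown}")
        for row in df.itertuples():
            if not by_site[row.site_id].active_at(row.arrival_time):
                raise ValueError(
                    f"salient point for howl {row.howl_id} at site {row.site_id} "
                    f"falls outside that recorder's active interval"
                )

    return [
        SalientPoint(
            event_id=row.event_id,
            howl_id=row.howl_id,
            site_id=row.site_id,
            arrival_time=row.arrival_time,
        )
        for row in df.itertuples()
    ]


def read_raven_selection_table(
    path: str | Path,
    site_id: str,
    recording_file: str | None = None,
    *,
    howl_column: str = "Annotation",
    event_id: str = "",
    filename_pattern: str = DEFAULT_FILENAME_PATTERN,
) -> list[SalientPoint]:
    """Read a Raven-style tab-separated selection table for one recorder.

    Raven tables carry per-selection offsets ("Begin Time (s)") relative to
    the recording start; the absolute start is parsed from the recording
    filename — passed explicitly, or taken from a "Begin File" column.
    The howl label is read from ``howl_column`` (one selection per howl).
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("Selection", "Begin Time (s)"):
        if col not in df.columns:
            raise ValueError(f"Raven table {path} missing column {col!r}")
    if howl_column not in df.columns:
        raise ValueError(f"Raven table {path} missing howl-label column {howl_column!r}")

    points = []
    for row in df.itertuples(index=False):
        rowd = dict(zip(df.columns, row))
        fname = recording_file or rowd.get("Begin File")
        if not fname:
            raise ValueError(
                f"Raven table {path}: no recording filename — pass recording_file "
                "or include a 'Begin File' column"
            )
        start = parse_recording_start(str(fname), filename_pattern)
        points.append(
            SalientPoint(
                event_id=event_id,
                howl_id=str(rowd[howl_column]),
                site_id=site_id,
                arrival_time=start + float(rowd["Begin Time (s)"]),
            )
        )
    return points


def build_howl_observations(
    points: Iterable[SalientPoint],
    *,
    min_recorders: int = 3,
    max_tdoa_window: float = MAX_TDOA_WINDOW_S,
) -> tuple[list[HowlObservation], list[HowlObservation]]:
    """Group salient points by howl and split localisable from not.

    Returns ``(localisable, rejected)``: a howl is localisable when marked on
    at least ``min_recorders`` distinct recorders with an arrival-time spread
    below ``max_tdoa_window`` seconds.
    """
    by_howl: dict[str, HowlObservation] = {}
    for p in points:
        obs = by_howl.setdefault(p.howl_id, HowlObservation(p.howl_id, p.event_id))
        if p.site_id in obs.points:
            raise ValueError(
                f"howl {p.howl_id}: duplicate salient point at site {p.site_id}"
            )
        obs.points[p.site_id] = p

    localisable, rejected = [], []
    for obs in by_howl.values():
        ok = obs.n_recorders >= min_recorders and obs.spread_s <= max_tdoa_window
        (localisable if ok else rejected).append(obs)
    order = lambda o: min(p.arrival_time for p in o.points.values())
    return sorted(localisable, key=order), sorted(rejected, key=order)


def group_events(
    howls: Sequence[tuple[str, float]], gap_s: float = 60.0
) -> dict[str, str]:
    """Assign howls to events separated by silences of ``gap_s`` or more.

    An event runs from the first howl until a gap of at least ``gap_s``
    seconds precedes the next one (gaps measured start-to-start).  Returns a
    mapping howl_id → event label ("e1", "e2", ... in time order).  Input
    order is irrelevant; the assignment is idempotent.
    """
    if gap_s <= 0:
        raise ValueError("gap_s must be positive")
    if not howls:
        return {}
    ordered = sorted(howls, key=lambda ht: (ht[1], ht[0]))
    assignment: dict[str, str] = {}
    event_no = 1
    prev_time = ordered[0][1]
    for howl_id, t in ordered:
        if t - prev_time >= gap_s:
            event_no += 1
        assignment[howl_id] = f"e{event_no}"
        prev_time = t
    return assignment


# --- result output -----------------------------------------------------------

RESULT_COLUMNS = [
    "howl_id",
    "event_id",
    "lat",
    "lon",
    "rms_residual_s",
    "n_recorders",
    "recorder_subset",
    "in_local_hull",
]


def _result_row(r) -> dict:
    return {
        "howl_id": r.howl_id,
        "event_id": r.event_id,
        "lat": round(r.position.lat, 6),
        "lon": round(r.position.lon, 6),
        "rms_residual_s": r.rms_residual_s,
        "n_recorders": r.n_recorders,
        "recorder_subset": ";".join(r.recorder_subset),
        "in_local_hull": r.in_local_hull,
    }


def write_results_csv(results: Sequence, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=RESULT_COLUMNS)
        writer.writeheader()
        for r in results:
            writer.writerow(_result_row(r))


def write_results_geojson(results: Sequence, path: str | Path) -> None:
    """Write estimates as a GeoJSON FeatureCollection (WGS84, lon-lat order)."""
    features = []
    for r in results:
        props = _result_row(r)
        lat, lon = props.pop("lat"), props.pop("lon")
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [lon, lat]},
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=2)
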