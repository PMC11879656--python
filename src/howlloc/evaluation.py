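"""Accuracy and detection-distance analyses for localised howls.

Given position estimates, known (howl-survey) source positions, and per-howl
detection outcomes, this module computes the survey's headline quantities:
localisation error against ground truth, distances from each howl to the
recorders that did and did not detect it, and their summaries.

Convention for detection distances, following standard practice for
howl-survey validation: distances for howls with known sources (human howls
elicited at surveyed points) are measured from the *true* location, while
distances for wild (jackal) howls are measured from the *estimated*
location, since no ground truth exists for them.  The latter are therefore
biased by the localisation error itself — typically tens of metres against
kilometre-scale distances.

Metre quantities are reported rounded to whole metres, kilometre quantities
to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .annotations_io import Recorder, parse_timestamp
from .geodesy import GeoPoint, geo_distance
from .localisation import LocalisationResult

__all__ = [
    "GroundTruthHowl",
    "DetectionProfile",
    "localisation_error",
    "summarize_errors",
    "detection_profile",
    "detection_summary",
    "load_table1",
    "table1_ground_truth",
    "table1_estimates",
]


@dataclass(frozen=True)
class GroundTruthHowl:
    """A howl with a surveyed (known) source position."""

    howl_id: str
    true_position: GeoPoint
    timestamp: float
    group: str = ""


@dataclass(frozen=True)
class DetectionProfile:
    """Distances from one howl to every recorder active at its time,
    split by whether the howl was detected (salient-point-markable) there."""

    howl_id: str
    detections: tuple[tuple[str, float], ...]
    non_detections: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        det = {s for s, _ in self.detections}
        non = {s for s, _ in self.non_detections}
        if det & non:
            raise ValueError(f"site(s) in both lists: {sorted(det & non)}")


def localisation_error(result: LocalisationResult, truth: GroundTruthHowl) -> int:
    """Ground distance (m, nearest metre) between estimate and true source."""
    if result.howl_id != truth.howl_id:
        raise ValueError(
            f"howl id mismatch: result {result.howl_id!r} vs truth {truth.howl_id!r}"
        )
    return round(geo_distance(result.position, truth.true_position))


def summarize_errors(errors: Sequence[float]) -> dict:
    """Mean (nearest metre), min, max and count of localisation errors."""
    if len(errors) == 0:
        raise ValueError("cannot summarise an empty error list")
    return {
        "mean_m": round(sum(errors) / len(errors)),
        "min_m": round(min(errors)),
        "max_m": round(max(errors)),
        "n": len(errors),
    }


def detection_profile(
    howl_id: str,
    position: GeoPoint,
    timestamp: float,
    deployment: Sequence[Recorder],
    detected_sites: Iterable[str],
) -> DetectionProfile:
    """Distances from a howl's position to every recorder active at its time.

    ``position`` is the true location for ground-truthed howls and the
    estimate for wild howls.  Only recorders active at ``timestamp`` appear;
    a detected site that was inactive then is an inconsistency and raises.
    """
    detected = set(detected_sites)
    active = {r.site_id: r for r in deployment if r.active_at(timestamp)}
    inactive_detections = detected - set(active)
    if inactive_detections:
        raise ValueError(
            f"howl {howl_id}: detected on site(s) not active at its timestamp: "
            f"{sorted(inactive_detections)}"
        )
    dets, nons = [], []
    for site_id, rec in sorted(active.items()):
        d = geo_distance(position, rec.position)
        (dets if site_id in detected else nons).append((site_id, d))
    return DetectionProfile(
        howl_id=howl_id, detections=tuple(dets), non_detections=tuple(nons)
    )


def detection_summary(profiles: Sequence[DetectionProfile]) -> dict:
    """Pooled detection-distance statistics over a set of howls.

    mean_detection_m : mean over every (howl, detecting recorder) distance
    max_detection_m : the single largest detection distance
    mean_max_detection_m : per-howl furthest detection, averaged
    min_nondetection_m : nearest recorder that missed any howl (None if all
        recorders detected everything)
    n_closer_nondetections : count of non-detections at recorders nearer
        than the same howl's furthest detecting recorder — the overlap that
        limits how far apart recorders can safely be spaced
    """
    if not profiles:
        raise ValueError("cannot summarise an empty profile list")
    all_det = [d for p in profiles for _, d in p.detections]
    all_non = [d for p in profiles for _, d in p.non_detections]
    if not all_det:
        raise ValueError("no detections in any profile")
    per_howl_max = [
        max(d for _, d in p.detections) for p in profiles if p.detections
    ]
    n_closer = sum(
        1
        for p in profiles
        if p.detections
        for _, d in p.non_detections
        if d < max(dd for _, dd in p.detections)
    )
    return {
        "mean_detection_m": round(sum(all_det) / len(all_det)),
        "max_detection_m": round(max(all_det)),
        "mean_max_detection_m": round(sum(per_howl_max) / len(per_howl_max)),
        "min_nondetection_m": round(min(all_non)) if all_non else None,
        "n_closer_nondetections": n_closer,
        "n_howls": len(profiles),
    }


# --- bundled validation fixture ---------------------------------------------


def load_table1() -> pd.DataFrame:
    """The bundled howl-survey validation table: 16 human howls with true
    (surveyed) and estimated positions, printed distances, contributing
    recorder subsets and local-hull flags."""
    with resources.files("howlloc.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh, dtype={"howl_no": str, "group": str})


def table1_ground_truth() -> list[GroundTruthHowl]:
    return [
        GroundTruthHowl(
            howl_id=row.howl_no,
            true_position=GeoPoint(row.true_lat, row.true_lon),
            timestamp=parse_timestamp(row.timestamp),
            group=row.group,
        )
        for row in load_table1().itertuples()
    ]


def table1_estimates() -> list[LocalisationResult]:
    """The fixture's estimated positions wrapped as localisation results
    (residuals unknown, recorded as 0)."""
    out = []
    for row in load_table1().itertuples():
        subset = tuple(row.recorder_sites.split(";"))
        out.append(
            LocalisationResult(
                howl_id=row.howl_no,
                event_id=row.group,
                position=GeoPoint(row.est_lat, row.est_lon),
                rms_residual_s=0.0,
                n_recorders=len(subset),
                recorder_subset=subset,
                in_local_hull=(row.local_hull == "Inside"),
                converged=True,
            )
        )
    return out


def evaluate_results(
    results: Sequence[LocalisationResult],
    truths: Sequence[GroundTruthHowl],
) -> dict:
    """Per-howl errors plus their summary for all (result, truth) id matches."""
    by_id = {t.howl_id: t for t in truths}
    rows = []
    for r in results:
        if r.howl_id not in by_id:
            continue
        t = by_id[r.howl_id]
        rows.append(
            {
                "howl_id": r.howl_id,
                "error_m": localisation_error(r, t),
                "in_local_hull": r.in_local_hull,
                "n_recorders": r.n_recorders,
                "group": t.group,
            }
        )
    if not rows:
        raise ValueError("no howl ids shared between results and ground truth")
    return {
        "per_howl": rows,
        "summary": summarize_errors([r["error_m"] for r in rows]),
    }
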