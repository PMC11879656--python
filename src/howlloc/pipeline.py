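"""End-to-end wiring: salient points → TDOAs → positions → evaluation report.

`localise_table` / `localise_points` run the full localisation stage for a
batch of annotated howls; `run_pipeline` executes localise-then-evaluate
from a `RunConfig` and returns a provenance-stamped report dict.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotations_io import (
    HowlObservation,
    Recorder,
    SalientPoint,
    build_howl_observations,
    read_deployment,
    read_salient_points,
    write_results_csv,
    write_results_geojson,
)
from .evaluation import GroundTruthHowl, evaluate_results
from .geodesy import GeoPoint
from .localisation import (
    GeometryError,
    LocalisationResult,
    NotLocalisableError,
    SolverConfig,
    compute_tdoa,
    multilaterate,
)

log = logging.getLogger("howlloc")

__all__ = ["RunConfig", "localise_points", "localise_table", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and solver settings for one pipeline run."""

    deployment: str
    salient: str
    truth: str | None = None
    out_results: str | None = None
    out_report: str | None = None
    solver: SolverConfig = field(default_factory=SolverConfig)
    seed: int = 20210831
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = {
            "deployment": self.deployment,
            "salient": self.salient,
            "truth": self.truth,
            "solver": asdict(self.solver),
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def localise_points(
    points: list[SalientPoint],
    deployment: list[Recorder],
    config: SolverConfig | None = None,
) -> tuple[list[LocalisationResult], list[HowlObservation]]:
    """Localise every howl with enough salient points.

    Returns (results, not_localisable); howls whose geometry is degenerate
    or whose solver finds no finite objective are logged and dropped into
    the second list as well.
    """
    cfg = config or SolverConfig()
    localisable, rejected = build_howl_observations(
        points, min_recorders=cfg.min_recorders
    )
    results = []
    for obs in localisable:
        try:
            tdoa = compute_tdoa(obs)
            results.append(multilaterate(tdoa, deployment, cfg))
        except (NotLocalisableError, GeometryError) as exc:
            log.warning("localise howl=%s failed: %s", obs.howl_id, exc)
            rejected.append(obs)
    log.info(
        "localise localised=%d not_localisable=%d", len(results), len(rejected)
    )
    return results, rejected


def localise_table(
    salient: pd.DataFrame,
    deployment: list[Recorder],
    config: SolverConfig | None = None,
) -> tuple[list[LocalisationResult], list[HowlObservation]]:
    """Localise from an in-memory salient-point table (same columns as the
    CSV layout: event_id, howl_id, site_id, arrival_time_iso)."""
    from .annotations_io import parse_timestamp

    points = [
        SalientPoint(
            event_id=str(r.event_id),
            howl_id=str(r.howl_id),
            site_id=str(r.site_id),
            arrival_time=parse_timestamp(str(r.arrival_time_iso)),
        )
        for r in salient.itertuples()
    ]
    return localise_points(points, deployment, config)


def _read_truth(path: str) -> list[GroundTruthHowl]:
    from .annotations_io import parse_timestamp

    df = pd.read_csv(path, dtype={"howl_id": str})
    required = {"howl_id", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"truth table {path} missing columns: {sorted(missing)}")
    time_col = "emit_time_iso" if "emit_time_iso" in df.columns else None
    return [
        GroundTruthHowl(
            howl_id=r.howl_id,
            true_position=GeoPoint(r.lat, r.lon),
            timestamp=parse_timestamp(str(getattr(r, time_col))) if time_col else 0.0,
            group=str(getattr(r, "group", "")),
        )
        for r in df.itertuples()
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Localise, optionally evaluate against ground truth, write outputs.

    The report echoes the solver settings, package version and a config
    hash so a run can be reproduced from its report alone.
    """
    for name in ("deployment", "salient", "truth"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"{name} file not found: {path}")

    log.info("stage=read deployment=%s salient=%s", config.deployment, config.salient)
    deployment = read_deployment(config.deployment)
    points = read_salient_points(config.salient, deployment)
    results, rejected = localise_points(points, deployment, config.solver)

    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "settings": asdict(config.solver) | {"seed": config.seed},
        "n_localised": len(results),
        "n_not_localisable": len(rejected),
        "results": [
            {
                "howl_id": r.howl_id,
                "event_id": r.event_id,
                "lat": round(r.position.lat, 6),
                "lon": round(r.position.lon, 6),
                "rms_residual_s": r.rms_residual_s,
                "n_recorders": r.n_recorders,
                "recorder_subset": list(r.recorder_subset),
                "in_local_hull": r.in_local_hull,
                "ambiguous": r.ambiguous,
            }
            for r in results
        ],
    }

    if config.truth:
        log.info("stage=evaluate truth=%s", config.truth)
        truths = _read_truth(config.truth)
        evaluation = evaluate_results(results, truths) if results else None
        report["evaluation"] = evaluation

    if config.out_results:
        out = Path(config.out_results)
        if out.suffix == ".geojson" or out.suffix == ".json":
            write_results_geojson(results, out)
        else:
            write_results_csv(results, out)
        log.info("stage=write results=%s", out)
    if config.out_report:
        with open(config.out_report, "w") as fh:
            json.dump(report, fh, indent=2)
        log.info("stage=write report=%s", config.out_report)
    return report
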