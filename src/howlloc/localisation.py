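"""Hyperbolic multilateration of howl positions from arrival-time differences.

Each time difference of arrival (TDOA) between a recorder and the reference
(earliest-arrival) recorder constrains the source to one branch of a
hyperbola.  With three or more non-collinear recorders the 2-D source
position is estimated by minimising the sum of squared TDOA residuals

    J(s) = Σ_i [ (|s − r_i| − |s − r_ref|)/c − Δt_i ]²

over candidate positions s, where c is the speed of sound.  The objective is
multimodal — with exactly three recorders two hyperbola branches can
intersect twice, both with near-zero residual — so the solver enumerates
basins with a coarse grid over the array's bounding box (padded by the
maximum plausible range) and polishes the best cells with derivative-free
Nelder–Mead.  Ties are broken by lowest RMS residual, then by proximity to
the recorder centroid; an unresolved near-tie is flagged ambiguous.

Altitude is not modelled: the method targets flat terrain where recorders
and sources share a plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize
from shapely.geometry import MultiPoint, Point

from .annotations_io import MAX_TDOA_WINDOW_S, HowlObservation, Recorder
from .geodesy import GeoPoint, make_projection

__all__ = [
    "TDOASet",
    "SolverConfig",
    "LocalisationResult",
    "NotLocalisableError",
    "GeometryError",
    "speed_of_sound",
    "compute_tdoa",
    "multilaterate",
    "local_hull_classification",
    "flag_multiple_sources",
]


class NotLocalisableError(ValueError):
    """The observation cannot yield a position estimate."""


class GeometryError(ValueError):
    """The recorder geometry is degenerate (e.g. collinear)."""


def speed_of_sound(temperature_c: float = 20.0) -> float:
    """Speed of sound in dry air (m/s): c(T) = 331.3 + 0.606·T(°C)."""
    return 331.3 + 0.606 * temperature_c


def _check_speed(c: float) -> None:
    if not 300.0 <= c <= 360.0:
        raise ValueError(f"speed of sound {c} m/s outside plausible air range [300, 360]")


@dataclass(frozen=True)
class TDOASet:
    """Arrival-time differences of one howl relative to its earliest arrival.

    ``deltas`` maps each non-reference site to (arrival there − arrival at
    the reference); all values are ≥ 0 because the reference is earliest.
    """

    howl_id: str
    event_id: str
    reference_site: str
    deltas: dict[str, float]

    @property
    def sites(self) -> list[str]:
        return [self.reference_site, *self.deltas]


@dataclass(frozen=True)
class SolverConfig:
    """Multilateration solver settings.

    c : speed of sound (m/s), default 343 (≈ 20 °C)
    grid_cell : coarse grid spacing (m) for basin enumeration
    max_range : padding (m) around the array bounding box; sources further
        out than this are considered undetectable
    n_refine : number of best grid cells polished by Nelder–Mead
    residual_tol : RMS residual (s) below which a fit counts as converged
    collinearity_tol : smallest singular value (m) of the centred recorder
        coordinates below which the array is treated as collinear
    """

    c: float = 343.0
    grid_cell: float = 50.0
    max_range: float = 4000.0
    n_refine: int = 3
    residual_tol: float = 1e-6
    min_recorders: int = 3
    collinearity_tol: float = 1.0

    def __post_init__(self) -> None:
        _check_speed(self.c)
        if self.grid_cell <= 0 or self.max_range <= 0:
            raise ValueError("grid_cell and max_range must be positive")


@dataclass
class LocalisationResult:
    """A howl's estimated position with its fit diagnostics."""

    howl_id: str
    event_id: str
    position: GeoPoint
    rms_residual_s: float
    n_recorders: int
    recorder_subset: tuple[str, ...]
    in_local_hull: bool
    converged: bool
    ambiguous: bool = False
    alternate: GeoPoint | None = None
    local_xy: tuple[float, float] = field(default=(0.0, 0.0), repr=False)


def compute_tdoa(
    obs: HowlObservation, max_tdoa_window: float = MAX_TDOA_WINDOW_S
) -> TDOASet:
    """Reduce a howl's salient points to TDOAs against the earliest arrival.

    The absolute emission time is a nuisance parameter: shifting every
    arrival by a constant leaves the TDOA set unchanged.
    """
    if obs.n_recorders < 3:
        raise NotLocalisableError(
            f"howl {obs.howl_id}: salient points on {obs.n_recorders} recorder(s); "
            "at least 3 are required for multilateration"
        )
    if obs.spread_s > max_tdoa_window:
        raise ValueError(
            f"howl {obs.howl_id}: arrival spread {obs.spread_s:.2f} s exceeds the "
            f"{max_tdoa_window} s window — salient points likely mismatched"
        )
    ref_site = min(obs.points, key=lambda s: (obs.points[s].arrival_time, s))
    t_ref = obs.points[ref_site].arrival_time
    deltas = {
        s: p.arrival_time - t_ref for s, p in obs.points.items() if s != ref_site
    }
    return TDOASet(
        howl_id=obs.howl_id,
        event_id=obs.event_id,
        reference_site=ref_site,
        deltas=deltas,
    )


def tdoa_objective(
    xy: np.ndarray, rec_xy: np.ndarray, ref_idx: int, deltas: np.ndarray, c: float
) -> np.ndarray:
    """Sum of squared TDOA residuals (s²) at candidate position(s) ``xy``.

    ``xy`` may be a single (2,) point or an (m, 2) batch; ``deltas`` holds
    the observed TDOAs for the non-reference recorders, in recorder order
    with the reference removed.
    """
    pts = np.atleast_2d(np.asarray(xy, dtype=float))
    d = np.linalg.norm(pts[:, None, :] - rec_xy[None, :, :], axis=2)  # (m, n)
    rel = np.delete(d, ref_idx, axis=1) - d[:, ref_idx:ref_idx + 1]
    resid = rel / c - deltas[None, :]
    out = np.sum(resid**2, axis=1)
    return out if np.ndim(xy) > 1 else float(out[0])


def _collinearity_check(rec_xy: np.ndarray, tol: float) -> None:
    centred = rec_xy - rec_xy.mean(axis=0)
    smin = np.linalg.svd(centred, compute_uv=False)[-1]
    if smin < tol:
        raise GeometryError(
            f"recorder array is collinear to within {tol} m "
            f"(smallest singular value {smin:.3g} m); 2-D multilateration is degenerate"
        )


def multilaterate(
    tdoa: TDOASet,
    recorders: list[Recorder],
    config: SolverConfig | None = None,
) -> LocalisationResult:
    """Estimate a howl's position from its TDOA set.

    ``recorders`` must cover every site in the TDOA set; extra recorders are
    ignored.  Works in a local metric frame centred on the contributing
    recorders' centroid and converts the minimiser back to WGS84.
    """
    cfg = config or SolverConfig()
    by_site = {r.site_id: r for r in recorders}
    missing = [s for s in tdoa.sites if s not in by_site]
    if missing:
        raise ValueError(f"no deployment entry for site(s): {missing}")
    sites = tdoa.sites
    if len(sites) < cfg.min_recorders:
        raise NotLocalisableError(
            f"howl {tdoa.howl_id}: {len(sites)} recorders < minimum {cfg.min_recorders}"
        )

    subset = [by_site[s] for s in sites]
    centroid = GeoPoint(
        lat=float(np.mean([r.position.lat for r in subset])),
        lon=float(np.mean([r.position.lon for r in subset])),
    )
    proj = make_projection(centroid)
    rec_xy = proj.to_local_array([r.position for r in subset])
    _collinearity_check(rec_xy, cfg.collinearity_tol)

    ref_idx = 0  # sites[0] is the reference by construction
    deltas = np.array([tdoa.deltas[s] for s in sites[1:]], dtype=float)

    # Coarse grid over the padded bounding box enumerates objective basins.
    lo = rec_xy.min(axis=0) - cfg.max_range
    hi = rec_xy.max(axis=0) + cfg.max_range
    gx = np.arange(lo[0], hi[0] + cfg.grid_cell, cfg.grid_cell)
    gy = np.arange(lo[1], hi[1] + cfg.grid_cell, cfg.grid_cell)
    xx, yy = np.meshgrid(gx, gy)
    grid = np.column_stack([xx.ravel(), yy.ravel()])
    obj = tdoa_objective(grid, rec_xy, ref_idx, deltas, cfg.c)
    finite = np.isfinite(obj)
    if not finite.any():
        raise NotLocalisableError(
            f"howl {tdoa.howl_id}: no grid cell with a finite objective"
        )

    # Refine the n_refine best well-separated cells (one seed per basin).
    order = np.argsort(obj)
    seeds: list[np.ndarray] = []
    for idx in order:
        cand = grid[idx]
        if all(np.linalg.norm(cand - s) > 2 * cfg.grid_cell for s in seeds):
            seeds.append(cand)
        if len(seeds) >= cfg.n_refine:
            break

    candidates: list[tuple[float, np.ndarray, bool]] = []
    for seed in seeds:
        res = minimize(
            tdoa_objective,
            seed,
            args=(rec_xy, ref_idx, deltas, cfg.c),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-18, "maxiter": 2000},
        )
        candidates.append((float(res.fun), res.x, bool(res.success)))

    n_dt = len(deltas)
    rms = lambda f: float(np.sqrt(max(f, 0.0) / n_dt))
    arr_centroid = rec_xy.mean(axis=0)
    # Lowest RMS residual wins; near-ties resolved by centroid proximity.
    candidates.sort(
        key=lambda fvs: (fvs[0], np.linalg.norm(fvs[1] - arr_centroid))
    )
    best_f, best_xy, best_ok = candidates[0]

    ambiguous = False
    alternate = None
    for f, xy, _ok in candidates[1:]:
        far = np.linalg.norm(xy - best_xy) > 2 * cfg.grid_cell
        tie = rms(f) <= max(cfg.residual_tol, 10.0 * rms(best_f) + cfg.residual_tol)
        if far and tie:
            # Two near-exact hyperbola intersections: keep the one nearer
            # the array centroid as primary, report the other.
            if np.linalg.norm(xy - arr_centroid) < np.linalg.norm(
                best_xy - arr_centroid
            ):
                best_f, best_xy, xy = f, xy, best_xy
            ambiguous = True
            alternate = proj.to_geo(_to_local_point(xy))
            break

    position = proj.to_geo(_to_local_point(best_xy))
    inside = local_hull_classification(position, subset)
    return LocalisationResult(
        howl_id=tdoa.howl_id,
        event_id=tdoa.event_id,
        position=position,
        rms_residual_s=rms(best_f),
        n_recorders=len(sites),
        recorder_subset=tuple(sites),
        in_local_hull=inside,
        converged=rms(best_f) <= cfg.residual_tol or best_ok,
        ambiguous=ambiguous,
        alternate=alternate,
        local_xy=(float(best_xy[0]), float(best_xy[1])),
    )


def _to_local_point(xy: np.ndarray):
    from .geodesy import LocalPoint

    return LocalPoint(float(xy[0]), float(xy[1]))


def local_hull_classification(
    position: GeoPoint, subset: list[Recorder], boundary_tol_m: float = 1e-6
) -> bool:
    """Whether an estimate lies inside the convex hull of its recorders.

    Estimates outside the local hull are typically less accurate, so each
    localisation is flagged.  Points on the hull boundary count as inside.
    A collinear subset has a degenerate (segment) hull: the point is inside
    only if it lies on the segment, and a warning is emitted.
    """
    if len(subset) < 3:
        raise ValueError("hull classification requires at least 3 recorders")
    centroid = GeoPoint(
        lat=float(np.mean([r.position.lat for r in subset])),
        lon=float(np.mean([r.position.lon for r in subset])),
    )
    proj = make_projection(centroid)
    rec_xy = proj.to_local_array([r.position for r in subset])
    p = proj.to_local(position)
    hull = MultiPoint([tuple(q) for q in rec_xy]).convex_hull
    if hull.geom_type != "Polygon":
        warnings.warn(
            "degenerate (collinear) recorder hull; classifying against the segment",
            stacklevel=2,
        )
        return bool(hull.distance(Point(p.x, p.y)) <= boundary_tol_m)
    return bool(hull.covers(Point(p.x, p.y)))


def flag_multiple_sources(
    event_results: list[LocalisationResult], separation_m: float = 500.0
) -> tuple[dict[str, int], int]:
    """Cluster an event's estimates into distinct howling locations.

    Single-linkage clustering on pairwise ground distances, cut at
    ``separation_m``: howls whose chains of neighbours stay closer than the
    threshold share a source group.  Returns (howl_id → group label starting
    at 1, number of groups).  Distinct groups indicate different animals (or
    groups) howling within one event.
    """
    if not event_results:
        return {}, 0
    events = {r.event_id for r in event_results}
    if len(events) > 1:
        raise ValueError(f"results span multiple events: {sorted(events)}")
    if len(event_results) == 1:
        return {event_results[0].howl_id: 1}, 1

    from .geodesy import geo_distance

    n = len(event_results)
    condensed = [
        geo_distance(event_results[i].position, event_results[j].position)
        for i in range(n)
        for j in range(i + 1, n)
    ]
    # Cut strictly below separation_m: pairs exactly at the threshold count
    # as distinct howling locations.
    labels = fcluster(
        linkage(np.asarray(condensed), method="single"),
        t=np.nextafter(separation_m, 0.0),
        criterion="distance",
    )
    # Relabel in order of first appearance for determinism.
    remap: dict[int, int] = {}
    assignment = {}
    for r, lab in zip(event_results, labels):
        remap.setdefault(int(lab), len(remap) + 1)
        assignment[r.howl_id] = remap[int(lab)]
    return assignment, len(remap)
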