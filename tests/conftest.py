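import math

import numpy as np
import pytest

from howlloc.annotations_io import Recorder
from howlloc.geodesy import GeoPoint, LocalPoint, make_projection

ORIGIN = GeoPoint(46.147, 21.19)
T0 = 1630368000.0  # 2021-08-31T00:00:00Z
T1 = T0 + 7 * 86400.0


def recorder_at(site_id: str, x: float, y: float, origin: GeoPoint = ORIGIN) -> Recorder:
    """A recorder placed x m east / y m north of the shared test origin."""
    proj = make_projection(origin)
    return Recorder(
        site_id=site_id,
        position=proj.to_geo(LocalPoint(x, y)),
        active_from=T0,
        active_to=T1,
    )


def forward_arrivals(
    source_xy: tuple[float, float],
    recorders: list[Recorder],
    c: float = 343.0,
    t0: float = T0 + 3600.0,
    origin: GeoPoint = ORIGIN,
) -> dict[str, float]:
    """Noise-free forward model: arrival_i = t0 + |source - r_i| / c."""
    proj = make_projection(origin)
    out = {}
    for r in recorders:
        p = proj.to_local(r.position)
        d = math.hypot(p.x - source_xy[0], p.y - source_xy[1])
        out[r.site_id] = t0 + d / c
    return out


@pytest.fixture
def square_array() -> list[Recorder]:
    """Four recorders on a 1 km square around the test origin."""
    return [
        recorder_at("1", -500.0, -500.0),
        recorder_at("2", 500.0, -500.0),
        recorder_at("3", 500.0, 500.0),
        recorder_at("4", -500.0, 500.0),
    ]


@pytest.fixture
def triangle_array() -> list[Recorder]:
    """Equilateral triangle of recorders, 1 km sides, centroid at origin."""
    r = 1000.0 / math.sqrt(3.0)
    return [
        recorder_at("A", r * math.cos(math.radians(90)), r * math.sin(math.radians(90))),
        recorder_at("B", r * math.cos(math.radians(210)), r * math.sin(math.radians(210))),
        recorder_at("C", r * math.cos(math.radians(330)), r * math.sin(math.radians(330))),
    ]


def brute_force_grid_min(
    rec_xy: np.ndarray,
    ref_idx: int,
    deltas: np.ndarray,
    c: float,
    lo: np.ndarray,
    hi: np.ndarray,
    cell: float = 1.0,
    chunk: int = 400_000,
) -> float:
    """Exhaustive grid minimum of the TDOA least-squares objective.

    Independent of the solver: evaluates Σ[(|s−r_i|−|s−r_ref|)/c − Δt_i]²
    directly on every grid node.
    """
    gx = np.arange(lo[0], hi[0] + cell, cell)
    gy = np.arange(lo[1], hi[1] + cell, cell)
    best = np.inf
    n_chunks = max(1, len(gx) * len(gy) // chunk)
    for ys in np.array_split(gy, n_chunks):
        xx, yy = np.meshgrid(gx, ys)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        d = np.linalg.norm(pts[:, None, :] - rec_xy[None, :, :], axis=2)
        rel = np.delete(d, ref_idx, axis=1) - d[:, ref_idx : ref_idx + 1]
        obj = np.sum((rel / c - deltas[None, :]) ** 2, axis=1)
        best = min(best, float(obj.min()))
    return best


def point_in_convex_polygon_oracle(p: np.ndarray, vertices: np.ndarray) -> bool:
    """Hand-rolled containment check for a convex polygon (CCW or CW hull
    vertices): the point is inside iff every edge cross product has the
    same sign (zero allowed — boundary counts as inside)."""
    n = len(vertices)
    signs = []
    for i in range(n):
        a, b = vertices[i], vertices[(i + 1) % n]
        cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
        signs.append(cross)
    signs = np.asarray(signs)
    return bool((signs >= -1e-9).all() or (signs <= 1e-9).all())
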