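"""Fold-front geometry: containers and the core measurement operators.

A fold front is an open polyline in the transverse plane of the animal:
x is the medial-lateral (ML) position in µm (midline at 0) and z is depth in
µm, positive inward (basal), so deepening increases z.

The measurement convention throughout is the triplet convention of the source
data: local curvature at an anchor is the inverse circumradius of the circle
through the anchor point and the two points located ``half_span`` (22.5 µm by
default) away *along arc length* on either side; the local tangent is the
chord between those two flanking points, and the local normal is the
perpendicular to that chord oriented toward +z (inward).  Signed curvature is
positive when the circumcenter lies on the +z side, so that under tension the
model predicts a positive (deepening) normal speed wherever curvature is
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, GeometryError

#: Default triplet half-span (µm, along arc length).
DEFAULT_HALF_SPAN = 22.5

#: Default temporal smoothing window, 1 h 45 min.
DEFAULT_TIME_WINDOW = 1.75


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FoldFront:
    """One sampled fold front at one time point.

    Parameters
    ----------
    time : float
        Developmental time in hAPF.
    points : (N, 2) ndarray
        Ordered ``(x, z)`` landmark positions in µm.
    side : str
        ``"apical"`` or ``"basal"``.
    closed : bool
        Whether the polyline is a closed loop (used by the flow simulator for
        periodic test geometries; measured fronts are open).
    """

    time: float
    points: np.ndarray
    side: str = "apical"
    closed: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise GeometryError("a fold front needs at least 3 (x, z) points")
        if np.any(~np.isfinite(pts)):
            raise GeometryError("non-finite coordinates in fold front")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise GeometryError("consecutive duplicate points in fold front")
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each vertex (0 at the first point)."""
        return _cumlen(self.points, self.closed)[: self.n_points]

    @property
    def length(self) -> float:
        """Total arc length (including the closing segment if closed)."""
        return float(_cumlen(self.points, self.closed)[-1])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Point(s) at arc length ``s``, linearly interpolated on the polyline.

        For closed fronts ``s`` wraps modulo the total length.
        """
        return _point_at_s(self.points, np.asarray(s, dtype=float), self.closed)

    def with_points(self, points: np.ndarray) -> "FoldFront":
        return replace(self, points=np.asarray(points, dtype=float))


@dataclass
class FrontSeries:
    """Time-indexed fronts for one animal."""

    animal_id: str
    fronts: list[FoldFront]
    side: str = "apical"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fronts = sorted(self.fronts, key=lambda f: f.time)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.fronts])

    def __len__(self) -> int:
        return len(self.fronts)

    def __iter__(self):
        return iter(self.fronts)

    def at_time(self, t: float, atol: float = 1e-6) -> FoldFront:
        times = self.times
        i = int(np.argmin(np.abs(times - t)))
        if abs(times[i] - t) > atol:
            raise ConfigurationError(f"no front at time {t} (nearest {times[i]})")
        return self.fronts[i]


@dataclass(frozen=True)
class ConvergenceCenter:
    """Point toward which each tracked ML position moves (midline x, adult neck depth z)."""

    x: float
    z: float


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _cumlen(points: np.ndarray, closed: bool) -> np.ndarray:
    d = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if closed:
        d = np.append(d, np.linalg.norm(points[0] - points[-1]))
    return np.concatenate([[0.0], np.cumsum(d)])


def _point_at_s(points: np.ndarray, s: np.ndarray, closed: bool) -> np.ndarray:
    cs = _cumlen(points, closed)
    total = cs[-1]
    if total == 0.0:
        raise GeometryError("zero-length polyline")
    if closed:
        s = np.mod(s, total)
        xs = np.append(points[:, 0], points[0, 0])
        zs = np.append(points[:, 1], points[0, 1])
    else:
        s = np.clip(s, 0.0, total)
        xs, zs = points[:, 0], points[:, 1]
    x = np.interp(s, cs, xs)
    z = np.interp(s, cs, zs)
    return np.stack([x, z], axis=-1)


def circumcircle_curvature(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float | np.ndarray:
    """Signed curvature (1/circumradius) of the circle through a point triplet.

    Positive when the circumcenter lies to the left of the direction of travel
    p1→p3, which for a front ordered by increasing x means the center is on the
    +z (inward) side.  Exactly 0 for collinear triplets.  Vectorized: the three
    arguments may be (..., 2) arrays.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    p3 = np.asarray(p3, float)
    a = p2 - p1
    b = p3 - p2
    c = p3 - p1
    cross = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    la = np.linalg.norm(a, axis=-1)
    lb = np.linalg.norm(b, axis=-1)
    lc = np.linalg.norm(c, axis=-1)
    denom = la * lb * lc
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(denom > 0, 2.0 * cross / np.where(denom > 0, denom, 1.0), np.nan)
    return kappa if kappa.ndim else float(kappa)


def circumcenter(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Circumcenter of a triplet; rows with collinear points return NaN."""
    p1 = np.atleast_2d(np.asarray(p1, float))
    p2 = np.atleast_2d(np.asarray(p2, float))
    p3 = np.atleast_2d(np.asarray(p3, float))
    ax, ay = p1[:, 0], p1[:, 1]
    bx, by = p2[:, 0], p2[:, 1]
    cx, cy = p3[:, 0], p3[:, 1]
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
              + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
              + (cx**2 + cy**2) * (bx - ax)) / d
    out = np.stack([ux, uy], axis=-1)
    out[d == 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_front(front: FoldFront, n_points: int) -> FoldFront:
    """Resample a front at uniform arc-length spacing.

    Output points lie on the input polyline; the first and last points are
    preserved exactly (for open fronts).
    """
    if n_points < 3:
        raise ConfigurationError("n_points must be >= 3")
    total = front.length
    if total == 0:
        raise GeometryError("zero-length front")
    if front.closed:
        s = np.linspace(0.0, total, n_points, endpoint=False)
        pts = front.point_at(s)
    else:
        s = np.linspace(0.0, total, n_points)
        pts = front.point_at(s)
        pts[0] = front.points[0]
        pts[-1] = front.points[-1]
    return front.with_points(pts)


# ---------------------------------------------------------------------------
# local curvature and normal speed
# ---------------------------------------------------------------------------

def _triplet(front: FoldFront, s: float, half_span: float) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Anchor and flanking points at arc lengths s, s±half_span; None if out of support."""
    total = front.length
    if not front.closed and (s < half_span - 1e-9 or s > total - half_span + 1e-9):
        return None
    p = front.point_at(np.array([s - half_span, s, s + half_span]))
    return p[0], p[1], p[2]


def local_curvature(front: FoldFront, s: float, half_span: float = DEFAULT_HALF_SPAN) -> float:
    """Signed local curvature (µm⁻¹) at arc-length anchor ``s``.

    Inverse circumradius of the circle through the anchor and the two points
    ``half_span`` µm away along arc length.  Returns NaN when the anchor is
    closer than ``half_span`` to an endpoint (out-of-support: the caller drops
    the position).  Collinear triplets give exactly 0.
    """
    trip = _triplet(front, s, half_span)
    if trip is None:
        return float("nan")
    return float(circumcircle_curvature(*trip))


def curvatures_at(front: FoldFront, s: np.ndarray, half_span: float = DEFAULT_HALF_SPAN) -> np.ndarray:
    """Vectorized :func:`local_curvature` over an array of arc-length anchors."""
    s = np.asarray(s, float)
    pl = front.point_at(s - half_span)
    p0 = front.point_at(s)
    pr = front.point_at(s + half_span)
    kappa = np.asarray(circumcircle_curvature(pl, p0, pr), float)
    if not front.closed:
        out = (s < half_span - 1e-9) | (s > front.length - half_span + 1e-9)
        kappa = np.where(out, np.nan, kappa)
    return kappa


def local_normal(front: FoldFront, s: float, half_span: float = DEFAULT_HALF_SPAN) -> np.ndarray:
    """Unit normal at anchor ``s``: perpendicular to the flanking-point chord,
    oriented toward +z (ties broken toward +x)."""
    trip = _triplet(front, s, half_span)
    if trip is None:
        return np.array([np.nan, np.nan])
    pl, _, pr = trip
    t = pr - pl
    nt = np.linalg.norm(t)
    if nt == 0:
        raise GeometryError("degenerate tangent chord")
    t = t / nt
    n = np.array([-t[1], t[0]])
    if n[1] < 0 or (n[1] == 0 and n[0] < 0):
        n = -n
    return n


def _ray_polyline_intersection(origin: np.ndarray, direction: np.ndarray,
                               points: np.ndarray, closed: bool = False) -> float:
    """Signed distance along ``direction`` from ``origin`` to the nearest
    intersection with the polyline; NaN if there is none.

    The full line is intersected and the crossing with the smallest absolute
    parameter is returned, so a front that moved slightly backwards yields a
    small negative distance rather than a miss.
    """
    a = points[:-1]
    b = points[1:]
    if closed:
        a = np.vstack([a, points[-1]])
        b = np.vstack([b, points[0]])
    d = direction
    e = b - a
    # solve origin + t*d = a + u*e
    denom = d[0] * e[:, 1] - d[1] * e[:, 0]
    ao = a - origin
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ao[:, 0] * e[:, 1] - ao[:, 1] * e[:, 0]) / denom
        u = (ao[:, 0] * d[1] - ao[:, 1] * d[0]) / denom
    valid = (np.abs(denom) > 1e-300) & (u >= -1e-9) & (u <= 1 + 1e-9) & np.isfinite(t)
    if not np.any(valid):
        return float("nan")
    t = t[valid]
    return float(t[np.argmin(np.abs(t))])


def normal_speed(front_t: FoldFront, front_t1: FoldFront, s: float,
                 half_span: float = DEFAULT_HALF_SPAN) -> float:
    """Local normal deepening speed (µm/h) at arc-length anchor ``s``.

    Distance from the anchor point on ``front_t`` to the intersection of its
    local normal (oriented +z-ward) with the piecewise-linear front at the next
    time point, divided by the time difference.  Positive = deepening.
    Returns NaN when the anchor is out of support or the normal misses the
    next front.
    """
    dt = front_t1.time - front_t.time
    if dt <= 0:
        raise ConfigurationError("front_t1 must be later than front_t")
    n = local_normal(front_t, s, half_span)
    if np.any(np.isnan(n)):
        return float("nan")
    origin = front_t.point_at(s)
    dist = _ray_polyline_intersection(origin, n, front_t1.points, front_t1.closed)
    return dist / dt


# ---------------------------------------------------------------------------
# profiles: curvature and speed at fixed ML anchors
# ---------------------------------------------------------------------------

def _arclength_of_x(front: FoldFront, x: float) -> float:
    """Arc length of the first crossing of the vertical line at ML position x."""
    pts = front.points
    cs = front.arc_lengths()
    dx = pts[:, 0] - x
    sign = np.sign(dx)
    hit = np.where(dx == 0)[0]
    if hit.size:
        return float(cs[hit[0]])
    crossing = np.where(sign[:-1] * sign[1:] < 0)[0]
    if not crossing.size:
        return float("nan")
    i = crossing[0]
    frac = dx[i] / (dx[i] - dx[i + 1])
    seg = np.linalg.norm(pts[i + 1] - pts[i])
    return float(cs[i] + frac * seg)


def curvature_speed_profile(series: FrontSeries, positions_ml: Sequence[float],
                            half_span: float = DEFAULT_HALF_SPAN) -> pd.DataFrame:
    """Per (time, ML position) curvature and normal deepening speed for one animal.

    For each consecutive frame pair the front at time t is anchored at the
    requested ML positions (first crossing of the vertical line at each x);
    curvature is the triplet circumcircle estimate and speed the normal-ray
    distance to the next front over Δt.  Rows whose anchor is out of support
    or whose normal misses the next front are dropped.

    Returns a tidy frame with columns
    ``animal_id, time, position_ml, curvature, speed``.
    """
    rows = []
    for f0, f1 in zip(series.fronts[:-1], series.fronts[1:]):
        for x in positions_ml:
            s = _arclength_of_x(f0, x)
            if np.isnan(s):
                continue
            kappa = local_curvature(f0, s, half_span)
            if np.isnan(kappa):
                continue
            v = normal_speed(f0, f1, s, half_span)
            if np.isnan(v):
                continue
            rows.append((series.animal_id, f0.time, float(x), kappa, v))
    return pd.DataFrame(rows, columns=["animal_id", "time", "position_ml", "curvature", "speed"])


# ---------------------------------------------------------------------------
# temporal smoothing and ensemble averaging
# ---------------------------------------------------------------------------

def smooth_time(times: np.ndarray, values: np.ndarray,
                window: float = DEFAULT_TIME_WINDOW) -> np.ndarray:
    """Centered boxcar mean over a time window (default 1 h 45 min).

    Each value is replaced by the mean of the values whose times lie within
    ±window/2 (inclusive, with a small tolerance for float spacing); windows
    truncate at the edges of the series.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if times.size == 0:
        return values.copy()
    order = np.argsort(times)
    half = window / 2 + 1e-9
    out = np.empty_like(values)
    ts, vs = times[order], values[order]
    for j, t in enumerate(ts):
        m = np.abs(ts - t) <= half
        out[j] = np.nanmean(vs[m])
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    return out[inv]


def smooth_profile_time(profile: pd.DataFrame, window: float = DEFAULT_TIME_WINDOW,
                        columns: Iterable[str] = ("curvature", "speed")) -> pd.DataFrame:
    """Apply :func:`smooth_time` to profile columns, per (animal, ML position)."""
    out = profile.copy()
    for _, idx in out.groupby(["animal_id", "position_ml"]).groups.items():
        sub = out.loc[idx]
        for col in columns:
            out.loc[idx, col] = smooth_time(sub["time"].to_numpy(), sub[col].to_numpy(), window)
    return out


def ensemble_average(profiles: pd.DataFrame, min_animals: int = 5,
                     max_curvature_sem: float = 0.002) -> pd.DataFrame:
    """Average per-animal profiles over animals with the exclusion rules applied.

    Entries at a (time, ML position) sampled in fewer than ``min_animals``
    animals, or whose curvature s.e.m. exceeds ``max_curvature_sem`` (µm⁻¹),
    are removed.  The fraction of (time, position) entries removed is stored in
    ``result.attrs["removed_fraction"]``.

    Returns columns ``time, position_ml, curvature, curvature_sem, speed,
    speed_sem, n_animals``; s.e.m. is sample sd (ddof=1) over animals divided
    by √n.
    """
    g = profiles.groupby(["time", "position_ml"])
    agg = g.agg(
        curvature=("curvature", "mean"),
        curvature_sd=("curvature", lambda v: v.std(ddof=1)),
        speed=("speed", "mean"),
        speed_sd=("speed", lambda v: v.std(ddof=1)),
        n_animals=("animal_id", "nunique"),
    ).reset_index()
    agg["curvature_sem"] = (agg["curvature_sd"] / np.sqrt(agg["n_animals"])).fillna(0.0)
    agg["speed_sem"] = (agg["speed_sd"] / np.sqrt(agg["n_animals"])).fillna(0.0)
    n0 = len(agg)
    keep = (agg["n_animals"] >= min_animals) & (agg["curvature_sem"] <= max_curvature_sem)
    out = agg.loc[keep, ["time", "position_ml", "curvature", "curvature_sem",
                         "speed", "speed_sem", "n_animals"]].reset_index(drop=True)
    out.attrs["removed_fraction"] = 0.0 if n0 == 0 else 1.0 - len(out) / n0
    return out


# ---------------------------------------------------------------------------
# depth, material tracking, thickness
# ---------------------------------------------------------------------------

def track_toward_center(series: FrontSeries, center: ConvergenceCenter,
                        positions_ml: Sequence[float] | None = None,
                        t0: float | None = None) -> pd.DataFrame:
    """Material trajectories of labelled ML positions.

    Each tracked position starts at its location on the front at ``t0`` (first
    frame by default) and at every later time is the intersection of the
    straight ray from that initial location toward the convergence center with
    the front polyline.  A later front the ray fails to reach truncates the
    trajectory; truncated rows are flagged.

    Returns columns ``position_ml, time, x, z, truncated``.
    """
    if t0 is None:
        t0 = series.fronts[0].time
    f0 = series.at_time(t0)
    if positions_ml is None:
        positions_ml = f0.points[:, 0]
    rows = []
    for p in positions_ml:
        s = _arclength_of_x(f0, float(p))
        if np.isnan(s):
            continue
        start = f0.point_at(s)
        ray = np.array([center.x, center.z]) - start
        nray = np.linalg.norm(ray)
        if nray == 0:
            raise ConfigurationError("convergence center coincides with a front point")
        ray = ray / nray
        truncated = False
        for f in series.fronts:
            if f.time < t0:
                continue
            if truncated:
                rows.append((float(p), f.time, np.nan, np.nan, True))
                continue
            d = _ray_polyline_intersection(start, ray, f.points, f.closed)
            if np.isnan(d):
                truncated = True
                rows.append((float(p), f.time, np.nan, np.nan, True))
                continue
            q = start + d * ray
            rows.append((float(p), f.time, q[0], q[1], False))
    return pd.DataFrame(rows, columns=["position_ml", "time", "x", "z", "truncated"])


def neck_depth(series: FrontSeries, reference_time: float = 16.0,
               ml_range: tuple[float, float] = (-250.0, 250.0),
               positions_ml: Sequence[float] | None = None,
               center: ConvergenceCenter | None = None,
               time_atol: float = 0.51) -> pd.DataFrame:
    """Fold depth over time, relative to the front at the reference time.

    For each tracked ML position the depth at time t is the distance between
    its location on the reference front and its location on the front at t;
    depths are then averaged over positions inside ``ml_range``.  Positions are
    tracked along rays toward ``center`` when one is given (the convergence
    center has no printed value in the source data and is a required input for
    that mode), else vertically (same ML position, distance along z).

    Returns columns ``time, depth, n_positions``; depth at the reference time
    is 0.
    """
    times = series.times
    i = int(np.argmin(np.abs(times - reference_time)))
    if abs(times[i] - reference_time) > time_atol:
        raise ConfigurationError(
            f"no reference front near {reference_time} hAPF for neck_depth")
    f_ref = series.fronts[i]
    if positions_ml is None:
        positions_ml = [x for x in f_ref.points[:, 0] if ml_range[0] <= x <= ml_range[1]]
    else:
        positions_ml = [x for x in positions_ml if ml_range[0] <= x <= ml_range[1]]

    if center is not None:
        traj = track_toward_center(series, center, positions_ml, t0=f_ref.time)
        ref = traj[traj["time"] == f_ref.time].set_index("position_ml")[["x", "z"]]
        rows = []
        for t, sub in traj.groupby("time"):
            sub = sub[~sub["truncated"]].set_index("position_ml")
            common = sub.index.intersection(ref.index)
            if len(common) == 0:
                continue
            d = np.linalg.norm(sub.loc[common, ["x", "z"]].to_numpy()
                               - ref.loc[common].to_numpy(), axis=1)
            rows.append((t, float(np.mean(d)), len(common)))
        return pd.DataFrame(rows, columns=["time", "depth", "n_positions"])

    rows = []
    ref_z = {}
    for x in positions_ml:
        s = _arclength_of_x(f_ref, float(x))
        if not np.isnan(s):
            ref_z[float(x)] = f_ref.point_at(s)[1]
    for f in series.fronts:
        ds = []
        for x, z0 in ref_z.items():
            s = _arclength_of_x(f, x)
            if np.isnan(s):
                continue
            ds.append(f.point_at(s)[1] - z0)
        if ds:
            rows.append((f.time, float(np.mean(ds)), len(ds)))
    return pd.DataFrame(rows, columns=["time", "depth", "n_positions"])


def tissue_thickness(apical: FoldFront, basal: FoldFront,
                     half_span: float = DEFAULT_HALF_SPAN,
                     n_anchors: int = 50) -> pd.DataFrame:
    """Thickness profile: distance from apical anchors along the apical local
    normal to the basal polyline (NaN where the normal misses it)."""
    if abs(apical.time - basal.time) > 1e-6:
        raise ConfigurationError("apical and basal fronts must share a time point")
    total = apical.length
    anchors = np.linspace(half_span, total - half_span, n_anchors)
    rows = []
    for s in anchors:
        n = local_normal(apical, s, half_span)
        if np.any(np.isnan(n)):
            continue
        origin = apical.point_at(s)
        d = _ray_polyline_intersection(origin, n, basal.points, basal.closed)
        rows.append((origin[0], abs(d) if np.isfinite(d) else np.nan))
    return pd.DataFrame(rows, columns=["x", "thickness"])
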