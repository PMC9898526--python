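"""The curvature-tension folding model.

A thin epithelial strip under in-plane tension T(t) experiences a net inward
(Laplace) force per unit length of magnitude κT, where κ is the local
curvature of the fold front.  With inertia negligible, this force is balanced
by a normal viscous drag −μ·v_n, so the front obeys the normal-velocity law

    v_n = κ T(t) / μ .

This module provides

* :func:`simulate_flow` — explicit forward integration of that law for a
  polyline front (the forward model behind all synthetic studies),
* :func:`build_collapse` / :func:`fit_through_origin` / :func:`recover_mu` —
  the collapse of measured deepening speed against the product κ·T and the
  origin-constrained linear fit whose slope estimates 1/μ,
* :class:`TensionCurvatureModel` — a model/results wrapper around the collapse
  fit with a ``summary()`` table,
* :func:`product_error` — the first-order error propagated onto the product
  of two averaged quantities, σ_{κ·v} = κ̄σ_v + v̄σ_κ + σ_vσ_κ,
* :func:`homogeneity_cv` — the curvature-homogenisation diagnostic (under
  v_n ∝ κ, more curved regions shrink faster, so the coefficient of variation
  of curvature decreases while its mean increases).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, SimulationError
from .geometry import (
    DEFAULT_HALF_SPAN,
    FoldFront,
    FrontSeries,
    circumcenter,
    circumcircle_curvature,
    resample_front,
)

TensionFn = Callable[[float], float]


def _nearest_vertex(grid: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Index of the nearest value in sorted ``grid`` for each target."""
    j = np.searchsorted(grid, targets)
    j = np.clip(j, 1, grid.size - 1)
    left_closer = (targets - grid[j - 1]) <= (grid[j] - targets)
    return np.where(left_closer, j - 1, j)


def _as_tension_fn(schedule: TensionFn | float) -> TensionFn:
    if callable(schedule):
        return schedule
    value = float(schedule)
    return lambda t: value


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowConfig:
    """Discretisation of the normal-velocity flow.

    dt is capped by ``dt_max``, by the advective bound
    cfl·Δs_min/max|v| and by the diffusive stability bound
    cfl·Δs_min²·μ/(2T) (curvature flow is locally diffusive, so the advective
    cap alone is not sufficient for an explicit scheme).

    curvature_half_span is the arc-length half-span of the triplet used to
    evaluate the driving curvature; it defaults to the measurement convention
    (22.5 µm) so that measured and driving curvature agree pointwise.
    Per-step uniform resampling is available but off by default: resampled
    nodes land on chords of the polyline, which biases convex fronts inward by
    the chord sagitta at every step.
    """

    dt_max: float = 0.05
    cfl_fraction: float = 0.2
    boundary: str = "fixed_endpoints"
    resample_every_step: bool = False
    n_points: int | None = None
    curvature_half_span: float = DEFAULT_HALF_SPAN

    def __post_init__(self) -> None:
        if not (0.0 < self.cfl_fraction < 1.0):
            raise ConfigurationError("cfl_fraction must be in (0, 1)")
        if self.dt_max <= 0:
            raise ConfigurationError("dt_max must be positive")
        if self.boundary not in ("fixed_endpoints", "closed"):
            raise ConfigurationError(f"unknown boundary condition {self.boundary!r}")


def _node_velocities(front: FoldFront, tension: float, mu: float,
                     half_span: float) -> np.ndarray:
    """Velocity vector (µm/h) of every node: |κ|·T/μ toward the local
    circumcenter; zero where curvature vanishes or is out of support.

    The driving-curvature triplet snaps its flanks to the *vertices* nearest
    to s ± half_span rather than interpolating on the polyline: interpolated
    flank points sit on chords slightly inside a convex front, which would
    bias the curvature (and hence the shrink rate) upward at every step,
    while vertices lie on the evolving curve itself.
    """
    pts = front.points
    n = pts.shape[0]
    s = front.arc_lengths()
    total = front.length
    if front.closed:
        h = np.full(n, min(half_span, total / 4))
        idx = np.arange(n)
        # periodic nearest-vertex lookup
        s_ext = np.concatenate([s - total, s, s + total])
        il = _nearest_vertex(s_ext, s[idx] - h) % n
        ir = _nearest_vertex(s_ext, s[idx] + h) % n
        il = np.where(il == idx, (idx - 1) % n, il)
        ir = np.where(ir == idx, (idx + 1) % n, ir)
    else:
        # interior nodes only; shrink the span symmetrically near the ends
        idx = np.arange(1, n - 1)
        h = np.minimum(half_span, np.minimum(s[idx], total - s[idx]))
        il = _nearest_vertex(s, s[idx] - h)
        ir = _nearest_vertex(s, s[idx] + h)
        il = np.minimum(il, idx - 1)
        ir = np.maximum(ir, idx + 1)
    pl = pts[il]
    p0 = pts[idx]
    pr = pts[ir]
    kappa = np.asarray(circumcircle_curvature(pl, p0, pr), float)
    centers = circumcenter(pl, p0, pr)
    vel = np.zeros((n, 2))
    curved = np.isfinite(kappa) & (kappa != 0.0) & np.isfinite(centers).all(axis=-1) & (h > 1e-9)
    if np.any(curved):
        to_center = centers[curved] - p0[curved]
        # |center - p| = 1/|κ|, so the unit direction is (center - p)·|κ|
        u = to_center * np.abs(kappa[curved])[:, None]
        speed = np.abs(kappa[curved]) * tension / mu
        vel[idx[curved]] = speed[:, None] * u
    return vel


def simulate_flow(front0: FoldFront, tension_schedule: TensionFn | float, mu: float,
                  t_start: float, t_end: float, config: FlowConfig | None = None,
                  record_times: Sequence[float] | None = None) -> FrontSeries:
    """Integrate v_n = κT(t)/μ forward in time for one front.

    Explicit Euler stepping with adaptive dt (see :class:`FlowConfig`).  Open
    fronts keep their endpoints fixed (pinned tissue edges); closed fronts are
    treated periodically.  Returns a :class:`FrontSeries` holding the front at
    ``record_times`` (default: 25 evenly spaced times including both ends).
    """
    if mu <= 0:
        raise ConfigurationError("mu must be positive")
    if t_end <= t_start:
        raise ConfigurationError("t_end must exceed t_start")
    config = config or FlowConfig()
    if config.boundary == "closed" and not front0.closed:
        front0 = replace(front0, closed=True)
    tension = _as_tension_fn(tension_schedule)
    if record_times is None:
        record_times = np.linspace(t_start, t_end, 25)
    record_times = np.sort(np.asarray(record_times, dtype=float))
    if record_times[0] < t_start - 1e-9 or record_times[-1] > t_end + 1e-9:
        raise ConfigurationError("record_times outside [t_start, t_end]")

    half_span = config.curvature_half_span
    pts = front0.points.copy()
    t = t_start
    recorded: list[FoldFront] = []
    next_rec = 0
    eps = 1e-9

    def maybe_record(time: float) -> None:
        nonlocal next_rec
        while next_rec < len(record_times) and record_times[next_rec] <= time + eps:
            recorded.append(FoldFront(time=float(record_times[next_rec]),
                                      points=pts.copy(), side=front0.side,
                                      closed=front0.closed))
            next_rec += 1

    maybe_record(t)
    guard = 0
    max_steps = 5_000_000
    while t < t_end - eps:
        guard += 1
        if guard > max_steps:
            raise SimulationError(f"step limit exceeded at t = {t:.4f} h")
        front = FoldFront(time=t, points=pts, side=front0.side, closed=front0.closed)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if front0.closed:
            seg = np.append(seg, np.linalg.norm(pts[0] - pts[-1]))
        min_seg = float(seg.min())
        if not np.isfinite(min_seg) or min_seg < 1e-9:
            raise SimulationError(f"degenerate segment at t = {t:.4f} h")
        T = float(tension(t))
        if T < 0:
            raise ConfigurationError(f"negative tension at t = {t:.4f} h")
        vel = _node_velocities(front, T, mu, half_span)
        vmax = float(np.max(np.linalg.norm(vel, axis=1)))
        dt = config.dt_max
        if vmax > 0:
            dt = min(dt, config.cfl_fraction * min_seg / vmax)
        if T > 0:
            dt = min(dt, config.cfl_fraction * min_seg**2 * mu / (2.0 * T))
        if dt <= 0 or not np.isfinite(dt):
            raise SimulationError(f"stability bound collapsed at t = {t:.4f} h")
        # land exactly on the next record time and on t_end
        if next_rec < len(record_times):
            dt = min(dt, record_times[next_rec] - t)
        dt = min(dt, t_end - t)
        dt = max(dt, eps)
        pts = pts + vel * dt
        t = t + dt
        if config.resample_every_step:
            n_res = config.n_points or pts.shape[0]
            pts = resample_front(
                FoldFront(time=t, points=pts, side=front0.side, closed=front0.closed),
                n_res).points
        maybe_record(t)
    maybe_record(t_end)
    return FrontSeries(animal_id="sim", fronts=recorded, side=front0.side,
                       metadata={"mu": mu, "flow_config": config})


# ---------------------------------------------------------------------------
# error propagation, collapse assembly
# ---------------------------------------------------------------------------

def product_error(kappa_mean: float | np.ndarray, kappa_err: float | np.ndarray,
                  v_mean: float | np.ndarray, v_err: float | np.ndarray) -> float | np.ndarray:
    """Error on the product of two averaged quantities:
    σ_{κ·v} = κ̄·σ_v + v̄·σ_κ + σ_v·σ_κ (cross term included)."""
    kappa_mean = np.abs(np.asarray(kappa_mean, float))
    v_mean = np.abs(np.asarray(v_mean, float))
    kappa_err = np.asarray(kappa_err, float)
    v_err = np.asarray(v_err, float)
    if np.any(kappa_err < 0) or np.any(v_err < 0):
        raise ConfigurationError("errors must be nonnegative")
    out = kappa_mean * v_err + v_mean * kappa_err + v_err * kappa_err
    return out if out.ndim else float(out)


def build_collapse(profile: pd.DataFrame,
                   tension: pd.DataFrame | Mapping[float, pd.DataFrame],
                   time_tolerance: float = 1e-6) -> pd.DataFrame:
    """Join an ensemble curvature/speed profile with a tension-proxy curve.

    ``profile`` has columns ``time, position_ml, curvature, curvature_sem,
    speed, speed_sem`` (see :func:`foldflow.geometry.ensemble_average`);
    ``tension`` is either one curve with columns ``dev_time, mean, sd``
    (applied at every ML position) or a mapping position → curve (the output
    of :func:`foldflow.recoil.assemble_tension_proxy`).  Rows are matched on
    nearest time within ``time_tolerance``; the unmatched rest is dropped
    (inner join).  Adds ``tension, tension_sd, product = curvature·tension``
    and the propagated ``product_sem`` (:func:`product_error`).
    """
    req = {"time", "position_ml", "curvature", "speed"}
    if not req.issubset(profile.columns):
        raise ConfigurationError(f"profile must have columns {sorted(req)}")
    prof = profile.copy()
    for col in ("curvature_sem", "speed_sem"):
        if col not in prof.columns:
            prof[col] = 0.0

    def join_one(sub: pd.DataFrame, curve: pd.DataFrame) -> pd.DataFrame:
        curve = curve.rename(columns={"dev_time": "time"}).sort_values("time")
        if "sd" not in curve.columns:
            curve = curve.assign(sd=0.0)
        merged = pd.merge_asof(sub.sort_values("time"), curve[["time", "mean", "sd"]],
                               on="time", direction="nearest",
                               tolerance=time_tolerance)
        merged = merged.dropna(subset=["mean"])
        return merged.rename(columns={"mean": "tension", "sd": "tension_sd"})

    if isinstance(tension, pd.DataFrame):
        out = join_one(prof, tension)
    else:
        parts = []
        for pos, sub in prof.groupby("position_ml"):
            if pos in tension:
                parts.append(join_one(sub, tension[pos]))
        out = pd.concat(parts, ignore_index=True) if parts else prof.iloc[0:0].assign(
            tension=np.nan, tension_sd=np.nan)
    if out.empty:
        import warnings

        warnings.warn("collapse dataset is empty (no overlapping support)")
        out = out.assign(product=np.nan, product_sem=np.nan)
        return out.reset_index(drop=True)
    out["product"] = out["curvature"] * out["tension"]
    out["product_sem"] = product_error(out["curvature"], out["curvature_sem"],
                                       out["tension"], out["tension_sd"])
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# origin-constrained fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Line-through-origin fit y = slope·x."""

    slope: float
    slope_sd: float
    r_squared: float
    r_squared_uncentered: float
    n_points: int
    weighted: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, float)


def fit_through_origin(x: np.ndarray, y: np.ndarray,
                       weights: np.ndarray | None = None) -> FitResult:
    """Least-squares line through the origin.

    slope = Σwxy/Σwx² (unweighted by default; pass 1/sem² weights for a
    dispersion-weighted fit).  R² is reported both centered
    (1 − SS_res/Σ(y−ȳ)², can be ≤ 0 for a poor fit) and uncentered
    (1 − SS_res/Σy²).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if weights is not None:
        w = np.asarray(weights, float)[ok]
    else:
        w = np.ones_like(x)
    n = x.size
    if n < 2:
        raise ConfigurationError("need at least 2 points for the origin fit")
    sxx = float(np.sum(w * x * x))
    if sxx == 0:
        raise ConfigurationError("singular origin fit: all x are zero")
    slope = float(np.sum(w * x * y)) / sxx
    resid = y - slope * x
    ss_res = float(np.sum(w * resid**2))
    dof = max(n - 1, 1)
    slope_var = ss_res / dof / sxx
    ybar = float(np.sum(w * y) / np.sum(w))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    ss_tot_unc = float(np.sum(w * y**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    r2u = 1.0 - ss_res / ss_tot_unc if ss_tot_unc > 0 else 1.0
    return FitResult(slope=slope, slope_sd=float(np.sqrt(slope_var)),
                     r_squared=r2, r_squared_uncentered=r2u, n_points=n,
                     weighted=weights is not None)


@dataclass(frozen=True)
class MuEstimate:
    """Dissipative prefactor recovered from a collapse dataset."""

    mu: float
    mu_sd: float
    r_squared: float
    slope: float
    model_violation: bool
    fit: FitResult


def recover_mu(collapse: pd.DataFrame, weighted: bool = False) -> MuEstimate:
    """Estimate μ from a collapse dataset: μ̂ = 1/slope of the origin fit of
    deepening speed against κ·T.

    A nonpositive slope (speed anti-correlated with κT) is a signalled model
    violation, not an exception: ``model_violation`` is set and μ̂ is NaN.
    """
    if collapse.empty:
        raise ConfigurationError("empty collapse dataset")
    w = None
    if weighted:
        sem = collapse["speed_sem"].to_numpy(float)
        w = np.where(sem > 0, 1.0 / sem**2, np.nan)
        w = np.where(np.isfinite(w), w, np.nanmax(w[np.isfinite(w)]) if np.any(np.isfinite(w)) else 1.0)
    fit = fit_through_origin(collapse["product"].to_numpy(float),
                             collapse["speed"].to_numpy(float), weights=w)
    if fit.slope <= 0:
        return MuEstimate(mu=float("nan"), mu_sd=float("nan"),
                          r_squared=fit.r_squared, slope=fit.slope,
                          model_violation=True, fit=fit)
    mu = 1.0 / fit.slope
    mu_sd = fit.slope_sd / fit.slope**2  # first-order delta method
    return MuEstimate(mu=mu, mu_sd=mu_sd, r_squared=fit.r_squared,
                      slope=fit.slope, model_violation=False, fit=fit)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class TensionCurvatureModel:
    """Origin-constrained linear model v_n = (1/μ)·(κT) on a collapse dataset.

    Examples
    --------
    >>> model = TensionCurvatureModel.from_collapse(collapse_df)  # doctest: +SKIP
    >>> res = model.fit()                                         # doctest: +SKIP
    >>> print(res.summary())                                      # doctest: +SKIP
    """

    def __init__(self, speed: np.ndarray, product: np.ndarray,
                 speed_sem: np.ndarray | None = None,
                 product_sem: np.ndarray | None = None,
                 data: pd.DataFrame | None = None):
        self.speed = np.asarray(speed, float)
        self.product = np.asarray(product, float)
        self.speed_sem = None if speed_sem is None else np.asarray(speed_sem, float)
        self.product_sem = None if product_sem is None else np.asarray(product_sem, float)
        self.data = data

    @classmethod
    def from_collapse(cls, collapse: pd.DataFrame) -> "TensionCurvatureModel":
        return cls(speed=collapse["speed"].to_numpy(float),
                   product=collapse["product"].to_numpy(float),
                   speed_sem=collapse.get("speed_sem"),
                   product_sem=collapse.get("product_sem"),
                   data=collapse)

    from_dataframe = from_collapse

    def fit(self, weighted: bool = False) -> "TensionCurvatureResults":
        w = None
        if weighted:
            if self.speed_sem is None:
                raise ConfigurationError("weighted fit requires speed_sem")
            sem = np.asarray(self.speed_sem, float)
            w = np.where(sem > 0, 1.0 / sem**2, np.nan)
            if np.any(np.isfinite(w)):
                w = np.where(np.isfinite(w), w, np.nanmax(w))
            else:
                w = None
        fit = fit_through_origin(self.product, self.speed, weights=w)
        return TensionCurvatureResults(self, fit)


@dataclass
class TensionCurvatureResults:
    """Fit results: slope (≙ 1/μ), its uncertainty, μ̂ and goodness of fit."""

    model: TensionCurvatureModel
    fit_result: FitResult

    @property
    def slope(self) -> float:
        return self.fit_result.slope

    @property
    def bse(self) -> float:
        return self.fit_result.slope_sd

    @property
    def rsquared(self) -> float:
        return self.fit_result.r_squared

    @property
    def rsquared_uncentered(self) -> float:
        return self.fit_result.r_squared_uncentered

    @property
    def nobs(self) -> int:
        return self.fit_result.n_points

    @property
    def model_violation(self) -> bool:
        return self.fit_result.slope <= 0

    @property
    def mu(self) -> float:
        return float("nan") if self.model_violation else 1.0 / self.slope

    @property
    def mu_sd(self) -> float:
        return float("nan") if self.model_violation else self.bse / self.slope**2

    def predict(self, product: np.ndarray) -> np.ndarray:
        return self.fit_result.predict(product)

    def summary(self) -> str:
        lines = [
            "Tension-curvature collapse fit (line through origin)",
            "=" * 54,
            f"{'n points':<28}{self.nobs:>26d}",
            f"{'slope (1/mu)':<28}{self.slope:>26.6g}",
            f"{'slope std err':<28}{self.bse:>26.6g}",
            f"{'mu (dissipative prefactor)':<28}{self.mu:>26.6g}",
            f"{'mu std err':<28}{self.mu_sd:>26.6g}",
            f"{'R^2 (centered)':<28}{self.rsquared:>26.4f}",
            f"{'R^2 (uncentered)':<28}{self.rsquared_uncentered:>26.4f}",
            f"{'weighted':<28}{str(self.fit_result.weighted):>26}",
        ]
        if self.model_violation:
            lines.append("WARNING: nonpositive slope — speed anti-correlates with kappa*T")
        return "\n".join(lines)

    def plot_collapse(self, ax=None):
        """Deepening speed against κ·T with the fitted line (error bars when
        the model carries sems)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.errorbar(m.product, m.speed,
                    xerr=m.product_sem, yerr=m.speed_sem,
                    fmt="o", ms=4, alpha=0.7, label="data")
        xs = np.linspace(0, np.nanmax(m.product) * 1.05, 50)
        ax.plot(xs, self.predict(xs), "k--",
                label=f"slope = {self.slope:.3g}, $R^2$ = {self.rsquared:.2f}")
        ax.set_xlabel("curvature × tension proxy")
        ax.set_ylabel("deepening speed (µm/h)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# curvature homogenisation diagnostic
# ---------------------------------------------------------------------------

def homogeneity_cv(series: FrontSeries, half_span: float = DEFAULT_HALF_SPAN) -> pd.DataFrame:
    """Coefficient of variation of curvature along each front over time.

    For each front, curvature is evaluated at every vertex whose triplet is in
    support; CV = sd(κ)/mean(κ).  Times with nonpositive mean curvature give
    NaN (the CV of a sign-changing profile is not meaningful).

    Returns columns ``time, mean_curvature, cv, n_samples``.
    """
    rows = []
    from .geometry import curvatures_at

    for f in series.fronts:
        s = f.arc_lengths()
        kappa = curvatures_at(f, s, half_span)
        kappa = kappa[np.isfinite(kappa)]
        if kappa.size < 3:
            raise ConfigurationError("front too short for >=3 curvature samples")
        mean = float(np.mean(kappa))
        if mean <= 0:
            rows.append((f.time, mean, np.nan, kappa.size))
            continue
        cv = float(np.std(kappa, ddof=1) / mean)
        rows.append((f.time, mean, cv, kappa.size))
    return pd.DataFrame(rows, columns=["time", "mean_curvature", "cv", "n_samples"])
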