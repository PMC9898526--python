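"""Synthetic study generator: every input the analysis pipeline consumes,
with known ground truth.

The generator emulates a multi-animal live-imaging study of an invaginating
fold observed in transverse (ML × depth) sections:

* fold-front ensembles evolving under v_n = κT(t)/μ from a configurable
  initial geometry — a uniform ~300 µm arc, an arc flattened medially by
  coverslip contact, or an arc with one lateral flank flattened;
* an increasing tension schedule T(t) (laser-ablation recoil velocities rise
  during folding, so the default study uses a linear ramp);
* Gaussian landmark measurement noise on the sampled fronts;
* recoil-velocity proxy tables (T times a proxy constant, with multiplicative
  log-normal noise so values stay positive);
* post-ablation displacement traces d(t) = v₀τ(1 − e^{−t/τ}) + noise;
* fiber images (bright straight bars with known orientation/length) and
  z-stacks with a known surface height map for the image operators.

Tension units are arbitrary (the proxy is a recoil velocity, µm/s): the
collapse slope absorbs the units, so μ carries hybrid units
(µm⁻¹·µm/s)/(µm/h).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .exceptions import ConfigurationError
from .geometry import FoldFront, FrontSeries, resample_front
from .model import FlowConfig, simulate_flow


# ---------------------------------------------------------------------------
# tension schedules
# ---------------------------------------------------------------------------

class TensionSchedule(BaseModel):
    """Tension as a function of developmental time (arbitrary units ≥ 0).

    ``constant``: parameters = [T0].
    ``linear_ramp``: parameters = [T0, T1, t0, t1]; linear between (t0, T0)
    and (t1, T1), clamped outside.
    ``piecewise_table``: parameters = [[t, T], ...] with strictly increasing
    times; linear interpolation, clamped outside.
    """

    kind: Literal["constant", "linear_ramp", "piecewise_table"]
    parameters: list

    @model_validator(mode="after")
    def _check(self) -> "TensionSchedule":
        if self.kind == "constant":
            if len(self.parameters) != 1:
                raise ValueError("constant schedule takes [T0]")
            if self.parameters[0] < 0:
                raise ValueError("tension must be nonnegative")
        elif self.kind == "linear_ramp":
            if len(self.parameters) != 4:
                raise ValueError("linear_ramp takes [T0, T1, t0, t1]")
            t0_, t1_ = self.parameters[2], self.parameters[3]
            if t1_ <= t0_:
                raise ValueError("ramp breakpoint times must increase")
            if self.parameters[0] < 0 or self.parameters[1] < 0:
                raise ValueError("tension must be nonnegative")
        else:
            pts = self.parameters
            if len(pts) < 2:
                raise ValueError("piecewise_table needs >= 2 breakpoints")
            times = [p[0] for p in pts]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError("breakpoint times must be strictly increasing")
            if any(p[1] < 0 for p in pts):
                raise ValueError("tension must be nonnegative")
        return self

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            out = np.full_like(t, float(self.parameters[0]))
        elif self.kind == "linear_ramp":
            T0, T1, t0, t1 = (float(p) for p in self.parameters)
            out = np.interp(t, [t0, t1], [T0, T1])
        else:
            times = np.array([p[0] for p in self.parameters], float)
            vals = np.array([p[1] for p in self.parameters], float)
            out = np.interp(t, times, vals)
        return out if out.ndim else float(out)


def make_tension_schedule(kind: str, parameters: Sequence) -> TensionSchedule:
    """Validated :class:`TensionSchedule` constructor."""
    try:
        return TensionSchedule(kind=kind, parameters=list(parameters))
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from exc


# ---------------------------------------------------------------------------
# initial geometries
# ---------------------------------------------------------------------------

def make_initial_front(geometry: str, arc_radius: float = 300.0,
                       flat_half_width: float = 100.0, span: float = 600.0,
                       n_points: int = 101, time: float = 18.0,
                       side: str = "apical") -> FoldFront:
    """Initial fold-front geometry, parameterised by arc length.

    ``uniform_arc``
        circular arc of radius ``arc_radius`` (curvature center on the +z /
        inward side), total arc length ``span``, apex at the midline (0, 0);
    ``flattened_medial``
        straight horizontal segment for |s| ≤ flat_half_width joined
        tangentially to circular flanks of radius ``arc_radius`` (coverslip
        contact centered on the midline);
    ``flattened_lateral``
        the uniform arc with one flank replaced by its tangent line: for
        s below −span/2 + 2·flat_half_width the curve continues straight
        along the tangent at the junction (lateral coverslip contact).

    Points are uniformly spaced in arc length.
    """
    if n_points < 5:
        raise ConfigurationError("n_points must be >= 5")
    if arc_radius <= 0 or span <= 0:
        raise ConfigurationError("arc_radius and span must be positive")
    if flat_half_width < 0:
        raise ConfigurationError("flat_half_width must be >= 0")
    if geometry in ("flattened_medial", "flattened_lateral") and flat_half_width >= span / 2:
        raise GeometryDegenerateError(geometry, flat_half_width, span)
    if geometry == "uniform_arc" and span > np.pi * arc_radius:
        raise ConfigurationError("span exceeds half the circle circumference")

    s = np.linspace(-span / 2, span / 2, n_points)

    def arc_point(sv: np.ndarray, center_x: float, s_offset: np.ndarray) -> np.ndarray:
        """Point on a circle of radius arc_radius centered at (center_x, r),
        at arc length |s_offset| from its lowest point, on the sign(sv) side."""
        phi = np.abs(s_offset) / arc_radius
        x = center_x + np.sign(sv) * arc_radius * np.sin(phi)
        z = arc_radius * (1.0 - np.cos(phi))
        return np.stack([x, z], axis=-1)

    if geometry == "uniform_arc":
        phi = s / arc_radius
        pts = np.stack([arc_radius * np.sin(phi),
                        arc_radius * (1.0 - np.cos(phi))], axis=-1)
    elif geometry == "flattened_medial":
        w = flat_half_width
        flat = np.abs(s) <= w
        pts = np.empty((n_points, 2))
        pts[flat] = np.stack([s[flat], np.zeros(flat.sum())], axis=-1)
        sf = s[~flat]
        pts[~flat] = arc_point(sf, np.sign(sf) * w, np.abs(sf) - w)
    elif geometry == "flattened_lateral":
        s_j = -span / 2 + 2.0 * flat_half_width  # junction arc length
        pts = np.empty((n_points, 2))
        on_arc = s >= s_j
        phi = s[on_arc] / arc_radius
        pts[on_arc] = np.stack([arc_radius * np.sin(phi),
                                arc_radius * (1.0 - np.cos(phi))], axis=-1)
        # tangent continuation beyond the junction
        phi_j = s_j / arc_radius
        p_j = np.array([arc_radius * np.sin(phi_j), arc_radius * (1.0 - np.cos(phi_j))])
        tangent = np.array([np.cos(phi_j), np.sin(phi_j)])  # d(point)/ds at s_j
        ds = (s[~on_arc] - s_j)[:, None]
        pts[~on_arc] = p_j + ds * tangent
    else:
        raise ConfigurationError(f"unknown geometry {geometry!r}")
    return FoldFront(time=time, points=pts, side=side)


def make_flattened_contour(arc_radius: float = 300.0, flat_half_width: float = 100.0,
                           n_points: int = 200, time: float = 18.0) -> FoldFront:
    """Closed transverse body outline flattened by coverslip contact.

    A circle of radius ``arc_radius`` (the ~300 µm transverse outline) whose
    apical-most region is clipped by the coverslip plane: every point closer
    to the plane than the chord at half-width ``flat_half_width`` is projected
    onto it.  The result is the closed analogue of the ``flattened_medial``
    open front and is the natural geometry for curvature-homogenisation
    studies: a closed convex contour under v_n = κT/μ conserves its total
    turning (2π) while its length shrinks, so its mean curvature rises while
    flat regions round out.

    Points are returned at uniform arc-length spacing; the front is marked
    ``closed``.
    """
    if flat_half_width >= arc_radius:
        raise ConfigurationError("flat_half_width must be smaller than arc_radius")
    r, w = arc_radius, flat_half_width
    clip_z = r - np.sqrt(r**2 - w**2)  # coverslip plane depth below the apex
    theta = np.linspace(0.0, 2.0 * np.pi, 4 * n_points, endpoint=False)
    # apex of the outline at z = 0, center at (0, r)
    pts = np.stack([r * np.sin(theta), r - r * np.cos(theta)], axis=-1)
    pts[:, 1] = np.maximum(pts[:, 1], clip_z)
    contour = FoldFront(time=time, points=pts, closed=True)
    return resample_front(contour, n_points)


class GeometryDegenerateError(ConfigurationError):
    def __init__(self, geometry: str, flat_half_width: float, span: float):
        super().__init__(
            f"{geometry}: flat_half_width {flat_half_width} >= span/2 {span / 2}"
            " leaves no curved flank")


# ---------------------------------------------------------------------------
# study configuration
# ---------------------------------------------------------------------------

def default_tension_schedule() -> TensionSchedule:
    """Linear ramp 0.2 → 0.6 µm/s (recoil-proxy units) over 18 → 24 hAPF."""
    return TensionSchedule(kind="linear_ramp", parameters=[0.2, 0.6, 18.0, 24.0])


class SyntheticStudyConfig(BaseModel):
    """Complete description of a synthetic multi-animal folding study.

    Defaults describe the reference study: 10 animals, a 300 µm arc flattened
    medially over ±100 µm, tension ramping 0.2 → 0.6 (proxy units) over
    18 → 24 hAPF, frames every 15 min, landmarks every ~20 µm with 0.5 µm
    Gaussian noise, and 5 % multiplicative recoil-proxy noise.  μ = 5e-4 sets
    deepening speeds of ≈ 0.5–2.5 µm/h: slow enough that the initial
    curvature heterogeneity (the signal the collapse fit rests on) survives
    the 6 h observation window instead of being erased by homogenisation,
    while staying inside the speed range observed in vivo.
    """

    n_animals: int = Field(default=10, ge=1)
    initial_geometry: Literal["uniform_arc", "flattened_medial", "flattened_lateral"] = (
        "flattened_medial")
    arc_radius: float = Field(default=300.0, gt=0)
    flat_half_width: float = Field(default=100.0, ge=0)
    span: float = Field(default=600.0, gt=0)
    n_points: int = Field(default=101, ge=5)
    mu: float = Field(default=5e-4, gt=0)
    tension_schedule: TensionSchedule = Field(default_factory=default_tension_schedule)
    landmark_noise_sd: float = Field(default=0.5, ge=0)
    landmark_spacing: float | None = Field(default=20.0, gt=0)
    proxy_constant: float = Field(default=1.0, gt=0)
    proxy_noise_cv: float = Field(default=0.05, ge=0)
    frame_interval: float = Field(default=0.25, gt=0)
    t_start: float = 18.0
    t_end: float = 24.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticStudyConfig":
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        return self


@dataclass
class GroundTruth:
    """Noiseless truth for a synthetic study."""

    mu: float
    tension_schedule: TensionSchedule
    true_fronts: dict[str, FrontSeries]

    def tension_at(self, t: float) -> float:
        return float(self.tension_schedule(t))


# ---------------------------------------------------------------------------
# forward simulation of animals and ensembles
# ---------------------------------------------------------------------------

def simulate_animal(front0: FoldFront, schedule: TensionSchedule, mu: float,
                    frame_interval: float, t_start: float, t_end: float,
                    landmark_noise_sd: float = 0.0, seed: int = 0,
                    animal_id: str = "animal_0",
                    landmark_spacing: float | None = None,
                    flow_config: FlowConfig | None = None) -> tuple[FrontSeries, FrontSeries]:
    """Simulate one animal: noiseless flow plus landmark measurement.

    The flow is integrated on the (dense) node grid of ``front0``; the
    *observed* series then emulates manual segmentation: each frame is
    resampled to landmarks spaced ``landmark_spacing`` µm apart (the manual
    protocol places one roughly every 20 µm; ``None`` keeps the simulation
    nodes) and every landmark is displaced by independent zero-mean Gaussian
    offsets of sd ``landmark_noise_sd`` in both coordinates.

    Returns ``(observed, truth)`` front series sampled at every frame time;
    with zero noise and no respacing the two are identical.  Identical seeds
    give identical output.
    """
    if frame_interval <= 0:
        raise ConfigurationError("frame_interval must be positive")
    n_frames = int(round((t_end - t_start) / frame_interval)) + 1
    frames = t_start + frame_interval * np.arange(n_frames)
    truth = simulate_flow(front0, schedule, mu, t_start, t_end,
                          config=flow_config, record_times=frames)
    truth = FrontSeries(animal_id, truth.fronts, truth.side, truth.metadata)
    rng = np.random.default_rng(seed)
    observed_fronts = []
    for f in truth.fronts:
        g = f
        if landmark_spacing is not None:
            n_marks = max(3, int(round(g.length / landmark_spacing)) + 1)
            g = resample_front(g, n_marks)
        pts = g.points.copy()
        if landmark_noise_sd > 0:
            pts = pts + rng.normal(0.0, landmark_noise_sd, size=pts.shape)
        observed_fronts.append(FoldFront(time=g.time, points=pts, side=g.side,
                                         closed=g.closed))
    observed = FrontSeries(animal_id, observed_fronts, truth.side,
                           {"landmark_noise_sd": landmark_noise_sd, "seed": seed,
                            "landmark_spacing": landmark_spacing})
    return observed, truth


def simulate_ensemble(config: SyntheticStudyConfig,
                      flow_config: FlowConfig | None = None
                      ) -> tuple[list[FrontSeries], pd.DataFrame, GroundTruth]:
    """Simulate the full study: per-animal front series, a recoil-proxy table
    and the ground truth.

    Per-animal seeds are derived as ``config.seed + animal_index`` so that a
    subset of animals is reproducible independently of ``n_animals``.  The
    recoil table holds, per animal and frame time, T(t)·proxy_constant times
    multiplicative log-normal noise of coefficient of variation
    ``proxy_noise_cv``.
    """
    front0 = make_initial_front(config.initial_geometry, config.arc_radius,
                                config.flat_half_width, config.span,
                                config.n_points, time=config.t_start)
    series_list: list[FrontSeries] = []
    truth_fronts: dict[str, FrontSeries] = {}
    recoil_rows = []
    frames = config.t_start + config.frame_interval * np.arange(
        int(round((config.t_end - config.t_start) / config.frame_interval)) + 1)
    schedule = config.tension_schedule
    for i in range(config.n_animals):
        animal_id = f"animal_{i}"
        seed_i = config.seed + i
        observed, truth = simulate_animal(
            front0, schedule, config.mu, config.frame_interval,
            config.t_start, config.t_end, config.landmark_noise_sd,
            seed=seed_i, animal_id=animal_id,
            landmark_spacing=config.landmark_spacing, flow_config=flow_config)
        series_list.append(observed)
        truth_fronts[animal_id] = truth
        # recoil proxy: separate stream so front noise and proxy noise decouple
        rng = np.random.default_rng(seed_i + 1_000_003)
        base = np.asarray(schedule(frames), float) * config.proxy_constant
        if config.proxy_noise_cv > 0:
            sigma = np.sqrt(np.log1p(config.proxy_noise_cv**2))
            noise = np.exp(rng.normal(-sigma**2 / 2, sigma, size=base.shape))
        else:
            noise = np.ones_like(base)
        for t, v in zip(frames, base * noise):
            recoil_rows.append((animal_id, float(t), float(v)))
    recoil = pd.DataFrame(recoil_rows, columns=["animal_id", "dev_time", "recoil"])
    truth = GroundTruth(mu=config.mu, tension_schedule=schedule,
                        true_fronts=truth_fronts)
    return series_list, recoil, truth


# ---------------------------------------------------------------------------
# ablation recoil traces
# ---------------------------------------------------------------------------

def synth_recoil_trace(v0: float, tau: float, duration: float, dt: float,
                       noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Post-ablation displacement trace d(t) = v₀·τ·(1 − e^{−t/τ}) + noise.

    Initial recoil velocity d'(0) = v₀ (µm/s); the displacement saturates at
    v₀τ.  Sampled every ``dt`` seconds from 0 to ``duration``; d(0) = 0 when
    noise is 0.  Returns columns ``t_s, displacement_um``.
    """
    if v0 < 0 or tau <= 0:
        raise ConfigurationError("need v0 >= 0 and tau > 0")
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    t = np.arange(0.0, duration + dt / 2, dt)
    d = v0 * tau * (1.0 - np.exp(-t / tau))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        d = d + rng.normal(0.0, noise_sd, size=d.shape)
    return pd.DataFrame({"t_s": t, "displacement_um": d})


# ---------------------------------------------------------------------------
# image fixtures
# ---------------------------------------------------------------------------

def fold_angle(theta_deg: float | np.ndarray) -> np.ndarray:
    """Fold an orientation into [0°, 90°]: min(θ mod 180, 180 − θ mod 180)."""
    m = np.mod(np.asarray(theta_deg, float), 180.0)
    out = np.minimum(m, 180.0 - m)
    return out if out.ndim else float(out)


def synth_fiber_image(fiber_specs: Sequence[tuple], image_size: tuple[int, int],
                      pixel_size: float, background: float = 10.0,
                      noise_sd: float = 0.0, seed: int = 0
                      ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render straight bright bars ('fibers') on a uniform background.

    Each spec is ``(center_xy_um, angle_deg, length_um, width_um, intensity)``
    with the angle measured from the ML (x) axis in [0°, 180°).  The truth
    table records each bar's folded orientation (0–90°) and endpoint length.

    Returns ``(image, truth)`` with image indexed [row=y, col=x].
    """
    if pixel_size <= 0:
        raise ConfigurationError("pixel_size must be positive")
    ny, nx = image_size
    img = np.full((ny, nx), float(background))
    yy, xx = np.mgrid[0:ny, 0:nx]
    px = (xx + 0.5) * pixel_size
    py = (yy + 0.5) * pixel_size
    rows = []
    for k, (center, angle, length, width, intensity) in enumerate(fiber_specs):
        if not (0.0 <= angle < 180.0):
            raise ConfigurationError("fiber angle must be in [0, 180)")
        cx, cy = center
        u = np.array([np.cos(np.deg2rad(angle)), np.sin(np.deg2rad(angle))])
        half = length / 2.0
        e1 = np.array([cx, cy]) - half * u
        e2 = np.array([cx, cy]) + half * u
        for e in (e1, e2):
            if not (0 <= e[0] <= nx * pixel_size and 0 <= e[1] <= ny * pixel_size):
                raise ConfigurationError(f"fiber {k} extends outside the image")
        dx = px - cx
        dy = py - cy
        along = dx * u[0] + dy * u[1]
        across = -dx * u[1] + dy * u[0]
        mask = (np.abs(along) <= half) & (np.abs(across) <= width / 2.0)
        img[mask] += float(intensity)
        rows.append((k, cx, cy, float(fold_angle(angle)), float(length)))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    truth = pd.DataFrame(rows, columns=["fiber_id", "center_x_um", "center_y_um",
                                        "orientation_deg", "length_um"])
    return img, truth


def synth_zstack(height_map: np.ndarray, n_slices: int,
                 signal_amplitude: float = 100.0, signal_sd_slices: float = 1.5,
                 noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """3D stack (z, y, x) whose per-pixel z-profile is a Gaussian bump centered
    at the height map value, plus optional Gaussian noise."""
    hm = np.asarray(height_map, float)
    if np.any(hm < 0) or np.any(hm >= n_slices):
        raise ConfigurationError("height_map values must lie in [0, n_slices)")
    z = np.arange(n_slices, dtype=float)[:, None, None]
    stack = signal_amplitude * np.exp(-0.5 * ((z - hm[None]) / signal_sd_slices) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    return stack
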