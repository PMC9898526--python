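"""Spatial and temporal registration of fold-front movies.

ML positions are normalised against three landmarks: the midline maps to
Position_ML = 0 %, the left/right posterior head macrochaetae to ∓100 %.
The two sides get independent affine scales, since the landmark definition
does not assert left-right symmetry.  The AP axis maps the neck-thorax
boundary to 0 % and the anterior scutum macrochaetae to 100 %.

Developmental time is anchored on the last microchaete precursor division
(set to 22 hAPF); raw intervals recorded at 29 °C are stretched by 1.27 to
match the 25 °C clock.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigurationError, RegistrationError
from .geometry import FoldFront, FrontSeries

#: Developmental time assigned to the last microchaete precursor division.
LAST_DIVISION_HAPF = 22.0

#: Raw-interval stretch factor for data acquired at 29 °C.
TEMPERATURE_FACTOR_29C = 1.27

MAX_TILT_DEG = 15.0


@dataclass(frozen=True)
class RegistrationFrame:
    """Landmark positions and acquisition metadata for one movie."""

    midline_x: float
    left_macrochaeta_x: float
    right_macrochaeta_x: float
    neck_thorax_boundary_y: float = 0.0
    scutum_macrochaetae_y: float = 1.0
    xy_tilt_deg: float = 0.0
    xz_tilt_deg: float = 0.0
    last_division_time: float | None = None
    temperature_c: float = 25.0

    def __post_init__(self) -> None:
        if not (self.left_macrochaeta_x < self.midline_x < self.right_macrochaeta_x):
            raise RegistrationError(
                "macrochaetae must bracket the midline (left < midline < right)")
        if abs(self.xy_tilt_deg) > MAX_TILT_DEG or abs(self.xz_tilt_deg) > MAX_TILT_DEG:
            raise RegistrationError(f"tilt exceeds {MAX_TILT_DEG} deg")
        if self.scutum_macrochaetae_y == self.neck_thorax_boundary_y:
            raise RegistrationError("AP landmarks coincide")

    @classmethod
    def identity(cls) -> "RegistrationFrame":
        """Frame that maps µm straight onto the ±100 % convention with unit scale."""
        return cls(midline_x=0.0, left_macrochaeta_x=-100.0, right_macrochaeta_x=100.0)


def ml_percent(x: float | np.ndarray, frame: RegistrationFrame) -> np.ndarray:
    """Map raw ML coordinates (µm) to Position_ML (%), per-side affine."""
    x = np.asarray(x, dtype=float)
    left_scale = frame.midline_x - frame.left_macrochaeta_x
    right_scale = frame.right_macrochaeta_x - frame.midline_x
    dx = x - frame.midline_x
    return np.where(dx < 0, 100.0 * dx / left_scale, 100.0 * dx / right_scale)


def ap_percent(y: float | np.ndarray, frame: RegistrationFrame) -> np.ndarray:
    """Map raw AP coordinates to Position_AP (%)."""
    y = np.asarray(y, dtype=float)
    return 100.0 * (y - frame.neck_thorax_boundary_y) / (
        frame.scutum_macrochaetae_y - frame.neck_thorax_boundary_y)


def _rotate(points: np.ndarray, angle_deg: float, pivot: np.ndarray) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return (points - pivot) @ rot.T + pivot


def register_space(series: FrontSeries, frame: RegistrationFrame,
                   to_percent: bool = True) -> FrontSeries:
    """Tilt-correct a front series and normalise ML positions to %.

    The in-plane tilt is removed by rotating each front by −xz_tilt about the
    midline anchor; ML coordinates are then mapped through :func:`ml_percent`
    (z stays in µm so curvature remains a physical quantity computed *before*
    normalisation).  With ``to_percent=False`` only the tilt correction and the
    midline shift are applied, keeping µm units.
    """
    pivot = np.array([frame.midline_x, 0.0])
    fronts = []
    for f in series.fronts:
        pts = _rotate(f.points, -frame.xz_tilt_deg, pivot)
        if to_percent:
            x = ml_percent(pts[:, 0], frame)
        else:
            x = pts[:, 0] - frame.midline_x
        fronts.append(replace(f, points=np.stack([x, pts[:, 1]], axis=1)))
    meta = dict(series.metadata)
    meta["ml_units"] = "percent" if to_percent else "um"
    meta["registration_frame"] = frame
    return FrontSeries(series.animal_id, fronts, series.side, meta)


def register_time(raw_times: np.ndarray | float, frame: RegistrationFrame) -> np.ndarray:
    """Map raw acquisition times (h) to developmental time (hAPF).

    Intervals relative to the last-division anchor are stretched by 1.27 when
    acquired at 29 °C, left unscaled at 25 °C, and the anchor is pinned to
    22 hAPF.
    """
    if frame.last_division_time is None:
        raise ConfigurationError("registration frame lacks last_division_time")
    if frame.temperature_c == 25.0:
        factor = 1.0
    elif frame.temperature_c == 29.0:
        factor = TEMPERATURE_FACTOR_29C
    else:
        raise ConfigurationError(
            f"no developmental-time correction known for {frame.temperature_c} degC")
    raw = np.asarray(raw_times, dtype=float)
    out = LAST_DIVISION_HAPF + factor * (raw - frame.last_division_time)
    return out if out.ndim else float(out)
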