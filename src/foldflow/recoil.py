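"""Laser-ablation recoil analysis: the tension proxy.

The initial tissue recoil velocity immediately after ablation is a relative
proxy of the in-plane tension that existed before the cut (relative only: the
proxy carries an unknown dissipation prefactor, which the collapse slope
absorbs).  This module turns displacement traces into initial recoil
velocities, aggregates them over developmental time with a 2 h sliding window,
and assembles position-resolved tension proxies, including the
initial-curvature threshold rule used for laterally flattened datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError, InsufficientDataError

#: Default measurement window (s) for the rectangular-ROI ablation protocol.
DEFAULT_WINDOW = (1.0, 7.0)

#: Measurement window (s) for the small circular-ROI protocol.
CIRCULAR_ROI_WINDOW = (0.25, 1.25)

#: Initial-curvature threshold (µm⁻¹) splitting flattened vs non-flattened
#: recoil datasets when assembling per-position tension proxies.
CURVATURE_THRESHOLD = 0.00015


@dataclass
class RecoilTrace:
    """One post-ablation displacement time series."""

    times: np.ndarray
    displacement: np.ndarray
    side: str = "apical"
    axis: str = "ML"
    region: str = "medial"
    dev_time: float = float("nan")
    animal_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        d = np.asarray(self.displacement, float)
        if t.shape != d.shape or t.ndim != 1:
            raise ConfigurationError("times and displacement must be 1-D and equal length")
        if t.size and t[0] < 0:
            raise ConfigurationError("times must start at >= 0")
        if np.any(np.diff(t) <= 0):
            raise ConfigurationError("times must be strictly increasing")
        self.times = t
        self.displacement = d


def initial_recoil_velocity(trace: RecoilTrace, t_start: float = DEFAULT_WINDOW[0],
                            t_end: float = DEFAULT_WINDOW[1],
                            method: str = "regression") -> float:
    """Initial recoil velocity (µm/s) from the samples in [t_start, t_end].

    Default is the least-squares slope of displacement against time over all
    samples in the window (noise-robust; reduces to the difference quotient
    for linear traces).  ``method="two_point"`` uses the difference quotient
    between the first and last in-window samples, for sensitivity checks.
    """
    if t_end <= t_start:
        raise ConfigurationError("t_end must exceed t_start")
    m = (trace.times >= t_start - 1e-12) & (trace.times <= t_end + 1e-12)
    t = trace.times[m]
    d = trace.displacement[m]
    if t.size < 2:
        raise InsufficientDataError(
            f"fewer than 2 samples in the window [{t_start}, {t_end}] s")
    if method == "two_point":
        return float((d[-1] - d[0]) / (t[-1] - t[0]))
    if method != "regression":
        raise ConfigurationError(f"unknown method {method!r}")
    slope = np.polyfit(t, d, 1)[0]
    return float(slope)


def sliding_average_by_devtime(measurements: pd.DataFrame | list,
                               window: float = 2.0) -> pd.DataFrame:
    """Centered sliding mean ± sd of recoil velocities over developmental time.

    ``measurements`` is a DataFrame with columns ``dev_time, value`` (or a
    list of such pairs).  At each distinct dev_time the mean, sample sd
    (ddof=1; 0 for a single value) and count of all measurements within
    ±window/2 are reported; windows truncate at the ends of the data.

    Returns columns ``dev_time, mean, sd, n``.
    """
    if not isinstance(measurements, pd.DataFrame):
        measurements = pd.DataFrame(measurements, columns=["dev_time", "value"])
    if measurements.empty:
        raise InsufficientDataError("no measurements")
    t = measurements["dev_time"].to_numpy(float)
    v = measurements["value"].to_numpy(float)
    half = window / 2 + 1e-9
    rows = []
    for tq in np.unique(t):
        m = np.abs(t - tq) <= half
        vals = v[m]
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append((float(tq), float(np.mean(vals)), sd, int(vals.size)))
    return pd.DataFrame(rows, columns=["dev_time", "mean", "sd", "n"])


def assemble_tension_proxy(position_curvatures: dict[float, float],
                           flattened_curve: pd.DataFrame,
                           nonflattened_curve: pd.DataFrame,
                           threshold: float = CURVATURE_THRESHOLD
                           ) -> dict[float, pd.DataFrame]:
    """Assign a tension-proxy curve to each ML position by initial curvature.

    Positions whose initial curvature is below ``threshold`` (µm⁻¹) take the
    recoil curve measured in flattened animals; the others take the
    non-flattened curve.  Positions with missing (NaN) curvature are omitted
    with a warning.  The returned curves carry a ``source_dataset`` column
    recording the assignment; the output is a pure selection — every value
    comes unmodified from one of the two inputs.
    """
    out: dict[float, pd.DataFrame] = {}
    for pos, kappa in position_curvatures.items():
        if kappa is None or (isinstance(kappa, float) and np.isnan(kappa)):
            warnings.warn(f"position {pos}: initial curvature missing, omitted")
            continue
        if kappa < threshold:
            curve, label = flattened_curve, "flattened"
        else:
            curve, label = nonflattened_curve, "nonflattened"
        out[pos] = curve.assign(source_dataset=label)
    return out


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int
    undefined: bool = False


def correlate_apical_basal(apical: np.ndarray, basal: np.ndarray) -> CorrelationResult:
    """Pearson correlation and ordinary (origin-free) least-squares fit of
    basal against apical recoil velocities, paired by animal.

    Zero variance in either variable is an undefined-correlation signal
    (``undefined=True``), not an exception.
    """
    a = np.asarray(apical, float)
    b = np.asarray(basal, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("apical and basal must be paired 1-D arrays")
    if a.size < 3:
        raise InsufficientDataError("need >= 3 pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        return CorrelationResult(r=float("nan"), p_value=float("nan"),
                                 slope=float("nan"), intercept=float("nan"),
                                 n=a.size, undefined=True)
    r, p = sps.pearsonr(a, b)
    lr = sps.linregress(a, b)
    return CorrelationResult(r=float(r), p_value=float(p), slope=float(lr.slope),
                             intercept=float(lr.intercept), n=a.size)


def proxy_curve_from_table(recoil_table: pd.DataFrame, window: float = 2.0) -> pd.DataFrame:
    """Tension-proxy curve from an ensemble recoil table
    (columns ``animal_id, dev_time, recoil``) via the 2 h sliding average."""
    return sliding_average_by_devtime(
        recoil_table.rename(columns={"recoil": "value"})[["dev_time", "value"]], window)
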