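"""Statistical utilities matching the study's reporting conventions.

Per-time-point Welch tests with the three-level p-value banding used in the
figures (none: p > 0.05; weak: p < 0.05; strong: p < 0.01), one-way ANOVA for
intensity-vs-position comparisons, and a generic one-sample t.  No
multiple-testing correction is applied by default, mirroring the reporting
convention; a Benjamini-Hochberg option is available.

Boundary p-values: the banding convention leaves p = 0.05 and p = 0.01
undefined; here p = 0.05 → weak and p = 0.01 → weak (strict inequality for
the strong band).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError, InsufficientDataError


class Band(str, Enum):
    NONE = "none"
    WEAK = "weak"
    STRONG = "strong"


def p_band(p: float) -> Band:
    """Band a p-value: > 0.05 → none; [0.01, 0.05] → weak; < 0.01 → strong."""
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError("p must be in [0, 1]")
    if p > 0.05:
        return Band.NONE
    if p < 0.01:
        return Band.STRONG
    return Band.WEAK


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    band: Band


def welch_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> WelchResult:
    """Two-sided Welch unequal-variance t test.

    Degenerate conventions: both samples with zero variance and equal means
    give p = 1 (t = 0); zero variance everywhere with different means gives
    p = 0 (t = ±inf).
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0, Band.NONE)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return WelchResult(float(t), float(a.size + b.size - 2), 0.0, Band.STRONG)
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df),
                       float(res.pvalue), p_band(float(res.pvalue)))


def compare_timecourses(condition_a: pd.DataFrame, condition_b: pd.DataFrame,
                        value_col: str = "value", time_col: str = "time",
                        adjust: str | None = None) -> pd.DataFrame:
    """Per-time-point Welch tests between two per-animal time courses.

    Each condition is a tidy frame with one row per (animal, time) holding
    ``value_col``.  Only times present in both conditions with >= 2 animals
    each are compared.  No multiple-comparison adjustment by default;
    ``adjust="bh"`` applies Benjamini-Hochberg and re-bands the adjusted
    p-values.

    Returns columns ``time, n_a, n_b, t, df, p, band``.
    """
    rows = []
    times = sorted(set(condition_a[time_col]).intersection(condition_b[time_col]))
    for t in times:
        va = condition_a.loc[condition_a[time_col] == t, value_col].to_numpy(float)
        vb = condition_b.loc[condition_b[time_col] == t, value_col].to_numpy(float)
        if va.size < 2 or vb.size < 2:
            continue
        res = welch_test(va, vb)
        rows.append((t, va.size, vb.size, res.t_statistic,
                     res.degrees_of_freedom, res.p_value, res.band.value))
    out = pd.DataFrame(rows, columns=["time", "n_a", "n_b", "t", "df", "p", "band"])
    if adjust == "bh" and not out.empty:
        out["p_adjusted"] = _benjamini_hochberg(out["p"].to_numpy())
        out["band"] = [p_band(p).value for p in out["p_adjusted"]]
    elif adjust not in (None, "bh"):
        raise ConfigurationError(f"unknown adjustment {adjust!r}")
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA (F, p) across >= 2 groups of n >= 2 each.

    All values identical across all groups gives (F, p) = (0, 1) by
    convention.
    """
    arrs = [np.asarray(g, float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise InsufficientDataError("need >= 2 groups with n >= 2 each")
    allv = np.concatenate(arrs)
    if np.all(allv == allv[0]):
        return 0.0, 1.0
    f, p = sps.f_oneway(*arrs)
    return float(f), float(p)


def one_sample_t(sample: Sequence[float], popmean: float = 0.0) -> tuple[float, float]:
    """Two-sided one-sample t test against ``popmean``."""
    a = np.asarray(sample, float)
    if a.size < 2:
        raise InsufficientDataError("need n >= 2")
    res = sps.ttest_1samp(a, popmean)
    return float(res.statistic), float(res.pvalue)
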