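"""Plain-text I/O for all pipeline artifacts.

Fronts travel as tidy CSV (``animal_id, time_hAPF, point_index, x_um, z_um``,
plus a ``side`` column), recoil traces and proxy curves as CSV, configurations
and fit summaries as JSON, images and stacks as TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError
from .geometry import FoldFront, FrontSeries
from .simulate import SyntheticStudyConfig

FRONT_COLUMNS = ["animal_id", "time_hAPF", "point_index", "x_um", "z_um", "side"]


def fronts_to_frame(series_list: list[FrontSeries]) -> pd.DataFrame:
    rows = []
    for series in series_list:
        for f in series.fronts:
            for i, (x, z) in enumerate(f.points):
                rows.append((series.animal_id, f.time, i, x, z, f.side))
    return pd.DataFrame(rows, columns=FRONT_COLUMNS)


def write_fronts_csv(series_list: list[FrontSeries], path: str | Path) -> None:
    fronts_to_frame(series_list).to_csv(path, index=False)


def read_fronts_csv(path: str | Path) -> list[FrontSeries]:
    df = pd.read_csv(path)
    missing = set(FRONT_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise DataError(f"fronts CSV missing columns {sorted(missing)}")
    if "side" not in df.columns:
        df["side"] = "apical"
    out = []
    for animal, adf in df.groupby("animal_id", sort=False):
        fronts = []
        for t, tdf in adf.groupby("time_hAPF", sort=True):
            tdf = tdf.sort_values("point_index")
            side = str(tdf["side"].iloc[0])
            fronts.append(FoldFront(time=float(t),
                                    points=tdf[["x_um", "z_um"]].to_numpy(float),
                                    side=side))
        out.append(FrontSeries(str(animal), fronts, fronts[0].side))
    return out


TRACE_COLUMNS = ["animal_id", "side", "axis", "region", "dev_time_hAPF",
                 "t_s", "displacement_um"]


def write_recoil_traces_csv(traces: pd.DataFrame, path: str | Path) -> None:
    missing = set(TRACE_COLUMNS) - set(traces.columns)
    if missing:
        raise DataError(f"trace table missing columns {sorted(missing)}")
    traces[TRACE_COLUMNS].to_csv(path, index=False)


def read_recoil_traces_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"trace CSV missing columns {sorted(missing)}")
    return df


def write_profile_csv(profile: pd.DataFrame, path: str | Path) -> None:
    profile.to_csv(path, index=False)


def write_config_json(config: SyntheticStudyConfig, path: str | Path) -> None:
    Path(path).write_text(config.model_dump_json(indent=2))


def read_config_json(path: str | Path) -> SyntheticStudyConfig:
    try:
        return SyntheticStudyConfig.model_validate_json(Path(path).read_text())
    except Exception as exc:  # pydantic ValidationError or bad JSON
        raise DataError(f"invalid study config: {exc}") from exc


def config_json_schema() -> dict:
    """Published JSON schema for the study configuration."""
    return SyntheticStudyConfig.model_json_schema()


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def write_tiff(image: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.asarray(image, np.float32))


def read_tiff(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path))
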