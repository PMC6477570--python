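"""File-format adapters: PNG frame directories, array archives and CSVs.

Layouts match the extraction CLIs: a frame directory holds lexicographically
ordered 8-bit grayscale PNGs plus ``timestamps.csv`` (column ``t_s``); an
archive is an ``.npz`` with keys ``frames`` and ``t_s``.  Thermal input is
``thermal.csv`` (``t_s,temp_c``); scores are
``scores.csv`` (``participant_id,session_id,vas``).
"""
from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .signals import (
    BvpSignal,
    FrameStack,
    PPIntervalSeries,
    ThermalSeries,
    ThermalVariabilitySequence,
)

__all__ = [
    "read_frame_stack",
    "write_frame_stack",
    "read_thermal_csv",
    "write_thermal_csv",
    "write_bvp_csv",
    "write_pp_csv",
    "write_variability_csv",
    "read_scores_csv",
]


def read_frame_stack(path: str | Path) -> FrameStack:
    """Load a frame stack from a PNG directory or an ``.npz`` archive."""
    path = Path(path)
    if path.is_dir():
        ts_file = path / "timestamps.csv"
        if not ts_file.exists():
            raise InvalidInputError(f"missing {ts_file}")
        t = pd.read_csv(ts_file)["t_s"].to_numpy(dtype=float)
        pngs = sorted(path.glob("*.png"))
        if len(pngs) != len(t):
            raise InvalidInputError(
                f"{len(pngs)} PNG files but {len(t)} timestamps"
            )
        frames = np.stack([iio.imread(p) for p in pngs])
        if frames.ndim == 4:  # collapse an accidental color axis
            frames = frames[..., 0]
        return FrameStack(frames, t)
    if path.suffix == ".npz":
        with np.load(path) as archive:
            return FrameStack(archive["frames"], archive["t_s"])
    raise InvalidInputError(f"{path} is neither a directory nor an .npz archive")


def write_frame_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as a PNG directory with ``timestamps.csv``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    digits = len(str(len(stack) - 1))
    for i, frame in enumerate(stack.frames):
        iio.imwrite(path / f"frame_{i:0{digits}d}.png",
                    frame.astype(np.uint8))
    pd.DataFrame({"t_s": stack.timestamps}).to_csv(
        path / "timestamps.csv", index=False)


def read_thermal_csv(path: str | Path) -> ThermalSeries:
    df = pd.read_csv(path)
    return ThermalSeries(df["temp_c"].to_numpy(dtype=float),
                         df["t_s"].to_numpy(dtype=float))


def write_thermal_csv(series: ThermalSeries, path: str | Path) -> None:
    pd.DataFrame({"t_s": series.timestamps, "temp_c": series.temps}
                 ).to_csv(path, index=False)


def write_bvp_csv(bvp: BvpSignal, path: str | Path) -> None:
    pd.DataFrame({"t_s": bvp.times, "value": bvp.values}
                 ).to_csv(path, index=False)


def write_pp_csv(pp: PPIntervalSeries, path: str | Path) -> None:
    pd.DataFrame({
        "peak_time_s": pp.peak_times[1:],
        "pp_ms": pp.intervals,
        "valid": pp.valid.astype(int),
    }).to_csv(path, index=False)


def write_variability_csv(tv: ThermalVariabilitySequence,
                          path: str | Path) -> None:
    pd.DataFrame({"t_s": tv.times, "scaled": tv.values,
                  "filtered_c": tv.raw_filtered}).to_csv(path, index=False)


def read_scores_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant_id", "session_id", "vas"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"scores CSV needs columns {sorted(required)}")
    return df
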