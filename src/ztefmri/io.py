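"""Plain-text and NIfTI I/O helpers.

Time series travel as 2-column delimited text (time_s, value) with a
header; schedules and parameter sets as JSON; pipeline configuration as
YAML. A small NIfTI phantom writer plants a time course in ROI voxels for
exercising ROI extraction end to end.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .synth import StimulusSchedule
from .timeseries import TimeSeries

__all__ = [
    "write_timeseries", "read_timeseries", "write_schedule", "read_schedule",
    "write_onsets", "read_onsets", "make_phantom_nifti",
]

PathLike = Union[str, Path]


def write_timeseries(path: PathLike, ts: TimeSeries, delimiter: str = "\t"):
    """Write (time_s, value) columns with a one-line header."""
    df = pd.DataFrame({"time_s": ts.times, "value": ts.values})
    df.to_csv(path, sep=delimiter, index=False, float_format="%.9g")


def read_timeseries(path: PathLike, delimiter: str = "\t") -> TimeSeries:
    """Read a 2-column time series; the sampling rate is inferred and checked."""
    df = pd.read_csv(path, sep=delimiter)
    if df.shape[1] < 2:
        raise InvalidArgumentError(f"{path}: expected two columns (time_s, value)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise InvalidArgumentError(f"{path}: need at least two samples to infer the rate")
    dt = np.diff(t)
    dt0 = float(np.median(dt))
    if dt0 <= 0 or np.max(np.abs(dt - dt0)) > 0.01 * dt0 + 1e-12:
        raise InvalidArgumentError(f"{path}: time column is not uniformly sampled")
    return TimeSeries(t0=float(t[0]), fs=1.0 / dt0, values=v)


def write_schedule(path: PathLike, schedule: StimulusSchedule):
    Path(path).write_text(json.dumps(schedule.to_dict(), indent=1))


def read_schedule(path: PathLike) -> StimulusSchedule:
    return StimulusSchedule.from_dict(json.loads(Path(path).read_text()))


def write_onsets(path: PathLike, onsets: Sequence[float]):
    np.savetxt(path, np.asarray(onsets, dtype=float), fmt="%.9g")


def read_onsets(path: PathLike) -> np.ndarray:
    return np.atleast_1d(np.loadtxt(path, dtype=float))


def make_phantom_nifti(timecourse: TimeSeries, shape: Tuple[int, int, int] = (8, 8, 8),
                       roi_slice: Tuple[slice, slice, slice] = (slice(2, 5),) * 3,
                       background: float = 100.0):
    """Build a synthetic 4-D NIfTI volume series plus its ROI mask.

    ROI voxels carry ``background + timecourse``; all other voxels are
    constant ``background``. Returns ``(volumes_img, mask_img)`` as nibabel
    images with the volume TR recorded in the header, so
    ``extract_roi_timecourse`` recovers the planted time course exactly.
    """
    import nibabel as nib

    n_t = timecourse.n
    data = np.full(shape + (n_t,), background, dtype=float)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[roi_slice] = 1
    data[mask.astype(bool)] = background + timecourse.values
    affine = np.eye(4)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((1.0, 1.0, 1.0, 1.0 / timecourse.fs))
    mask_img = nib.Nifti1Image(mask, affine)
    return img, mask_img
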