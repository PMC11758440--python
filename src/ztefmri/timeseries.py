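"""Uniformly sampled time series and epoch containers.

``TimeSeries`` is the universal carrier for every signal in the pipeline:
iEEG voltage (mV), instantaneous power (mV^2), and fMRI region-of-interest
traces (arbitrary signal units). ``EpochSet`` holds stimulus-locked windows
cut from one or more recordings on a common relative time base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = ["TimeSeries", "EpochSet", "downsample_bins"]


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    t0:
        Time of the first sample in seconds (absolute, or relative to a
        stimulus onset for epoch-like series).
    fs:
        Sampling rate in samples per second.
    values:
        Sample values; one-dimensional.
    """

    t0: float
    fs: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise InvalidArgumentError("values must be a non-empty 1-D array")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise InvalidArgumentError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def copy_with(self, values: np.ndarray, t0: Optional[float] = None,
                  fs: Optional[float] = None) -> "TimeSeries":
        return TimeSeries(self.t0 if t0 is None else t0,
                          self.fs if fs is None else fs,
                          np.asarray(values, dtype=float))


@dataclass
class EpochSet:
    """Stimulus-locked windows on a shared relative time grid.

    ``epochs`` is (n_epochs, n_samples); ``rel_t0`` is the time of the first
    sample relative to stimulus onset (negative when the window includes a
    pre-stimulus baseline). ``labels`` carries one row of metadata per epoch
    (frequency, experiment, subject, ...).
    """

    epochs: np.ndarray
    rel_t0: float
    fs: float
    labels: Optional[pd.DataFrame] = field(default=None)

    def __post_init__(self):
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        if self.labels is not None and len(self.labels) != self.epochs.shape[0]:
            raise InvalidArgumentError("labels must have one row per epoch")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[1]

    @property
    def rel_times(self) -> np.ndarray:
        return self.rel_t0 + np.arange(self.n_samples) / self.fs

    def mean(self) -> TimeSeries:
        """Average across epochs, returned on the relative time base."""
        return TimeSeries(self.rel_t0, self.fs, self.epochs.mean(axis=0))


def downsample_bins(sig: TimeSeries, bin_s: float) -> TimeSeries:
    """Average adjacent samples in non-overlapping bins of width ``bin_s``.

    The output sampling rate is ``1 / bin_s``; a trailing partial bin is
    dropped. The output timestamps sit at the centre of each bin of input
    samples (``t0 + (m - 1) / (2 fs)`` for the first bin, with ``m`` samples
    per bin), so binning introduces no net time shift.
    """
    if bin_s < sig.dt:
        raise InvalidArgumentError(f"bin width {bin_s} s is below the sample interval {sig.dt} s")
    m_float = bin_s * sig.fs
    m = int(round(m_float))
    if m < 1 or abs(m_float - m) > 1e-6 * max(1, m):
        raise InvalidArgumentError(
            f"bin width {bin_s} s is not commensurate with the sampling rate {sig.fs} Hz")
    n_bins = sig.n // m
    if n_bins < 1:
        raise InvalidArgumentError("signal shorter than one bin")
    binned = sig.values[: n_bins * m].reshape(n_bins, m).mean(axis=1)
    t0 = sig.t0 + (m - 1) / (2.0 * sig.fs)
    return TimeSeries(t0, 1.0 / bin_s, binned)
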