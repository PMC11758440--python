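"""Intracranial EEG processing chain.

MRI gradient-artifact template subtraction, 4-190 Hz band-pass plus
50/100/150 Hz notch filtering (all zero-phase), stimulus-sensitivity-based
electrode selection, squaring to instantaneous power, stimulus-locked
epoching and pre-stimulus baseline correction.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, iirnotch, sosfiltfilt

from .errors import (InsufficientBaselineError, InvalidArgumentError,
                     OutOfRangeError)
from .timeseries import EpochSet, TimeSeries

__all__ = [
    "build_artifact_template", "subtract_artifact_template", "bandpass_notch",
    "select_electrode", "instantaneous_power", "extract_epochs",
    "baseline_correct",
]

logger = logging.getLogger(__name__)


def _trigger_indices(sig: TimeSeries, triggers: Sequence[float]) -> np.ndarray:
    return np.asarray(np.round((np.asarray(triggers, float) - sig.t0) * sig.fs), dtype=int)


def build_artifact_template(sig: TimeSeries, volume_triggers: Sequence[float],
                            n_volumes: int, period_s: float) -> np.ndarray:
    """Average the signal over the first ``n_volumes`` volume windows.

    The gradient artifact is phase-locked to the volume triggers, so the
    mean over many stimulus-free (baseline) volumes converges on the
    artifact waveform while uncorrelated signal averages out as 1/sqrt(n).
    """
    if n_volumes < 1:
        raise InvalidArgumentError("n_volumes must be >= 1")
    triggers = np.asarray(volume_triggers, dtype=float)
    if triggers.size < n_volumes:
        raise InsufficientBaselineError(
            f"need {n_volumes} baseline volume triggers, got {triggers.size}")
    m_float = period_s * sig.fs
    m = int(round(m_float))
    if abs(m_float - m) > 0.5 or m < 1:
        raise InvalidArgumentError(
            f"volume period {period_s} s is not commensurate with fs {sig.fs} Hz")
    idx = _trigger_indices(sig, triggers[:n_volumes])
    if idx.min() < 0 or idx.max() + m > sig.n:
        raise InvalidArgumentError("a baseline volume window exceeds the recording")
    segs = np.stack([sig.values[i:i + m] for i in idx])
    return segs.mean(axis=0)


def subtract_artifact_template(sig: TimeSeries, template: np.ndarray,
                               volume_triggers: Sequence[float]) -> TimeSeries:
    """Subtract the artifact template at every volume trigger.

    Samples outside any trigger window are unchanged. Trigger windows must
    not overlap; trailing windows that do not fully fit in the recording are
    skipped with a warning.
    """
    template = np.asarray(template, dtype=float)
    m = template.size
    idx = _trigger_indices(sig, volume_triggers)
    order = np.argsort(idx)
    idx = idx[order]
    if idx.size > 1 and np.any(np.diff(idx) < m):
        raise InvalidArgumentError("volume trigger windows overlap the template length")
    out = sig.values.copy()
    skipped = 0
    for i in idx:
        if i < 0 or i + m > out.size:
            skipped += 1
            continue
        out[i:i + m] -= template
    if skipped:
        logger.warning("skipped %d trigger window(s) not fully inside the recording", skipped)
    return sig.copy_with(out)


def bandpass_notch(sig: TimeSeries, band: Tuple[float, float] = (4.0, 190.0),
                   notches: Sequence[float] = (50.0, 100.0, 150.0),
                   order: int = 4, notch_q: float = 30.0) -> TimeSeries:
    """Zero-phase band-pass plus notch filtering.

    A Butterworth band-pass of the given order and second-order IIR notches
    (quality factor ``notch_q``), each applied forward-backward so evoked
    component timing is preserved. Requires ``fs > 2 * band[1]``.
    """
    lo, hi = band
    if not (0 < lo < hi):
        raise InvalidArgumentError(f"invalid band {band}")
    if sig.fs <= 2 * hi:
        raise InvalidArgumentError(
            f"fs = {sig.fs} Hz too low for a {hi} Hz band edge (need > {2 * hi})")
    sos = butter(order, [lo, hi], btype="bandpass", fs=sig.fs, output="sos")
    out = sosfiltfilt(sos, sig.values)
    for f0 in notches:
        b, a = iirnotch(f0, notch_q, fs=sig.fs)
        out = filtfilt(b, a, out)
    return sig.copy_with(out)


def select_electrode(sigs: Sequence[TimeSeries],
                     stim_intervals: Sequence[Tuple[float, float]]) -> int:
    """Pick the electrode most sensitive to stimulus-driven activity.

    Scores each candidate by the mean power of its (filtered) signal during
    stimulation relative to the mean power over the whole recording and
    returns the index of the highest ratio; ties resolve to the lowest index.
    """
    if not sigs:
        raise InvalidArgumentError("at least one candidate electrode required")
    if not stim_intervals:
        raise InvalidArgumentError("stimulation interval list is empty")
    ratios = []
    for s in sigs:
        t = s.times
        mask = np.zeros(s.n, dtype=bool)
        for a, b in stim_intervals:
            if a < s.t0 - 1e-9 or b > s.t0 + s.duration + 1e-9:
                raise InvalidArgumentError(f"stimulation interval ({a}, {b}) outside recording")
            mask |= (t >= a) & (t < b)
        if not mask.any():
            raise InvalidArgumentError("no samples fall inside the stimulation intervals")
        power = s.values ** 2
        ratios.append(power[mask].mean() / power.mean())
    return int(np.argmax(ratios))


def instantaneous_power(sig: TimeSeries) -> TimeSeries:
    """Element-wise square of a voltage trace (mV -> mV^2)."""
    return sig.copy_with(sig.values ** 2)


def extract_epochs(sig: TimeSeries, onsets: Sequence[float], rel_start: float,
                   duration: float,
                   labels: Optional[pd.DataFrame] = None) -> EpochSet:
    """Cut fixed-length windows ``[onset + rel_start, onset + rel_start + duration)``.

    The epoch grid is the recording's own sample grid: the first sample of
    each epoch is the first grid point at or after ``onset + rel_start``
    (no resampling), so per-epoch alignment error is below one sample
    interval. Raises ``OutOfRangeError`` listing every onset whose window
    does not fit in the recording.
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    n = int(round(duration * sig.fs))
    starts, bad = [], []
    for onset in onsets:
        i0 = int(np.ceil((onset + rel_start - sig.t0) * sig.fs - 1e-9))
        if i0 < 0 or i0 + n > sig.n:
            bad.append(onset)
        else:
            starts.append(i0)
    if bad:
        raise OutOfRangeError(
            f"epoch window [{rel_start}, {rel_start + duration}) s does not fit the "
            f"recording for onsets {bad}", offending_onsets=bad)
    epochs = np.stack([sig.values[i:i + n] for i in starts])
    return EpochSet(epochs=epochs, rel_t0=rel_start, fs=sig.fs, labels=labels)


def baseline_correct(ep: EpochSet, baseline: Tuple[float, float]) -> EpochSet:
    """Subtract the per-epoch mean over the relative window [start, end).

    After correction the mean over the baseline window is exactly zero in
    every epoch.
    """
    start, end = baseline
    rel = ep.rel_times
    mask = (rel >= start - 1e-9) & (rel < end - 1e-9)
    if not mask.any() or start < rel[0] - 1e-9 or end > rel[-1] + 1.0 / ep.fs + 1e-9:
        raise InvalidArgumentError(
            f"baseline window {baseline} outside the epoch extent "
            f"[{rel[0]}, {rel[-1] + 1.0 / ep.fs})")
    corrected = ep.epochs - ep.epochs[:, mask].mean(axis=1, keepdims=True)
    return EpochSet(epochs=corrected, rel_t0=ep.rel_t0, fs=ep.fs, labels=ep.labels)
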