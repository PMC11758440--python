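"""Quantifying fMRI-neuronal coupling across stimulation frequencies.

Response sizes are window sums of baseline-corrected time courses (fMRI
ROI traces and IRF-convolved, down-sampled iEEG power). Sizes are z-scored
within each experiment, averaged per subject and frequency, and related by
ordinary least squares: with-intercept fits (y = x*b1 + b0) between
response sizes, and no-intercept fits (y = x*b1) between mean time
courses, separately per frequency. A fixed-scaling residual analysis pins
one global gain on the early part of the reference-frequency response and
exposes stimulation-dependent departures from linear coupling everywhere
else.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import (DegenerateFitError, DegenerateStandardizationError,
                     InvalidArgumentError)
from .timeseries import TimeSeries

__all__ = [
    "ResponseRecord", "LinearFit", "response_size",
    "standardize_within_experiment", "aggregate_subject_frequency",
    "linear_fit", "frequency_wise_timecourse_fit", "fixed_scaling_residuals",
    "mean_of_means", "records_to_frame", "LOW_FREQUENCIES",
]

#: The restricted frequency subset used for the "low frequency" analyses (Hz).
LOW_FREQUENCIES: Tuple[float, ...] = (1.0, 3.0, 5.0, 7.0)


@dataclass
class ResponseRecord:
    """One stimulation block's paired fMRI and neuronal response sizes."""

    subject: str
    experiment: str
    modality: str  # "electrical" | "airpuff"
    frequency_hz: float
    trial: int
    fmri_size: float
    neural_size: float

    def __post_init__(self):
        if self.modality not in ("electrical", "airpuff"):
            raise InvalidArgumentError(f"unknown modality {self.modality!r}")
        if not (np.isfinite(self.fmri_size) and np.isfinite(self.neural_size)):
            raise InvalidArgumentError("response sizes must be finite")


@dataclass
class LinearFit:
    """OLS summary: slope, optional intercept, R^2 and MSE (= SSR / n)."""

    beta1: float
    beta0: Optional[float]
    r2: float
    mse: float
    n: int


def records_to_frame(records: Sequence[ResponseRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def response_size(epoch: np.ndarray, fs: float, window: Tuple[float, float],
                  rel_t0: float = 0.0) -> float:
    """Sum of epoch samples whose relative time falls in ``[start, end)``.

    ``rel_t0`` is the relative time of the first sample; at the 2-s volume
    resolution a 22-s window therefore sums 11 samples.
    """
    epoch = np.asarray(epoch, dtype=float)
    start, end = window
    rel = rel_t0 + np.arange(epoch.size) / fs
    if start < rel[0] - 1e-9 or end > rel[-1] + 1.0 / fs + 1e-9:
        raise InvalidArgumentError(
            f"window {window} outside epoch extent [{rel[0]}, {rel[-1] + 1.0 / fs})")
    mask = (rel >= start - 1e-9) & (rel < end - 1e-9)
    return float(epoch[mask].sum())


def standardize_within_experiment(records: Sequence[ResponseRecord]
                                  ) -> List[ResponseRecord]:
    """z-score fMRI and neuronal sizes across the trials of each experiment.

    Uses the sample standard deviation (n-1 denominator). After
    standardization each measure has mean 0 and sd 1 within every
    experiment; a zero-variance experiment raises.
    """
    out: List[ResponseRecord] = []
    df = records_to_frame(records)
    if df.empty:
        return []
    for exp, grp in df.groupby("experiment", sort=False):
        if len(grp) < 2:
            raise InvalidArgumentError(
                f"experiment {exp!r} has fewer than 2 trials; cannot standardize")
        for col in ("fmri_size", "neural_size"):
            sd = grp[col].std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                raise DegenerateStandardizationError(
                    f"zero variance of {col} within experiment {exp!r}")
        f_mean, f_sd = grp["fmri_size"].mean(), grp["fmri_size"].std(ddof=1)
        n_mean, n_sd = grp["neural_size"].mean(), grp["neural_size"].std(ddof=1)
        for _, row in grp.iterrows():
            rec = records[int(row.name)]
            out.append(replace(rec,
                               fmri_size=(rec.fmri_size - f_mean) / f_sd,
                               neural_size=(rec.neural_size - n_mean) / n_sd))
    return out


def aggregate_subject_frequency(records: Sequence[ResponseRecord]) -> pd.DataFrame:
    """Mean standardized sizes per (subject, modality, frequency).

    One row per cell, averaging the 4-12 trials a subject contributes at
    each frequency; each row is one data point of the response-size
    regressions.
    """
    df = records_to_frame(records)
    if df.empty:
        return pd.DataFrame(columns=["subject", "modality", "frequency_hz",
                                     "fmri_size", "neural_size", "n_trials"])
    agg = (df.groupby(["subject", "modality", "frequency_hz"], sort=True)
             .agg(fmri_size=("fmri_size", "mean"),
                  neural_size=("neural_size", "mean"),
                  n_trials=("trial", "count"))
             .reset_index())
    return agg


def linear_fit(x: np.ndarray, y: np.ndarray, with_intercept: bool = True) -> LinearFit:
    """Ordinary least squares y = x*b1 (+ b0).

    R^2 is 1 - SSR/TSS with TSS about the mean when an intercept is fitted
    and about zero otherwise; MSE is SSR / n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise InvalidArgumentError("need at least 2 points")
    if with_intercept:
        if np.ptp(x) == 0:
            raise DegenerateFitError("x is constant; intercept fit is singular")
        X = np.column_stack([x, np.ones(n)])
    else:
        if not np.any(x != 0):
            raise DegenerateFitError("x is identically zero; no-intercept fit is singular")
        X = x[:, None]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ssr = float(resid @ resid)
    if with_intercept:
        tss = float(np.sum((y - y.mean()) ** 2))
        beta1, beta0 = float(coef[0]), float(coef[1])
    else:
        tss = float(y @ y)
        beta1, beta0 = float(coef[0]), None
    r2 = 1.0 - ssr / tss if tss > 0 else (1.0 if ssr == 0 else 0.0)
    return LinearFit(beta1=beta1, beta0=beta0, r2=r2, mse=ssr / n, n=n)


def _check_common_grid(a: TimeSeries, b: TimeSeries):
    if a.n != b.n or abs(a.fs - b.fs) > 1e-9 * a.fs or abs(a.t0 - b.t0) > 0.5 / a.fs:
        raise InvalidArgumentError("paired epochs must share one time grid")


def frequency_wise_timecourse_fit(mean_fmri: Mapping[float, TimeSeries],
                                  mean_convolved_power: Mapping[float, TimeSeries]
                                  ) -> Dict[float, LinearFit]:
    """No-intercept fit of the convolved neuronal epoch to the fMRI epoch per frequency.

    Returns one ``LinearFit`` (slope b1 and MSE) per stimulation frequency;
    a rising b1 across frequencies signals frequency-dependent coupling gain.
    """
    if set(mean_fmri) != set(mean_convolved_power):
        raise InvalidArgumentError("frequency sets of the two epoch maps differ")
    fits: Dict[float, LinearFit] = {}
    for f in sorted(mean_fmri):
        y, x = mean_fmri[f], mean_convolved_power[f]
        _check_common_grid(y, x)
        if not np.any(y.values):  # zero fMRI epoch: slope 0 by convention
            fits[f] = LinearFit(beta1=0.0, beta0=None, r2=1.0, mse=0.0, n=y.n)
        else:
            fits[f] = linear_fit(x.values, y.values, with_intercept=False)
    return fits


def fixed_scaling_residuals(mean_fmri: Mapping[float, TimeSeries],
                            mean_convolved_power: Mapping[float, TimeSeries],
                            ref_frequency: float = 7.0,
                            ref_window: Tuple[float, float] = (0.0, 4.0)
                            ) -> Dict[float, TimeSeries]:
    """Residual epochs under one global coupling gain.

    A single no-intercept slope is fitted on the reference frequency's
    epochs restricted to ``ref_window`` (relative seconds) - the regime the
    IRF was derived in - and ``fmri - b1 * convolved_power`` is returned for
    every frequency and time point. Systematic nonzero residuals away from
    the reference window expose duration- and frequency-dependent coupling
    nonlinearity.
    """
    if ref_frequency not in mean_fmri or ref_frequency not in mean_convolved_power:
        raise InvalidArgumentError(f"reference frequency {ref_frequency} Hz missing")
    y_ref, x_ref = mean_fmri[ref_frequency], mean_convolved_power[ref_frequency]
    _check_common_grid(y_ref, x_ref)
    rel = y_ref.times
    mask = (rel >= ref_window[0] - 1e-9) & (rel < ref_window[1] - 1e-9)
    if not mask.any():
        raise InvalidArgumentError(f"reference window {ref_window} outside the epochs")
    fit = linear_fit(x_ref.values[mask], y_ref.values[mask], with_intercept=False)
    out: Dict[float, TimeSeries] = {}
    for f in sorted(mean_fmri):
        y, x = mean_fmri[f], mean_convolved_power[f]
        _check_common_grid(y, x)
        out[f] = y.copy_with(y.values - fit.beta1 * x.values)
    return out


def mean_of_means(epochs_by_subject: Mapping[str, np.ndarray]) -> np.ndarray:
    """Grand mean epoch: average of per-subject trial means.

    Subjects weigh equally regardless of how many trials they contribute
    (a subject's trials are averaged first, then subjects are averaged).
    """
    if not epochs_by_subject:
        raise InvalidArgumentError("no subjects supplied")
    subject_means = [np.atleast_2d(np.asarray(e, dtype=float)).mean(axis=0)
                     for e in epochs_by_subject.values()]
    lengths = {m.size for m in subject_means}
    if len(lengths) != 1:
        raise InvalidArgumentError("subjects' epochs differ in length")
    return np.mean(subject_means, axis=0)
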