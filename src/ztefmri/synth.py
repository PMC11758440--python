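"""Synthetic whisker-stimulation datasets with the structure the analysis assumes.

No raw recordings are distributed with this package, so every downstream
stage is exercised against simulated data that emulates the two study
designs:

* Design 1 (IRF derivation): 20 repetitions of a 1-s train of 7 pulses at
  7 Hz, one per 48-s cycle, with onsets jittered on a deterministic grid so
  that the post-stimulus sampling phases tile the sub-volume interval
  (the event-reordered acquisition needs this to reach ~100-ms resolution).
* Design 2 (frequency tuning): a 180-s baseline followed by 28 blocks of
  16-s stimulation (44-s breaks) at randomised frequencies
  1, 3, 5, 7, 9, 13 and 17 Hz, four blocks per frequency.

Evoked iEEG is built from a triphasic waveform (three Gaussian lobes: a
fast positive deflection, a larger negative one, and a slower positive
tail) with exponential within-block adaptation whose rate constant falls
with stimulation frequency. Recordings are contaminated with broadband
noise, 50-Hz line noise and harmonics, and an MRI gradient artifact tiled
at the volume triggers. fMRI traces are generated as IRF-convolved
neuronal power plus slow drift and Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import InvalidArgumentError
from .irf import IRFParams, convolve_power_with_irf, required_kernel_span
from .timeseries import TimeSeries, downsample_bins

__all__ = [
    "StimulusEvent", "StimulusSchedule", "WaveformParams", "NoiseParams",
    "make_group1_schedule", "make_group2_schedule",
    "triphasic_waveform", "simulate_evoked_ieeg", "simulate_ieeg_recording",
    "simulate_fmri_timecourse", "make_gradient_template", "modulate_power",
    "GROUP2_FREQUENCIES",
]

#: The stimulation frequencies of the frequency-tuning design (Hz).
GROUP2_FREQUENCIES: Tuple[float, ...] = (1.0, 3.0, 5.0, 7.0, 9.0, 13.0, 17.0)


@dataclass(frozen=True)
class StimulusEvent:
    onset_s: float
    frequency_hz: float
    n_pulses: int
    duration_s: float


@dataclass
class StimulusSchedule:
    """Ordered stimulus events plus fMRI volume trigger timestamps."""

    events: List[StimulusEvent]
    baseline_s: float
    total_duration_s: float
    volume_trigger_times_s: np.ndarray

    def __post_init__(self):
        self.volume_trigger_times_s = np.asarray(self.volume_trigger_times_s, dtype=float)
        onsets = [e.onset_s for e in self.events]
        if onsets != sorted(onsets):
            raise InvalidArgumentError("events must be sorted by onset")
        if any(o < self.baseline_s - 1e-12 for o in onsets):
            raise InvalidArgumentError("event onsets must not precede the baseline")
        for a, b in zip(self.events, self.events[1:]):
            if a.onset_s + a.duration_s > b.onset_s + 1e-12:
                raise InvalidArgumentError("events must not overlap")
        if self.events:
            last = self.events[-1]
            if self.total_duration_s + 1e-9 < last.onset_s + last.duration_s:
                raise InvalidArgumentError("total duration must cover the last event")
        if self.volume_trigger_times_s.size > 1 and \
                not np.all(np.diff(self.volume_trigger_times_s) > 0):
            raise InvalidArgumentError("volume triggers must be strictly increasing")

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset_s for e in self.events])

    def stim_intervals(self) -> List[Tuple[float, float]]:
        return [(e.onset_s, e.onset_s + e.duration_s) for e in self.events]

    def to_dict(self) -> dict:
        return {
            "events": [asdict(e) for e in self.events],
            "baseline_s": self.baseline_s,
            "total_duration_s": self.total_duration_s,
            "volume_trigger_times_s": self.volume_trigger_times_s.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        return cls(events=[StimulusEvent(**e) for e in d["events"]],
                   baseline_s=d["baseline_s"],
                   total_duration_s=d["total_duration_s"],
                   volume_trigger_times_s=np.asarray(d["volume_trigger_times_s"]))


def _default_kappa(frequency_hz: float) -> float:
    """Adaptation rate constant (in pulses) falling with stimulation frequency.

    kappa(f) = 21 / f gives ~3 pulses at 7 Hz and ~1.2 at 17 Hz: fast, deep
    adaptation at high frequencies, slow at 1 Hz, matching the qualitative
    frequency dependence of barrel-cortex evoked responses.
    """
    return 21.0 / frequency_hz


def _default_a_inf(frequency_hz: float) -> float:
    """Adaptation floor falling with stimulation frequency.

    a_inf(f) = 1 / sqrt(1 + (f / 5)^2) makes the total per-block evoked
    power peak at 5-7 Hz and decline gently towards 17 Hz, the tuning shape
    both the fMRI and the field-potential responses display (the degree of
    adaptation, like its rate, grows with stimulation frequency).
    """
    return 1.0 / np.sqrt(1.0 + (frequency_hz / 5.0) ** 2)


@dataclass
class WaveformParams:
    """Triphasic evoked waveform: three Gaussian lobes plus adaptation law.

    Amplitudes in mV (``a_neg`` < 0 and larger in magnitude than the first
    positive lobe), latencies and Gaussian widths in seconds with the final
    positive lobe slower than the first. The k-th pulse in a block is scaled
    by ``a(k) = a_inf + (1 - a_inf) * exp(-(k - 1) / kappa(f))``; both the
    floor ``a_inf`` and the rate constant ``kappa`` may be callables of the
    stimulation frequency, since rate and degree of adaptation both depend
    on it. The default lobes span < 143 ms, one inter-pulse interval at 7 Hz.
    """

    a_pos1: float = 0.20
    a_neg: float = -0.50
    a_pos2: float = 0.12
    l1: float = 0.012
    l2: float = 0.030
    l3: float = 0.075
    w1: float = 0.004
    w2: float = 0.009
    w3: float = 0.016
    a_inf: Union[float, Callable[[float], float]] = _default_a_inf
    kappa: Callable[[float], float] = _default_kappa

    def __post_init__(self):
        if not (self.a_pos1 > 0 and self.a_pos2 > 0 and self.a_neg < 0):
            raise InvalidArgumentError("lobe amplitudes must satisfy a_pos1>0, a_neg<0, a_pos2>0")
        if abs(self.a_neg) <= self.a_pos1:
            raise InvalidArgumentError("the negative lobe must dominate the first positive lobe")
        if not (self.l1 < self.l2 < self.l3):
            raise InvalidArgumentError("latencies must be ordered l1 < l2 < l3")
        if min(self.w1, self.w2, self.w3) <= 0 or self.w3 <= self.w1:
            raise InvalidArgumentError("widths must be positive with w3 > w1")
        if not callable(self.a_inf) and not (0 < self.a_inf <= 1):
            raise InvalidArgumentError("adaptation floor must lie in (0, 1]")

    def floor_at(self, frequency_hz: float) -> float:
        a = self.a_inf(frequency_hz) if callable(self.a_inf) else self.a_inf
        if not (0 < a <= 1):
            raise InvalidArgumentError(
                f"adaptation floor {a} at {frequency_hz} Hz outside (0, 1]")
        return a

    @property
    def span_s(self) -> float:
        """Support of the waveform (last lobe latency + 4 sigma)."""
        return self.l3 + 4.0 * self.w3


@dataclass
class NoiseParams:
    """Contamination model for simulated recordings.

    ``line_amps`` are the amplitudes (mV) of sinusoids at ``line_freqs``
    (50 Hz and harmonics). ``gradient_template`` is one volume-period of
    MRI gradient artifact inserted at every volume trigger. fMRI noise is
    white Gaussian (signal units) on top of a slow sinusoidal drift whose
    period exceeds the 100-s detrending cutoff.
    """

    broadband_sd: float = 0.05
    line_amps: Tuple[float, ...] = (0.10, 0.04, 0.02)
    line_freqs: Tuple[float, ...] = (50.0, 100.0, 150.0)
    gradient_template: Optional[np.ndarray] = None
    fmri_noise_sd: float = 0.0
    drift_amplitude: float = 0.0
    drift_period_s: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.broadband_sd < 0 or any(a < 0 for a in self.line_amps):
            raise InvalidArgumentError("noise standard deviations/amplitudes must be >= 0")
        if self.fmri_noise_sd < 0 or self.drift_amplitude < 0:
            raise InvalidArgumentError("fMRI noise/drift amplitudes must be >= 0")
        if len(self.line_amps) != len(self.line_freqs):
            raise InvalidArgumentError("one amplitude per line frequency required")
        if self.gradient_template is not None:
            self.gradient_template = np.asarray(self.gradient_template, dtype=float)


def make_gradient_template(fs: float, period_s: float, amplitude: float = 0.5,
                           seed: int = 0) -> np.ndarray:
    """A reproducible volume-period-long gradient-artifact waveform.

    Built as a sum of sharp sawtooth-like harmonics of the volume rate with
    seeded random phases; deterministic given (fs, period_s, amplitude, seed).
    """
    n = int(round(period_s * fs))
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    tpl = np.zeros(n)
    for h in range(1, 40):
        tpl += np.sin(2 * np.pi * h * t / period_s + rng.uniform(0, 2 * np.pi)) / h
    peak = np.max(np.abs(tpl))
    return amplitude * tpl / peak if peak > 0 else tpl


def make_group1_schedule(n_events: int = 20, train_hz: float = 7.0,
                         train_s: float = 1.0, cycle_s: float = 48.0,
                         jitter_grid_s: float = 0.1, seed: int = 0,
                         baseline_s: float = 0.0,
                         volume_tr_s: float = 2.0) -> StimulusSchedule:
    """Stimulus schedule of the IRF-derivation design.

    ``n_events`` short trains (``train_s`` seconds at ``train_hz``), one per
    ``cycle_s``-second cycle. Event k receives a jitter offset
    ``perm(k) * jitter_grid_s`` where ``perm`` is a seed-determined
    permutation of 0..n_events-1: the offsets form a deterministic grid that
    tiles ``n_events * jitter_grid_s`` seconds (with the defaults, one 2-s
    volume period in 0.1-s steps), so the post-stimulus sampling phases of
    the repeated events tile the sub-volume interval for event-reordered
    rebinning. Total duration is exactly ``baseline_s + n_events * cycle_s``.
    """
    if n_events < 1:
        raise InvalidArgumentError("n_events must be >= 1")
    if train_s <= 0 or cycle_s <= 0 or train_hz <= 0:
        raise InvalidArgumentError("train/cycle durations and rate must be positive")
    if train_s >= cycle_s:
        raise InvalidArgumentError("train must be shorter than the cycle")
    if jitter_grid_s < 0:
        raise InvalidArgumentError("jitter grid step must be >= 0")
    max_jitter = jitter_grid_s * (n_events - 1)
    if train_s + max_jitter >= cycle_s:
        raise InvalidArgumentError("jitter range overruns the inter-train break")
    rng = np.random.default_rng(seed)
    offsets = rng.permutation(n_events) * jitter_grid_s
    n_pulses = int(round(train_hz * train_s))
    events = [StimulusEvent(onset_s=baseline_s + k * cycle_s + offsets[k],
                            frequency_hz=train_hz, n_pulses=n_pulses,
                            duration_s=train_s)
              for k in range(n_events)]
    total = baseline_s + n_events * cycle_s
    triggers = np.arange(0.0, total - volume_tr_s / 2, volume_tr_s)
    return StimulusSchedule(events=events, baseline_s=baseline_s,
                            total_duration_s=total,
                            volume_trigger_times_s=triggers)


def make_group2_schedule(frequencies_hz: Sequence[float] = GROUP2_FREQUENCIES,
                         blocks_per_freq: int = 4, block_s: float = 16.0,
                         break_s: float = 44.0, baseline_s: float = 180.0,
                         seed: int = 0,
                         volume_tr_s: float = 2.0) -> StimulusSchedule:
    """Stimulus schedule of the frequency-tuning design.

    ``len(frequencies_hz) * blocks_per_freq`` blocks of ``block_s`` seconds
    of continuous stimulation separated by ``break_s``-second breaks, after
    an initial ``baseline_s``-second baseline. The block order is a
    seed-determined random permutation; each block carries
    ``round(frequency * block_s)`` pulses. With the defaults the experiment
    lasts 180 + 28 * 60 = 1860 s (31 min).
    """
    freqs = list(frequencies_hz)
    if not freqs or any(f <= 0 for f in freqs):
        raise InvalidArgumentError("frequencies must be non-empty and positive")
    if len(set(freqs)) != len(freqs):
        raise InvalidArgumentError("duplicate stimulation frequencies")
    if blocks_per_freq < 1:
        raise InvalidArgumentError("blocks_per_freq must be >= 1")
    if block_s <= 0 or break_s < 0 or baseline_s < 0:
        raise InvalidArgumentError("durations must be non-negative (block > 0)")
    order = [f for f in freqs for _ in range(blocks_per_freq)]
    rng = np.random.default_rng(seed)
    order = [order[i] for i in rng.permutation(len(order))]
    events = []
    for j, f in enumerate(order):
        onset = baseline_s + j * (block_s + break_s)
        events.append(StimulusEvent(onset_s=onset, frequency_hz=f,
                                    n_pulses=int(round(f * block_s)),
                                    duration_s=block_s))
    total = baseline_s + len(order) * (block_s + break_s)
    triggers = np.arange(0.0, total - volume_tr_s / 2, volume_tr_s)
    return StimulusSchedule(events=events, baseline_s=baseline_s,
                            total_duration_s=total,
                            volume_trigger_times_s=triggers)


def triphasic_waveform(t: np.ndarray, wf: WaveformParams) -> np.ndarray:
    """Evaluate the single-pulse evoked waveform at times ``t`` after the pulse."""
    t = np.asarray(t, dtype=float)
    return (wf.a_pos1 * np.exp(-0.5 * ((t - wf.l1) / wf.w1) ** 2)
            + wf.a_neg * np.exp(-0.5 * ((t - wf.l2) / wf.w2) ** 2)
            + wf.a_pos2 * np.exp(-0.5 * ((t - wf.l3) / wf.w3) ** 2))


def pulse_amplitude(k: int, frequency_hz: float, wf: WaveformParams) -> float:
    """Adaptation scaling of the k-th (1-based) pulse within a block."""
    kappa = wf.kappa(frequency_hz)
    a_inf = wf.floor_at(frequency_hz)
    return a_inf + (1.0 - a_inf) * np.exp(-(k - 1) / kappa)


def simulate_evoked_ieeg(schedule: StimulusSchedule, wf: WaveformParams,
                         fs: float = 5000.0) -> TimeSeries:
    """Noise-free evoked iEEG: adapted triphasic responses to every pulse.

    Pulses within a block are spaced ``1 / frequency`` apart; the k-th pulse
    is scaled by the adaptation law. The trace is zero outside responses.
    """
    if fs <= 0:
        raise InvalidArgumentError("fs must be positive")
    if fs * min(wf.w1, wf.w2, wf.w3) < 2.0:
        raise InvalidArgumentError(
            f"fs = {fs} Hz undersamples the waveform (narrowest lobe {min(wf.w1, wf.w2, wf.w3)} s)")
    n = int(round(schedule.total_duration_s * fs))
    out = np.zeros(n)
    n_wave = int(np.ceil(wf.span_s * fs)) + 1
    rel = np.arange(n_wave) / fs
    base_wave = triphasic_waveform(rel, wf)
    for ev in schedule.events:
        for k in range(ev.n_pulses):
            t_pulse = ev.onset_s + k / ev.frequency_hz
            amp = pulse_amplitude(k + 1, ev.frequency_hz, wf)
            i0 = int(round(t_pulse * fs))
            i1 = min(i0 + n_wave, n)
            if i0 >= n:
                continue
            # pulse times off the sample grid: evaluate the (smooth) waveform
            # at the actual sample offsets rather than shifting by a rounded lag
            frac = t_pulse - i0 / fs
            if abs(frac) < 1e-12:
                out[i0:i1] += amp * base_wave[: i1 - i0]
            else:
                tt = np.arange(i1 - i0) / fs - frac
                out[i0:i1] += amp * triphasic_waveform(tt, wf)
    return TimeSeries(0.0, fs, out)


def simulate_ieeg_recording(clean: TimeSeries, schedule: StimulusSchedule,
                            noise: NoiseParams) -> TimeSeries:
    """Contaminate a clean evoked trace the way a scanner-side recording is.

    Adds broadband Gaussian noise, power-line sinusoids (seeded random
    phases) and the gradient-artifact template tiled at every volume trigger
    whose full window fits in the recording. Bit-reproducible from the seed.
    """
    rng = np.random.default_rng(noise.seed)
    out = clean.values.copy()
    t = clean.times
    for amp, f in zip(noise.line_amps, noise.line_freqs):
        if amp > 0:
            out += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if noise.broadband_sd > 0:
        out += rng.normal(0.0, noise.broadband_sd, size=out.size)
    tpl = noise.gradient_template
    if tpl is not None and tpl.size > 0:
        trig = schedule.volume_trigger_times_s
        if trig.size > 1:
            period = float(np.median(np.diff(trig)))
            expected = int(round(period * clean.fs))
            if tpl.size != expected:
                raise InvalidArgumentError(
                    f"gradient template has {tpl.size} samples but the volume period "
                    f"corresponds to {expected}")
        for tt in trig:
            i0 = int(round((tt - clean.t0) * clean.fs))
            if i0 < 0 or i0 + tpl.size > out.size:
                continue  # partial trailing window skipped
            out[i0:i0 + tpl.size] += tpl
    return clean.copy_with(out)


def modulate_power(power: TimeSeries, schedule: StimulusSchedule,
                   freq_gain: Optional[Callable[[float], float]] = None,
                   sustained_onset_s: Optional[float] = None,
                   sustained_factor: Union[float, Callable[[float], float]] = 1.0
                   ) -> TimeSeries:
    """Apply neurovascular-coupling gain structure to a neuronal power trace.

    Used to plant controlled departures from a single global coupling gain
    before the power is convolved into an fMRI trace:

    * ``freq_gain(f)`` scales the power within blocks of frequency ``f``
      (emulates coupling gain rising with stimulation frequency);
    * ``sustained_factor`` scales the power from ``sustained_onset_s``
      seconds after each block onset to the block end (emulates the extra
      hemodynamic component that builds up during sustained stimulation);
      it may be a callable of the block frequency, since the sustained
      mismatch observed between hemodynamics and field-potential power
      grows with stimulation frequency.

    With both options off this is the identity.
    """
    out = power.values.copy()
    t = power.times
    for ev in schedule.events:
        sel = (t >= ev.onset_s) & (t < ev.onset_s + ev.duration_s)
        if freq_gain is not None:
            out[sel] *= freq_gain(ev.frequency_hz)
        if sustained_onset_s is not None:
            s = (sustained_factor(ev.frequency_hz) if callable(sustained_factor)
                 else sustained_factor)
            if s != 1.0:
                late = (t >= ev.onset_s + sustained_onset_s) & \
                       (t < ev.onset_s + ev.duration_s)
                out[late] *= s
    return power.copy_with(out)


def simulate_fmri_timecourse(neural_power: TimeSeries, irf: IRFParams,
                             gain: float, dt_out: float,
                             noise: NoiseParams,
                             kernel_span_s: Optional[float] = None) -> TimeSeries:
    """fMRI ROI trace: IRF-convolved neuronal power plus drift and noise.

    The power series is convolved with the gamma IRF at its own rate,
    scaled by ``gain``, bin-averaged into ``dt_out`` bins, and contaminated
    with a slow sinusoidal drift and white Gaussian noise (both seeded).
    ``dt_out`` must be a multiple of the power sample interval.
    """
    m = dt_out * neural_power.fs
    if abs(m - round(m)) > 1e-6 or round(m) < 1:
        raise InvalidArgumentError(
            f"dt_out = {dt_out} s is not a multiple of the power sample interval")
    if kernel_span_s is None:
        kernel_span_s = max(60.0, required_kernel_span(irf) * 1.05)
    conv = convolve_power_with_irf(neural_power, irf, kernel_span_s)
    binned = downsample_bins(conv.copy_with(gain * conv.values), dt_out)
    out = binned.values
    rng = np.random.default_rng(noise.seed)
    if noise.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out = out + noise.drift_amplitude * np.sin(
            2 * np.pi * binned.times / noise.drift_period_s + phase)
    if noise.fmri_noise_sd > 0:
        out = out + rng.normal(0.0, noise.fmri_noise_sd, size=out.size)
    return binned.copy_with(out)
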