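"""Shared fixtures.

The expensive object is the full-grid model-curve matrix for the design-1
mean power epoch (247,500 binned convolution curves); it is built once per
session and shared between the grid-search tests and the noise-replicate
recovery tests.
"""

import pytest

import ztefmri as z
from ztefmri.irf import (IRFParams, convolve_power_with_irf, grid_model_curves)
from ztefmri.timeseries import TimeSeries, downsample_bins

TRUTH = IRFParams(alpha=2.9, beta=1.2, tau=0.5)


def group1_power_epoch(fs_fit: float = 100.0) -> TimeSeries:
    """Mean evoked power epoch of the design-1 stimulus (1-s 7 Hz train).

    Built noise-free: clean evoked trace at 5 kHz, squared,
    baseline-corrected over the 3-s pre-stimulus window, bin-averaged to
    ``fs_fit`` and trimmed to the 14-s window [-3, 11) s.
    """
    sched = z.make_group1_schedule(n_events=1, cycle_s=14.0, jitter_grid_s=0.0,
                                   baseline_s=3.0, seed=0)
    clean = z.simulate_evoked_ieeg(sched, z.WaveformParams(), fs=5000.0)
    power = downsample_bins(TimeSeries(-3.0, 5000.0, clean.values ** 2), 1.0 / fs_fit)
    corrected = power.values - power.values[power.times < 0].mean()
    n = int(round(14.0 * fs_fit))
    return TimeSeries(power.t0, power.fs, corrected[:n])


def noise_free_fmri_epoch(power: TimeSeries, truth: IRFParams = TRUTH,
                          bin_s: float = 0.1) -> TimeSeries:
    conv = convolve_power_with_irf(power, truth, 60.0)
    f = downsample_bins(conv, bin_s)
    return f.copy_with(f.values - f.values[f.times < 0].mean())


@pytest.fixture(scope="session")
def power_epoch():
    return group1_power_epoch()


@pytest.fixture(scope="session")
def fmri_epoch(power_epoch):
    return noise_free_fmri_epoch(power_epoch)


@pytest.fixture(scope="session")
def full_grid_curves(power_epoch, fmri_epoch):
    """(grid, curves) for the complete published parameter grid."""
    grid = z.IRFGrid.default()
    curves = grid_model_curves(power_epoch, grid, 0.1, n_bins=fmri_epoch.n)
    return grid, curves
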