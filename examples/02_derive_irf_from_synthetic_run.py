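"""Derive the IRF from a complete synthetic design-1 experiment.

Simulates 20 jittered 1-s 7 Hz whisker-stimulation trains with
contaminated 5-kHz iEEG (broadband + line noise + gradient artifacts) and
a ~1-ms-spoke fMRI stream, then runs the full derivation path: filter,
select electrode, average and square the evoked response, rebin the
spokes into a 140-point 100-ms-resolution fMRI epoch, and grid-search the
gamma kernel over all 150 x 150 x 11 parameter combinations.
"""

import logging

from ztefmri import PipelineConfig, run_derive_irf, simulate_group1

logging.basicConfig(level=logging.INFO, format="%(levelname)s: %(message)s")

cfg = PipelineConfig(seed=11, group=1)
dataset = simulate_group1(cfg)
print(f"simulated: {len(dataset.schedule.events)} stimulation events, "
      f"{dataset.spokes.n} fMRI spokes, "
      f"{len(dataset.ieeg)} iEEG electrodes\n")

report = run_derive_irf(cfg, dataset=dataset)
best, char = report["best"], report["characterization"]
print(f"\nbest-fit kernel over {report['n_grid_combinations']} combinations:")
print(f"  alpha = {best['alpha']:.1f}, beta = {best['beta']:.1f} 1/s, "
      f"tau = {best['tau']:.1f} s")
print(f"  R^2 = {report['r2']:.3f} against the rebinned fMRI epoch")
print(f"  OT = {char['onset_time_s']:.1f} s, TTP = {char['time_to_peak_s']:.1f} s, "
      f"FWHM = {char['fwhm_s']:.1f} s")
print("\nUnder measurement noise the (alpha, beta, tau) triple can wander")
print("along a ridge of near-equivalent kernels; the characterization")
print("(OT/TTP/FWHM) is the stable summary of the response shape.")
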