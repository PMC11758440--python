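"""Frequency-tuning coupling analysis with a planted nonlinearity.

Simulates design-2 experiments (16-s stimulation blocks at 1-17 Hz) in
which the hemodynamic response acquires an extra gain after 4 s of
sustained stimulation, growing with stimulation frequency - the kind of
duration- and frequency-dependent coupling residual seen in real
recordings. The analysis regresses fMRI response size on IRF-convolved
neuronal power size over the full 22-s window and over the first 4 s,
for all frequencies and for the 1-7 Hz subset.
"""

import logging

from ztefmri import PipelineConfig, run_correlate, simulate_group2

logging.basicConfig(level=logging.WARNING)

cfg = PipelineConfig(seed=0, group=2, n_subjects=5, sessions_per_subject=1,
                     coupling_sustained_factor=6.0)
dataset = simulate_group2(cfg)
report = run_correlate(cfg, dataset=dataset)

print(f"{report['n_experiments']} experiments, {report['n_blocks']} blocks\n")
print("response-size regressions (window x frequency subset):")
for key, fit in report["response_size_fits"].items():
    window = "22-s window " if key.startswith("full") else "first 4 s  "
    subset = "all freqs" if key.endswith("all") else "1-7 Hz    "
    print(f"  {window} {subset}: R^2 = {fit['r2']:.3f}  MSE = {fit['mse']:.3f} "
          f"(n = {fit['n']})")
print("\nper-frequency time-course regression coefficients (beta1):")
for f, b in report["per_frequency_beta1"].items():
    print(f"  {float(f):5.1f} Hz: beta1 = {b:8.1f}")
print("\nThe full-window fit degrades because the sustained component is")
print("invisible to the neuronal regressor; restricting to the first 4 s")
print("(and to 1-7 Hz) recovers tight linear coupling - the same ordering")
print("of fits motivates nonlinear coupling models for sustained stimuli.")
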