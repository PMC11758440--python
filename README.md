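# ztefmri

Hemodynamic impulse-response estimation and neurovascular-coupling analysis
for **zero echo time (zero-TE) fMRI** with simultaneous intracranial EEG
(iEEG), built for the rodent whisker-stimulation setting: epidural
electrodes over the barrel cortex recorded at 5 kHz inside the scanner,
radial zero-TE acquisition at ~1 ms per spoke, and somatosensory
stimulation delivered either as brief 7-Hz trains or as 16-s blocks at
1–17 Hz.

Zero-TE sequences are quiet and artifact-free but carry a functional
contrast of non-BOLD (blood volume/flow) origin, so the canonical BOLD
response models do not apply. This package implements the analysis that
derives the zero-TE impulse response function (IRF) from data and
quantifies how well neuronal activity predicts the zero-TE signal.

## The model

The fMRI response to neuronal activity is modelled as a causal linear
convolution of instantaneous iEEG power with a gamma-form kernel

```
f(t) = (t − τ)^(α−1) β^α exp(−β (t − τ)) / Γ(α)    for t ≥ τ,  else 0
```

with shape `α`, rate `β` (1/s) and onset delay `τ` (s). The IRF is
*defined* by exhaustive grid search: the mean evoked power epoch is
convolved with the kernel at every combination of `α ∈ {0.1, 0.2, …, 15}`,
`β ∈ {0.1, 0.2, …, 15}`, `τ ∈ {0, 0.1, …, 1}` (247,500 kernels),
bin-averaged to the 100-ms fMRI resolution, scaled by a single
least-squares amplitude, and scored by the sum of squared residuals
against the measured fMRI epoch. The winning triple is characterized by
onset time (OT), time-to-peak (TTP) and full-width-at-half-maximum (FWHM).

Around the fit, the package implements the full processing chain:
gradient-artifact template subtraction, 4–190 Hz band-pass with
50/100/150 Hz notches (all zero-phase), stimulus-sensitivity electrode
selection, squaring to power, epoching and baseline correction on the
iEEG side; 100-s high-pass detrending, ROI extraction and the
event-reordered spoke rebinning scheduler (140 × 0.1-s bins pooled over
20 jittered events, ~2000 spokes per bin) on the fMRI side; and
response-size regressions (`y = xβ₁ + β₀` and `y = xβ₁`), per-frequency
time-course fits, and fixed-scaling residual analysis for the coupling
question. A seeded synthetic-data generator emulates both study designs
— triphasic evoked waveforms with frequency-dependent adaptation, MRI
gradient artifacts, line noise, drift — so the whole pipeline is testable
without any recordings.

## Worked example

`examples/02_derive_irf_from_synthetic_run.py` simulates a complete
IRF-derivation experiment (20 stimulation events, ~10⁶ spokes, two noisy
electrodes) and runs the full derivation:

```
simulated: 20 stimulation events, 993814 fMRI spokes, 2 iEEG electrodes

best-fit kernel over 247500 combinations:
  alpha = 4.8, beta = 1.7 1/s, tau = 0.0 s
  R^2 = 0.958 against the rebinned fMRI epoch
  OT = 0.0 s, TTP = 2.2 s, FWHM = 2.7 s
```

The generating kernel was `(α, β, τ) = (2.9, 1.2, 0.5)` with TTP 2.1 s and
FWHM 2.8 s: under realistic noise the recovered triple wanders along a
ridge of nearly equivalent kernels, but the response *shape* summary
(TTP/FWHM, and the variance explained) is stable — which is why the
characterization, not the raw triple, is the quantity to report.

`examples/04_frequency_coupling.py` plants a duration- and
frequency-dependent coupling nonlinearity and reproduces its signature:

```
response-size regressions (window x frequency subset):
  22-s window  all freqs: R^2 = 0.189
  22-s window  1-7 Hz   : R^2 = 0.834
  first 4 s   all freqs : R^2 = 0.826
  first 4 s   1-7 Hz    : R^2 = 0.851
```

i.e. neuronal power predicts the zero-TE response well early in
stimulation and at moderate frequencies, while sustained high-frequency
stimulation drives an fMRI component the electrode does not see. The
per-frequency regression coefficients β₁ rise monotonically with
stimulation frequency (158 → 616 in the run above), the other half of the
same signature.

The other examples characterize the IRF against literature reference
kernels (`01`) and demonstrate the event-reordered rebinning scheduler
(`03`). A thin CLI wraps the pipeline:
`ztefmri simulate|derive-irf|correlate --config cfg.yaml --out DIR`.

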