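"""Characterize the zero-TE fMRI impulse response and reference kernels.

Evaluates the gamma-form IRF at the best-fit parameters derived from rat
barrel cortex (shape 2.9, rate 1.2 1/s, onset 0.5 s) and reports onset
time (OT), time-to-peak (TTP) and full-width-at-half-maximum (FWHM),
alongside literature reference kernels: a double-gamma BOLD response and
a best-effort gamma-variate CBV/CBF response.
"""

from ztefmri import RAT_S1BF_IRF, characterize_gamma_irf
from ztefmri.irf import (characterize_irf, lambers_double_gamma,
                         martindale_gamma_variate)

char = characterize_gamma_irf(RAT_S1BF_IRF)
print("zero-TE fMRI IRF, gamma(alpha=2.9, beta=1.2, tau=0.5):")
print(f"  OT  = {char.onset_time_s:.1f} s   (response onset delay = tau)")
print(f"  TTP = {char.time_to_peak_s:.1f} s   (time from stimulus onset to peak)")
print(f"  FWHM = {char.fwhm_s:.1f} s  (duration of the response bump)")

bold = characterize_irf(lambda t: lambers_double_gamma(2.5, 10, 11.7, 1.5, t),
                        t_max=20.0)
print("\ndouble-gamma BOLD reference (b=2.5, p1=10, p2=11.7, V=1.5):")
print(f"  TTP = {bold.time_to_peak_s:.1f} s, FWHM = {bold.fwhm_s:.1f} s")
print("  -> the BOLD kernel peaks a second later than the zero-TE kernel,")
print("     consistent with a blood volume/flow (non-BOLD) contrast origin")

cbv = characterize_irf(lambda t: martindale_gamma_variate(2.49, 1.22, t),
                       t_max=20.0)
print("\ngamma-variate CBV reference (delta=2.49, tau=1.22; best-effort reading):")
print(f"  TTP = {cbv.time_to_peak_s:.1f} s, FWHM = {cbv.fwhm_s:.1f} s")
print("  -> close to the zero-TE kernel's timing, as expected for CBV/CBF")
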