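"""Fitting a FRAP recovery curve.

Generates a noisy synthetic recovery trace for the short-DNA PEG/Mg
condensate regime (mobile fraction 0.66, exchange time constant 99 s, 300
frames at 0.8 s with 2% Gaussian noise), fits the single-exponential
model FRAP(t) = a (1 - exp(-k t)), and prints the estimates.

The mobile fraction a is the plateau of the normalized recovery -- the
fraction of molecules exchanging between the condensate and the dilute
phase; t_1/2 = ln 2 / k is the half-time of recovery.
"""

from dnacondense import fit_frap
from dnacondense.synthetic import gen_frap

curve, truth = gen_frap(seed=1, preset="psi_short", noise_sd=0.02)
fit = fit_frap(curve)

print("true:   a = {mobile_fraction:.3f}, k = {rate_k:.5f} 1/s".format(**truth))
print(
    f"fitted: a = {fit.mobile_fraction_a:.3f} +/- {fit.stderr_a:.3f}, "
    f"k = {fit.rate_k:.5f} +/- {fit.stderr_k:.5f} 1/s"
)
print(f"half-time of recovery: t_1/2 = {fit.t_half:.1f} s")
print(f"residual SD: {fit.residual_sd:.4f} (noise was 0.02)")
print(
    "\nA mobile fraction of ~2/3 with a ~100 s exchange time is the"
    "\nsignature of a liquid-like condensate; immobile fractions near 1"
    "\nindicate solid-like assemblies."
)
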