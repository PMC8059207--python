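"""Condensate stability under flow and molecule counting.

Generates a two-channel time series of surface-anchored condensates in
which a fast minority population (e.g. weakly tethered condensates)
disassembles quickly and a slow majority gradually, extracts
background-subtracted max-pixel intensity traces (keeping only
condensates visible in both channels), fits the ensemble decay, and
counts DNA molecules per condensate from the intensity.
"""

import numpy as np

from dnacondense import count_molecules, extract_traces, select_decay_model
from dnacondense.flow_stability import normalize_traces
from dnacondense.synthetic import gen_flow_stack

DYE = 1000.0       # single-dye intensity, a.u.
FRACTION = 0.5     # labeled fraction of molecules

stack, truth = gen_flow_stack(
    seed=11,
    n_spots=8,
    n_frames=200,
    molecule_numbers=[4, 6, 8, 10, 20, 24, 36, 48],
    labeled_fraction=FRACTION,
    single_dye_intensity=DYE,
    decay_populations=((0.3, 0.1), (0.7, 0.005)),
    read_noise_sd=2.0,
)
traces = extract_traces(stack)
print(f"extracted {len(traces)} traces ({len(traces)//2} dual-channel condensates)")

times, mean, sem = normalize_traces([t for t in traces if t.channel == 0])
fit = select_decay_model(mean, times=times)
print(f"ensemble decay model selected by AICc: {fit.model}")
print(
    "rates: fast = {:.3f} 1/s, slow = {:.4f} 1/s (programmed 0.1 / 0.005)".format(
        fit.rates[0], fit.rates[-1]
    )
)

print("\nmolecules per condensate (initial intensity / dye / labeled fraction):")
for tr in traces:
    if tr.channel != 0:
        continue
    est = count_molecules(tr.intensity[0], DYE, FRACTION, condensate_id=tr.condensate_id)
    print(f"  condensate {tr.condensate_id}: {est.n_molecules:6.1f}  (~{est.n_rounded})")
print(
    "\nCondensates of short oligomers disassemble in minutes under"
    "\ndecondensation-buffer flow, while long-DNA condensates persist --"
    "\nthe flow assay reads out the same length-dependent stability as"
    "\nFRAP."
)
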