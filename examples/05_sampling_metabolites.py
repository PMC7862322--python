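"""Automated metabolite sampling from a stimulated muscle culture.

Runs the four-phase sampling cycle (circulate, sample, drain, wait) at
the programmed times for a stimulated and a control arm, reads each
40 uL aliquot with the virtual biosensor, and prints the lactate excess
caused by electrical stimulation.
"""

import numpy as np

from ochip_loop import (
    MetabolitePlant,
    MixCompartments,
    SamplerState,
    biosensor_read,
    metabolite_concentrations,
    run_sampling_cycle,
)
from ochip_loop.fluidics import time_to_uniform

plant = MetabolitePlant(stim_window=(0.0, float("inf")))
arms = {}
for name, stimulated in (("stim", True), ("ctrl", False)):
    sampler = SamplerState()  # schedule 0, 3, 6, 12, 18, 24 h
    for t in sampler.schedule:
        conc = metabolite_concentrations(plant, t, stimulated)
        sampler = run_sampling_cycle(sampler, t, conc)
    arms[name] = [biosensor_read(a) for a in sampler.containers]

print("time_h  lactate_stim  lactate_ctrl  excess_%")
for t, (ls, _), (lc, _) in zip((0, 3, 6, 12, 18, 24), arms["stim"], arms["ctrl"]):
    excess = 100 * (ls - lc) / lc if lc else 0.0
    print(f"{t:6.0f}  {ls:12.3f}  {lc:12.3f}  {excess:8.2f}")

bolus = MixCompartments(dye=np.array([8.0] + [0.0] * 7))
print(f"\ndye bolus homogenized (CV < 5%) after {time_to_uniform(bolus):.0f} s of circulation")
# The excess grows from 0% to 14% at 6 h and 26% at 24 h of stimulation;
# homogenization completes well inside the 180 s circulating phase.
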