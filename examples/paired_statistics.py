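"""Paired-eye statistics: does a simulated pSTR deficit reach significance?

Simulates a cohort of 13 animals in which each ocular-hypertensive eye
keeps only 70% of its partner eye's pSTR amplitude, measures the pSTR
through the pipeline's threshold-response stage, and applies the paired
t-test (each OHT eye vs. its contralateral control).
"""

import numpy as np

from ergdecomp import CohortDesign, ComponentParams, paired_t, simulate_cohort
from ergdecomp.filters import p2_lowpass
from ergdecomp.p2 import pstr_amplitude

design = CohortDesign(
    n_pairs=13, base=ComponentParams(), inter_animal_cv=0.2,
    effects={"pstr_amp_uv": 0.7}, seed=21,
)
recordings, _ = simulate_cohort(design)

lowpass = p2_lowpass(recordings[0].fs_hz)
nt, oht = [], []
for rec in recordings:
    trace = rec.trace_at(-5.30)
    trace = trace.with_voltage(trace.v_uv - trace.baseline())
    amp = pstr_amplitude(lowpass.apply(trace), intensity_log=-5.30)
    (nt if rec.pressure_group == "NT" else oht).append(amp)

t, df, p = paired_t(np.array(oht), np.array(nt))
print(f"pSTR at -5.30 log cd·s/m²: NT mean {np.mean(nt):.2f} µV, "
      f"OHT mean {np.mean(oht):.2f} µV over {design.n_pairs} pairs")
print(f"paired t = {t:.3f}, df = {df}, two-sided p = {p:.2e}")
print()
print("A negative t with small p indicates the ganglion-cell-driven "
      "threshold response is reliably smaller in the hypertensive eyes, "
      "as built into the simulation (30% reduction).")
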