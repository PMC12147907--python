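"""Joint delayed-Gaussian P3 fit on the two brightest flashes.

Builds a noise-free photoreceptor-only recording with known parameters,
fits the model, and reports the recovered triple and residual RMS.
"""

from ergdecomp import CohortDesign, ComponentParams, fit_p3_joint, simulate_cohort

base = ComponentParams(
    rmp3_uv=400.0, s_sens=1600.0, td_ms=3.5,
    p2max_uv=0.0, op_amp_uv=0.0, pstr_amp_uv=0.0, noise_sd_uv=0.0,
)
recordings, _ = simulate_cohort(
    CohortDesign(n_pairs=1, base=base, inter_animal_cv=0.0, seed=1)
)
fit = fit_p3_joint(recordings[0])

print(f"RmP3 = {fit.rmp3_uv:10.4f} µV        (true 400: saturated a-wave amplitude)")
print(f"S    = {fit.s_sens:10.4f} cd⁻¹m²s⁻³ (true 1600: transduction amplification)")
print(f"td   = {fit.td_ms:10.4f} ms        (true 3.5: transduction + recording delay)")
print(f"rms  = {fit.rms_uv:.2e} µV over window {fit.window_ms} ms")
print()
print("One shared parameter triple is fitted to both bright flashes "
      f"({fit.intensities_fit} log cd·s/m²) by pooled RMS minimisation; "
      "a near-zero residual confirms exact recovery on clean data.")
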