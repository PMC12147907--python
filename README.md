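# ergdecomp

Component decomposition of dark-adapted (scotopic) flash
electroretinograms, for retinal electrophysiology labs quantifying how
disease models — ocular hypertension in particular — affect each retinal
cell class.  A single multi-intensity flash series per eye is decomposed
into the responses of photoreceptors, bipolar cells, amacrine circuits
and retinal ganglion cells, and paired-eye cohorts (each treated eye
against its contralateral control) are compared statistically.

## The model

**P3 (photoreceptors).** The leading corneal-negative a-wave is modelled
by a delayed-Gaussian saturating function of flash energy *i* (cd·s/m²)
and time *t*:

    P3(i, t) = −RmP3 · [1 − exp(−i · S · (t − t_d)²)]   for t > t_d

with saturated amplitude RmP3 (µV), phototransduction amplification S
(cd⁻¹·m²·s⁻³) and delay t_d.  One shared (RmP3, S, t_d) is fitted to the
two brightest flashes (1.0 and 1.48 log cd·s/m²) by pooled RMS
minimisation, then the modelled P3 family is subtracted from every raw
trace.

**P2 (bipolar cells).** The remnant is low-pass filtered (zero-phase,
composite −3 dB at 50 Hz) to remove the oscillatory potentials; its
baseline-to-peak amplitude per intensity is fitted with the saturating
hyperbola

    P2(i) = P2max · i / (i + K)

giving saturated amplitude P2max (µV) and semi-saturation constant K
(sensitivity reported as −log₁₀ K).

**Oscillatory potentials (amacrine circuits).** Band-pass isolation
(zero-phase, composite −3 dB at 50 and 280 Hz) at the brightest flash;
peak amplitude and implicit time are reported.

**pSTR (retinal ganglion cells).** The positive scotopic threshold
response amplitude — baseline to positive-lobe peak — at the two dimmest
flashes (−5.30 and −5.0 log cd·s/m²).

**Statistics.** Paired t-tests (OHT vs. contralateral NT eye) and
balanced two-way repeated-measures ANOVA (group × time), computed from
explicit sums of squares; unsupervised hierarchical clustering of
optic-nerve marker profiles with correlation distance (1 − Pearson's r)
and average linkage.

**Simulator.** Because every stage is validated by parameter recovery,
the package ships a generator of paired-eye cohorts with known ground
truth, emulating the acquisition protocol: 12-step intensity ladder,
sweep averaging (20 below −3.5, 5 at −3.5, single sweeps above), noise
shrinking with the square root of the sweep count, log-normal
inter-animal variability shared within eye pairs, and multiplicative
per-component disease effects.

## Worked example

```sh
python examples/p3_fit_demo.py
```

prints

```
RmP3 =   400.0000 µV        (true 400: saturated a-wave amplitude)
S    =  1600.0000 cd⁻¹m²s⁻³ (true 1600: transduction amplification)
td   =     3.5000 ms        (true 3.5: transduction + recording delay)
rms  = 5.64e-14 µV over window (1.0, 17.0) ms
```

— a noise-free photoreceptor-only recording is simulated and the joint
fit returns the generating parameters with a numerically-zero residual.
`examples/decompose_cohort.py` runs the complete decomposition on a
small cohort with a built-in 30% ganglion-cell deficit,
`examples/paired_statistics.py` shows the paired t-test detecting that
deficit (t = −7.29, p ≈ 1e−5 at n = 13 pairs), and
`examples/marker_clustering.py` clusters synthetic optic-nerve marker
profiles.

A thin CLI wraps the same functions:

```sh
ergdecomp simulate --config cohort.yaml --seed 3 --out sim/
ergdecomp decompose --in sim/ --out metrics.csv
ergdecomp stats --metrics metrics.csv --out stats.csv
```

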