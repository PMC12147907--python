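# Methods

## Signal model and conventions

A scotopic flash ERG trace is treated as an additive superposition of
component waveforms plus recording noise.  Time is in milliseconds with
t = 0 at flash onset (pre-stimulus samples negative); voltage in µV with
the standard display sign (a-wave negative, b-wave positive); flash
energy is keyed in log₁₀ cd·s/m² and converted to linear units inside
the models.  The delayed-Gaussian P3 exponent multiplies linear flash
energy, S (cd⁻¹·m²·s⁻³) and (t − t_d)² with time converted to seconds,
so S keeps its conventional units while the API works in ms.

The acquisition protocol is fixed by the recording hardware this
emulates: a 12-step ladder from −5.3 to 1.48 log cd·s/m², 20 sweeps
averaged below −3.5, 5 at −3.5, single sweeps above, with a 0.125–300 Hz
hardware band-pass stored as metadata.  The sampling rate is not part of
that protocol; the package defaults to 2 kHz and accepts anything
≥ 1 kHz.  Epochs must cover at least −20 to 250 ms.

## P3 fitting

One (RmP3, S, t_d) triple is fitted jointly to the 1.0 and 1.48
log cd·s/m² traces by bounded least squares on the pooled residual
(log-parameterised in RmP3 and S for conditioning), after subtracting
each trace's pre-stimulus mean.  A deterministic multi-start grid
(t_d ∈ {2, 3, 4} ms, S on a 4-point log grid over [10², 10⁴], RmP3 from
the deepest trough) guards against local minima; the start with the best
pooled RMS wins, ties broken by the smaller S, so the fit is
bit-reproducible.

The fit window defaults to [1, 18] ms, further truncated per trace at
the a-wave trough (located on a 2.5 ms moving-average smoothed copy so
single-sweep noise cannot drag the edge).  The end point balances two
errors that pull in opposite directions: post-receptoral intrusion —
windows extending toward 30 ms let the rising b-wave and the
oscillatory potentials bias S by 1–2% even on clean data — against
statistical precision, since under single-sweep noise the sampling
error of S grows quickly as the window shrinks below ~15 ms.  At 18 ms
the bright-flash P3 is fully saturated, b-wave intrusion is still in
the 0.1 µV range, and the remaining oscillatory leakage is handled by a
refinement pass: after the first fit, the OPs are estimated from the
band-passed remnant, subtracted from the bright traces, and the model
is refitted.  Window, refinement count and an optional band-limiting
prefilter (applied identically to data and model, hence unbiased;
useful against narrow-band interference, off by default because least
squares is already efficient under white noise) are all configurable.

Degenerate inputs: traces with no corneal-negative deflection are not
trough-truncated; an all-zero trace family drives RmP3 to its lower
bound with ~0 residual rather than producing a spurious amplitude.
Baseline handling matters — a DC offset with baseline correction
disabled distorts all three parameters (the model cannot represent an
offset), which is why the pipeline always baseline-corrects first.

## Component isolation filters

Both isolation filters are 4th-order-per-pass Butterworth designs
applied forward–backward (zero phase).  The stated corners describe the
*composite* (two-pass) magnitude: a numeric root-finder calibrates the
per-pass design corner(s) until the measured composite response is
−3 dB at each stated frequency, which also absorbs bilinear-transform
warping.  Verified properties: −3.00 ± 0.05 dB at 50 Hz (low-pass) and
at 50/280 Hz (band-pass), passband deviation ≤ 0.1 dB, exactly zero
group delay, DC gain 1 (low-pass) and full DC rejection (band-pass).
Traces are reflection-padded by at least three time constants of the
slowest corner before filtering to suppress endpoint transients.

The acquisition hardware's OP channel setting (75–300 Hz) differs from
the analysis band (50–280 Hz); the analysis corners are what this
package implements, and the acquisition setting is carried as metadata
only.

## P2, OP and pSTR measurement

P2 amplitude is baseline-to-positive-peak of the low-passed remnant over
[0, 150] ms — after P3 subtraction the baseline-to-peak convention is
the natural one.  Amplitudes across all 12 intensities feed the
saturating-hyperbola fit (log-parameterised bounded least squares;
initial P2max from the largest amplitude, initial K from the
half-amplitude crossing by interpolation).  Near threshold the measured
"P2" amplitude is actually dominated by the pSTR; this mirrors real
recordings, and because the hyperbola is insensitive to K at intensities
far below K, it perturbs the fitted (P2max, K) by well under 0.1%.
Both K and −log₁₀ K are reported, covering both readings of
"sensitivity".

OP metrics (peak amplitude, implicit time) are taken from the
band-passed remnant of the brightest flash over [0, 100] ms.  The pSTR
is the positive-lobe peak minus pre-stimulus baseline over [60, 200] ms
at −5.30 and −5.0 log cd·s/m², measured on the 50 Hz low-passed remnant:
the pSTR itself has essentially no content above ~10 Hz, while
peak-picking on broadband noise would otherwise inflate the estimate by
the expected maximum of several hundred noise samples.  All windows are
configurable.

## The simulator

Component shapes not constrained by the fitted models are simulator
choices:

* **b-wave time course** — unit-peak gamma pulse
  g(t) = (t/t_p)^m · exp(m(1 − t/t_p)), peak 60 ms, FWHM 40 ms (m solved
  numerically), spectral content almost entirely below 50 Hz so low-pass
  isolation is faithful by construction;
* **OP packet** — Gaussian-windowed 120 Hz cosine centred at 45 ms
  (envelope SD = 1.5 carrier periods), amplitude ∝ √(flash energy)
  capped at 30 µV at 1 cd·s/m²;
* **pSTR** — Gaussian bump peaking at 110 ms (SD 25 ms), amplitude 15 µV
  at the two dimmest flashes, halved at −4.3, quartered at −4.0, absent
  above, reflecting its confinement to near-threshold light levels;
* **noise** — white Gaussian, 20 µV SD per sweep, divided by √n_sweeps
  on averaged traces;
* **variability** — mean-preserving log-normal per-animal factors (CV
  0.2 by default) on the magnitude parameters (RmP3, S, P2max, K, OP and
  pSTR amplitudes), shared between the two eyes of an animal before the
  OHT effect factors multiply the hypertensive eye.

Defaults (RmP3 400 µV, S 1600, t_d 3.5 ms, P2max 600 µV, K 0.05 cd·s/m²)
are typical healthy-rodent scotopic values.  Randomness comes from one
cohort seed through named substreams per (subject, eye, stimulus), so
cohorts are bit-reproducible and adding an animal does not perturb the
others.

What the simulator does **not** emulate: hardware filtering by default
(a causal 0.125–300 Hz option exists but recovery tests run without it),
1/f and mains interference, blink/movement artefacts, adaptation drift
across the session, inter-intensity correlations of biological origin,
or any dependence of time-course shape on intensity.  Passing recovery
tests therefore demonstrates correctness of the estimation machinery
under the stated signal model, not robustness to every artefact of real
recordings.

## Statistics

The paired t-test and the split-plot ANOVA are computed from explicit
formulas (p-values via SciPy's t and F distributions, accurate to
≈ 1e-15) rather than delegated, and are cross-checked in the tests
against SciPy/pingouin and hand-computed sums of squares.  The ANOVA
supports balanced complete designs only and applies no sphericity
correction.  Identical paired samples return t = 0, p = 1; zero-variance
differences around a non-zero mean raise instead of fabricating a
p-value.  No multiple-testing correction is applied; significance stars
(0.05/0.01/0.001) appear only in formatted CLI output.

Clustering uses SciPy's average-linkage on 1 − Pearson distance; flat
memberships are cut by requested cluster count k (memberships, not
heights, are the scientific readout).  A brute-force O(n³) oracle that
recomputes every inter-cluster mean at each step verifies the merge
sequences in the tests.

The dosing utility uses the full-mixing replacement convention
(c · v_inj / v_vit), the convention consistent with the published
example of 1 µL of 25 µM stock into a 5 µL vitreous yielding 5 µM; a
stock value sometimes quoted alongside the 500 µM target is not
reproducible under any mixing convention and is treated as a typo.

## Verification scale

Problem sizes in the shipped tests and acceptance script were chosen to
give stable statistics at desk scale: noiseless closure on a 2-pair
cohort (worst-case relative error ≤ 0.5% across all recovered
parameters), Monte-Carlo recovery over 200 single-pair replicates at
protocol noise, and power estimation over 500 cohorts of 13 pairs with a
30% pSTR reduction, mirroring the chronic-model design scale.  The
recovery harness records per-replicate failures rather than aborting,
and reports bias, relative RMSE and median absolute relative error per
parameter.

## Known limitations

* Per-intensity (non-joint) P3 fitting is not offered; the joint fit
  assumes both bright flashes share one parameter triple.
* Individual OP wavelets (OP1…OP4) are not indexed; only the packet peak
  and implicit time are reported.
* The cone-isolating twin-flash sequence is stored as metadata only; no
  photopic analysis.
* The trace dialect is the package's own plain-text format; proprietary
  vendor exports must be converted upstream.
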