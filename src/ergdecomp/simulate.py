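"""Synthetic paired-eye ERG cohorts with known ground truth.

Every trace is an additive composition of the components the analysis
pipeline estimates, so parameter recovery can be checked exactly::

    v(t) = P3(i, t) + A_P2(i) * g(t) + OP(i, t) + pSTR(i, t) + noise

* P3 follows the delayed-Gaussian saturating model (negative-going).
* A_P2(i) follows the saturating hyperbola P2max * i / (i + K); g(t) is a
  unit-peak gamma-shaped time course whose spectral content lies below
  the 50 Hz isolation corner by construction.
* OP is a Gaussian-windowed cosine packet (default 120 Hz, inside the
  50-280 Hz analysis band) riding the rising limb of the b-wave, with
  amplitude growing as sqrt(flash energy) and capped at ``op_amp_uv``.
* pSTR is a slow positive Gaussian bump present only near absolute
  threshold: full amplitude at the two dimmest flashes, reduced at
  -4.3/-4.0, absent above.
* noise is zero-mean Gaussian with SD ``noise_sd_uv / sqrt(n_sweeps)``,
  emulating sweep averaging.

Paired eyes share each animal's parameter draw; the ocular-hypertensive
(OHT) eye's parameters are the normotensive (NT) eye's multiplied by
per-component effect factors.  All randomness derives from a single
cohort seed through named substreams, so cohorts are bit-reproducible.

Also houses the intravitreal dosing utility used to plan injections into
a fixed vitreal volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InputError, ValidationError
from .p3 import p3_model
from .p2 import p2_hyperbola
from .protocol import ACQUISITION_BANDPASS_HZ, TWIN_FLASH, protocol_stimuli
from .types import DEFAULT_FS_HZ, Recording, Stimulus, Trace

DEFAULT_EPOCH_MS = (-20.0, 250.0)

#: flash energy (linear cd·s/m²) at which the OP packet reaches full size
OP_SATURATION_CDSM = 1.0

#: pSTR amplitude scaling near threshold: full at the two dimmest
#: flashes, reduced at -4.3 and -4.0, absent above
_PSTR_SCALE_STEPS = ((-5.0, 1.0), (-4.3, 0.5), (-4.0, 0.25))


@dataclass(frozen=True)
class ComponentParams:
    """Ground-truth parameters for every simulated waveform component.

    Defaults describe a healthy dark-adapted rodent eye: a ~400 µV
    saturated a-wave, a ~600 µV saturated b-wave half-saturating at
    0.05 cd·s/m², 120 Hz oscillatory potentials, and a ~15 µV pSTR.
    ``noise_sd_uv`` is the per-sweep additive noise SD (20 µV; the
    averaged-trace SD falls with the square root of the sweep count).
    """

    rmp3_uv: float = 400.0
    s_sens: float = 1600.0  # cd^-1 m^2 s^-3
    td_ms: float = 3.5
    p2max_uv: float = 600.0
    k_semisat: float = 0.05  # linear cd·s/m²
    p2_peak_ms: float = 60.0
    p2_width_ms: float = 40.0  # FWHM of the b-wave time course
    op_freq_hz: float = 120.0
    op_amp_uv: float = 30.0
    op_latency_ms: float = 45.0
    pstr_amp_uv: float = 15.0
    pstr_peak_ms: float = 110.0
    pstr_width_ms: float = 25.0  # Gaussian SD
    noise_sd_uv: float = 20.0

    def __post_init__(self):
        for name in ("rmp3_uv", "p2max_uv", "op_amp_uv", "pstr_amp_uv",
                     "noise_sd_uv", "td_ms"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("s_sens", "k_semisat", "p2_peak_ms", "p2_width_ms",
                     "pstr_peak_ms", "pstr_width_ms", "op_freq_hz"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (50.0 < self.op_freq_hz < 280.0):
            raise ValidationError(
                "op_freq_hz must lie inside (50, 280) Hz so the OPs survive "
                f"the analysis band-pass; got {self.op_freq_hz:g}"
            )


#: parameter fields that vary between animals (magnitudes/sensitivities;
#: timing and shape parameters are held fixed across the cohort)
VARIABLE_PARAMS = ("rmp3_uv", "s_sens", "p2max_uv", "k_semisat",
                   "op_amp_uv", "pstr_amp_uv")


@dataclass(frozen=True)
class CohortDesign:
    """Design of a paired-eye simulated cohort.

    ``effects`` maps ComponentParams field names to multiplicative
    factors applied to the OHT eye (e.g. ``{"pstr_amp_uv": 0.7}`` for a
    30% pSTR reduction).  ``inter_animal_cv`` is the coefficient of
    variation of the log-normal per-animal draws of the magnitude
    parameters; paired eyes share the draw, preserving the within-animal
    correlation the paired statistics rely on.
    """

    n_pairs: int
    base: ComponentParams = field(default_factory=ComponentParams)
    effects: dict = field(default_factory=dict)
    inter_animal_cv: float = 0.2
    seed: int = 0
    treatment_group: str = "vehicle"
    fs_hz: float = DEFAULT_FS_HZ
    epoch_ms: tuple = DEFAULT_EPOCH_MS

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")
        if not (0 <= self.inter_animal_cv < 1):
            raise ValidationError("inter_animal_cv must lie in [0, 1)")
        valid = {f.name for f in fields(ComponentParams)}
        for key, factor in self.effects.items():
            if key not in valid:
                raise ValidationError(f"unknown effect parameter {key!r}")
            if factor <= 0:
                raise ValidationError(f"effect factor for {key!r} must be > 0")


def gamma_shape_exponent(peak_ms: float, fwhm_ms: float) -> float:
    """Exponent m of the unit-peak gamma pulse with the requested FWHM.

    g(t) = (t/tp)^m * exp(m * (1 - t/tp)) peaks at tp with value 1; its
    full width at half maximum shrinks monotonically as m grows
    (approximately 2.355 * tp / sqrt(m)), so m is found by bisection.
    """
    if fwhm_ms >= 2.0 * peak_ms:
        raise ValidationError(
            f"p2 width {fwhm_ms:g} ms too large for peak at {peak_ms:g} ms"
        )

    def fwhm_of(m):
        ln2 = np.log(2.0)
        # solutions of m*(ln x + 1 - x) = -ln 2 around x = 1
        f = lambda x: m * (np.log(x) + 1.0 - x) + ln2
        x_lo = brentq(f, 1e-12, 1.0 - 1e-12)
        x_hi = brentq(f, 1.0 + 1e-12, 50.0)
        return peak_ms * (x_hi - x_lo)

    return brentq(lambda m: fwhm_of(m) - fwhm_ms, 0.05, 5e4, xtol=1e-10)


def p2_time_course(t_ms, peak_ms: float, fwhm_ms: float):
    """Unit-peak gamma-shaped b-wave time course; zero for t <= 0."""
    m = gamma_shape_exponent(peak_ms, fwhm_ms)
    t = np.asarray(t_ms, dtype=float)
    g = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / peak_ms
    g[pos] = np.exp(m * (np.log(x) + 1.0 - x))
    return g


def pstr_scale(intensity_log: float) -> float:
    """Amplitude scaling of the pSTR toward absolute threshold."""
    for threshold, scale in _PSTR_SCALE_STEPS:
        if intensity_log <= threshold + 1e-9:
            return scale
    return 0.0


def noiseless_components(params: ComponentParams, stim: Stimulus, t_ms):
    """Each component evaluated on ``t_ms`` (dict of name -> array)."""
    i_lin = stim.intensity_linear
    t = np.asarray(t_ms, dtype=float)

    p3 = (p3_model(i_lin, t, params.rmp3_uv, params.s_sens, params.td_ms)
          if params.rmp3_uv > 0 else np.zeros_like(t))

    a_p2 = p2_hyperbola(i_lin, params.p2max_uv, params.k_semisat)
    p2 = a_p2 * p2_time_course(t, params.p2_peak_ms, params.p2_width_ms)

    op_amp = params.op_amp_uv * min(1.0, np.sqrt(i_lin / OP_SATURATION_CDSM))
    sigma_ms = 1500.0 / params.op_freq_hz  # 1.5 cycles of envelope SD
    envelope = np.exp(-((t - params.op_latency_ms) ** 2) / (2.0 * sigma_ms**2))
    carrier = np.cos(2.0 * np.pi * params.op_freq_hz * (t - params.op_latency_ms) / 1000.0)
    op = np.where(t > 0, op_amp * envelope * carrier, 0.0)

    scale = pstr_scale(stim.intensity_log)
    pstr = scale * params.pstr_amp_uv * np.exp(
        -((t - params.pstr_peak_ms) ** 2) / (2.0 * params.pstr_width_ms**2)
    )

    return {"p3": p3, "p2": p2, "op": op, "pstr": pstr}


def _time_grid(epoch_ms, fs_hz):
    t_min, t_max = float(epoch_ms[0]), float(epoch_ms[1])
    if t_min > DEFAULT_EPOCH_MS[0] + 1e-9 or t_max < DEFAULT_EPOCH_MS[1] - 1e-9:
        raise ValidationError(
            f"epoch [{t_min:g}, {t_max:g}] ms must cover "
            f"[{DEFAULT_EPOCH_MS[0]:g}, {DEFAULT_EPOCH_MS[1]:g}] ms"
        )
    dt = 1000.0 / fs_hz
    n_pre = int(round(-t_min / dt))
    n_post = int(round(t_max / dt))
    return (np.arange(-n_pre, n_post + 1)) * dt


def simulate_trace(
    params: ComponentParams,
    stim: Stimulus,
    fs_hz: float = DEFAULT_FS_HZ,
    epoch_ms=DEFAULT_EPOCH_MS,
    rng: np.random.Generator | None = None,
    apply_acquisition_filter: bool = False,
) -> Trace:
    """Simulate one averaged trace for one flash condition.

    ``rng`` is required when ``params.noise_sd_uv > 0``; an identical
    generator state yields an identical trace.  When
    ``apply_acquisition_filter`` is set, a causal second-order 0.125-300
    Hz band-pass mimics the hardware front end (off by default so
    component recovery is exact by construction).
    """
    if params.op_freq_hz >= fs_hz / 2:
        raise ValidationError(
            f"op_freq_hz {params.op_freq_hz:g} at or above Nyquist ({fs_hz / 2:g})"
        )
    t = _time_grid(epoch_ms, fs_hz)
    comps = noiseless_components(params, stim, t)
    v = comps["p3"] + comps["p2"] + comps["op"] + comps["pstr"]

    if params.noise_sd_uv > 0:
        if rng is None:
            raise InputError("rng is required when noise_sd_uv > 0")
        v = v + rng.normal(0.0, params.noise_sd_uv / np.sqrt(stim.n_sweeps), t.shape)

    if apply_acquisition_filter:
        from scipy import signal
        sos = signal.butter(2, ACQUISITION_BANDPASS_HZ, btype="bandpass",
                            fs=fs_hz, output="sos")
        v = signal.sosfilt(sos, v)

    return Trace(t_ms=t, v_uv=v, fs_hz=fs_hz)


def _lognormal_factor(rng, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return float(np.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0))


def _apply_factors(params: ComponentParams, factors: dict) -> ComponentParams:
    return replace(params, **{
        k: getattr(params, k) * f for k, f in factors.items()
    })


def simulate_cohort(design: CohortDesign):
    """Simulate a paired-eye cohort.

    Returns
    -------
    (recordings, ground_truth)
        ``recordings`` is a list of 2 * n_pairs :class:`Recording`
        objects (left eye NT, right eye OHT per subject);
        ``ground_truth`` a DataFrame with one row per eye listing every
        drawn component parameter.  Fully reproducible from
        ``design.seed``.
    """
    recordings = []
    truth_rows = []
    acquisition = {
        "bandpass_hz": list(ACQUISITION_BANDPASS_HZ),
        "electrodes": {"dim": "Ag-AgCl", "bright": "Ag"},
        "twin_flash": dict(TWIN_FLASH),
    }
    stimuli = protocol_stimuli()

    for subj_idx in range(design.n_pairs):
        subject_id = f"s{subj_idx + 1:03d}"
        param_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=design.seed, spawn_key=(0, subj_idx))
        )
        animal_factors = {
            name: _lognormal_factor(param_rng, design.inter_animal_cv)
            for name in VARIABLE_PARAMS
        }
        nt_params = _apply_factors(design.base, animal_factors)
        oht_params = _apply_factors(nt_params, design.effects)

        for eye_idx, (eye, group, params) in enumerate(
            [("left", "NT", nt_params), ("right", "OHT", oht_params)]
        ):
            rec = Recording(
                subject_id=subject_id,
                eye=eye,
                pressure_group=group,
                treatment_group=design.treatment_group,
                acquisition=acquisition,
            )
            for stim_idx, stim in enumerate(stimuli):
                rng = np.random.default_rng(np.random.SeedSequence(
                    entropy=design.seed,
                    spawn_key=(1, subj_idx, eye_idx, stim_idx),
                ))
                rec.add_trace(stim, simulate_trace(
                    params, stim, fs_hz=design.fs_hz,
                    epoch_ms=design.epoch_ms, rng=rng,
                ))
            recordings.append(rec)
            row = {"subject_id": subject_id, "eye": eye,
                   "pressure_group": group,
                   "treatment_group": design.treatment_group}
            row.update({f.name: getattr(params, f.name)
                        for f in fields(ComponentParams)})
            truth_rows.append(row)

    return recordings, pd.DataFrame(truth_rows)


def vitreal_concentration(c_stock: float, v_inj_ul: float, v_vit_ul: float) -> float:
    """Final intravitreal concentration after full mixing.

    A bolus of ``v_inj_ul`` µL at concentration ``c_stock`` distributed
    through a vitreal volume of ``v_vit_ul`` µL (replacement convention:
    the injected volume displaces, rather than adds to, the vitreous)
    gives ``c_stock * v_inj / v_vit``.  Units of ``c_stock`` are
    preserved.
    """
    if v_vit_ul <= 0:
        raise InputError(f"vitreal volume must be > 0 µL, got {v_vit_ul}")
    if v_inj_ul < 0:
        raise InputError(f"injection volume must be >= 0 µL, got {v_inj_ul}")
    if c_stock < 0:
        raise InputError(f"stock concentration must be >= 0, got {c_stock}")
    return c_stock * v_inj_ul / v_vit_ul
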