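"""Post-receptoral components: P2 (bipolar cell), oscillatory potentials,
and the positive scotopic threshold response (pSTR).

After the modelled P3 family is subtracted from the raw traces, the
remnant is split by frequency content: a zero-phase low-pass (composite
-3 dB at 50 Hz) isolates the slow bipolar-cell P2 wave, and a zero-phase
band-pass (composite -3 dB at 50 and 280 Hz) isolates the oscillatory
potentials.  P2 amplitude as a function of flash energy follows a
saturating hyperbola::

    P2(i) = P2max * i / (i + K)

with saturated amplitude ``P2max`` (µV) and semi-saturation constant
``K`` (linear cd·s/m²); sensitivity is reported both as K and as
-log10(K).  The pSTR, a slow positive wave near absolute threshold
dominated by retinal ganglion cells, is quantified as the
baseline-to-peak amplitude of its positive lobe at the two dimmest
flashes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import ConvergenceError, InputError, ValidationError
from .filters import ZeroPhaseFilter, op_bandpass, p2_lowpass
from .types import Trace

DEFAULT_P2_WINDOW_MS = (0.0, 150.0)
DEFAULT_OP_WINDOW_MS = (0.0, 100.0)
DEFAULT_PSTR_WINDOW_MS = (60.0, 200.0)
#: flash energies (log cd·s/m²) at which the pSTR is reported
PSTR_INTENSITIES_LOG = (-5.30, -5.0)
#: flash energy at which OP metrics are reported
OP_INTENSITY_LOG = 1.48


@dataclass(frozen=True)
class P2Fit:
    """Saturating-hyperbola intensity-response fit of P2 amplitude."""

    p2max_uv: float
    k_semisat: float  #: linear cd·s/m²
    rms_uv: float
    n_points: int

    def __post_init__(self):
        if self.p2max_uv <= 0:
            raise ValidationError("p2max_uv must be > 0")
        if self.k_semisat <= 0:
            raise ValidationError("k_semisat must be > 0")
        if self.rms_uv < 0:
            raise ValidationError("rms_uv must be >= 0")

    @property
    def log_sensitivity(self) -> float:
        """-log10(K): higher means the retina half-saturates at dimmer flashes."""
        return -math.log10(self.k_semisat)


@dataclass(frozen=True)
class OPMetrics:
    """Peak amplitude and implicit time of the oscillatory potentials."""

    peak_amplitude_uv: float
    implicit_time_ms: float

    def __post_init__(self):
        if self.implicit_time_ms <= 0:
            raise ValidationError("implicit_time_ms must be > 0")
        if self.peak_amplitude_uv < 0:
            raise ValidationError("peak_amplitude_uv must be >= 0")


def p2_hyperbola(intensity_linear, p2max_uv, k_semisat):
    """P2max * i / (i + K); handles scalars and arrays, zero at i = 0."""
    i = np.asarray(intensity_linear, dtype=float)
    out = p2max_uv * i / (i + k_semisat)
    return float(out) if np.isscalar(intensity_linear) else out


def _check_window(trace: Trace, window_ms):
    start, end = float(window_ms[0]), float(window_ms[1])
    if start >= end:
        raise InputError(f"empty window [{start:g}, {end:g}] ms")
    if start < trace.t_ms[0] - 1e-9 or end > trace.t_ms[-1] + 1e-9:
        raise InputError(
            f"window [{start:g}, {end:g}] ms outside trace span "
            f"[{trace.t_ms[0]:g}, {trace.t_ms[-1]:g}] ms"
        )
    return start, end


def extract_p2(
    remnant: Trace,
    window_ms=DEFAULT_P2_WINDOW_MS,
    lowpass: ZeroPhaseFilter | None = None,
):
    """Low-pass the P3-subtracted remnant and measure the P2 amplitude.

    The filter removes the oscillatory potentials; the amplitude is the
    maximum of the filtered trace over ``window_ms`` minus the filtered
    trace's pre-stimulus baseline (baseline-to-positive-peak).

    Returns
    -------
    (filtered Trace, p2_amplitude_uv)
    """
    start, end = _check_window(remnant, window_ms)
    if lowpass is None:
        lowpass = p2_lowpass(remnant.fs_hz)
    filtered = lowpass.apply(remnant)
    baseline = filtered.baseline()
    mask = filtered.window_mask(start, end)
    amplitude = float(filtered.v_uv[mask].max() - baseline)
    return filtered, amplitude


def extract_ops(
    remnant: Trace,
    window_ms=DEFAULT_OP_WINDOW_MS,
    bandpass: ZeroPhaseFilter | None = None,
):
    """Band-pass the remnant and return the OP trace and its metrics.

    Peak amplitude is the maximum of the band-passed trace over the OP
    window; implicit time is the latency of that peak from flash onset.
    The band-pass removes DC, so the metrics are offset-invariant.
    """
    start, end = _check_window(remnant, window_ms)
    if bandpass is None:
        bandpass = op_bandpass(remnant.fs_hz)
    op_trace = bandpass.apply(remnant)
    mask = op_trace.window_mask(start, end)
    v = op_trace.v_uv[mask]
    t = op_trace.t_ms[mask]
    idx = int(np.argmax(v))
    return op_trace, OPMetrics(
        peak_amplitude_uv=max(float(v[idx]), 0.0),
        implicit_time_ms=float(t[idx]),
    )


def pstr_amplitude(
    trace: Trace,
    window_ms=DEFAULT_PSTR_WINDOW_MS,
    intensity_log: float | None = None,
) -> float:
    """Baseline-to-peak amplitude (µV) of the pSTR positive lobe.

    The amplitude is the maximum over ``window_ms`` minus the
    pre-stimulus baseline, making it invariant to DC offsets.  If
    ``intensity_log`` is supplied and is not one of the threshold-level
    flashes the pSTR is defined at, a warning is emitted but the value is
    still computed.
    """
    start, end = _check_window(trace, window_ms)
    if intensity_log is not None and not any(
        abs(intensity_log - ref) <= 1e-6 for ref in PSTR_INTENSITIES_LOG
    ):
        warnings.warn(
            f"pSTR requested at {intensity_log:g} log cd·s/m²; it is defined "
            f"at {PSTR_INTENSITIES_LOG} — computing anyway",
            stacklevel=2,
        )
    baseline = trace.baseline()
    mask = trace.window_mask(start, end)
    return float(trace.v_uv[mask].max() - baseline)


def fit_p2_intensity(amplitudes: dict, init=None) -> P2Fit:
    """Fit the saturating hyperbola to P2 amplitude vs. flash energy.

    Parameters
    ----------
    amplitudes
        Mapping of flash energy in log10 cd·s/m² to P2 amplitude in µV,
        covering at least 4 intensities spanning >= 2 log units.
    init
        Optional (p2max, k) starting point overriding the default
        initialisation (P2max from the largest amplitude, K from the
        half-amplitude intensity by interpolation).

    Returns
    -------
    P2Fit with least-RMS (P2max, K) under positivity bounds.
    """
    logs = np.array(sorted(amplitudes), dtype=float)
    amps = np.array([amplitudes[lg] for lg in logs], dtype=float)
    if len(logs) < 4:
        raise InputError(f"need >= 4 intensities, got {len(logs)}")
    if logs[-1] - logs[0] < 2.0:
        raise InputError(
            f"intensities span {logs[-1] - logs[0]:.2f} log units; >= 2 required"
        )
    if np.all(amps <= 0):
        raise InputError("all P2 amplitudes are <= 0; nothing to fit")

    i_lin = 10.0 ** logs
    if init is None:
        a_max = float(amps.max())
        half = a_max / 2.0
        # first crossing of half-amplitude, linear interpolation in log i
        k0 = float(i_lin[np.argmax(amps >= half)])
        above = np.nonzero(amps >= half)[0]
        j = above[0]
        if j > 0 and amps[j] != amps[j - 1]:
            frac = (half - amps[j - 1]) / (amps[j] - amps[j - 1])
            k0 = 10.0 ** (logs[j - 1] + frac * (logs[j] - logs[j - 1]))
        init = (a_max, k0)

    def residuals(x):
        return p2_hyperbola(i_lin, 10.0 ** x[0], 10.0 ** x[1]) - amps

    lb = [-6.0, math.log10(i_lin[0]) - 3.0]
    ub = [6.0, math.log10(i_lin[-1]) + 3.0]
    x0 = [
        np.clip(math.log10(max(init[0], 1e-6)), lb[0], ub[0]),
        np.clip(math.log10(max(init[1], 1e-30)), lb[1], ub[1]),
    ]
    result = least_squares(
        residuals, x0, bounds=(lb, ub),
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
    )
    if not result.success:
        raise ConvergenceError("P2 intensity-response fit failed", result)
    rms = math.sqrt(float(np.mean(residuals(result.x) ** 2)))
    return P2Fit(
        p2max_uv=10.0 ** result.x[0],
        k_semisat=10.0 ** result.x[1],
        rms_uv=rms,
        n_points=len(logs),
    )
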