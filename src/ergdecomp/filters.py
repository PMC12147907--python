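"""Zero-phase Butterworth filtering with corners on the composite response.

Component isolation uses forward-backward (zero-phase) filtering.  The
corner frequencies are specified on the *composite* magnitude response —
the squared single-pass response — because the attenuation figures that
matter scientifically ("-3 dB at 50 Hz") describe what the data actually
experienced, not one pass of the topology.

A single-pass Butterworth designed at the stated corner would leave the
composite at -6 dB there, so the per-pass corner is calibrated
numerically: a root-finder adjusts the design corner(s) until the
measured composite magnitude is exactly -3 dB at each stated frequency.
This also absorbs the bilinear-transform frequency warping of the digital
design.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.optimize import brentq, root

from .errors import FilterDesignError
from .types import FilterSpec, Trace


class ZeroPhaseFilter:
    """An applicable zero-phase filter realising a :class:`FilterSpec`."""

    def __init__(self, spec: FilterSpec, sos: np.ndarray):
        self.spec = spec
        self.sos = sos

    def response_db(self, freqs_hz) -> np.ndarray:
        """Composite (two-pass) magnitude response in dB at ``freqs_hz``."""
        freqs = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
        _, h = signal.sosfreqz(self.sos, worN=freqs, fs=self.spec.fs_hz)
        return 40.0 * np.log10(np.abs(h) + 1e-300)

    def _padlen(self, n: int) -> int:
        # >= 3 filter time constants of the slowest corner, capped by length
        tau_samples = self.spec.fs_hz / (2.0 * np.pi * min(self.spec.corners_hz))
        default = 3 * (2 * len(self.sos) + 1)
        return int(min(n - 1, max(default, np.ceil(3.0 * tau_samples))))

    def apply(self, x):
        """Filter an array or :class:`Trace` forward-backward (zero phase)."""
        if isinstance(x, Trace):
            return x.with_voltage(self.apply(x.v_uv))
        x = np.asarray(x, dtype=float)
        return signal.sosfiltfilt(self.sos, x, padlen=self._padlen(len(x)))

    __call__ = apply


def _design_sos(kind: str, corners, order: int, fs: float) -> np.ndarray:
    return signal.butter(order, corners, btype=kind, fs=fs, output="sos")


def _composite_db_at(sos, f, fs) -> float:
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(float(f)), fs=fs)
    return float(40.0 * np.log10(np.abs(h[0]) + 1e-300))


def design_filter(spec: FilterSpec) -> ZeroPhaseFilter:
    """Design the zero-phase filter whose composite response is -3 dB at
    each corner in ``spec.corners_hz``.

    Raises
    ------
    FilterDesignError
        If the calibration cannot place the corners (e.g. too close to
        Nyquist for the requested order).
    """
    fs = spec.fs_hz
    nyq = fs / 2.0
    if spec.kind == "lowpass":
        target = spec.corners_hz[0]

        def err(wc):
            sos = _design_sos("lowpass", wc, spec.order, fs)
            return _composite_db_at(sos, target, fs) + 3.0

        hi = min(4.0 * target, 0.999 * nyq)
        try:
            wc = brentq(err, target, hi, xtol=1e-10)
        except ValueError as exc:
            raise FilterDesignError(
                f"cannot calibrate lowpass corner at {target:g} Hz "
                f"(fs {fs:g} Hz, order {spec.order})"
            ) from exc
        sos = _design_sos("lowpass", wc, spec.order, fs)
    else:
        lo, hi_c = spec.corners_hz

        def err2(w):
            w_lo, w_hi = w
            if not (0 < w_lo < w_hi < nyq):
                return [1e6, 1e6]
            sos = _design_sos("bandpass", [w_lo, w_hi], spec.order, fs)
            return [
                _composite_db_at(sos, lo, fs) + 3.0,
                _composite_db_at(sos, hi_c, fs) + 3.0,
            ]

        sol = root(err2, x0=[0.95 * lo, min(1.05 * hi_c, 0.99 * nyq)],
                   method="hybr", tol=1e-12)
        if not sol.success or max(abs(np.asarray(err2(sol.x)))) > 1e-6:
            raise FilterDesignError(
                f"cannot calibrate bandpass corners at {lo:g}/{hi_c:g} Hz "
                f"(fs {fs:g} Hz, order {spec.order})"
            )
        sos = _design_sos("bandpass", list(sol.x), spec.order, fs)

    return ZeroPhaseFilter(spec, sos)


def p2_lowpass(fs_hz: float, corner_hz: float = 50.0, order: int = 4) -> ZeroPhaseFilter:
    """The P2-isolation low-pass: composite -3 dB at 50 Hz."""
    return design_filter(FilterSpec("lowpass", (corner_hz,), fs_hz, order))


def op_bandpass(fs_hz: float, corners_hz=(50.0, 280.0), order: int = 4) -> ZeroPhaseFilter:
    """The oscillatory-potential band-pass: composite -3 dB at 50 and 280 Hz."""
    return design_filter(FilterSpec("bandpass", tuple(corners_hz), fs_hz, order))
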