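"""Domain types shared by every stage of the ERG decomposition pipeline.

Conventions
-----------
* Time is in milliseconds with t = 0 at flash onset; pre-stimulus samples
  carry negative t.
* Voltage is in microvolts with the standard ERG display sign: the
  corneal-negative a-wave is negative, the b-wave positive.
* Flash energy ("intensity") is stored in log10 cd·s/m²; the linear value
  in cd·s/m² is derived.  Intensities are compared with a 1e-6 tolerance
  to avoid float-key mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .errors import ValidationError

#: tolerance (log units) when matching stimulus intensities used as keys
INTENSITY_TOL = 1e-6

#: smallest accepted sampling rate (Hz); the default acquisition rate
MIN_FS_HZ = 1000.0
DEFAULT_FS_HZ = 2000.0

#: minimum epoch every trace must cover, ms relative to flash onset
EPOCH_MIN_MS = -20.0
EPOCH_MAX_MS = 250.0


@dataclass(frozen=True)
class Stimulus:
    """One flash condition: energy, averaging count and inter-stimulus interval.

    Parameters
    ----------
    intensity_log
        Flash energy in log10 cd·s/m².
    n_sweeps
        Number of presentations averaged into the stored trace.
    isi_s
        Inter-stimulus interval in seconds (acquisition metadata).
    """

    intensity_log: float
    n_sweeps: int = 1
    isi_s: float = 2.0

    def __post_init__(self):
        if not np.isfinite(self.intensity_log):
            raise ValidationError("intensity_log must be finite")
        if self.n_sweeps < 1:
            raise ValidationError(f"n_sweeps must be >= 1, got {self.n_sweeps}")
        if self.isi_s <= 0:
            raise ValidationError(f"isi_s must be > 0, got {self.isi_s}")

    @property
    def intensity_linear(self) -> float:
        """Flash energy in linear cd·s/m² (10**intensity_log)."""
        return float(10.0 ** self.intensity_log)

    def matches(self, intensity_log: float, tol: float = INTENSITY_TOL) -> bool:
        return abs(self.intensity_log - intensity_log) <= tol


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled voltage series anchored at flash onset.

    ``t_ms`` must be a strictly increasing uniform grid whose spacing is
    1000/fs_hz, spanning at least [-20, 250] ms.
    """

    t_ms: np.ndarray
    v_uv: np.ndarray
    fs_hz: float

    def __post_init__(self):
        t = np.asarray(self.t_ms, dtype=float)
        v = np.asarray(self.v_uv, dtype=float)
        object.__setattr__(self, "t_ms", t)
        object.__setattr__(self, "v_uv", v)
        if t.ndim != 1 or v.ndim != 1:
            raise ValidationError("t_ms and v_uv must be 1-D arrays")
        if len(t) != len(v):
            raise ValidationError(
                f"t_ms ({len(t)}) and v_uv ({len(v)}) differ in length"
            )
        if len(t) < 2:
            raise ValidationError("trace needs at least two samples")
        if self.fs_hz < MIN_FS_HZ:
            raise ValidationError(
                f"sampling rate {self.fs_hz} Hz below minimum {MIN_FS_HZ} Hz"
            )
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError("t_ms must be strictly increasing")
        expected = 1000.0 / self.fs_hz
        if np.any(np.abs(dt - expected) > 1e-9):
            raise ValidationError(
                "non-uniform time grid: spacing deviates from 1000/fs_hz"
            )
        if t[0] > EPOCH_MIN_MS + 1e-9 or t[-1] < EPOCH_MAX_MS - 1e-9:
            raise ValidationError(
                f"epoch [{t[0]:g}, {t[-1]:g}] ms does not cover "
                f"[{EPOCH_MIN_MS:g}, {EPOCH_MAX_MS:g}] ms"
            )

    def __len__(self) -> int:
        return len(self.t_ms)

    def window_mask(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Boolean mask of samples with start_ms <= t <= end_ms."""
        return (self.t_ms >= start_ms) & (self.t_ms <= end_ms)

    def baseline(self, start_ms: float = EPOCH_MIN_MS, end_ms: float = 0.0) -> float:
        """Mean voltage over the pre-stimulus window [start_ms, end_ms)."""
        mask = (self.t_ms >= start_ms) & (self.t_ms < end_ms)
        if not mask.any():
            raise ValidationError("no pre-stimulus samples for baseline")
        return float(self.v_uv[mask].mean())

    def with_voltage(self, v_uv: np.ndarray) -> "Trace":
        return Trace(t_ms=self.t_ms, v_uv=np.asarray(v_uv, dtype=float),
                     fs_hz=self.fs_hz)


@dataclass(frozen=True)
class FilterSpec:
    """Specification of a zero-phase filter by its composite -3 dB corners.

    ``corners_hz`` are the frequencies at which the magnitude of the
    *composite* (forward-backward) response is -3 dB; ``order`` is the
    per-pass Butterworth order.
    """

    kind: str  # "lowpass" | "bandpass"
    corners_hz: tuple
    fs_hz: float
    order: int = 4

    def __post_init__(self):
        corners = tuple(float(c) for c in np.atleast_1d(self.corners_hz))
        object.__setattr__(self, "corners_hz", corners)
        if self.kind not in ("lowpass", "bandpass"):
            raise ValidationError(f"unknown filter kind {self.kind!r}")
        n_expected = 1 if self.kind == "lowpass" else 2
        if len(corners) != n_expected:
            raise ValidationError(
                f"{self.kind} needs {n_expected} corner(s), got {len(corners)}"
            )
        if any(c <= 0 for c in corners):
            raise ValidationError("corner frequencies must be positive")
        if any(c >= self.fs_hz / 2 for c in corners):
            raise ValidationError(
                f"corner at or above Nyquist ({self.fs_hz / 2:g} Hz)"
            )
        if self.kind == "bandpass" and corners[0] >= corners[1]:
            raise ValidationError("bandpass lower corner must be below upper")
        if self.order < 1:
            raise ValidationError("order must be >= 1")


@dataclass
class Recording:
    """One eye's per-intensity trace family plus subject and acquisition metadata.

    ``traces`` maps :class:`Stimulus` to :class:`Trace`; at most one trace
    per intensity, all traces on the same sampling grid.
    """

    subject_id: str
    eye: str  # "left" | "right"
    pressure_group: str  # "NT" | "OHT"
    treatment_group: str = "vehicle"  # "vehicle" | "supplement"
    traces: dict = field(default_factory=dict)
    acquisition: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.eye not in ("left", "right"):
            raise ValidationError(f"eye must be 'left' or 'right', got {self.eye!r}")
        if self.pressure_group not in ("NT", "OHT"):
            raise ValidationError(
                f"pressure_group must be 'NT' or 'OHT', got {self.pressure_group!r}"
            )
        if self.treatment_group not in ("vehicle", "supplement"):
            raise ValidationError(
                "treatment_group must be 'vehicle' or 'supplement', "
                f"got {self.treatment_group!r}"
            )
        self._validate_traces()

    def _validate_traces(self):
        logs = [s.intensity_log for s in self.traces]
        for i, a in enumerate(logs):
            for b in logs[i + 1:]:
                if abs(a - b) <= INTENSITY_TOL:
                    raise ValidationError(
                        f"duplicate trace at intensity {a:g} log cd·s/m²"
                    )
        rates = {tr.fs_hz for tr in self.traces.values()}
        if len(rates) > 1:
            raise ValidationError(f"traces carry mixed sampling rates: {rates}")

    @property
    def fs_hz(self) -> float:
        if not self.traces:
            raise ValidationError("recording has no traces")
        return next(iter(self.traces.values())).fs_hz

    @property
    def intensities_log(self) -> list:
        return sorted(s.intensity_log for s in self.traces)

    def stimulus_at(self, intensity_log: float) -> Stimulus:
        for s in self.traces:
            if s.matches(intensity_log):
                return s
        raise KeyError(f"no trace at {intensity_log:g} log cd·s/m²")

    def trace_at(self, intensity_log: float) -> Trace:
        return self.traces[self.stimulus_at(intensity_log)]

    def has_intensity(self, intensity_log: float) -> bool:
        return any(s.matches(intensity_log) for s in self.traces)

    def add_trace(self, stim: Stimulus, trace: Trace):
        if self.has_intensity(stim.intensity_log):
            raise ValidationError(
                f"duplicate trace at intensity {stim.intensity_log:g} log cd·s/m²"
            )
        if self.traces and abs(trace.fs_hz - self.fs_hz) > 1e-9:
            raise ValidationError("trace sampling rate differs from recording's")
        self.traces[stim] = trace

    def items(self) -> Iterator:
        """(Stimulus, Trace) pairs ordered by increasing intensity."""
        return iter(sorted(self.traces.items(), key=lambda kv: kv[0].intensity_log))

    def map_traces(self, fn) -> "Recording":
        """New Recording with fn(stimulus, trace) -> Trace applied to every trace."""
        new = {s: fn(s, tr) for s, tr in self.traces.items()}
        return replace(self, traces=new)
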