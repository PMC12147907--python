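"""The scotopic flash protocol: intensity ladder, averaging and timing.

Dim flashes are recorded with one electrode set and heavy sweep
averaging; bright flashes with another set and single presentations at
progressively longer inter-stimulus intervals so the rods recover.
"""

from __future__ import annotations

from .types import Stimulus

#: dim-series flash energies, log10 cd·s/m²
DIM_INTENSITIES_LOG = (-5.3, -5.0, -4.3, -4.0, -3.5, -2.5, -2.0)
#: bright-series flash energies, log10 cd·s/m²
BRIGHT_INTENSITIES_LOG = (-1.5, -1.0, 0.0, 1.0, 1.48)
#: full ladder in ascending order
PROTOCOL_INTENSITIES_LOG = DIM_INTENSITIES_LOG + BRIGHT_INTENSITIES_LOG

#: hardware acquisition band-pass corners, Hz (metadata; 75-300 Hz was the
#: acquisition setting for the OP channel)
ACQUISITION_BANDPASS_HZ = (0.125, 300.0)

#: cone-isolating twin-flash sequence at the brightest energy (metadata
#: only; photopic analysis is out of scope)
TWIN_FLASH = {"intensity_log": 1.48, "n_flashes": 16, "interval_ms": 500.0}

# inter-stimulus intervals (s): 2 s for the dimmest set, 5 s at -3.5,
# then progressively longer up to 90 s at the brightest flash
_ISI_S = {
    -5.3: 2.0, -5.0: 2.0, -4.3: 2.0, -4.0: 2.0,
    -3.5: 5.0, -2.5: 10.0, -2.0: 15.0,
    -1.5: 20.0, -1.0: 30.0, 0.0: 45.0, 1.0: 60.0, 1.48: 90.0,
}


def n_sweeps_for(intensity_log: float) -> int:
    """Averaging count: 20 below -3.5, 5 at -3.5, single sweep above."""
    if intensity_log < -3.5 - 1e-9:
        return 20
    if abs(intensity_log - (-3.5)) <= 1e-9:
        return 5
    return 1


def isi_for(intensity_log: float) -> float:
    best = min(_ISI_S, key=lambda k: abs(k - intensity_log))
    return _ISI_S[best]


def protocol_stimuli() -> list:
    """The full scotopic ladder as :class:`Stimulus` objects, ascending."""
    return [
        Stimulus(intensity_log=lg, n_sweeps=n_sweeps_for(lg), isi_s=isi_for(lg))
        for lg in PROTOCOL_INTENSITIES_LOG
    ]
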