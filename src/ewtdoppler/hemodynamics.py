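"""Clinical Doppler indices from a sonogram velocity envelope.

From the maximum-velocity envelope of a pulsatile Doppler spectrum the
standard uterine-artery indices are computed per cardiac cycle:

    RI  = (S - D) / S          resistance index
    PI  = (S - D) / TAMV       pulsatility index
    S/D = S / D                systolic/diastolic ratio

where S is the peak systolic velocity, D the end-diastolic velocity and
TAMV the time-averaged envelope over the cycle.  At least three complete,
consistent cycles are required before indices are reported, mirroring
clinical acquisition practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .errors import DegenerateSignalError, DomainError, InsufficientCyclesError
from .phantom import FlowPhantom, velocity_from_shift
from .velocity import TimeFrequencyMap

__all__ = [
    "SpectralEnvelope",
    "DopplerIndices",
    "extract_envelope",
    "detect_cycles",
    "compute_indices",
]


@dataclass(frozen=True)
class SpectralEnvelope:
    """Per-frame peak-velocity trace, optionally with cycle boundaries."""

    times: np.ndarray
    peak_velocity: np.ndarray
    cycle_boundaries: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int)
    )

    def __post_init__(self) -> None:
        if len(self.times) != len(self.peak_velocity):
            raise DomainError("times and peak_velocity must share one length")
        if np.any(self.peak_velocity < 0):
            raise DomainError("envelope velocities must be non-negative")

    @property
    def n_cycles(self) -> int:
        """Complete (peak-to-peak) cycles delimited by the boundaries."""
        return max(0, len(self.cycle_boundaries) - 1)


def extract_envelope(
    tfmap: TimeFrequencyMap,
    phantom: FlowPhantom,
    percentile: float = 95.0,
) -> SpectralEnvelope:
    """Sonogram maximum-velocity trace via a spectral power percentile.

    Per frame, the frequency below which ``percentile`` percent of the
    frame power lies is found by linear interpolation of the cumulative
    power (sub-bin resolution) and converted to velocity.  The percentile
    (default 95) rather than the argmax makes the trace robust to the
    noise floor above the signal band.
    """
    if not 0.0 < percentile <= 100.0:
        raise DomainError("percentile must lie in (0, 100]")
    power = tfmap.power
    totals = power.sum(axis=1)
    if np.any(totals <= 0):
        raise DegenerateSignalError("empty spectrogram frame")
    freqs = tfmap.frequencies
    target = percentile / 100.0
    env_f = np.empty(power.shape[0])
    for i, frame in enumerate(power):
        cum = np.cumsum(frame) / totals[i]
        env_f[i] = np.interp(target, cum, freqs)
    velocities = np.asarray(velocity_from_shift(phantom, env_f), dtype=float)
    return SpectralEnvelope(tfmap.times, np.maximum(velocities, 0.0))


def detect_cycles(
    envelope: SpectralEnvelope,
    min_cycles: int = 3,
    min_prominence_fraction: float = 0.2,
) -> SpectralEnvelope:
    """Locate systolic peaks and mark cycle boundaries at them.

    Peaks need a prominence of at least ``min_prominence_fraction`` of the
    envelope range.  ``min_cycles`` complete peak-to-peak cycles are
    required (clinical rule: several consecutive stable cycles), otherwise
    an :class:`InsufficientCyclesError` is raised.
    """
    v = envelope.peak_velocity
    vrange = float(np.ptp(v))
    if vrange <= 0:
        raise InsufficientCyclesError("flat envelope: no cardiac cycles")
    peaks, _ = scipy.signal.find_peaks(
        v, prominence=min_prominence_fraction * vrange
    )
    if len(peaks) - 1 < min_cycles:
        raise InsufficientCyclesError(
            f"found {max(0, len(peaks) - 1)} complete cycles, "
            f"need at least {min_cycles}"
        )
    return SpectralEnvelope(envelope.times, v, np.asarray(peaks, dtype=int))


@dataclass(frozen=True)
class DopplerIndices:
    """Cycle-averaged clinical indices plus the per-cycle table."""

    RI: float
    PI: float
    SD_ratio: float
    S: float
    D: float
    TAMV: float
    n_cycles: int
    per_cycle: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "RI": self.RI,
            "PI": self.PI,
            "SD_ratio": self.SD_ratio,
            "S": self.S,
            "D": self.D,
            "TAMV": self.TAMV,
            "n_cycles": self.n_cycles,
        }


def _end_diastolic(v: np.ndarray, start: int, stop: int, mode: str) -> float:
    """End-diastolic velocity of the cycle v[start:stop] ending at peak stop."""
    if mode == "pre_peak_min":
        # walk back from the next systolic peak through its upstroke to the
        # last local minimum: the clinical end-diastolic point
        j = stop
        while j > start + 1 and v[j - 1] <= v[j]:
            j -= 1
        return float(v[j])
    if mode == "cycle_min":
        return float(np.min(v[start : stop + 1]))
    raise DomainError(f"unknown end-diastole mode {mode!r}")


def compute_indices(
    envelope: SpectralEnvelope,
    end_diastole: str = "pre_peak_min",
) -> DopplerIndices:
    """RI, PI and S/D averaged over the detected cycles.

    Per cycle (between consecutive systolic peaks): S is the envelope
    maximum, D the end-diastolic value immediately before the next peak
    (``end_diastole="cycle_min"`` switches to the global cycle minimum) and
    TAMV the time-averaged envelope.  The identities ``RI = 1 - D/S`` and
    ``S/D = 1/(1 - RI)`` hold exactly for every cycle.
    """
    if envelope.n_cycles < 1:
        raise InsufficientCyclesError(
            "no cycle boundaries: run detect_cycles first"
        )
    v = envelope.peak_velocity
    rows = []
    b = envelope.cycle_boundaries
    for start, stop in zip(b[:-1], b[1:]):
        s = float(np.max(v[start : stop + 1]))
        if s <= 0:
            raise DegenerateSignalError("zero systolic velocity: indices undefined")
        d = _end_diastolic(v, int(start), int(stop), end_diastole)
        tamv = float(np.mean(v[start:stop]))
        rows.append(
            {
                "S": s,
                "D": d,
                "TAMV": tamv,
                "RI": (s - d) / s,
                "PI": (s - d) / tamv,
                "SD_ratio": s / d if d > 0 else np.inf,
            }
        )
    per_cycle = pd.DataFrame(rows)
    return DopplerIndices(
        RI=float(per_cycle["RI"].mean()),
        PI=float(per_cycle["PI"].mean()),
        SD_ratio=float(per_cycle["SD_ratio"].mean()),
        S=float(per_cycle["S"].mean()),
        D=float(per_cycle["D"].mean()),
        TAMV=float(per_cycle["TAMV"].mean()),
        n_cycles=len(per_cycle),
        per_cycle=per_cycle,
    )
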