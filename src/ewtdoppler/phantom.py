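"""Scattering-particle phantom for multigate Doppler blood-flow signals.

A straight vessel of radius ``L`` carries steady laminar (Poiseuille) flow,
so the velocity at radial distance ``l`` from the lumen centre is

    v(l) = v0 * (1 - (l / L)**2),

with ``v0`` the centreline velocity and ``v(L) = 0`` at the wall (no slip).
The insonated sample volume is populated with point scatterers, ten per
cubic wavelength.  Each scatterer at radius ``l_j`` moves with ``v(l_j)``
and returns a demodulated echo at its Doppler shift

    f_d = 2 * f0 * v * cos(theta) / c,

so the received signal for one range gate is a sum of unit (or Rayleigh)
amplitude cosines with phases drawn uniformly on [0, 2*pi), plus white
Gaussian noise at a configurable SNR.  An optional multiplicative cardiac
envelope turns the steady signal into a pulsatile one for exercising the
spectral-envelope / index pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "FlowPhantom",
    "ScattererSet",
    "DopplerSignal",
    "PulsatileWaveform",
    "radial_velocity",
    "scatterer_count",
    "doppler_shift",
    "velocity_from_shift",
    "womersley_number",
    "draw_scatterers",
    "synthesize_gate_signal",
    "synthesize_profile_dataset",
]

#: maximum physically plausible blood velocity (m/s) accepted by doppler_shift
V_CAP = 10.0


@dataclass(frozen=True)
class FlowPhantom:
    """Geometry, acoustics and flow parameters of the simulated vessel/beam.

    Defaults describe a uterine-artery-like setup: 3.5 MHz carrier, 1540 m/s
    tissue sound speed, 45 degree beam angle, 1 mm lumen radius, 1 m/s
    centreline velocity, a 2 mm^3 pulsed-Doppler sample volume and a 20 kHz
    demodulated sampling rate.
    """

    lumen_radius: float = 1.0e-3          # L, m
    center_velocity: float = 1.0          # v0, m/s
    sample_volume_dims: tuple[float, float, float] = (1.26e-3, 1.26e-3, 1.26e-3)
    sound_speed: float = 1540.0           # c, m/s
    carrier_frequency: float = 3.5e6      # f0, Hz
    beam_angle: float = 45.0              # theta, degrees
    dynamic_viscosity: float = 3.5e-3     # u, Pa s
    pulsation_angular_frequency: float = 2.0 * math.pi * 1.2  # omega, rad/s
    snr_db: float | None = 10.0           # None -> noiseless
    sampling_rate: float = 20e3           # fs, Hz
    duration: float = 0.1                 # s per gate
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lumen_radius", "center_velocity", "sound_speed",
                     "carrier_frequency", "sampling_rate", "duration",
                     "dynamic_viscosity"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if any(d <= 0 for d in self.sample_volume_dims):
            raise DomainError("sample_volume_dims must be positive")
        if not 0.0 <= self.beam_angle < 60.0:
            raise DomainError(
                "beam_angle must lie in [0, 60) degrees; larger acoustic "
                "angles make the Doppler angle correction unreliable"
            )
        f_max = abs(doppler_shift(self, self.center_velocity))
        if self.sampling_rate <= 2.0 * f_max:
            raise ConfigurationError(
                f"sampling_rate {self.sampling_rate:g} Hz violates Nyquist for "
                f"the peak Doppler shift {f_max:g} Hz (need fs > {2 * f_max:g})"
            )

    @property
    def wavelength(self) -> float:
        """Carrier wavelength lambda = c / f0, in metres."""
        return self.sound_speed / self.carrier_frequency

    @property
    def beam_angle_rad(self) -> float:
        return math.radians(self.beam_angle)

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.sampling_rate)

    def describe(self) -> dict:
        """Flat dict of all parameters (for manifests and configs)."""
        return {
            "lumen_radius": self.lumen_radius,
            "center_velocity": self.center_velocity,
            "sample_volume_dims": list(self.sample_volume_dims),
            "sound_speed": self.sound_speed,
            "carrier_frequency": self.carrier_frequency,
            "beam_angle": self.beam_angle,
            "dynamic_viscosity": self.dynamic_viscosity,
            "pulsation_angular_frequency": self.pulsation_angular_frequency,
            "snr_db": self.snr_db,
            "sampling_rate": self.sampling_rate,
            "duration": self.duration,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FlowPhantom":
        d = dict(d)
        if "sample_volume_dims" in d:
            d["sample_volume_dims"] = tuple(d["sample_volume_dims"])
        return cls(**d)

    def with_(self, **kw) -> "FlowPhantom":
        return replace(self, **kw)


@dataclass(frozen=True)
class ScattererSet:
    """Point scatterers inside one range gate."""

    radial_positions: np.ndarray   # l_j, m
    amplitudes: np.ndarray         # dimensionless echo amplitudes
    phases: np.ndarray             # radians, uniform on [0, 2*pi)

    def __post_init__(self) -> None:
        n = len(self.radial_positions)
        if len(self.amplitudes) != n or len(self.phases) != n:
            raise DomainError("scatterer arrays must share one length")
        if np.any(self.phases < 0) or np.any(self.phases >= 2 * math.pi):
            raise DomainError("phases must lie in [0, 2*pi)")

    def __len__(self) -> int:
        return len(self.radial_positions)


@dataclass(frozen=True)
class PulsatileWaveform:
    """Raised-cosine cardiac envelope multiplying the steady velocity field.

    The envelope oscillates between the end-diastolic floor ``1/sd_ratio``
    and the systolic peak 1, with one raised-cosine systolic pulse of
    fractional width ``systolic_fraction`` per cardiac period.
    """

    heart_rate_hz: float = 1.2
    sd_ratio: float = 3.67
    systolic_fraction: float = 0.35

    def __post_init__(self) -> None:
        if self.heart_rate_hz <= 0:
            raise DomainError("heart_rate_hz must be positive")
        if self.sd_ratio < 1.0:
            raise DomainError("sd_ratio must be >= 1 (systole >= diastole)")
        if not 0 < self.systolic_fraction <= 1:
            raise DomainError("systolic_fraction must lie in (0, 1]")

    def envelope(self, t: np.ndarray) -> np.ndarray:
        """Envelope value in [1/sd_ratio, 1] at times ``t`` (seconds)."""
        d = 1.0 / self.sd_ratio
        phase = np.mod(t * self.heart_rate_hz, 1.0)
        pulse = np.where(
            phase < self.systolic_fraction,
            0.5 * (1.0 - np.cos(2.0 * np.pi * phase / self.systolic_fraction)),
            0.0,
        )
        return d + (1.0 - d) * pulse


@dataclass(frozen=True)
class DopplerSignal:
    """One demodulated Doppler time series with its ground truth."""

    samples: np.ndarray
    sampling_rate: float
    gate_radial_position: float
    true_velocity: float
    phantom_ref: str = ""

    def __post_init__(self) -> None:
        if len(self.samples) == 0:
            raise DomainError("empty signal")
        if not np.all(np.isfinite(self.samples)):
            raise DomainError("signal contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate

    def __len__(self) -> int:
        return len(self.samples)


def radial_velocity(phantom: FlowPhantom, l) -> float | np.ndarray:
    """Poiseuille velocity v0 * (1 - (l/L)^2) at radial distance ``l``.

    Raises
    ------
    DomainError
        if ``l`` lies outside [0, L].
    """
    l_arr = np.asarray(l, dtype=float)
    L = phantom.lumen_radius
    if np.any(l_arr < 0) or np.any(l_arr > L):
        raise DomainError(f"radial position must lie in [0, {L}]")
    v = phantom.center_velocity * (1.0 - (l_arr / L) ** 2)
    return float(v) if np.isscalar(l) else v


def scatterer_count(phantom: FlowPhantom) -> int:
    """Number of scatterers in the sample volume: ceil(10 x y z / lambda^3)."""
    x, y, z = phantom.sample_volume_dims
    lam = phantom.wavelength
    # tiny slack so an exactly integer ratio is not pushed up by fp rounding
    return int(math.ceil(10.0 * x * y * z / lam**3 - 1e-9))


def doppler_shift(phantom: FlowPhantom, v: float) -> float:
    """Doppler shift 2 f0 v cos(theta) / c for axial velocity ``v`` (m/s)."""
    if abs(v) > V_CAP:
        raise DomainError(f"|v| exceeds the physical cap {V_CAP} m/s")
    return (2.0 * phantom.carrier_frequency * v
            * math.cos(phantom.beam_angle_rad) / phantom.sound_speed)


def velocity_from_shift(phantom: FlowPhantom, f) -> float | np.ndarray:
    """Inverse of :func:`doppler_shift`: velocity for a Doppler frequency."""
    return (np.asarray(f, dtype=float) * phantom.sound_speed
            / (2.0 * phantom.carrier_frequency * math.cos(phantom.beam_angle_rad)))


def womersley_number(phantom: FlowPhantom, density: float = 1060.0) -> float:
    """Womersley number alpha = L * sqrt(omega * rho / mu).

    Ratio of pulsatile inertial to viscous forces; alpha << 1 means the flow
    follows the quasi-steady Poiseuille profile at every instant.
    """
    if density <= 0:
        raise DomainError("density must be positive")
    if phantom.pulsation_angular_frequency < 0:
        raise DomainError("pulsation_angular_frequency must be non-negative")
    return phantom.lumen_radius * math.sqrt(
        phantom.pulsation_angular_frequency * density / phantom.dynamic_viscosity
    )


def _default_gate_extent(phantom: FlowPhantom) -> float:
    # L/50 gives realistic intra-gate spectral broadening
    return phantom.lumen_radius / 50.0


def draw_scatterers(
    phantom: FlowPhantom,
    gate_center: float,
    gate_extent: float,
    rng: np.random.Generator,
    amplitudes: str = "unit",
) -> ScattererSet:
    """Draw the scatterer population of one gate.

    Positions are uniform over the gate interval clipped to [0, L]; phases
    uniform on [0, 2*pi).  ``amplitudes`` is ``"unit"`` (all ones, keeps the
    ground-truth spectrum analytically checkable) or ``"rayleigh"``.
    """
    L = phantom.lumen_radius
    lo = max(0.0, gate_center - gate_extent / 2.0)
    hi = min(L, gate_center + gate_extent / 2.0)
    if not (0.0 <= gate_center <= L) or hi <= lo:
        raise DomainError("gate interval must be a sub-interval of [0, L]")
    n = scatterer_count(phantom)
    positions = rng.uniform(lo, hi, size=n)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=n)
    if amplitudes == "unit":
        amps = np.ones(n)
    elif amplitudes == "rayleigh":
        amps = rng.rayleigh(scale=1.0 / math.sqrt(2.0), size=n)
    else:
        raise DomainError(f"unknown amplitude mode {amplitudes!r}")
    return ScattererSet(positions, amps, phases)


def synthesize_gate_signal(
    phantom: FlowPhantom,
    gate_center: float,
    gate_extent: float | None = None,
    seed: int | np.random.SeedSequence | None = None,
    amplitudes: str = "unit",
    pulsatile: PulsatileWaveform | None = None,
) -> DopplerSignal:
    """Simulate the demodulated Doppler signal of one range gate.

    Each scatterer contributes ``a_j * cos(2*pi*f_dj*t + phi_j)`` with
    ``f_dj = doppler_shift(radial_velocity(l_j))``; contributions are summed
    and white Gaussian noise is added so the realised signal-to-noise power
    ratio equals ``phantom.snr_db``.  With a :class:`PulsatileWaveform`, the
    Doppler frequency of every scatterer is modulated by the cardiac
    envelope and the phase is accumulated by trapezoidal integration.

    The result is reproducible for a fixed ``(phantom, seed)``.
    """
    if gate_extent is None:
        gate_extent = _default_gate_extent(phantom)
    if seed is None:
        seed = phantom.seed
    rng = np.random.default_rng(seed)
    scatterers = draw_scatterers(phantom, gate_center, gate_extent, rng, amplitudes)

    t = np.arange(phantom.n_samples) / phantom.sampling_rate
    v_j = radial_velocity(phantom, scatterers.radial_positions)
    f_j = np.array([doppler_shift(phantom, v) for v in np.atleast_1d(v_j)])

    if pulsatile is None:
        phase = 2.0 * np.pi * f_j[:, None] * t[None, :]
    else:
        env = pulsatile.envelope(t)
        # instantaneous frequency f_j * env(t); phase by cumulative integral
        dt = 1.0 / phantom.sampling_rate
        cum = np.concatenate([[0.0], np.cumsum((env[:-1] + env[1:]) * 0.5 * dt)])
        phase = 2.0 * np.pi * f_j[:, None] * cum[None, :]

    signal = np.einsum(
        "j,jt->t",
        scatterers.amplitudes,
        np.cos(phase + scatterers.phases[:, None]),
    )

    if phantom.snr_db is not None:
        p_sig = float(np.mean(signal**2))
        if p_sig > 0:
            p_noise = p_sig / 10.0 ** (phantom.snr_db / 10.0)
            noise = rng.standard_normal(len(t))
            noise *= math.sqrt(p_noise) / math.sqrt(float(np.mean(noise**2)))
            signal = signal + noise

    return DopplerSignal(
        samples=signal,
        sampling_rate=phantom.sampling_rate,
        gate_radial_position=gate_center,
        true_velocity=radial_velocity(phantom, gate_center),
        phantom_ref=f"phantom-seed{phantom.seed}",
    )


def synthesize_profile_dataset(
    phantom: FlowPhantom,
    m: int = 500,
    seed: int | None = None,
    gate_extent: float | None = None,
    wall_margin: float = 0.02,
    amplitudes: str = "unit",
) -> list[DopplerSignal]:
    """Simulate ``m`` gates with centres uniformly spaced on [0, L*(1-eps)].

    The near-wall margin ``eps`` keeps the outermost gate away from the
    zero-velocity wall, where the Doppler shift would vanish.  Per-gate seeds
    are spawned deterministically from the master ``seed``.
    """
    if m < 2:
        raise DomainError("need at least 2 gates for a profile")
    if seed is None:
        seed = phantom.seed
    centers = np.linspace(0.0, phantom.lumen_radius * (1.0 - wall_margin), m)
    children = np.random.SeedSequence(seed).spawn(m)
    return [
        synthesize_gate_signal(
            phantom, c, gate_extent=gate_extent, seed=ss, amplitudes=amplitudes
        )
        for c, ss in zip(centers, children)
    ]
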