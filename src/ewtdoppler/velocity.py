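"""Per-gate velocity estimation, radial profiles and the NRMSE benchmark.

Two estimators convert a demodulated Doppler time series into an axial
velocity via ``v = f * c / (2 f0 cos(theta))``:

* STFT baseline — the time-averaged first spectral moment (mean frequency)
  of a Hann-windowed spectrogram, the conventional sonogram estimator.
* EWT — adaptive filter-bank decomposition of the gate spectrum; the
  maximal-energy band-pass mode inside the physiologic Doppler band is
  selected and its median Hilbert instantaneous frequency taken.  Broadband
  noise outside the selected band and near-DC clutter (isolated in the
  approximation band) no longer bias the estimate, which is why the EWT
  profile tracks the parabolic ground truth more closely at moderate SNR.

Profiles over ``m`` range gates are scored with the normalised root mean
square error

    NRMSE = sqrt( sum_k (v_k - vbar_k)^2 / sum_k vbar_k^2 )

against the Poiseuille ground truth ``vbar``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .errors import DegenerateSignalError, DomainError
from .ewt import build_filter_bank, decompose, detect_boundaries, instantaneous_frequency
from .phantom import (
    V_CAP,
    DopplerSignal,
    FlowPhantom,
    doppler_shift,
    synthesize_profile_dataset,
    velocity_from_shift,
)

__all__ = [
    "TimeFrequencyMap",
    "VelocityProfile",
    "BenchmarkConfig",
    "BenchmarkReport",
    "stft_spectrogram",
    "mean_frequency",
    "estimate_gate_velocity_stft",
    "estimate_gate_velocity_ewt",
    "estimate_profile",
    "nrmse",
    "run_benchmark",
]


@dataclass(frozen=True)
class TimeFrequencyMap:
    """Spectrogram: power is (time x frequency), frequencies in Hz."""

    times: np.ndarray
    frequencies: np.ndarray
    power: np.ndarray
    window_length: int
    overlap_fraction: float

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.times), len(self.frequencies)):
            raise DomainError("power matrix must be (n_times, n_frequencies)")
        if np.any(self.power < 0):
            raise DomainError("spectrogram power must be non-negative")


def stft_spectrogram(
    signal: DopplerSignal,
    window_length: int = 256,
    overlap_fraction: float = 0.75,
) -> TimeFrequencyMap:
    """Hann-windowed magnitude-squared STFT of one gate signal."""
    x = signal.samples
    if window_length > len(x):
        raise DomainError("window_length exceeds the signal length")
    if not 0.0 <= overlap_fraction < 1.0:
        raise DomainError("overlap_fraction must lie in [0, 1)")
    noverlap = int(overlap_fraction * window_length)
    freqs, times, sxx = scipy.signal.spectrogram(
        x,
        fs=signal.sampling_rate,
        window="hann",
        nperseg=window_length,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    return TimeFrequencyMap(times, freqs, sxx.T, window_length, overlap_fraction)


def mean_frequency(map_or_spectrum) -> float:
    """First spectral moment sum(f * P) / sum(P), in Hz.

    Accepts a :class:`TimeFrequencyMap` (time-averaged over frames) or a
    ``(frequencies, power)`` pair for a single spectrum.
    """
    if isinstance(map_or_spectrum, TimeFrequencyMap):
        freqs = map_or_spectrum.frequencies
        power = map_or_spectrum.power.mean(axis=0)
    else:
        freqs, power = map_or_spectrum
        freqs = np.asarray(freqs, dtype=float)
        power = np.asarray(power, dtype=float)
    if np.any(power < 0):
        raise DomainError("power must be non-negative")
    total = power.sum()
    if total <= 0:
        raise DegenerateSignalError("zero total power: mean frequency undefined")
    return float(np.dot(freqs, power) / total)


def estimate_gate_velocity_stft(
    signal: DopplerSignal,
    phantom: FlowPhantom,
    window_length: int = 256,
    overlap_fraction: float = 0.75,
) -> float:
    """STFT mean-frequency velocity estimate; NaN flags a missing estimate."""
    try:
        tf = stft_spectrogram(signal, window_length, overlap_fraction)
        f_mean = mean_frequency(tf)
    except DegenerateSignalError:
        return float("nan")
    return float(velocity_from_shift(phantom, f_mean))


def estimate_gate_velocity_ewt(
    signal: DopplerSignal,
    phantom: FlowPhantom,
    bands: int = 3,
    kappa: float | None = None,
    smooth_window: int = 9,
    min_doppler_hz: float = 50.0,
) -> float:
    """EWT velocity estimate for one gate; NaN flags a missing estimate.

    The gate spectrum is segmented into ``bands`` segments (DC-anchored, so
    the approximation band collects clutter and the near-DC noise floor).
    Among the band-pass modes, the one with maximal spectral energy inside
    the physiologic Doppler band — shifts between ``min_doppler_hz`` and the
    shift of the 10 m/s velocity cap — is selected; its median interior
    Hilbert instantaneous frequency is converted to velocity.  If all the
    energy sits in the approximation band the estimate is flagged missing.
    """
    if bands < 2:
        raise DomainError("need at least 2 bands (approximation + detail)")
    x = signal.samples
    if float(np.max(np.abs(x))) == 0.0:
        return float("nan")
    fs = signal.sampling_rate
    mag = np.abs(np.fft.rfft(x))

    partition = detect_boundaries(mag, bands, smooth_window=smooth_window,
                                  anchor_dc=True)
    if partition.n_segments < 2:
        return float("nan")
    bank = build_filter_bank(partition, kappa=kappa, fft_length=len(x))
    dec = decompose(x, bank)

    f_bins = np.fft.rfftfreq(len(x), d=1.0 / fs)
    f_hi = min(abs(doppler_shift(phantom, V_CAP)), fs / 2.0)
    in_band = (f_bins > min_doppler_hz) & (f_bins <= f_hi)
    if not np.any(in_band):
        return float("nan")

    energies = [
        float(np.sum(np.abs(np.fft.rfft(mode))[in_band] ** 2))
        for mode in dec.details
    ]
    total = float(np.sum(np.abs(np.fft.rfft(x)) ** 2))
    best = int(np.argmax(energies))
    if energies[best] <= 1e-12 * total:
        return float("nan")  # everything the bank kept is in the approximation

    inst = instantaneous_frequency(dec.details[best], fs)
    if inst.degenerate:
        return float("nan")
    return float(velocity_from_shift(phantom, inst.median()))


@dataclass(frozen=True)
class VelocityProfile:
    """Paired (radius, estimate, truth) across the gates of one dataset."""

    radial_positions: np.ndarray
    estimated_velocities: np.ndarray
    theoretical_velocities: np.ndarray
    method_label: str
    n_missing: int = 0

    def __post_init__(self) -> None:
        m = len(self.radial_positions)
        if m < 2:
            raise DomainError("a profile needs at least 2 gates")
        if len(self.estimated_velocities) != m or len(self.theoretical_velocities) != m:
            raise DomainError("profile arrays must share one length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius_m": self.radial_positions,
                "true_velocity": self.theoretical_velocities,
                f"{self.method_label}_velocity": self.estimated_velocities,
            }
        )


def estimate_profile(
    dataset: list[DopplerSignal],
    phantom: FlowPhantom,
    method: str = "ewt",
    **estimator_kwargs,
) -> VelocityProfile:
    """Apply a per-gate estimator to every gate of a simulated dataset.

    Missing estimates (degenerate gates) are imputed as 0 and counted in
    ``n_missing`` so the NRMSE stays defined on all m points.
    """
    if not dataset:
        raise DomainError("empty dataset")
    if method == "stft":
        est_fn = estimate_gate_velocity_stft
    elif method == "ewt":
        est_fn = estimate_gate_velocity_ewt
    else:
        raise DomainError(f"unknown method {method!r}")

    order = np.argsort([s.gate_radial_position for s in dataset])
    radii, est, truth = [], [], []
    n_missing = 0
    for idx in order:
        sig = dataset[idx]
        v = est_fn(sig, phantom, **estimator_kwargs)
        if np.isnan(v):
            n_missing += 1
            v = 0.0
        radii.append(sig.gate_radial_position)
        est.append(v)
        truth.append(sig.true_velocity)
    return VelocityProfile(
        np.array(radii), np.array(est), np.array(truth), method, n_missing
    )


def nrmse(profile_or_estimates, theoretical=None) -> float:
    """Normalised RMSE sqrt(sum (v - vbar)^2 / sum vbar^2).

    Accepts a :class:`VelocityProfile` or two arrays ``(estimates, truth)``.
    """
    if isinstance(profile_or_estimates, VelocityProfile):
        v = profile_or_estimates.estimated_velocities
        vbar = profile_or_estimates.theoretical_velocities
    else:
        v = np.asarray(profile_or_estimates, dtype=float)
        vbar = np.asarray(theoretical, dtype=float)
    denom = float(np.sum(vbar**2))
    if denom <= 0:
        raise DomainError("zero theoretical energy: NRMSE undefined")
    return float(np.sqrt(np.sum((v - vbar) ** 2) / denom))


@dataclass(frozen=True)
class BenchmarkConfig:
    """Protocol of the STFT-vs-EWT profile benchmark."""

    phantom: FlowPhantom = field(default_factory=FlowPhantom)
    m: int = 500
    n_seeds: int = 20
    master_seed: int = 0
    window_length: int = 256
    overlap_fraction: float = 0.75
    bands: int = 3
    kappa: float | None = None


@dataclass(frozen=True)
class BenchmarkReport:
    """Per-seed NRMSEs, their means, and one example profile table."""

    per_seed: pd.DataFrame            # columns: seed, stft_nrmse, ewt_nrmse
    profile: pd.DataFrame             # radius, truth, stft, ewt (first seed)
    config: BenchmarkConfig

    @property
    def stft_nrmse(self) -> float:
        return float(self.per_seed["stft_nrmse"].mean())

    @property
    def ewt_nrmse(self) -> float:
        return float(self.per_seed["ewt_nrmse"].mean())

    @property
    def nrmse_difference(self) -> float:
        """mean EWT NRMSE minus mean STFT NRMSE (negative favours EWT)."""
        return self.ewt_nrmse - self.stft_nrmse

    def summary(self) -> dict:
        return {
            "stft_nrmse": self.stft_nrmse,
            "ewt_nrmse": self.ewt_nrmse,
            "ewt_minus_stft": self.nrmse_difference,
            "m": self.config.m,
            "n_seeds": self.config.n_seeds,
            "per_seed": {
                "seed": self.per_seed["seed"].tolist(),
                "stft_nrmse": self.per_seed["stft_nrmse"].tolist(),
                "ewt_nrmse": self.per_seed["ewt_nrmse"].tolist(),
            },
        }


def run_benchmark(config: BenchmarkConfig = BenchmarkConfig()) -> BenchmarkReport:
    """Simulate, estimate with both methods and score, over several seeds.

    For each seed an independent ``m``-gate dataset is drawn from the
    phantom; both estimators are applied gate by gate and their profile
    NRMSEs recorded.  Seeds are spawned deterministically from
    ``master_seed``, so the whole benchmark is reproducible.
    """
    rows = []
    profile_tbl = None
    seed_roots = np.random.SeedSequence(config.master_seed).generate_state(
        config.n_seeds
    ) % (2**31)
    for i, seed in enumerate(seed_roots):
        dataset = synthesize_profile_dataset(
            config.phantom, m=config.m, seed=int(seed)
        )
        prof_stft = estimate_profile(
            dataset, config.phantom, "stft",
            window_length=config.window_length,
            overlap_fraction=config.overlap_fraction,
        )
        prof_ewt = estimate_profile(
            dataset, config.phantom, "ewt",
            bands=config.bands, kappa=config.kappa,
        )
        rows.append(
            {
                "seed": int(seed),
                "stft_nrmse": nrmse(prof_stft),
                "ewt_nrmse": nrmse(prof_ewt),
                "stft_missing": prof_stft.n_missing,
                "ewt_missing": prof_ewt.n_missing,
            }
        )
        if i == 0:
            profile_tbl = pd.DataFrame(
                {
                    "radius_m": prof_stft.radial_positions,
                    "true_velocity": prof_stft.theoretical_velocities,
                    "stft_velocity": prof_stft.estimated_velocities,
                    "ewt_velocity": prof_ewt.estimated_velocities,
                }
            )
    return BenchmarkReport(pd.DataFrame(rows), profile_tbl, config)
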