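# Methods

## Flow phantom

The simulator models one straight vessel segment of lumen radius `L`
carrying steady, laminar, axisymmetric flow of a Newtonian fluid, so the
axial velocity at distance `l` from the centreline is the Poiseuille
parabola

    v(l) = v0 (1 − (l/L)²),  0 ≤ l ≤ L,

with no slip at the wall.  Pulsatility is characterised by the Womersley
number `α = L sqrt(ω ρ / μ)`; at the defaults (L = 1 mm, ω = 2π·1.2 rad/s,
ρ = 1060 kg/m³, μ = 3.5 mPa·s) α ≈ 1.5, small enough that a quasi-steady
parabolic profile is a reasonable idealisation, and the benchmark uses
strictly steady flow so the ground truth is exact.

The insonated volume is populated with point scatterers at a density of
ten per cubic wavelength, `N = ceil(10 x y z / λ³)` with `λ = c/f0`
(235 scatterers for the default 2 mm³ sample volume at 3.5 MHz; a 1 ns
slack inside the ceil keeps exactly-integer ratios from rounding up).
Each scatterer `j` sits at a radius `l_j` drawn uniformly over the gate
interval and returns a demodulated echo

    a_j cos(2π f_dj t + φ_j),  f_dj = 2 f0 v(l_j) cos(θ) / c,

with phase uniform on [0, 2π) and unit amplitude by default (a Rayleigh
amplitude mode exists; unit amplitudes keep the expected spectrum
analytically checkable).  Gate signals are the scatterer sum plus white
Gaussian noise scaled against the realised signal power so the sample SNR
equals `snr_db` exactly.  For pulsatile runs every scatterer's
instantaneous frequency is modulated by a raised-cosine cardiac envelope
(floor `1/sd_ratio`, peak 1, systolic fraction 0.35 of the cycle) and the
phase is accumulated by trapezoidal integration.

Default parameters and their provenance:

| parameter | default | why |
|---|---|---|
| `sound_speed c` | 1540 m/s | soft-tissue convention |
| `carrier_frequency f0` | 3.5 MHz | abdominal probe setting |
| `beam_angle θ` | 45° | inside the <60° clinical constraint |
| `lumen_radius L` | 1 mm | uterine-artery scale |
| `center_velocity v0` | 1 m/s | canonical centreline velocity |
| `sample_volume_dims` | (1.26 mm)³ ≈ 2 mm³ | pulsed-Doppler gate volume |
| `sampling_rate fs` | 20 kHz | > 2× the 3.2 kHz peak shift (Nyquist checked at construction) |
| `duration` | 0.1 s per gate | 2000 samples, ≈ 28 STFT frames |
| `snr_db` | 10 dB | places both estimators in a regime where their difference is visible; see the SNR sweep below |
| gate extent | L/50 | narrow enough that intra-gate broadening stays ≪ the Doppler shift |
| wall margin ε | 0.02 | keeps the outermost gate off the zero-velocity wall, where the shift (and any relative error) would vanish |

Profile datasets place `m` gate centres uniformly on [0, L(1−ε)], with
per-gate seeds spawned from the master seed (`numpy.random.SeedSequence`),
so datasets are bit-reproducible.

What the generator does *not* emulate: RF-level physics (beamforming,
attenuation, frequency-dependent scattering, speckle imaging), pulse
repetition and aliasing, wall clutter and tissue motion, and the full
pulsatile Womersley velocity solution.  Passing benchmarks therefore show
that the estimators recover a known narrowband velocity law under
additive white noise — not that they are robust to clutter filters,
aliasing or attenuation encountered in vivo.

## Empirical wavelet transform

The Fourier support [0, π] (normalised angular frequency; π = fs/2) is
split into `N` contiguous segments `[ϖ_n, ϖ_{n+1}]`.  Boundary detection
follows the local-maxima rule: the half-spectrum magnitude is smoothed
with a 9-point moving average (configurable), the `N` largest local maxima
are retained and interior boundaries placed at midpoints between
consecutive maxima; with fewer maxima than requested, `N` is reduced with
a warning.  For Doppler estimation a DC-anchored variant always keeps the
DC bin as the first retained "maximum", so the lowest (approximation)
band ends halfway up to the first real peak and becomes a dedicated
clutter/noise-floor band — the wall-filter convention.  Without the
anchor, a gate whose Doppler peak happens to be the lowest retained
maximum would have its signal assigned to the approximation band, which
the estimator deliberately excludes.

On a partition, Meyer-type responses are built with the auxiliary
polynomial `β(x) = x⁴(35 − 84x + 70x² − 20x³)` and transition half-widths
`ξ_n = κ ϖ_n`: the scaling response is 1 below `ϖ_1 − ξ_1` and falls as
`cos(π/2 β(·))`; each wavelet rises as `sin(π/2 β(·))` through `ϖ_n` and
falls as `cos(π/2 β(·))` through `ϖ_{n+1}`.  The cos/sin pairing makes
the squared responses sum to one (partition of unity, enforced to 1e−10),
so the bank is a tight frame: band energies sum to the input energy and
decompose→reconstruct round-trips are exact to better than 1e−8 relative.
Admissibility requires `κ < min_n (ϖ_{n+1} − ϖ_n)/(ϖ_{n+1} + ϖ_n)`;
`κ = None` picks half that bound.  Numerical conventions worth noting:

- No roll-off is applied at the global edge π (the last band stays flat
  to Nyquist).  A transition centred on π would extend past the support
  and break the partition of unity there; with the flat edge, the
  single-segment bank degenerates to the identity filter.
- Filtering multiplies the full FFT by responses folded symmetrically
  around Nyquist, so modes are real; an internal assertion rejects any
  imaginary residue above 1e−10 (relative).
- The filter bank is built at the signal length, so no padding or
  cropping enters the round trip.

Instantaneous frequency is the unwrapped phase derivative of the analytic
signal (`scipy.signal.hilbert`) divided by 2π; the first and last 5 % of
samples are flagged unreliable and excluded from summaries; a constant
mode returns zeros with a degenerate flag.

## Velocity estimators and benchmark

STFT baseline: Hann window of 256 samples (12.8 ms at 20 kHz) with 75 %
overlap — conventional sonogram parameters, exposed in the benchmark
config — and the estimate is the time-averaged first spectral moment
mapped through `v = f c / (2 f0 cos θ)`.  The first moment integrates the
full band, so white noise (mean frequency fs/4) biases it toward mid-band;
this is the textbook failure mode the adaptive method addresses.

EWT estimator: 3 bands by default (clutter floor / Doppler band /
high-frequency residue), DC-anchored boundaries, κ at half the admissible
bound.  Among the band-pass modes, the one with maximal spectral energy
inside the physiologic Doppler band — shifts between 50 Hz (below which
clinical wall filters discard everything) and the shift of a 10 m/s
velocity cap — is selected, and the median instantaneous frequency over
interior samples is converted to velocity.  The median is robust to edge
effects and brief in-band noise excursions.  Gates whose energy sits
entirely in the approximation band are flagged missing; profiles impute
missing estimates as 0 and report the count, so the NRMSE is always
computed on all m points.

Profiles are scored with `NRMSE = sqrt(Σ (v−v̄)² / Σ v̄²)`.  The default
benchmark uses m = 500 gates, SNR 10 dB and 20 seeded repetitions
(≈ 75 s on one CPU); `scripts/acceptance.py` reruns exactly this and
prints the two mean NRMSEs.  The clean-limit check uses SNR 40 dB,
4096-sample gates and m = 60 — enough gates to sample the parabola
densely while keeping the property test under a minute.

### Sensitivity to SNR (config-search note)

The commonly reported NRMSE pair for this comparison is 0.19 (STFT) and
0.13 (EWT), from a protocol whose SNR, windows and seeds are not public.
`scripts/snr_sweep.py --seed 1` (m = 200, 3 seeds) maps our benchmark
across SNR:

| SNR (dB) | STFT | EWT |
|---|---|---|
| 0 | 0.631 | 0.287 |
| 2 | 0.489 | 0.144 |
| 4 | 0.361 | 0.082 |
| 6 | 0.255 | 0.047 |
| 8 | 0.174 | 0.028 |
| 10 | 0.116 | 0.017 |
| 12 | 0.076 | 0.011 |

The STFT value crosses 0.19 near 7.5 dB and the EWT value crosses 0.13
near 2.3 dB: no single SNR reproduces the pair jointly, because our EWT
implementation degrades much more slowly with noise than the reference
pair implies.  The shipped default stays at 10 dB, where the STFT error
sits in the reported 0.1–0.2 regime and the ordering between methods is
unambiguous; the default was not tuned to reproduce the printed pair.

## Hemodynamic indices

The sonogram envelope is the per-frame frequency below which 95 % of
frame power lies (linearly interpolated on the cumulative power for
sub-bin resolution; the percentile, rather than the argmax, tolerates a
noise floor above the band), converted to velocity.  Systolic peaks are
detected with a prominence threshold of 20 % of the envelope range, and at
least three complete peak-to-peak cycles are required before indices are
reported — mirroring the clinical several-stable-cycles rule.  Per cycle,
S is the envelope maximum, D the end-diastolic value found by walking back
from the next systolic peak through its upstroke to the last local
minimum (clinical convention; a global-cycle-minimum mode is available),
and TAMV the time-averaged envelope.  RI = (S−D)/S, PI = (S−D)/TAMV and
S/D are averaged across cycles; the identities RI = 1 − D/S and
S/D = 1/(1−RI) hold per cycle to machine precision by construction.

## Clinical table arithmetic

Rates are `100·count/n` rounded to one decimal (display convention of the
tables).  The 2×2 chi-square is the Pearson statistic
`n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))` with an optional Yates correction and
p-values from χ²(1); two-sample t from summaries defaults to the Welch
form with Welch–Satterthwaite degrees of freedom (the source tables never
state their test), with a pooled option.  The bundled delivery-outcome
table stores its printed totals verbatim because one arm's components sum
to more than the printed total — a reporting inconsistency the package
documents rather than repairs.  The printed χ² and t values accompanying
the bundled tables are not reproducible from the printed counts and
summaries; the implementations are instead validated against hand
arithmetic and independent scipy oracles.

## Known limitations

- The phantom's additive white noise is a crude stand-in for clutter,
  speckle decorrelation and electronic noise; the EWT-vs-STFT gap
  measured here is an upper bound on what less idealised interference
  would allow.
- Boundary detection assumes a unimodal Doppler band per gate; disturbed
  or turbulent flow with multimodal spectra would need more bands and a
  different mode-selection rule.
- The envelope pipeline assumes non-aliased, positive-direction flow;
  there is no spectral unwrapping for velocities beyond the Nyquist
  shift.
- Index extraction expects a periodic envelope with prominent systolic
  peaks; arrhythmic waveforms will fail the cycle-count rule rather than
  produce silently averaged indices.
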