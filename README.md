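# ewtdoppler

Time–frequency velocity estimation for ultrasound Doppler blood-flow
signals, built around the empirical wavelet transform (EWT), with a
scattering-particle flow phantom for validation, the conventional STFT
sonogram baseline, clinical Doppler indices (RI, PI, S/D) and the
arithmetic of grouped clinical outcome tables.

## The problem

Pulsed-Doppler ultrasound measures blood velocity from the frequency shift
of echoes returned by moving scatterers:

```
f_d = 2 f0 v cos(θ) / c
```

with carrier frequency `f0`, beam–flow angle `θ` and sound speed `c`.
Estimating the radial velocity profile across a vessel from the noisy,
nonstationary demodulated signal is a spectral-estimation problem.  The
classic approach — the mean frequency of an STFT spectrogram — weighs the
entire spectrum, so broadband noise and near-DC clutter bias the estimate.
The EWT instead segments the Fourier spectrum adaptively, builds a
Meyer-type tight-frame filter bank on the segments

```
β(x) = x⁴(35 − 84x + 70x² − 20x³),   ξ_n = κ ϖ_n,
κ < min_n (ϖ_{n+1} − ϖ_n)/(ϖ_{n+1} + ϖ_n)
```

and extracts the Doppler band as a single band-limited mode whose Hilbert
instantaneous frequency gives the velocity, unaffected by out-of-band
noise.

The package ships a validation phantom: a vessel of radius `L` with
steady parabolic (Poiseuille) flow `v(l) = v0 (1 − (l/L)²)`, populated
with ten point scatterers per cubic wavelength, each echoing a
random-phase cosine at its own Doppler shift, plus white Gaussian noise at
a configurable SNR.  Estimated profiles over `m` range gates are scored
against the ground truth with

```
NRMSE = sqrt( Σ_k (v(k) − v̄(k))² / Σ_k v̄(k)² ).
```

## Worked example

```python
>>> import ewtdoppler as ed
>>> phantom = ed.FlowPhantom()            # 3.5 MHz, 45°, 1 mm lumen, SNR 10 dB
>>> phantom.wavelength, ed.scatterer_count(phantom)
(0.00044, 235)
>>> ed.doppler_shift(phantom, 1.0)        # Hz at the 1 m/s centreline
3214.1217326661254

>>> signal = ed.synthesize_gate_signal(phantom, gate_center=0.3e-3, seed=42)
>>> signal.true_velocity                  # parabola at l = 0.3 mm
0.91
>>> ed.estimate_gate_velocity_stft(signal, phantom)
0.9638511355916901
>>> ed.estimate_gate_velocity_ewt(signal, phantom)
0.9068764113574412
```

The STFT mean frequency overshoots (the white noise floor pulls the first
spectral moment toward mid-band), while the EWT estimate isolates the
Doppler band first and lands within 0.4 % of the truth.  Over the full
benchmark the gap is systematic:

```python
>>> report = ed.run_benchmark(ed.BenchmarkConfig(m=100, n_seeds=3, master_seed=1))
>>> report.stft_nrmse, report.ewt_nrmse
(0.11522641748897439, 0.016225754932762747)
```

Pulsatile signals feed the clinical index pipeline:

```python
>>> phantom = ed.FlowPhantom(snr_db=35.0, duration=5.0, seed=11)
>>> wave = ed.PulsatileWaveform(heart_rate_hz=1.2, sd_ratio=3.0)
>>> sig = ed.synthesize_gate_signal(phantom, gate_center=0.0, seed=11, pulsatile=wave)
>>> tf = ed.stft_spectrogram(sig, window_length=256)
>>> env = ed.detect_cycles(ed.extract_envelope(tf, phantom))
>>> ed.compute_indices(env).to_dict()
{'RI': 0.661, 'PI': 1.451, 'SD_ratio': 2.954, 'S': 1.016, 'D': 0.344,
 'TAMV': 0.463, 'n_cycles': 5}
```

The recovered S/D of 2.95 matches the programmed ratio of 3.0 within 2 %,
and RI obeys the identity `RI = 1 − D/S` exactly.  Clinical count tables
are handled by the `clinical` module:

```python
>>> table = ed.load_efficacy_table()
>>> ed.effective_rate(table, "control"), ed.effective_rate(table, "observation")
(90.4, 97.6)
```

A command-line interface mirrors the library:
`ewtdoppler simulate|ewt|benchmark|indices|stats --help`.

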