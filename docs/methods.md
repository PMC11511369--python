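# Methods

## Problem and model

Stored-product insects produce trains of short (3–30 ms) wide-band impulses
as they move and feed in grain.  Contact sensors (piezoelectric pickups,
accelerometers, PVDF films, microphones) record these pulses over a
stationary self-noise floor, but are not calibrated, so every quantity the
package reports is a *ratio* against a noise reference and is therefore
invariant under any common amplitude gain.

The chain is: Butterworth band-pass → Hilbert-transform envelope →
noise-referenced normalization → NSPA (strong-pulse amplitude SNR) and NSEL
(band-energy SNR).  NSPA is computed once per record per channel over the
analysis segment, not per individual pulse; batch aggregation then averages
record-level values per (insect, material) pairing.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| band | 500–6000 Hz | where insect pulses carry most energy; per-sensor bands override per manifest row |
| filter order *n* | 10 | exponent in the band-pass magnitude response |
| strong-pulse window | [0.5, 0.9] of envelope max, inclusive | samples entering the NSPA RMS |
| spectrum window | 1024-sample Blackman–Harris, 50% overlap | Welch PSD for NSEL / SNR spectra |
| edge guard | 1024 samples per end | region excluded from envelope statistics |
| record length | 60 s at 24 kHz | the standard analysis unit |

Recordings at other rates are analyzed at native rate (an explicit resample
option exists); the only hard requirement is that the band edge stays below
Nyquist.

## Numerical choices

- **Zero-phase filtering.**  The band-pass is applied forward–backward
  (`sosfiltfilt`, second-order sections for stability at a 500 Hz edge on a
  24 kHz rate).  Envelope peaks therefore stay aligned with pulse times; the
  effective magnitude response is the *square* of the single-pass response,
  so band edges sit at −6 dB.  All filter-gain tests compare against the
  squared closed form.
- **PSD convention.**  One-sided density scaling, per-segment mean removal.
  NSEL depends only on level differences, so the scaling constant cancels as
  long as signal and reference use the same estimator; Parseval
  (∫PSD df = mean square) holds within the Welch estimator tolerance.
- **Band integration** sums PSD bins whose centers fall inside the band,
  times the bin width.
- **Edge guard.**  The discrete analytic signal and the filter start-up are
  unreliable at record boundaries; the first and last 1024 samples of every
  extracted envelope are excluded from downstream maxima/RMS.  Envelopes
  constructed directly (hand cases) carry no guard.
- **Median normalization** takes the noise set *strictly* below the median,
  as the formula states; ties at the median are excluded (measure-zero for
  continuous envelopes).  Even-length medians are the midpoint of the two
  central order statistics.  A constant envelope leaves the noise set empty
  and raises a degenerate-input error rather than returning NaN; the same
  policy applies to the NSPA window of a constant envelope.  Degenerate
  channels are excluded from best-channel selection with a warning instead
  of aborting a batch.
- **NSEL noise reference under the median method.**  With no self-noise
  recording, the noise PSD is estimated from the raw samples at times where
  the band envelope sits below its median — noise-dominated stretches by
  construction.  Concatenating non-contiguous runs introduces negligible
  spectral leakage relative to the pulse energy being measured, since for
  sparse records those runs are long.
- **Best channel** is the arg-max of NSPA with ties broken to the lowest
  index.

## The two normalization denominators are not equal

For Gaussian sensor noise the envelope is Rayleigh-distributed, and
E[X² | X < median] / E[X²] = 1 − ln 2, so the median-method denominator sits
a constant 10·log₁₀(1 − ln 2) ≈ −5.13 dB below the self-noise denominator
(`MEDIAN_SELF_NOISE_OFFSET_DB`).  Median-normalized levels therefore run
≈5.1 dB *higher* than self-noise-normalized levels on the same record.  The
median method still tracks the self-noise floor faithfully — the offset is a
fixed, distribution-determined constant, which the test suite verifies to
within ±1 dB on sparse scenes — but values from the two methods should not
be compared without accounting for it.

## Synthetic scenes: what they emulate and what they do not

Each pulse is a damped sinusoid
a(t) = A·e^(−(t−t₀)/τ)·sin(2πf_c(t−t₀)) with carrier inside the analysis
band and decay τ = 8 ms in the standard fixtures — the minimal model
matching the known band and duration of real insect pulses, since no
published waveform model exists.  Noise is stationary white Gaussian
(matching the self-noise role of the reference; pink noise is available for
robustness checks).  Per-channel proximity is a static gain in (0, 1].

Ground truth is computed without the analysis code: the in-band noise
envelope RMS is √2·σ_b with σ_b² = ∫PSD·M(f)⁴ df from the closed-form
magnitude response; the true NSPA applies the 50–90% window directly to the
noiseless exponential envelope.  The standard fixture ladder spans peak-SNRs
of 10–50 dB (12 pulses per 60 s scene, ≈1.6% duty), plus a 40-pulse dense
scene and a 4-channel scene with gains (0.3, 1.0, 0.55, 0.4).

Real recordings differ in ways the generator does not model: pulse-shape
variability and bursts of overlapping pulses, substrate-dependent
propagation and dispersion, nonstationary background noise, and sensor
nonlinearity.  Passing the recovery tests therefore demonstrates the
correctness of the measurement chain, not field detection performance; no
detection decision rule is included.

Measured NSPA recovers the analytic ground truth within ±1.5 dB for
peak-SNR ≥ 20 dB (noise inflation dominates below that, e.g. ≈+1.9 dB at
10 dB peak-SNR), is monotone in injected amplitude, and exceeds NSEL on
every sparse fixture — all recomputed by the test suite and
`scripts/acceptance.py` at run time.

## Problem sizes

Fixtures and acceptance runs use 60 s single- or four-channel scenes at
24 kHz (1.44 M samples per channel), the standard record length for this
analysis; the full suite renders and analyzes them in well under a minute on
one core.

## Known limitations

- Per-pulse NSPA statistics (segmenting individual pulses) are not
  implemented; the record-level definition is the only one with an
  unambiguous specification.
- The median method assumes pulses occupy a minority of samples; beyond
  ~50% duty the median itself is pulse-contaminated.
- 24-bit WAV writing uses the stdlib `wave` packer; all other WAV I/O goes
  through `scipy.io.wavfile`.
- No external-noise cancellation (body-microphone channels are carried as
  metadata roles only) and no species classification.
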