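# pestpulse

Vibro-acoustic detection metrics for stored-product insect pests.

Insects moving and feeding inside stored grain (e.g. *Tribolium confusum*,
*Tenebrio molitor* larvae, *Sitophilus oryzae*) emit sparse, millisecond-scale
wide-band impulses that contact sensors pick up in the 500–6000 Hz band.
Because such sensors are uncalibrated, raw amplitudes mean nothing on their
own: `pestpulse` expresses pulse strength relative to the sensor's own noise
floor and reduces a recording to two signal-to-noise figures that can be
compared across insects, substrates and sensor types.

## Method

For each channel of a recording sampled at rate *f*ₛ:

1. **Band-pass filter** — Butterworth band-pass with magnitude response
   *M*(ω) = [1 + ((ω_c² − ω²)/(ω·ω_Δ))^(2n)]^(−1/2), where
   ω_c = √(ω₁ω₂), ω_Δ = ω₂ − ω₁; default 500–6000 Hz, order *n* = 10,
   applied forward–backward (zero phase).
2. **Envelope** — the magnitude of the analytic signal,
   S_E(t) = |S(t) + i·H{S(t)}|, with H the Hilbert transform.
3. **Normalization** — S_n = S_E / RMS(N_E), where N_E is the envelope of a
   matched *self-noise* reference recording (no insect present).  When no
   clean reference exists, the *median* fallback uses
   N_s = {S_E : S_E < median(S_E)} and divides by RMS(N_s).
4. **NSPA** (normalized strong-pulse amplitude) =
   20·log₁₀ RMS{S_n : 0.5·max ≤ S_n ≤ 0.9·max} — an amplitude SNR driven by
   the strongest pulses.
5. **NSEL** (normalized signal energy level) =
   SPL_band(signal) − SPL_band(noise), with SPL_band = 10·log₁₀ ∫ PSD df over
   the analysis band (Welch PSD, 1024-sample Blackman–Harris window) — an
   averaged-energy SNR.

On a multi-channel rig the channel with the highest NSPA is taken as closest
to the insect.  For sparse pulse activity NSPA runs far above NSEL, which is
why amplitude-based detection is the more sensitive of the two.

A synthetic scene generator (`pestpulse.synth`) renders damped-sinusoid pulse
trains over seeded Gaussian noise with closed-form ground truth (in-band
noise envelope RMS, true normalized peaks, true NSPA), so the whole chain is
testable without any recordings.

## Worked example

```sh
pestpulse simulate --fixture-suite --seed 1 --out-dir scenes/
pestpulse analyze --input scenes/snr40.wav --reference scenes/snr40_reference.wav \
    --method self-noise --out metrics.csv
```

prints

```
channel 0: NSPA 37.39 dB  NSEL 9.64 dB  (n_qualifying=1358)
best channel: 0
```

The scene injects twelve pulses whose true normalized peak is 40 dB above
the noise-envelope floor; the analytic ground-truth NSPA for this pulse
shape is 36.78 dB, so the measured 37.39 dB recovers it to within 1 dB.
NSEL is far lower because twelve 8 ms pulses contribute little energy to a
60 s average — the expected ordering for sparse activity.  `metrics.csv`
holds one row per channel and `metrics.csv.config.yaml` records the exact
configuration used.

Batch runs over labelled datasets use a manifest CSV (file, insect,
material, sensor, per-row band and method) and produce per-record metrics
plus a per-(insect, material) summary table of means, medians and quartiles:

```sh
pestpulse batch --manifest scenes/manifest.csv --out summary.csv
```

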