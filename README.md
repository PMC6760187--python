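# wormstim

Analysis toolkit for giant-fiber electrophysiology under electrical,
mechanical, and pulsed-ultrasound stimulation, together with a calibrated
synthetic-recording generator used to validate the whole pipeline by
parameter recovery.

The package covers:

- **`wormstim.synthetic`** — simulation of two-pair bipolar extracellular
  recordings (biphasic AP waveforms, modality-specific stimulus artifacts,
  burst/pulse ultrasound timing, within-trial adaptation, dose-response),
  with a per-AP ground-truth log.
- **`wormstim.signal`** — zero-phase 120–1200 Hz Butterworth band-pass,
  stimulus-onset detection from the artifact channel, and MAD-thresholded
  biphasic AP detection with artifact blanking.
- **`wormstim.latency`** — greedy cross-channel AP matching, conduction
  velocity from the inter-anode delay, fiber classification, and the
  latency decomposition *arrival delay = propagation time + generation
  time* (`compute_top`, `compute_tog`), plus per-stimulus success rates.
- **`wormstim.parametrics`** — randomized pulse-repetition-frequency (PRF)
  comparisons, descending-amplitude threshold searches over pulse
  durations, pulse-timing identities, and strength-duration summaries.
- **`wormstim.stats`** — median [Q1–Q3] summaries, a Jarque–Bera normality
  screen, the Mann–Whitney rank-sum test (exact for small tie-free
  samples) and the Wilcoxon signed-rank test for paired designs.
- **`wormstim.io` / `wormstim.cli` / `wormstim.pipeline`** — CSV/YAML
  formats, strict configuration with documented defaults, and an
  end-to-end reproducible pipeline.

## Command line

```bash
# full synthetic comparative trial -> report.json + intermediate CSVs
wormstim run --seed 7 --out out/

# individual stages
wormstim simulate --protocol protocol.yml --seed 1 --out sim/
wormstim detect --in sim/trace.csv --out events.csv --onsets-out onsets.csv
wormstim analyze --events events.csv --onsets onsets.csv --out analysis/
wormstim compare-prf --design design.yml --out prf/
wormstim map-thresholds --design design.yml --out thresholds/
```

A protocol file declares either an explicit `stimuli:` list or a
`generate:` block (modalities, count, interval, region, LEUS parameters);
a config file overrides any subset of the defaults in
`wormstim.config.DEFAULTS` (unknown keys are rejected). Reports embed a
SHA-256 of the full configuration, the seed, and the package version, and
re-running with the same config reproduces them bit for bit.

## Notes

- All quantities are SI internally (seconds, metres, volts, pascals);
  reports round to the display conventions (0.1 ms for latencies, two
  decimals for sub-millisecond pulse durations).
- Synthetic generation times are log-normal, parameterised directly by the
  printed median and quartiles of each modality.
- The ultrasound success-probability model is the product of a logistic
  PRF plateau and a steep amplitude gate whose threshold decreases with
  pulse duration, with a hard 4.0 MPa pressure floor.
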