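# ffrpipe

A tested, reusable analysis pipeline for frequency-following responses
(FFR) to a consonant-vowel speech syllable:

* **`ffrpipe.synthetic`** — surrogate stimulus synthesis (harmonic complex
  with a fricative-like consonant and formant-boosted vowel) and
  cohort-scale sweep simulation: three groups (14/18/10 subjects by
  default), alternating stimulus polarity, polarity-locked temporal fine
  structure, a non-inverting envelope component, Gaussian noise, and
  occasional large artifacts. Group effects are injected as standardized
  per-band gain offsets on the formant-range harmonics.
* **`ffrpipe.preprocess`** — 70–2000 Hz Butterworth bandpass (12 dB/octave
  per edge, causal by default), ±30 µV artifact rejection (strict
  exceedance), baseline correction to −30..0 ms, and polarity-subtracted
  averaging `(mean_A − mean_B)/2` over the −30..230 ms epoch.
* **`ffrpipe.spectral`** — whole-stimulus FFT peak refinement, region-wise
  (consonant 20–67 ms, vowel 67–220 ms) zero-padded amplitude spectra, peak
  amplitude extraction in a closed 20 Hz window around each refined peak
  (a peak at 118 Hz is searched in [108, 128] Hz), and classification of
  harmonics H2–H6 into F1-band (400–700 Hz ± 20 Hz → H3–H5) versus non-F1
  (H2, H6) features.
* **`ffrpipe.stats`** — split-plot ANOVA implemented from scratch (group
  between-subjects; time region and spectral component within-subjects;
  each within effect tested against its own effect-by-subject stratum; no
  sphericity correction), per-region models, per-component one-way ANOVAs,
  Fisher LSD post-hocs and Cohen's d.
* **`ffrpipe.cli` / `ffrpipe.config` / `ffrpipe.io` / `ffrpipe.report`** —
  a deterministic five-stage CLI with TOML configuration, plain-text file
  formats, a checksummed run manifest, and summary figures (per-band
  grouped bars with ±1 SEM, per-region grand-average spectra).

## CLI

```bash
ffrpipe init-config my.toml          # write the default configuration
ffrpipe run-all --config my.toml --outdir out   # simulate ... report
# or stage by stage:
ffrpipe simulate   --config my.toml --outdir out
ffrpipe preprocess --config my.toml --outdir out
ffrpipe extract    --config my.toml --outdir out
ffrpipe stats      --config my.toml --outdir out
ffrpipe report     --config my.toml --outdir out
```

Outputs under `--outdir`: `stimulus.wav`, `sweeps/*.txt` (documented
plain-text sweep sets), `cohort_manifest.tsv`, `averaged/*.txt`,
`stimulus_peaks.tsv`, `features.csv`, `results.json`, `figures/*.png`, and
`manifest.json` (config hash + per-file checksums + rejection counts).
Runs are bit-identical under a fixed config and `--seed`.

A quick small-scale run:

```bash
ffrpipe run-all --outdir out --sweeps-per-polarity 100 --seed 1
```

(The full default cohort — 42 subjects × 6000 sweeps at 30 kHz — is large;
reduce `sampling_rate_hz` and `sweeps_per_polarity` in the config for
desk-scale experiments.)

## Library use

```python
import ffrpipe as ffr

spec = ffr.StimulusSpec()                      # frequency/time plan
stim = ffr.synthesize_stimulus(spec)
peaks = ffr.stimulus_peak_frequencies(stim, spec)

cohort = ffr.CohortConfig(sweeps_per_polarity=200, sampling_rate_hz=6000.0)
rows = []
for sid, group, sweeps in ffr.simulate_cohort(cohort, spec):
    avg = ffr.preprocess_sweeps(sweeps)
    rows.append(ffr.compute_features(avg, spec, peaks, sid, group))

from ffrpipe.spectral import features_to_frame
results = ffr.run_paper_analysis(features_to_frame(rows))
```
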