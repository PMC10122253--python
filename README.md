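# tbikit

Quantitative readouts for a **weight-drop *in vitro* traumatic brain
injury (TBI) assay**.  A falling weight transmits a pressure pulse — via
the growth and rapid collapse of an air bubble, a cavitation-like
mechanism — to cells cultured in standard labware.  The injury phenotype
is read out on three platforms, and this package implements the complete
analysis chain for all of them, plus the physics of the stimulus and a
matched synthetic-data generator:

* **MEA electrophysiology** — band-pass filter (300–1100 Hz), spike
  detection at 4.5x the trace SD, active-electrode gating
  (>= 15 spikes/min), burst grouping (>= 3 spikes, inter-spike interval
  <= 300 ms), per-well summaries and percent change versus the pre-injury
  baseline.
* **Live/dead imaging** — Otsu segmentation and size-filtered counting of
  Hoechst/calcein/propidium-iodide fields, dominant-channel live/dead
  classification, covered-area fraction versus control.
* **TEER barrier analysis** — blank-corrected, area-normalized
  trans-endothelial resistance `(R_raw - R_blank) x A` in Ohm*cm^2, with
  condition x timepoint summaries.
* **Biophysics** — drop energy `E = m g h` and velocity `v = sqrt(2 g h)`,
  bubble growth/collapse speeds from radius–time traces, point-sink
  `1/r^2` velocity decay, and a quadratic surface-pressure law `p = C v^2`
  calibrated on the observed (1 m/s, 10 Pa) anchor.
* **Statistics** — one-/two-way ANOVA with Tukey's HSD and the
  conventional significance stars.
* **Synthetic generators** — seeded, bit-reproducible simulators for all
  four modalities whose *injury presets* encode the assay's reported
  effect sizes (24-h firing-rate changes of +1.43 % / −16 % / −35.8 % for
  control / 1x hit / 3x hit; 53.0 / 38.4 / 30 bursts per 5 min; a
  21.5-point viable-percentage deficit after three hits; TEER group means
  from 50.73 to 28.31 Ohm*cm^2).  Every analysis stage is validated by
  recovering these presets from freshly rendered raw data.

Intended users: groups running (or modeling) *in vitro* neurotrauma
assays who need a transparent, scriptable, fully seeded alternative to
spreadsheet/ImageJ/MATLAB one-offs.

## Worked example

Run the end-to-end pipeline (synthesis -> detection -> imaging census ->
TEER table -> physics -> ANOVA) at desk scale:

```sh
tbikit run --out demo_run --seed 1
```

which prints, among other entries (seed 1, 60-s two-well recordings,
~25 s total):

```json
{
  "mea_percent_change": {"control": 0.65, "hit1": -13.99, "hit3": -34.47},
  "mea_bursts_per_5min": {"control": 60.0, "hit1": 25.0, "hit3": 15.0},
  "viability_percent": {"control": 100.0, "hit3": 78.33},
  "viability_deficit_hit3_points": 21.67,
  "teer_ohm_cm2": {"control@1h": {"mean": 45.21, "sd": 0.95, "n": 3},
                   "hit3@24h": {"mean": 22.38, "sd": 5.28, "n": 3}},
  "teer_anova_24h": {"F": 75.39, "p": 1.49e-08},
  "physics": {"impact_energy_j": 0.04325, "impact_velocity_m_s": 1.534,
              "growth_speed_m_s": 0.040, "collapse_to_growth_ratio": 100.0,
              "pressure_at_10_m_s_pa": 1000.0}
}
```

Read it as: the detection chain recovers the programmed firing-rate
changes (−16 % / −35.8 % / +1.43 % in expectation — a 60-s two-well demo
carries a few points of sampling noise, and its tiny burst counts scatter
widely around the 53.0 / 38.4 / 30 per-5-min presets; the multi-seed
reproduction script below is the precise version), the image census
recovers the 21.5-point viability deficit, the TEER table lands on the
programmed group means with a decisive condition effect in the ANOVA, and
the physics report gives the 0.043-J / 1.53-m/s impact, the 40-mm/s
bubble growth with 100x faster collapse, and 1000 Pa at a 10-m/s collapse
velocity from the quadratic pressure law.  Each library call is also
available directly, e.g.:

```python
from tbikit import synth, mea

cfg = synth.RecordingConfig(duration_s=60.0, n_wells=1, seed=7)
rec, truth = synth.simulate_recording(cfg, synth.FiringModel(tonic_rate_hz=2.0))
params = mea.DetectionParams()
trains = mea.detect_spikes(mea.bandpass_filter(rec, params), params)
bursts = [mea.detect_bursts(t) for t in trains]
wells = mea.summarize_wells(trains, bursts, rec.well_map, rec.duration_s)
```

See `docs/methods.md` for the models, parameter choices, and the
generators' scope of validity.

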