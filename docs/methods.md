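# Methods

`tbikit` implements the complete quantitative readout chain of a
weight-drop *in vitro* traumatic-brain-injury (TBI) assay: extracellular
electrophysiology on multi-electrode arrays (MEA), live/dead fluorescence
imaging, trans-endothelial electrical resistance (TEER), and the
biophysics of the injury stimulus itself.  Because no raw data are
deposited for this assay, every analysis stage is validated by *parameter
recovery*: a seeded synthetic generator is programmed with the assay's
reported effect sizes, and the analysis pipeline must recover them from
rendered raw data within sampling error.

## Injury conditions and presets

The assay compares an uninjured **control** with one impact (**hit1**) and
three consecutive impacts (**hit3**), read out pre-injury (0 h) and 1 h /
24 h after the last impact.  An `InjuryPreset` holds, per condition x
timepoint: the firing-rate multiplier versus the same-well baseline, the
expected detected bursts per well per 5-minute recording, the viable cell
fraction, the coverage fraction relative to control, and the TEER group
mean +- SD in Ohm*cm^2.  The default table encodes the reported 24-h
firing-rate changes (control +1.43 %, hit1 -16 %, hit3 -35.8 %, i.e.
multipliers 1.0143 / 0.840 / 0.642), burst rates (53.0 / 38.4 / 30 per
5 min), the 21.5-point viable-percentage deficit of hit3 versus control
(16.9 points versus hit1), and the 1-h and 24-h TEER group values
(50.73 +- 7.40 ... 28.31 +- 7.51 Ohm*cm^2).  Where the assay is only
qualitative — all 1-h electrophysiology, pre-injury TEER, coverage
fractions — the presets carry configurable placeholders (hit3 rate
multiplier 0.80 at 1 h; pre-injury TEER 48 +- 7 Ohm*cm^2; coverage 0.85 /
0.60 / 0.80 / 0.50) that nothing downstream asserts against.

## MEA analysis

* **Filtering.** Zero-phase (forward-backward) Butterworth band-pass,
  300–1100 Hz, order 4.  Zero-phase filtering preserves spike timing;
  linearity holds to ~1e-9 relative.
* **Spike detection.** Threshold at `k x SD` of the entire filtered trace
  per electrode, `k = 4.5`, negative-going crossings by default (an
  absolute-value mode and a robust scale estimate `median(|x|)/0.6745` are
  available but off).  Each continuous sub-threshold excursion yields one
  event aligned to its extremum.  Interpreting the SD base as the whole
  filtered trace (spikes included) makes the threshold mildly
  rate-dependent; at the amplitudes the generator renders (>= 8x noise SD)
  the detection margin is large enough that this does not bias rate
  ratios measurably.
* **Dead time.** 3 ms after each accepted event.  A ~1-ms biphasic
  waveform passed through this zero-phase band-pass rings for 2–3 ms with
  side lobes of roughly a third of the trough amplitude; a 1-ms dead time
  re-detects those lobes as spurious spikes (about +5 % at desk scale,
  and, because the threshold is rate-dependent, a systematic bias in
  percent-change recovery), while at 3 ms the residual lobes sit far below
  threshold for any plausible spike amplitude.
* **Edge guard.** Events within 5 ms of either trace end are discarded:
  the zero-phase filter's startup transient can itself cross threshold.
* **Active electrodes.** >= 15 spikes/min (0.25 Hz), boundary inclusive,
  applied per recording over its full duration.  Only active electrodes
  enter well summaries.
* **Bursts.** Maximal runs of >= 3 spikes with every inter-spike interval
  <= 300 ms.  The boundary is inclusive; a 1-ns absolute slack absorbs
  floating-point representation of "exactly 300 ms".  The detector is
  tested for exact equality against an exhaustive maximal-window oracle.
* **Summaries.** Spikes per active electrode (total / count), bursts per
  well rescaled to a 300-s window.  Wells with no active electrode report
  `nan`, never zero.  Percent change is computed per well against the same
  condition's pre-injury baseline and averaged per condition; the value is
  signed (a decrease is negative).

## Synthetic recordings

Per electrode, events are the union of a background ("tonic") process and
a compound burst process, thinned by a 5-ms refractory period:

* **Tonic, Poisson mode (default).** Homogeneous Poisson.  The drawn
  intensity is dead-time-compensated (`lambda = r / (1 - r rho)`) so the
  realized mean rate equals the nominal rate exactly; without this the
  refractory thinning removes a rate-dependent fraction and realized rates
  are no longer proportional to the preset multiplier.
* **Tonic, quasi-periodic mode.** Jittered-periodic spikes (SD 15 % of the
  period), whose gaps never approach 300 ms at the rates used.  This mode
  backs the burst-recovery experiments: the preset's burst rate is defined
  as *expected detected bursts*, and a Poisson background at
  activity-sustaining rates would contribute chance ISI triples (about
  +3–6 bursts/well/5 min at 0.25–0.5 Hz) that the ISI rule must count,
  biasing recovery.  A quiet quasi-periodic background (default 0.5 Hz)
  keeps every electrode above the 0.25-Hz activity floor while
  contributing essentially no chance triples.
* **Bursts.** Poisson event process; each event carries `3 + G` spikes
  (`G` geometric, truncated at 3x the mean, mean 5 spikes/burst) at a
  fixed 50-ms intra-burst interval — comfortably inside the 300-ms
  detection boundary.  Burst rates are stated per well and split evenly
  over the well's nine electrodes.
* **Waveform.** One Hann-windowed cycle of an 850-Hz sine, negated so the
  trough leads (total width ~1.2 ms), rendered analytically at each
  electrode's sample phase.  The dominant frequency sits inside the
  300–1100 Hz band, so the filtered trough retains 40–60 % of its
  amplitude depending on sampling rate.  Ground-truth times mark the
  trough.  Defaults: noise SD 3 uV, trough -45 uV (15x), six wells of nine
  electrodes, 20-kHz sampling, 5-minute duration.
* **Determinism.** One `numpy` PCG64 generator per recording; identical
  configuration and seed give bit-identical traces and ground truth.

What the generator does *not* emulate: electrode-tissue coupling, spike
waveform diversity or overlap, non-stationary firing, correlated network
activity, 1/f or line noise.  Passing recovery therefore shows the
*analysis chain* is correct and unbiased under the assumed statistics; it
does not certify performance on real recordings.

## Imaging

Cells are counted on a global-threshold (Otsu by default, fixed value
optional) binary mask via connected components, keeping components >= the
area of a 5-um-diameter disk (debris filter, configurable).  Live/dead
assignment compares the mean calcein vs propidium-iodide intensity in a
5-um disk around each centroid; exact ties stay unclassified, and
viability is `100 x live / (live + dead)`.  Coverage is the thresholded
foreground fraction (live channel for viability figures, nuclei as a
brightfield proxy), reported relative to a control image (control =
100 %).

The image generator renders unit-intensity disks (nuclei at 60 % radius)
at non-overlapping random centers with Gaussian background noise, exact
counts (`round(viable_fraction x n)` live), and bounded-retry placement.
For dense confluent fields an overlapping (Boolean-model) mode targets a
covered fraction of `1 - exp(-n pi r^2 / A)`; counting is not meaningful
in that mode.  No point-spread-function optics are simulated.

## TEER

Normalization is `(raw - blank) x membrane_area`, exact and affine in the
raw reading; readings below blank are flagged, not rejected.  The
membrane area is **not stated** by the assay; the default 0.336 cm^2 is a
typical 24-well Transwell insert and is always configurable and logged.
Summaries treat the independent experiment as the replication unit
(inserts averaged first), with pooling optional, mirroring the assay's
three-experiments-by-two-inserts scheme.  The generator draws
`N(mean, sd)` in Ohm*cm^2 and inverts the normalization exactly, so TEER
recovery validates the barrier module end to end.  Blanks are modeled
per plate; a per-timepoint override exists.

## Biophysics

* **Drop kinematics.** Free fall of the 36.74-g cylinder from 12 cm:
  `E = m g h` (0.0433 J), `v = sqrt(2 g h)` (1.53 m/s).  The optional
  rubber-band accelerator is an ideal linear spring whose stored energy
  adds to the balance; stiffness and stretch are user inputs.
* **Bubble kinematics.** The radius-time trace is segmented at its global
  maximum; growth and collapse speeds are least-squares slopes of the two
  segments (collapse ends at the first return to zero).  An optional
  3-point median prefilter absorbs single-sample jitter.  The generator's
  default profile grows at 40 mm/s to 2 mm and collapses 100x faster —
  the top of the observed one-to-two-orders-of-magnitude range,
  configurable.
* **Sink flow.** `v(r) = v_front (R/r)^2`, the point-sink potential-flow
  decay, defined for `r >= R`.
* **Pressure law.** `p = C v^2` with `C` fixed by the observed
  (~1 m/s, 10 Pa) surface-pressure anchor, giving 1000 Pa at the 10 m/s
  instantaneous collapse velocity — both observed anchors lie on the one
  quadratic.  This is a descriptive, dynamic-pressure-like calibration,
  not a cavitation (Rayleigh–Plesset) model, and should not be
  extrapolated far outside the anchored range.

## Statistics

One- or two-way fixed-effects ANOVA (statsmodels OLS, type-II sums of
squares; with two factors the interaction is included) followed by Tukey's
HSD on the group cells at alpha = 0.05, with Tukey–Kramer handling of
unbalanced designs and the conventional star mapping (`* p < 0.05`,
`** p < 0.01`, `*** p < 0.001`, strict boundaries).  When every group is
an exact constant the residual variance is zero and F/q are undefined; a
deterministic jitter of relative size 1e-9 restores a well-defined
(astronomically significant) comparison without perturbing any
non-degenerate analysis.  Tukey quantiles come from the studentized-range
distribution (numerical, no table lookup); the implementation is tested
against an independently coded sums-of-squares/studentized-range oracle.

## Problem sizes and numerical choices

Recovery experiments run at desk scale, chosen so the full suite and the
reproduction script each finish in minutes on one core while keeping the
Monte-Carlo standard error well inside each comparison's tolerance:

* Percent-change recovery: 6 wells x 9 electrodes, 100-s recordings,
  5-kHz sampling, 8-Hz background, 20 seeds (the small +1.43 % control
  effect is an order of magnitude below the hit effects, so it gets 300-s
  recordings and 40 seeds).  The detection
  band needs < 2.5 kHz of bandwidth, so a 5-kHz grid exercises the
  identical chain at a quarter of the cost of the hardware's 20 kHz;
  detector *timing* tests run at 20 kHz.
* Burst recovery: 6 wells, full 300-s recordings, 20 seeds.
* TEER recovery: 3 experiments x 2 inserts x 20 seeds per group.
* Viability recovery: 500 cells per image, 10 seeds.
* Tests use the same experiments at reduced seed counts with
  self-scaling (empirical 95 %-interval) tolerances.

Seeds are explicit everywhere; every CLI run and pipeline run logs its
seed and parameters.  Tolerances: ISI boundary slack 1e-9 s; filter
linearity 1e-9 relative; TEER linearity machine precision; ANOVA oracle
agreement 1e-10.

## Known limitations

* The percent-change experiments assume detection efficiency is
  rate-independent; this holds at the rendered signal-to-noise ratios but
  would degrade near threshold.
* The burst-rate preset is recovered under the quasi-periodic background;
  under a Poisson background of equal rate, the ISI rule genuinely counts
  additional chance triples — a property of the rule, not an artifact.
* The quadratic pressure law is calibration-only; no fluid dynamics are
  solved.
* Axonal-swelling morphometry and proliferation assays are out of scope
  (the assay reports them qualitatively or by kit instructions only).
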