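"""Seeded parameter-recovery experiments.

Each experiment generates synthetic data under an injury preset, runs the
full corresponding analysis chain, and returns the recovered quantity per
seed, so that generator presets can be compared with pipeline output under
sampling error.  These are the validation workhorses behind the test suite
and the reproduction script.

Recordings for the rate experiments default to a 5-kHz sampling grid
(the 300-1100 Hz detection band needs < 2.5 kHz of bandwidth) so that a
full multi-seed recovery runs in minutes on one core; the detection chain
itself is identical at any sampling rate.
"""

from __future__ import annotations

import numpy as np

from . import barrier, imaging, mea, synth
from .presets import InjuryCondition, InjuryPreset, default_presets

__all__ = [
    "recover_percent_change",
    "recover_burst_rates",
    "recover_teer_means",
    "recover_viability_deficit",
    "detection_quality",
]

_CONDITION_SEED_OFFSET = {"control": 0, "hit1": 1, "hit3": 2}


def _analyze(rec: mea.Recording, params: mea.DetectionParams):
    trains = mea.detect_spikes(mea.bandpass_filter(rec, params), params)
    bursts = [mea.detect_bursts(t) for t in trains]
    return trains, bursts


def recover_percent_change(
    label: str,
    seeds,
    timepoint_h: float = 24.0,
    sampling_rate_hz: float = 5000.0,
    duration_s: float = 100.0,
    n_wells: int = 6,
    tonic_rate_hz: float = 8.0,
    presets: dict | None = None,
) -> np.ndarray:
    """Per-seed mean percent change in spikes per active electrode.

    For every seed a pre-injury baseline plate and a post-injury plate
    (firing rates scaled by the preset's multiplier) are simulated, both
    run through band-pass -> 4.5 x SD detection -> active-electrode gating,
    and the per-well percent changes are averaged.  The expectation of the
    result is ``100 x (rate_multiplier - 1)``.
    """
    presets = presets if presets is not None else default_presets()
    preset = presets[(label, timepoint_h)]
    params = mea.DetectionParams()
    firing = synth.FiringModel(tonic_rate_hz=tonic_rate_hz)
    offset = _CONDITION_SEED_OFFSET.get(label, 3) * 10_000_019
    changes = []
    for s in seeds:
        pair = ([], [])
        # one well per simulation keeps the working set small
        for w in range(n_wells):
            for phase, (tp, p) in enumerate(((0.0, None), (timepoint_h, preset))):
                cfg = synth.RecordingConfig(
                    sampling_rate_hz=sampling_rate_hz,
                    duration_s=duration_s,
                    n_wells=1,
                    seed=offset + 1000 * int(s) + 2 * w + phase,
                )
                rec, _ = synth.simulate_recording(cfg, firing, p)
                trains, bursts = _analyze(rec, params)
                pair[phase].extend(
                    mea.summarize_wells(
                        trains, bursts, np.full(rec.n_electrodes, w),
                        rec.duration_s, condition=InjuryCondition(label, tp),
                    )
                )
        per_condition = mea.percent_change(pair[0], pair[1])
        changes.append(per_condition[label])
    return np.asarray(changes)


def recover_burst_rates(
    label: str,
    seeds,
    timepoint_h: float = 24.0,
    sampling_rate_hz: float = 5000.0,
    duration_s: float = 300.0,
    n_wells: int = 6,
    presets: dict | None = None,
) -> np.ndarray:
    """Detected bursts per well per 5 minutes, pooled over seeds.

    Recordings carry the preset's burst process over a quiet quasi-periodic
    background; the detection chain (band-pass, threshold, active gating,
    ISI grouping) recovers ``preset.burst_rate_per_5min`` per well.
    """
    presets = presets if presets is not None else default_presets()
    preset = presets[(label, timepoint_h)]
    params = mea.DetectionParams()
    offset = _CONDITION_SEED_OFFSET.get(label, 3) * 10_000_019
    rates = []
    for s in seeds:
        for w in range(n_wells):
            cfg = synth.RecordingConfig(
                sampling_rate_hz=sampling_rate_hz,
                duration_s=duration_s,
                n_wells=1,
                seed=offset + 40_000_000 + 100 * int(s) + w,
            )
            rec, _ = synth.simulate_recording(
                cfg, synth.burst_firing_from_preset(preset, cfg)
            )
            trains, bursts = _analyze(rec, params)
            summaries = mea.summarize_wells(
                trains, bursts, rec.well_map, rec.duration_s
            )
            rates.extend(s_.bursts_per_5min for s_ in summaries)
    return np.asarray(rates)


def recover_teer_means(
    label: str,
    seeds,
    timepoint_h: float = 24.0,
    n_experiments: int = 3,
    n_inserts: int = 2,
    blank_ohm: float = 300.0,
    area_cm2: float = barrier.DEFAULT_MEMBRANE_AREA_CM2,
    presets: dict | None = None,
) -> np.ndarray:
    """Per-seed recovered group mean of normalized TEER (Ohm*cm^2)."""
    presets = presets if presets is not None else default_presets()
    preset = presets[(label, timepoint_h)]
    offset = _CONDITION_SEED_OFFSET.get(label, 3) * 10_000_019
    means = []
    for s in seeds:
        records = synth.simulate_teer(
            preset,
            n_inserts=n_inserts,
            n_experiments=n_experiments,
            blank_ohm=blank_ohm,
            area_cm2=area_cm2,
            seed=offset + int(s),
        )
        table = barrier.teer_condition_summary(records)
        means.append(float(table.mean_ohm_cm2.iloc[0]))
    return np.asarray(means)


def census_viability(image: imaging.ViabilityImage) -> float:
    """Viable percentage from detection + live/dead classification."""
    centroids, _ = imaging.detect_cells(
        image.channels["nuclei"], image.pixel_size_um
    )
    return imaging.classify_live_dead(image, centroids).viability_percent


def recover_viability_deficit(
    seeds,
    n_cells: int = 500,
    timepoint_h: float = 24.0,
    presets: dict | None = None,
) -> np.ndarray:
    """Per-seed control-minus-hit3 difference in viable percentage."""
    presets = presets if presets is not None else default_presets()
    diffs = []
    for s in seeds:
        v = {}
        for phase, label in enumerate(("control", "hit3")):
            img, _ = synth.simulate_viability_image(
                n_cells,
                presets[(label, timepoint_h)].viable_fraction,
                seed=2 * int(s) + phase,
            )
            v[label] = census_viability(img)
        diffs.append(v["control"] - v["hit3"])
    return np.asarray(diffs)


def detection_quality(
    seeds,
    amplitude_over_noise: float = 8.0,
    noise_sd_uv: float = 3.0,
    sampling_rate_hz: float = 20000.0,
    duration_s: float = 30.0,
    tonic_rate_hz: float = 2.0,
    match_tol_s: float = 0.0005,
) -> tuple[float, float]:
    """Spike-detection precision and recall against generator ground truth.

    Each ground-truth trough is matched to the nearest unclaimed detection
    within ``match_tol_s``.  Returns pooled ``(precision, recall)``.
    """
    params = mea.DetectionParams()
    tp = fp = fn = 0
    for s in seeds:
        cfg = synth.RecordingConfig(
            sampling_rate_hz=sampling_rate_hz,
            duration_s=duration_s,
            n_wells=1,
            noise_sd_uv=noise_sd_uv,
            spike_amplitude_uv=-amplitude_over_noise * noise_sd_uv,
            seed=int(s),
        )
        rec, truth = synth.simulate_recording(
            cfg, synth.FiringModel(tonic_rate_hz=tonic_rate_hz)
        )
        trains, _ = _analyze(rec, params)
        for t_true, train in zip(truth, trains):
            det = train.times_s
            used = np.zeros(len(det), dtype=bool)
            for t in t_true:
                if len(det) == 0:
                    fn += 1
                    continue
                d = np.abs(det - t)
                d[used] = np.inf
                j = int(np.argmin(d))
                if d[j] <= match_tol_s:
                    tp += 1
                    used[j] = True
                else:
                    fn += 1
            fp += int((~used).sum())
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return precision, recall
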