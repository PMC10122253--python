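"""Multi-electrode array spike and burst analysis.

Implements the assay's electrophysiology readout chain: zero-phase
band-pass filtering (300-1100 Hz), amplitude-threshold spike detection at
``k x SD`` of the filtered trace (k = 4.5), the active-electrode rule
(>= 15 spikes/min, i.e. >= 0.25 Hz, boundary inclusive), interspike-interval
burst grouping (>= 3 spikes with every ISI <= 300 ms, inclusive), per-well
summaries (spikes per active electrode, bursts per 5 minutes), and signed
percent change versus the pre-injury baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .presets import InjuryCondition

__all__ = [
    "Recording",
    "DetectionParams",
    "SpikeTrain",
    "Burst",
    "BurstSet",
    "WellSummary",
    "bandpass_filter",
    "detect_spikes",
    "active_electrodes",
    "detect_bursts",
    "summarize_wells",
    "percent_change",
]

#: absolute slack (s) applied to the ISI boundary so that gaps intended to be
#: exactly 300 ms are not rejected by floating-point representation error
_ISI_TOL_S = 1e-9


@dataclass
class Recording:
    """Multichannel extracellular voltage recording.

    traces
        ``(n_electrodes, n_samples)`` array of voltages in microvolts.
    well_map
        Per-electrode well identifier, length ``n_electrodes``.
    """

    traces: np.ndarray
    sampling_rate_hz: float
    well_map: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (electrodes x samples)")
        self.well_map = np.asarray(self.well_map)
        if len(self.well_map) != self.traces.shape[0]:
            raise ValueError("well_map length must match electrode count")
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sampling rate and duration must be positive")
        n_expected = self.duration_s * self.sampling_rate_hz
        if abs(self.traces.shape[1] - n_expected) > 1:
            raise ValueError(
                f"trace length {self.traces.shape[1]} inconsistent with "
                f"duration {self.duration_s} s at {self.sampling_rate_hz} Hz"
            )

    @property
    def n_electrodes(self) -> int:
        return self.traces.shape[0]


@dataclass(frozen=True)
class DetectionParams:
    """Filtering and spike-detection parameters.

    The threshold is ``threshold_k`` times the SD of the entire filtered
    trace of each electrode; ``robust_sd`` switches the scale estimate to
    ``median(|x|)/0.6745``, which is insensitive to the spikes themselves.
    The 3-ms dead time covers the ringing of one ~1-ms waveform through the
    zero-phase band-pass, whose side lobes persist past 1 ms and would
    otherwise be re-detected as spurious events.
    """

    band_low_hz: float = 300.0
    band_high_hz: float = 1100.0
    threshold_k: float = 4.5
    refractory_ms: float = 3.0
    polarity: str = "negative"
    filter_order: int = 4
    robust_sd: bool = False
    #: events this close to either trace end are discarded: the zero-phase
    #: filter's startup transient can itself cross threshold there
    edge_guard_ms: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("require 0 < band_low_hz < band_high_hz")
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be positive")
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be positive")
        if self.polarity not in ("negative", "absolute"):
            raise ValueError("polarity must be 'negative' or 'absolute'")


@dataclass
class SpikeTrain:
    """Sorted spike times (s) for one electrode."""

    electrode: int
    times_s: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1:
            raise ValueError("times_s must be 1-D")
        if len(self.times_s) > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass(frozen=True)
class Burst:
    start_s: float
    end_s: float
    n_spikes: int


@dataclass
class BurstSet:
    """Non-overlapping, maximal bursts detected on one electrode."""

    electrode: int
    bursts: list[Burst] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.bursts)


@dataclass
class WellSummary:
    """Per-well firing summary over the active electrodes.

    Rates are ``nan`` (flagged missing, not zero) when no electrode in the
    well passes the active-electrode rule.
    """

    well: object
    n_active_electrodes: int
    spikes_per_active_electrode: float
    bursts_per_5min: float
    condition: InjuryCondition | None = None


def _design_sos(params: DetectionParams, fs: float) -> np.ndarray:
    if params.band_high_hz >= fs / 2:
        raise ValueError(
            f"band edge {params.band_high_hz} Hz not below Nyquist ({fs / 2} Hz)"
        )
    return signal.butter(
        params.filter_order,
        [params.band_low_hz, params.band_high_hz],
        btype="bandpass",
        fs=fs,
        output="sos",
    )


def bandpass_filter(recording: Recording, params: DetectionParams) -> Recording:
    """Zero-phase band-pass filter all traces of a recording.

    Forward-backward (``sosfiltfilt``) Butterworth filtering preserves trace
    length and spike timing while removing DC and out-of-band components.
    """
    sos = _design_sos(params, recording.sampling_rate_hz)
    filtered = signal.sosfiltfilt(sos, np.asarray(recording.traces, dtype=float), axis=-1)
    return Recording(
        traces=filtered,
        sampling_rate_hz=recording.sampling_rate_hz,
        well_map=recording.well_map,
        duration_s=recording.duration_s,
    )


def _trace_scale(x: np.ndarray, robust: bool) -> float:
    if robust:
        return float(np.median(np.abs(x)) / 0.6745)
    return float(np.std(x))


def detect_spikes(
    filtered: Recording, params: DetectionParams = DetectionParams()
) -> list[SpikeTrain]:
    """Threshold-cross spike detection on band-passed traces.

    For each electrode the threshold is ``threshold_k x SD`` of its entire
    filtered trace.  Each continuous sub-threshold excursion yields one
    event aligned to its extremum; later events within ``refractory_ms`` of
    an accepted one are suppressed.  A zero-variance trace yields an empty
    train.
    """
    fs = filtered.sampling_rate_hz
    dead = params.refractory_ms / 1000.0
    trains: list[SpikeTrain] = []
    for e in range(filtered.n_electrodes):
        x = np.asarray(filtered.traces[e], dtype=float)
        scale = _trace_scale(x, params.robust_sd)
        if scale == 0.0 or not np.isfinite(scale):
            trains.append(SpikeTrain(electrode=e, times_s=np.empty(0)))
            continue
        thr = params.threshold_k * scale
        below = (x < -thr) if params.polarity == "negative" else (np.abs(x) > thr)
        if not below.any():
            trains.append(SpikeTrain(electrode=e, times_s=np.empty(0)))
            continue
        edges = np.diff(below.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if below[0]:
            starts = np.r_[0, starts]
        if below[-1]:
            ends = np.r_[ends, len(x)]
        # vectorized per-excursion extremum: pad every excursion to the
        # longest one and mask samples past its end
        lengths = ends - starts
        offs = np.arange(int(lengths.max()))
        idx = np.minimum(starts[:, None] + offs, len(x) - 1)
        vals = x[idx] if params.polarity == "negative" else -np.abs(x[idx])
        vals = np.where(offs < lengths[:, None], vals, np.inf)
        peak_idx = starts + np.argmin(vals, axis=1)
        guard = int(params.edge_guard_ms / 1000.0 * fs)
        peak_idx = peak_idx[(peak_idx >= guard) & (peak_idx < len(x) - guard)]
        times = peak_idx / fs
        # greedy dead-time suppression, earliest event wins
        kept = []
        last = -np.inf
        for t in times:
            if t - last >= dead:
                kept.append(t)
                last = t
        trains.append(SpikeTrain(electrode=e, times_s=np.array(kept)))
    return trains


def active_electrodes(
    trains: Iterable[SpikeTrain], duration_s: float, min_rate_hz: float = 0.25
) -> list[SpikeTrain]:
    """Keep electrodes firing at >= ``min_rate_hz`` (boundary inclusive).

    The default 0.25 Hz corresponds to the assay's >= 15 spikes/min rule.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    return [t for t in trains if len(t) / duration_s >= min_rate_hz]


def detect_bursts(
    train: SpikeTrain, min_spikes: int = 3, max_isi_s: float = 0.300
) -> BurstSet:
    """Group a spike train into maximal runs with every ISI <= ``max_isi_s``.

    Runs of at least ``min_spikes`` spikes become bursts; the ISI boundary is
    inclusive (a gap of exactly 300 ms stays inside the burst).  Each spike
    belongs to at most one burst and bursts are maximal: the spikes
    immediately before and after any burst are separated from it by more
    than ``max_isi_s``.
    """
    t = train.times_s
    out = BurstSet(electrode=train.electrode)
    if len(t) < min_spikes:
        return out
    short = np.diff(t) <= max_isi_s + _ISI_TOL_S
    i = 0
    n_gaps = len(short)
    while i < n_gaps:
        if short[i]:
            j = i
            while j < n_gaps and short[j]:
                j += 1
            n = j - i + 1  # spikes i..j inclusive
            if n >= min_spikes:
                out.bursts.append(Burst(start_s=t[i], end_s=t[j], n_spikes=n))
            i = j + 1
        else:
            i += 1
    return out


def summarize_wells(
    trains: Sequence[SpikeTrain],
    bursts: Sequence[BurstSet],
    well_map: np.ndarray,
    duration_s: float,
    condition: InjuryCondition | None = None,
    min_rate_hz: float = 0.25,
) -> list[WellSummary]:
    """Per-well summaries over active electrodes.

    ``spikes_per_active_electrode`` is the total spike count on active
    electrodes divided by their number; ``bursts_per_5min`` is the total
    burst count on active electrodes rescaled to a 300-s window.  Wells with
    no active electrode report ``nan`` rates.
    """
    well_map = np.asarray(well_map)
    bursts_by_electrode = {b.electrode: b for b in bursts}
    summaries = []
    for well in dict.fromkeys(well_map.tolist()):  # preserve first-seen order
        in_well = [t for t in trains if well_map[t.electrode] == well]
        active = active_electrodes(in_well, duration_s, min_rate_hz)
        if not active:
            summaries.append(
                WellSummary(well, 0, float("nan"), float("nan"), condition)
            )
            continue
        n_spikes = sum(len(t) for t in active)
        n_bursts = sum(
            len(bursts_by_electrode.get(t.electrode, BurstSet(t.electrode)))
            for t in active
        )
        summaries.append(
            WellSummary(
                well=well,
                n_active_electrodes=len(active),
                spikes_per_active_electrode=n_spikes / len(active),
                bursts_per_5min=n_bursts * (300.0 / duration_s),
                condition=condition,
            )
        )
    return summaries


def percent_change(
    baseline: Sequence[WellSummary], followup: Sequence[WellSummary]
) -> dict[str | None, float]:
    """Signed percent change in spikes per active electrode, per condition.

    Wells are paired by identifier; per-well changes
    ``100 x (followup - baseline) / baseline`` are averaged over the wells
    of each follow-up condition label.  A zero or missing baseline makes the
    well's change undefined (``nan``, with a warning) and it is dropped from
    the average.
    """
    base_by_well = {s.well: s for s in baseline}
    per_condition: dict[str | None, list[float]] = {}
    for f in followup:
        b = base_by_well.get(f.well)
        if b is None:
            raise ValueError(f"well {f.well!r} missing from baseline")
        label = f.condition.label if f.condition is not None else None
        if (
            not np.isfinite(b.spikes_per_active_electrode)
            or b.spikes_per_active_electrode == 0
        ):
            warnings.warn(
                f"well {f.well!r}: baseline rate zero or missing; "
                "percent change undefined"
            )
            change = float("nan")
        else:
            change = (
                100.0
                * (f.spikes_per_active_electrode - b.spikes_per_active_electrode)
                / b.spikes_per_active_electrode
            )
        per_condition.setdefault(label, []).append(change)
    return {
        label: float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
        for label, vals in (
            (label, np.asarray(vals)) for label, vals in per_condition.items()
        )
    }
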