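"""Synthetic assay-data generators with exact ground truth.

Every generator is seeded and bit-reproducible, and returns the ground
truth alongside the rendered data so the downstream analysis modules can be
validated by parameter recovery:

* extracellular MEA recordings -- point-process spike times (background
  firing plus a compound burst process) rendered as ~1-ms biphasic
  templates in additive white Gaussian noise;
* three-channel viability fields -- non-overlapping cell disks split into
  live/dead populations with Gaussian background noise;
* raw Transwell resistance readings -- the exact inverse of the
  blank-correction / area-normalization formula;
* piecewise-linear bubble radius-time traces with a configurable
  collapse-to-growth speed ratio.

Injury presets scale the firing rates; their defaults encode the assay's
reported effect sizes (see :mod:`tbikit.presets`).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .barrier import DEFAULT_MEMBRANE_AREA_CM2, TeerRecord
from .biophysics import BubbleTrace
from .imaging import ViabilityImage
from .mea import Recording
from .presets import InjuryPreset

__all__ = [
    "RecordingConfig",
    "FiringModel",
    "spike_template",
    "simulate_recording",
    "burst_firing_from_preset",
    "simulate_viability_image",
    "simulate_teer",
    "simulate_bubble_trace",
]

#: events are kept away from the trace edges so every ground-truth spike is
#: rendered in full
_EDGE_MARGIN_S = 0.005


@dataclass(frozen=True)
class RecordingConfig:
    """Geometry and acquisition parameters of a simulated MEA recording.

    Defaults mirror the assay hardware: six wells of nine 30-um gold
    electrodes at 200-um pitch, 5-minute recordings sampled at 20 kHz.
    ``spike_amplitude_uv`` is the (negative) trough amplitude of the
    rendered extracellular waveform.
    """

    sampling_rate_hz: float = 20000.0
    duration_s: float = 300.0
    n_wells: int = 6
    electrodes_per_well: int = 9
    electrode_diameter_um: float = 30.0
    electrode_pitch_um: float = 200.0
    noise_sd_uv: float = 3.0
    spike_amplitude_uv: float = -45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sampling rate and duration must be positive")
        if self.n_wells < 1 or self.electrodes_per_well < 1:
            raise ValueError("need at least one well and one electrode")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be non-negative")
        if self.spike_amplitude_uv >= 0:
            raise ValueError("spike_amplitude_uv is a trough: must be negative")


@dataclass(frozen=True)
class FiringModel:
    """Generative firing statistics per electrode.

    Background ("tonic") spikes fire at ``tonic_rate_hz``; burst events
    arrive as a Poisson process at ``burst_event_rate_per_5min`` and each
    carries ``>= 3`` spikes (truncated-geometric count around
    ``spikes_per_burst_mean``) at a fixed ``intra_burst_isi_ms`` spacing,
    well inside the 300-ms detection boundary.  ``tonic_mode`` selects a
    homogeneous Poisson background or a jittered-periodic ("quasi_periodic")
    one whose gaps never fall below ~40 % of the mean period -- the latter
    sustains electrode activity without contributing chance ISI triples
    that would be counted as bursts.
    """

    tonic_rate_hz: float = 2.0
    burst_event_rate_per_5min: float = 0.0
    spikes_per_burst_mean: float = 5.0
    intra_burst_isi_ms: float = 50.0
    refractory_ms: float = 5.0
    tonic_mode: str = "poisson"

    def __post_init__(self) -> None:
        if self.tonic_rate_hz < 0 or self.burst_event_rate_per_5min < 0:
            raise ValueError("rates must be non-negative")
        if self.spikes_per_burst_mean < 3:
            raise ValueError("spikes_per_burst_mean must be >= 3")
        if not 0 < self.intra_burst_isi_ms < 300:
            raise ValueError("intra_burst_isi_ms must lie in (0, 300) ms")
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be positive")
        if self.tonic_mode not in ("poisson", "quasi_periodic"):
            raise ValueError("tonic_mode must be 'poisson' or 'quasi_periodic'")

    def scaled(self, multiplier: float) -> "FiringModel":
        """Tonic and burst rates scaled by a common factor."""
        if multiplier <= 0:
            raise ValueError("multiplier must be positive")
        return FiringModel(
            tonic_rate_hz=self.tonic_rate_hz * multiplier,
            burst_event_rate_per_5min=self.burst_event_rate_per_5min * multiplier,
            spikes_per_burst_mean=self.spikes_per_burst_mean,
            intra_burst_isi_ms=self.intra_burst_isi_ms,
            refractory_ms=self.refractory_ms,
            tonic_mode=self.tonic_mode,
        )


_TEMPLATE_F0_HZ = 850.0  # dominant frequency, inside the 300-1100 Hz band


def spike_template(u: np.ndarray, f0_hz: float = _TEMPLATE_F0_HZ) -> np.ndarray:
    """Unit biphasic waveform (trough then overshoot) on support [0, 1/f0].

    A Hann-windowed single cycle of a ``f0`` sine, negated so the trough
    leads; total width 1/f0 ~ 1.2 ms.  Amplitude is normalized to a trough
    of -1.  Zero outside the support.
    """
    u = np.asarray(u, dtype=float)
    dur = 1.0 / f0_hz
    w = -np.sin(2 * np.pi * f0_hz * u) * 0.5 * (1 - np.cos(2 * np.pi * u / dur))
    w[(u < 0) | (u > dur)] = 0.0
    return w / _template_trough_depth(f0_hz)


@lru_cache(maxsize=8)
def _template_trough_depth(f0_hz: float) -> float:
    fine = np.linspace(0.0, 1.0 / f0_hz, 4001)
    w = -np.sin(2 * np.pi * f0_hz * fine) * 0.5 * (
        1 - np.cos(2 * np.pi * f0_hz * fine)
    )
    return float(-w.min())


@lru_cache(maxsize=8)
def _template_trough_offset(f0_hz: float = _TEMPLATE_F0_HZ) -> float:
    fine = np.linspace(0.0, 1.0 / f0_hz, 4001)
    w = -np.sin(2 * np.pi * f0_hz * fine) * 0.5 * (
        1 - np.cos(2 * np.pi * f0_hz * fine)
    )
    return float(fine[np.argmin(w)])


def _tonic_times(rng, firing: FiringModel, rate: float, t0: float, t1: float):
    span = t1 - t0
    if rate <= 0 or span <= 0:
        return np.empty(0)
    if firing.tonic_mode == "poisson":
        # dead-time compensation: the refractory thinning removes a
        # rate-dependent fraction of a homogeneous process, so the drawn
        # intensity is raised to lambda = r / (1 - r * rho) to make the
        # realized mean rate equal the nominal one (requires r * rho < 1)
        rho = firing.refractory_ms / 1000.0
        if rate * rho >= 0.5:
            raise ValueError(
                "tonic rate too high for the refractory period "
                f"({rate} Hz x {rho * 1e3} ms)"
            )
        lam = rate / (1.0 - rate * rho)
        n = rng.poisson(lam * span)
        return np.sort(rng.uniform(t0, t1, n))
    period = 1.0 / rate
    n = int(span * rate)
    if n == 0:
        return np.empty(0)
    times = t0 + (np.arange(n) + rng.uniform()) * period
    times = times + rng.normal(0.0, 0.15 * period, n)
    times = times[(times >= t0) & (times < t1)]
    return np.sort(times)


def _burst_times(rng, firing: FiringModel, rate_per_5min: float, t0: float, t1: float):
    if rate_per_5min <= 0:
        return np.empty(0)
    isi = firing.intra_burst_isi_ms / 1000.0
    m = firing.spikes_per_burst_mean
    size_cap = max(3, int(np.ceil(3 * m)))
    n_events = rng.poisson(rate_per_5min * (t1 - t0) / 300.0)
    spikes = []
    for _ in range(n_events):
        if m <= 3:
            size = 3
        else:
            size = min(3 + rng.geometric(1.0 / (m - 2.0)) - 1, size_cap)
        max_start = t1 - (size - 1) * isi
        if max_start <= t0:
            continue
        start = rng.uniform(t0, max_start)
        spikes.append(start + np.arange(size) * isi)
    if not spikes:
        return np.empty(0)
    return np.sort(np.concatenate(spikes))


def _thin_refractory(times: np.ndarray, dead_s: float) -> np.ndarray:
    if len(times) == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= dead_s:
            kept.append(t)
    return np.asarray(kept)


def simulate_recording(
    config: RecordingConfig,
    firing: FiringModel,
    preset: InjuryPreset | None = None,
) -> tuple[Recording, list[np.ndarray]]:
    """Render a multichannel recording plus ground-truth spike times.

    Per electrode, spike times are drawn from the firing model (tonic plus
    compound burst process, both rates scaled by ``preset.rate_multiplier``
    when a preset is given), thinned by the model refractory period, and
    rendered as biphasic templates with trough ``spike_amplitude_uv`` in
    white Gaussian noise of SD ``noise_sd_uv``.  Ground-truth times mark the
    template troughs.  Identical configuration and seed give bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    mult = preset.rate_multiplier if preset is not None else 1.0
    fs = config.sampling_rate_hz
    n_samples = int(round(config.duration_s * fs))
    n_electrodes = config.n_wells * config.electrodes_per_well
    t0, t1 = _EDGE_MARGIN_S, config.duration_s - _EDGE_MARGIN_S
    if t1 <= t0:
        raise ValueError("duration too short for edge margins")

    dur = 1.0 / _TEMPLATE_F0_HZ
    trough_off = _template_trough_offset()
    traces = np.empty((n_electrodes, n_samples), dtype=np.float32)
    truth: list[np.ndarray] = []
    for e in range(n_electrodes):
        tonic = _tonic_times(rng, firing, firing.tonic_rate_hz * mult, t0, t1)
        bursty = _burst_times(
            rng, firing, firing.burst_event_rate_per_5min * mult, t0, t1
        )
        times = _thin_refractory(
            np.sort(np.concatenate([tonic, bursty])), firing.refractory_ms / 1000.0
        )
        if config.noise_sd_uv > 0:
            x = rng.standard_normal(n_samples, dtype=np.float32)
            x *= config.noise_sd_uv
        else:
            x = np.zeros(n_samples, dtype=np.float32)
        if len(times):
            starts = times - trough_off
            i0 = np.ceil(starts * fs).astype(np.int64)
            offs = np.arange(int(dur * fs) + 2)
            idx = i0[:, None] + offs  # (n_events, L); template is zero
            u = idx / fs - starts[:, None]  # outside its support
            w = -config.spike_amplitude_uv * spike_template(u)
            keep = (idx >= 0) & (idx < n_samples)
            np.add.at(x, idx[keep], w[keep].astype(np.float32))
        traces[e] = x
        truth.append(times)

    well_map = np.repeat(np.arange(config.n_wells), config.electrodes_per_well)
    rec = Recording(
        traces=traces,
        sampling_rate_hz=fs,
        well_map=well_map,
        duration_s=config.duration_s,
    )
    return rec, truth


def burst_firing_from_preset(
    preset: InjuryPreset,
    config: RecordingConfig,
    tonic_rate_hz: float = 0.5,
) -> FiringModel:
    """Firing model whose expected detected bursts match the preset.

    The per-well burst rate is split evenly over the well's electrodes.  The
    background is quasi-periodic at ``tonic_rate_hz`` so that every
    electrode comfortably clears the 0.25-Hz activity floor while
    contributing essentially no chance ISI triples of its own; the burst
    process is then the only source of detected bursts, and
    ``preset.burst_rate_per_5min`` is recovered directly.  Pass the result
    to :func:`simulate_recording` without a preset (the preset's burst rate
    is already the post-injury value).
    """
    return FiringModel(
        tonic_rate_hz=tonic_rate_hz,
        burst_event_rate_per_5min=(
            preset.burst_rate_per_5min / config.electrodes_per_well
        ),
        tonic_mode="quasi_periodic",
    )


def simulate_viability_image(
    n_cells: int,
    viable_fraction: float,
    field_um: float = 700.0,
    cell_radius_um: float = 5.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    pixel_size_um: float = 1.0,
    allow_overlap: bool = False,
) -> tuple[ViabilityImage, dict]:
    """Render a three-channel live/dead field with exact labels.

    ``round(viable_fraction * n_cells)`` cells are drawn in the live
    channel and the rest in the dead channel; every cell appears in the
    nuclei channel (at 60 % radius, a nuclear stain).  Disks of unit
    amplitude are placed at non-overlapping random centers; Gaussian
    background noise is added and clipped at zero.  Returns the image and a
    ground-truth dict (``centers_px``, ``is_live``, counts).  Raises if the
    requested density cannot be placed within bounded retries.

    ``allow_overlap=True`` switches to a Boolean (overlapping-disk) model
    for dense confluent fields: cell counting is no longer meaningful, but
    the covered-area fraction follows ``1 - exp(-n pi r^2 / A)``, which is
    what the coverage readout measures.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if not 0.0 <= viable_fraction <= 1.0:
        raise ValueError("viable_fraction must lie in [0, 1]")
    if field_um <= 0 or cell_radius_um <= 0 or pixel_size_um <= 0:
        raise ValueError("field, radius and pixel size must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    size = int(round(field_um / pixel_size_um))
    r_px = cell_radius_um / pixel_size_um
    min_sep2 = (2 * r_px + 2.0) ** 2
    margin = r_px + 1.0

    if allow_overlap:
        centers_arr = rng.uniform(margin, size - margin, (n_cells, 2))
    else:
        centers: list[tuple[float, float]] = []
        tries = 0
        max_tries = max(1000, 200 * n_cells)
        while len(centers) < n_cells:
            if tries >= max_tries:
                raise RuntimeError(
                    f"placed only {len(centers)}/{n_cells} cells after "
                    f"{max_tries} tries: density too high for "
                    "non-overlapping placement"
                )
            tries += 1
            c = tuple(rng.uniform(margin, size - margin, 2))
            if all(
                (c[0] - a) ** 2 + (c[1] - b) ** 2 >= min_sep2 for a, b in centers
            ):
                centers.append(c)
        centers_arr = np.asarray(centers).reshape(-1, 2)

    n_live = int(round(viable_fraction * n_cells))
    is_live = np.zeros(n_cells, dtype=bool)
    is_live[rng.permutation(n_cells)[:n_live]] = True

    channels = {k: np.zeros((size, size)) for k in ("nuclei", "live", "dead")}

    def _stamp(img: np.ndarray, center, radius: float) -> None:
        row, col = center
        r0, r1 = int(max(0, row - radius)), int(min(size, row + radius + 1))
        c0, c1 = int(max(0, col - radius)), int(min(size, col + radius + 1))
        rr, cc = np.ogrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1][(rr - row) ** 2 + (cc - col) ** 2 <= radius**2] = 1.0

    for i, c in enumerate(centers_arr):
        _stamp(channels["nuclei"], c, 0.6 * r_px)
        _stamp(channels["live" if is_live[i] else "dead"], c, r_px)
    if noise_sd > 0:
        for k in channels:
            channels[k] = np.clip(
                channels[k] + rng.normal(0.0, noise_sd, (size, size)), 0.0, None
            )

    image = ViabilityImage(channels=channels, pixel_size_um=pixel_size_um)
    truth = {
        "centers_px": centers_arr,
        "is_live": is_live,
        "n_total": n_cells,
        "n_live": n_live,
        "n_dead": n_cells - n_live,
    }
    return image, truth


def simulate_teer(
    preset: InjuryPreset,
    n_inserts: int = 2,
    blank_ohm: float = 300.0,
    area_cm2: float = DEFAULT_MEMBRANE_AREA_CM2,
    seed: int = 0,
    n_experiments: int = 1,
) -> list[TeerRecord]:
    """Raw resistance readings that normalize back to the preset.

    Each reading is ``blank + N(mean, sd) / area`` -- the exact inverse of
    the blank-correction / area-normalization step -- so recovering the
    preset mean validates the barrier module end to end.  Records carry
    experiment and insert identifiers matching the assay's replication
    scheme (independent experiments x technical inserts).
    """
    if n_inserts < 0 or n_experiments < 1:
        raise ValueError("n_inserts must be >= 0 and n_experiments >= 1")
    if blank_ohm <= 0 or area_cm2 <= 0:
        raise ValueError("blank_ohm and area_cm2 must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for exp in range(n_experiments):
        for ins in range(n_inserts):
            teer = rng.normal(preset.teer_mean_ohm_cm2, preset.teer_sd_ohm_cm2)
            records.append(
                TeerRecord(
                    raw_ohm=blank_ohm + teer / area_cm2,
                    blank_ohm=blank_ohm,
                    membrane_area_cm2=area_cm2,
                    condition=preset.condition,
                    insert_id=ins,
                    experiment_id=exp,
                )
            )
    return records


def simulate_bubble_trace(
    growth_speed_mm_s: float = 40.0,
    collapse_factor: float = 100.0,
    r_max_mm: float = 2.0,
    dt_s: float = 1e-4,
    noise_sd_mm: float = 0.0,
    seed: int = 0,
) -> BubbleTrace:
    """Piecewise-linear bubble radius-time trace (SI output units).

    Radius grows linearly at ``growth_speed_mm_s`` to ``r_max_mm`` and
    collapses at ``collapse_factor`` times the growth speed back to zero
    (the default factor of 100 sits at the top of the observed 1-2 orders
    of magnitude).  Optional Gaussian jitter is added to the radii.  Slopes
    recovered from the noiseless trace are exact when the apex lies on the
    sample grid.
    """
    if growth_speed_mm_s <= 0 or r_max_mm <= 0 or dt_s <= 0:
        raise ValueError("speed, r_max and dt must be positive")
    if collapse_factor < 1:
        raise ValueError("collapse_factor must be >= 1 (collapse is faster)")
    if noise_sd_mm < 0:
        raise ValueError("noise_sd_mm must be non-negative")
    t_grow = r_max_mm / growth_speed_mm_s
    t_total = t_grow * (1.0 + 1.0 / collapse_factor)
    times = np.arange(0.0, t_total + dt_s / 2.0, dt_s)
    radius_mm = np.interp(times, [0.0, t_grow, t_total], [0.0, r_max_mm, 0.0])
    if noise_sd_mm > 0:
        rng = np.random.default_rng(seed)
        radius_mm = np.clip(
            radius_mm + rng.normal(0.0, noise_sd_mm, len(times)), 0.0, None
        )
    return BubbleTrace(times_s=times, radius_m=radius_mm * 1e-3)
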