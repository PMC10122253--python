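"""Fluorescence viability and coverage quantification.

Quantifies triple-stained (Hoechst nuclei / calcein-AM live / propidium
iodide dead) fields: global-threshold segmentation with a size filter for
cell counting, dominant-channel live/dead classification around each
centroid, and covered-area fraction relative to a control image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import filters, measure

__all__ = [
    "ViabilityImage",
    "CellCensus",
    "CoverageResult",
    "detect_cells",
    "classify_live_dead",
    "coverage_vs_control",
]

CHANNEL_ORDER = ("nuclei", "live", "dead")

#: default minimum component area: a 5-um-diameter disk, excludes debris
DEFAULT_MIN_AREA_UM2 = np.pi * 2.5**2


@dataclass
class ViabilityImage:
    """Registered three-channel fluorescence field.

    channels
        Mapping with 2-D non-negative intensity arrays for ``nuclei``,
        ``live`` and ``dead``; all channels share one shape.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {k: np.asarray(v).shape for k, v in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for k, v in self.channels.items():
            v = np.asarray(v, dtype=float)
            if v.ndim != 2:
                raise ValueError(f"channel {k!r} must be 2-D")
            if np.any(v < 0):
                raise ValueError(f"channel {k!r} has negative intensities")
            self.channels[k] = v

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class CellCensus:
    """Counts from live/dead classification.

    ``n_live + n_dead <= n_total``: cells with tied channel intensities stay
    unclassified.  ``viability_percent`` is
    ``100 x n_live / (n_live + n_dead)`` (``nan`` when the denominator is 0).
    """

    n_total: int
    n_live: int
    n_dead: int
    viability_percent: float


@dataclass
class CoverageResult:
    covered_fraction: float
    percent_of_control: float


def _threshold(channel: np.ndarray, method) -> float | None:
    """Global threshold; ``None`` signals an unusable (constant) channel."""
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method)
    if method == "otsu":
        if np.ptp(channel) == 0:
            return None
        return float(filters.threshold_otsu(channel))
    raise ValueError(f"unknown threshold method {method!r}")


def detect_cells(
    channel: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    threshold_method="otsu",
) -> tuple[np.ndarray, int]:
    """Count cells in one channel by threshold + connected components.

    Returns ``(centroids, count)`` where centroids are ``(row, col)`` pixel
    coordinates of components with area >= ``min_area_um2``.  A constant
    (blank) channel yields zero cells with a warning.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("channel is empty")
    thr = _threshold(channel, threshold_method)
    if thr is None:
        warnings.warn("constant channel: no cells detected")
        return np.empty((0, 2)), 0
    mask = channel > thr
    labels = measure.label(mask, connectivity=2)
    min_px = min_area_um2 / pixel_size_um**2
    centroids = [
        p.centroid for p in measure.regionprops(labels) if p.area >= min_px
    ]
    return np.asarray(centroids).reshape(-1, 2), len(centroids)


def classify_live_dead(
    image: ViabilityImage,
    centroids: np.ndarray,
    radius_um: float = 5.0,
) -> CellCensus:
    """Assign each detected cell to live or dead by dominant channel signal.

    The mean intensity of the calcein (live) and PI (dead) channels is taken
    over a disk of ``radius_um`` around each centroid; the larger mean wins,
    exact ties stay unclassified.
    """
    live_ch = image.channels["live"]
    dead_ch = image.channels["dead"]
    h, w = live_ch.shape
    r_px = max(1.0, radius_um / image.pixel_size_um)
    n_live = n_dead = 0
    for row, col in np.asarray(centroids).reshape(-1, 2):
        r0, r1 = int(max(0, row - r_px)), int(min(h, row + r_px + 1))
        c0, c1 = int(max(0, col - r_px)), int(min(w, col + r_px + 1))
        rr, cc = np.ogrid[r0:r1, c0:c1]
        disk = (rr - row) ** 2 + (cc - col) ** 2 <= r_px**2
        if not disk.any():
            continue
        m_live = float(live_ch[r0:r1, c0:c1][disk].mean())
        m_dead = float(dead_ch[r0:r1, c0:c1][disk].mean())
        if m_live > m_dead:
            n_live += 1
        elif m_dead > m_live:
            n_dead += 1
    classified = n_live + n_dead
    viability = 100.0 * n_live / classified if classified else float("nan")
    return CellCensus(
        n_total=len(np.asarray(centroids).reshape(-1, 2)),
        n_live=n_live,
        n_dead=n_dead,
        viability_percent=viability,
    )


def covered_fraction(
    image: ViabilityImage, channel: str = "live", threshold_method="otsu"
) -> float:
    """Thresholded foreground fraction of one channel."""
    ch = image.channels[channel]
    thr = _threshold(ch, threshold_method)
    if thr is None:
        return 0.0
    return float(np.mean(ch > thr))


def coverage_vs_control(
    treated: ViabilityImage,
    control: ViabilityImage,
    channel: str = "live",
    threshold_method="otsu",
) -> CoverageResult:
    """Covered-area fraction of the treated image relative to control.

    ``percent_of_control = 100 x covered(treated) / covered(control)``; a
    control with zero coverage makes the ratio undefined (``nan``, warned).
    Use ``channel='nuclei'`` for a brightfield-proxy area readout.
    """
    cov_t = covered_fraction(treated, channel, threshold_method)
    cov_c = covered_fraction(control, channel, threshold_method)
    if cov_c == 0.0:
        warnings.warn("control coverage is zero; percent_of_control undefined")
        return CoverageResult(covered_fraction=cov_t, percent_of_control=float("nan"))
    return CoverageResult(
        covered_fraction=cov_t, percent_of_control=100.0 * cov_t / cov_c
    )
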