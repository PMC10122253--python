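"""Injury conditions and generative effect presets.

The assay compares an uninjured control against one weight-drop impact
(``hit1``) and three consecutive impacts (``hit3``), read out before injury
(0 h) and 1 h / 24 h after the last impact.  Each :class:`InjuryPreset`
bundles the generative parameters the synthetic-data module uses for one
condition x timepoint cell -- firing-rate multiplier versus the same-well
baseline, expected detected bursts per well per 5-minute recording, viable
cell fraction, monolayer coverage relative to control, and the mean +- SD of
area-normalized TEER in Ohm*cm^2.

The default table encodes the published effect sizes for this assay
(24 h firing-rate changes of -16 % / -35.8 % / +1.43 %, burst rates of
53.0 / 38.4 / 30 per 5 min, a 21.5-point viable-fraction deficit after three
hits, and the TEER group means at 1 h and 24 h).  Cells the source reports
only qualitatively (all 1-h electrophysiology, pre-injury TEER) carry
configurable placeholder values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "CONDITION_LABELS",
    "InjuryCondition",
    "InjuryPreset",
    "default_presets",
]

CONDITION_LABELS = ("control", "hit1", "hit3")


@dataclass(frozen=True)
class InjuryCondition:
    """A (condition label, hours after last impact) pair.

    ``timepoint_h == 0`` denotes the pre-injury baseline recording.
    """

    label: str
    timepoint_h: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in CONDITION_LABELS:
            raise ValueError(
                f"label must be one of {CONDITION_LABELS}, got {self.label!r}"
            )
        if self.timepoint_h < 0:
            raise ValueError("timepoint_h must be non-negative")


@dataclass(frozen=True)
class InjuryPreset:
    """Generative effect parameters for one condition x timepoint.

    rate_multiplier
        Firing-rate scale relative to the same condition's pre-injury
        baseline (1.0 = unchanged).
    burst_rate_per_5min
        Expected number of detected bursts per well in a 5-minute recording.
    viable_fraction
        Fraction of cells rendered calcein-positive (live) by the image
        generator.
    coverage_fraction_of_control
        Monolayer covered-area fraction relative to the control image.
    teer_mean_ohm_cm2 / teer_sd_ohm_cm2
        Group mean and SD of blank-corrected, area-normalized TEER.
    """

    condition: InjuryCondition
    rate_multiplier: float = 1.0
    burst_rate_per_5min: float = 53.0
    viable_fraction: float = 1.0
    coverage_fraction_of_control: float = 1.0
    teer_mean_ohm_cm2: float = 48.0
    teer_sd_ohm_cm2: float = 7.0

    def __post_init__(self) -> None:
        if self.rate_multiplier <= 0:
            raise ValueError("rate_multiplier must be positive")
        if self.burst_rate_per_5min < 0:
            raise ValueError("burst_rate_per_5min must be non-negative")
        if not 0.0 <= self.viable_fraction <= 1.0:
            raise ValueError("viable_fraction must lie in [0, 1]")
        if not 0.0 <= self.coverage_fraction_of_control <= 1.0:
            raise ValueError("coverage_fraction_of_control must lie in [0, 1]")
        if self.teer_mean_ohm_cm2 <= 0:
            raise ValueError("teer_mean_ohm_cm2 must be positive")
        if self.teer_sd_ohm_cm2 < 0:
            raise ValueError("teer_sd_ohm_cm2 must be non-negative")

    def with_(self, **changes) -> "InjuryPreset":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def _p(label: str, t: float, **kw) -> tuple[tuple[str, float], InjuryPreset]:
    return (label, t), InjuryPreset(condition=InjuryCondition(label, t), **kw)


def default_presets() -> dict[tuple[str, float], InjuryPreset]:
    """Default preset table keyed by ``(label, timepoint_h)``.

    24-h rate multipliers map the printed percent changes
    (control +1.43 %, hit1 -16 %, hit3 -35.8 %); viable fractions map the
    printed 21.5-point (hit3 vs control) and 16.9-point (hit3 vs hit1)
    deficits onto a control reference of 1.0; TEER means/SDs are the printed
    1-h and 24-h group values.  The hit3 1-h rate multiplier (0.80) is a
    configurable placeholder for the early-onset effect that is shown but
    not quantified; pre-injury TEER (48 +- 7) is likewise a placeholder.
    """
    table = dict(
        (
            # Pre-injury baseline: all conditions share one state.
            _p("control", 0.0),
            _p("hit1", 0.0),
            _p("hit3", 0.0),
            # 1 h after last impact.
            _p("control", 1.0, teer_mean_ohm_cm2=50.73, teer_sd_ohm_cm2=7.40),
            _p(
                "hit1", 1.0,
                viable_fraction=0.97,
                coverage_fraction_of_control=0.85,
                teer_mean_ohm_cm2=35.35, teer_sd_ohm_cm2=5.62,
            ),
            _p(
                "hit3", 1.0,
                rate_multiplier=0.80,
                burst_rate_per_5min=40.0,
                viable_fraction=0.85,
                coverage_fraction_of_control=0.60,
                teer_mean_ohm_cm2=22.45, teer_sd_ohm_cm2=8.64,
            ),
            # 24 h after last impact.
            _p(
                "control", 24.0,
                rate_multiplier=1.0143,
                teer_mean_ohm_cm2=74.64, teer_sd_ohm_cm2=14.45,
            ),
            _p(
                "hit1", 24.0,
                rate_multiplier=0.840,
                burst_rate_per_5min=38.4,
                viable_fraction=0.954,
                coverage_fraction_of_control=0.80,
                teer_mean_ohm_cm2=42.85, teer_sd_ohm_cm2=3.48,
            ),
            _p(
                "hit3", 24.0,
                rate_multiplier=0.642,
                burst_rate_per_5min=30.0,
                viable_fraction=0.785,
                coverage_fraction_of_control=0.50,
                teer_mean_ohm_cm2=28.31, teer_sd_ohm_cm2=7.51,
            ),
        )
    )
    return table
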