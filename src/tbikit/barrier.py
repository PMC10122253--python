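"""TEER barrier analysis for Transwell monolayers.

Raw voltohmmeter readings are blank-corrected and area-normalized to
Ohm*cm^2, then summarized as mean +- SD per condition x timepoint.  The
membrane area is configurable (default 0.336 cm^2, a typical 24-well
Transwell insert).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .presets import CONDITION_LABELS, InjuryCondition

__all__ = ["DEFAULT_MEMBRANE_AREA_CM2", "TeerRecord", "teer_normalize", "teer_condition_summary"]

DEFAULT_MEMBRANE_AREA_CM2 = 0.336


@dataclass
class TeerRecord:
    """One raw Transwell resistance reading.

    ``raw_ohm < blank_ohm`` indicates a compromised (or missing) monolayer;
    it is flagged with a warning during normalization, not rejected.
    """

    raw_ohm: float
    blank_ohm: float
    membrane_area_cm2: float
    condition: InjuryCondition
    insert_id: object = None
    experiment_id: object = None

    def __post_init__(self) -> None:
        if self.raw_ohm <= 0 or self.blank_ohm <= 0:
            raise ValueError("resistances must be positive")
        if self.membrane_area_cm2 <= 0:
            raise ValueError("membrane_area_cm2 must be positive")


def teer_normalize(record: TeerRecord) -> float:
    """Blank-corrected, area-normalized TEER in Ohm*cm^2.

    ``(raw_ohm - blank_ohm) x membrane_area_cm2``; exact and linear in the
    raw reading.  A raw reading below the blank returns a negative value
    with a warning.
    """
    value = (record.raw_ohm - record.blank_ohm) * record.membrane_area_cm2
    if value < 0:
        warnings.warn(
            f"raw reading {record.raw_ohm} below blank {record.blank_ohm}: "
            "negative TEER (monolayer integrity suspect)"
        )
    return value


def teer_condition_summary(
    records: Sequence[TeerRecord],
    by_experiment: bool | None = None,
) -> pd.DataFrame:
    """Mean +- SD table of normalized TEER per condition x timepoint.

    When experiment identifiers are present (and ``by_experiment`` is not
    False) the independent experiment is the replication unit: technical
    inserts are averaged within each experiment first.  Rows are ordered
    control / hit1 / hit3 by ascending timepoint; groups with fewer than two
    replicates report ``nan`` SD with a warning.
    """
    if not records:
        return pd.DataFrame(
            columns=["condition", "timepoint_h", "mean_ohm_cm2", "sd_ohm_cm2", "n"]
        )
    df = pd.DataFrame(
        {
            "condition": [r.condition.label for r in records],
            "timepoint_h": [r.condition.timepoint_h for r in records],
            "experiment": [r.experiment_id for r in records],
            "teer": [teer_normalize(r) for r in records],
        }
    )
    if by_experiment is None:
        by_experiment = df["experiment"].notna().all()
    if by_experiment:
        df = (
            df.groupby(["condition", "timepoint_h", "experiment"], as_index=False)
            .teer.mean()
        )
    grouped = df.groupby(["condition", "timepoint_h"]).teer
    out = grouped.agg(mean_ohm_cm2="mean", sd_ohm_cm2="std", n="count").reset_index()
    for _, row in out.iterrows():
        if row["n"] < 2:
            warnings.warn(
                f"group {row['condition']}@{row['timepoint_h']} h has "
                f"{int(row['n'])} replicate(s): SD undefined"
            )
    order = {label: i for i, label in enumerate(CONDITION_LABELS)}
    out["_o"] = out["condition"].map(lambda c: order.get(c, len(order)))
    out = (
        out.sort_values(["_o", "timepoint_h"])
        .drop(columns="_o")
        .reset_index(drop=True)
    )
    return out
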