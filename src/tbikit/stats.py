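"""Group-comparison layer: ANOVA + Tukey HSD and significance stars.

One- or two-way fixed-effects ANOVA (via statsmodels OLS) followed by
Tukey's multiple-comparison test on the group cells, with alpha = 0.05.
Unbalanced designs use the Tukey-Kramer adjustment (statsmodels default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["AnovaTukeyResult", "anova_tukey", "star_annotation"]

_VALID_FACTORS = ("condition", "timepoint")

#: relative scale of the deterministic jitter applied when every group is an
#: exact constant (zero residual variance makes F/q degenerate otherwise)
_JITTER_REL = 1e-9


@dataclass
class AnovaTukeyResult:
    anova: pd.DataFrame
    tukey: pd.DataFrame
    alpha: float = 0.05


def _maybe_jitter(values: np.ndarray, groups: pd.Series) -> np.ndarray:
    """Break exact within-group degeneracy with a tiny deterministic jitter.

    If every group is constant the residual variance is exactly zero and
    both F and the studentized range are undefined; a fixed-seed jitter of
    relative size 1e-9 restores a well-defined (astronomically significant)
    comparison without perturbing any non-degenerate analysis.
    """
    within_var = pd.Series(values).groupby(groups.values).var(ddof=1)
    if np.nansum(within_var.values) > 0:
        return values
    scale = _JITTER_REL * max(1.0, float(np.max(np.abs(values))))
    rng = np.random.default_rng(0)
    return values + rng.normal(0.0, scale, size=len(values))


def anova_tukey(
    data: pd.DataFrame,
    factors: tuple[str, ...] = ("condition",),
    value_col: str = "value",
    alpha: float = 0.05,
) -> AnovaTukeyResult:
    """Fixed-effects ANOVA with Tukey HSD pairwise comparisons.

    ``data`` needs a ``value`` column plus the factor columns (``condition``
    and/or ``timepoint_h``).  With two factors the model includes main
    effects and their interaction, and Tukey compares all
    condition x timepoint cells; with one factor it compares its levels.
    Groups with fewer than two replicates are excluded with a warning.
    """
    if not factors or not set(factors) <= set(_VALID_FACTORS):
        raise ValueError(f"factors must be a subset of {_VALID_FACTORS}")
    df = data.copy()
    if "timepoint" in factors and "timepoint" not in df.columns:
        df["timepoint"] = df["timepoint_h"]
    cols = list(factors)
    df = df.dropna(subset=[value_col, *cols])

    counts = df.groupby(cols)[value_col].count()
    small = counts[counts < 2]
    if len(small):
        warnings.warn(f"excluding groups with < 2 replicates: {list(small.index)}")
        df = df[~df.set_index(cols).index.isin(small.index)]
    if df.empty or df.groupby(cols).ngroups < 2:
        raise ValueError("need at least two groups with >= 2 replicates")

    group_key = df[cols[0]].astype(str)
    for c in cols[1:]:
        group_key = group_key + "@" + df[c].astype(str)
    df = df.assign(
        _value=_maybe_jitter(df[value_col].to_numpy(dtype=float), group_key),
        _group=group_key.to_numpy(),
    )

    terms = " * ".join(f"C({c})" for c in cols)
    model = smf.ols(f"_value ~ {terms}", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    tk = pairwise_tukeyhsd(df["_value"], df["_group"], alpha=alpha)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    tukey = tukey.rename(columns={"p-adj": "p_adj"})
    for col in ("meandiff", "p_adj", "lower", "upper"):
        tukey[col] = tukey[col].astype(float)
    tukey["stars"] = [star_annotation(p) for p in tukey["p_adj"]]
    return AnovaTukeyResult(anova=anova, tukey=tukey, alpha=alpha)


def star_annotation(p: float) -> str:
    """Map a p-value to the conventional star code.

    ``* p < 0.05``, ``** p < 0.01``, ``*** p < 0.001`` -- boundaries strict,
    so p = 0.05 is ``ns``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
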