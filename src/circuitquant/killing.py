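"""Killing-assay confluence analysis.

Suicide-gene (HSV-TK/ganciclovir) killing assays are read out as confluence
time series per condition.  To correct for pre-drug differences, each series
is background adjusted to the constitutive-HSV-TK reference of the same cell
line at the drug-addition time (46 h by default):

    adjusted_mean(t) = mean(t) + (mean_ref(t_ref) - mean(t_ref)),

a rigid vertical shift that leaves replicate SDs and all within-series
differences unchanged.  Killing strength is summarized as the endpoint fold
change control/condition (larger = stronger killing) with a delta-method SD,
and conditions are compared to the control with one-way ANOVA followed by
Dunnett's many-to-one test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cytometry import FoldChange
from .synthetic import ConfluenceSeries

__all__ = [
    "AdjustedSeries",
    "background_adjust",
    "endpoint_fold",
    "compare_to_control",
    "series_from_frame",
]


@dataclass
class AdjustedSeries(ConfluenceSeries):
    """A confluence series after background adjustment; ``offset`` in % units."""

    offset: float = 0.0


def background_adjust(series: ConfluenceSeries, reference: ConfluenceSeries,
                      t_ref: float = 46.0) -> AdjustedSeries:
    """Shift ``series`` so its mean equals the reference's at ``t_ref``.

    Raises ``KeyError`` when either series lacks the reference time point.
    """
    ref_mean, _ = reference.at(t_ref)
    own_mean, _ = series.at(t_ref)
    offset = ref_mean - own_mean
    return AdjustedSeries(series.condition, series.channel, series.time,
                          series.mean + offset, series.sd.copy(), series.n,
                          offset=offset)


def endpoint_fold(series: ConfluenceSeries, control: ConfluenceSeries,
                  t_end: float = 180.0) -> FoldChange:
    """Endpoint fold change control/condition at ``t_end``.

    Defined so stronger killing (lower condition confluence) gives a larger
    fold.  The SD is propagated from the two endpoint SDs by the delta method.
    A nonpositive condition mean is flagged as an infinite fold.
    """
    c_mean, c_sd = control.at(t_end)
    s_mean, s_sd = series.at(t_end)
    if c_mean <= 0:
        raise ValueError("control mean must be positive at the endpoint")
    if s_mean <= 0:
        return FoldChange(np.inf, np.nan, c_mean, s_mean, finite=False)
    value = c_mean / s_mean
    sd = value * np.sqrt((c_sd / c_mean) ** 2 + (s_sd / s_mean) ** 2)
    return FoldChange(value, float(sd), c_mean, s_mean)


def compare_to_control(conditions: dict[str, np.ndarray],
                       control: np.ndarray) -> pd.DataFrame:
    """One-way ANOVA plus Dunnett's many-to-one comparisons vs the control.

    ``conditions`` maps condition name to replicate endpoint values; returns
    one row per condition with the shared ANOVA F/p and the Dunnett-adjusted
    p-value for that contrast.
    """
    control = np.asarray(control, dtype=float)
    groups = {name: np.asarray(v, dtype=float) for name, v in conditions.items()}
    if control.size < 2 or any(v.size < 2 for v in groups.values()):
        raise ValueError("every group needs at least 2 replicates")
    names = list(groups)
    samples = [groups[n] for n in names]
    anova = stats.f_oneway(*samples, control)
    dunnett = stats.dunnett(*samples, control=control)
    return pd.DataFrame({
        "condition": names,
        "anova_F": float(anova.statistic),
        "anova_p": float(anova.pvalue),
        "statistic": dunnett.statistic,
        "p_adjusted": dunnett.pvalue,
    })


def series_from_frame(df: pd.DataFrame) -> list[ConfluenceSeries]:
    """Read confluence series from a long-format table.

    Expected columns: ``condition, channel, time_h, mean, sd, n``.
    """
    needed = {"condition", "channel", "time_h", "mean", "sd", "n"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"confluence table is missing columns: {sorted(missing)}")
    out = []
    for (cond, chan), grp in df.groupby(["condition", "channel"], sort=False):
        grp = grp.sort_values("time_h")
        out.append(ConfluenceSeries(
            cond, chan,
            grp["time_h"].to_numpy(dtype=float),
            grp["mean"].to_numpy(dtype=float),
            grp["sd"].to_numpy(dtype=float),
            int(grp["n"].iloc[0]),
        ))
    return out
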