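"""Flow-cytometry gating, binning, normalization and fold-change propagation.

Gating proceeds hierarchically: live cells on SSC-A vs FSC-A, singlets on
FSC-H vs FSC-A, true reporter signal by agreement between two detectors of
the same fluorophore, then binning on the transfection-control channel to
keep only highly transfected cells (control > 10^3 by default).

Normalization follows the absolute-units convention

    AU = frequency-of-parent x mean fluorescence among positive cells,
    RU = AU_output / AU_control,

and the dynamic range between ON- and OFF-state wells is a fold change with a
first-order (delta-method) propagated uncertainty

    sd = fold x sqrt((SD_on/mean_on)^2 + (SD_off/mean_off)^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GateConfig",
    "WellSummary",
    "FoldChange",
    "CorrelationResult",
    "gate_live",
    "gate_singlets",
    "gate_true_signal",
    "bin_transfected",
    "apply_gates",
    "summarize_well",
    "fold_change",
    "correlate",
    "output_positive_threshold",
]

_SCATTER_COLS = ("fsc_a", "fsc_h", "ssc_a")


@dataclass(frozen=True)
class GateConfig:
    """Parametric stand-ins for graphically drawn gates.

    The live gate is a rectangle in (FSC-A, SSC-A); singlets satisfy
    |FSC-H/FSC-A - 1| <= ``singlet_band``; true signal requires the two output
    detectors to agree within a factor ``detector_k`` on the log scale after
    removing their median offset.  ``transfection_threshold`` is the strict
    lower bound on the transfection-control channel for the high-transfection
    bin.
    """

    fsc_bounds: tuple[float, float] = (3e4, 4e5)
    ssc_bounds: tuple[float, float] = (2e4, 3e5)
    singlet_band: float = 0.2
    detector_k: float = 3.0
    transfection_threshold: float = 1e3
    output_positive_threshold: float = 100.0
    control_positive_threshold: float = 100.0
    instrument_floor: float = 1.0

    def validate(self) -> None:
        if self.transfection_threshold <= 0:
            raise ValueError("transfection_threshold must be > 0")
        if self.detector_k < 1:
            raise ValueError("detector_k must be >= 1")


@dataclass
class WellSummary:
    """Per-well frequency-of-parent, means, AU and RU for one channel pair."""

    n_parent: int
    freq_output: float
    mean_output: float
    au_output: float
    freq_control: float
    mean_control: float
    au_control: float
    ru: float
    valid: bool = True


@dataclass(frozen=True)
class FoldChange:
    """ON/OFF fold change with delta-method propagated SD."""

    value: float
    sd: float
    mean_on: float = np.nan
    mean_off: float = np.nan
    finite: bool = True


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    r_squared: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    defined: bool = True


def _require(events: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing columns: {missing}")


def gate_live(events: pd.DataFrame, cfg: GateConfig = GateConfig()) -> pd.DataFrame:
    """Set the ``live`` flag for events inside the rectangular scatter gate."""
    _require(events, _SCATTER_COLS)
    events = events.copy()
    flo, fhi = cfg.fsc_bounds
    slo, shi = cfg.ssc_bounds
    events["live"] = (
        (events["fsc_a"] >= flo) & (events["fsc_a"] <= fhi)
        & (events["ssc_a"] >= slo) & (events["ssc_a"] <= shi)
    )
    return events


def gate_singlets(events: pd.DataFrame, cfg: GateConfig = GateConfig()) -> pd.DataFrame:
    """Flag live events whose FSC-H/FSC-A ratio lies within 1 +/- band."""
    _require(events, ("live",))
    events = events.copy()
    fsc_a = events["fsc_a"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fsc_a > 0, events["fsc_h"].to_numpy(dtype=float) / fsc_a, np.inf)
    events["singlet"] = events["live"] & (np.abs(ratio - 1.0) <= cfg.singlet_band)
    return events


def gate_true_signal(events: pd.DataFrame, cfg: GateConfig = GateConfig()) -> pd.DataFrame:
    """Flag singlets whose two output detectors agree on the log scale.

    Both detectors read the same fluorophore; an event is kept when
    |log(d1) - log(d2) - offset| <= log(k), with the offset fit as the median
    log-difference over singlets (absorbing the detectors' gain ratio).
    Nonpositive detector values are floored at the instrument minimum.
    """
    _require(events, ("singlet", "output_d1", "output_d2"))
    events = events.copy()
    d1 = np.maximum(events["output_d1"].to_numpy(dtype=float), cfg.instrument_floor)
    d2 = np.maximum(events["output_d2"].to_numpy(dtype=float), cfg.instrument_floor)
    diff = np.log10(d1) - np.log10(d2)
    singlet = events["singlet"].to_numpy(dtype=bool)
    offset = float(np.median(diff[singlet])) if singlet.any() else 0.0
    events["true_signal"] = singlet & (np.abs(diff - offset) <= math.log10(cfg.detector_k))
    return events


def bin_transfected(events: pd.DataFrame, cfg: GateConfig = GateConfig()) -> pd.DataFrame:
    """Flag gated events with transfection-control signal strictly above threshold."""
    _require(events, ("true_signal", "control"))
    events = events.copy()
    events["transfected_bin"] = events["true_signal"] & (
        events["control"] > cfg.transfection_threshold
    )
    return events


def apply_gates(events: pd.DataFrame, cfg: GateConfig = GateConfig()) -> pd.DataFrame:
    """Run the full gate hierarchy: live -> singlet -> true signal -> bin."""
    cfg.validate()
    return bin_transfected(gate_true_signal(gate_singlets(gate_live(events, cfg), cfg), cfg), cfg)


def output_positive_threshold(untransfected: pd.DataFrame,
                              quantile: float = 0.99,
                              column: str = "output_d1") -> float:
    """Output-positivity threshold as an upper quantile of untransfected events."""
    vals = untransfected[column].to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError("no untransfected events provided")
    return float(np.quantile(vals, quantile))


def summarize_well(events: pd.DataFrame, cfg: GateConfig = GateConfig(),
                   binned: bool = True) -> WellSummary:
    """Compute per-well AU and RU over the fully gated population.

    With ``binned=True`` both the output and control statistics are taken over
    events in the high-transfection bin (control strictly above the
    transfection threshold); with ``binned=False`` over all control-positive
    events.  AU = frequency-of-parent x mean; RU = AU_output / AU_control.
    """
    _require(events, ("true_signal", "transfected_bin", "control", "output_d1"))
    parent = events[events["true_signal"]]
    n_parent = len(parent)
    if n_parent == 0:
        return WellSummary(0, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                           np.nan, valid=False)
    ctrl_thr = cfg.transfection_threshold if binned else cfg.control_positive_threshold
    ctrl_sel = parent[parent["control"] > ctrl_thr]
    out_sel = ctrl_sel[ctrl_sel["output_d1"] > cfg.output_positive_threshold]

    freq_out = len(out_sel) / n_parent
    mean_out = float(out_sel["output_d1"].mean()) if len(out_sel) else 0.0
    au_out = freq_out * mean_out
    freq_ctrl = len(ctrl_sel) / n_parent
    mean_ctrl = float(ctrl_sel["control"].mean()) if len(ctrl_sel) else 0.0
    au_ctrl = freq_ctrl * mean_ctrl

    if au_ctrl > 0:
        return WellSummary(n_parent, freq_out, mean_out, au_out,
                           freq_ctrl, mean_ctrl, au_ctrl, au_out / au_ctrl)
    return WellSummary(n_parent, freq_out, mean_out, au_out,
                       freq_ctrl, mean_ctrl, au_ctrl, np.nan, valid=False)


def fold_change(on_values, off_values) -> FoldChange:
    """ON/OFF fold change of replicate means with propagated uncertainty.

    value = mean_on / mean_off and
    sd = value * sqrt((SD_on/mean_on)^2 + (SD_off/mean_off)^2), with sample
    SDs (n-1 denominator; zero for a single replicate).  A zero OFF mean is
    flagged as an infinite dynamic range rather than raising.
    """
    on = np.asarray(on_values, dtype=float)
    off = np.asarray(off_values, dtype=float)
    if on.size == 0 or off.size == 0:
        raise ValueError("at least one replicate required per state")
    mean_on, mean_off = float(on.mean()), float(off.mean())
    sd_on = float(on.std(ddof=1)) if on.size > 1 else 0.0
    sd_off = float(off.std(ddof=1)) if off.size > 1 else 0.0
    if mean_off == 0:
        return FoldChange(np.inf, np.nan, mean_on, mean_off, finite=False)
    value = mean_on / mean_off
    cv2 = 0.0
    if mean_on != 0:
        cv2 += (sd_on / mean_on) ** 2
    cv2 += (sd_off / mean_off) ** 2
    return FoldChange(value, abs(value) * math.sqrt(cv2), mean_on, mean_off)


def correlate(x, y) -> CorrelationResult:
    """Pearson (reported as R^2) and Spearman correlation of paired values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with >= 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, np.nan, defined=False)
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(float(pr.statistic), float(pr.statistic) ** 2,
                             float(pr.pvalue), float(sr.statistic), float(sr.pvalue))
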