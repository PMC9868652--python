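"""Windowed temporal means at fixed pre-diagnosis anchors and the
normal-range-adjusted slope.

At each anchor (0, 3, 6, 12 months before the index date by default) a
patient's value is the mean of measurements recorded within ±2 months of
that anchor. A linear regression of the anchor means against time —
oriented so that approaching diagnosis is the positive direction — gives
a slope in value/month, which is normalized by the diagonal slope of the
variable's normal-range window, (high − low) / anchor span, to make
slopes comparable across variables with different reference intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import DAYS_PER_MONTH

__all__ = ["NormalRange", "TrendEstimate", "windowed_means", "adjusted_slope",
           "group_trends"]


@dataclass
class NormalRange:
    variable_id: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"normal range requires low < high, got "
                             f"({self.low}, {self.high})")


@dataclass
class TrendEstimate:
    variable_id: str
    anchors: list[float]
    means: dict[float, float]
    coefficient: float            # value per month approaching diagnosis
    coefficient_adjusted: float   # dimensionless


def windowed_means(
    records: pd.DataFrame,
    cohort: pd.DataFrame,
    anchors: tuple[float, ...] = (0.0, 3.0, 6.0, 12.0),
    half_window: float = 2.0,
) -> pd.DataFrame:
    """Per-patient, per-variable mean value near each anchor month.

    Anchor ``m`` collects pre-diagnosis measurements whose
    months-before-index lies within ``half_window`` of ``m`` (inclusive;
    adjacent anchor windows may overlap). Absent combinations are simply
    missing rows — these feed regressions, not the network, so no
    zero-filling here.
    """
    known = set(cohort["patient_id"])
    unknown = set(records["patient_id"]) - known
    if unknown:
        raise ValueError(f"records reference unknown patient(s): "
                         f"{sorted(unknown)[:5]}")
    pre = records[records["t_days"] < 0]
    months_before = -pre["t_days"].to_numpy() / DAYS_PER_MONTH
    frames = []
    for m in anchors:
        sel = np.abs(months_before - m) <= half_window
        sub = pre[sel]
        if sub.empty:
            continue
        g = (sub.groupby(["patient_id", "variable_id"])["value"]
                .mean().reset_index())
        g["anchor"] = m
        frames.append(g)
    if not frames:
        return pd.DataFrame(columns=["patient_id", "variable_id", "value", "anchor"])
    return pd.concat(frames, ignore_index=True)


def adjusted_slope(
    anchor_means: dict[float, float] | pd.Series,
    normal_range: NormalRange,
    variable_id: str | None = None,
) -> TrendEstimate:
    """OLS slope of the anchor means, normalized by the normal-range
    diagonal.

    The time axis is months-to-diagnosis reversed (so rising values on
    the approach to diagnosis give a positive coefficient); the adjusted
    coefficient divides by ``(high - low) / (max anchor - min anchor)``.
    A series climbing exactly from ``low`` to ``high`` across the anchor
    span therefore scores 1.
    """
    if isinstance(anchor_means, pd.Series):
        anchor_means = {float(k): float(v) for k, v in anchor_means.items()}
    items = sorted((m, v) for m, v in anchor_means.items() if np.isfinite(v))
    if len(items) < 2:
        raise ValueError("need >= 2 non-missing anchor means for a slope")
    months = np.array([m for m, _ in items], dtype=float)
    vals = np.array([v for _, v in items], dtype=float)
    x = -months                       # approaching diagnosis = positive
    coef = float(np.polyfit(x, vals, 1)[0])
    span = months.max() - months.min()
    diagonal = (normal_range.high - normal_range.low) / span
    return TrendEstimate(
        variable_id=variable_id or normal_range.variable_id,
        anchors=list(months),
        means=dict(items),
        coefficient=coef,
        coefficient_adjusted=coef / diagonal,
    )


def group_trends(
    records: pd.DataFrame,
    cohort: pd.DataFrame,
    normal_ranges: pd.DataFrame,
    anchors: tuple[float, ...] = (0.0, 3.0, 6.0, 12.0),
    half_window: float = 2.0,
) -> pd.DataFrame:
    """Case/control group-level trends for every variable.

    The group trend regresses the per-anchor group means (mean of the
    patient means) on the anchor months; returns tidy rows
    ``(variable_id, group, coefficient, coefficient_adjusted)``.
    """
    wm = windowed_means(records, cohort, anchors, half_window)
    labels = cohort.set_index("patient_id")["label"]
    wm = wm.assign(group=labels.reindex(wm["patient_id"]).to_numpy())
    ranges = {r.variable_id: NormalRange(r.variable_id, r.low, r.high)
              for r in normal_ranges.itertuples()}
    rows = []
    for (vid, grp), sub in wm.groupby(["variable_id", "group"]):
        means = sub.groupby("anchor")["value"].mean()
        if len(means) < 2 or vid not in ranges:
            continue
        est = adjusted_slope(means, ranges[vid], variable_id=vid)
        rows.append({
            "variable_id": vid, "group": grp,
            "coefficient": est.coefficient,
            "coefficient_adjusted": est.coefficient_adjusted,
        })
    return pd.DataFrame(rows)
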