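"""Promoter-strength quantification from bioluminescence plate-reader runs.

Light emission of a lux reporter fusion is normalized to culture density,

    RLU(t) = Light_AU(t) / OD565_AU(t),

and the curve maximum (RLU_max, after median smoothing against detector
spikes) is the promoter-strength statistic.  A promoter is *active* when its
RLU_max strictly exceeds that of a promoterless control cassette measured in
the same run — the control's residual signal (read-through from neighboring
promoters) is treated as a reproducible background threshold, not
subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import median_filter

from .io_formats import WellSeries

__all__ = [
    "PromoterActivity",
    "compute_rlu",
    "rlu_max",
    "call_active",
    "relative_strength",
    "compare_groups",
    "summarize_plate",
]


@dataclass
class PromoterActivity:
    label: str
    well_id: str
    time_h: np.ndarray
    rlu_series: np.ndarray      # NaN where masked
    mask: np.ndarray            # True = usable timepoint
    rlu_max: float | None = None
    t_max: float | None = None
    active: bool | None = None


def compute_rlu(series: WellSeries, od_floor: float = 0.01) -> PromoterActivity:
    """Per-timepoint RLU = light / OD, masking timepoints with OD below
    ``od_floor`` (early sparse cultures make the ratio blow up)."""
    mask = series.od565 >= od_floor
    if not mask.any():
        raise ValueError(f"well {series.well_id!r}: no usable timepoints (all OD < {od_floor})")
    rlu = np.full(len(series), np.nan)
    rlu[mask] = series.light_au[mask] / series.od565[mask]
    return PromoterActivity(
        label=series.label,
        well_id=series.well_id,
        time_h=series.time_h,
        rlu_series=rlu,
        mask=mask,
    )


def rlu_max(activity: PromoterActivity, smooth_window: int = 3) -> tuple[float, float]:
    """Maximum of the median-smoothed RLU curve and its time (earliest on ties).

    The rolling median (odd ``smooth_window``) removes isolated detector
    spikes without shifting a sustained maximum.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    vals = activity.rlu_series[activity.mask]
    times = activity.time_h[activity.mask]
    if len(vals) < smooth_window:
        raise ValueError(
            f"well {activity.well_id!r}: need >= {smooth_window} unmasked points, have {len(vals)}"
        )
    smooth = median_filter(vals, size=smooth_window, mode="nearest") if smooth_window > 1 else vals
    idx = int(np.argmax(smooth))
    activity.rlu_max = float(smooth[idx])
    activity.t_max = float(times[idx])
    return activity.rlu_max, activity.t_max


def call_active(promoter_rlu_max: float, control_rlu_max: float) -> bool:
    """Strictly exceeding the promoterless-control RLU_max counts as active."""
    return promoter_rlu_max > control_rlu_max


def relative_strength(
    a_rlu_max_values,
    b_rlu_max_values,
    from_ranges: bool = False,
) -> float:
    """Mean RLU_max of A as a percentage of mean RLU_max of B.

    With ``from_ranges=True`` each argument is a (low, high) printed range
    and its midpoint is used — an approximation for comparing against
    published ranges when per-replicate values are unavailable.
    """
    if from_ranges:
        a_mean = (a_rlu_max_values[0] + a_rlu_max_values[1]) / 2
        b_mean = (b_rlu_max_values[0] + b_rlu_max_values[1]) / 2
    else:
        a = np.asarray(a_rlu_max_values, dtype=float)
        b = np.asarray(b_rlu_max_values, dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError("need at least one value per group")
        a_mean, b_mean = float(a.mean()), float(b.mean())
    if b_mean == 0:
        raise ValueError("reference group mean is zero")
    return 100.0 * a_mean / b_mean


def compare_groups(x, y, method: str = "welch_t") -> tuple[float, float]:
    """Two-group comparison: Welch's unequal-variance t or Kruskal-Wallis.

    Returns (statistic, two-sided p).  Degenerate Welch input (zero
    variance in both groups, equal means) yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method == "welch_t":
        if len(x) < 2 or len(y) < 2:
            raise ValueError("Welch t test needs >= 2 observations per group")
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
            if x.mean() == y.mean():
                return 0.0, 1.0
            return float("inf") * np.sign(x.mean() - y.mean()), 0.0
        res = stats.ttest_ind(x, y, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if method == "kruskal_wallis":
        if len(x) < 1 or len(y) < 1 or len(x) + len(y) < 3:
            raise ValueError("Kruskal-Wallis needs >= 1 per group and >= 3 total")
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            return 0.0, 1.0
        res = stats.kruskal(x, y)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}; use 'welch_t' or 'kruskal_wallis'")


def summarize_plate(
    series_list: list[WellSeries],
    control_label: str,
    od_floor: float = 0.01,
    smooth_window: int = 3,
) -> "pd.DataFrame":
    """Per-label activity table from a plate run.

    Each well yields one RLU_max; labels aggregate replicate wells.  The
    activity threshold is the maximum RLU_max observed among the control
    label's wells, applied with strict inequality to the per-label mean.
    """
    import pandas as pd

    per_label: dict[str, list[tuple[float, float]]] = {}
    for s in series_list:
        act = compute_rlu(s, od_floor=od_floor)
        per_label.setdefault(s.label, []).append(rlu_max(act, smooth_window=smooth_window))
    if control_label not in per_label:
        raise ValueError(
            f"control label {control_label!r} not found; available: {sorted(per_label)}"
        )
    threshold = max(v for v, _t in per_label[control_label])
    rows = []
    for label, vals in sorted(per_label.items()):
        maxima = [v for v, _t in vals]
        mean_max = float(np.mean(maxima))
        rows.append(
            {
                "label": label,
                "n_replicates": len(vals),
                "rlu_max_mean": mean_max,
                "rlu_max_sd": float(np.std(maxima, ddof=1)) if len(vals) > 1 else 0.0,
                "t_max_mean": float(np.mean([t for _v, t in vals])),
                "active": bool(call_active(mean_max, threshold)) and label != control_label,
            }
        )
    return pd.DataFrame(rows)
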