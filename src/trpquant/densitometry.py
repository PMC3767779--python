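"""Quantitative Western-blot computations.

Lane signals are integrated band densities (sum of pixel intensities, net
of background, as produced by the imaging software).  The phosphospecific
signal of a lane is normalized by the generic-antibody (total protein)
signal of the same sample; comparisons across genotypes or timepoints are
expressed relative to a control lane on the same membrane, which cancels
membrane-specific antibody gains and exposure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DensitometryError",
    "LinearityReport",
    "normalize_lane",
    "lane_ratios",
    "linearity_check",
    "relative_phosphorylation",
    "timecourse_normalize",
    "sem",
]


class DensitometryError(ValueError):
    pass


@dataclass
class LinearityReport:
    """OLS fit of band signal against loaded protein amount."""

    signal: str
    slope: float
    intercept: float
    r_squared: float
    passed: bool
    threshold: float


def sem(values: np.ndarray | Sequence[float]) -> float:
    """Standard error of the mean: sample SD / sqrt(k)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    return float(np.std(v, ddof=1) / np.sqrt(v.size))


def normalize_lane(phospho_signal: float, total_signal: float, lane_id: str = "?") -> float:
    """Phospho/total signal ratio of one lane."""
    if total_signal <= 0:
        raise DensitometryError(
            f"lane {lane_id}: total signal must be positive, got {total_signal}"
        )
    if phospho_signal < 0:
        raise DensitometryError(f"lane {lane_id}: negative phospho signal")
    return float(phospho_signal) / float(total_signal)


def lane_ratios(panel: pd.DataFrame) -> pd.DataFrame:
    """Panel with a ``ratio`` column (phospho/total per lane)."""
    out = panel.copy()
    out["ratio"] = [
        normalize_lane(p, t, str(l))
        for p, t, l in zip(panel["phospho_signal"], panel["total_signal"], panel["lane_id"])
    ]
    return out


def linearity_check(
    panel: pd.DataFrame,
    signal: str = "total_signal",
    threshold: float = 0.95,
    force_zero_intercept: bool = False,
) -> LinearityReport:
    """Signal-vs-amount linearity QC on a dilution series.

    Ordinary least squares of ``signal`` on ``heads_loaded``; r² is the
    squared Pearson correlation (0 for a flat response).  Passes when
    r² meets the threshold (default 0.95).
    """
    x = panel["heads_loaded"].to_numpy(dtype=float)
    y = panel[signal].to_numpy(dtype=float)
    if np.unique(x).size < 3:
        raise DensitometryError(
            f"linearity check needs >= 3 distinct amounts, got {np.unique(x).size}"
        )
    if np.ptp(y) == 0.0:
        slope, intercept, r2 = 0.0, float(y[0]), 0.0
    elif force_zero_intercept:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        ss_res = float(np.sum((y - slope * x) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
    else:
        fit = stats.linregress(x, y)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    return LinearityReport(signal, slope, intercept, r2, bool(r2 >= threshold), threshold)


def relative_phosphorylation(
    panel: pd.DataFrame,
    control: tuple[str, str] = ("wt", "light"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-lane phosphorylation relative to a same-membrane control (= 100%).

    Each lane's phospho/total ratio is divided by the mean ratio of the
    control genotype × condition lanes on its own membrane; signals from
    different membranes are never compared directly.  Returns the per-lane
    table and a per-(genotype, condition) summary with mean ± SEM across
    membranes (lanes are first averaged within a membrane).
    """
    ctrl_gt, ctrl_cond = control
    with_ratio = lane_ratios(panel)
    pct = np.full(len(with_ratio), np.nan)
    for membrane, idx in with_ratio.groupby("membrane_id").groups.items():
        sub = with_ratio.loc[idx]
        ctrl = sub[(sub["genotype"] == ctrl_gt) & (sub["condition"] == ctrl_cond)]
        if ctrl.empty:
            raise DensitometryError(
                f"membrane {membrane}: no control lane ({ctrl_gt}, {ctrl_cond})"
            )
        ctrl_ratio = float(ctrl["ratio"].mean())
        if ctrl_ratio <= 0:
            raise DensitometryError(f"membrane {membrane}: control ratio is zero")
        pct[with_ratio.index.get_indexer(idx)] = 100.0 * sub["ratio"] / ctrl_ratio
    with_ratio["relative_phospho_pct"] = pct

    per_membrane = (
        with_ratio.groupby(["genotype", "condition", "membrane_id"], sort=True)[
            "relative_phospho_pct"
        ]
        .mean()
        .reset_index()
    )
    summary = (
        per_membrane.groupby(["genotype", "condition"], sort=True)["relative_phospho_pct"]
        .agg(mean_pct="mean", sem_pct=sem, n_membranes="count")
        .reset_index()
    )
    return with_ratio, summary


def timecourse_normalize(
    panel: pd.DataFrame,
    anchor: float,
    anchor_condition: str | None = None,
) -> pd.DataFrame:
    """Time-course phosphorylation with the anchor timepoint set to 100%.

    Per membrane (= replicate), every timepoint's phospho/total ratio is
    divided by that membrane's anchor-timepoint ratio; per-timepoint
    results are then averaged across membranes (mean ± SEM).  A pooled
    variant (anchoring the across-membrane mean ratios) is reported
    alongside.
    """
    with_ratio = lane_ratios(panel)
    if anchor_condition is not None:
        anchor_mask = (with_ratio["timepoint"] == anchor) & (
            with_ratio["condition"] == anchor_condition
        )
    else:
        anchor_mask = with_ratio["timepoint"] == anchor
    if not anchor_mask.any():
        raise DensitometryError(f"anchor timepoint {anchor} not present in panel")

    rows = []
    for membrane, sub in with_ratio.groupby("membrane_id"):
        a = sub[anchor_mask.loc[sub.index]]
        if a.empty:
            raise DensitometryError(
                f"membrane {membrane}: anchor timepoint {anchor} missing"
            )
        a_ratio = float(a["ratio"].mean())
        if a_ratio <= 0:
            raise DensitometryError(f"membrane {membrane}: anchor ratio is zero")
        for _, lane in sub.iterrows():
            rows.append(
                {
                    "membrane_id": membrane,
                    "condition": lane["condition"],
                    "timepoint": lane["timepoint"],
                    "pct": 100.0 * lane["ratio"] / a_ratio,
                }
            )
    per_rep = pd.DataFrame(rows)
    summary = (
        per_rep.groupby(["condition", "timepoint"], sort=True)["pct"]
        .agg(mean_pct="mean", sem_pct=sem, n="count")
        .reset_index()
    )
    # pooled alternative: mean ratios across membranes, then anchored
    pooled_ratio = (
        with_ratio.groupby(["condition", "timepoint"], sort=True)["ratio"].mean()
    )
    if anchor_condition is not None:
        pooled_anchor = float(pooled_ratio.loc[(anchor_condition, anchor)])
    else:
        pooled_anchor = float(
            with_ratio.loc[with_ratio["timepoint"] == anchor, "ratio"].mean()
        )
    summary["pooled_pct"] = [
        100.0 * pooled_ratio.loc[(c, t)] / pooled_anchor
        for c, t in zip(summary["condition"], summary["timepoint"])
    ]
    return summary
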