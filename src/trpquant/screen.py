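"""Candidate-screen hit calling for TRP kinase/phosphatase mutants.

The screen compares each mutant's relative TRP phosphorylation at T849 and
T864 (light-adapted wild type on the same blot = 100%) against literal
fold-change boundaries: up-regulation of at least 2-fold (inclusive) or
down-regulation below 0.5-fold (exclusive) in any site × light condition
makes an initial hit.  Initial hits are rescreened to three experiments
total; confirmation requires the fold criterion to hold on the mean and,
in the default mode, a two-sided one-sample t-test against 100% at
α = 0.05 ("threshold" mode drops the test).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .densitometry import sem

__all__ = [
    "ScreenError",
    "UP_FOLD",
    "DOWN_FOLD",
    "screen_records_from_panel",
    "call_initial_hits",
    "confirm_hits",
    "summarize_screen",
]

UP_FOLD = 2.0
DOWN_FOLD = 0.5


class ScreenError(ValueError):
    pass


def _is_hit(fold: float, up: float = UP_FOLD, down: float = DOWN_FOLD) -> bool:
    """Literal boundary semantics: >= up is a hit, < down is a hit."""
    return fold >= up or fold < down


def screen_records_from_panel(panel: pd.DataFrame, wt: str = "wt") -> pd.DataFrame:
    """Per-mutant relative phosphorylation from raw screen blot signals.

    Every membrane carries the mutant lane and a wild-type control lane;
    the record value is 100 × (mutant phospho/total) / (wt phospho/total),
    which cancels membrane-specific gains.
    """
    recs = []
    for membrane, sub in panel.groupby("membrane_id", sort=True):
        ctrl = sub[sub["genotype"] == wt]
        test = sub[sub["genotype"] != wt]
        if ctrl.empty or test.empty:
            raise ScreenError(f"membrane {membrane}: needs a wt and a mutant lane")
        ctrl_ratio = float((ctrl["phospho_signal"] / ctrl["total_signal"]).mean())
        if ctrl_ratio <= 0:
            raise ScreenError(f"membrane {membrane}: wild-type ratio is zero")
        for _, lane in test.iterrows():
            ratio = float(lane["phospho_signal"]) / float(lane["total_signal"])
            recs.append(
                {
                    "mutant_id": lane["mutant_id"],
                    "site_id": lane["site_id"],
                    "condition": lane["condition"],
                    "stage": lane["stage"],
                    "replicate": int(lane["replicate"]),
                    "relative_phospho_pct": 100.0 * ratio / ctrl_ratio,
                }
            )
    return pd.DataFrame(recs)


def call_initial_hits(
    records: pd.DataFrame,
    up: float = UP_FOLD,
    down: float = DOWN_FOLD,
) -> pd.DataFrame:
    """Initial-screen hit calls, one row per mutant × site × condition.

    Uses stage == "initial" rows when a stage column is present.  The fold
    change is relative_phospho_pct / 100; a mutant is an initial hit if any
    of its cells crosses a boundary.
    """
    df = records
    if "stage" in df.columns:
        df = df[df["stage"] == "initial"]
    if df.empty:
        return pd.DataFrame(
            columns=["mutant_id", "site_id", "condition", "fold_change", "hit", "initial_hit"]
        )
    cells = (
        df.groupby(["mutant_id", "site_id", "condition"], sort=True)["relative_phospho_pct"]
        .mean()
        .reset_index()
    )
    cells["fold_change"] = cells["relative_phospho_pct"] / 100.0
    cells["hit"] = [_is_hit(f, up, down) for f in cells["fold_change"]]
    any_hit = cells.groupby("mutant_id")["hit"].transform("any")
    cells["initial_hit"] = any_hit
    return cells.drop(columns=["relative_phospho_pct"])


def initial_hit_mutants(initial_calls: pd.DataFrame) -> list[str]:
    """Sorted ids of mutants flagged in the initial screen."""
    if initial_calls.empty:
        return []
    return sorted(initial_calls.loc[initial_calls["initial_hit"], "mutant_id"].unique())


def confirm_hits(
    records: pd.DataFrame,
    initial_hits: Sequence[str],
    n_required: int = 3,
    mode: str = "ttest",
    alpha: float = 0.05,
    up: float = UP_FOLD,
    down: float = DOWN_FOLD,
) -> pd.DataFrame:
    """Rescreen confirmation of initial hits (three experiments per mutant).

    Per mutant × site × condition: mean and SEM of the replicate relative
    phosphorylation, the fold change of the mean, its direction, and the
    confirmation verdict — fold criterion on the mean AND (in "ttest" mode)
    a two-sided one-sample t-test against 100% with p < α.  Mutants with
    fewer than ``n_required`` rescreen replicates are flagged
    ``unconfirmable`` rather than dropped.
    """
    if mode not in ("ttest", "threshold"):
        raise ScreenError(f"unknown confirmation mode {mode!r}")
    df = records
    if "stage" in df.columns:
        df = df[df["stage"] == "rescreen"]
    if df.empty:
        df = pd.DataFrame(
            columns=["mutant_id", "site_id", "condition", "relative_phospho_pct"]
        )
    rows = []
    for mut in sorted(set(initial_hits)):
        sub = df[df["mutant_id"] == mut]
        if sub.empty:
            rows.append(
                {
                    "mutant_id": mut,
                    "site_id": "NA",
                    "condition": "NA",
                    "n": 0,
                    "mean_pct": np.nan,
                    "sem_pct": np.nan,
                    "fold_change": np.nan,
                    "direction": "NA",
                    "p_value": np.nan,
                    "status": "unconfirmable",
                    "confirmed": False,
                }
            )
            continue
        for (site, cond), cell in sub.groupby(["site_id", "condition"], sort=True):
            vals = cell["relative_phospho_pct"].to_numpy(dtype=float)
            mean = float(vals.mean())
            fold = mean / 100.0
            direction = "up" if fold >= 1.0 else "down"
            if vals.size < n_required:
                rows.append(
                    {
                        "mutant_id": mut,
                        "site_id": site,
                        "condition": cond,
                        "n": int(vals.size),
                        "mean_pct": mean,
                        "sem_pct": sem(vals),
                        "fold_change": fold,
                        "direction": direction,
                        "p_value": np.nan,
                        "status": "unconfirmable",
                        "confirmed": False,
                    }
                )
                continue
            meets_fold = _is_hit(fold, up, down)
            p_value = _one_sample_p(vals, 100.0)
            confirmed = meets_fold and (mode == "threshold" or p_value < alpha)
            rows.append(
                {
                    "mutant_id": mut,
                    "site_id": site,
                    "condition": cond,
                    "n": int(vals.size),
                    "mean_pct": mean,
                    "sem_pct": sem(vals),
                    "fold_change": fold,
                    "direction": direction,
                    "p_value": p_value,
                    "status": "ok",
                    "confirmed": bool(confirmed),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mutant_id", "site_id", "condition", "n", "mean_pct", "sem_pct",
            "fold_change", "direction", "p_value", "status", "confirmed",
        ],
    )


def _one_sample_p(values: np.ndarray, popmean: float) -> float:
    """Two-sided one-sample t-test p-value; zero-variance samples resolve to
    p=1 when the mean equals the reference and p=0 otherwise."""
    if np.std(values, ddof=1) == 0.0:
        return 1.0 if float(np.mean(values)) == popmean else 0.0
    return float(stats.ttest_1samp(values, popmean).pvalue)


def summarize_screen(confirmations: pd.DataFrame) -> pd.DataFrame:
    """Confirmed-mutant counts per site and direction.

    A mutant confirmed in several conditions of one site counts once for
    that site; a mutant altered at both sites counts once per site.
    """
    if confirmations.empty:
        return pd.DataFrame(columns=["site_id", "direction", "n_mutants"])
    conf = confirmations[confirmations["confirmed"]]
    if conf.empty:
        return pd.DataFrame(columns=["site_id", "direction", "n_mutants"])
    per_site = conf.drop_duplicates(["mutant_id", "site_id", "direction"])
    summary = (
        per_site.groupby(["site_id", "direction"], sort=True)["mutant_id"]
        .nunique()
        .reset_index(name="n_mutants")
    )
    return summary
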