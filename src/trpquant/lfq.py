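"""Label-free relative quantification of phosphopeptides.

Implements the quantification chain applied to aligned LC-MS feature
tables: charge-state filtering, run-level median-ratio normalization
(iterated, MAD-trimmed "recursive median"), phosphopeptide eligibility and
variant selection, per-condition relative abundance with the higher
condition set to 100%, unpaired t-tests, and light-dependence
classification.

The normalization rests on the assumption that most features do not change
in abundance between any two runs: for each run, the log abundance ratios
against a reference run are summarised by a robust location estimate, and
the run is rescaled by its exponential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import run_columns
from .synthetic import RunDesign

__all__ = [
    "NormalizationError",
    "NormalizationResult",
    "SiteQuantResult",
    "filter_charge",
    "normalize_runs",
    "select_quantifiable",
    "quantify_site",
    "quantify_all",
    "classify_sites",
    "results_frame",
]

QUANT_CHARGES = (2, 3, 4, 5)
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

CLASSES = ("light_elevated", "dark_elevated", "not_light_dependent", "not_quantifiable")


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizationResult:
    factors: dict[str, float]
    reference_run: str
    normalized: pd.DataFrame
    method: str = "recursive_median"


@dataclass
class SiteQuantResult:
    """Per-site relative quantification between two light conditions."""

    site_id: str
    chosen_feature: str | None
    n_per_condition: dict[str, int] = field(default_factory=dict)
    mean_abundance: dict[str, float] = field(default_factory=dict)
    relative_abundance: dict[str, float] = field(default_factory=dict)
    p_value: float = np.nan
    stars: str = "n.d."
    light_class: str = "not_quantifiable"
    enzyme: str = ""


def filter_charge(table: pd.DataFrame, keep: Sequence[int] = QUANT_CHARGES) -> pd.DataFrame:
    """Restrict a feature table to quantifiable charge states (default +2..+5)."""
    return table[table["charge"].isin(list(keep))].reset_index(drop=True)


def _iterated_median(d: np.ndarray, max_iter: int, tol: float) -> float:
    """MAD-trimmed iterated median of log ratios.

    Starting from the plain median, repeatedly discard points farther than
    1.48 × MAD from the current median (1.48 makes the MAD consistent with
    a normal σ) and re-take the median of what remains, until it moves by
    less than ``tol``.  Robust against a minority of genuinely changing
    features shifting the ratio distribution's tails.
    """
    d = np.asarray(d, dtype=float)
    m = float(np.median(d))
    for _ in range(max_iter):
        mad = float(np.median(np.abs(d - m)))
        if mad == 0.0:
            break
        sub = d[np.abs(d - m) <= 1.48 * mad]
        if sub.size < 3 or sub.size == d.size:
            d = sub if sub.size >= 3 else d
            m_new = float(np.median(d))
            if abs(m_new - m) < tol:
                m = m_new
                break
            m = m_new
            continue
        d = sub
        m_new = float(np.median(d))
        if abs(m_new - m) < tol:
            m = m_new
            break
        m = m_new
    return m


def normalize_runs(
    table: pd.DataFrame,
    reference_run: str | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
    method: str = "recursive_median",
) -> NormalizationResult:
    """Normalize per-run abundances to a reference run by robust log-median ratio.

    For each run r, over the features detected in both r and the reference,
    the log ratios d_i = log(ref_i / r_i) are reduced to a single location m
    (iterated MAD-trimmed median, or plain median with ``method="median"``);
    the run's factor is exp(m) and its abundances are multiplied by it.  The
    reference run keeps factor 1.
    """
    runs = run_columns(table)
    if not runs:
        raise NormalizationError("feature table has no run columns")
    if reference_run is None:
        reference_run = sorted(runs)[0]
    if reference_run not in runs:
        raise NormalizationError(f"reference run {reference_run!r} not in table")
    if method not in ("recursive_median", "median"):
        raise ValueError(f"unknown normalization method {method!r}")

    ref = table[reference_run].to_numpy(dtype=float)
    factors: dict[str, float] = {}
    normalized = table.copy()
    for run in runs:
        if run == reference_run:
            factors[run] = 1.0
            continue
        ab = table[run].to_numpy(dtype=float)
        if np.all(np.isnan(ab)):
            raise NormalizationError(f"run {run!r}: all abundances missing")
        shared = ~np.isnan(ref) & ~np.isnan(ab) & (ref > 0) & (ab > 0)
        if shared.sum() < 3:
            raise NormalizationError(
                f"run {run!r}: only {int(shared.sum())} features shared with "
                f"reference {reference_run!r} (need >= 3)"
            )
        d = np.log(ref[shared]) - np.log(ab[shared])
        if method == "median":
            m = float(np.median(d))
        else:
            m = _iterated_median(d, max_iter=max_iter, tol=tol)
        factor = float(np.exp(m))
        factors[run] = factor
        normalized[run] = ab * factor
    return NormalizationResult(factors, reference_run, normalized, method)


def _runs_by_condition(
    design: Sequence[RunDesign] | pd.DataFrame, conditions: Sequence[str]
) -> dict[str, list[str]]:
    if isinstance(design, pd.DataFrame):
        pairs = list(zip(design["run_id"], design["condition"]))
    else:
        pairs = [(r.run_id, r.condition) for r in design]
    out = {c: [rid for rid, cond in pairs if cond == c] for c in conditions}
    empty = [c for c, rids in out.items() if not rids]
    if empty:
        raise ValueError(f"no runs for conditions {empty}")
    return out


def select_quantifiable(
    table: pd.DataFrame,
    design: Sequence[RunDesign] | pd.DataFrame,
    conditions: Sequence[str] = ("light", "dark"),
) -> dict[str, str | None]:
    """Choose, per phosphosite, the peptide variant used for quantification.

    A variant is eligible if it is singly phosphorylated, its site is
    unambiguously localized, and it was detected in every run of at least
    one condition.  Among eligible variants of a site the one with the
    highest mean normalized abundance over all its non-missing runs wins;
    ties break to the lexicographically smallest feature_id.  Sites with no
    eligible variant map to ``None`` (not quantifiable).
    """
    by_cond = _runs_by_condition(design, conditions)
    all_runs = [rid for rids in by_cond.values() for rid in rids]
    missing_cols = [rid for rid in all_runs if rid not in table.columns]
    if missing_cols:
        raise ValueError(f"design runs absent from feature table: {missing_cols}")

    chosen: dict[str, str | None] = {}
    sites = table.loc[table["site_id"] != "background", "site_id"].unique()
    for site in sites:
        variants = table[table["site_id"] == site]
        eligible = []
        for _, row in variants.iterrows():
            if int(row["n_phospho"]) != 1 or not bool(row["site_localized"]):
                continue
            complete_somewhere = any(
                row[rids].notna().all() for rids in by_cond.values()
            )
            if not complete_somewhere:
                continue
            vals = row[all_runs].astype(float)
            eligible.append((float(vals.mean()), str(row["feature_id"])))
        if not eligible:
            chosen[site] = None
            continue
        # max mean abundance; ties -> lowest feature_id
        best_mean = max(m for m, _ in eligible)
        chosen[site] = min(fid for m, fid in eligible if m == best_mean)
    return chosen


def _stars(p: float) -> str:
    if np.isnan(p):
        return "n.d."
    for thr, label in STAR_THRESHOLDS:
        if p < thr:
            return label
    return "n.s."


def _t_test(a: np.ndarray, b: np.ndarray, test: str) -> float:
    """Two-sided unpaired t-test p-value; degenerate zero-variance samples
    resolve to p=1 when the means agree and p=0 otherwise."""
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    res = stats.ttest_ind(a, b, equal_var=(test == "student"))
    return float(res.pvalue)


def quantify_site(
    table: pd.DataFrame,
    site_id: str,
    feature_id: str | None,
    design: Sequence[RunDesign] | pd.DataFrame,
    conditions: Sequence[str] = ("light", "dark"),
    test: str = "student",
) -> SiteQuantResult:
    """Relative quantification of one site from its chosen peptide variant.

    Per condition, the mean normalized abundance over that condition's runs
    is computed (missing values excluded); the higher condition is set to
    100%.  Significance comes from a two-sided unpaired t-test (pooled
    variance by default, Welch with ``test="welch"``).  A condition with
    fewer than two detected values renders the site not quantifiable.
    """
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}")
    result = SiteQuantResult(site_id=site_id, chosen_feature=feature_id)
    if feature_id is None:
        return result
    rows = table[table["feature_id"] == feature_id]
    if len(rows) != 1:
        raise ValueError(f"feature {feature_id!r}: expected exactly one row")
    row = rows.iloc[0]
    by_cond = _runs_by_condition(design, conditions)
    values = {
        c: row[rids].astype(float).dropna().to_numpy() for c, rids in by_cond.items()
    }
    result.n_per_condition = {c: int(v.size) for c, v in values.items()}
    if any(v.size < 2 for v in values.values()):
        return result
    means = {c: float(v.mean()) for c, v in values.items()}
    top = max(means.values())
    result.mean_abundance = means
    result.relative_abundance = {c: 100.0 * m / top for c, m in means.items()}
    c1, c2 = conditions
    result.p_value = _t_test(values[c1], values[c2], test)
    result.stars = _stars(result.p_value)
    if result.p_value < 0.05 and means[c1] != means[c2]:
        winner = c1 if means[c1] > means[c2] else c2
        result.light_class = f"{winner}_elevated"
    else:
        result.light_class = "not_light_dependent"
    return result


def quantify_all(
    table: pd.DataFrame,
    design: Sequence[RunDesign] | pd.DataFrame,
    reference_run: str | None = None,
    conditions: Sequence[str] = ("light", "dark"),
    test: str = "student",
    normalizer: str = "recursive_median",
    by_enzyme: str | bool = "auto",
) -> tuple[list[SiteQuantResult], NormalizationResult]:
    """Full quantification chain on a feature table.

    Charge filtering → normalization (all runs together) → per-site variant
    selection → relative quantification.  When the design contains more
    than one digestion enzyme and ``by_enzyme`` is "auto" or True, sites
    are selected and quantified separately within each enzyme's runs
    (tryptic and chymotryptic peptides are distinct molecules and are not
    mixed); the result carries the enzyme label.
    """
    if isinstance(design, pd.DataFrame):
        ddf = design
    else:
        from .synthetic import design_frame

        ddf = design_frame(design)
    filtered = filter_charge(table)
    norm = normalize_runs(filtered, reference_run=reference_run, method=normalizer)

    enzymes = sorted(ddf["enzyme"].unique()) if "enzyme" in ddf.columns else [""]
    split = by_enzyme is True or (by_enzyme == "auto" and len(enzymes) > 1)
    groups = (
        [(enz, ddf[ddf["enzyme"] == enz]) for enz in enzymes] if split else [("", ddf)]
    )

    results: list[SiteQuantResult] = []
    for enz, sub in groups:
        sub_runs = list(sub["run_id"])
        sub_table = norm.normalized[
            [c for c in norm.normalized.columns if c not in run_columns(norm.normalized)]
            + sub_runs
        ]
        chosen = select_quantifiable(sub_table, sub, conditions)
        for site in sorted(chosen):
            res = quantify_site(sub_table, site, chosen[site], sub, conditions, test)
            res.enzyme = enz
            results.append(res)
    return results, norm


def results_frame(results: Sequence[SiteQuantResult]) -> pd.DataFrame:
    """Results as the interchange table (one row per site [× enzyme])."""
    recs = []
    for r in results:
        recs.append(
            {
                "site_id": r.site_id,
                "enzyme": r.enzyme,
                "peptide": r.chosen_feature if r.chosen_feature else "NA",
                "n_light": r.n_per_condition.get("light", 0),
                "n_dark": r.n_per_condition.get("dark", 0),
                "rel_light_pct": r.relative_abundance.get("light", np.nan),
                "rel_dark_pct": r.relative_abundance.get("dark", np.nan),
                "p_value": r.p_value,
                "stars": r.stars,
                "class": r.light_class,
            }
        )
    return pd.DataFrame(recs)


def classify_sites(results: Sequence[SiteQuantResult]) -> pd.DataFrame:
    """Tabulate sites per light-dependence class (deterministic order)."""
    counts = {c: 0 for c in CLASSES}
    for r in results:
        counts[r.light_class] = counts.get(r.light_class, 0) + 1
    return pd.DataFrame(
        {"class": list(counts.keys()), "n_sites": list(counts.values())}
    )
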