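"""End-to-end driver: synthetic truth → quantification → reports.

``run_pipeline`` executes every stage on generated data with known ground
truth and writes all intermediate tables, a JSON run manifest (config,
package versions, seed) and a human-readable summary.  Identical config
and seed reproduce the output bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import densitometry, lfq, occupancy, screen, synthetic
from .io import write_json, write_table

log = logging.getLogger("trpquant")

__all__ = ["PipelineConfig", "run_pipeline", "default_screen_effects"]


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run (JSON-serializable, lossless)."""

    seed: int = 0
    # synthetic LC-MS data
    n_background_features: int = 300
    background_change_fraction: float = 0.1
    ms_noise_cv: float = 0.2
    detect_prob: float = 0.95
    site_fold: float = 4.0
    scale_spread: float = 2.0
    n_bio: int = 3
    n_tech: int = 3
    # lfq options
    reference_run: str | None = None
    normalizer: str = "recursive_median"
    test: str = "student"
    # densitometry
    blot_noise_cv: float = 0.15
    linearity_threshold: float = 0.95
    dilution_amounts: tuple = (3.0, 1.5, 0.75, 0.375)
    # occupancy: true per-subunit probabilities per site
    occupancy_p: dict = field(default_factory=lambda: {"T849": 0.186, "T864": 0.099})
    n_subunits: int = 4
    capture_eff: float = 1.0
    n_channels: int = 100_000
    ip_replicates: int = 3
    # screen
    n_mutants: int = 85
    screen_noise_cv: float = 0.15
    screen_up_fold: float = 2.0
    screen_down_fold: float = 0.5
    screen_mode: str = "ttest"
    # significance coding
    star_thresholds: tuple = (0.05, 0.01, 0.001)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dilution_amounts"] = list(d["dilution_amounts"])
        d["star_thresholds"] = list(d["star_thresholds"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("dilution_amounts", "star_thresholds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def default_screen_effects(
    sites=("T849", "T864"),
    folds=(0.15, 0.1, 0.2, 0.25),
    condition="light",
    n_mutants: int = 85,
) -> dict:
    """Planted screen truth: four down-regulated mutants per site (distinct
    mutants, reductions of 4- to 10-fold, incl. a 6.7-fold one as observed
    for the eye-PKC null), all in the light condition, spread over the panel."""
    n_planted = len(sites) * len(folds)
    if n_mutants < n_planted:
        raise ValueError(f"need at least {n_planted} mutants to plant effects")
    spacing = max(1, n_mutants // (n_planted + 1))
    effects: dict[str, dict] = {}
    i = 0
    for site in sites:
        for fold in folds:
            i += 1
            effects[f"mut{i * spacing:03d}"] = {(site, condition): fold}
    return effects


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run all stages on synthetic data; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeder = np.random.default_rng(config.seed)

    def child_seed() -> int:
        return int(seeder.integers(0, 2**31 - 1))

    outputs: list[str] = []

    def save(table: pd.DataFrame, name: str):
        write_table(table, out / name)
        outputs.append(name)

    # ---- stage 1: synthetic LC-MS + label-free quantification -------------
    ms_seed = child_seed()
    truth = synthetic.default_site_truth(fold=config.site_fold)
    design_rng = np.random.default_rng(child_seed())
    design = synthetic.make_run_design(
        n_bio=config.n_bio,
        n_tech=config.n_tech,
        rng=design_rng,
        scale_spread=config.scale_spread,
    )
    cfg = synthetic.SimConfig(
        n_background_features=config.n_background_features,
        background_change_fraction=config.background_change_fraction,
        noise_cv=config.ms_noise_cv,
        detect_prob=config.detect_prob,
        seed=ms_seed,
    )
    table, truth_record = synthetic.simulate_feature_table(truth, design, cfg)
    log.info("simulated %d features x %d runs", len(table), len(design))
    save(synthetic.design_frame(design), "run_design.tsv")
    save(table, "feature_table.tsv")
    write_json(truth_record, out / "ms_truth.json")
    outputs.append("ms_truth.json")

    results, norm = lfq.quantify_all(
        table,
        design,
        reference_run=config.reference_run,
        test=config.test,
        normalizer=config.normalizer,
    )
    log.info(
        "lfq: %d/%d features kept after charge filter; reference run %s",
        len(lfq.filter_charge(table)),
        len(table),
        norm.reference_run,
    )
    factors = pd.DataFrame(
        {"run_id": list(norm.factors), "factor": list(norm.factors.values())}
    )
    save(factors, "normalization_factors.tsv")
    res_df = lfq.results_frame(results)
    save(res_df, "site_quantification.tsv")
    classification = lfq.classify_sites(results)
    save(classification, "site_classification.tsv")

    # ---- stage 2: densitometry -------------------------------------------
    blot_seed = child_seed()
    lanes = synthetic.dilution_lanes(config.dilution_amounts)
    dilution = synthetic.simulate_blot_panel(
        {("wt", "light"): 0.5}, lanes, noise_cv=config.blot_noise_cv, seed=blot_seed
    )
    save(dilution, "dilution_panel.tsv")
    lin_rows = []
    for signal in ("total_signal", "phospho_signal"):
        rep = densitometry.linearity_check(
            dilution, signal=signal, threshold=config.linearity_threshold
        )
        lin_rows.append(dataclasses.asdict(rep))
    linearity = pd.DataFrame(lin_rows)
    save(linearity, "linearity_report.tsv")

    relphos_lanes = [
        synthetic.BlotLane(f"m{m}_{gt}_{cond}", f"mem{m}", gt, cond)
        for m in (1, 2, 3)
        for gt in ("wt", "norpA")
        for cond in ("light", "dark")
    ]
    relphos_truth = {
        ("wt", "light"): 0.5,
        ("wt", "dark"): 0.1,
        ("norpA", "light"): 0.12,
        ("norpA", "dark"): 0.1,
    }
    relphos_panel = synthetic.simulate_blot_panel(
        relphos_truth, relphos_lanes, noise_cv=config.blot_noise_cv, seed=child_seed()
    )
    per_lane, relphos_summary = densitometry.relative_phosphorylation(
        relphos_panel, control=("wt", "light")
    )
    save(relphos_panel, "relphos_panel.tsv")
    save(relphos_summary, "relphos_summary.tsv")

    # ---- stage 3: phosphate occupancy ------------------------------------
    model = occupancy.OccupancyModel(config.n_subunits, config.capture_eff)
    occ_rows = []
    for site, p_true in sorted(config.occupancy_p.items()):
        for rep in range(1, config.ip_replicates + 1):
            sim = synthetic.simulate_ip(
                p_true,
                config.n_channels,
                subunits_per_channel=config.n_subunits,
                capture_eff=config.capture_eff,
                seed=child_seed(),
                site_id=site,
                replicate=rep,
            )
            est = occupancy.occupancy_from_simulation(sim, model, seed=child_seed())
            occ_rows.append(
                {
                    "site_id": site,
                    "replicate": rep,
                    "p_true": p_true,
                    "oc_measured_pct": est.oc_measured,
                    "oc_se_pct": est.oc_se,
                    "p_hat": est.p_hat,
                    "p_se": est.p_se,
                }
            )
    occ_df = pd.DataFrame(occ_rows)
    occ_summary = (
        occ_df.groupby("site_id", sort=True)
        .agg(
            p_true=("p_true", "first"),
            oc_mean_pct=("oc_measured_pct", "mean"),
            oc_sem_pct=("oc_measured_pct", densitometry.sem),
            p_hat_mean=("p_hat", "mean"),
        )
        .reset_index()
    )
    save(occ_df, "occupancy_replicates.tsv")
    save(occ_summary, "occupancy_summary.tsv")

    # ---- stage 4: candidate screen ----------------------------------------
    effects = default_screen_effects(n_mutants=config.n_mutants)
    panel = synthetic.simulate_screen_panel(
        effects,
        n_mutants=config.n_mutants,
        noise_cv=config.screen_noise_cv,
        seed=child_seed(),
    )
    records = screen.screen_records_from_panel(panel)
    save(records, "screen_records.tsv")
    initial = screen.call_initial_hits(
        records, up=config.screen_up_fold, down=config.screen_down_fold
    )
    save(initial, "screen_initial_calls.tsv")
    hits = screen.initial_hit_mutants(initial)
    log.info("screen: %d initial hits of %d mutants", len(hits), config.n_mutants)
    confirmations = screen.confirm_hits(
        records,
        hits,
        mode=config.screen_mode,
        up=config.screen_up_fold,
        down=config.screen_down_fold,
    )
    save(confirmations, "screen_confirmations.tsv")
    screen_summary = screen.summarize_screen(confirmations)
    save(screen_summary, "screen_summary.tsv")

    # ---- manifest + summary ------------------------------------------------
    manifest = {
        "package": "trpquant",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": outputs,
    }
    write_json(manifest, out / "manifest.json")

    lines = ["trpquant pipeline summary", "========================", ""]
    lines.append("Site classification (label-free MS):")
    for _, row in classification.iterrows():
        lines.append(f"  {row['class']:>22}: {row['n_sites']}")
    lines.append("")
    lines.append("Blot linearity r^2:")
    for _, row in linearity.iterrows():
        lines.append(f"  {row['signal']:>16}: {row['r_squared']:.4f} (pass={row['passed']})")
    lines.append("")
    lines.append("Phosphate occupancy (mean over replicates):")
    for _, row in occ_summary.iterrows():
        lines.append(
            f"  {row['site_id']}: OC={row['oc_mean_pct']:.1f}% "
            f"(true p={row['p_true']:.3f}, model p_hat={row['p_hat_mean']:.3f})"
        )
    lines.append("")
    lines.append(f"Screen: {len(hits)} initial hits; confirmed per site/direction:")
    for _, row in screen_summary.iterrows():
        lines.append(f"  {row['site_id']} {row['direction']}: {row['n_mutants']}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    outputs.append("summary.txt")
    return manifest
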