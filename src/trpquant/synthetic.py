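"""Synthetic data generators with known ground truth.

Every downstream stage (label-free quantification, densitometry, phosphate
occupancy, mutant screen) is exercised on data produced here, so each
generator writes down the exact data-generating equation it implements:

* LC-MS feature abundance:  ``base × condition_effect × run_scale × noise``
  with multiplicative log-normal noise of unit mean and fixed CV, and
  missing-at-random detection applied after the noise.
* Western-blot lane signals: ``gain × amount × (fraction) × noise``.
* Immunoprecipitation: channels are tetramers whose subunits are
  phosphorylated i.i.d. Bernoulli(p); a channel with k phospho-subunits is
  captured with probability 1 − (1 − capture_eff)^k.

A single master seed drives everything; per-generator substreams are
derived deterministically so identical (config, seed) gives byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FEATURE_META_COLUMNS

__all__ = [
    "TrueSiteState",
    "RunDesign",
    "SimConfig",
    "IPExperiment",
    "BlotLane",
    "simulate_feature_table",
    "simulate_blot_panel",
    "simulate_ip",
    "simulate_screen_panel",
    "make_run_design",
    "default_site_truth",
    "dilution_lanes",
    "design_frame",
]

# substream labels -> fixed offsets mixed into the master seed sequence
_STREAMS = {"features": 0, "blot": 1, "ip": 2, "screen": 3}


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-generator random stream derived from a master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[label]]))


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with coefficient of variation cv."""
    if cv < 0:
        raise ValueError(f"noise_cv must be >= 0, got {cv}")
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=size))


@dataclass(frozen=True)
class TrueSiteState:
    """Ground-truth phosphorylation state of one site.

    ``condition_effect`` gives the relative true phosphopeptide abundance per
    condition, max-normalised so exactly one condition sits at 1.0.
    ``subunit_prob`` gives the per-subunit phosphorylation probability
    (the true phosphate occupancy) per condition, used by the IP simulator.
    """

    site_id: str
    condition_effect: Mapping[str, float]
    subunit_prob: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        effects = dict(self.condition_effect)
        if not effects:
            raise ValueError(f"site {self.site_id}: empty condition_effect")
        for cond, eff in effects.items():
            if not (0.0 < eff <= 1.0):
                raise ValueError(
                    f"site {self.site_id}: effect for {cond!r} must be in (0, 1], got {eff}"
                )
        if max(effects.values()) != 1.0:
            raise ValueError(
                f"site {self.site_id}: effects must be max-normalised (top condition = 1.0)"
            )
        for cond, p in dict(self.subunit_prob).items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"site {self.site_id}: p for {cond!r} outside [0, 1]")


@dataclass(frozen=True)
class RunDesign:
    """One LC-MS run: genotype, light condition, replicate indices, enzyme."""

    run_id: str
    genotype: str
    condition: str
    bio_replicate: int
    tech_replicate: int
    enzyme: str = "trypsin"
    scale_factor: float = 1.0

    def __post_init__(self):
        if self.scale_factor <= 0:
            raise ValueError(f"run {self.run_id}: scale_factor must be > 0")


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the feature-table generator.

    ``background_change_fraction`` must stay below 0.5: the normalization
    downstream assumes most features do not change between conditions.
    ``detect_prob`` is the per-run detection probability (constant, or a
    callable of the underlying abundance for abundance-dependent dropout).
    """

    n_background_features: int = 300
    background_change_fraction: float = 0.1
    noise_cv: float = 0.2
    detect_prob: float | Callable[[np.ndarray], np.ndarray] = 0.95
    seed: int = 0
    n_variants_per_site: int = 2
    multi_phospho_prob: float = 0.2
    ambiguous_prob: float = 0.2
    charge_weights: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.40, 3: 0.30, 4: 0.15, 5: 0.05, 6: 0.05}
    )
    site_base_abundance: float = 1e5
    background_base_abundance: float = 1e5

    def __post_init__(self):
        if not (0.0 <= self.background_change_fraction < 0.5):
            raise ValueError("background_change_fraction must be in [0, 0.5)")
        if callable(self.detect_prob):
            return
        if not (0.0 < self.detect_prob <= 1.0):
            raise ValueError("detect_prob must be in (0, 1]")


@dataclass
class IPExperiment:
    """Signal quadruple of one phospho-IP occupancy experiment.

    ``p_*`` are phosphospecific-antibody signals, ``t_*`` generic-antibody
    signals, for the extract before IP (input) and the immunoprecipitate.
    Simulated experiments additionally carry the per-channel phospho-subunit
    counts and capture mask, which allow bootstrap Monte-Carlo standard
    errors downstream; experiments read from file leave them ``None``.
    """

    p_input: float
    t_input: float
    p_ip: float
    t_ip: float
    site_id: str = ""
    replicate: int = 0
    phospho_counts: np.ndarray | None = None
    captured: np.ndarray | None = None


@dataclass(frozen=True)
class BlotLane:
    lane_id: str
    membrane_id: str
    genotype: str
    condition: str
    heads_loaded: float = 1.0
    timepoint: float | None = None

    def __post_init__(self):
        if self.heads_loaded < 0:
            raise ValueError(f"lane {self.lane_id}: negative amount loaded")


def make_run_design(
    genotypes: Sequence[str] = ("wt",),
    conditions: Sequence[str] = ("light", "dark"),
    n_bio: int = 3,
    n_tech: int = 3,
    enzymes: Sequence[str] = ("trypsin",),
    scale_factors: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
    scale_spread: float = 0.0,
) -> list[RunDesign]:
    """Build a factorial run design.

    The default (one enzyme, 3 biological × 3 technical replicates) yields
    nine runs per genotype × condition, the per-condition sample size the
    quantification operates on.  ``scale_spread`` > 0 draws run-level
    loading factors log-uniform in [1/spread, spread] (requires ``rng``);
    ``scale_factors`` sets them explicitly by run id.
    """
    runs = []
    for gt in genotypes:
        for cond in conditions:
            for enz in enzymes:
                for b in range(1, n_bio + 1):
                    for t in range(1, n_tech + 1):
                        rid = f"{gt}_{cond}_{enz[:4]}_b{b}t{t}"
                        sf = 1.0
                        if scale_factors and rid in scale_factors:
                            sf = scale_factors[rid]
                        elif scale_spread > 0:
                            if rng is None:
                                raise ValueError("scale_spread > 0 requires rng")
                            sf = float(
                                np.exp(rng.uniform(-np.log(scale_spread), np.log(scale_spread)))
                            )
                        runs.append(RunDesign(rid, gt, cond, b, t, enz, sf))
    return runs


def design_frame(design: Sequence[RunDesign]) -> pd.DataFrame:
    """Run design as a DataFrame (the TSV interchange form)."""
    return pd.DataFrame(
        {
            "run_id": [r.run_id for r in design],
            "genotype": [r.genotype for r in design],
            "condition": [r.condition for r in design],
            "bio_replicate": [r.bio_replicate for r in design],
            "tech_replicate": [r.tech_replicate for r in design],
            "enzyme": [r.enzyme for r in design],
            "scale_factor": [r.scale_factor for r in design],
        }
    )


# The TRP channel's light-regulated phosphosites: 13 C-terminal sites gain
# phosphate in the light; S936 is the lone site phosphorylated in the dark.
LIGHT_ELEVATED_SITES = (
    "S726", "T849", "T864", "S872", "S876", "S958", "S961",
    "S964", "S982", "T998", "S1056", "S1123", "S1254",
)
DARK_ELEVATED_SITE = "S936"


def default_site_truth(fold: float = 4.0) -> list[TrueSiteState]:
    """Ground truth mirroring the wild-type pattern: 13 light-elevated sites
    plus one dark-elevated site, each with the given fold change."""
    if fold <= 1:
        raise ValueError("fold must be > 1")
    low = 1.0 / fold
    truth = [
        TrueSiteState(s, {"light": 1.0, "dark": low}) for s in LIGHT_ELEVATED_SITES
    ]
    truth.append(TrueSiteState(DARK_ELEVATED_SITE, {"light": low, "dark": 1.0}))
    return truth


def simulate_feature_table(
    truth: Sequence[TrueSiteState],
    design: Sequence[RunDesign],
    cfg: SimConfig,
) -> tuple[pd.DataFrame, dict]:
    """Generate an aligned LC-MS feature table plus its ground-truth record.

    Returns ``(table, truth_record)``.  The table has the fixed metadata
    columns followed by one abundance column per run (NaN = not detected);
    the record holds everything needed for parameter-recovery tests.
    """
    if len(design) < 2:
        raise ValueError("need at least two runs")
    if len(truth) < 1:
        raise ValueError("need at least one true site")
    run_ids = [r.run_id for r in design]
    if len(set(run_ids)) != len(run_ids):
        raise ValueError("duplicate run ids in design")
    keys = [(r.genotype, r.condition, r.bio_replicate, r.tech_replicate, r.enzyme) for r in design]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (genotype, condition, replicate, enzyme) in design")
    conditions = sorted({r.condition for r in design})
    for site in truth:
        missing = [c for c in conditions if c not in site.condition_effect]
        if missing:
            raise ValueError(f"site {site.site_id}: no effect for conditions {missing}")

    rng = substream(cfg.seed, "features")
    charges = np.array(sorted(cfg.charge_weights))
    cw = np.array([cfg.charge_weights[c] for c in charges], dtype=float)
    cw = cw / cw.sum()

    rows: list[dict] = []
    effects: list[dict[str, float]] = []
    changed_background: list[str] = []

    def add_feature(fid, peptide, site_id, n_phospho, localized, base, effect):
        rows.append(
            {
                "feature_id": fid,
                "peptide_sequence": peptide,
                "site_id": site_id,
                "n_phospho": n_phospho,
                "site_localized": localized,
                "charge": int(rng.choice(charges, p=cw)),
                "mz": float(np.round(rng.uniform(250.0, 1800.0), 4)),
                "rt": float(np.round(rng.uniform(1.0, 120.0), 2)),
                "_base": base,
            }
        )
        effects.append(effect)

    # site-derived phosphopeptide variants (charge / missed-cleavage variants
    # share the site's condition effect; flagged extras are multiply
    # phosphorylated or carry an ambiguous site assignment)
    for site in truth:
        eff = {c: site.condition_effect[c] for c in conditions}
        site_base = cfg.site_base_abundance * float(_lognormal_noise(rng, 1.0, ()))
        for v in range(cfg.n_variants_per_site):
            base = site_base * float(_lognormal_noise(rng, 0.5, ()))
            add_feature(
                f"{site.site_id}_v{v + 1}",
                f"PEP{site.site_id}V{v + 1}",
                site.site_id,
                1,
                True,
                base,
                eff,
            )
        if rng.random() < cfg.multi_phospho_prob:
            add_feature(
                f"{site.site_id}_multi",
                f"PEP{site.site_id}MULTI",
                site.site_id,
                2,
                True,
                site_base * 0.3,
                eff,
            )
        if rng.random() < cfg.ambiguous_prob:
            add_feature(
                f"{site.site_id}_ambig",
                f"PEP{site.site_id}AMB",
                site.site_id,
                1,
                False,
                site_base * 0.5,
                eff,
            )

    # background (non-phospho) features; a minority change between conditions
    n_bg = cfg.n_background_features
    changer = rng.random(n_bg) < cfg.background_change_fraction
    for i in range(n_bg):
        fid = f"bg{i + 1:05d}"
        eff = {c: 1.0 for c in conditions}
        if changer[i]:
            up_cond = conditions[int(rng.integers(len(conditions)))]
            fold = float(np.exp(rng.uniform(np.log(2.0), np.log(8.0))))
            eff = {c: (1.0 if c == up_cond else 1.0 / fold) for c in conditions}
            changed_background.append(fid)
        base = cfg.background_base_abundance * float(_lognormal_noise(rng, 1.0, ()))
        add_feature(fid, f"BGPEP{i + 1}", "background", 0, False, base, eff)

    n_feat = len(rows)
    n_runs = len(design)
    base = np.array([r.pop("_base") for r in rows])
    eff_mat = np.array([[e[r.condition] for r in design] for e in effects])
    scale = np.array([r.scale_factor for r in design])
    noise = _lognormal_noise(rng, cfg.noise_cv, (n_feat, n_runs))
    abundance = base[:, None] * eff_mat * scale[None, :] * noise

    if callable(cfg.detect_prob):
        detect_p = np.asarray(cfg.detect_prob(abundance), dtype=float)
    else:
        detect_p = np.full((n_feat, n_runs), float(cfg.detect_prob))
    detected = rng.random((n_feat, n_runs)) < detect_p
    abundance = np.where(detected, abundance, np.nan)

    table = pd.DataFrame(rows)
    for j, r in enumerate(design):
        table[r.run_id] = abundance[:, j]

    record = {
        "sites": {
            s.site_id: {
                "condition_effect": dict(s.condition_effect),
                "subunit_prob": dict(s.subunit_prob),
            }
            for s in truth
        },
        "changed_background_features": changed_background,
        "scale_factors": {r.run_id: r.scale_factor for r in design},
        "config": {
            "n_background_features": cfg.n_background_features,
            "background_change_fraction": cfg.background_change_fraction,
            "noise_cv": cfg.noise_cv,
            "detect_prob": cfg.detect_prob if not callable(cfg.detect_prob) else "callable",
            "seed": cfg.seed,
            "n_variants_per_site": cfg.n_variants_per_site,
        },
    }
    return table[FEATURE_META_COLUMNS + [r.run_id for r in design]], record


def dilution_lanes(
    amounts: Sequence[float] = (3.0, 1.5, 0.75, 0.375),
    genotype: str = "wt",
    condition: str = "light",
    membrane_id: str = "dilution1",
) -> list[BlotLane]:
    """Dilution-series lane layout: decreasing TRP amounts (in fly-head
    equivalents) at constant total protein, for signal-linearity QC."""
    return [
        BlotLane(f"dil{i + 1}", membrane_id, genotype, condition, heads_loaded=a)
        for i, a in enumerate(amounts)
    ]


def simulate_blot_panel(
    occupancy_truth: Mapping[tuple, float] | Callable[[BlotLane], float],
    lanes: Sequence[BlotLane],
    noise_cv: float = 0.15,
    seed: int = 0,
    gain_total: float = 1.0e4,
    gain_phospho: float = 2.0e4,
) -> pd.DataFrame:
    """Simulate lane-wise Western-blot signals.

    ``occupancy_truth`` maps (genotype, condition) — or, when time courses
    are simulated, (genotype, condition, timepoint) — to the phosphorylated
    fraction in [0, 1]; a callable receives the whole lane.  Signals follow
    ``total = gain_total × amount × noise`` and
    ``phospho = gain_phospho × amount × fraction × noise`` with independent
    unit-mean log-normal noise per measurement.
    """
    if not lanes:
        raise ValueError("empty lane design")
    rng = substream(seed, "blot")

    def fraction_of(lane: BlotLane) -> float:
        if callable(occupancy_truth):
            frac = occupancy_truth(lane)
        else:
            key3 = (lane.genotype, lane.condition, lane.timepoint)
            key2 = (lane.genotype, lane.condition)
            if key3 in occupancy_truth:
                frac = occupancy_truth[key3]
            elif key2 in occupancy_truth:
                frac = occupancy_truth[key2]
            else:
                raise KeyError(f"no occupancy truth for lane {lane.lane_id} ({key2})")
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"lane {lane.lane_id}: fraction {frac} outside [0, 1]")
        return float(frac)

    recs = []
    for lane in lanes:
        frac = fraction_of(lane)
        total = gain_total * lane.heads_loaded * float(_lognormal_noise(rng, noise_cv, ()))
        phospho = (
            gain_phospho * lane.heads_loaded * frac * float(_lognormal_noise(rng, noise_cv, ()))
        )
        recs.append(
            {
                "lane_id": lane.lane_id,
                "membrane_id": lane.membrane_id,
                "genotype": lane.genotype,
                "condition": lane.condition,
                "timepoint": np.nan if lane.timepoint is None else lane.timepoint,
                "heads_loaded": lane.heads_loaded,
                "phospho_signal": phospho,
                "total_signal": total,
            }
        )
    return pd.DataFrame(recs)


def simulate_ip(
    p: float,
    n_channels: int,
    subunits_per_channel: int = 4,
    capture_eff: float = 1.0,
    seed: int = 0,
    site_id: str = "",
    replicate: int = 0,
) -> IPExperiment:
    """Simulate a phospho-IP experiment on a population of channel tetramers.

    Each of ``n_channels`` channels has ``subunits_per_channel`` subunits
    phosphorylated i.i.d. Bernoulli(p).  Input signals are proportional to
    epitope counts over all channels; a channel with k phospho-subunits is
    captured with probability 1 − (1 − capture_eff)^k, and IP signals sum
    over captured channels only.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if not (0.0 < capture_eff <= 1.0):
        raise ValueError(f"capture_eff must be in (0, 1], got {capture_eff}")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if subunits_per_channel < 1:
        raise ValueError("subunits_per_channel must be >= 1")
    rng = substream(seed, "ip")
    n = subunits_per_channel
    k = rng.binomial(n, p, size=n_channels)
    p_capture = 1.0 - (1.0 - capture_eff) ** k
    captured = rng.random(n_channels) < p_capture
    return IPExperiment(
        p_input=float(k.sum()),
        t_input=float(n * n_channels),
        p_ip=float(k[captured].sum()),
        t_ip=float(n * captured.sum()),
        site_id=site_id,
        replicate=replicate,
        phospho_counts=k,
        captured=captured,
    )


def simulate_screen_panel(
    effects: Mapping[str, Mapping[tuple[str, str], float]] | None = None,
    n_mutants: int = 85,
    rescreen_replicates: int = 3,
    noise_cv: float = 0.15,
    seed: int = 0,
    sites: Sequence[str] = ("T849", "T864"),
    conditions: Sequence[str] = ("light", "dark"),
    baseline_fraction: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate the kinase/phosphatase candidate-screen blots.

    ``effects`` maps mutant id → {(site, condition): fold change of the
    phosphorylated fraction vs wild type}; unlisted cells are 1.0 (no
    effect).  Each (mutant, site, condition, stage, replicate) is one blot
    membrane carrying a wild-type control lane and the mutant lane, with
    membrane-specific antibody gains — downstream relative quantification
    must cancel them.  Stage ``initial`` has one replicate; ``rescreen``
    has ``rescreen_replicates``.

    ``noise_cv`` is the coefficient of variation of a lane's phospho/total
    ratio — the measurement the screen actually scores — so the log-normal
    noise is split evenly (σ/√2 each) between the two signals of a lane.
    """
    effects = dict(effects or {})
    if baseline_fraction is None:
        baseline_fraction = {"light": 0.5, "dark": 0.1}
    for mut, table in effects.items():
        for key, fold in table.items():
            if fold <= 0:
                raise ValueError(f"mutant {mut}: fold change must be > 0 at {key}")
    mutants = [f"mut{i + 1:03d}" for i in range(n_mutants)]
    unknown = [m for m in effects if m not in mutants]
    if unknown:
        raise ValueError(f"effects given for unknown mutants {unknown}")

    rng = substream(seed, "screen")
    sigma_sig = np.sqrt(np.log1p(noise_cv**2) / 2.0)  # per-signal share

    def signal_noise() -> float:
        return float(np.exp(rng.normal(-sigma_sig**2 / 2.0, sigma_sig)))

    recs = []
    stages = [("initial", 1), ("rescreen", rescreen_replicates)]
    for mut in mutants:
        for site in sites:
            for cond in conditions:
                fold = effects.get(mut, {}).get((site, cond), 1.0)
                base = baseline_fraction[cond]
                for stage, n_rep in stages:
                    for rep in range(1, n_rep + 1):
                        membrane = f"{mut}_{site}_{cond}_{stage}_{rep}"
                        gain_t = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0)))) * 1e4
                        gain_p = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0)))) * 1e4
                        for genotype, frac in (("wt", base), (mut, base * fold)):
                            total = gain_t * signal_noise()
                            phospho = gain_p * frac * signal_noise()
                            recs.append(
                                {
                                    "lane_id": f"{membrane}_{genotype}",
                                    "membrane_id": membrane,
                                    "mutant_id": mut,
                                    "genotype": genotype,
                                    "site_id": site,
                                    "condition": cond,
                                    "stage": stage,
                                    "replicate": rep,
                                    "phospho_signal": phospho,
                                    "total_signal": total,
                                }
                            )
    return pd.DataFrame(recs)
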