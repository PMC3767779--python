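"""Phosphate occupancy from phospho-IP signal quadruples, with a tetramer
co-capture bias model.

The measured occupancy of a site is

    OC = (pTRP_input / TRP_input) × (TRP_IP / pTRP_IP) × 100%

where the input ratio compares phosphospecific to generic antibody signal
in the extract and the IP ratio corrects for the antibodies' different
reactivities using the immunoprecipitate, in which (ideally) every molecule
is phosphorylated.  TRP channels are tetramers, however, and a
phosphospecific antibody pulls down whole channels: non-phosphorylated
subunits co-precipitate whenever at least one subunit of their tetramer is
phosphorylated, inflating OC above the per-subunit phosphorylation
probability p.  With subunits phosphorylated i.i.d. Bernoulli(p) and a
channel with k phospho-subunits captured with probability
1 − (1 − c)^k (capture efficiency c per phospho-epitope),

    OC_app = 100 · p · n · E[P_cap(K)] / E[K · P_cap(K)],   K ~ Binomial(n, p)

which reduces to the closed form 100 · (1 − (1 − p)^n) at c = 1, and to
100 · p (no bias) for monomers.  ``invert_occupancy`` recovers p from a
measured OC under this model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .synthetic import IPExperiment

__all__ = [
    "OccupancyError",
    "OccupancyModel",
    "OccupancyEstimate",
    "occupancy",
    "occupancy_summary",
    "apparent_occupancy",
    "invert_occupancy",
    "occupancy_from_simulation",
]


class OccupancyError(ValueError):
    pass


@dataclass(frozen=True)
class OccupancyModel:
    """Subunit-level model of the IP: n subunits per channel, per-epitope
    capture efficiency, and the per-subunit phosphorylation probability."""

    n_subunits: int = 4
    capture_eff: float = 1.0
    p: float = float("nan")

    def __post_init__(self):
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")
        if not (0.0 < self.capture_eff <= 1.0):
            raise ValueError("capture_eff must be in (0, 1]")


@dataclass
class OccupancyEstimate:
    oc_measured: float
    oc_se: float
    p_hat: float
    p_se: float
    site_id: str = ""


def occupancy(exp: IPExperiment) -> float:
    """Measured phosphate occupancy (%) from one signal quadruple."""
    if exp.t_input <= 0:
        raise OccupancyError(f"{exp.site_id or 'experiment'}: TRP input signal must be > 0")
    if exp.p_input < 0 or exp.t_ip < 0:
        raise OccupancyError(f"{exp.site_id or 'experiment'}: negative signal")
    if exp.p_input == 0:
        return 0.0
    if exp.p_ip <= 0:
        raise OccupancyError(
            f"{exp.site_id or 'experiment'}: phospho IP signal must be > 0"
        )
    return 100.0 * (exp.p_input / exp.t_input) * (exp.t_ip / exp.p_ip)


def occupancy_summary(exps: Sequence[IPExperiment]) -> tuple[float, float]:
    """Mean ± SEM of occupancy over replicate experiments."""
    if not exps:
        raise OccupancyError("no experiments")
    ocs = np.array([occupancy(e) for e in exps])
    se = float(np.std(ocs, ddof=1) / np.sqrt(ocs.size)) if ocs.size > 1 else float("nan")
    return float(ocs.mean()), se


def apparent_occupancy(p: float, n_subunits: int = 4, capture_eff: float = 1.0) -> float:
    """Occupancy (%) the IP assay reports for true per-subunit probability p.

    Exact binomial expectation over the number of phospho-subunits per
    channel; closed form 100·(1 − (1 − p)^n) when every phosphorylated
    channel is captured (capture_eff = 1).
    """
    if not (0.0 <= p <= 1.0):
        raise OccupancyError(f"p must be in [0, 1], got {p}")
    if n_subunits < 1:
        raise OccupancyError("n_subunits must be >= 1")
    if not (0.0 < capture_eff <= 1.0):
        raise OccupancyError(f"capture_eff must be in (0, 1], got {capture_eff}")
    if p == 0.0:
        return 0.0
    n = n_subunits
    if capture_eff == 1.0:
        return 100.0 * (1.0 - (1.0 - p) ** n)
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, p)
    p_cap = 1.0 - (1.0 - capture_eff) ** k
    e_cap = float(np.sum(pmf * p_cap))       # P(channel captured)
    e_kcap = float(np.sum(pmf * p_cap * k))  # E[phospho-subunits | captured] * P(captured)
    # (p_in/t_in) = p; (t_ip/p_ip) = n * P(captured) / E[K·P_cap(K)]
    return 100.0 * p * n * e_cap / e_kcap


def invert_occupancy(
    oc_apparent: float,
    n_subunits: int = 4,
    capture_eff: float = 1.0,
    tol: float = 1e-10,
) -> float:
    """Per-subunit phosphorylation probability p implied by a measured OC.

    Closed form p = 1 − (1 − OC/100)^(1/n) at capture_eff = 1; otherwise a
    monotone bisection on :func:`apparent_occupancy`.
    """
    if not (0.0 <= oc_apparent <= 100.0):
        raise OccupancyError(f"OC must be in [0, 100], got {oc_apparent}")
    if oc_apparent == 0.0:
        return 0.0
    if oc_apparent == 100.0:
        return 1.0
    if capture_eff == 1.0:
        return float(1.0 - (1.0 - oc_apparent / 100.0) ** (1.0 / n_subunits))
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if apparent_occupancy(mid, n_subunits, capture_eff) < oc_apparent:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def occupancy_from_simulation(
    sim: IPExperiment,
    model: OccupancyModel | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> OccupancyEstimate:
    """Measured OC and model-corrected p from a simulated IP experiment.

    The Monte-Carlo standard errors come from a nonparametric bootstrap
    over channels (available only when the simulation retained per-channel
    phospho-subunit counts).
    """
    model = model or OccupancyModel()
    oc = occupancy(sim)
    p_hat = invert_occupancy(min(oc, 100.0), model.n_subunits, model.capture_eff)
    oc_se = p_se = float("nan")
    if sim.phospho_counts is not None and sim.captured is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        k = np.asarray(sim.phospho_counts)
        cap = np.asarray(sim.captured, dtype=bool)
        n = model.n_subunits
        n_ch = k.size
        ocs = np.empty(n_boot)
        ps = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n_ch, n_ch)
            kb, cb = k[idx], cap[idx]
            exp = IPExperiment(
                p_input=float(kb.sum()),
                t_input=float(n * n_ch),
                p_ip=float(kb[cb].sum()),
                t_ip=float(n * cb.sum()),
            )
            ocs[b] = occupancy(exp)
            ps[b] = invert_occupancy(min(ocs[b], 100.0), n, model.capture_eff)
        oc_se = float(ocs.std(ddof=1))
        p_se = float(ps.std(ddof=1))
    return OccupancyEstimate(oc, oc_se, p_hat, p_se, site_id=sim.site_id)
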