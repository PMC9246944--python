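"""Proteomics quantification and integration into ecModels.

Two halves:

* **absolute quantification** from spectral counts — the normalized spectral
  abundance factor NSAF_i = (SpC_i/L_i) / Σ_j (SpC_j/L_j) gives relative
  abundances; a log-log regression of known spiked standard amounts on their
  NSAF values converts them to absolute terms (rescaled to mmol/gDW through
  a configured loading factor);

* **constraint integration** — measured abundances become upper bounds on
  the corresponding enzyme-usage reactions (those proteins' mass is already
  spent, so they are detached from the pool), while unmeasured proteins draw
  from a remaining pool bounded by ``(Ptot − measured mass) · f · σ``.
  Because abundance data are noisy, an infeasible condition triggers a
  greedy flexibilization: bounds are loosened one protein at a time (the one
  whose relaxation buys the most growth), falling back to joint relaxation
  of the top-k candidates with k doubling, until the target growth rate is
  reachable.  Every loosening is logged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import solve_fba
from .simulate import ConditionSpec, UsageProfile, apply_exchange_bounds
from .transform import (
    ECModel,
    ENZYME_COMPARTMENT,
    POOL_MET,
    POOL_RXN,
    PROT_PREFIX,
)
from .core import Metabolite, Reaction

__all__ = [
    "SpectralCounts",
    "StandardsTable",
    "ProteomicsDataset",
    "FlexEntry",
    "FlexLog",
    "NonProteomicLimitError",
    "nsaf",
    "calibrate_absolute",
    "constrain_with_proteomics",
    "flexibilize_proteins",
    "condition_responsive",
    "make_condition_models",
    "read_proteomics",
]

BOUND_TOL = 1e-9
RELAX_HEADROOM = 1.01


class NonProteomicLimitError(RuntimeError):
    """Growth target unreachable even with all measured bounds removed."""


@dataclass
class SpectralCounts:
    """Per-protein spectral counts and sequence lengths (residues)."""

    spc: dict[str, float]
    length: dict[str, float]

    def __post_init__(self) -> None:
        for pid, L in self.length.items():
            if not L > 0:
                raise ValueError(f"{pid}: sequence length must be positive")
        missing = set(self.spc) - set(self.length)
        if missing:
            raise ValueError(f"proteins without length: {sorted(missing)}")


@dataclass
class StandardsTable:
    """Spiked standards: known amount (mol-scale) and observed NSAF."""

    amount: dict[str, float]
    nsaf: dict[str, float]

    def __post_init__(self) -> None:
        if len(set(self.amount.values())) < 2:
            raise ValueError("need >= 2 standards with distinct amounts")
        for pid, x in self.nsaf.items():
            if not x > 0:
                raise ValueError(f"standard {pid}: non-positive NSAF")


@dataclass
class ProteomicsDataset:
    """Absolute abundances (mmol/gDW) per condition, with provenance."""

    abundance: pd.DataFrame  # index protein_id, one column per condition
    provenance: pd.DataFrame | None = None  # "measured" | "imputed"

    def __post_init__(self) -> None:
        if (self.abundance.fillna(0.0).to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def conditions(self) -> list[str]:
        return list(self.abundance.columns)

    def condition(self, name: str) -> dict[str, float]:
        col = self.abundance[name].dropna()
        return {str(p): float(v) for p, v in col.items()}


@dataclass
class FlexEntry:
    protein_id: str
    original_bound: float
    relaxed_bound: float
    iteration: int


@dataclass
class FlexLog:
    entries: list[FlexEntry] = field(default_factory=list)
    feasible: bool = False

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def proteins(self) -> list[str]:
        return [e.protein_id for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------


def nsaf(counts: SpectralCounts) -> dict[str, float]:
    """Normalized spectral abundance factors; values sum to 1."""
    ratios = {pid: counts.spc[pid] / counts.length[pid] for pid in counts.spc}
    total = sum(ratios.values())
    if total <= 0:
        raise ValueError("all spectral counts are zero")
    return {pid: r / total for pid, r in ratios.items()}


def calibrate_absolute(
    nsaf_values: Mapping[str, float],
    standards: StandardsTable,
    scale: float = 1.0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Convert NSAF to absolute abundance via log-log standards regression.

    Least squares fit of log10(amount) on log10(NSAF) over the standards;
    applied to every protein and rescaled by ``scale`` (the configured
    protein-loading factor mapping mol-scale amounts to mmol/gDW).
    Returns (abundances, fit) with fit slope/intercept/r2.
    """
    pids = sorted(standards.amount)
    x = np.log10([standards.nsaf[p] for p in pids])
    y = np.log10([standards.amount[p] for p in pids])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    out = {}
    for pid, val in nsaf_values.items():
        if val <= 0:
            out[pid] = 0.0
        else:
            out[pid] = float(10 ** (slope * math.log10(val) + intercept)) * scale
    return out, {"slope": float(slope), "intercept": float(intercept), "r2": r2}


def read_proteomics(path: str | Path) -> ProteomicsDataset:
    df = pd.read_csv(path, sep="\t").set_index("protein_id")
    return ProteomicsDataset(abundance=df)


# ---------------------------------------------------------------------------
# Constraint integration
# ---------------------------------------------------------------------------


def constrain_with_proteomics(
    ec: ECModel,
    abundances: Mapping[str, float],
    Ptot: float,
    f: float,
    sigma: float,
) -> ECModel:
    """Impose measured abundances as usage bounds; pool the unmeasured rest.

    Measured proteins get ``usage ub = [E_i]`` and stay disconnected from the
    pool (their mass is already spent); unmeasured proteins share a remaining
    pool of ``max(0, Ptot − Σ MW·[E_i]) · f · σ`` g/gDW.
    """
    if ec.pool is not None:
        raise ValueError("proteomics constraints need the unbounded-usage flavour")
    measured = {p: a for p, a in abundances.items() if p in ec.map.usage_rxn}
    measured_mass = sum(ec.enzymes[p].mw_kda * a for p, a in measured.items())
    if measured_mass > Ptot:
        raise ValueError(
            f"measured protein mass {measured_mass:.4g} g/gDW exceeds Ptot {Ptot}: "
            "inconsistent data"
        )
    out = ec.copy()
    remaining = max(0.0, Ptot - measured_mass) * f * sigma
    out.model.metabolites.append(
        Metabolite(POOL_MET, name="remaining protein pool", compartment=ENZYME_COMPARTMENT)
    )
    for pid, uid in out.map.usage_rxn.items():
        rxn = out.model.reaction(uid)
        if pid in measured:
            rxn.ub = float(measured[pid])
        else:
            rxn.stoichiometry = {
                POOL_MET: -out.enzymes[pid].mw_kda,
                PROT_PREFIX + pid: 1.0,
            }
    out.model.reactions.append(
        Reaction(
            id=POOL_RXN, name="remaining protein pool exchange",
            stoichiometry={POOL_MET: 1.0}, lb=0.0, ub=remaining,
        )
    )
    out.pool = {
        "pool_rxn_id": POOL_RXN, "Ptot": Ptot, "f": f, "sigma": sigma,
        "remaining": remaining, "measured": sorted(measured),
    }
    out.model.validate()
    return out


def _max_mu(ec: ECModel, biomass_rxn: str) -> float:
    flux = solve_fba(ec.model, objective=biomass_rxn)
    return flux.objective_value if flux.optimal else 0.0


def flexibilize_proteins(
    ec: ECModel,
    cond: ConditionSpec,
    max_iter: int = 100,
) -> tuple[ECModel, FlexLog]:
    """Loosen measured usage bounds until growth at the target rate is feasible.

    Greedy: probe the growth gained by unbounding each measured protein
    alone; relax the best one to its probe usage × 1.01.  When no single
    relaxation helps, relax the top-k jointly with k doubling.  Exchange
    bounds are expected to be applied to ``ec`` already.
    """
    target = cond.dilution_rate if cond.dilution_rate is not None else cond.mu_exp
    if target is None:
        raise ValueError("condition needs a dilution rate or experimental mu")
    out = ec.copy()
    log = FlexLog()
    measured = list((out.pool or {}).get("measured", []))
    if not measured:
        log.feasible = _max_mu(out, cond.biomass_rxn) >= target - BOUND_TOL
        return out, log

    # is the limitation proteomic at all?
    free = out.copy()
    for pid in measured:
        free.model.reaction(free.map.usage_rxn[pid]).ub = math.inf
    if _max_mu(free, cond.biomass_rxn) < target - BOUND_TOL:
        raise NonProteomicLimitError(
            f"target growth {target} 1/h unreachable even with every measured "
            "bound removed: the limitation is not proteomic"
        )

    for iteration in range(1, max_iter + 1):
        base = solve_fba(out.model, objective=cond.biomass_rxn)
        mu = base.objective_value if base.optimal else 0.0
        if mu >= target - BOUND_TOL:
            log.feasible = True
            return out, log
        # only proteins sitting at their bound can be responsible
        at_bound = [
            pid
            for pid in measured
            if base.optimal
            and base.fluxes[out.map.usage_rxn[pid]]
            >= out.model.reaction(out.map.usage_rxn[pid]).ub - BOUND_TOL
        ] or list(measured)
        gains: list[tuple[float, str, float]] = []  # (mu gain, protein, probe usage)
        for pid in at_bound:
            uid = out.map.usage_rxn[pid]
            rxn = out.model.reaction(uid)
            old_ub = rxn.ub
            rxn.ub = math.inf
            probe = solve_fba(out.model, objective=cond.biomass_rxn)
            rxn.ub = old_ub
            if probe.optimal:
                gains.append((probe.objective_value - mu, pid, probe.fluxes[uid]))
        gains.sort(key=lambda t: (-t[0], t[1]))
        if gains and gains[0][0] > BOUND_TOL:
            gain, pid, usage = gains[0]
            uid = out.map.usage_rxn[pid]
            rxn = out.model.reaction(uid)
            new_ub = max(usage * RELAX_HEADROOM, rxn.ub)
            log.entries.append(FlexEntry(pid, rxn.ub, new_ub, iteration))
            rxn.ub = new_ub
            continue
        # joint fallback: no single bound is responsible
        k = 2
        relaxed_any = False
        while k <= len(gains):
            subset = gains[:k]
            olds = {}
            for _, pid, _ in subset:
                uid = out.map.usage_rxn[pid]
                olds[pid] = out.model.reaction(uid).ub
                out.model.reaction(uid).ub = math.inf
            probe = solve_fba(out.model, objective=cond.biomass_rxn)
            if probe.optimal and probe.objective_value > mu + BOUND_TOL:
                for _, pid, _ in subset:
                    uid = out.map.usage_rxn[pid]
                    new_ub = probe.fluxes[uid] * RELAX_HEADROOM
                    if new_ub > olds[pid] + BOUND_TOL:
                        out.model.reaction(uid).ub = new_ub
                        log.entries.append(FlexEntry(pid, olds[pid], new_ub, iteration))
                    else:  # this bound was not responsible: restore it
                        out.model.reaction(uid).ub = olds[pid]
                relaxed_any = True
                break
            for _, pid, _ in subset:
                out.model.reaction(out.map.usage_rxn[pid]).ub = olds[pid]
            k *= 2
        if not relaxed_any:
            break
    log.feasible = _max_mu(out, cond.biomass_rxn) >= target - BOUND_TOL
    if not log.feasible:
        raise NonProteomicLimitError(
            f"flexibilization stalled below the target growth rate {target} 1/h"
        )
    return out, log


def condition_responsive(
    ref: UsageProfile,
    stress: UsageProfile,
    saturation_min: float = 0.95,
) -> list[str]:
    """Enzymes upregulated *and* more saturated under stress.

    A protein qualifies when its measured abundance fold-change (stress over
    reference) exceeds 1, its saturation fold-change exceeds 1, and its
    stress saturation is at least ``saturation_min``.
    """
    out = []
    for pid in sorted(set(ref.saturation) & set(stress.saturation)):
        ab_ref, ab_str = ref.abundance.get(pid, 0.0), stress.abundance.get(pid, 0.0)
        sat_ref, sat_str = ref.saturation[pid], stress.saturation[pid]
        if ab_ref <= 0 or sat_ref <= 0:
            continue
        if (
            ab_str / ab_ref > 1.0
            and sat_str / sat_ref > 1.0
            and sat_str >= saturation_min
        ):
            out.append(pid)
    return out


def make_condition_models(
    ec: ECModel,
    dataset: ProteomicsDataset,
    conditions: Mapping[str, ConditionSpec],
    f: float,
    sigma: float,
) -> dict[str, tuple[ECModel, FlexLog]]:
    """Per condition: constrain with that column, apply bounds, flexibilize."""
    out: dict[str, tuple[ECModel, FlexLog]] = {}
    for name, cond in conditions.items():
        if name not in dataset.abundance.columns:
            raise KeyError(f"condition {name!r} has no column in the dataset")
        if cond.Ptot is None:
            raise ValueError(f"condition {name!r} needs Ptot")
        constrained = constrain_with_proteomics(
            ec, dataset.condition(name), cond.Ptot, f, sigma
        )
        apply_exchange_bounds(
            constrained.model, cond.exchange_bounds, constrained.map.net_to_copies
        )
        out[name] = flexibilize_proteins(constrained, cond)
    return out
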