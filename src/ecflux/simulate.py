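"""Simulation recipes and enzyme-usage analytics for ecModels.

Three headline protocols, each finishing with a parsimonious-FBA polish so
the reported flux vector is reproducible across solvers:

* **batch growth** — unconstrained uptake of minimal-medium components plus
  the named carbon source, maximise biomass;
* **protein demand** — biomass fixed at a measured growth rate, pool bound
  released, minimise the protein pool exchange (the minimal enzyme mass able
  to sustain that rate);
* **chemostat** — biomass fixed at the dilution rate D with measured
  exchange bounds applied, then maximise the non-growth-associated
  maintenance (NGAM) reaction as a stand-in for unaccounted energy demands;
  proteomics-constrained models instead minimise the total usage of
  unmeasured proteins.

Downstream analytics turn an optimal flux vector into per-protein usage and
saturation profiles, per-pathway protein mass burdens, and flux fold-change
classifications between two conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core import FluxDistribution, MetabolicModel, solve_fba, solve_pfba
from .transform import ECModel, map_net_fluxes

__all__ = [
    "ConditionSpec",
    "UsageProfile",
    "PathwayBurden",
    "ZeroGrowthError",
    "InfeasibleConditionError",
    "apply_exchange_bounds",
    "set_net_bounds",
    "simulate_batch",
    "predict_protein_demand",
    "simulate_chemostat",
    "usage_profile",
    "pathway_burden",
    "flux_fold_change_report",
]

ACTIVITY_EPS = 1e-8


class ZeroGrowthError(RuntimeError):
    """The model is feasible but cannot grow under the given condition."""


class InfeasibleConditionError(RuntimeError):
    """The imposed condition makes the model infeasible."""

    def __init__(self, message: str, binding_bounds: list[str] | None = None):
        super().__init__(message)
        self.binding_bounds = binding_bounds or []


@dataclass
class ConditionSpec:
    """One cultivation condition: rates, exchange bounds and key reaction ids."""

    biomass_rxn: str
    carbon_source_rxn: str
    ngam_rxn: str | None = None
    dilution_rate: float | None = None  # 1/h (chemostat)
    mu_exp: float | None = None  # 1/h (batch)
    exchange_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    Ptot: float | None = None  # g protein / gDW

    def __post_init__(self) -> None:
        if self.dilution_rate is not None and self.dilution_rate < 0:
            raise ValueError("dilution rate must be non-negative")


@dataclass
class UsageProfile:
    """Per-protein predicted usage, measured abundance and saturation."""

    usage: dict[str, float]  # e_i, mmol/gDW
    abundance: dict[str, float] = field(default_factory=dict)  # [E_i], mmol/gDW
    saturation: dict[str, float] = field(default_factory=dict)  # e_i / [E_i]

    @property
    def proteins(self) -> list[str]:
        return sorted(self.usage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.proteins,
                "usage": [self.usage[p] for p in self.proteins],
                "abundance": [self.abundance.get(p, math.nan) for p in self.proteins],
                "saturation": [self.saturation.get(p, math.nan) for p in self.proteins],
            }
        )


@dataclass
class PathwayBurden:
    burden: dict[str, float]  # subsystem -> g/gDW
    members: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        subs = sorted(self.burden)
        return pd.DataFrame(
            {
                "subsystem": subs,
                "burden_g_per_gDW": [self.burden[s] for s in subs],
                "members": [self.members[s] for s in subs],
            }
        )

    @property
    def total(self) -> float:
        return sum(self.burden.values())


# ---------------------------------------------------------------------------
# Condition plumbing
# ---------------------------------------------------------------------------


def _as_model(m: MetabolicModel | ECModel) -> MetabolicModel:
    return m.model if isinstance(m, ECModel) else m


def _net_map(m: MetabolicModel | ECModel) -> dict | None:
    return m.map.net_to_copies if isinstance(m, ECModel) else None


def set_net_bounds(
    model: MetabolicModel,
    net_map: Mapping[str, list[tuple[str, str]]] | None,
    rid: str,
    lb: float,
    ub: float,
) -> None:
    """Set bounds on a net GEM reaction, translating to split copies.

    In an irreversible model a net interval [lb, ub] maps to forward-copy
    bounds [max(lb,0), max(ub,0)] and backward-copy bounds
    [max(-ub,0), max(-lb,0)], which reproduces the net range exactly for a
    single fwd/rev pair.  Nets expanded into several isoenzyme copies cannot
    be bounded per copy and are rejected.
    """
    if net_map is None or rid not in net_map:
        rxn = model.reaction(rid)
        rxn.lb, rxn.ub = float(lb), float(ub)
        return
    copies = net_map[rid]
    fwd = [cid for cid, d in copies if d == "fwd"]
    rev = [cid for cid, d in copies if d == "rev"]
    if len(fwd) > 1 or len(rev) > 1:
        raise ValueError(
            f"cannot bound net reaction {rid!r}: expanded into isoenzyme copies"
        )
    for cid in fwd:
        rxn = model.reaction(cid)
        rxn.lb, rxn.ub = max(float(lb), 0.0), max(float(ub), 0.0)
    for cid in rev:
        rxn = model.reaction(cid)
        rxn.lb, rxn.ub = max(-float(ub), 0.0), max(-float(lb), 0.0)


def apply_exchange_bounds(
    model: MetabolicModel,
    bounds: Mapping[str, tuple[float, float]],
    net_map: Mapping[str, list[tuple[str, str]]] | None = None,
) -> None:
    for rid, (lb, ub) in bounds.items():
        set_net_bounds(model, net_map, rid, lb, ub)


def _diagnose_binding(
    model: MetabolicModel, cond: ConditionSpec, net_map: dict | None = None
) -> list[str]:
    """Greedy probe: which imposed exchange bounds, relaxed alone, restore feasibility."""
    binding = []
    for rid in cond.exchange_bounds:
        probe = model.copy()
        set_net_bounds(probe, net_map, rid, -1000.0, 1000.0)
        if solve_fba(probe, objective=cond.biomass_rxn).optimal:
            binding.append(rid)
    return binding


# ---------------------------------------------------------------------------
# Headline simulations
# ---------------------------------------------------------------------------


def simulate_batch(ec: ECModel | MetabolicModel, cond: ConditionSpec) -> FluxDistribution:
    """Maximise biomass with open carbon-source uptake, then pFBA-polish."""
    net_map = _net_map(ec)
    model = _as_model(ec).copy()
    apply_exchange_bounds(model, cond.exchange_bounds, net_map)
    if cond.carbon_source_rxn not in cond.exchange_bounds:
        set_net_bounds(model, net_map, cond.carbon_source_rxn, -1000.0, 0.0)
    flux = solve_pfba(model, objective=cond.biomass_rxn)
    if not flux.optimal:
        raise InfeasibleConditionError(
            f"batch simulation infeasible ({flux.status})",
            _diagnose_binding(model, cond, net_map),
        )
    if flux.objective_value <= ACTIVITY_EPS:
        raise ZeroGrowthError("model is feasible but predicts zero growth")
    return flux


def predict_protein_demand(
    ec: ECModel, mu_fixed: float, cond: ConditionSpec
) -> tuple[float, FluxDistribution]:
    """Minimal protein pool (g/gDW) able to sustain a fixed growth rate."""
    if ec.pool is None:
        raise ValueError("protein-demand prediction needs a pooled ecModel")
    if mu_fixed < 0:
        raise ValueError("growth rate must be non-negative")
    net_map = _net_map(ec)
    model = ec.model.copy()
    apply_exchange_bounds(model, cond.exchange_bounds, net_map)
    if cond.carbon_source_rxn not in cond.exchange_bounds:
        set_net_bounds(model, net_map, cond.carbon_source_rxn, -1000.0, 0.0)
    set_net_bounds(model, net_map, cond.biomass_rxn, mu_fixed, mu_fixed)
    pool_rxn = model.reaction(ec.pool["pool_rxn_id"])
    pool_rxn.ub = math.inf
    flux = solve_pfba(model, objective=ec.pool["pool_rxn_id"], direction="min")
    if not flux.optimal:
        raise InfeasibleConditionError(
            f"growth fixing at {mu_fixed} is infeasible ({flux.status})"
        )
    return float(flux.objective_value), flux


def simulate_chemostat(
    m: MetabolicModel | ECModel,
    cond: ConditionSpec,
    proteomics_mode: bool = False,
    unmeasured_proteins: Sequence[str] | None = None,
) -> FluxDistribution:
    """Fix biomass at the dilution rate and optimise the secondary objective.

    Plain GEMs and pool models maximise the NGAM reaction; proteomics models
    (``proteomics_mode=True``) minimise the summed usage of unmeasured
    proteins instead.
    """
    if cond.dilution_rate is None:
        raise ValueError("chemostat simulation needs a dilution rate")
    net_map = _net_map(m)
    model = _as_model(m).copy()
    apply_exchange_bounds(model, cond.exchange_bounds, net_map)
    set_net_bounds(model, net_map, cond.biomass_rxn, cond.dilution_rate, cond.dilution_rate)
    if proteomics_mode:
        if not isinstance(m, ECModel):
            raise ValueError("proteomics mode needs an ecModel")
        targets = set(unmeasured_proteins if unmeasured_proteins is not None else m.proteins)
        for pid in targets:
            uid = m.map.usage_rxn[pid]
            model.reaction(uid).objective_coef = 1.0
        for rxn in model.reactions:
            if rxn.id not in {m.map.usage_rxn[p] for p in targets}:
                rxn.objective_coef = 0.0
        if not targets:
            # every protein measured: nothing to minimise, report the base point
            flux = solve_pfba(model, objective=cond.biomass_rxn)
            if flux.optimal:
                return FluxDistribution(flux.fluxes, 0.0, "optimal")
        else:
            flux = solve_pfba(model, direction="min")
            if flux.optimal:
                return flux
    else:
        if cond.ngam_rxn is None:
            raise ValueError("chemostat simulation needs an NGAM reaction id")
        flux = solve_pfba(model, objective=cond.ngam_rxn)
        if flux.optimal:
            return flux
    raise InfeasibleConditionError(
        f"dilution rate {cond.dilution_rate} infeasible under the imposed bounds",
        _diagnose_binding(model, cond, net_map),
    )


# ---------------------------------------------------------------------------
# Usage analytics
# ---------------------------------------------------------------------------


def usage_profile(
    ec: ECModel,
    flux: FluxDistribution,
    abundances: Mapping[str, float] | None = None,
) -> UsageProfile:
    """Per-protein usage e_i; saturation e_i/[E_i] for measured proteins only."""
    usage = {pid: flux.fluxes.get(uid, 0.0) for pid, uid in ec.map.usage_rxn.items()}
    profile = UsageProfile(usage=usage)
    if abundances:
        for pid, ab in abundances.items():
            if pid not in usage:
                continue
            profile.abundance[pid] = float(ab)
            if ab > 0:
                profile.saturation[pid] = usage[pid] / ab
    return profile


def pathway_burden(
    ec: ECModel,
    profile: UsageProfile,
    subsystems: Mapping[str, str] | None = None,
) -> PathwayBurden:
    """Protein mass (Σ MW·e_i, g/gDW) grouped by subsystem; unassigned → "other"."""
    burden: dict[str, float] = {}
    members: dict[str, int] = {}
    subsystems = subsystems or {}
    for pid, e in profile.usage.items():
        sub = subsystems.get(pid, "other")
        mw = ec.enzymes[pid].mw_kda
        burden[sub] = burden.get(sub, 0.0) + mw * e
        members[sub] = members.get(sub, 0) + 1
    return PathwayBurden(burden=burden, members=members)


def flux_fold_change_report(
    vA: FluxDistribution,
    vB: FluxDistribution,
    eps: float = ACTIVITY_EPS,
) -> pd.DataFrame:
    """Classify per-reaction flux changes between two conditions.

    Classes: ``within_2x`` (0.5 < FC < 2), ``within_10x``, ``changed``
    (active in both, FC outside 10x), ``enabled`` (off → on), ``disabled``
    (on → off), ``inactive``.  The summary row fractions are over active
    reactions (active in either condition).
    """
    if set(vA.fluxes) != set(vB.fluxes):
        raise ValueError("flux distributions cover different reaction sets")
    rows = []
    for rid in sorted(vA.fluxes):
        a, b = vA.fluxes[rid], vB.fluxes[rid]
        active_a, active_b = abs(a) > eps, abs(b) > eps
        fc = b / a if active_a else math.nan
        if not active_a and not active_b:
            cls = "inactive"
        elif active_a and not active_b:
            cls = "disabled"
        elif active_b and not active_a:
            cls = "enabled"
        else:
            ratio = fc
            if 0.5 < ratio < 2.0:
                cls = "within_2x"
            elif 0.1 < ratio < 10.0:
                cls = "within_10x"
            else:
                cls = "changed"
        rows.append({"reaction": rid, "vA": a, "vB": b, "fold_change": fc, "class": cls})
    return pd.DataFrame(rows)


def fold_change_fractions(report: pd.DataFrame) -> dict[str, float]:
    """Fractions of each class among active (non-``inactive``) reactions."""
    active = report[report["class"] != "inactive"]
    n = len(active)
    if n == 0:
        return {}
    frac = (active["class"].value_counts() / n).to_dict()
    # within_10x is cumulative over within_2x in the reported fractions
    frac["within_10x"] = frac.get("within_10x", 0.0) + frac.get("within_2x", 0.0)
    return frac
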