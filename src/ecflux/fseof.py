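"""Overexpression-target scanning by enforced objective flux (FSEOF-style).

To find reactions and enzymes whose activity must rise when a product is
made in larger amounts, production of the target is enforced at K evenly
spaced levels between its flux at the growth optimum and a fraction of its
theoretical maximum; at each level growth is re-maximised and pFBA-polished.
Candidates whose flux (net GEM reactions) or usage (proteins — a natural
extension in ecModels, where usage reactions are first-class) increases
strictly and with consistent sign across the scan are putative
overexpression targets, ranked by the slope of a linear fit against the
enforced production level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import solve_fba, solve_pfba
from .simulate import InfeasibleConditionError
from .transform import ECModel, map_net_fluxes

__all__ = ["FseofResult", "run_fseof"]

MONOTONE_TOL = 1e-9


@dataclass
class FseofResult:
    levels: list[float]  # enforced production fluxes, strictly increasing
    growth: list[float]  # growth at each level
    profiles: pd.DataFrame  # one row per candidate, value columns per step
    targets: pd.DataFrame  # monotone candidates ranked by slope (per kind)

    @property
    def top_protein(self) -> str | None:
        prot = self.targets[self.targets["kind"] == "protein"]
        if prot.empty:
            return None
        return str(prot.iloc[0]["candidate"])


def _monotone(values: np.ndarray, tol: float = MONOTONE_TOL) -> bool:
    diffs = np.diff(values)
    if not (diffs > tol).all():
        return False
    nz = values[np.abs(values) > tol]
    return len(nz) == 0 or (nz > 0).all() or (nz < 0).all()


def run_fseof(
    ec: ECModel,
    target_rxn: str,
    biomass_rxn: str | None = None,
    steps: int = 10,
    max_fraction: float = 0.9,
    min_growth_fraction: float = 0.1,
) -> FseofResult:
    """Scan enforced production of ``target_rxn`` and rank rising candidates.

    ``v_init`` is the target flux at the (pFBA-polished) growth optimum and
    ``v_max`` its maximum subject to growth staying above
    ``min_growth_fraction`` of the optimum; the scan enforces ``steps``
    levels up to ``max_fraction · v_max``.
    """
    if steps < 3:
        raise ValueError("need at least 3 scan steps")
    model = ec.model
    if not model.has_reaction(target_rxn):
        raise KeyError(f"target reaction {target_rxn!r} not in model")
    objective_ids = model.objective_ids if biomass_rxn is None else [biomass_rxn]
    if target_rxn in objective_ids:
        raise ValueError("target reaction must not be the biomass objective")

    base = solve_pfba(model, objective=biomass_rxn)
    if not base.optimal:
        raise InfeasibleConditionError("base growth FBA is infeasible")
    mu_max = base.objective_value
    v_init = base.fluxes[target_rxn]

    capped = model.copy()
    if biomass_rxn is not None:
        capped.reaction(biomass_rxn).lb = min_growth_fraction * mu_max
    else:
        for rid in objective_ids:
            capped.reaction(rid).lb = min_growth_fraction * mu_max
    vmax_sol = solve_fba(capped, objective=target_rxn)
    if not vmax_sol.optimal:
        raise InfeasibleConditionError("target maximisation is infeasible")
    v_max = vmax_sol.objective_value
    top = max_fraction * v_max
    if top <= v_init + MONOTONE_TOL:
        raise ValueError(
            f"nothing to scan: target flux at growth optimum ({v_init:.6g}) already "
            f"reaches {max_fraction:.0%} of its maximum ({v_max:.6g})"
        )

    levels = list(np.linspace(v_init, top, steps))
    growth: list[float] = []
    net_rows: dict[str, list[float]] = {nid: [] for nid in ec.map.net_to_copies}
    usage_rows: dict[str, list[float]] = {pid: [] for pid in ec.map.usage_rxn}
    for level in levels:
        step_model = model.copy()
        rxn = step_model.reaction(target_rxn)
        rxn.lb = rxn.ub = float(level)
        flux = solve_pfba(step_model, objective=biomass_rxn)
        if not flux.optimal:
            raise InfeasibleConditionError(
                f"enforced production level {level:.6g} is infeasible"
            )
        growth.append(flux.objective_value)
        net = map_net_fluxes(ec, flux)
        for nid in net_rows:
            net_rows[nid].append(net.fluxes[nid])
        for pid, uid in ec.map.usage_rxn.items():
            usage_rows[pid].append(flux.fluxes[uid])

    records = []
    x = np.asarray(levels)
    for kind, rows in (("reaction", net_rows), ("protein", usage_rows)):
        for cid, values in rows.items():
            v = np.asarray(values)
            slope = float(np.polyfit(x, v, 1)[0]) if np.ptp(v) > 0 else 0.0
            records.append(
                {
                    "candidate": cid,
                    "kind": kind,
                    "slope": slope,
                    "monotone": _monotone(v),
                    **{f"step_{i}": float(val) for i, val in enumerate(values)},
                }
            )
    profiles = pd.DataFrame(records)
    targets = (
        profiles[profiles["monotone"]]
        .sort_values(["kind", "slope"], ascending=[True, False])
        .copy()
    )
    targets["rank"] = targets.groupby("kind")["slope"].rank(
        ascending=False, method="first"
    ).astype(int)
    targets = targets.sort_values(["kind", "rank"]).reset_index(drop=True)
    return FseofResult(levels=levels, growth=growth, profiles=profiles, targets=targets)
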