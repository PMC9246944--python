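"""Automatic curation of over-constraining kcats and σ calibration.

An automatically parameterised ecModel often under-predicts the measured
maximum growth rate because one or a few kcats are far too small (wrong
substrate, distant donor organism, atypical assay).  The curation loop
identifies the top kinetic limitation through *enzyme control coefficients*
(ECC): for protein *i*, all of its kcats are scaled by a large factor α and

    ECC_i = (μ_i − μ0) / μ0

measures the relative growth gain from relaxing that single enzyme's
constraint.  The protein with the largest ECC has its kcat replaced by the
largest value reachable in the kinetic catalog for its EC class (widening
wildcards as needed), and the loop repeats until the experimental growth
rate is reached.  Because raising a kcat only shrinks an LP constraint
coefficient, μ is non-decreasing along the loop.

σ — the average in-vivo enzyme saturation scaling the shared pool bound
``Ptot·f·σ`` — is fitted separately by bisection against the experimental
growth rate, exploiting monotonicity of μ in the pool bound.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .core import solve_fba
from .kinetics import (
    KcatQuery,
    KineticCatalog,
    Taxonomy,
    sa_to_kcat,
    wildcard_levels,
)
from .transform import ECModel

__all__ = [
    "CurationStep",
    "CurationLog",
    "StoichiometricLimitError",
    "enzyme_control_coefficients",
    "best_catalog_kcat",
    "flexibilize_kcats",
    "fit_sigma",
]


class StoichiometricLimitError(RuntimeError):
    """The growth target is unreachable even with all enzyme costs removed."""


@dataclass
class CurationStep:
    protein_id: str
    copy_id: str
    old_kcat: float
    new_kcat: float
    donor_ec: str
    source: str  # kcat | SA | cost_removed
    mu_before: float
    mu_after: float


@dataclass
class CurationLog:
    iterations: list[CurationStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.iterations)

    @property
    def proteins(self) -> list[str]:
        out: list[str] = []
        for step in self.iterations:
            if step.protein_id not in out:
                out.append(step.protein_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.iterations])


def _mu(ec: ECModel, biomass_rxn: str | None) -> float:
    flux = solve_fba(ec.model, objective=biomass_rxn)
    return flux.objective_value if flux.optimal else 0.0


def enzyme_control_coefficients(
    ec: ECModel,
    alpha: float = 1000.0,
    biomass_rxn: str | None = None,
) -> list[tuple[str, float]]:
    """(protein, ECC) sorted by descending control over growth.

    α scales each protein's kcats in turn (α ≫ 1 effectively removes that
    enzyme's constraint); an enzyme that is not limiting at the optimum has
    ECC ≈ 0.
    """
    if alpha <= 1.0:
        raise ValueError("alpha must exceed 1")
    mu0 = _mu(ec, biomass_rxn)
    if mu0 <= 0:
        raise ZeroDivisionError("baseline growth is zero or infeasible")
    eccs: list[tuple[str, float]] = []
    for pid in ec.proteins:
        probe = ec.copy()
        for (p, cid), kc in list(ec.kcats.items()):
            if p == pid:
                probe.set_kcat(p, cid, kc * alpha)
        eccs.append((pid, (_mu(probe, biomass_rxn) - mu0) / mu0))
    eccs.sort(key=lambda t: -t[1])
    return eccs


def best_catalog_kcat(
    ec: ECModel,
    protein_id: str,
    catalog: KineticCatalog,
    tax: Taxonomy,
) -> tuple[float, str, str]:
    """Largest kcat reachable for a protein's EC class, widening wildcards.

    Returns ``(kcat_s, donor_ec, source)``; falls back to the catalog-wide
    maximum (source ``"cost_removed"``) when no EC-compatible entry exists.
    """
    enz = ec.enzymes[protein_id]
    complete = [e for e in enz.ecs if e.complete]
    for w in range(4):
        best: tuple[float, str, str] | None = None
        for ecn in complete:
            for entry in catalog.query(wildcard_levels(ecn)[w]):
                value = (
                    entry.value
                    if entry.ptype == "kcat"
                    else sa_to_kcat(entry.value, enz.mw_kda)
                )
                if best is None or value > best[0]:
                    best = (value, str(entry.ec), entry.ptype)
        if best is not None:
            return best
    return catalog.max_kcat(), "", "cost_removed"


def flexibilize_kcats(
    ec: ECModel,
    mu_exp: float,
    catalog: KineticCatalog,
    tax: Taxonomy,
    alpha: float = 1000.0,
    max_iter: int = 100,
    tol: float = 1e-3,
    biomass_rxn: str | None = None,
) -> tuple[ECModel, CurationLog]:
    """Iteratively substitute the most limiting kcat until μ reaches μ_exp.

    One protein per iteration: the top-ECC enzyme (ties broken by larger
    pool mass share MW·e, then protein id) has the kcat on **all** of its
    reaction copies replaced by the best catalog value for its EC class.
    Stops at μ ≥ μ_exp·(1−tol), after ``max_iter`` rounds, or when no
    substitution improves growth.
    """
    if not mu_exp > 0:
        raise ValueError("experimental growth rate must be positive")
    out = ec.copy()
    log = CurationLog()

    # distinguish kinetic from stoichiometric/medium limitation up front
    free = ec.copy()
    for (pid, cid), kc in list(free.kcats.items()):
        free.set_kcat(pid, cid, 1e9)
    mu_free = _mu(free, biomass_rxn)
    if mu_free < mu_exp * (1 - tol):
        raise StoichiometricLimitError(
            f"target {mu_exp} 1/h unreachable even without enzyme costs "
            f"(max {mu_free:.6g} 1/h): the medium or stoichiometry is limiting, "
            "not the kinetic parameters"
        )

    exhausted: set[str] = set()
    for _ in range(max_iter):
        mu_before = _mu(out, biomass_rxn)
        if mu_before >= mu_exp * (1 - tol):
            break
        eccs = enzyme_control_coefficients(out, alpha=alpha, biomass_rxn=biomass_rxn)
        base = solve_fba(out.model, objective=biomass_rxn)
        mass = {
            pid: out.enzymes[pid].mw_kda * base.fluxes.get(out.map.usage_rxn[pid], 0.0)
            for pid in out.proteins
        }
        ranked = sorted(
            (t for t in eccs if t[0] not in exhausted),
            key=lambda t: (-t[1], -mass[t[0]], t[0]),
        )
        if not ranked:
            break
        pid = ranked[0][0]
        new_kcat, donor_ec, source = best_catalog_kcat(out, pid, catalog, tax)
        improved = False
        for cid in out.copies_of(pid):
            old = out.kcats[(pid, cid)]
            if new_kcat > old:
                out.set_kcat(pid, cid, new_kcat)
                improved = True
                log.iterations.append(
                    CurationStep(
                        protein_id=pid, copy_id=cid, old_kcat=old,
                        new_kcat=new_kcat, donor_ec=donor_ec, source=source,
                        mu_before=mu_before, mu_after=math.nan,
                    )
                )
        if not improved:
            exhausted.add(pid)
            continue
        mu_after = _mu(out, biomass_rxn)
        for step in log.iterations:
            if math.isnan(step.mu_after):
                step.mu_after = mu_after
        if mu_after <= mu_before + 1e-12:
            exhausted.add(pid)
    return out, log


def fit_sigma(
    ec: ECModel,
    mu_exp: float,
    bounds: tuple[float, float] = (0.0, 1.0),
    tol_mu: float = 1e-4,
    max_iter: int = 200,
    biomass_rxn: str | None = None,
) -> float:
    """Bisect σ so that the pooled model grows at μ_exp.

    μ is non-decreasing in σ (a larger pool only relaxes the LP), so plain
    bisection on the pool bound converges.  If μ_exp exceeds μ(σ=1) the upper
    boundary is returned with a warning.
    """
    if ec.pool is None:
        raise ValueError("sigma fitting needs a pooled ecModel")
    if not mu_exp > 0:
        raise ValueError("experimental growth rate must be positive")
    lo, hi = bounds
    Ptot, f = ec.pool["Ptot"], ec.pool["f"]
    pool_rxn = ec.pool["pool_rxn_id"]

    def mu_at(sigma: float) -> float:
        probe = ec.copy()
        probe.model.reaction(pool_rxn).ub = Ptot * f * sigma
        return _mu(probe, biomass_rxn)

    if mu_at(hi) < mu_exp - tol_mu:
        warnings.warn(
            f"mu_exp={mu_exp} exceeds mu(sigma={hi})={mu_at(hi):.6g}; "
            "returning the boundary value",
            stacklevel=2,
        )
        return hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        mu_mid = mu_at(mid)
        if abs(mu_mid - mu_exp) <= tol_mu:
            return mid
        if mu_mid < mu_exp:
            lo = mid
        else:
            hi = mid
    warnings.warn(
        f"sigma bisection did not reach |mu - mu_exp| <= {tol_mu}; returning midpoint",
        stacklevel=2,
    )
    return 0.5 * (lo + hi)
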