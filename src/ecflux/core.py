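"""Core data model for constraint-based metabolic models, I/O and LP solving.

A :class:`MetabolicModel` is a plain stoichiometric network: metabolites,
bounded reactions with gene-protein-reaction (GPR) rules, and a linear
objective.  Flux balance analysis (FBA) finds a flux vector ``v`` maximising
the objective subject to ``S v = 0`` and ``lb <= v <= ub``; parsimonious FBA
(pFBA) additionally minimises total absolute flux at (a fraction of) the FBA
optimum, removing most alternate-optima ambiguity.

Models round-trip through two dialects: SBML Level 3 with the FBC v2 package
(via cobrapy) and a plain-text tabular dialect (``reactions.tsv`` +
``metabolites.tsv``) suitable for diffable fixtures.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

__all__ = [
    "DEFAULT_BOUND",
    "FEASIBILITY_TOL",
    "ASSERTION_TOL",
    "FormatError",
    "SolverError",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxDistribution",
    "gpr_genes",
    "parse_equation",
    "format_equation",
    "read_model",
    "write_model",
    "to_cobra",
    "from_cobra",
    "solve_fba",
    "solve_pfba",
]

#: Default magnitude for unspecified reaction bounds (mmol/gDW/h).
DEFAULT_BOUND = 1000.0
#: Solver-level feasibility/optimality tolerance.
FEASIBILITY_TOL = 1e-9
#: Tolerance used when asserting mass balance / bound respect on solutions.
ASSERTION_TOL = 1e-6


class FormatError(ValueError):
    """A file does not conform to the named model dialect."""


class SolverError(RuntimeError):
    """The LP solver failed for a reason other than infeasible/unbounded."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lb: float = -DEFAULT_BOUND
    ub: float = DEFAULT_BOUND
    gpr: str = ""
    subsystem: str | None = None
    objective_coef: float = 0.0

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1


_GPR_SPLIT = re.compile(r"\band\b|\bor\b|[()]", flags=re.IGNORECASE)


def gpr_genes(gpr: str) -> list[str]:
    """All gene ids appearing in a GPR string (whitespace-free tokens)."""
    if not gpr or not gpr.strip():
        return []
    tokens = [t.strip() for t in _GPR_SPLIT.split(gpr)]
    seen: dict[str, None] = {}
    for t in tokens:
        if t:
            seen.setdefault(t)
    return list(seen)


@dataclass
class MetabolicModel:
    """A stoichiometric model with bounds, GPRs and a linear objective."""

    id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            self.genes = sorted({g for r in self.reactions for g in gpr_genes(r.gpr)})

    # -- lookups ----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        try:
            return next(m for m in self.metabolites if m.id == mid)
        except StopIteration:
            raise KeyError(f"no metabolite {mid!r} in model {self.id!r}") from None

    def reaction(self, rid: str) -> Reaction:
        try:
            return next(r for r in self.reactions if r.id == rid)
        except StopIteration:
            raise KeyError(f"no reaction {rid!r} in model {self.id!r}") from None

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    @property
    def objective_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.objective_coef != 0.0]

    # -- structure --------------------------------------------------------
    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S with metabolites as rows and reactions as columns."""
        midx = {m: i for i, m in enumerate(self.metabolite_ids)}
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                rows.append(midx[met])
                cols.append(j)
                vals.append(coef)
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def validate(self) -> None:
        """Raise ``FormatError`` on any violated structural invariant."""
        mids = self.metabolite_ids
        if len(set(mids)) != len(mids):
            raise FormatError(f"duplicate metabolite ids in {self.id!r}")
        rids = self.reaction_ids
        if len(set(rids)) != len(rids):
            raise FormatError(f"duplicate reaction ids in {self.id!r}")
        for m in self.metabolites:
            if not m.compartment:
                raise FormatError(f"metabolite {m.id!r} has empty compartment")
        mset = set(mids)
        gset = set(self.genes)
        for r in self.reactions:
            if r.lb > r.ub:
                raise FormatError(f"reaction {r.id!r}: lb {r.lb} > ub {r.ub}")
            missing = set(r.stoichiometry) - mset
            if missing:
                raise FormatError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}"
                )
            for g in gpr_genes(r.gpr):
                if g not in gset:
                    raise FormatError(
                        f"reaction {r.id!r}: GPR gene {g!r} not in model gene list"
                    )
        if self.reactions and not any(r.is_exchange for r in self.reactions):
            raise FormatError(f"model {self.id!r} has no exchange reaction")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[
                replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions
            ],
            genes=list(self.genes),
        )


@dataclass
class FluxDistribution:
    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "=>")


def parse_equation(eq: str) -> dict[str, float]:
    """Parse ``"2 A + B => C"`` into a signed stoichiometry mapping.

    Either side may be empty (exchange/sink reactions).  Coefficients default
    to 1; metabolite ids are whitespace-free tokens.
    """
    arrow = next((a for a in _ARROWS if a in eq), None)
    if arrow is None:
        raise FormatError(f"equation {eq!r} lacks an arrow (=> or <=>)")
    left, right = eq.split(arrow, 1)
    stoich: dict[str, float] = {}

    def _side(text: str, sign: float) -> None:
        text = text.strip()
        if not text:
            return
        for term in text.split(" + "):
            parts = term.split()
            if not parts:
                continue
            if len(parts) == 2:
                coef, met = float(parts[0]), parts[1]
            elif len(parts) == 1:
                coef, met = 1.0, parts[0]
            else:
                raise FormatError(f"cannot parse term {term!r} in equation {eq!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    _side(left, -1.0)
    _side(right, +1.0)
    return {m: c for m, c in stoich.items() if c != 0.0}


def _fmt_coef(c: float) -> str:
    return f"{c:.12g}"


def format_equation(stoich: Mapping[str, float], reversible: bool) -> str:
    lhs = [
        (f"{_fmt_coef(-c)} {m}" if c != -1.0 else m)
        for m, c in stoich.items()
        if c < 0
    ]
    rhs = [
        (f"{_fmt_coef(c)} {m}" if c != 1.0 else m) for m, c in stoich.items() if c > 0
    ]
    arrow = "<=>" if reversible else "=>"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


def _read_tabular(path: Path) -> MetabolicModel:
    rxn_file = path / "reactions.tsv"
    met_file = path / "metabolites.tsv"
    for f in (rxn_file, met_file):
        if not f.exists():
            raise FormatError(f"tabular model is missing {f.name} under {path}")
    mets = pd.read_csv(met_file, sep="\t", dtype=str).fillna("")
    rxns = pd.read_csv(rxn_file, sep="\t", dtype=str).fillna("")
    for col in ("id", "name", "compartment"):
        if col not in mets.columns:
            raise FormatError(f"metabolites.tsv lacks column {col!r}")
    for col in ("id", "name", "equation", "lb", "ub", "gpr", "subsystem", "objective"):
        if col not in rxns.columns:
            raise FormatError(f"reactions.tsv lacks column {col!r}")
    metabolites = [
        Metabolite(
            id=row["id"],
            name=row["name"],
            compartment=row["compartment"],
            formula=row.get("formula") or None,
        )
        for _, row in mets.iterrows()
    ]
    reactions = []
    for _, row in rxns.iterrows():
        try:
            lb, ub = float(row["lb"]), float(row["ub"])
        except ValueError as exc:
            raise FormatError(f"reaction {row['id']!r}: non-numeric bound") from exc
        reactions.append(
            Reaction(
                id=row["id"],
                name=row["name"],
                stoichiometry=parse_equation(row["equation"]),
                lb=lb,
                ub=ub,
                gpr=row["gpr"],
                subsystem=row["subsystem"] or None,
                objective_coef=float(row["objective"] or 0.0),
            )
        )
    model = MetabolicModel(id=path.name, metabolites=metabolites, reactions=reactions)
    model.validate()
    return model


def _write_tabular(model: MetabolicModel, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "id": [m.id for m in model.metabolites],
            "name": [m.name for m in model.metabolites],
            "compartment": [m.compartment for m in model.metabolites],
            "formula": [m.formula or "" for m in model.metabolites],
        }
    ).to_csv(path / "metabolites.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "id": [r.id for r in model.reactions],
            "name": [r.name for r in model.reactions],
            "equation": [
                format_equation(r.stoichiometry, r.reversible) for r in model.reactions
            ],
            "lb": [f"{r.lb:.12g}" for r in model.reactions],
            "ub": [f"{r.ub:.12g}" for r in model.reactions],
            "gpr": [r.gpr for r in model.reactions],
            "subsystem": [r.subsystem or "" for r in model.reactions],
            "objective": [f"{r.objective_coef:g}" for r in model.reactions],
        }
    ).to_csv(path / "reactions.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# SBML (FBC v2) via cobrapy
# ---------------------------------------------------------------------------


def to_cobra(model: MetabolicModel):
    """Convert to a ``cobra.Model`` (used for SBML export and as LP oracle)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment, formula=m.formula
        )
        for m in model.metabolites
    }
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name, subsystem=r.subsystem or "")
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r, cr in zip(model.reactions, rxns):
        cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        cr.bounds = (r.lb, r.ub)
        if r.gpr:
            cr.gene_reaction_rule = r.gpr
    cm.objective = {
        cm.reactions.get_by_id(r.id): r.objective_coef
        for r in model.reactions
        if r.objective_coef
    }
    return cm


def from_cobra(cm) -> MetabolicModel:
    from cobra.util.solver import linear_reaction_coefficients

    coefs = {r.id: c for r, c in linear_reaction_coefficients(cm).items()}
    metabolites = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment or "c",
            formula=m.formula or None,
        )
        for m in cm.metabolites
    ]
    reactions = [
        Reaction(
            id=r.id,
            name=r.name or "",
            stoichiometry={m.id: c for m, c in r.metabolites.items()},
            lb=r.lower_bound,
            ub=r.upper_bound,
            gpr=r.gene_reaction_rule or "",
            subsystem=r.subsystem or None,
            objective_coef=coefs.get(r.id, 0.0),
        )
        for r in cm.reactions
    ]
    return MetabolicModel(id=cm.id or "model", metabolites=metabolites, reactions=reactions)


def _read_sbml(path: Path) -> MetabolicModel:
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml reports positional parse errors
        raise FormatError(f"cannot parse SBML model {path}: {exc}") from exc
    model = from_cobra(cm)
    if not model.objective_ids:
        raise FormatError(f"SBML model {path}: no objective defined")
    model.validate()
    return model


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import cobra.io

    path.parent.mkdir(parents=True, exist_ok=True)
    cobra.io.write_sbml_model(to_cobra(model), str(path))


def read_model(path: str | Path, format: str = "tabular") -> MetabolicModel:
    """Read a model in the ``sbml_fbc2`` or ``tabular`` dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tabular":
        return _read_tabular(path)
    if format == "sbml_fbc2":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path: str | Path, format: str = "tabular") -> None:
    if not model.reactions:
        raise FormatError("model has no reactions")
    model.validate()
    path = Path(path)
    if format == "tabular":
        _write_tabular(model, path)
    elif format == "sbml_fbc2":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# LP solving
# ---------------------------------------------------------------------------

_LP_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _objective_vector(
    model: MetabolicModel, objective: str | None
) -> np.ndarray:
    c = np.zeros(len(model.reactions))
    if objective is not None:
        idx = {r.id: j for j, r in enumerate(model.reactions)}
        if objective not in idx:
            raise KeyError(f"objective reaction {objective!r} not in model")
        c[idx[objective]] = 1.0
    else:
        for j, r in enumerate(model.reactions):
            c[j] = r.objective_coef
        if not c.any():
            raise ValueError(f"model {model.id!r} has no objective")
    return c


def _run_lp(c, A_eq, b_eq, bounds):
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL,
                 "dual_feasibility_tolerance": FEASIBILITY_TOL},
    )
    if res.status not in _LP_STATUS:
        raise SolverError(f"LP solver failed: {res.message}")
    return res


def solve_fba(
    model: MetabolicModel,
    objective: str | None = None,
    direction: str = "max",
) -> FluxDistribution:
    """Flux balance analysis: optimise the (or a named) objective reaction."""
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    c = _objective_vector(model, objective)
    sign = -1.0 if direction == "max" else 1.0
    S = model.stoichiometric_matrix()
    bounds = [(r.lb, r.ub) for r in model.reactions]
    res = _run_lp(sign * c, S, np.zeros(S.shape[0]), bounds)
    status = _LP_STATUS[res.status]
    if status != "optimal":
        return FluxDistribution({}, math.nan, status)
    fluxes = dict(zip(model.reaction_ids, res.x))
    return FluxDistribution(fluxes, float(c @ res.x), "optimal")


def solve_pfba(
    model: MetabolicModel,
    objective_fraction: float = 1.0,
    objective: str | None = None,
    direction: str = "max",
) -> FluxDistribution:
    """Parsimonious FBA.

    Stage one solves FBA; stage two fixes the objective at
    ``objective_fraction`` times the optimum (as an equality band) and
    minimises total absolute flux over the positive/negative split of every
    reaction.  The reported objective value is the stage-one target.
    """
    if not (0.0 < objective_fraction <= 1.0):
        raise ValueError("objective_fraction must be in (0, 1]")
    first = solve_fba(model, objective=objective, direction=direction)
    if not first.optimal:
        return first
    target = objective_fraction * first.objective_value
    c = _objective_vector(model, objective)
    n = len(model.reactions)
    m = len(model.metabolites)
    S = model.stoichiometric_matrix()
    # Variables [v, p, q]: S v = 0; v - p + q = 0 with p, q >= 0 so that
    # p + q >= |v|; minimise sum(p + q) with c.v held at the target band.
    eye = sparse.identity(n, format="csr")
    zero = sparse.csr_matrix((m, n))
    crow = sparse.csr_matrix(np.concatenate([c, np.zeros(2 * n)])[None, :])
    A_balance = sparse.hstack([S, zero, zero])
    A_split = sparse.hstack([eye, -eye, eye])
    bounds = (
        [(r.lb, r.ub) for r in model.reactions]
        + [(0.0, None)] * n
        + [(0.0, None)] * n
    )
    cost = np.concatenate([np.zeros(n), np.ones(2 * n)])

    def _stage_two(slack: float):
        if slack == 0.0:
            A_eq = sparse.vstack([A_balance, A_split, crow]).tocsr()
            b_eq = np.concatenate([np.zeros(m), np.zeros(n), [target]])
            return linprog(cost, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
        A_eq = sparse.vstack([A_balance, A_split]).tocsr()
        b_eq = np.zeros(m + n)
        A_ub = sparse.vstack([crow, -crow]).tocsr()
        b_ub = np.array([target + slack, -(target - slack)])
        return linprog(
            cost, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
            bounds=bounds, method="highs",
        )

    res = _stage_two(0.0)
    if res.status != 0:
        # numerical: widen the equality band once by the assertion tolerance
        res = _stage_two(ASSERTION_TOL * max(1.0, abs(target)))
        if res.status != 0:
            raise SolverError(
                f"pFBA stage two infeasible even with widened band: {res.message}"
            )
    v = res.x[:n]
    fluxes = dict(zip(model.reaction_ids, v))
    return FluxDistribution(fluxes, float(target), "optimal")


def total_absolute_flux(flux: FluxDistribution) -> float:
    return float(sum(abs(v) for v in flux.fluxes.values()))
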