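"""GEM → enzyme-constrained model (ecModel) transformation.

The transformation makes enzyme demand an explicit part of the stoichiometry:

1. every reversible reaction is split into forward and backward copies so
   each direction can carry its own enzyme cost;
2. each reaction's GPR is expanded to disjunctive normal form — every OR
   disjunct (isoenzyme alternative) becomes its own reaction copy, every AND
   conjunct a multi-subunit complex;
3. each protein becomes a pseudo-metabolite ``prot_<id>`` produced by a usage
   pseudo-reaction ``draw_prot_<id>`` (mmol/gDW) and consumed by its reaction
   copies with coefficient ``copies / (3600 · kcat)`` so that one unit of flux
   (mmol/gDW/h) draws the enzyme amount needed at full turnover;
4. optionally all usage reactions are coupled to a shared protein pool
   (g/gDW) bounded by ``Ptot · f · σ`` — total protein × metabolic-enzyme
   mass fraction × average saturation — giving the "batch" model flavour.

Reactions whose genes lack enzyme annotation or a kcat assignment stay
enzyme-free (conservative: enzyme coverage below 100% must not block flux).
A :class:`ECReactionMap` retains the mapping from net GEM reactions to their
copies so ecModel fluxes can be projected back onto the parent network.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .core import (
    FluxDistribution,
    FormatError,
    MetabolicModel,
    Metabolite,
    Reaction,
    read_model,
    write_model,
)
from .kinetics import EnzymeInfo, MatchRecord

__all__ = [
    "EnzymeAlternative",
    "ECReactionMap",
    "ECModel",
    "to_irreversible",
    "gpr_alternatives",
    "build_ec_model",
    "add_protein_pool",
    "map_net_fluxes",
    "write_ec_model",
    "read_ec_model",
    "PROT_PREFIX",
    "USAGE_PREFIX",
    "POOL_MET",
    "POOL_RXN",
    "ENZYME_COMPARTMENT",
]

logger = logging.getLogger(__name__)

PROT_PREFIX = "prot_"
USAGE_PREFIX = "draw_prot_"
POOL_MET = "prot_pool"
POOL_RXN = "prot_pool_exchange"
ENZYME_COMPARTMENT = "enzyme"
SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class EnzymeAlternative:
    """One way of catalysing a reaction: an AND-conjunct of subunits."""

    subunits: tuple[tuple[str, int], ...]  # (protein or gene id, copies)

    def __post_init__(self) -> None:
        if not self.subunits:
            raise ValueError("enzyme alternative must have at least one subunit")
        ids = [s for s, _ in self.subunits]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate subunit ids in alternative {ids}")


@dataclass
class ECReactionMap:
    net_to_copies: dict[str, list[tuple[str, str]]]  # net id -> [(copy id, fwd|rev)]
    usage_rxn: dict[str, str]  # protein id -> usage reaction id


@dataclass
class ECModel:
    model: MetabolicModel
    map: ECReactionMap
    enzymes: dict[str, EnzymeInfo]
    kcats: dict[tuple[str, str], float]  # (protein id, copy reaction id) -> s^-1
    pool: dict | None = None  # {pool_rxn_id, Ptot, f, sigma}

    @property
    def proteins(self) -> list[str]:
        return sorted(self.map.usage_rxn)

    def copy(self) -> "ECModel":
        return ECModel(
            model=self.model.copy(),
            map=ECReactionMap(
                net_to_copies={k: list(v) for k, v in self.map.net_to_copies.items()},
                usage_rxn=dict(self.map.usage_rxn),
            ),
            enzymes=dict(self.enzymes),
            kcats=dict(self.kcats),
            pool=dict(self.pool) if self.pool else None,
        )

    def set_kcat(self, protein_id: str, copy_id: str, kcat_s: float) -> None:
        """Re-parameterise one (protein, reaction copy) pair in place."""
        if not kcat_s > 0:
            raise ValueError("kcat must be positive")
        enz = self.enzymes[protein_id]
        rxn = self.model.reaction(copy_id)
        rxn.stoichiometry[PROT_PREFIX + protein_id] = -enz.subunit_copies / (
            SECONDS_PER_HOUR * kcat_s
        )
        self.kcats[(protein_id, copy_id)] = kcat_s

    def copies_of(self, protein_id: str) -> list[str]:
        return [cid for (pid, cid) in self.kcats if pid == protein_id]


# ---------------------------------------------------------------------------
# Irreversible split
# ---------------------------------------------------------------------------


def to_irreversible(
    model: MetabolicModel,
) -> tuple[MetabolicModel, dict[str, list[tuple[str, str]]]]:
    """Split reversible reactions into forward [0, ub] and ``_REV`` [0, -lb] copies.

    Irreversible forward reactions pass through unchanged; backward-only
    reactions (ub <= 0) are flipped into a single ``_REV`` copy.  The linear
    objective is preserved under the net mapping (rev copies get the negated
    coefficient).
    """
    out: list[Reaction] = []
    pairing: dict[str, list[tuple[str, str]]] = {}
    for r in model.reactions:
        if r.lb >= 0:
            out.append(
                Reaction(
                    id=r.id, name=r.name, stoichiometry=dict(r.stoichiometry),
                    lb=r.lb, ub=r.ub, gpr=r.gpr, subsystem=r.subsystem,
                    objective_coef=r.objective_coef,
                )
            )
            pairing[r.id] = [(r.id, "fwd")]
        elif r.ub <= 0:
            rev_id = r.id + "_REV"
            out.append(
                Reaction(
                    id=rev_id, name=r.name, subsystem=r.subsystem, gpr=r.gpr,
                    stoichiometry={m: -c for m, c in r.stoichiometry.items()},
                    lb=-r.ub, ub=-r.lb, objective_coef=-r.objective_coef,
                )
            )
            pairing[r.id] = [(rev_id, "rev")]
        else:
            rev_id = r.id + "_REV"
            out.append(
                Reaction(
                    id=r.id, name=r.name, stoichiometry=dict(r.stoichiometry),
                    lb=0.0, ub=r.ub, gpr=r.gpr, subsystem=r.subsystem,
                    objective_coef=r.objective_coef,
                )
            )
            out.append(
                Reaction(
                    id=rev_id, name=r.name, subsystem=r.subsystem, gpr=r.gpr,
                    stoichiometry={m: -c for m, c in r.stoichiometry.items()},
                    lb=0.0, ub=-r.lb, objective_coef=-r.objective_coef,
                )
            )
            pairing[r.id] = [(r.id, "fwd"), (rev_id, "rev")]
    irr = MetabolicModel(
        id=model.id,
        metabolites=[Metabolite(m.id, m.name, m.compartment, m.formula) for m in model.metabolites],
        reactions=out,
        genes=list(model.genes),
    )
    return irr, pairing


# ---------------------------------------------------------------------------
# GPR parsing to disjunctive normal form
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(gpr: str) -> list[str]:
    return _TOKEN.findall(gpr)


def gpr_alternatives(gpr: str, dnf_cap: int = 32) -> list[EnzymeAlternative]:
    """Expand a GPR into its list of catalytic alternatives (DNF).

    ``"g1 or g2"`` → two single-subunit alternatives; ``"g1 and g2"`` → one
    two-subunit alternative.  ``and``/``or`` are case-insensitive keywords;
    gene ids are arbitrary whitespace-free tokens.  Duplicate alternatives
    are removed; a DNF larger than ``dnf_cap`` raises.
    """
    tokens = _tokenize(gpr)
    if not tokens:
        return []
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    # DNF terms are frozensets of gene ids
    def parse_or() -> list[frozenset[str]]:
        terms = parse_and()
        while peek() is not None and peek().lower() == "or":
            take()
            terms = terms + parse_and()
        return terms

    def parse_and() -> list[frozenset[str]]:
        terms = parse_atom()
        while peek() is not None and peek().lower() == "and":
            take()
            rhs = parse_atom()
            terms = [a | b for a in terms for b in rhs]
            if len(terms) > dnf_cap:
                raise FormatError(
                    f"GPR {gpr!r}: DNF exceeds cap of {dnf_cap} alternatives"
                )
        return terms

    def parse_atom() -> list[frozenset[str]]:
        tok = peek()
        if tok is None:
            raise FormatError(f"malformed GPR {gpr!r}: unexpected end")
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise FormatError(f"malformed GPR {gpr!r}: missing ')'")
            take()
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise FormatError(f"malformed GPR {gpr!r}: unexpected {tok!r}")
        take()
        return [frozenset([tok])]

    terms = parse_or()
    if pos != len(tokens):
        raise FormatError(f"malformed GPR {gpr!r}: trailing tokens")
    seen: list[frozenset[str]] = []
    for t in terms:
        if t not in seen:
            seen.append(t)
    if len(seen) > dnf_cap:
        raise FormatError(f"GPR {gpr!r}: DNF exceeds cap of {dnf_cap} alternatives")
    return [
        EnzymeAlternative(tuple((g, 1) for g in sorted(t))) for t in seen
    ]


# ---------------------------------------------------------------------------
# ecModel construction
# ---------------------------------------------------------------------------


def _kcat_for(
    kcats: Mapping, net_rxn_id: str, protein_id: str
) -> float | None:
    """Look up a kcat keyed by (reaction, protein), protein, or MatchRecord."""
    for key in ((net_rxn_id, protein_id), protein_id):
        if key in kcats:
            val = kcats[key]
            if isinstance(val, MatchRecord):
                return val.kcat_s
            return float(val)
    return None


def build_ec_model(
    model: MetabolicModel,
    enzymes: list[EnzymeInfo],
    kcats: Mapping,
    dnf_cap: int = 32,
) -> ECModel:
    """Build the unbounded-usage ecModel flavour from a GEM.

    ``kcats`` maps ``protein_id`` (or ``(net_reaction_id, protein_id)``) to a
    turnover number in s⁻¹ or to a :class:`~ecflux.kinetics.MatchRecord`.
    Genes with no enzyme annotation, and alternatives with unmatched kcats,
    carry no enzyme cost (logged); a protein appearing in several reactions
    gets exactly one pseudo-metabolite and one usage reaction.
    """
    model.validate()
    irr, pairing = to_irreversible(model)
    gene_to_protein: dict[str, str] = {}
    enz_by_id: dict[str, EnzymeInfo] = {}
    for enz in enzymes:
        enz_by_id[enz.protein_id] = enz
        for g in enz.gene_ids:
            if g in gene_to_protein and gene_to_protein[g] != enz.protein_id:
                raise FormatError(
                    f"gene {g!r} maps to multiple proteins "
                    f"({gene_to_protein[g]!r}, {enz.protein_id!r})"
                )
            gene_to_protein[g] = enz.protein_id

    net_gpr = {r.id: r.gpr for r in model.reactions}
    reactions: list[Reaction] = []
    net_to_copies: dict[str, list[tuple[str, str]]] = {rid: [] for rid in pairing}
    ec_kcats: dict[tuple[str, str], float] = {}
    used_proteins: set[str] = set()

    irr_by_id = {r.id: r for r in irr.reactions}
    for net_id, copies in pairing.items():
        gpr = net_gpr[net_id]
        alternatives = gpr_alternatives(gpr, dnf_cap=dnf_cap) if gpr.strip() else []
        # keep only alternatives whose every subunit has annotation + kcat
        costed: list[list[tuple[str, int, float]]] = []
        for alt in alternatives:
            subunits: list[tuple[str, int, float]] = []
            for gene, _ in alt.subunits:
                pid = gene_to_protein.get(gene)
                if pid is None:
                    subunits = []
                    break
                kc = _kcat_for(kcats, net_id, pid)
                if kc is None:
                    subunits = []
                    break
                if not kc > 0:
                    raise ValueError(
                        f"reaction {net_id!r}, protein {pid!r}: kcat must be positive"
                    )
                subunits.append((pid, enz_by_id[pid].subunit_copies, kc))
            if subunits:
                costed.append(subunits)
        if alternatives and not costed:
            logger.warning(
                "reaction %s: no alternative fully annotated; left enzyme-free", net_id
            )
        for copy_id, direction in copies:
            base = irr_by_id[copy_id]
            if not costed:
                reactions.append(base)
                net_to_copies[net_id].append((copy_id, direction))
                continue
            for k, subunits in enumerate(costed, start=1):
                cid = copy_id if len(costed) == 1 else f"{copy_id}_No{k}"
                stoich = dict(base.stoichiometry)
                for pid, ncopies, kc in subunits:
                    stoich[PROT_PREFIX + pid] = -ncopies / (SECONDS_PER_HOUR * kc)
                    ec_kcats[(pid, cid)] = kc
                    used_proteins.add(pid)
                reactions.append(
                    Reaction(
                        id=cid, name=base.name, stoichiometry=stoich,
                        lb=base.lb, ub=base.ub, gpr=base.gpr,
                        subsystem=base.subsystem, objective_coef=base.objective_coef,
                    )
                )
                net_to_copies[net_id].append((cid, direction))

    metabolites = [
        Metabolite(m.id, m.name, m.compartment, m.formula) for m in model.metabolites
    ]
    usage_rxn: dict[str, str] = {}
    for pid in sorted(used_proteins):
        metabolites.append(
            Metabolite(PROT_PREFIX + pid, name=f"protein {pid}", compartment=ENZYME_COMPARTMENT)
        )
        uid = USAGE_PREFIX + pid
        reactions.append(
            Reaction(
                id=uid, name=f"usage of {pid}",
                stoichiometry={PROT_PREFIX + pid: 1.0}, lb=0.0, ub=math.inf,
            )
        )
        usage_rxn[pid] = uid

    ec_model = MetabolicModel(
        id=model.id + "_ec", metabolites=metabolites, reactions=reactions,
        genes=list(model.genes),
    )
    ec_model.validate()
    return ECModel(
        model=ec_model,
        map=ECReactionMap(net_to_copies=net_to_copies, usage_rxn=usage_rxn),
        enzymes={p: enz_by_id[p] for p in used_proteins},
        kcats=ec_kcats,
        pool=None,
    )


def add_protein_pool(ec: ECModel, Ptot: float, f: float, sigma: float) -> ECModel:
    """Couple all usage reactions to a shared protein pool (batch flavour).

    Each usage reaction is rewritten to convert ``mw_kda`` grams of pool per
    mmol of protein drawn; the pool exchange is bounded by ``Ptot·f·σ``
    (g protein available to metabolic enzymes per gDW).
    """
    if ec.pool is not None:
        raise ValueError("ecModel already has a protein pool")
    if not Ptot > 0:
        raise ValueError("Ptot must be positive")
    for name, val in (("f", f), ("sigma", sigma)):
        if not (0 < val <= 1):
            raise ValueError(f"{name} must be in (0, 1]")
    out = ec.copy()
    out.model.metabolites.append(
        Metabolite(POOL_MET, name="shared protein pool", compartment=ENZYME_COMPARTMENT)
    )
    for pid, uid in out.map.usage_rxn.items():
        rxn = out.model.reaction(uid)
        rxn.stoichiometry = {
            POOL_MET: -out.enzymes[pid].mw_kda,
            PROT_PREFIX + pid: 1.0,
        }
    out.model.reactions.append(
        Reaction(
            id=POOL_RXN, name="protein pool exchange",
            stoichiometry={POOL_MET: 1.0}, lb=0.0, ub=Ptot * f * sigma,
        )
    )
    out.pool = {"pool_rxn_id": POOL_RXN, "Ptot": Ptot, "f": f, "sigma": sigma}
    out.model.validate()
    return out


def map_net_fluxes(ec: ECModel, flux: FluxDistribution) -> FluxDistribution:
    """Project an ecModel flux vector back onto the parent GEM's reactions."""
    if not flux.optimal:
        return FluxDistribution({}, flux.objective_value, flux.status)
    net: dict[str, float] = {}
    for net_id, copies in ec.map.net_to_copies.items():
        total = 0.0
        for copy_id, direction in copies:
            if copy_id not in flux.fluxes:
                raise KeyError(f"flux vector lacks ecModel copy {copy_id!r}")
            v = flux.fluxes[copy_id]
            total += v if direction == "fwd" else -v
        net[net_id] = total
    return FluxDistribution(net, flux.objective_value, flux.status)


# ---------------------------------------------------------------------------
# Serialisation (model file + sidecar tables)
# ---------------------------------------------------------------------------


def write_ec_model(ec: ECModel, path: str | Path, format: str = "tabular") -> None:
    """Write the ecModel plus sidecar tables (map, kcats, enzymes, pool)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if format == "tabular":
        write_model(ec.model, path / "model", format="tabular")
    else:
        write_model(ec.model, path / "model.xml", format="sbml_fbc2")
    rows = [
        {"net_id": nid, "copy_id": cid, "direction": d}
        for nid, copies in ec.map.net_to_copies.items()
        for cid, d in copies
    ]
    pd.DataFrame(rows).to_csv(path / "reaction_map.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"protein_id": p, "usage_rxn": u} for p, u in sorted(ec.map.usage_rxn.items())]
    ).to_csv(path / "usage_map.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"protein_id": p, "copy_id": c, "kcat_s": f"{k:.10g}"}
            for (p, c), k in sorted(ec.kcats.items())
        ]
    ).to_csv(path / "kcats.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "protein_id": e.protein_id,
                "gene_ids": ";".join(e.gene_ids),
                "ec_numbers": ";".join(str(x) for x in e.ecs),
                "mw_kda": f"{e.mw_kda:g}",
                "subunit_copies": e.subunit_copies,
            }
            for e in sorted(ec.enzymes.values(), key=lambda e: e.protein_id)
        ]
    ).to_csv(path / "enzymes.tsv", sep="\t", index=False)
    with open(path / "pool.json", "w") as fh:
        json.dump(ec.pool, fh, indent=1)


def read_ec_model(path: str | Path, format: str = "tabular") -> ECModel:
    from .kinetics import ECNumber

    path = Path(path)
    if format == "tabular":
        model = read_model(path / "model", format="tabular")
    else:
        model = read_model(path / "model.xml", format="sbml_fbc2")
    rmap = pd.read_csv(path / "reaction_map.tsv", sep="\t", dtype=str)
    net_to_copies: dict[str, list[tuple[str, str]]] = {}
    for _, row in rmap.iterrows():
        net_to_copies.setdefault(row["net_id"], []).append(
            (row["copy_id"], row["direction"])
        )
    umap = pd.read_csv(path / "usage_map.tsv", sep="\t", dtype=str)
    usage_rxn = dict(zip(umap["protein_id"], umap["usage_rxn"]))
    kdf = pd.read_csv(path / "kcats.tsv", sep="\t", dtype=str)
    kcats = {
        (row["protein_id"], row["copy_id"]): float(row["kcat_s"])
        for _, row in kdf.iterrows()
    }
    edf = pd.read_csv(path / "enzymes.tsv", sep="\t", dtype=str)
    enzymes = {
        row["protein_id"]: EnzymeInfo(
            protein_id=row["protein_id"],
            gene_ids=row["gene_ids"].split(";"),
            ecs=[ECNumber.parse(x) for x in row["ec_numbers"].split(";") if x],
            mw_kda=float(row["mw_kda"]),
            subunit_copies=int(row["subunit_copies"]),
        )
        for _, row in edf.iterrows()
    }
    with open(path / "pool.json") as fh:
        pool = json.load(fh)
    return ECModel(
        model=model,
        map=ECReactionMap(net_to_copies=net_to_copies, usage_rxn=usage_rxn),
        enzymes=enzymes,
        kcats=kcats,
        pool=pool,
    )
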