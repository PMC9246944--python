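"""Deterministic synthetic fixtures: toy GEMs, kinetic catalogs, proteomics.

Every generator is a pure function of its arguments and a seed, and every
planted quantity (GEM optimum, enzyme cost of the chain, expected match
provenance) is recomputed independently at generation time and asserted, so
a corrupted fixture fails loudly instead of silently skewing tests.

The main toy network (``make_toy_gem``) packs all enzyme-constraint motifs
into 12 reactions: a glucose uptake chain, an isoenzyme pair (``g1 or g2``),
a two-subunit complex (``g3 and g4``), a promiscuous enzyme (``g5`` on two
reactions), a reversible step, an unbounded futile cycle, an NGAM reaction
and a biomass objective with a hand-solvable optimum.  A linear chain
generator (``make_chain_gem``) provides the closed-form relationship
μ = pool / Σ MW_i/(3600·kcat_i) used by the calibration tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MetabolicModel, Metabolite, Reaction, solve_fba, write_model
from .kinetics import (
    ECNumber,
    EnzymeInfo,
    KcatQuery,
    KineticCatalog,
    KineticEntry,
    Taxonomy,
)
from .proteomics import ProteomicsDataset
from .transform import ECModel, add_protein_pool, build_ec_model

__all__ = [
    "ToySpec",
    "make_toy_gem",
    "make_chain_gem",
    "make_toy_kinetics",
    "make_flex_fixture",
    "random_match_instance",
    "make_synthetic_proteomics",
    "write_fixture_set",
    "TOY_ORGANISM",
    "TOY_KCATS",
    "TOY_MWS",
]

TOY_ORGANISM = "sp1"
GLC_UPTAKE = 10.0  # mmol/gDW/h

#: Planted toy kcats (s⁻¹) spanning the orders of magnitude seen in real
#: catalogs; keys are protein ids of the main toy.
TOY_KCATS = {
    "P0": 10.0,
    "P1": 20.0,
    "P2": 5.0,
    "P3": 8.0,
    "P4": 8.0,
    "P5": 15.0,
    "P6": 30.0,
    "P8": 2.0,
    "P9": 3.0,
}

TOY_MWS = {
    "P0": 40.0, "P1": 50.0, "P2": 60.0, "P3": 30.0, "P4": 20.0,
    "P5": 55.0, "P6": 45.0, "P8": 25.0, "P9": 28.0,
}


@dataclass
class ToySpec:
    seed: int = 7
    reversible: bool = True
    isoenzymes: bool = True
    complex_: bool = True
    promiscuous: bool = True
    futile_cycle: bool = True
    ngam: bool = True
    chain_length: int = 3
    planted: dict = field(default_factory=dict)


def make_toy_gem(spec: ToySpec | None = None) -> tuple[MetabolicModel, list[EnzymeInfo]]:
    """The 12-reaction motif toy; records its closed-form optimum in planted.

    Glucose (uptake 10) is converted through a chain into precursor D and
    energy (2 ATP per C routed to the energy branch); biomass consumes one D
    and one ATP, so the split R4 = b, R5 = 10 − b with 2(10 − b) = b gives
    μ* = 20/3.
    """
    spec = spec or ToySpec()
    mets = [
        Metabolite("glc_e", "glucose", "e"),
        Metabolite("glc_c", "glucose", "c"),
        Metabolite("A", "metabolite A", "c"),
        Metabolite("B", "metabolite B", "c"),
        Metabolite("C", "metabolite C", "c"),
        Metabolite("D", "precursor D", "c"),
        Metabolite("E", "metabolite E", "c"),
        Metabolite("atp", "ATP", "c"),
    ]
    r3_lb = -1000.0 if spec.reversible else 0.0
    r1_gpr = "g1 or g2" if spec.isoenzymes else "g1"
    r2_gpr = "g3 and g4" if spec.complex_ else "g3"
    r4_gpr = "g5" if spec.promiscuous else "g7"
    rxns = [
        Reaction("EX_glc", "glucose exchange", {"glc_e": -1.0}, lb=-GLC_UPTAKE, ub=0.0),
        Reaction("GLCt", "glucose transport", {"glc_e": -1.0, "glc_c": 1.0}, lb=0.0, gpr="g0"),
        Reaction("R1", "glc -> A", {"glc_c": -1.0, "A": 1.0}, lb=0.0, gpr=r1_gpr,
                 subsystem="upper"),
        Reaction("R2", "A -> B", {"A": -1.0, "B": 1.0}, lb=0.0, gpr=r2_gpr,
                 subsystem="upper"),
        Reaction("R3", "B <-> C", {"B": -1.0, "C": 1.0}, lb=r3_lb, gpr="g5",
                 subsystem="central"),
        Reaction("R4", "C -> D", {"C": -1.0, "D": 1.0}, lb=0.0, gpr=r4_gpr,
                 subsystem="central"),
        Reaction("R5", "C -> 2 ATP", {"C": -1.0, "atp": 2.0}, lb=0.0, gpr="g6",
                 subsystem="energy"),
        Reaction("BIOMASS", "growth", {"D": -1.0, "atp": -1.0}, lb=0.0,
                 objective_coef=1.0),
        Reaction("EX_D", "D secretion", {"D": -1.0}, lb=0.0),
    ]
    if spec.ngam:
        rxns.append(Reaction("NGAM", "maintenance ATPase", {"atp": -1.0}, lb=0.0))
    if spec.futile_cycle:
        # both legs reversible and enzyme-catalysed: the GEM leaves the pair
        # fully variable while enzyme costs cap it in the ecModel
        fc_lb = -1000.0 if spec.reversible else 0.0
        rxns.append(Reaction("FC1", "D <-> E", {"D": -1.0, "E": 1.0}, lb=fc_lb, gpr="g8"))
        rxns.append(Reaction("FC2", "E <-> D", {"E": -1.0, "D": 1.0}, lb=fc_lb, gpr="g9"))
    model = MetabolicModel(id="TOY1", metabolites=mets, reactions=rxns)
    model.validate()

    enzymes = [
        EnzymeInfo("P0", ["g0"], [ECNumber.parse("7.2.2.1")], TOY_MWS["P0"]),
        EnzymeInfo("P1", ["g1"], [ECNumber.parse("1.1.1.1")], TOY_MWS["P1"]),
        EnzymeInfo("P2", ["g2"], [ECNumber.parse("1.1.1.2")], TOY_MWS["P2"]),
        EnzymeInfo("P3", ["g3"], [ECNumber.parse("2.2.1.1")], TOY_MWS["P3"], subunit_copies=2),
        EnzymeInfo("P4", ["g4"], [ECNumber.parse("2.2.1.1")], TOY_MWS["P4"]),
        EnzymeInfo("P5", ["g5"], [ECNumber.parse("3.1.1.3")], TOY_MWS["P5"]),
        EnzymeInfo("P6", ["g6"], [ECNumber.parse("4.1.1.1")], TOY_MWS["P6"]),
    ]
    if spec.futile_cycle:
        enzymes.append(
            EnzymeInfo("P8", ["g8"], [ECNumber.parse("5.3.1.1")], TOY_MWS["P8"])
        )
        enzymes.append(
            EnzymeInfo("P9", ["g9"], [ECNumber.parse("5.3.1.2")], TOY_MWS["P9"])
        )
    if not spec.promiscuous:
        enzymes.append(EnzymeInfo("P7", ["g7"], [ECNumber.parse("3.1.1.4")], 35.0))

    # self-check: the closed-form optimum b = 2*uptake/3 must match the LP
    mu_expected = 2.0 * GLC_UPTAKE / 3.0
    mu_lp = solve_fba(model).objective_value
    assert abs(mu_lp - mu_expected) < 1e-6, (mu_lp, mu_expected)
    spec.planted.update(
        {
            "mu_gem": mu_expected,
            "uptake": GLC_UPTAKE,
            "kcats": dict(TOY_KCATS),
            "biomass_rxn": "BIOMASS",
            "carbon_source_rxn": "EX_glc",
            "ngam_rxn": "NGAM" if spec.ngam else None,
        }
    )
    return model, enzymes


def make_chain_gem(
    n_enzymes: int = 10,
    kcats: list[float] | None = None,
    mws: list[float] | None = None,
    uptake: float = 10.0,
) -> tuple[MetabolicModel, list[EnzymeInfo], dict]:
    """Linear chain S → M1 → … → Mn → biomass, one enzyme per step.

    Returns (model, enzymes, planted) with the closed-form enzyme cost
    ``cost = Σ MW_i / (3600 · kcat_i)`` (g·h/mmol flux) so that a pooled
    model grows at ``min(uptake, pool_ub / cost)``.
    """
    if kcats is None:
        kcats = [10.0] * n_enzymes
    if mws is None:
        mws = [30.0 + 2.0 * i for i in range(n_enzymes)]
    assert len(kcats) == len(mws) == n_enzymes
    mets = [Metabolite("S_e", "substrate", "e")] + [
        Metabolite(f"M{i}", f"intermediate {i}", "c") for i in range(n_enzymes + 1)
    ]
    rxns = [
        Reaction("EX_S", "substrate exchange", {"S_e": -1.0}, lb=-uptake, ub=0.0),
        Reaction("T0", "uptake", {"S_e": -1.0, "M0": 1.0}, lb=0.0),
    ]
    enzymes = []
    for i in range(n_enzymes):
        rxns.append(
            Reaction(
                f"R{i+1}", f"step {i+1}", {f"M{i}": -1.0, f"M{i+1}": 1.0},
                lb=0.0, gpr=f"gch{i+1}", subsystem="chain",
            )
        )
        enzymes.append(
            EnzymeInfo(
                f"PC{i+1}", [f"gch{i+1}"], [ECNumber.parse(f"1.1.1.{i+1}")], mws[i]
            )
        )
    rxns.append(
        Reaction("BIOMASS", "growth", {f"M{n_enzymes}": -1.0}, lb=0.0, objective_coef=1.0)
    )
    model = MetabolicModel(id="CHAIN", metabolites=mets, reactions=rxns)
    model.validate()
    cost = sum(mw / (3600.0 * kc) for mw, kc in zip(mws, kcats))
    mu_lp = solve_fba(model).objective_value
    assert abs(mu_lp - uptake) < 1e-6
    planted = {
        "mu_gem": uptake,
        "enzyme_cost": cost,
        "kcats": {f"PC{i+1}": kcats[i] for i in range(n_enzymes)},
        "biomass_rxn": "BIOMASS",
        "carbon_source_rxn": "EX_S",
    }
    return model, enzymes, planted


def make_toy_kinetics(spec: ToySpec | None = None) -> tuple[KineticCatalog, Taxonomy]:
    """Catalog + taxonomy with one planted winner per lattice cell of interest.

    Planted expectations (query organism sp1), recorded in ``spec.planted``:
    an organism-specific kcat (EC 1.1.1.1), a closest-organism kcat
    (EC 1.1.1.2, donor sp2 at distance 2 beating sp4 at distance 6), an
    SA-only EC (2.2.1.1) and an EC matched only through wildcards (query
    3.1.1.3 served by a 3.1.2.9 entry at two wildcards).
    """
    spec = spec or ToySpec()
    tax = Taxonomy(
        lineage={
            "sp1": ["Root", "K1", "G1", "sp1"],
            "sp2": ["Root", "K1", "G1", "sp2"],
            "sp3": ["Root", "K1", "G2", "sp3"],
            "sp4": ["Root", "K2", "G3", "sp4"],
        }
    )
    entries = [
        KineticEntry(ECNumber.parse("1.1.1.1"), "sp1", "glucose", 20.0, "kcat"),
        KineticEntry(ECNumber.parse("1.1.1.1"), "sp4", "glucose", 90.0, "kcat"),
        KineticEntry(ECNumber.parse("1.1.1.2"), "sp2", "glucose", 5.0, "kcat"),
        KineticEntry(ECNumber.parse("1.1.1.2"), "sp4", "glucose", 50.0, "kcat"),
        KineticEntry(ECNumber.parse("2.2.1.1"), "sp3", "fructose", 600.0, "SA"),
        KineticEntry(ECNumber.parse("3.1.2.9"), "sp2", "ester", 7.0, "kcat"),
        KineticEntry(ECNumber.parse("4.1.1.1"), "sp2", "pyruvate", 30.0, "kcat"),
        KineticEntry(ECNumber.parse("7.2.2.1"), "sp3", "glucose", 10.0, "kcat"),
    ]
    catalog = KineticCatalog(entries=entries, mutant_count=0)
    spec.planted["matches"] = {
        "1.1.1.1": {"kcat_s": 20.0, "class": "org_substrate", "donor": "sp1", "w": 0},
        "1.1.1.2": {"kcat_s": 5.0, "class": "any_substrate", "donor": "sp2", "w": 0,
                    "distance": 2.0},
        "2.2.1.1": {"source": "SA", "w": 0},
        "3.1.1.3": {"kcat_s": 7.0, "w": 2, "donor": "sp2"},
    }
    return catalog, tax


def make_flex_fixture(
    seed: int,
    n_enzymes: int = 10,
    pool_ub: float = 0.01,
    slow_kcat: float = 1e-3,
    fast_kcat: float = 10.0,
) -> tuple[ECModel, KineticCatalog, Taxonomy, float, str]:
    """Pooled chain ecModel with one randomly planted slow kcat.

    The catalog holds an entry at ``fast_kcat`` for every chain EC, so one
    substitution on the planted protein restores growth.  Returns
    ``(ec_pool, catalog, taxonomy, mu_exp, planted_protein)`` where
    ``mu_exp`` is the closed-form growth rate with the bottleneck repaired.
    """
    rng = np.random.default_rng(seed)
    slow_idx = int(rng.integers(n_enzymes))
    kcats = [fast_kcat] * n_enzymes
    kcats[slow_idx] = slow_kcat
    mws = [float(20.0 + rng.integers(1, 40)) for _ in range(n_enzymes)]
    model, enzymes, planted = make_chain_gem(n_enzymes, kcats, mws)
    ec = build_ec_model(model, enzymes, planted["kcats"])
    # Ptot*f*sigma folded into pool_ub through f=sigma=1
    ec_pool = add_protein_pool(ec, Ptot=pool_ub, f=1.0, sigma=1.0)
    tax = Taxonomy(lineage={"sp1": ["Root", "K1", "sp1"], "sp2": ["Root", "K1", "sp2"]})
    entries = [
        KineticEntry(ECNumber.parse(f"1.1.1.{i+1}"), "sp2", "substrate", fast_kcat, "kcat")
        for i in range(n_enzymes)
    ]
    catalog = KineticCatalog(entries=entries)
    cost_fixed = sum(mw / (3600.0 * fast_kcat) for mw in mws)
    mu_exp = min(planted["mu_gem"], pool_ub / cost_fixed)
    return ec_pool, catalog, tax, mu_exp, f"PC{slow_idx+1}"


# ---------------------------------------------------------------------------
# Randomised matching instances
# ---------------------------------------------------------------------------

_ORGS = ["spA1", "spA2", "spB1", "spB2", "spC1", "spC2"]
_ORG_LINEAGES = {
    "spA1": ["Root", "KA", "GA", "spA1"],
    "spA2": ["Root", "KA", "GA", "spA2"],
    "spB1": ["Root", "KA", "GB", "spB1"],
    "spB2": ["Root", "KA", "GB", "spB2"],
    "spC1": ["Root", "KC", "GC", "spC1"],
    "spC2": ["Root", "KC", "GC", "spC2"],
}
_EC_POOL = [
    "1.1.1.1", "1.1.1.2", "1.1.2.3", "1.2.1.1", "2.3.1.5",
    "2.3.1.9", "2.7.1.1", "3.1.1.3", "3.5.1.2", "4.1.1.1",
]
_SUBSTRATES = ["glucose", "ethanol", "pyruvate", "acetate"]


def random_match_instance(
    rng: np.random.Generator,
    max_entries: int = 50,
) -> tuple[KineticCatalog, Taxonomy, KcatQuery]:
    """A randomised (catalog, taxonomy, query) triple for matching tests."""
    tax = Taxonomy(lineage={o: list(l) for o, l in _ORG_LINEAGES.items()})
    n = int(rng.integers(1, max_entries + 1))
    entries = []
    for i in range(n):
        entries.append(
            KineticEntry(
                ec=ECNumber.parse(_EC_POOL[rng.integers(len(_EC_POOL))]),
                organism=_ORGS[rng.integers(len(_ORGS))],
                substrate=_SUBSTRATES[rng.integers(len(_SUBSTRATES))],
                value=float(10 ** rng.uniform(-3, 3)),
                # at least one true kcat so the median fallback is defined
                ptype="kcat" if (i == 0 or rng.random() < 0.8) else "SA",
            )
        )
    catalog = KineticCatalog(entries=entries)
    n_ecs = int(rng.integers(1, 3))
    query = KcatQuery(
        ecs=[ECNumber.parse(_EC_POOL[rng.integers(len(_EC_POOL))]) for _ in range(n_ecs)],
        substrates=list(
            rng.choice(_SUBSTRATES, size=int(rng.integers(1, 3)), replace=False)
        ),
        organism=_ORGS[rng.integers(len(_ORGS))],
        mw_kda=float(10 ** rng.uniform(1, 2)),
    )
    return catalog, tax, query


# ---------------------------------------------------------------------------
# Synthetic proteomics
# ---------------------------------------------------------------------------


def make_synthetic_proteomics(
    ec: ECModel,
    flux,
    noise_cv: float = 0.0,
    dropout: float = 0.0,
    seed: int = 0,
    saturations: dict[str, float] | None = None,
    condition: str = "cond1",
) -> tuple[ProteomicsDataset, dict]:
    """Abundances implied by a flux solution: [E_i] = e_i / s_i × noise.

    ``saturations`` plants per-protein ground-truth saturations in (0, 1]
    (default 1); multiplicative lognormal noise with coefficient of
    variation ``noise_cv``; a ``dropout`` fraction of proteins is removed
    (unmeasured).  Returns the dataset and the ground truth (saturations,
    noiseless abundances, dropped proteins).
    """
    if not (0 <= dropout < 1):
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    sats = {pid: 1.0 for pid in ec.proteins}
    if saturations:
        for pid, s in saturations.items():
            if not (0 < s <= 1):
                raise ValueError(f"planted saturation for {pid} must be in (0, 1]")
            sats[pid] = s
    usage = {pid: flux.fluxes.get(ec.map.usage_rxn[pid], 0.0) for pid in ec.proteins}
    sigma_ln = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    clean = {pid: usage[pid] / sats[pid] for pid in ec.proteins}
    noisy = {
        pid: val * float(np.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln)))
        if sigma_ln > 0
        else val
        for pid, val in clean.items()
    }
    proteins = sorted(noisy)
    n_drop = int(round(dropout * len(proteins)))
    dropped = set(
        rng.choice(proteins, size=n_drop, replace=False) if n_drop else []
    )
    kept = [p for p in proteins if p not in dropped]
    dataset = ProteomicsDataset(
        abundance=pd.DataFrame({condition: [noisy[p] for p in kept]}, index=kept)
    )
    truth = {"saturations": sats, "abundance_clean": clean, "dropped": sorted(dropped)}
    return dataset, truth


# ---------------------------------------------------------------------------
# On-disk fixture sets
# ---------------------------------------------------------------------------


def write_fixture_set(outdir: str | Path, seed: int = 7) -> dict:
    """Write the full toy fixture family as plain-text files + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = ToySpec(seed=seed)
    model, enzymes = make_toy_gem(spec)
    catalog, tax = make_toy_kinetics(spec)
    write_model(model, outdir / "model", format="tabular")
    pd.DataFrame(
        [
            {
                "protein_id": e.protein_id,
                "gene_ids": ";".join(e.gene_ids),
                "ec_numbers": ";".join(str(x) for x in e.ecs),
                "mw_kda": f"{e.mw_kda:g}",
                "subunit_copies": e.subunit_copies,
            }
            for e in enzymes
        ]
    ).to_csv(outdir / "enzymes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "ec_number": str(e.ec),
                "organism": e.organism,
                "substrate": e.substrate,
                "value": f"{e.value:g}",
                "parameter_type": e.ptype,
                "mutant": 0,
            }
            for e in catalog.entries
        ]
    ).to_csv(outdir / "catalog.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"organism": org, "lineage": ";".join(ranks)}
            for org, ranks in sorted(tax.lineage.items())
        ]
    ).to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)

    ec = build_ec_model(model, enzymes, TOY_KCATS)
    ec_pool = add_protein_pool(ec, Ptot=0.05, f=0.5, sigma=0.5)
    flux = solve_fba(ec_pool.model)
    dataset, truth = make_synthetic_proteomics(
        ec_pool, flux, noise_cv=0.05, dropout=0.2, seed=seed
    )
    dataset.abundance.rename_axis("protein_id").to_csv(
        outdir / "proteomics.tsv", sep="\t"
    )
    manifest = {
        "seed": seed,
        "organism": TOY_ORGANISM,
        "planted": {
            "mu_gem": spec.planted["mu_gem"],
            "kcats": spec.planted["kcats"],
            "matches": spec.planted["matches"],
            "proteomics_truth_dropped": truth["dropped"],
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
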