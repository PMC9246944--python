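"""Irreversible split, GPR expansion, ecModel construction and pooling."""

import math

import numpy as np
import pytest

from conftest import POOL_F, POOL_PTOT, POOL_SIGMA
from ecflux.core import (
    FormatError,
    MetabolicModel,
    Metabolite,
    Reaction,
    solve_fba,
)
from ecflux.fixtures import TOY_KCATS, make_chain_gem
from ecflux.kinetics import ECNumber, EnzymeInfo
from ecflux.transform import (
    POOL_RXN,
    PROT_PREFIX,
    add_protein_pool,
    build_ec_model,
    gpr_alternatives,
    map_net_fluxes,
    read_ec_model,
    to_irreversible,
    write_ec_model,
)


class TestIrreversibleSplit:
    def _model(self, lb, ub):
        mets = [Metabolite("A", compartment="c"), Metabolite("B", compartment="c")]
        rxns = [
            Reaction("EX_A", stoichiometry={"A": 1.0}, lb=-5.0, ub=10.0),
            Reaction("R", stoichiometry={"A": -1.0, "B": 1.0}, lb=lb, ub=ub),
            Reaction("EX_B", stoichiometry={"B": -1.0}, lb=-5.0, ub=10.0,
                     objective_coef=1.0),
        ]
        return MetabolicModel(id="t", metabolites=mets, reactions=rxns)

    def test_reversible_reaction_splits_into_two(self):
        irr, pairing = to_irreversible(self._model(-5.0, 10.0))
        assert pairing["R"] == [("R", "fwd"), ("R_REV", "rev")]
        assert (irr.reaction("R").lb, irr.reaction("R").ub) == (0.0, 10.0)
        assert (irr.reaction("R_REV").lb, irr.reaction("R_REV").ub) == (0.0, 5.0)
        assert irr.reaction("R_REV").stoichiometry == {"A": 1.0, "B": -1.0}

    def test_forward_reaction_untouched(self):
        irr, pairing = to_irreversible(self._model(0.0, 10.0))
        assert pairing["R"] == [("R", "fwd")]
        assert (irr.reaction("R").lb, irr.reaction("R").ub) == (0.0, 10.0)

    def test_backward_only_flipped_and_optimum_preserved(self):
        m = self._model(-3.0, 0.0)
        m.reaction("EX_B").objective_coef = 0.0
        m.reaction("EX_A").objective_coef = 1.0  # B -> A now productive
        irr, pairing = to_irreversible(m)
        assert pairing["R"] == [("R_REV", "rev")]
        assert (irr.reaction("R_REV").lb, irr.reaction("R_REV").ub) == (0.0, 3.0)
        assert solve_fba(irr).objective_value == pytest.approx(
            solve_fba(m).objective_value, abs=1e-9
        )


class TestGPRAlternatives:
    @pytest.mark.parametrize(
        "gpr,expected",
        [
            ("g1 or g2", [("g1",), ("g2",)]),
            ("g1 and g2", [("g1", "g2")]),
            ("(g1 and g2) or g3", [("g1", "g2"), ("g3",)]),
            ("g1 OR (g2 AND g3)", [("g1",), ("g2", "g3")]),
            ("g1 or g1", [("g1",)]),  # deduplicated
        ],
    )
    def test_dnf_expansion(self, gpr, expected):
        alts = gpr_alternatives(gpr)
        got = [tuple(s for s, _ in a.subunits) for a in alts]
        assert got == expected

    @pytest.mark.parametrize("bad", ["g1 or", "and g1", "(g1 or g2", "g1 g2"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(FormatError):
            gpr_alternatives(bad)

    def test_dnf_cap_enforced(self):
        wide = " and ".join(f"(a{i} or b{i})" for i in range(8))  # 256 conjuncts
        with pytest.raises(FormatError, match="cap"):
            gpr_alternatives(wide)


class TestBuildEcModel:
    def test_unit_kcat_gives_unit_protein_coefficient(self):
        # kcat = 1/3600 s⁻¹ means 1 mmol enzyme per unit flux
        model, enzymes, planted = make_chain_gem(1, kcats=[1.0 / 3600.0])
        ec = build_ec_model(model, enzymes, planted["kcats"])
        coef = ec.model.reaction("R1").stoichiometry[PROT_PREFIX + "PC1"]
        assert coef == pytest.approx(-1.0, rel=1e-12)

    def test_isoenzymes_expand_and_lp_picks_cheaper(self, toy_ec_pool):
        # R1 has "g1 or g2": two copies, one protein each
        copies = [cid for cid, _ in toy_ec_pool.map.net_to_copies["R1"]]
        assert sorted(copies) == ["R1_No1", "R1_No2"]
        flux = solve_fba(toy_ec_pool.model)
        used = {
            pid: flux.fluxes[toy_ec_pool.map.usage_rxn[pid]] for pid in ("P1", "P2")
        }
        # P1 is cheaper per unit flux (MW/kcat smaller): P2 stays unused
        assert used["P1"] > 1e-6
        assert used["P2"] == pytest.approx(0.0, abs=1e-9)

    def test_promiscuous_enzyme_shares_one_usage_reaction(self, toy_ec):
        # g5 catalyses R3 (reversible, split) and R4: one prot_P5, many consumers
        consumers = [
            r.id
            for r in toy_ec.model.reactions
            if r.stoichiometry.get(PROT_PREFIX + "P5", 0.0) < 0
        ]
        assert set(consumers) == {"R3", "R3_REV", "R4"}
        assert toy_ec.map.usage_rxn["P5"] == "draw_prot_P5"

    def test_complex_subunit_copies_scale_cost(self, toy_ec):
        # P3 enters R2 with two copies: coefficient doubles relative to one copy
        c3 = toy_ec.model.reaction("R2").stoichiometry[PROT_PREFIX + "P3"]
        c4 = toy_ec.model.reaction("R2").stoichiometry[PROT_PREFIX + "P4"]
        assert c3 == pytest.approx(-2.0 / (3600.0 * TOY_KCATS["P3"]))
        assert c4 == pytest.approx(-1.0 / (3600.0 * TOY_KCATS["P4"]))

    def test_relaxation_equivalence(self, toy, toy_ec):
        _, model, _ = toy
        mu_gem = solve_fba(model).objective_value
        mu_ec = solve_fba(toy_ec.model).objective_value
        assert mu_ec == pytest.approx(mu_gem, abs=1e-6)

    def test_unannotated_genes_leave_reaction_enzyme_free(self, toy):
        _, model, enzymes = toy
        # drop P6: R5's only alternative loses its annotation
        pruned = [e for e in enzymes if e.protein_id != "P6"]
        ec = build_ec_model(model, pruned, TOY_KCATS)
        assert "P6" not in ec.proteins
        assert PROT_PREFIX + "P6" not in [m.id for m in ec.model.metabolites]
        assert solve_fba(ec.model).objective_value == pytest.approx(
            solve_fba(model).objective_value, abs=1e-6
        )

    def test_nonpositive_kcat_rejected(self, toy):
        _, model, enzymes = toy
        bad = dict(TOY_KCATS, P1=0.0)
        with pytest.raises(ValueError, match="positive"):
            build_ec_model(model, enzymes, bad)


class TestProteinPool:
    def test_hand_lp_single_enzyme(self):
        # MW 1 kDa, kcat 1/3600: 1 g pool per unit flux; pool ub 0.001 caps flux
        model, enzymes, planted = make_chain_gem(
            1, kcats=[1.0 / 3600.0], mws=[1.0], uptake=10.0
        )
        ec = build_ec_model(model, enzymes, planted["kcats"])
        pooled = add_protein_pool(ec, Ptot=0.001, f=1.0, sigma=1.0)
        assert solve_fba(pooled.model).objective_value == pytest.approx(0.001, abs=1e-9)

    def test_sigma_to_zero_kills_enzymatic_flux(self, toy_ec):
        pooled = add_protein_pool(toy_ec, POOL_PTOT, POOL_F, 1e-9)
        assert solve_fba(pooled.model).objective_value == pytest.approx(0.0, abs=1e-6)

    def test_doubling_ptot_doubles_pool_limited_flux(self, toy_ec):
        mu1 = solve_fba(
            add_protein_pool(toy_ec, POOL_PTOT, POOL_F, POOL_SIGMA).model
        ).objective_value
        mu2 = solve_fba(
            add_protein_pool(toy_ec, 2 * POOL_PTOT, POOL_F, POOL_SIGMA).model
        ).objective_value
        assert mu2 == pytest.approx(2 * mu1, rel=1e-6)

    def test_pool_mass_accounting(self, toy_ec_pool):
        flux = solve_fba(toy_ec_pool.model)
        mass = sum(
            toy_ec_pool.enzymes[p].mw_kda * flux.fluxes[toy_ec_pool.map.usage_rxn[p]]
            for p in toy_ec_pool.proteins
        )
        bound = POOL_PTOT * POOL_F * POOL_SIGMA
        assert mass <= bound + 1e-9
        assert mass == pytest.approx(flux.fluxes[POOL_RXN], abs=1e-9)

    def test_parameter_validation(self, toy_ec):
        with pytest.raises(ValueError):
            add_protein_pool(toy_ec, -1.0, 0.5, 0.5)
        with pytest.raises(ValueError):
            add_protein_pool(toy_ec, 0.5, 1.5, 0.5)

    def test_kcat_monotonicity_on_randomized_chains(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            kcats = list(10 ** rng.uniform(-1, 2, size=4))
            model, enzymes, planted = make_chain_gem(4, kcats=kcats)
            ec = build_ec_model(model, enzymes, planted["kcats"])
            pooled = add_protein_pool(ec, 0.01, 1.0, 1.0)
            mu0 = solve_fba(pooled.model).objective_value
            i = int(rng.integers(4))
            pid = f"PC{i+1}"
            for cid in pooled.copies_of(pid):
                pooled.set_kcat(pid, cid, kcats[i] * 10.0)
            assert solve_fba(pooled.model).objective_value >= mu0 - 1e-9


class TestNetMapping:
    def test_fwd_minus_rev_and_isoenzyme_sums(self, toy_ec_pool):
        flux = solve_fba(toy_ec_pool.model)
        net = map_net_fluxes(toy_ec_pool, flux)
        r3 = flux.fluxes["R3"] - flux.fluxes["R3_REV"]
        assert net.fluxes["R3"] == pytest.approx(r3, abs=1e-12)
        r1 = flux.fluxes["R1_No1"] + flux.fluxes["R1_No2"]
        assert net.fluxes["R1"] == pytest.approx(r1, abs=1e-12)

    def test_mapped_vector_mass_balanced_in_gem(self, toy, toy_ec_pool):
        _, model, _ = toy
        flux = solve_fba(toy_ec_pool.model)
        net = map_net_fluxes(toy_ec_pool, flux)
        S = model.stoichiometric_matrix()
        v = np.array([net.fluxes[r] for r in model.reaction_ids])
        assert np.max(np.abs(S @ v)) < 1e-6


class TestSerialisation:
    def test_tabular_roundtrip_same_optimum(self, toy_ec_pool, tmp_path):
        write_ec_model(toy_ec_pool, tmp_path / "ec", format="tabular")
        back = read_ec_model(tmp_path / "ec", format="tabular")
        assert back.kcats == toy_ec_pool.kcats
        assert back.pool["Ptot"] == toy_ec_pool.pool["Ptot"]
        assert solve_fba(back.model).objective_value == pytest.approx(
            solve_fba(toy_ec_pool.model).objective_value, abs=1e-9
        )

    def test_sbml_roundtrip_same_optimum(self, toy_ec_pool, tmp_path):
        write_ec_model(toy_ec_pool, tmp_path / "ec", format="sbml_fbc2")
        back = read_ec_model(tmp_path / "ec", format="sbml_fbc2")
        assert solve_fba(back.model).objective_value == pytest.approx(
            solve_fba(toy_ec_pool.model).objective_value, abs=1e-6
        )
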