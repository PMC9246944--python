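"""NSAF quantification, abundance constraints and bound flexibilization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import POOL_F, POOL_PTOT, POOL_SIGMA
from ecflux.core import solve_fba
from ecflux.fixtures import make_synthetic_proteomics
from ecflux.proteomics import (
    FlexLog,
    NonProteomicLimitError,
    ProteomicsDataset,
    SpectralCounts,
    StandardsTable,
    calibrate_absolute,
    condition_responsive,
    constrain_with_proteomics,
    flexibilize_proteins,
    make_condition_models,
    nsaf,
)
from ecflux.simulate import ConditionSpec, UsageProfile, usage_profile
from ecflux.transform import add_protein_pool

import pandas as pd

TOY_COND = dict(biomass_rxn="BIOMASS", carbon_source_rxn="EX_glc")


class TestNSAF:
    def test_equal_length_normalised_counts(self):
        values = nsaf(SpectralCounts(spc={"p1": 10, "p2": 30}, length={"p1": 100, "p2": 300}))
        assert values == {"p1": pytest.approx(0.5), "p2": pytest.approx(0.5)}

    def test_single_protein_gets_everything(self):
        assert nsaf(SpectralCounts(spc={"p": 7}, length={"p": 42}))["p"] == 1.0

    def test_scaling_invariance(self):
        base = SpectralCounts(spc={"a": 2, "b": 9, "c": 1}, length={"a": 10, "b": 30, "c": 5})
        scaled = SpectralCounts(
            spc={k: 7 * v for k, v in base.spc.items()}, length=base.length
        )
        for k, v in nsaf(base).items():
            assert nsaf(scaled)[k] == pytest.approx(v, rel=1e-12)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            nsaf(SpectralCounts(spc={"p": 0}, length={"p": 10}))

    @settings(derandomize=True, max_examples=40)
    @given(
        st.dictionaries(
            st.text("abcdef", min_size=1, max_size=3),
            st.tuples(st.integers(0, 10_000), st.integers(1, 5_000)),
            min_size=1,
            max_size=20,
        )
    )
    def test_normalisation_sums_to_one(self, data):
        counts = SpectralCounts(
            spc={k: float(s) for k, (s, _) in data.items()},
            length={k: float(l) for k, (_, l) in data.items()},
        )
        if sum(counts.spc.values()) == 0:
            return
        assert sum(nsaf(counts).values()) == pytest.approx(1.0, abs=1e-12)


class TestStandardsRegression:
    def test_identity_line_is_identity_on_nsaf(self):
        standards = StandardsTable(
            amount={"s1": 1e-3, "s2": 1e-2}, nsaf={"s1": 1e-3, "s2": 1e-2}
        )
        out, fit = calibrate_absolute({"p": 0.5}, standards)
        assert fit["slope"] == pytest.approx(1.0, abs=1e-12)
        assert fit["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(0.5, rel=1e-12)

    def test_planted_slope_intercept_recovered_exactly(self):
        slope, intercept = 0.8, -2.0
        nsafs = {f"s{i}": 10 ** (-4 + i) for i in range(5)}
        amounts = {
            k: 10 ** (slope * math.log10(v) + intercept) for k, v in nsafs.items()
        }
        standards = StandardsTable(amount=amounts, nsaf=nsafs)
        out, fit = calibrate_absolute({"p": 1e-3}, standards, scale=2.0)
        assert fit["slope"] == pytest.approx(slope, abs=1e-12)
        assert fit["intercept"] == pytest.approx(intercept, abs=1e-12)
        assert fit["r2"] == pytest.approx(1.0, abs=1e-12)
        assert out["p"] == pytest.approx(2.0 * 10 ** (slope * -3 + intercept), rel=1e-10)

    def test_single_standard_rejected(self):
        with pytest.raises(ValueError, match="2 standards"):
            StandardsTable(amount={"s1": 1.0}, nsaf={"s1": 0.5})


class TestConstraining:
    def test_remaining_pool_arithmetic(self, toy_ec):
        # Ptot 0.5, measured mass 0.1 (P1 at 0.002 mmol * 50 g/mmol), f sigma 0.5
        ec = constrain_with_proteomics(toy_ec, {"P1": 0.002}, 0.5, 0.5, 0.5)
        assert ec.pool["remaining"] == pytest.approx((0.5 - 0.1) * 0.25)
        assert ec.model.reaction(ec.pool["pool_rxn_id"]).ub == pytest.approx(0.1)
        assert ec.model.reaction("draw_prot_P1").ub == pytest.approx(0.002)
        # measured usage is detached from the pool
        assert "prot_pool" not in ec.model.reaction("draw_prot_P1").stoichiometry

    def test_measured_mass_above_ptot_rejected(self, toy_ec):
        with pytest.raises(ValueError, match="exceeds Ptot"):
            constrain_with_proteomics(toy_ec, {"P1": 1.0}, 0.01, 0.5, 0.5)

    def test_slack_constraints_reproduce_pool_model(self, toy, toy_ec):
        # generous Ptot: both the pooled and the proteomics-constrained model
        # are medium-limited, so all three growth rates coincide
        _, model, _ = toy
        mu_gem = solve_fba(model).objective_value
        generous = add_protein_pool(toy_ec, Ptot=5000.0, f=0.5, sigma=0.5)
        mu_pool = solve_fba(generous.model).objective_value
        ab = {p: 10.0 for p in toy_ec.proteins}
        prot = constrain_with_proteomics(toy_ec, ab, 5000.0, 0.5, 0.5)
        mu_prot = solve_fba(prot.model).objective_value
        assert mu_pool == pytest.approx(mu_gem, abs=1e-6)
        assert mu_prot == pytest.approx(mu_pool, abs=1e-6)

    def test_zero_abundance_on_essential_enzyme_blocks_growth(self, toy_ec):
        ec = constrain_with_proteomics(toy_ec, {"P6": 0.0}, 0.5, 0.5, 0.5)
        assert solve_fba(ec.model).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_bound_respect_at_optimum(self, toy_ec_pool, toy_ec):
        flux0 = solve_fba(toy_ec_pool.model)
        ds, _ = make_synthetic_proteomics(toy_ec_pool, flux0, 0.0, 0.0, seed=2)
        ab = {p: v for p, v in ds.condition("cond1").items() if v > 0}
        ec = constrain_with_proteomics(toy_ec, ab, 0.5, 0.5, 0.5)
        flux = solve_fba(ec.model)
        for pid, bound in ab.items():
            assert flux.fluxes[ec.map.usage_rxn[pid]] <= bound + 1e-9
        unmeasured_mass = sum(
            ec.enzymes[p].mw_kda * flux.fluxes[ec.map.usage_rxn[p]]
            for p in ec.proteins
            if p not in ab
        )
        assert unmeasured_mass <= ec.pool["remaining"] + 1e-9


class TestFlexibilization:
    def _planted(self, toy_ec_pool, toy_ec, squeeze):
        flux = solve_fba(toy_ec_pool.model)
        mu_pool = flux.objective_value
        ds, _ = make_synthetic_proteomics(toy_ec_pool, flux, 0.0, 0.0, seed=3)
        ab = {p: v * 2.0 + 1e-9 for p, v in ds.condition("cond1").items()}
        for pid, factor in squeeze.items():
            ab[pid] = flux.fluxes[toy_ec_pool.map.usage_rxn[pid]] * factor
        ec = constrain_with_proteomics(toy_ec, ab, 0.5, 0.5, 0.5)
        return ec, mu_pool

    def test_planted_single_low_bound_found(self, toy_ec_pool, toy_ec):
        ec, mu_pool = self._planted(toy_ec_pool, toy_ec, {"P6": 0.3})
        cond = ConditionSpec(dilution_rate=mu_pool * 0.999, **TOY_COND)
        fixed, log = flexibilize_proteins(ec, cond)
        assert log.proteins == ["P6"]
        assert log.feasible
        assert solve_fba(fixed.model).objective_value >= cond.dilution_rate - 1e-9
        for entry in log.entries:
            assert entry.relaxed_bound > entry.original_bound

    def test_already_feasible_leaves_empty_log(self, toy_ec_pool, toy_ec):
        ec, mu_pool = self._planted(toy_ec_pool, toy_ec, {})
        cond = ConditionSpec(dilution_rate=mu_pool * 0.5, **TOY_COND)
        _, log = flexibilize_proteins(ec, cond)
        assert len(log) == 0
        assert log.feasible

    def test_greedy_relaxation_is_minimal(self, toy_ec_pool, toy_ec):
        # undoing the single logged relaxation must drop growth below target
        ec, mu_pool = self._planted(toy_ec_pool, toy_ec, {"P6": 0.3})
        cond = ConditionSpec(dilution_rate=mu_pool * 0.999, **TOY_COND)
        fixed, log = flexibilize_proteins(ec, cond)
        entry = log.entries[0]
        fixed.model.reaction(fixed.map.usage_rxn[entry.protein_id]).ub = (
            entry.original_bound
        )
        assert solve_fba(fixed.model).objective_value < cond.dilution_rate - 1e-9

    def test_two_binding_bounds_relaxed_within_two_iterations(
        self, toy_ec_pool, toy_ec
    ):
        ec, mu_pool = self._planted(toy_ec_pool, toy_ec, {"P6": 0.3, "P5": 0.3})
        cond = ConditionSpec(dilution_rate=mu_pool * 0.999, **TOY_COND)
        fixed, log = flexibilize_proteins(ec, cond)
        assert set(log.proteins) == {"P5", "P6"}
        assert max(e.iteration for e in log.entries) <= 2
        assert solve_fba(fixed.model).objective_value >= cond.dilution_rate - 1e-9

    def test_non_proteomic_limit_detected(self, toy_ec_pool, toy_ec):
        ec, mu_pool = self._planted(toy_ec_pool, toy_ec, {})
        cond = ConditionSpec(dilution_rate=100.0, **TOY_COND)  # above GEM capacity
        with pytest.raises(NonProteomicLimitError):
            flexibilize_proteins(ec, cond)

    def test_noisy_abundances_with_margin_need_no_flexibilization(
        self, toy_ec_pool, toy_ec
    ):
        flux = solve_fba(toy_ec_pool.model)
        for seed in range(5):
            ds, _ = make_synthetic_proteomics(
                toy_ec_pool, flux, noise_cv=0.10, dropout=0.0, seed=seed
            )
            ab = {p: v * 1.2 + 1e-9 for p, v in ds.condition("cond1").items()}
            ec = constrain_with_proteomics(toy_ec, ab, 0.5, 0.5, 0.5)
            cond = ConditionSpec(
                dilution_rate=flux.objective_value * (1.2 / 1.1) * 0.8, **TOY_COND
            )
            _, log = flexibilize_proteins(ec, cond)
            assert len(log) == 0


class TestConditionResponsive:
    def _profile(self, ab, sat):
        usage = {p: ab[p] * sat[p] for p in ab}
        return UsageProfile(usage=usage, abundance=dict(ab), saturation=dict(sat))

    def test_rule_application(self):
        ref = self._profile({"p": 1.0}, {"p": 0.4})
        stress = self._profile({"p": 2.0}, {"p": 0.96})
        assert condition_responsive(ref, stress) == ["p"]

    def test_downregulated_never_responsive(self):
        ref = self._profile({"p": 2.0}, {"p": 0.5})
        stress = self._profile({"p": 1.0}, {"p": 0.99})
        assert condition_responsive(ref, stress) == []

    def test_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(77)
        ids = [f"p{i}" for i in range(300)]
        ref = self._profile(
            {p: float(rng.lognormal(0, 1)) for p in ids},
            {p: float(rng.uniform(0.01, 1.0)) for p in ids},
        )
        stress = self._profile(
            {p: float(rng.lognormal(0, 1)) for p in ids},
            {p: float(rng.uniform(0.01, 1.0)) for p in ids},
        )
        expected = sorted(
            p
            for p in ids
            if stress.abundance[p] / ref.abundance[p] > 1.0
            and stress.saturation[p] / ref.saturation[p] > 1.0
            and stress.saturation[p] >= 0.95
        )
        assert condition_responsive(ref, stress) == expected


class TestConditionModels:
    def test_identical_columns_give_identical_models(self, toy_ec_pool, toy_ec):
        flux = solve_fba(toy_ec_pool.model)
        ds, _ = make_synthetic_proteomics(toy_ec_pool, flux, 0.0, 0.0, seed=4)
        col = ds.abundance["cond1"]
        dataset = ProteomicsDataset(
            abundance=pd.DataFrame({"c1": col * 2.0, "c2": col * 2.0})
        )
        conds = {
            name: ConditionSpec(
                dilution_rate=flux.objective_value * 0.9, Ptot=0.5, **TOY_COND
            )
            for name in ("c1", "c2")
        }
        out = make_condition_models(toy_ec, dataset, conds, f=0.5, sigma=0.5)
        m1, m2 = out["c1"][0].model, out["c2"][0].model
        for r1, r2 in zip(m1.reactions, m2.reactions):
            assert (r1.id, r1.lb, r1.ub) == (r2.id, r2.lb, r2.ub)

    def test_planted_condition_difference_shows_in_flexlogs(self, toy_ec_pool, toy_ec):
        flux = solve_fba(toy_ec_pool.model)
        ds, _ = make_synthetic_proteomics(toy_ec_pool, flux, 0.0, 0.0, seed=4)
        col = ds.abundance["cond1"] * 2.0 + 1e-9
        squeezed = col.copy()
        squeezed["P6"] = flux.fluxes[toy_ec_pool.map.usage_rxn["P6"]] * 0.3
        dataset = ProteomicsDataset(
            abundance=pd.DataFrame({"ref": col, "stress": squeezed})
        )
        conds = {
            name: ConditionSpec(
                dilution_rate=flux.objective_value * 0.999, Ptot=0.5, **TOY_COND
            )
            for name in ("ref", "stress")
        }
        out = make_condition_models(toy_ec, dataset, conds, f=0.5, sigma=0.5)
        assert out["ref"][1].proteins == []
        assert out["stress"][1].proteins == ["P6"]
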