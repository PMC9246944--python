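"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import pytest

from ecflux.fixtures import (
    TOY_KCATS,
    ToySpec,
    make_chain_gem,
    make_toy_gem,
    make_toy_kinetics,
)
from ecflux.kinetics import (
    KcatQuery,
    KineticCatalog,
    MatchRecord,
    Taxonomy,
    lineage_distance,
    sa_to_kcat,
    wildcard_levels,
)
from ecflux.transform import add_protein_pool, build_ec_model

POOL_PTOT, POOL_F, POOL_SIGMA = 0.05, 0.5, 0.5


@pytest.fixture()
def toy():
    """(spec, GEM, enzyme list) for the 12-reaction motif toy."""
    spec = ToySpec()
    model, enzymes = make_toy_gem(spec)
    return spec, model, enzymes


@pytest.fixture()
def toy_ec(toy):
    _, model, enzymes = toy
    return build_ec_model(model, enzymes, TOY_KCATS)


@pytest.fixture()
def toy_ec_pool(toy_ec):
    return add_protein_pool(toy_ec, POOL_PTOT, POOL_F, POOL_SIGMA)


@pytest.fixture()
def toy_kinetics():
    spec = ToySpec()
    catalog, tax = make_toy_kinetics(spec)
    return spec, catalog, tax


@pytest.fixture()
def chain():
    """(model, enzymes, planted) for the 5-step closed-form chain."""
    return make_chain_gem(5)


# ---------------------------------------------------------------------------
# Independent matching oracle: exhaustive enumeration of the search lattice,
# written directly from its documented ordering, sharing no code with the
# implementation under test.
# ---------------------------------------------------------------------------

_CLASS_ORDER = ("org_substrate", "org_any", "any_substrate", "any_any")


def oracle_match(
    query: KcatQuery, catalog: KineticCatalog, tax: Taxonomy
) -> MatchRecord:
    subs = set(query.substrates)
    patterns = [wildcard_levels(ec) for ec in query.ecs if ec.complete]
    for source in ("kcat", "SA"):
        for w in range(4):
            level_entries = [
                e
                for e in catalog.entries
                if e.ptype == source
                and any(p[w].matches(e.ec) for p in patterns)
            ]
            for cls in _CLASS_ORDER:
                if cls == "org_substrate":
                    cell = [
                        e for e in level_entries
                        if e.organism == query.organism and e.substrate in subs
                    ]
                elif cls == "org_any":
                    cell = [e for e in level_entries if e.organism == query.organism]
                elif cls == "any_substrate":
                    cell = [e for e in level_entries if e.substrate in subs]
                else:
                    cell = list(level_entries)
                if cls.startswith("any") and cell:
                    dmin = min(
                        lineage_distance(query.organism, e.organism, tax) for e in cell
                    )
                    cell = [
                        e for e in cell
                        if lineage_distance(query.organism, e.organism, tax) == dmin
                    ]
                if not cell:
                    continue

                def value_of(e):
                    return (
                        e.value if e.ptype == "kcat"
                        else sa_to_kcat(e.value, query.mw_kda)
                    )

                best = max(cell, key=value_of)
                return MatchRecord(
                    kcat_s=value_of(best),
                    wildcards=w,
                    priority_class=cls,
                    source=source,
                    donor_organism=best.organism,
                    distance=lineage_distance(query.organism, best.organism, tax)
                    if cls.startswith("any")
                    else 0.0,
                    fallback=False,
                )
    return MatchRecord(
        kcat_s=catalog.median_kcat(),
        wildcards=3,
        priority_class="any_any",
        source="kcat",
        donor_organism="",
        distance=math.inf,
        fallback=True,
    )


def records_agree(a: MatchRecord, b: MatchRecord) -> bool:
    """Full provenance comparison with a value tolerance for SA conversion."""
    return (
        math.isclose(a.kcat_s, b.kcat_s, rel_tol=1e-12)
        and a.wildcards == b.wildcards
        and a.priority_class == b.priority_class
        and a.source == b.source
        and a.fallback == b.fallback
        and (a.fallback or a.donor_organism == b.donor_organism)
        and (a.distance == b.distance or (math.isinf(a.distance) and math.isinf(b.distance)))
    )
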