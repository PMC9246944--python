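# Methods

This note records the modelling choices behind `ecflux`: the constraint
formulation, the matching and calibration algorithms, what the synthetic
fixtures emulate, and the numerical conventions.

## Enzyme-constraint formulation

A GEM is first made irreversible: a reversible reaction (lb < 0 < ub)
splits into a forward copy [0, ub] and a `_REV` copy [0, −lb] with negated
stoichiometry; backward-only reactions are flipped into a single `_REV`
copy.  The linear objective is preserved under the net mapping (reverse
copies carry the negated coefficient).  GPRs are expanded to disjunctive
normal form (cap 32 disjuncts): each OR-disjunct becomes its own reaction
copy `<rxn>_No<k>`, each AND-conjunct a subunit list.  Every protein gets
one pseudo-metabolite `prot_<id>` (compartment `enzyme`) and one usage
reaction `draw_prot_<id>` regardless of how many copies consume it, so
promiscuity arises by construction.  A copy catalysed by protein *i* with
`n_i` subunit copies consumes `prot_i` at `n_i / (3600 · kcat)` per unit
flux — kcat is stored in s⁻¹ and converted to h⁻¹ at stoichiometry time
because fluxes are in mmol/gDW/h.

Reactions whose genes lack enzyme annotation, and GPR alternatives with no
matched kcat, stay **enzyme-free** rather than blocked: enzyme coverage of
real models is below 100% and a missing parameter must not delete
capability.  When some alternatives of a reaction are costed and others are
not, only the costed ones become copies (an uncosted copy would be a free
bypass that voids the enzyme constraints for that reaction); this is logged.

The pooled ("batch") flavour rewrites each usage reaction to convert
`MW_i` grams of a shared pool metabolite per mmol of protein (kDa ≡ g/mmol)
and bounds the pool exchange by `Ptot·f·σ`.  Defaults used by the fixtures:
`Ptot = 0.05 g/gDW`, `f = 0.5`, `σ = 0.5` — deliberately small so the pool,
not the medium, is the binding resource in the toy.

## Hierarchical kcat matching

Queries carry the enzyme's EC numbers, the reaction's substrate names
(lower-cased metabolite names; exact string equality, no chemical
similarity), the model organism and the enzyme's molecular weight.  The
search lattice is scanned in lexicographic order

    source ∈ {kcat, SA}  ×  wildcards ∈ {0..3}  ×
    class ∈ {org_substrate, org_any, any_substrate, any_any}

and the first non-empty cell wins.  Source outranks everything (a true
kcat at any wildcard level beats any specific activity), wildcard level
outranks class, and a substrate match outranks phylogenetic proximity
within a level.  Inside the `any_*` classes only entries from donor
organisms at minimal lineage distance are eligible; the distance between
two organisms is the edge count through their lowest common ancestor on
KEGG-style lineage paths, infinite when either organism is missing (such
donors are eligible only when no tree organism has entries).  Within the
winning cell the **maximum** value is taken — the optimistic-capacity
convention of enzyme-constrained modelling; over-constraint is later
repaired by flexibilization, under-constraint is not.  Specific activities
convert as `kcat = SA · MW / 60` (µmol·min⁻¹·mg⁻¹ × g/mmol → s⁻¹).  A query
matching nothing anywhere receives the catalog-wide median kcat, flagged
`fallback`.  No upper cap is applied to matched kcats.

## Calibration

**Enzyme control coefficients.**  With baseline growth μ₀ > 0, protein
*i*'s coefficient is `ECC_i = (μ_i − μ₀)/μ₀` where μ_i is the optimum after
multiplying all of *i*'s kcats by α = 1000 (large enough to effectively
remove that single constraint).  Note that an isoenzyme unused at the
baseline can still have ECC > 0 — the boost can make it the cheaper
alternative — so ECC = 0 is guaranteed only for enzymes whose relaxation
cannot reroute flux.

**kcat flexibilization.**  One protein per iteration: the top-ECC enzyme
(ties broken by larger pool mass share MW·e, then protein id) has the kcat
on *all* of its reaction copies replaced by the largest catalog value for
its EC class, found at the most specific non-empty wildcard level; if the
catalog holds nothing larger, the kcat jumps to the catalog-wide maximum
and the step is flagged `cost_removed`.  Because raising a kcat only
shrinks an LP coefficient, μ is non-decreasing and the loop terminates at
μ ≥ μ_exp·(1 − 10⁻³), after 100 iterations, or when no substitution
improves growth.  A pre-check with all enzyme costs removed distinguishes
kinetic from stoichiometric/medium limitation and errors on the latter.

**σ fitting.**  μ is monotone non-decreasing in the pool bound, so plain
bisection on σ ∈ (0, 1] converges; the stopping rule is
|μ(σ) − μ_exp| ≤ 10⁻⁴, and an unreachable target returns the boundary with
a warning.

## Proteomics integration

NSAF_i = (SpC_i/L_i)/Σ_j(SpC_j/L_j); absolute conversion fits
log₁₀(amount) on log₁₀(NSAF) over spiked standards by least squares and
applies the line to all proteins, rescaled by an explicit loading factor —
the unit chain from instrument to mmol/gDW is a configuration input, not a
hidden constant.

Measured abundances become usage upper bounds and those proteins are
**detached** from the pool (their mass is already spent); unmeasured
proteins share a remaining pool `max(0, Ptot − Σ MW·[E])·f·σ`.  Measured
mass above Ptot is a data inconsistency and errors.  An abundance of zero
is a hard bound, not a missing value.

Flexibilization of infeasible abundance sets is greedy and auditable: among
proteins sitting at their bound, probe the growth gained by unbounding each
alone; relax the best to its probe usage × 1.01.  When no single relaxation
helps, the top-k candidates are unbounded jointly with k doubling, and only
bounds that actually move are logged.  A final model below target with all
measured bounds removed raises "limitation not proteomic".

Condition-responsive enzymes require abundance fold-change > 1 *and*
saturation fold-change > 1 *and* stress saturation ≥ 0.95, computed only on
proteins measured in both conditions.

## Simulation recipes

Every headline objective is followed by a parsimonious-FBA polish
(objective fixed as an equality band, total |v| minimised over a
positive/negative split) so reported flux vectors are reproducible across
solvers.  Batch growth opens the named carbon source (uptake bound −1000)
and maximises biomass; protein demand fixes biomass, unbounds the pool and
minimises pool exchange; chemostat fixes biomass at the dilution rate,
applies measured exchange bounds first and maximises the NGAM reaction —
for proteomics-constrained models the objective is instead minimisation of
total unmeasured-protein usage.  Net bounds on split reactions map to
fwd [max(lb,0), max(ub,0)] / rev [max(−ub,0), max(−lb,0)]; nets expanded
into isoenzyme copies cannot be bounded per copy and are rejected.

Comparative FVA optimises the **net expression** (forward − reverse,
summed over isoenzyme copies) of each GEM reaction, because the comparison
against the parent GEM lives at net-reaction level.  "Fully variable" means
the range spans the default ±1000 mmol/gDW/h bounds within 10⁻⁶; "active"
means a GEM range above 10⁻⁸ (the fraction-reduced-by-≥95% statistic needs
a denominator and this is it).

The FSEOF scan enforces production at 10 evenly spaced levels between the
target flux at the growth optimum and 90% of its maximum (growth kept above
10% of optimum when computing that maximum), re-maximising growth + pFBA at
each level.  Candidates must increase strictly (tolerance 10⁻⁹) with
consistent sign; reactions and enzyme usages are ranked separately by the
slope of a linear fit against the enforced level, since their slopes carry
different units.

## Synthetic fixtures

The fixtures emulate the *structure* of real inputs, not their scale: a
12-reaction toy GEM containing every enzyme-constraint motif (isoenzyme
pair, two-subunit complex with subunit stoichiometry 2:1, promiscuous
enzyme on two reactions, reversible step, enzyme-catalysed reversible
futile cycle, NGAM, biomass), with the closed-form optimum μ* = 20/3 at
glucose uptake 10; a linear chain with closed-form enzyme cost
Σ MW_i/(3600·kcat_i) used wherever a hand-solvable μ(pool) relationship is
needed; planted kinetic catalogs covering each lattice cell of interest;
and proteomics abundances generated as `[E_i] = e_i/s_i × lognormal noise`
from a solved flux distribution with planted saturations, mean-one noise
(CV configurable) and a dropout fraction of unmeasured proteins.  Fixture
kcats span 10⁻³–10³ s⁻¹, mirroring the orders-of-magnitude spread of real
catalogs.  Every generator is a pure function of (spec, seed) and asserts
its planted optimum against the LP at generation time.

What passing tests do **not** show: behaviour on genome-scale networks
(thousands of reactions, degenerate alternate optima, numerically awkward
biomass equations), real BRENDA-style data heterogeneity (substrate
synonymy, unit errors, mutant mislabeling beyond a flag), or measurement
error structure beyond multiplicative lognormal noise.

## Numerical conventions

LP feasibility/optimality 10⁻⁹ at the solver (HiGHS via scipy), 10⁻⁶ at
assertion level; pFBA widens its equality band once by 10⁻⁶·max(1, |target|)
on numerical infeasibility, then errors.  Solver ties are broken by the
solver; all cross-model comparisons use objective values or pFBA-polished
vectors, never raw alternate-optimum fluxes.  Tabular serialisation keeps
12 significant digits so kcat-scaled coefficients round-trip.  Problem
sizes throughout (toys of ~10–25 reactions, 120 randomized matching
instances, 20 calibration seeds) are chosen so the whole suite and the
acceptance script each run in seconds while still exercising every code
path; the closed-form fixtures make larger sizes uninformative.

## Known limitations

No MILP/QP, thermodynamic constraints, or loopless FVA; no compartment
-specific enzyme copies, post-translational modification costs or membrane
occupancy constraints; substrate matching is exact-string only; the
tabular model dialect is this package's own (documented in the README),
not an interchange standard.
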