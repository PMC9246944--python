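"""Kinetic-parameter catalogs and hierarchical turnover-number matching.

Enzyme turnover numbers (kcat, s⁻¹) for a model organism are assembled from a
flat catalog of measured kcat and specific-activity (SA) entries keyed by EC
number, source organism and substrate.  Because few enzymes are kinetically
characterised in any one organism, assignment is hierarchical: an exact match
(same EC, organism, substrate) is preferred, and the search widens along three
axes when a cell of the hierarchy is empty —

* **EC wildcards**: trailing EC fields are generalised one at a time
  (``1.1.1.1 → 1.1.1.* → 1.1.*.* → 1.*.*.*``), admitting entries from related
  reaction mechanisms.
* **Priority class**: same organism + substrate, then same organism, then any
  organism with the substrate, then any organism.  Within the "any organism"
  classes, only entries from the phylogenetically closest donor organisms are
  eligible, with distance measured on KEGG-style lineage strings.
* **Source**: true kcat measurements outrank SA values; an SA entry
  (µmol·min⁻¹·mg⁻¹) is converted to a kcat via the query enzyme's molecular
  weight (kcat = SA × MW / 60).

Within the first non-empty cell the maximum value is taken (optimistic
capacity); every assignment records its full provenance in a
:class:`MatchRecord`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ECNumber",
    "KineticEntry",
    "KineticCatalog",
    "Taxonomy",
    "EnzymeInfo",
    "KcatQuery",
    "MatchRecord",
    "PRIORITY_CLASSES",
    "parse_catalog",
    "parse_taxonomy",
    "parse_enzyme_table",
    "wildcard_levels",
    "lineage_distance",
    "sa_to_kcat",
    "match_kcat",
    "summarize_matches",
]

WILDCARD = "*"
PRIORITY_CLASSES = ("org_substrate", "org_any", "any_substrate", "any_any")


@dataclass(frozen=True)
class ECNumber:
    """Four-field EC code; wildcards are only legal as a trailing run."""

    fields: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.fields) != 4:
            raise ValueError(f"EC number needs 4 fields, got {self.fields!r}")
        seen_wild = False
        for f in self.fields:
            if f == WILDCARD:
                seen_wild = True
            else:
                if seen_wild:
                    raise ValueError(
                        f"illegal EC {'.'.join(self.fields)!r}: wildcards must be a suffix run"
                    )
                if not f.isdigit() or int(f) <= 0:
                    raise ValueError(f"EC field {f!r} is not a positive integer")

    @classmethod
    def parse(cls, text: str) -> "ECNumber":
        text = text.strip()
        if text.lower().startswith("ec"):
            text = text[2:].lstrip(". ")
        parts = tuple(p.strip() for p in text.split("."))
        if len(parts) != 4:
            raise ValueError(f"cannot parse EC number {text!r}")
        return cls(parts)  # type: ignore[arg-type]

    @property
    def complete(self) -> bool:
        return WILDCARD not in self.fields

    @property
    def n_wildcards(self) -> int:
        return sum(1 for f in self.fields if f == WILDCARD)

    def matches(self, other: "ECNumber") -> bool:
        """True when ``other`` (complete) falls under this possibly-wild EC."""
        return all(a == WILDCARD or a == b for a, b in zip(self.fields, other.fields))

    def __str__(self) -> str:
        return ".".join(self.fields)


def wildcard_levels(ec: ECNumber) -> list[ECNumber]:
    """The four generalisation levels of a complete EC, most specific first."""
    if not ec.complete:
        raise ValueError(f"EC {ec} already contains wildcards")
    a, b, c, d = ec.fields
    return [
        ec,
        ECNumber((a, b, c, WILDCARD)),
        ECNumber((a, b, WILDCARD, WILDCARD)),
        ECNumber((a, WILDCARD, WILDCARD, WILDCARD)),
    ]


@dataclass(frozen=True)
class KineticEntry:
    ec: ECNumber
    organism: str
    substrate: str
    value: float
    ptype: str  # "kcat" (1/s) or "SA" (umol/min/mg)
    mutant: bool = False

    def __post_init__(self) -> None:
        if self.ptype not in ("kcat", "SA"):
            raise ValueError(f"unknown parameter type {self.ptype!r}")
        if not self.value > 0:
            raise ValueError(f"non-positive kinetic value {self.value!r}")
        if not self.ec.complete:
            raise ValueError("catalog entries must carry complete EC numbers")


@dataclass
class KineticCatalog:
    """Non-mutant kinetic entries, indexed by EC class-1 field for speed."""

    entries: list[KineticEntry]
    mutant_count: int = 0
    _by_class: dict[str, list[KineticEntry]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_class = {}
        for e in self.entries:
            self._by_class.setdefault(e.ec.fields[0], []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def query(self, pattern: ECNumber) -> list[KineticEntry]:
        pool = self._by_class.get(pattern.fields[0], ())
        return [e for e in pool if pattern.matches(e.ec)]

    def median_kcat(self) -> float:
        import statistics

        values = [e.value for e in self.entries if e.ptype == "kcat"]
        if not values:
            raise ValueError("catalog holds no kcat entries; no fallback possible")
        return statistics.median(values)

    def max_kcat(self) -> float:
        values = [e.value for e in self.entries if e.ptype == "kcat"]
        if not values:
            raise ValueError("catalog holds no kcat entries")
        return max(values)


@dataclass
class Taxonomy:
    """KEGG-style lineages: organism name → ordered ranks, root first."""

    lineage: dict[str, list[str]]

    def __post_init__(self) -> None:
        for org, ranks in self.lineage.items():
            if not ranks:
                raise ValueError(f"organism {org!r} has an empty lineage")
            if ranks[-1] != org:
                raise ValueError(
                    f"organism {org!r}: species name must equal the last rank "
                    f"(got {ranks[-1]!r})"
                )

    def __contains__(self, organism: str) -> bool:
        return organism in self.lineage


def lineage_distance(a: str, b: str, tax: Taxonomy) -> float:
    """Tree distance between two organisms on their lineage paths.

    Counts the edges from each species up to the lowest common ancestor rank;
    0 iff the organisms are identical, ``inf`` when either is absent.
    """
    if a == b and a in tax:
        return 0.0
    if a not in tax or b not in tax:
        return math.inf
    la, lb = tax.lineage[a], tax.lineage[b]
    common = 0
    for ra, rb in zip(la, lb):
        if ra != rb:
            break
        common += 1
    return float((len(la) - common) + (len(lb) - common))


@dataclass
class EnzymeInfo:
    protein_id: str
    gene_ids: list[str]
    ecs: list[ECNumber]
    mw_kda: float  # kDa == g/mmol
    subunit_copies: int = 1

    def __post_init__(self) -> None:
        if not self.mw_kda > 0:
            raise ValueError(f"{self.protein_id}: molecular weight must be positive")
        if not self.gene_ids:
            raise ValueError(f"{self.protein_id}: at least one gene id required")
        if self.subunit_copies < 1:
            raise ValueError(f"{self.protein_id}: subunit copies must be >= 1")


@dataclass
class KcatQuery:
    ecs: list[ECNumber]
    substrates: list[str]
    organism: str
    mw_kda: float = 1.0

    def __post_init__(self) -> None:
        self.substrates = [s.lower() for s in self.substrates]
        if not any(ec.complete for ec in self.ecs):
            raise ValueError("query needs at least one complete EC number")


@dataclass
class MatchRecord:
    kcat_s: float
    wildcards: int
    priority_class: str
    source: str  # kcat | SA
    donor_organism: str
    distance: float  # edges, or inf
    fallback: bool = False

    def key(self) -> tuple:
        return (self.wildcards, self.priority_class, self.source, self.fallback)


def sa_to_kcat(sa: float, mw_kda: float) -> float:
    """Specific activity (µmol·min⁻¹·mg⁻¹) to turnover number (s⁻¹).

    µmol·min⁻¹·mg⁻¹ × kDa(g/mmol) = mmol·min⁻¹·mmol⁻¹ → divide by 60 for s⁻¹.
    """
    if not mw_kda > 0:
        raise ValueError("molecular weight must be positive")
    if sa < 0:
        raise ValueError("specific activity cannot be negative")
    return sa * mw_kda / 60.0


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------


def parse_catalog(path: str | Path) -> KineticCatalog:
    """Read a kinetic catalog TSV; mutant rows are dropped and counted."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"ec_number", "organism", "substrate", "value", "parameter_type", "mutant"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog {path} lacks columns {sorted(missing)}")
    entries: list[KineticEntry] = []
    mutants = 0
    for _, row in df.iterrows():
        if str(row["mutant"]).strip() in ("1", "true", "True"):
            mutants += 1
            continue
        entries.append(
            KineticEntry(
                ec=ECNumber.parse(row["ec_number"]),
                organism=row["organism"].strip(),
                substrate=row["substrate"].strip().lower(),
                value=float(row["value"]),
                ptype=row["parameter_type"].strip(),
            )
        )
    return KineticCatalog(entries=entries, mutant_count=mutants)


def parse_taxonomy(path: str | Path) -> Taxonomy:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("organism", "lineage"):
        if col not in df.columns:
            raise ValueError(f"taxonomy {path} lacks column {col!r}")
    lineage = {
        row["organism"].strip(): [r.strip() for r in row["lineage"].split(";")]
        for _, row in df.iterrows()
    }
    return Taxonomy(lineage=lineage)


def parse_enzyme_table(path: str | Path) -> list[EnzymeInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "gene_ids", "ec_numbers", "mw_kda"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"enzyme table {path} lacks columns {sorted(missing)}")
    enzymes = []
    for _, row in df.iterrows():
        copies = 1
        if "subunit_copies" in df.columns and str(row.get("subunit_copies", "")).strip():
            copies = int(row["subunit_copies"])
        ecs = [
            ECNumber.parse(e)
            for e in str(row["ec_numbers"]).split(";")
            if e.strip()
        ]
        enzymes.append(
            EnzymeInfo(
                protein_id=row["protein_id"].strip(),
                gene_ids=[g.strip() for g in row["gene_ids"].split(";") if g.strip()],
                ecs=ecs,
                mw_kda=float(row["mw_kda"]),
                subunit_copies=copies,
            )
        )
    return enzymes


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def _class_filter(
    entries: list[KineticEntry],
    cls: str,
    query: KcatQuery,
    tax: Taxonomy,
) -> tuple[list[KineticEntry], float]:
    """Apply one priority class; returns (candidates, donor distance)."""
    subs = set(query.substrates)
    if cls == "org_substrate":
        cand = [
            e for e in entries if e.organism == query.organism and e.substrate in subs
        ]
        return cand, 0.0
    if cls == "org_any":
        cand = [e for e in entries if e.organism == query.organism]
        return cand, 0.0
    if cls == "any_substrate":
        cand = [e for e in entries if e.substrate in subs]
    elif cls == "any_any":
        cand = list(entries)
    else:  # pragma: no cover - guarded by PRIORITY_CLASSES
        raise ValueError(cls)
    if not cand:
        return [], math.inf
    # closest donors only: organisms at minimal lineage distance to the query
    dists = {e.organism: lineage_distance(query.organism, e.organism, tax) for e in cand}
    dmin = min(dists.values())
    return [e for e in cand if dists[e.organism] == dmin], dmin


def match_kcat(
    query: KcatQuery,
    catalog: KineticCatalog,
    tax: Taxonomy,
    allow_fallback: bool = True,
) -> MatchRecord:
    """Hierarchical kcat assignment over the (source × wildcards × class) lattice.

    The lattice is scanned source-major (kcat before SA), then by wildcard
    level 0..3, then by priority class; the first non-empty cell wins and the
    maximum value inside it is returned.  Queries matching nothing anywhere
    fall back to the catalog-wide median kcat (flagged).
    """
    complete = [ec for ec in query.ecs if ec.complete]
    levels = [wildcard_levels(ec) for ec in complete]
    for source in ("kcat", "SA"):
        for w in range(4):
            pool: list[KineticEntry] = []
            seen: set[int] = set()
            for lv in levels:
                for e in catalog.query(lv[w]):
                    if id(e) not in seen and e.ptype == source:
                        seen.add(id(e))
                        pool.append(e)
            if not pool:
                continue
            for cls in PRIORITY_CLASSES:
                cand, dist = _class_filter(pool, cls, query, tax)
                if not cand:
                    continue
                best = max(
                    cand,
                    key=lambda e: (
                        e.value if e.ptype == "kcat" else sa_to_kcat(e.value, query.mw_kda)
                    ),
                )
                kcat = (
                    best.value
                    if best.ptype == "kcat"
                    else sa_to_kcat(best.value, query.mw_kda)
                )
                return MatchRecord(
                    kcat_s=kcat,
                    wildcards=w,
                    priority_class=cls,
                    source=source,
                    donor_organism=best.organism,
                    distance=lineage_distance(query.organism, best.organism, tax)
                    if cls.startswith("any")
                    else 0.0,
                    fallback=False,
                )
    if not allow_fallback:
        raise LookupError(
            f"no kinetic entry matches ECs {[str(e) for e in query.ecs]} and fallback disabled"
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


def summarize_matches(records: Sequence[MatchRecord]) -> pd.DataFrame:
    """Count assignments per (wildcards, priority_class, source, fallback)."""
    if not records:
        return pd.DataFrame(
            columns=["wildcards", "priority_class", "source", "fallback", "count"]
        )
    df = pd.DataFrame(
        {
            "wildcards": [r.wildcards for r in records],
            "priority_class": [r.priority_class for r in records],
            "source": [r.source for r in records],
            "fallback": [r.fallback for r in records],
        }
    )
    out = (
        df.groupby(["wildcards", "priority_class", "source", "fallback"])
        .size()
        .reset_index(name="count")
        .sort_values(["wildcards", "priority_class", "source", "fallback"])
        .reset_index(drop=True)
    )
    return out
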