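"""Curated registry of characterized flavonoid-modifying enzyme queries.

The registry couples each query protein (beta-glucosidases, rhamnosidases,
C-deglycosylation subunits, the daidzein-to-equol reductases, Flr/Fcr/CHI/Phy
and the O-demethylase components) with its pathway group, its role label
within a multi-gene cluster, and the e-value regime used when searching a
large protein catalog.  E-value stratification follows pathway group rather
than per-sequence length: pathways dominated by long sequences (>350 aa,
O-glycosidases, rhamnosidases, Fcr) use 1e-60, short-sequence pathways
(150-350 aa) use 1e-25, and the C-deglycosylation clusters, which include
members below 150 aa, use 1e-20.

Multi-gene pathway requirements are expressed as :class:`PathwayRule` objects:
the dgpABC cluster requires all three catalytic subunits, dfgABCDE requires at
least three of five, daidzein-to-equol requires all of dzr/ddr/tdr with the
dihydrodaidzein racemase optional, and the O-demethylase operon requires
MT1/MT2/CP/AE each above 40 percent identity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

_DATA_DIR = Path(__file__).parent / "data"

#: Default manifest and synthetic stand-in query sequences shipped in-package.
DEFAULT_MANIFEST = _DATA_DIR / "query_manifest.tsv"
DEFAULT_QUERY_FASTA = _DATA_DIR / "query_sequences_synthetic.faa"

#: e-value regime per class: long (>350 aa pathways), short (150-350 aa
#: pathways), c_degly (C-deglycosylation clusters with members <150 aa).
EVALUE_BY_CLASS = {"long": 1e-60, "short": 1e-25, "c_degly": 1e-20}

#: Pathway group -> e-value class.  Fcr sequences are >350 aa and therefore
#: sit in the long regime together with O-glycosidases and rhamnosidases.
CLASS_BY_PATHWAY = {
    "o_deglycosylation": "long",
    "derhamnosylation": "long",
    "fcr": "long",
    "daidzein_equol": "short",
    "chi": "short",
    "o_demethylation": "short",
    "phy": "short",
    "flr": "short",
    "dfgCD": "short",
    "c_deglycosylation_dfg": "c_degly",
    "c_deglycosylation_dgp": "c_degly",
}

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


class RegistryError(ValueError):
    """Raised for malformed manifests or inconsistent registry content."""


@dataclass(frozen=True)
class EnzymeQuery:
    """One curated query protein."""

    query_id: str
    accession: str
    enzyme_name: str
    pathway_id: str
    role: str
    sequence: str
    evalue_class: str
    canonical: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if self.evalue_class not in EVALUE_BY_CLASS:
            raise RegistryError(
                f"unknown e-value class {self.evalue_class!r} for {self.query_id}"
            )
        expected = CLASS_BY_PATHWAY.get(self.pathway_id)
        if expected is not None and expected != self.evalue_class:
            raise RegistryError(
                f"{self.query_id}: e-value class {self.evalue_class!r} inconsistent "
                f"with pathway {self.pathway_id!r} (expected {expected!r})"
            )
        bad = set(self.sequence) - VALID_AA
        if bad:
            raise RegistryError(
                f"{self.query_id}: invalid residues {sorted(bad)} in sequence"
            )


@dataclass(frozen=True)
class Requirement:
    """Pathway requirement: ALL roles, AT_LEAST_K roles, or ANY role."""

    kind: str  # "ALL" | "AT_LEAST_K" | "ANY"
    k: int = 0

    def satisfied(self, n_found: int, n_roles: int) -> bool:
        if self.kind == "ALL":
            return n_found == n_roles
        if self.kind == "AT_LEAST_K":
            return n_found >= self.k
        if self.kind == "ANY":
            return n_found >= 1
        raise RegistryError(f"unknown requirement kind {self.kind!r}")


ALL = Requirement("ALL")
ANY = Requirement("ANY")


def AT_LEAST_K(k: int) -> Requirement:
    return Requirement("AT_LEAST_K", k)


@dataclass(frozen=True)
class PathwayRule:
    """Declarative multi-gene requirement for one pathway."""

    pathway_id: str
    member_roles: tuple[str, ...]
    requirement: Requirement
    optional_roles: tuple[str, ...] = ()
    min_pid_override: float | None = None

    def __post_init__(self) -> None:
        if self.requirement.kind == "AT_LEAST_K" and self.requirement.k > len(
            self.member_roles
        ):
            raise RegistryError(
                f"{self.pathway_id}: k={self.requirement.k} exceeds "
                f"{len(self.member_roles)} member roles"
            )
        if set(self.optional_roles) & set(self.member_roles):
            raise RegistryError(
                f"{self.pathway_id}: optional roles overlap member roles"
            )

    @property
    def is_multigene(self) -> bool:
        return len(self.member_roles) > 1 and self.requirement.kind != "ANY"


#: Roles never required for the pathway call (dihydrodaidzein racemase).
_OPTIONAL_ROLES = {"daidzein_equol": ("dhd_racemase",)}

#: PID floor applied per occurrence when evaluating the rule (PID > floor).
_MIN_PID_OVERRIDE = {"o_demethylation": 40.0}


def _build_rule(pathway_id: str, roles: Iterable[str]) -> PathwayRule:
    optional = _OPTIONAL_ROLES.get(pathway_id, ())
    members = tuple(sorted(set(roles) - set(optional)))
    if pathway_id == "c_deglycosylation_dgp":
        req = ALL
    elif pathway_id == "c_deglycosylation_dfg":
        req = AT_LEAST_K(3)
    elif pathway_id == "daidzein_equol":
        req = ALL
    elif pathway_id == "o_demethylation":
        req = ALL
    else:
        req = ANY
    return PathwayRule(
        pathway_id=pathway_id,
        member_roles=members,
        requirement=req,
        optional_roles=optional,
        min_pid_override=_MIN_PID_OVERRIDE.get(pathway_id),
    )


@dataclass
class QueryRegistry:
    """Immutable collection of queries plus one rule per pathway."""

    queries: list[EnzymeQuery]
    rules: dict[str, PathwayRule] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [q.query_id for q in self.queries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise RegistryError(f"duplicate query_id(s): {sorted(dupes)}")
        self._by_id = {q.query_id: q for q in self.queries}
        if not self.rules:
            roles_by_pathway: dict[str, set[str]] = {}
            for q in self.queries:
                roles_by_pathway.setdefault(q.pathway_id, set()).add(q.role)
            self.rules = {
                p: _build_rule(p, roles) for p, roles in sorted(roles_by_pathway.items())
            }

    def __len__(self) -> int:
        return len(self.queries)

    def __contains__(self, query_id: str) -> bool:
        return query_id in self._by_id

    def __getitem__(self, query_id: str) -> EnzymeQuery:
        return self._by_id[query_id]

    def get(self, query_id: str) -> EnzymeQuery | None:
        return self._by_id.get(query_id)

    def canonical_queries(self) -> list[EnzymeQuery]:
        """Queries used in default searches (non-canonical homolog sets of the
        daidzein cluster are excluded, mirroring the use of a single canonical
        sequence set per role)."""
        return [q for q in self.queries if q.canonical]

    def role_of(self, query_id: str) -> str:
        return self._by_id[query_id].role

    def pathway_of(self, query_id: str) -> str:
        return self._by_id[query_id].pathway_id

    def multigene_rules(self) -> list[PathwayRule]:
        return [r for r in self.rules.values() if r.is_multigene]


def evalue_threshold_for(query: EnzymeQuery) -> float:
    """e-value cutoff for a query: 1e-60 (long), 1e-25 (short), 1e-20 (c_degly)."""
    try:
        return EVALUE_BY_CLASS[query.evalue_class]
    except KeyError:
        raise RegistryError(f"unknown e-value class {query.evalue_class!r}") from None


_MANIFEST_COLUMNS = [
    "accession",
    "query_id",
    "enzyme_name",
    "pathway_id",
    "role",
    "evalue_class",
    "canonical",
]


def load_registry(
    query_fasta: str | Path = DEFAULT_QUERY_FASTA,
    manifest: str | Path = DEFAULT_MANIFEST,
) -> QueryRegistry:
    """Load the query registry from a manifest TSV and a query FASTA.

    The manifest has columns accession, query_id, enzyme_name, pathway_id,
    role, evalue_class, canonical; the FASTA header's first token is the
    accession.  Every manifest row must resolve to exactly one FASTA record.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(query_fasta), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    queries: list[EnzymeQuery] = []
    with open(manifest, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing_cols = set(_MANIFEST_COLUMNS) - set(reader.fieldnames or [])
        if missing_cols:
            raise RegistryError(f"manifest missing columns: {sorted(missing_cols)}")
        for row in reader:
            acc = row["accession"]
            if acc not in seqs:
                raise RegistryError(
                    f"manifest row {row['query_id']}: no FASTA record for "
                    f"accession {acc}"
                )
            queries.append(
                EnzymeQuery(
                    query_id=row["query_id"],
                    accession=acc,
                    enzyme_name=row["enzyme_name"],
                    pathway_id=row["pathway_id"],
                    role=row["role"],
                    sequence=seqs[acc],
                    evalue_class=row["evalue_class"],
                    canonical=row["canonical"].strip() in {"1", "true", "True"},
                )
            )
    return QueryRegistry(queries)
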