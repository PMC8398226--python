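"""Per-genome evaluation of multi-gene pathway rules and carrier statistics.

A genome "has" a role when at least one retained occurrence maps to it
(copy number is irrelevant for the call).  Rules with a PID floor
(O-demethylase operon: PID strictly above 40) only count occurrences passing
the floor.  Carrier statistics relate the genomes satisfying a rule to all
MAGs of the species in the metadata, including genomes with zero hits —
that denominator is what makes carrier fractions meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .registry import PathwayRule
from .taxonomy import parse_lineage


@dataclass(frozen=True)
class PathwayCall:
    """Rule evaluation for one genome and one multi-gene pathway."""

    genome_id: str
    pathway_id: str
    present: bool
    roles_found: frozenset[str]
    roles_missing: frozenset[str]
    min_pid_among_roles: float

    def __post_init__(self) -> None:
        if self.roles_found & self.roles_missing:
            raise ValueError("roles_found and roles_missing overlap")


@dataclass(frozen=True)
class SpeciesCarrierStat:
    species_name: str
    pathway_id: str
    n_carriers: int
    n_total: int

    @property
    def carrier_fraction(self) -> float:
        """Percent of the species' MAGs satisfying the pathway rule."""
        return 100.0 * self.n_carriers / self.n_total if self.n_total else 0.0


def evaluate_rule(rule: PathwayRule, roles_with_pids: Mapping[str, float]) -> PathwayCall | None:
    """Evaluate one rule against a genome's role -> best-PID mapping.

    Returns None when no member or optional role of the rule is present.
    Occurrence PIDs must already be the per-role maxima.
    """
    floor = rule.min_pid_override
    qualifying = {
        role: pid
        for role, pid in roles_with_pids.items()
        if floor is None or pid > floor
    }
    members_found = frozenset(r for r in rule.member_roles if r in qualifying)
    optional_found = frozenset(r for r in rule.optional_roles if r in qualifying)
    if not members_found and not optional_found:
        return None
    present = rule.requirement.satisfied(len(members_found), len(rule.member_roles))
    found = members_found | optional_found
    min_pid = min(qualifying[r] for r in found) if found else 0.0
    return PathwayCall(
        genome_id="",
        pathway_id=rule.pathway_id,
        present=present,
        roles_found=found,
        roles_missing=frozenset(rule.member_roles) - members_found,
        min_pid_among_roles=min_pid,
    )


def call_pathways(
    occurrences: pd.DataFrame,
    rules: Mapping[str, PathwayRule] | Iterable[PathwayRule],
) -> list[PathwayCall]:
    """One :class:`PathwayCall` per (genome, multi-gene pathway) with at least
    one role hit."""
    if not isinstance(rules, Mapping):
        rules = {r.pathway_id: r for r in rules}
    unknown = set(occurrences["pathway_id"]) - set(rules) if len(occurrences) else set()
    if unknown:
        raise KeyError(f"occurrences reference pathways without a rule: {sorted(unknown)}")
    calls: list[PathwayCall] = []
    if occurrences.empty:
        return calls
    for (genome_id, pathway_id), group in occurrences.groupby(
        ["genome_id", "pathway_id"], sort=True
    ):
        rule = rules[pathway_id]
        if not rule.is_multigene:
            continue
        best_pid = group.groupby("role")["pid"].max().to_dict()
        call = evaluate_rule(rule, best_pid)
        if call is not None:
            calls.append(
                PathwayCall(
                    genome_id=genome_id,
                    pathway_id=call.pathway_id,
                    present=call.present,
                    roles_found=call.roles_found,
                    roles_missing=call.roles_missing,
                    min_pid_among_roles=call.min_pid_among_roles,
                )
            )
    return calls


def _species_of_mags(metadata: pd.DataFrame) -> pd.DataFrame:
    mags = metadata[metadata["Genome_type"] == "MAG"].copy()
    labels = {lin: parse_lineage(lin).species_label() for lin in mags["Lineage"].unique()}
    mags["species_name"] = mags["Lineage"].map(labels)
    return mags


def species_carrier_stats(
    calls: Iterable[PathwayCall],
    metadata: pd.DataFrame | str | Path,
) -> list[SpeciesCarrierStat]:
    """Per (species, pathway) carrier counts over all MAGs of the species."""
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata, sep="\t")
    mags = _species_of_mags(metadata)
    species_of = mags.set_index("Genome")["species_name"].to_dict()
    totals = mags.groupby("species_name").size().to_dict()
    carriers: dict[tuple[str, str], int] = {}
    seen: set[tuple[str, str]] = set()
    for call in calls:
        species = species_of.get(call.genome_id)
        if species is None:
            continue  # isolate genome or genome outside metadata scope
        key = (species, call.pathway_id)
        seen.add(key)
        if call.present:
            carriers[key] = carriers.get(key, 0) + 1
    return [
        SpeciesCarrierStat(
            species_name=sp,
            pathway_id=pw,
            n_carriers=carriers.get((sp, pw), 0),
            n_total=int(totals.get(sp, 0)),
        )
        for sp, pw in sorted(seen)
    ]


def single_gene_report(
    occurrences: pd.DataFrame,
    pathway_id: str,
    rule: PathwayRule,
) -> pd.DataFrame:
    """Per-species counts of genomes carrying only a strict subset of a
    multi-gene pathway's roles, keyed by the exact role-subset signature
    (e.g. ``{dzr}`` for genomes with daidzein reductase only)."""
    if len(rule.member_roles) < 2:
        raise ValueError(f"pathway {pathway_id!r} has fewer than 2 roles")
    sub = occurrences[occurrences["pathway_id"] == pathway_id]
    rows = []
    full = set(rule.member_roles)
    for (species, genome_id), group in sub.groupby(["species_name", "genome_id"], sort=True):
        roles = set(group["role"]) & full
        if not roles or roles == full:
            continue
        rows.append({"species": species, "signature": "{" + ",".join(sorted(roles)) + "}"})
    if not rows:
        return pd.DataFrame(columns=["species", "signature", "n_genomes"])
    frame = pd.DataFrame(rows)
    return (
        frame.groupby(["species", "signature"], sort=True)
        .size()
        .reset_index(name="n_genomes")
    )


def calls_frame(calls: Iterable[PathwayCall]) -> pd.DataFrame:
    """Tabular view of pathway calls (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "genome_id": c.genome_id,
                "pathway_id": c.pathway_id,
                "present": c.present,
                "roles_found": ",".join(sorted(c.roles_found)),
                "roles_missing": ",".join(sorted(c.roles_missing)),
                "min_pid_among_roles": round(c.min_pid_among_roles, 3),
            }
            for c in calls
        ],
        columns=[
            "genome_id",
            "pathway_id",
            "present",
            "roles_found",
            "roles_missing",
            "min_pid_among_roles",
        ],
    )


def carrier_frame(stats: Iterable[SpeciesCarrierStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": s.species_name,
                "pathway_id": s.pathway_id,
                "n_carriers": s.n_carriers,
                "n_total": s.n_total,
                "carrier_fraction_pct": round(s.carrier_fraction, 4),
            }
            for s in stats
        ],
        columns=["species", "pathway_id", "n_carriers", "n_total", "carrier_fraction_pct"],
    )
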