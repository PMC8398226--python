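"""GTDB lineage parsing and species prevalence/abundance statistics.

Prevalence of a species is the percentage of distinct metagenome samples
(equated with individuals) that contain at least one MAG of that species;
abundance is the percentage of all MAGs assigned to it.  Matching against the
metadata lineage column is exact and case-sensitive on the GTDB species
binomial; species that do not exist in the taxonomy are reported with zero
prevalence and flagged ``not_in_taxonomy``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
_FIELDS = ("domain", "phylum", "class_", "order", "family", "genus", "species")

DEFAULT_CURATED_SPECIES = Path(__file__).parent / "data" / "curated_species.tsv"


class LineageError(ValueError):
    """Raised for strings that are not rank-prefixed GTDB lineages."""


@dataclass(frozen=True)
class LineageRecord:
    domain: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def species_label(self) -> str:
        """Species binomial, or the genus suffixed "(unclassified)" when the
        species rank is empty (empty string if both are missing)."""
        if self.species:
            return self.species
        if self.genus:
            return f"{self.genus} (unclassified)"
        return ""


def parse_lineage(lineage: str) -> LineageRecord:
    """Parse a semicolon-separated, rank-prefixed GTDB lineage string."""
    parts = lineage.split(";")
    if not parts or not parts[0].startswith("d__"):
        raise LineageError(f"lineage lacks the d__ prefix: {lineage!r}")
    values = {}
    for part, prefix, fieldname in zip(parts, _PREFIXES, _FIELDS):
        part = part.strip()
        if not part.startswith(prefix):
            raise LineageError(f"rank {fieldname} lacks prefix {prefix}: {lineage!r}")
        values[fieldname] = part[len(prefix):]
    return LineageRecord(**{f: values.get(f, "") for f in _FIELDS})


@dataclass(frozen=True)
class CuratedSpecies:
    """One curated flavonoid-modifying species with its modification classes."""

    species_name: str
    modification_classes: tuple[str, ...]
    flavonoid_classes: str = ""
    note: str = ""


@dataclass(frozen=True)
class PrevalenceRecord:
    species_name: str
    n_samples_with: int
    n_samples_total: int
    n_mags: int
    n_mags_total: int
    flags: str = ""

    @property
    def prevalence_pct(self) -> float:
        return 100.0 * self.n_samples_with / self.n_samples_total

    @property
    def abundance_pct(self) -> float:
        return 100.0 * self.n_mags / self.n_mags_total


def load_curated_species(
    fixture: str | Path = DEFAULT_CURATED_SPECIES,
) -> list[CuratedSpecies]:
    """Load the curated species list; a species appearing under several
    modification classes is merged into one entry carrying all classes."""
    merged: dict[str, dict] = {}
    with open(fixture, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            name = row["species"].strip()
            if not name:
                continue
            entry = merged.setdefault(
                name,
                {"classes": [], "flavonoids": row.get("flavonoid_classes", ""),
                 "note": row.get("note", "") or ""},
            )
            cls = row["modification_class"].strip()
            if cls not in entry["classes"]:
                entry["classes"].append(cls)
    return [
        CuratedSpecies(
            species_name=name,
            modification_classes=tuple(e["classes"]),
            flavonoid_classes=e["flavonoids"],
            note=e["note"],
        )
        for name, e in merged.items()
    ]


def compute_prevalence(
    metadata: pd.DataFrame | str | Path,
    species_list: Sequence[str],
    dedup_samples: bool = True,
) -> list[PrevalenceRecord]:
    """Prevalence (% of samples) and abundance (% of MAGs) per species.

    ``dedup_samples`` counts a sample once however many MAGs of the species
    it contains (presence-based prevalence, the default convention).
    """
    if not len(species_list):
        raise ValueError("species_list must be non-empty")
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata, sep="\t")
    n_samples_total = metadata["Sample_accession"].nunique()
    mags = metadata[metadata["Genome_type"] == "MAG"].copy()
    n_mags_total = len(mags)
    mags["species"] = [
        parse_lineage(lin).species_label() for lin in mags["Lineage"]
    ]
    records = []
    for name in species_list:
        rows = mags[mags["species"] == name]
        if rows.empty:
            records.append(
                PrevalenceRecord(name, 0, n_samples_total, 0, n_mags_total,
                                 flags="not_in_taxonomy")
            )
            continue
        if dedup_samples:
            n_with = rows["Sample_accession"].nunique()
        else:
            n_with = len(rows)
        records.append(
            PrevalenceRecord(name, int(n_with), n_samples_total, len(rows), n_mags_total)
        )
    return records


def prevalence_frame(records: Iterable[PrevalenceRecord]) -> pd.DataFrame:
    """Tabular view of prevalence records (TSV-ready)."""
    columns = [
        "species",
        "prevalence_pct",
        "abundance_pct",
        "n_samples_with",
        "n_samples_total",
        "n_mags",
        "n_mags_total",
        "flags",
    ]
    return pd.DataFrame(
        [
            {
                "species": r.species_name,
                "prevalence_pct": round(r.prevalence_pct, 4),
                "abundance_pct": round(r.abundance_pct, 4),
                "n_samples_with": r.n_samples_with,
                "n_samples_total": r.n_samples_total,
                "n_mags": r.n_mags,
                "n_mags_total": r.n_mags_total,
                "flags": r.flags,
            }
            for r in records
        ],
        columns=columns,
    )
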