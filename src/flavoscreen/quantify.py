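"""Redundancy expansion, metadata attachment and occurrence counting.

A deduplicated hit names one non-redundant representative protein; every
redundant member of that representative in the membership table becomes one
gene occurrence, inheriting the representative's identity, coverage and
bitscore.  Occurrences are joined with genome metadata (the genome id is the
prefix of the member protein id), isolate genomes are discarded by default,
and occurrences are counted per species, query and percent-identity bin —
the occurrence count is the "Freq" of a species/query/bin group.

Occurrence tables are plain pandas DataFrames with the columns in
``OCCURRENCE_COLUMNS``; summary tables use ``SUMMARY_COLUMNS``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .align import AlignmentHit
from .filtering import DEFAULT_BIN_EDGES, pid_bin
from .registry import QueryRegistry
from .taxonomy import parse_lineage

OCCURRENCE_COLUMNS = [
    "member_protein_id",
    "representative_id",
    "genome_id",
    "query_id",
    "pathway_id",
    "role",
    "pid",
    "qcov",
    "bitscore",
]

ANNOTATED_COLUMNS = OCCURRENCE_COLUMNS + [
    "sample_accession",
    "genome_type",
    "species_name",
]

SUMMARY_COLUMNS = ["species", "query_id", "pid_bin", "freq", "n_genomes_with_hit"]


def genome_of_protein(protein_id: str) -> str:
    """Genome id encoded as the protein id's prefix (``<genome>_<index>``)."""
    genome, _, index = protein_id.rpartition("_")
    if not genome or not index:
        raise ValueError(f"protein id {protein_id!r} does not encode a genome id")
    return genome


def read_membership(path: str | Path) -> pd.DataFrame:
    """Read a membership TSV (member, representative; extra columns ignored,
    no header)."""
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1],
        names=["member_id", "representative_id"],
        dtype=str,
    )


def expand_members(
    hits: Iterable[AlignmentHit],
    membership: pd.DataFrame | str | Path,
    registry: QueryRegistry,
) -> pd.DataFrame:
    """One occurrence row per redundant member of each hit representative.

    Every hit target must appear as a representative in the membership table;
    absent representatives raise an error listing the missing ids.
    """
    if not isinstance(membership, pd.DataFrame):
        membership = read_membership(membership)
    hits = list(hits)
    hit_frame = pd.DataFrame(
        [
            {
                "representative_id": h.target_id,
                "query_id": h.query_id,
                "pathway_id": registry.pathway_of(h.query_id),
                "role": registry.role_of(h.query_id),
                "pid": h.pid,
                "qcov": h.qcov,
                "bitscore": h.bitscore,
            }
            for h in hits
        ],
        columns=["representative_id", "query_id", "pathway_id", "role", "pid", "qcov", "bitscore"],
    )
    known = set(membership["representative_id"])
    missing = sorted(set(hit_frame["representative_id"]) - known)
    if missing:
        raise KeyError(f"representatives absent from membership table: {missing}")
    merged = membership.merge(hit_frame, on="representative_id", how="inner")
    merged = merged.rename(columns={"member_id": "member_protein_id"})
    merged["genome_id"] = merged["member_protein_id"].map(genome_of_protein)
    return merged[OCCURRENCE_COLUMNS].reset_index(drop=True)


def attach_metadata(
    occurrences: pd.DataFrame,
    metadata: pd.DataFrame | str | Path,
    mags_only: bool = True,
) -> pd.DataFrame:
    """Join genome metadata onto occurrences; drop non-MAG genomes by default.

    Adds sample accession, genome type and the species label parsed from the
    GTDB lineage (genus suffixed "(unclassified)" when the species rank is
    empty).
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata, sep="\t")
    meta = metadata.rename(
        columns={
            "Genome": "genome_id",
            "Genome_type": "genome_type",
            "Sample_accession": "sample_accession",
            "Lineage": "lineage",
        }
    )[["genome_id", "genome_type", "sample_accession", "lineage"]]
    missing = sorted(set(occurrences["genome_id"]) - set(meta["genome_id"]))
    if missing:
        raise KeyError(f"genomes absent from metadata: {missing}")
    species_by_lineage = {
        lin: parse_lineage(lin).species_label() for lin in meta["lineage"].unique()
    }
    meta["species_name"] = meta["lineage"].map(species_by_lineage)
    out = occurrences.merge(meta.drop(columns="lineage"), on="genome_id", how="left")
    if mags_only:
        out = out[out["genome_type"] == "MAG"]
    return out[ANNOTATED_COLUMNS].reset_index(drop=True)


def summarize(
    occurrences: pd.DataFrame,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    min_freq: int = 0,
) -> pd.DataFrame:
    """Occurrence counts per (species, query, PID bin).

    ``freq`` counts member proteins (a two-copy genome contributes 2);
    ``n_genomes_with_hit`` counts distinct genomes.  Groups below ``min_freq``
    are dropped; rows are sorted by descending freq, then group keys.
    """
    if occurrences.empty:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    work = occurrences.copy()
    work["pid_bin"] = [pid_bin(p, bin_edges) for p in work["pid"]]
    grouped = (
        work.groupby(["species_name", "query_id", "pid_bin"], sort=True)
        .agg(freq=("member_protein_id", "size"), n_genomes_with_hit=("genome_id", "nunique"))
        .reset_index()
        .rename(columns={"species_name": "species"})
    )
    grouped = grouped[grouped["freq"] >= min_freq]
    grouped = grouped.sort_values(
        by=["freq", "species", "query_id", "pid_bin"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return grouped[SUMMARY_COLUMNS]
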