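"""Synthetic protein-catalog generator with implanted enzyme homologs.

Emulates the layout of a UHGP-style catalog: a FASTA of non-redundant
representative proteins, a membership TSV mapping every redundant protein to
its representative (each representative maps to itself), and a genome
metadata TSV (genome id, MAG/Isolate, sample accession, GTDB lineage).
Homologs of registry queries are implanted at controlled percent identity,
carrier fraction, copy number, and per-genome role completeness, and every
implanted protein is recorded in a machine-readable truth table so pipeline
recovery can be checked exactly.

Background proteins are random sequences over the 20-residue alphabet at
lengths 100-600; their expected identity to any query is far below the
search thresholds, giving a near-zero false-positive floor.  Implanted
members of one role/species/target-identity combination share a single
mutated sequence and therefore form one redundancy cluster, which exercises
the membership-expansion stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import QueryRegistry, load_registry

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

METADATA_COLUMNS = [
    "Genome",
    "Genome_type",
    "Sample_accession",
    "Lineage",
    "Completeness",
    "Contamination",
]

TRUTH_COLUMNS = [
    "genome_id",
    "sample_id",
    "species_name",
    "genome_type",
    "pathway_id",
    "role",
    "query_id",
    "implanted_pid_realized",
    "protein_id",
    "representative_id",
]


class SimulationError(ValueError):
    """Raised for inconsistent species/implant specifications."""


def make_lineage(species_name: str, phylum: str = "Bacillota") -> str:
    """Build a plausible 7-rank GTDB lineage string for a binomial name."""
    genus = species_name.split()[0]
    return (
        f"d__Bacteria;p__{phylum};c__Clostridia;o__Lachnospirales;"
        f"f__Lachnospiraceae;g__{genus};s__{species_name}"
    )


@dataclass(frozen=True)
class SpeciesProfile:
    """A species' genome collection in the synthetic catalog."""

    species_name: str
    n_genomes: int
    lineage: str = ""
    genome_type_fraction_mag: float = 1.0
    genomes_per_sample: int = 1  # >1 places several genomes in one sample

    def __post_init__(self) -> None:
        if not self.lineage:
            object.__setattr__(self, "lineage", make_lineage(self.species_name))
        ranks = self.lineage.split(";")
        if len(ranks) != 7 or any(
            not r.startswith(p) for r, p in zip(ranks, _RANK_PREFIXES)
        ):
            raise SimulationError(f"malformed lineage: {self.lineage!r}")
        if self.n_genomes < 0:
            raise SimulationError("n_genomes must be >= 0")
        if not 0.0 <= self.genome_type_fraction_mag <= 1.0:
            raise SimulationError("genome_type_fraction_mag must be in [0, 1]")
        if self.genomes_per_sample < 1:
            raise SimulationError("genomes_per_sample must be >= 1")


@dataclass(frozen=True)
class ImplantSpec:
    """Implant homologs of one pathway's roles into one species."""

    species_name: str
    pathway_id: str
    roles_to_implant: tuple[str, ...]
    target_pid: float
    carrier_fraction: float
    copies_per_genome: int = 1
    role_completeness: float = 1.0  # per-carrier Bernoulli keep prob per role

    def __post_init__(self) -> None:
        if not self.roles_to_implant:
            raise SimulationError("roles_to_implant must be non-empty")
        if not 0.0 < self.target_pid <= 100.0:
            raise SimulationError("target_pid must be in (0, 100]")
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise SimulationError("carrier_fraction must be in [0, 1]")
        if self.copies_per_genome < 1:
            raise SimulationError("copies_per_genome must be >= 1")
        if not 0.0 < self.role_completeness <= 1.0:
            raise SimulationError("role_completeness must be in (0, 1]")


@dataclass
class Catalog:
    """In-memory catalog bundle plus ground truth."""

    representatives: list[tuple[str, str]]  # (protein_id, sequence)
    membership: pd.DataFrame  # columns: member_id, representative_id
    metadata: pd.DataFrame  # METADATA_COLUMNS
    truth: pd.DataFrame  # TRUTH_COLUMNS

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "catalog-100.faa",
            "membership": outdir / "catalog-100.tsv",
            "metadata": outdir / "genomes-metadata.tsv",
            "truth": outdir / "truth.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for pid, seq in self.representatives:
                fh.write(f">{pid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        self.membership.to_csv(paths["membership"], sep="\t", index=False, header=False)
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths

    @classmethod
    def read(cls, outdir: str | Path) -> "Catalog":
        from Bio import SeqIO

        outdir = Path(outdir)
        reps = [
            (rec.id, str(rec.seq))
            for rec in SeqIO.parse(str(outdir / "catalog-100.faa"), "fasta")
        ]
        membership = pd.read_csv(
            outdir / "catalog-100.tsv",
            sep="\t",
            header=None,
            names=["member_id", "representative_id"],
            usecols=[0, 1],
        )
        metadata = pd.read_csv(outdir / "genomes-metadata.tsv", sep="\t")
        truth_path = outdir / "truth.tsv"
        if truth_path.exists():
            truth = pd.read_csv(truth_path, sep="\t")
            if truth.empty:
                truth = pd.DataFrame(columns=TRUTH_COLUMNS)
        else:
            truth = pd.DataFrame(columns=TRUTH_COLUMNS)
        return cls(reps, membership, metadata, truth)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA20, size=length))


def mutate_to_identity(sequence: str, target_pid: float, seed: int) -> str:
    """Substitute residues to reach the nearest achievable percent identity.

    Positions are chosen without replacement; each substitution draws from the
    19 residues different from the original.  Deterministic for fixed inputs.
    """
    if not 0.0 < target_pid <= 100.0:
        raise ValueError("target_pid must be in (0, 100]")
    if len(sequence) < 20:
        raise ValueError("sequence too short to mutate meaningfully")
    rng = np.random.default_rng(seed)
    n = len(sequence)
    n_mut = int(round(n * (1.0 - target_pid / 100.0)))
    positions = rng.choice(n, size=n_mut, replace=False)
    out = list(sequence)
    for pos in positions:
        choices = _AA20[_AA20 != out[pos]]
        out[pos] = str(rng.choice(choices))
    return "".join(out)


def realized_identity(original: str, mutated: str) -> float:
    """Positional percent identity between two equal-length sequences."""
    if len(original) != len(mutated):
        raise ValueError("sequences differ in length")
    same = sum(a == b for a, b in zip(original, mutated))
    return 100.0 * same / len(original)


def generate_catalog(
    profiles: list[SpeciesProfile],
    implants: list[ImplantSpec],
    n_samples: int,
    background_proteins_per_genome: int = 5,
    redundancy: float = 2.0,
    seed: int = 0,
    registry: QueryRegistry | None = None,
) -> Catalog:
    """Generate a catalog bundle with implanted homologs and ground truth."""
    if sum(p.n_genomes for p in profiles) < 1:
        raise SimulationError("need at least one genome across profiles")
    if n_samples < 1:
        raise SimulationError("n_samples must be >= 1")
    if redundancy < 1.0:
        raise SimulationError("redundancy (mean cluster size) must be >= 1")
    registry = registry or load_registry()
    by_name = {p.species_name: p for p in profiles}
    if len(by_name) != len(profiles):
        raise SimulationError("duplicate species profiles")
    rng = np.random.default_rng(seed)

    # --- genomes and metadata ------------------------------------------------
    samples = [f"SAMP{i + 1:06d}" for i in range(n_samples)]
    sample_cursor = 0
    genome_rows = []
    genomes_by_species: dict[str, list[str]] = {}
    counter = 0
    for profile in profiles:
        n_mag = int(round(profile.genome_type_fraction_mag * profile.n_genomes))
        types = ["MAG"] * n_mag + ["Isolate"] * (profile.n_genomes - n_mag)
        rng.shuffle(types)
        for k in range(profile.n_genomes):
            counter += 1
            gid = f"SYNG{counter:05d}"
            if k % profile.genomes_per_sample == 0:
                sample = samples[sample_cursor % n_samples]
                sample_cursor += 1
            genome_rows.append(
                {
                    "Genome": gid,
                    "Genome_type": types[k],
                    "Sample_accession": sample,
                    "Lineage": profile.lineage,
                    "Completeness": 95.0,
                    "Contamination": 1.0,
                }
            )
            genomes_by_species.setdefault(profile.species_name, []).append(gid)
    metadata = pd.DataFrame(genome_rows, columns=METADATA_COLUMNS)
    meta_by_genome = metadata.set_index("Genome")
    protein_index = {row["Genome"]: 0 for row in genome_rows}

    def next_protein_id(genome_id: str) -> str:
        protein_index[genome_id] += 1
        return f"{genome_id}_{protein_index[genome_id]:05d}"

    representatives: list[tuple[str, str]] = []
    membership_rows: list[tuple[str, str]] = []
    truth_rows: list[dict] = []

    # --- implants ------------------------------------------------------------
    canonical_by_role = {
        (q.pathway_id, q.role): q for q in registry.canonical_queries()
    }
    for spec in implants:
        if spec.species_name not in by_name:
            raise SimulationError(f"implant references unknown species {spec.species_name!r}")
        genomes = genomes_by_species.get(spec.species_name, [])
        n_carriers = int(round(spec.carrier_fraction * len(genomes)))
        carriers = list(rng.permutation(genomes)[:n_carriers])
        role_seqs: dict[str, tuple[str, float]] = {}
        for role in spec.roles_to_implant:
            query = canonical_by_role.get((spec.pathway_id, role))
            if query is None:
                raise SimulationError(
                    f"implant references unknown role {role!r} of pathway "
                    f"{spec.pathway_id!r}"
                )
            mut_seed = int(rng.integers(0, 2**31 - 1))
            mutated = mutate_to_identity(query.sequence, spec.target_pid, mut_seed)
            role_seqs[role] = (mutated, realized_identity(query.sequence, mutated))
        for role in spec.roles_to_implant:
            mutated, realized = role_seqs[role]
            query = canonical_by_role[(spec.pathway_id, role)]
            rep_id: str | None = None
            for gid in carriers:
                if spec.role_completeness < 1.0 and rng.random() >= spec.role_completeness:
                    continue
                for _copy in range(spec.copies_per_genome):
                    prot_id = next_protein_id(gid)
                    if rep_id is None:
                        rep_id = prot_id
                        representatives.append((rep_id, mutated))
                    membership_rows.append((prot_id, rep_id))
                    meta = meta_by_genome.loc[gid]
                    truth_rows.append(
                        {
                            "genome_id": gid,
                            "sample_id": meta["Sample_accession"],
                            "species_name": spec.species_name,
                            "genome_type": meta["Genome_type"],
                            "pathway_id": spec.pathway_id,
                            "role": role,
                            "query_id": query.query_id,
                            "implanted_pid_realized": realized,
                            "protein_id": prot_id,
                            "representative_id": rep_id,
                        }
                    )

    # --- background clusters -------------------------------------------------
    slots = [g["Genome"] for g in genome_rows for _ in range(background_proteins_per_genome)]
    rng.shuffle(slots)
    pos = 0
    while pos < len(slots):
        size = 1 + (int(rng.poisson(redundancy - 1.0)) if redundancy > 1.0 else 0)
        size = min(size, len(slots) - pos)
        seq = random_protein(rng, int(rng.integers(100, 601)))
        rep_id = None
        for gid in slots[pos : pos + size]:
            prot_id = next_protein_id(gid)
            if rep_id is None:
                rep_id = prot_id
                representatives.append((rep_id, seq))
            membership_rows.append((prot_id, rep_id))
        pos += size

    membership = pd.DataFrame(membership_rows, columns=["member_id", "representative_id"])
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return Catalog(representatives, membership, metadata, truth)
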