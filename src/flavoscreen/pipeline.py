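"""End-to-end orchestration: search -> filter -> expand -> summarize ->
pathway calls -> prevalence, with a run manifest for reproducibility.

Every stage writes a TSV under the output directory and records its row
count in ``run_manifest.json`` together with the configuration hash, input
checksums and the seed, so reruns with identical inputs are byte-identical
and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import cluster as clustermod
from . import filtering, pathways, quantify, taxonomy
from .align import AlignerParams, read_tabular_hits, search_catalog, write_tabular_hits
from .registry import DEFAULT_MANIFEST, DEFAULT_QUERY_FASTA, load_registry
from .simulate import Catalog, ImplantSpec, SpeciesProfile, generate_catalog


@dataclass
class RunConfig:
    """Configuration for a screening run (YAML-loadable; flags override)."""

    catalog_fasta: str = ""
    membership_tsv: str = ""
    metadata_tsv: str = ""
    query_fasta: str = str(DEFAULT_QUERY_FASTA)
    query_manifest: str = str(DEFAULT_MANIFEST)
    out_dir: str = "screen_out"
    engine: str = "reference"  # "reference" | "external-file"
    external_hits: str = ""
    external_dialect: str = "outfmt6+qlen"
    min_pid: float = 30.0
    min_qcov: float = 75.0
    evalue_long: float = 1e-60
    evalue_short: float = 1e-25
    evalue_cdegly: float = 1e-20
    bin_edges: tuple = filtering.DEFAULT_BIN_EDGES
    min_freq: int = 0
    dedup_scope: str = "global"
    mags_only: bool = True
    max_targets: int = 100_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.bin_edges = tuple(cfg.bin_edges)
        return cfg

    def filter_config(self) -> filtering.FilterConfig:
        return filtering.FilterConfig(
            min_pid=self.min_pid,
            min_qcov=self.min_qcov,
            evalue_overrides={
                "long": self.evalue_long,
                "short": self.evalue_short,
                "c_degly": self.evalue_cdegly,
            },
        )

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _checksum(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_simulate(
    profiles: list[SpeciesProfile],
    implants: list[ImplantSpec],
    out_dir: str | Path,
    n_samples: int,
    background_proteins_per_genome: int = 5,
    redundancy: float = 2.0,
    seed: int = 0,
) -> dict[str, Path]:
    """Generate a synthetic catalog bundle and write it to ``out_dir``."""
    catalog = generate_catalog(
        profiles,
        implants,
        n_samples=n_samples,
        background_proteins_per_genome=background_proteins_per_genome,
        redundancy=redundancy,
        seed=seed,
    )
    return catalog.write(out_dir)


def default_scenario(
    n_genomes_per_species: int = 20,
) -> tuple[list[SpeciesProfile], list[ImplantSpec]]:
    """A small study scenario: five species with multi-gene clusters implanted
    at mixed identities and carrier fractions, plus a single-gene pathway and
    an isolate-containing species.

    Mirrors the situations the screen is meant to resolve: a species where
    only a minority of genomes carries a C-deglycosylation cluster, a
    daidzein-to-equol cluster confined to part of a species, a species with
    incomplete clusters, and two-copy single-gene carriers.
    """
    n = n_genomes_per_species
    profiles = [
        SpeciesProfile("Agathobacter synthetica", n),
        SpeciesProfile("Adlercreutzia synthetica", n),
        SpeciesProfile("Slackia synthetica", n, genome_type_fraction_mag=0.8),
        SpeciesProfile("Flavonifractor synthetica", n, genomes_per_sample=2),
        SpeciesProfile("Collinsella synthetica", n),
    ]
    implants = [
        ImplantSpec("Agathobacter synthetica", "c_deglycosylation_dgp",
                    ("dgpA", "dgpB", "dgpC"), target_pid=70.0, carrier_fraction=0.3),
        ImplantSpec("Adlercreutzia synthetica", "daidzein_equol",
                    ("dzr", "ddr", "tdr"), target_pid=85.0, carrier_fraction=0.1),
        ImplantSpec("Slackia synthetica", "daidzein_equol",
                    ("dzr",), target_pid=95.0, carrier_fraction=0.5),
        ImplantSpec("Flavonifractor synthetica", "flr",
                    ("Flr_Fp",), target_pid=95.0, carrier_fraction=1.0,
                    copies_per_genome=2),
        ImplantSpec("Collinsella synthetica", "o_demethylation",
                    ("MT1", "MT2", "CP", "AE"), target_pid=55.0,
                    carrier_fraction=0.5, role_completeness=0.5),
    ]
    return profiles, implants


def run_screen(config: RunConfig) -> dict[str, Path]:
    """Execute the screening pipeline and write all stage outputs."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = load_registry(config.query_fasta, config.query_manifest)
    counts: dict[str, int] = {}

    if config.engine == "reference":
        params = AlignerParams(max_targets=config.max_targets)
        raw_hits = search_catalog(registry, config.catalog_fasta, params)
    elif config.engine == "external-file":
        raw_hits = list(
            read_tabular_hits(config.external_hits, dialect=config.external_dialect)
        )
    else:
        raise ValueError(f"unknown engine {config.engine!r}")
    counts["raw_hits"] = len(raw_hits)

    filtered = filtering.apply_thresholds(raw_hits, config.filter_config(), registry)
    counts["filtered_hits"] = len(filtered)
    deduped = filtering.best_hit_per_target(
        filtered, scope_by=registry, dedup_scope=config.dedup_scope
    )
    counts["deduplicated_hits"] = len(deduped)
    write_tabular_hits(deduped, out / "filtered_hits.tsv")

    occurrences = quantify.expand_members(deduped, config.membership_tsv, registry)
    counts["occurrences"] = len(occurrences)
    annotated = quantify.attach_metadata(
        occurrences, config.metadata_tsv, mags_only=config.mags_only
    )
    counts["mag_occurrences"] = len(annotated)
    annotated.to_csv(out / "occurrences.tsv", sep="\t", index=False)

    summary = quantify.summarize(annotated, config.bin_edges, config.min_freq)
    summary.to_csv(out / "species_summary.tsv", sep="\t", index=False)
    counts["summary_groups"] = len(summary)

    calls = pathways.call_pathways(annotated, registry.rules)
    pathways.calls_frame(calls).to_csv(out / "pathway_calls.tsv", sep="\t", index=False)
    counts["pathway_calls"] = len(calls)
    stats = pathways.species_carrier_stats(calls, config.metadata_tsv)
    pathways.carrier_frame(stats).to_csv(out / "carrier_stats.tsv", sep="\t", index=False)

    species_seen = sorted(set(annotated["species_name"])) if len(annotated) else []
    if species_seen:
        prevalence = taxonomy.compute_prevalence(config.metadata_tsv, species_seen)
        taxonomy.prevalence_frame(prevalence).to_csv(
            out / "prevalence.tsv", sep="\t", index=False
        )
    else:
        taxonomy.prevalence_frame([]).to_csv(out / "prevalence.tsv", sep="\t", index=False)

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "config_hash": config.digest(),
        "seed": config.seed,
        "inputs": {
            name: _checksum(p)
            for name, p in {
                "catalog_fasta": config.catalog_fasta,
                "membership_tsv": config.membership_tsv,
                "metadata_tsv": config.metadata_tsv,
                "query_fasta": config.query_fasta,
                "query_manifest": config.query_manifest,
            }.items()
            if p and Path(p).exists()
        },
        "row_counts": counts,
        "runtime_s": round(time.time() - t0, 3),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {
        "filtered_hits": out / "filtered_hits.tsv",
        "occurrences": out / "occurrences.tsv",
        "species_summary": out / "species_summary.tsv",
        "pathway_calls": out / "pathway_calls.tsv",
        "carrier_stats": out / "carrier_stats.tsv",
        "prevalence": out / "prevalence.tsv",
        "run_manifest": out / "run_manifest.json",
    }


def run_cluster(
    fasta: str | Path,
    out_dir: str | Path,
    threshold_pid: float = 90.0,
    weights_tsv: str | Path | None = None,
) -> dict[str, Path]:
    """Greedy-cluster the sequences of a FASTA and export representatives."""
    from .align import read_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seqs = read_fasta(fasta)
    weights = None
    if weights_tsv:
        table = pd.read_csv(weights_tsv, sep="\t", header=None, names=["id", "weight"])
        weights = dict(zip(table["id"], table["weight"].astype(int)))
    clusters = clustermod.greedy_cluster(seqs, threshold_pid=threshold_pid, weights=weights)
    clustermod.export_cluster_fasta(clusters, dict(seqs), out / "cluster_representatives.faa")
    clustermod.membership_table(clusters).to_csv(
        out / "cluster_members.tsv", sep="\t", index=False
    )
    return {
        "representatives": out / "cluster_representatives.faa",
        "members": out / "cluster_members.tsv",
    }
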