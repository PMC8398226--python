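from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import flavoscreen as fs
from flavoscreen.pipeline import RunConfig, default_scenario, run_screen


@pytest.fixture(scope="session")
def registry():
    return fs.load_registry()


@pytest.fixture(scope="session")
def study_catalog(tmp_path_factory, registry):
    """The study scenario: 5 species x 20 genomes with implants at identities
    55-95, carrier fractions 0.1-1.0 and role completeness 0.5/1.0."""
    outdir = tmp_path_factory.mktemp("study_catalog")
    profiles, implants = default_scenario(20)
    catalog = fs.generate_catalog(
        profiles,
        implants,
        n_samples=60,
        background_proteins_per_genome=4,
        redundancy=2.0,
        seed=1,
        registry=registry,
    )
    paths = catalog.write(outdir)
    return catalog, paths


@pytest.fixture(scope="session")
def screen_outputs(tmp_path_factory, study_catalog):
    """Full pipeline outputs on the study catalog (reference aligner)."""
    catalog, paths = study_catalog
    out_dir = tmp_path_factory.mktemp("screen_out")
    config = RunConfig(
        catalog_fasta=str(paths["fasta"]),
        membership_tsv=str(paths["membership"]),
        metadata_tsv=str(paths["metadata"]),
        out_dir=str(out_dir),
        seed=1,
    )
    outputs = run_screen(config)
    return catalog, config, outputs


@pytest.fixture
def tiny_occurrences():
    """Hand-written occurrence table used by grouping and pathway tests."""
    rows = [
        # genome g1: full dgpABC
        ("g1_00001", "r1", "g1", "DgpA", "c_deglycosylation_dgp", "dgpA", 72.0),
        ("g1_00002", "r2", "g1", "DgpB", "c_deglycosylation_dgp", "dgpB", 65.0),
        ("g1_00003", "r3", "g1", "DgpC", "c_deglycosylation_dgp", "dgpC", 81.0),
        # genome g2: dgpA + dgpB only
        ("g2_00001", "r1", "g2", "DgpA", "c_deglycosylation_dgp", "dgpA", 70.0),
        ("g2_00002", "r2", "g2", "DgpB", "c_deglycosylation_dgp", "dgpB", 64.0),
        # genome g3: dzr only
        ("g3_00001", "r4", "g3", "DZR_Si", "daidzein_equol", "dzr", 90.0),
        # genome g4: dfgABCE (4 of 5)
        ("g4_00001", "r5", "g4", "DfgA_Ec", "c_deglycosylation_dfg", "dfgA", 55.0),
        ("g4_00002", "r6", "g4", "DfgB_Ec", "c_deglycosylation_dfg", "dfgB", 52.0),
        ("g4_00003", "r7", "g4", "DfgC_Ec", "c_deglycosylation_dfg", "dfgC", 58.0),
        ("g4_00004", "r8", "g4", "DfgE_Ec", "c_deglycosylation_dfg", "dfgE", 60.0),
        # genome g5: O-demethylase operon complete but AE below the PID floor
        ("g5_00001", "r9", "g5", "MT1_El", "o_demethylation", "MT1", 62.0),
        ("g5_00002", "r10", "g5", "MT2_El", "o_demethylation", "MT2", 47.0),
        ("g5_00003", "r11", "g5", "CP_El", "o_demethylation", "CP", 44.0),
        ("g5_00004", "r12", "g5", "AE_El", "o_demethylation", "AE", 38.0),
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "member_protein_id",
            "representative_id",
            "genome_id",
            "query_id",
            "pathway_id",
            "role",
            "pid",
        ],
    )
    frame["qcov"] = 90.0
    frame["bitscore"] = 300.0
    frame["sample_accession"] = "SAMP000001"
    frame["genome_type"] = "MAG"
    frame["species_name"] = "Testus synthetica"
    return frame


def random_hit(rng: np.random.Generator, query, target_id: str) -> fs.AlignmentHit:
    """A syntactically valid hit for a registry query (random scores)."""
    qlen = query.length
    qstart = int(rng.integers(1, max(2, qlen // 4)))
    qend = int(rng.integers(qstart, qlen + 1))
    return fs.AlignmentHit(
        query_id=query.query_id,
        target_id=target_id,
        pid=float(rng.uniform(30, 100)),
        aln_length=qend - qstart + 1,
        mismatch=0,
        gap_opens=0,
        qstart=qstart,
        qend=qend,
        sstart=1,
        send=qend - qstart + 1,
        evalue=float(10.0 ** rng.uniform(-80, -10)),
        bitscore=float(rng.uniform(50, 500)),
        qlen=qlen,
    )
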