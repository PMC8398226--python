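import numpy as np
import pandas as pd
import pytest

import flavoscreen as fs
from flavoscreen.quantify import (
    ANNOTATED_COLUMNS,
    OCCURRENCE_COLUMNS,
    SUMMARY_COLUMNS,
    attach_metadata,
    expand_members,
    genome_of_protein,
    summarize,
)

from test_filtering import make_hit


def membership_frame(pairs):
    return pd.DataFrame(pairs, columns=["member_id", "representative_id"])


def metadata_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["Genome", "Genome_type", "Sample_accession", "Lineage",
                 "Completeness", "Contamination"],
    )


LINEAGE = (
    "d__Bacteria;p__Actinobacteriota;c__Coriobacteriia;o__Coriobacteriales;"
    "f__Eggerthellaceae;g__Testus;s__Testus synthetica"
)


class TestExpansion:
    def test_genome_prefix_extraction(self):
        assert genome_of_protein("SYNG00007_00012") == "SYNG00007"
        with pytest.raises(ValueError):
            genome_of_protein("noseparator")

    def test_redundancy_expansion_counts_match_nested_loop_join(self, registry):
        """3-member, 1-member and 8-member representatives expand to 3+1+8
        occurrences, matching an explicit nested-loop join."""
        members = membership_frame(
            [(f"gA_{i:05d}", "R1") for i in range(3)]
            + [("gB_00001", "R2")]
            + [(f"gC_{i:05d}", "R3") for i in range(8)]
        )
        hits = [
            make_hit(registry, "BdR", "R1", 55.0, 90.0, 1e-70),
            make_hit(registry, "Phy_Er", "R2", 80.0, 90.0, 1e-30),
            make_hit(registry, "Flr_Fp", "R3", 95.0, 90.0, 1e-40),
        ]
        occ = expand_members(hits, members, registry)
        # oracle: loop over hits, loop over membership rows
        expected = [
            (row.member_id, h.target_id, h.query_id)
            for h in hits
            for row in members.itertuples()
            if row.representative_id == h.target_id
        ]
        got = list(zip(occ["member_protein_id"], occ["representative_id"], occ["query_id"]))
        assert sorted(got) == sorted(expected)
        assert len(occ) == 12
        assert list(occ.columns) == OCCURRENCE_COLUMNS

    def test_occurrences_inherit_representative_scores(self, registry):
        members = membership_frame([("gA_00001", "R1"), ("gA_00002", "R1")])
        hit = make_hit(registry, "BdR", "R1", 61.5, 90.0, 1e-70, bitscore=321.0)
        occ = expand_members([hit], members, registry)
        assert set(occ["pid"]) == {61.5}
        assert set(occ["bitscore"]) == {321.0}
        assert set(occ["role"]) == {registry.role_of("BdR")}
        assert set(occ["pathway_id"]) == {"derhamnosylation"}

    def test_missing_representative_is_an_error(self, registry):
        members = membership_frame([("gA_00001", "R1")])
        hit = make_hit(registry, "BdR", "R9", 55.0, 90.0, 1e-70)
        with pytest.raises(KeyError, match="R9"):
            expand_members([hit], members, registry)

    def test_no_hits_expand_to_empty_table(self, registry):
        members = membership_frame([("gA_00001", "R1")])
        occ = expand_members([], members, registry)
        assert occ.empty and list(occ.columns) == OCCURRENCE_COLUMNS


class TestAttachMetadata:
    def _occ(self, genomes):
        return pd.DataFrame(
            [
                {
                    "member_protein_id": f"{g}_00001",
                    "representative_id": "R1",
                    "genome_id": g,
                    "query_id": "BdR",
                    "pathway_id": "derhamnosylation",
                    "role": "BdR",
                    "pid": 55.0,
                    "qcov": 90.0,
                    "bitscore": 300.0,
                }
                for g in genomes
            ],
            columns=OCCURRENCE_COLUMNS,
        )

    def test_isolates_dropped_by_default(self):
        meta = metadata_frame(
            [
                ("gA", "MAG", "S1", LINEAGE, 95.0, 1.0),
                ("gB", "Isolate", "S2", LINEAGE, 99.0, 0.1),
            ]
        )
        occ = attach_metadata(self._occ(["gA", "gB"]), meta)
        assert list(occ["genome_id"]) == ["gA"]
        assert list(occ.columns) == ANNOTATED_COLUMNS
        both = attach_metadata(self._occ(["gA", "gB"]), meta, mags_only=False)
        assert sorted(both["genome_id"]) == ["gA", "gB"]

    def test_species_label_from_lineage(self):
        meta = metadata_frame([("gA", "MAG", "S1", LINEAGE, 95.0, 1.0)])
        occ = attach_metadata(self._occ(["gA"]), meta)
        assert list(occ["species_name"]) == ["Testus synthetica"]
        assert list(occ["sample_accession"]) == ["S1"]

    def test_unknown_genome_is_an_error(self):
        meta = metadata_frame([("gA", "MAG", "S1", LINEAGE, 95.0, 1.0)])
        with pytest.raises(KeyError, match="gZ"):
            attach_metadata(self._occ(["gZ"]), meta)


class TestSummarize:
    def test_counts_match_brute_force_group_by(self, tiny_occurrences):
        out = summarize(tiny_occurrences)
        # brute force: nested dict over the rows
        counts, genomes = {}, {}
        for row in tiny_occurrences.itertuples():
            key = (row.species_name, row.query_id, fs.pid_bin(row.pid))
            counts[key] = counts.get(key, 0) + 1
            genomes.setdefault(key, set()).add(row.genome_id)
        assert len(out) == len(counts)
        for row in out.itertuples():
            key = (row.species, row.query_id, row.pid_bin)
            assert row.freq == counts[key]
            assert row.n_genomes_with_hit == len(genomes[key])

    def test_freq_counts_copies_but_genomes_counted_once(self):
        occ = pd.DataFrame(
            [
                {"member_protein_id": f"gA_{i:05d}", "representative_id": "R1",
                 "genome_id": "gA", "query_id": "Flr_Fp", "pathway_id": "flr",
                 "role": "Flr_Fp", "pid": 95.0, "qcov": 90.0, "bitscore": 300.0,
                 "sample_accession": "S1", "genome_type": "MAG",
                 "species_name": "Testus synthetica"}
                for i in range(4)
            ]
        )
        out = summarize(occ)
        assert len(out) == 1
        assert out.loc[0, "freq"] == 4
        assert out.loc[0, "n_genomes_with_hit"] == 1

    def test_min_freq_boundary_is_inclusive(self, tiny_occurrences):
        big = pd.concat([tiny_occurrences] * 50, ignore_index=True)
        out = summarize(big, min_freq=50)
        assert (out["freq"] >= 50).all()
        # every group is a 50-fold copy of a base group of 1 or 2 rows
        assert set(out["freq"]) <= {50, 100}
        trimmed = summarize(big, min_freq=51)
        assert set(trimmed["freq"]) == {100}

    def test_sorted_by_descending_freq(self, tiny_occurrences):
        doubled = pd.concat(
            [tiny_occurrences, tiny_occurrences[tiny_occurrences["genome_id"] == "g1"]],
            ignore_index=True,
        )
        out = summarize(doubled)
        assert list(out["freq"]) == sorted(out["freq"], reverse=True)

    def test_total_freq_is_conserved(self, tiny_occurrences):
        out = summarize(tiny_occurrences)
        assert out["freq"].sum() == len(tiny_occurrences)

    def test_empty_input_gives_headed_empty_frame(self):
        out = summarize(pd.DataFrame(columns=ANNOTATED_COLUMNS))
        assert out.empty and list(out.columns) == SUMMARY_COLUMNS


def test_expansion_on_study_catalog_conserves_membership(study_catalog, registry):
    """Every occurrence is a real member of its representative's cluster, and
    the occurrence count per hit equals that cluster's size."""
    catalog, paths = study_catalog
    hits = fs.search_catalog(registry, paths["fasta"])
    kept = fs.best_hit_per_target(fs.apply_thresholds(hits, fs.FilterConfig(), registry))
    occ = expand_members(kept, catalog.membership, registry)
    sizes = catalog.membership.groupby("representative_id").size()
    per_rep = occ.groupby("representative_id").size()
    for rep, n in per_rep.items():
        assert n == sizes[rep]
    assert len(occ) == sum(sizes[h.target_id] for h in kept)
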