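import itertools

import pandas as pd
import pytest

from flavoscreen.pathways import (
    PathwayCall,
    call_pathways,
    carrier_frame,
    evaluate_rule,
    single_gene_report,
    species_carrier_stats,
)

from _oracles import rule_bruteforce

LINEAGE = (
    "d__Bacteria;p__Actinobacteriota;c__Coriobacteriia;o__Coriobacteriales;"
    "f__Eggerthellaceae;g__Testus;s__Testus synthetica"
)


def calls_by_genome(calls):
    return {(c.genome_id, c.pathway_id): c for c in calls}


class TestCallPathways:
    def test_known_genome_calls(self, registry, tiny_occurrences):
        calls = calls_by_genome(call_pathways(tiny_occurrences, registry.rules))
        # g1 has all of dgpABC -> present
        assert calls[("g1", "c_deglycosylation_dgp")].present is True
        # g2 lacks dgpC -> not present, dgpC reported missing
        g2 = calls[("g2", "c_deglycosylation_dgp")]
        assert g2.present is False
        assert g2.roles_missing == frozenset({"dgpC"})
        # g3 has dzr only: 1 of 3 required daidzein genes
        g3 = calls[("g3", "daidzein_equol")]
        assert g3.present is False
        assert g3.roles_found == frozenset({"dzr"})
        # g4 has 4 of 5 dfg genes, requirement is at-least-3 -> present
        assert calls[("g4", "c_deglycosylation_dfg")].present is True

    def test_pid_floor_excludes_subthreshold_role(self, registry, tiny_occurrences):
        """g5 carries all four O-demethylase components but AE sits at PID 38,
        below the strict > 40 floor, so the operon is not called present."""
        calls = calls_by_genome(call_pathways(tiny_occurrences, registry.rules))
        g5 = calls[("g5", "o_demethylation")]
        assert g5.present is False
        assert "AE" in g5.roles_missing
        assert g5.roles_found == frozenset({"MT1", "MT2", "CP"})

    def test_pid_floor_is_strict_at_the_boundary(self, registry):
        rule = registry.rules["o_demethylation"]
        at_floor = evaluate_rule(rule, {"MT1": 50, "MT2": 50, "CP": 50, "AE": 40.0})
        assert at_floor.present is False
        above = evaluate_rule(rule, {"MT1": 50, "MT2": 50, "CP": 50, "AE": 40.1})
        assert above.present is True

    def test_copy_number_does_not_change_call(self, registry, tiny_occurrences):
        doubled = pd.concat([tiny_occurrences] * 3, ignore_index=True)
        a = call_pathways(tiny_occurrences, registry.rules)
        b = call_pathways(doubled, registry.rules)
        assert calls_by_genome(a).keys() == calls_by_genome(b).keys()
        for key, call in calls_by_genome(a).items():
            assert calls_by_genome(b)[key].present == call.present

    def test_single_gene_pathways_produce_no_calls(self, registry):
        occ = pd.DataFrame(
            [{"member_protein_id": "g1_00001", "representative_id": "r1",
              "genome_id": "g1", "query_id": "Flr_Fp", "pathway_id": "flr",
              "role": "Flr_Fp", "pid": 95.0, "qcov": 90.0, "bitscore": 300.0}]
        )
        assert call_pathways(occ, registry.rules) == []

    def test_unknown_pathway_rejected(self, registry, tiny_occurrences):
        bad = tiny_occurrences.copy()
        bad.loc[0, "pathway_id"] = "mystery"
        with pytest.raises(KeyError, match="mystery"):
            call_pathways(bad, registry.rules)

    def test_empty_occurrences_give_no_calls(self, registry, tiny_occurrences):
        assert call_pathways(tiny_occurrences.iloc[:0], registry.rules) == []

    def test_adding_occurrences_never_revokes_presence(self, registry, tiny_occurrences):
        """Monotonicity: a genome called present stays present when more
        occurrences are appended."""
        before = calls_by_genome(call_pathways(tiny_occurrences, registry.rules))
        extra = tiny_occurrences.iloc[[5]].copy()  # duplicate a dzr row
        extra["genome_id"] = "g1"
        extra["member_protein_id"] = "g1_00099"
        after = calls_by_genome(
            call_pathways(pd.concat([tiny_occurrences, extra], ignore_index=True),
                          registry.rules)
        )
        for key, call in before.items():
            if call.present:
                assert after[key].present


class TestRuleBruteForce:
    @pytest.mark.parametrize(
        "pathway", ["c_deglycosylation_dgp", "c_deglycosylation_dfg",
                    "daidzein_equol", "o_demethylation"],
    )
    def test_all_role_subsets_match_oracle(self, registry, pathway):
        rule = registry.rules[pathway]
        roles = list(rule.member_roles)
        for r in range(len(roles) + 1):
            for subset in itertools.combinations(roles, r):
                found = {role: 75.0 for role in subset}
                call = evaluate_rule(rule, found)
                expected = rule_bruteforce(
                    rule.requirement.kind,
                    rule.requirement.k or 0,
                    set(roles),
                    set(subset),
                )
                if not subset:
                    assert call is None
                else:
                    assert call.present == expected


class TestCarrierStats:
    def _metadata(self, n_mags, n_isolates=0):
        rows = [("g%d" % i, "MAG", "S%d" % i, LINEAGE, 95.0, 1.0) for i in range(n_mags)]
        rows += [
            ("i%d" % i, "Isolate", "SI%d" % i, LINEAGE, 99.0, 0.2)
            for i in range(n_isolates)
        ]
        return pd.DataFrame(
            rows, columns=["Genome", "Genome_type", "Sample_accession", "Lineage",
                           "Completeness", "Contamination"],
        )

    def _call(self, genome, present):
        return PathwayCall(genome, "c_deglycosylation_dgp", present,
                           frozenset({"dgpA"}), frozenset(), 70.0)

    def test_three_carriers_of_ten_is_thirty_percent(self):
        calls = [self._call(f"g{i}", i < 3) for i in range(5)]
        (stat,) = species_carrier_stats(calls, self._metadata(10))
        assert (stat.n_carriers, stat.n_total) == (3, 10)
        assert stat.carrier_fraction == pytest.approx(30.0)

    def test_denominator_counts_hitless_mags_not_isolates(self):
        calls = [self._call("g0", True)]
        (stat,) = species_carrier_stats(calls, self._metadata(4, n_isolates=6))
        assert stat.n_total == 4
        assert stat.carrier_fraction == pytest.approx(25.0)

    def test_species_with_only_absent_calls_still_reported(self):
        calls = [self._call("g0", False)]
        (stat,) = species_carrier_stats(calls, self._metadata(4))
        assert stat.n_carriers == 0 and stat.n_total == 4

    def test_frame_round_trip(self):
        calls = [self._call("g0", True)]
        frame = carrier_frame(species_carrier_stats(calls, self._metadata(2)))
        assert frame.loc[0, "carrier_fraction_pct"] == pytest.approx(50.0)


class TestSingleGeneReport:
    def test_partial_signatures(self, registry, tiny_occurrences):
        report = single_gene_report(
            tiny_occurrences, "c_deglycosylation_dgp",
            registry.rules["c_deglycosylation_dgp"],
        )
        # g1 is complete (excluded); g2 has dgpA+dgpB
        assert len(report) == 1
        assert report.loc[0, "signature"] == "{dgpA,dgpB}"
        assert report.loc[0, "n_genomes"] == 1

    def test_dzr_only_signature(self, registry, tiny_occurrences):
        report = single_gene_report(
            tiny_occurrences, "daidzein_equol", registry.rules["daidzein_equol"]
        )
        assert list(report["signature"]) == ["{dzr}"]

    def test_single_role_pathway_rejected(self, tiny_occurrences):
        from flavoscreen.registry import PathwayRule, Requirement

        lone = PathwayRule("phy", ("Phy_Er",), Requirement("ANY"))
        with pytest.raises(ValueError, match="fewer than 2"):
            single_gene_report(tiny_occurrences, "phy", lone)
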