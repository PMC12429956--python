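"""Disease-related networks, drug categories, rate tables, fold change."""

import math
import random

import pytest

from netdrugmap.model import GeneMode, Phase
from netdrugmap.rates import (
    Category,
    categorize_drug,
    disease_network_sets,
    drugs_on_any_network,
    drugs_on_related_networks,
    pipeline_fold_change,
    rate_table,
    related_networks,
)

from oracles import (
    disease_targets_from_raw,
    oracle_category,
    oracle_dna,
    oracle_dngt,
    oracle_related_networks,
    random_raw_universe,
    to_study_universe,
)


class TestRelatedNetworks:
    def test_requires_both_gene_and_target(self, toy_universe):
        # disease 1 (all): Dg={g1,g3}, T={g2,g3,g9} → N1 (g1,g2), N2 (g3,g3)
        assert related_networks(toy_universe, 1, phase=Phase.ALL) == {"N1", "N2"}
        # clinical phase: same T minus g9 → unchanged here
        assert related_networks(toy_universe, 1, phase=Phase.CLINICAL) == {"N1", "N2"}

    def test_empty_without_disease_genes(self):
        raw = random_raw_universe(random.Random(0), max_diseases=1)
        raw["disease_omim"][1] = set()
        raw["disease_gwas"][1] = set()
        raw["disease_genes"][1] = set()
        universe = to_study_universe(raw)
        assert related_networks(universe, 1) == frozenset()

    def test_gene_and_target_in_different_networks_do_not_relate(self):
        raw = {
            "networks": {"N1": {"g1"}, "N2": {"g2"}},
            "pathways": {"P1": {"g1", "g2"}},
            "drug_targets": {"x": {"g2"}},
            "disease_omim": {1: {"g1"}}, "disease_gwas": {1: set()},
            "disease_genes": {1: {"g1"}},
            "disease_drugs": {1: {"all": {"x"}, "clinical": set(), "approved": set()}},
            "disease_groups": {1: {"Imm"}},
        }
        universe = to_study_universe(raw)
        assert related_networks(universe, 1, phase=Phase.ALL) == frozenset()


class TestCategorize:
    @pytest.fixture
    def four_case_universe(self):
        raw = {
            "networks": {"N1": {"g1", "g2"}, "N2": {"g3", "g4"}},
            "pathways": {"P1": {"g1", "g2", "g3", "g4"}},
            "drug_targets": {
                "hits_gene": {"g1"}, "hits_partner": {"g2"},
                "hits_other": {"g3"}, "hits_nothing": {"g9"},
                "mixed": {"g1", "g3"}, "empty": set(),
            },
            "disease_omim": {1: {"g1"}}, "disease_gwas": {1: set()},
            "disease_genes": {1: {"g1"}},
            "disease_drugs": {1: {
                "all": {"hits_gene", "hits_partner", "hits_other",
                        "hits_nothing", "mixed", "empty"},
                "clinical": set(), "approved": set(),
            }},
            "disease_groups": {1: {"Imm"}},
        }
        return to_study_universe(raw)

    @pytest.mark.parametrize("drug,expected", [
        ("hits_gene", Category.DISEASE_GENE),
        ("hits_partner", Category.RELATED_NETWORK_PARTNER),
        ("hits_other", Category.OTHER_NETWORK),
        ("hits_nothing", Category.NO_NETWORK),
        ("mixed", Category.DISEASE_GENE),       # priority order
        ("empty", Category.NO_NETWORK),
    ])
    def test_four_cases_and_priority(self, four_case_universe, drug, expected):
        assert categorize_drug(four_case_universe, 1, drug) == expected

    def test_unknown_drug_rejected(self, four_case_universe):
        with pytest.raises(KeyError):
            categorize_drug(four_case_universe, 1, "nope")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        raw = random_raw_universe(random.Random(seed + 3000))
        universe = to_study_universe(raw)
        elements = {n: set(universe.networks[n]) for n in universe.networks}
        for j in universe.diseases:
            for d in raw["disease_drugs"][j]["all"]:
                expected = oracle_category(
                    elements, raw["drug_targets"][d], raw["disease_genes"][j]
                )
                assert categorize_drug(universe, j, d).value == expected


class TestStageThreeSets:
    @pytest.mark.parametrize("seed", range(20))
    def test_nc_dngt_dna_match_brute_force(self, seed):
        raw = random_raw_universe(random.Random(seed + 4000))
        universe = to_study_universe(raw)
        elements = {n: set(universe.networks[n]) for n in universe.networks}
        targets = disease_targets_from_raw(raw, "all")
        for j in universe.diseases:
            assert related_networks(universe, j, phase=Phase.ALL) == \
                oracle_related_networks(elements, raw["disease_genes"][j], targets[j])
            assert drugs_on_related_networks(universe, j, phase=Phase.ALL) == \
                oracle_dngt(elements, raw["drug_targets"], raw["disease_genes"][j],
                            raw["disease_drugs"][j]["all"], targets[j])
            assert drugs_on_any_network(universe, j, Phase.ALL) == \
                oracle_dna(elements, raw["drug_targets"], raw["disease_drugs"][j]["all"])

    @pytest.mark.parametrize("seed", range(10))
    def test_set_chain_and_partition(self, seed):
        raw = random_raw_universe(random.Random(seed + 5000))
        universe = to_study_universe(raw)
        for j in universe.diseases:
            for phase in Phase:
                sets = disease_network_sets(universe, j, phase=phase)
                dd = universe.diseases[j].drugs(phase)
                assert sets.drugs_on_related_union <= sets.drugs_on_any_network <= dd
                by_cat = {c: 0 for c in Category}
                for d in dd:
                    by_cat[categorize_drug(universe, j, d)] += 1
                assert sum(by_cat.values()) == len(dd)

    @pytest.mark.parametrize("seed", range(10))
    def test_integrated_mode_never_shrinks_related_drugs(self, seed):
        raw = random_raw_universe(random.Random(seed + 6000))
        universe = to_study_universe(raw)
        for j in universe.diseases:
            omim = drugs_on_related_networks(universe, j, GeneMode.OMIM, Phase.ALL)
            integ = drugs_on_related_networks(universe, j, GeneMode.INTEGRATED, Phase.ALL)
            assert omim <= integ


class TestRateTable:
    @pytest.fixture
    def small_table(self, default_synth):
        universe, _ = default_synth
        numbers = sorted(universe.diseases)[:4]
        return universe, rate_table(universe, numbers)

    def test_percentages_sum_to_100_and_counts_to_denominator(self, small_table):
        universe, table = small_table
        for j in table.disease_numbers:
            for phase in table.phases:
                counts = [table.count(j, phase, c) for c in table.categories]
                percents = [table.percent(j, phase, c) for c in table.categories]
                assert sum(counts) == table.denominators[(j, phase)]
                assert sum(percents) == pytest.approx(100.0, abs=1e-9)

    def test_out_of_network_drugs_change_no_percentage(self, default_synth):
        """Removing a no-network drug leaves every dna-based rate alone."""
        universe, _ = default_synth
        j = sorted(universe.diseases)[0]
        table = rate_table(universe, [j])
        n_out = table.out_of_network[(j, Phase.ALL)]
        assert table.denominators[(j, Phase.ALL)] + n_out == len(
            universe.diseases[j].drugs(Phase.ALL)
        )

    def test_simple_arithmetic(self):
        raw = {
            "networks": {"N1": {"g1", "g2", "g3", "g4"}},
            "pathways": {"P1": {"g1", "g2", "g3", "g4"}},
            "drug_targets": {"a": {"g1"}, "b": {"g2"}, "c": {"g3"}, "d": {"g2"}},
            "disease_omim": {1: {"g1"}}, "disease_gwas": {1: set()},
            "disease_genes": {1: {"g1"}},
            "disease_drugs": {1: {
                "all": {"a", "b", "c", "d"},
                "clinical": {"a", "b", "c", "d"},
                "approved": {"a", "b", "c", "d"},
            }},
            "disease_groups": {1: {"Imm"}},
        }
        universe = to_study_universe(raw)
        table = rate_table(universe, [1])
        assert table.percent(1, Phase.ALL, Category.DISEASE_GENE) == 25.0
        assert table.percent(1, Phase.ALL, Category.RELATED_NETWORK_PARTNER) == 75.0

    def test_empty_denominator_names_the_cell(self):
        raw = {
            "networks": {"N1": {"g1"}},
            "pathways": {"P1": {"g1"}},
            "drug_targets": {"x": {"g9"}},
            "disease_omim": {1: {"g1"}}, "disease_gwas": {1: set()},
            "disease_genes": {1: {"g1"}},
            "disease_drugs": {1: {"all": {"x"}, "clinical": {"x"}, "approved": {"x"}}},
            "disease_groups": {1: {"Imm"}},
        }
        universe = to_study_universe(raw)
        with pytest.raises(ValueError, match="disease 1.*all"):
            rate_table(universe, [1])

    def test_all_drugs_denominator_includes_no_network_category(self, default_synth):
        universe, _ = default_synth
        j = sorted(universe.diseases)[0]
        table = rate_table(universe, [j], denominator="all_drugs")
        assert Category.NO_NETWORK in table.categories
        counts = [table.count(j, Phase.ALL, c) for c in table.categories]
        assert sum(counts) == len(universe.diseases[j].drugs(Phase.ALL))


class TestFoldChange:
    def test_equal_percentages_give_one(self, default_synth):
        universe, _ = default_synth
        j = sorted(universe.diseases)[0]
        table = rate_table(universe, [j])
        for c in table.categories:
            if table.percent(j, Phase.ALL, c) > 0:
                fold = pipeline_fold_change(table, j, c, endpoint=Phase.ALL)
                assert fold == pytest.approx(1.0)

    @staticmethod
    def _hand_table(percent_all, percent_approved):
        from netdrugmap.rates import IN_NETWORK_CATEGORIES, RateTable

        cat = Category.RELATED_NETWORK_PARTNER
        table = RateTable(
            gene_mode=GeneMode.INTEGRATED, denominator="dna",
            categories=IN_NETWORK_CATEGORIES, disease_numbers=[1],
            phases=(Phase.ALL, Phase.CLINICAL, Phase.APPROVED),
        )
        for phase, pct in ((Phase.ALL, percent_all),
                           (Phase.CLINICAL, percent_all),
                           (Phase.APPROVED, percent_approved)):
            for c in table.categories:
                table.cells[(1, phase, c)] = {
                    "count": 0, "percent": pct if c is cat else 0.0
                }
            table.denominators[(1, phase)] = 100
        return table

    def test_known_ratio(self):
        """A category at 2.0% of all drugs and 8.2% of approved drugs has
        risen 4.1-fold across the pipeline."""
        table = self._hand_table(2.0, 8.2)
        fold = pipeline_fold_change(table, 1, Category.RELATED_NETWORK_PARTNER)
        assert fold == pytest.approx(4.1)

    def test_zero_baseline_is_flagged_not_raised(self):
        table = self._hand_table(0.0, 8.2)
        assert math.isnan(pipeline_fold_change(table, 1, Category.RELATED_NETWORK_PARTNER))
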