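"""Knowledge-group/guild classification and group-level summaries."""

import numpy as np
import pandas as pd
import pytest

from sedistrat import (
    TaxonDictionary,
    classify,
    group_abundance,
    guild_summary,
    pathway_ratio,
    theoretical_pathway_ratio,
)
from sedistrat.taxa import DictionaryError, Rule, classify_lineage

METHANOSAETA = (
    "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;Methanosaetaceae;Methanosaeta"
)


@pytest.fixture(scope="module")
def dictionary():
    return TaxonDictionary.default()


class TestClassify:
    @pytest.mark.parametrize(
        "lineage,expected_in,expected_not_in",
        [
            ("Bacteria;Caldiserica;Caldisericia", "poorly_known", "well_characterized"),
            (METHANOSAETA, "well_characterized", "poorly_known"),
            ("Bacteria;unclassified", "unclassified_domain", "poorly_known"),
            ("Bacteria;Cyanobacteria;x;y", "well_characterized", "unclassified_domain"),
            ("Archaea;Bathyarchaeota", "poorly_known", "well_characterized"),
        ],
    )
    def test_knowledge_groups(self, dictionary, lineage, expected_in, expected_not_in):
        labels = classify_lineage(lineage, dictionary)
        assert expected_in in labels
        assert expected_not_in not in labels

    def test_methanosaeta_is_acetoclastic_methanogen(self, dictionary):
        labels = classify_lineage(METHANOSAETA, dictionary)
        assert "methanogen_acetoclastic" in labels
        assert "well_characterized" in labels

    def test_methanomicrobiales_is_hydrogenotrophic(self, dictionary):
        labels = classify_lineage(
            "Archaea;Euryarchaeota;Methanomicrobia;Methanomicrobiales;Methanoregulaceae;Methanoregula",
            dictionary,
        )
        assert "methanogen_hydrogenotrophic" in labels

    def test_methanosarcina_in_neither_pathway_guild(self, dictionary):
        labels = classify_lineage(
            "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;Methanosarcinaceae;Methanosarcina",
            dictionary,
        )
        assert "methanogen_other" in labels
        assert "methanogen_acetoclastic" not in labels
        assert "methanogen_hydrogenotrophic" not in labels

    def test_rule_order_invariance(self, dictionary):
        reversed_dict = TaxonDictionary(
            rules=list(reversed(dictionary.rules)), version=dictionary.version
        )
        for lineage in (METHANOSAETA, "Bacteria;Chloroflexi;x", "Archaea;unclassified"):
            assert classify_lineage(lineage, dictionary) == classify_lineage(
                lineage, reversed_dict
            )

    def test_duplicate_rules_rejected_at_load(self):
        rule = Rule("Caldiserica", "phylum", frozenset({"poorly_known"}))
        clash = Rule("Caldiserica", "phylum", frozenset({"well_characterized"}))
        with pytest.raises(DictionaryError, match="conflicting"):
            TaxonDictionary(rules=[rule, clash])

    def test_classify_over_table(self, tiny_table, dictionary):
        labels = classify(tiny_table, dictionary)
        assert "well_characterized" in labels["OtuA"]
        assert "poorly_known" in labels["OtuB"]
        assert labels["OtuC"] == frozenset({"unclassified_domain"})


class TestGroupAbundance:
    def _frame(self):
        return pd.DataFrame(
            {"0-2": [0.1, 0.2, 0.3, 0.4], "2-4": [0.4, 0.3, 0.2, 0.1]},
            index=["a", "b", "c", "d"],
        )

    def _labels(self):
        return pd.Series(
            {
                "a": frozenset({"poorly_known"}),
                "b": frozenset({"poorly_known"}),
                "c": frozenset({"well_characterized"}),
                "d": frozenset({"unclassified_domain"}),
            }
        )

    def test_sums_and_partition(self):
        gp = group_abundance(self._frame(), self._labels())
        assert gp.values.loc["poorly_known", "0-2"] == pytest.approx(0.3)
        assert np.allclose(gp.values.sum(axis=0), 1.0, atol=1e-9)

    def test_fold_unclassified_into_poorly_known(self):
        gp = group_abundance(self._frame(), self._labels(), fold_unclassified=True)
        assert gp.values.loc["poorly_known", "0-2"] == pytest.approx(0.7)
        assert set(gp.values.index) == {"well_characterized", "poorly_known"}
        assert np.allclose(gp.values.sum(axis=0), 1.0, atol=1e-9)

    def test_partition_sums_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            raw = rng.random((30, 5))
            frame = pd.DataFrame(raw / raw.sum(axis=0), index=[f"o{i}" for i in range(30)])
            groups = rng.choice(
                ["well_characterized", "poorly_known", "unclassified_domain"], size=30
            )
            labels = pd.Series([frozenset({g}) for g in groups], index=frame.index)
            gp = group_abundance(frame, labels)
            assert np.allclose(gp.values.sum(axis=0), 1.0, atol=1e-9)

    def test_empty_group_is_zero(self):
        labels = pd.Series(
            {k: frozenset({"poorly_known"}) for k in self._frame().index}
        )
        gp = group_abundance(self._frame(), labels)
        assert (gp.values.loc["well_characterized"] == 0).all()


class TestPathwayRatio:
    def _labels(self):
        return pd.Series(
            {
                "a": frozenset({"methanogen_acetoclastic"}),
                "h": frozenset({"methanogen_hydrogenotrophic"}),
                "x": frozenset(),
            }
        )

    def test_nine_to_one(self):
        frame = pd.DataFrame({"L": [0.45, 0.05, 0.5]}, index=["a", "h", "x"])
        assert pathway_ratio(frame, self._labels())["L"] == pytest.approx(9.0)

    def test_zero_denominator_undefined(self):
        frame = pd.DataFrame({"L": [0.0, 0.0, 1.0]}, index=["a", "h", "x"])
        assert np.isnan(pathway_ratio(frame, self._labels())["L"])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(11)
        frame = pd.DataFrame(rng.random((3, 6)) + 0.01, index=["a", "h", "x"])
        ratios = pathway_ratio(frame, self._labels())
        for col in frame.columns:
            assert ratios[col] == pytest.approx(frame.loc["a", col] / frame.loc["h", col])


class TestTheoreticalRatio:
    def test_complete_hexose_degradation_gives_two(self):
        assert theoretical_pathway_ratio() == 2.0

    def test_custom_stoichiometries(self):
        assert theoretical_pathway_ratio(1, 1) == 1.0
        assert theoretical_pathway_ratio(3, 1) == 3.0

    def test_nonpositive_hydrogenotrophic_rejected(self):
        with pytest.raises(ValueError):
            theoretical_pathway_ratio(2, 0)


class TestGuildSummary:
    def test_absent_guild_zero_and_max(self):
        frame = pd.DataFrame(
            {"L1": [0.001, 0.1], "L2": [0.006, 0.1], "L3": [0.002, 0.1]},
            index=["m", "x"],
        )
        labels = pd.Series(
            {"m": frozenset({"methanotroph_aerobic"}), "x": frozenset()}
        )
        gs = guild_summary(frame, labels)
        assert gs.max_across_layers["methanotroph_aerobic"] == pytest.approx(0.006)
        assert (gs.per_layer.loc["methanogen_acetoclastic"] == 0).all()
        assert gs.max_across_layers["methanogen_acetoclastic"] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame(rng.random((20, 4)), index=[f"o{i}" for i in range(20)])
        guilds = ["methanotroph_aerobic", "methanogen_acetoclastic"]
        assignment = rng.choice([0, 1, 2], size=20)
        labels = pd.Series(
            [frozenset({guilds[a]}) if a < 2 else frozenset() for a in assignment],
            index=frame.index,
        )
        gs = guild_summary(frame, labels, guilds=guilds)
        for g in guilds:
            member_sum = frame.loc[[o for o in frame.index if g in labels[o]]].sum(axis=0)
            assert np.allclose(gs.per_layer.loc[g], member_sum)
            assert gs.max_across_layers[g] == pytest.approx(member_sum.max())
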