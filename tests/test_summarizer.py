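"""Four-filter pipeline: novelty, relevance, connectivity, saliency arms."""

from math import log2

import pytest

import combosum as cs
from combosum.metrics import WILDCARD_SEMTYPE

from conftest import make_corpus

SEED = "Carcinoma of bladder"


class TestNoveltyFilter:
    def test_stoplisted_general_concept_removed(self):
        corpus = make_corpus(
            [
                ("Coronary Arteriosclerosis", "dsyn", "ISA", "Vascular Disease(s)", "dsyn"),
                ("G gene", "gngm", "ASSOCIATED_WITH", SEED, "neop"),
            ]
        )
        kept = cs.novelty_filter(corpus, {"Vascular Disease(s)"})
        assert len(kept) == 1
        assert kept.records[0].predicate == "ASSOCIATED_WITH"

    def test_empty_stoplist_is_identity(self):
        corpus = make_corpus([("A", "gngm", "P", "B", "neop")])
        assert cs.novelty_filter(corpus, frozenset()) is corpus

    def test_removed_plus_kept_partition_input(self):
        rows = [("A", "gngm", "P", "General", "dsyn")] * 3 + [("A", "gngm", "P", "B", "neop")] * 2
        corpus = make_corpus(rows)
        kept = cs.novelty_filter(corpus, {"general"})
        assert len(kept) == 2
        assert len(corpus) - len(kept) == 3


def _pattern(predicate, semtype, score, rank, count=10):
    return cs.PatternScore(
        key=cs.PatternKey(predicate, semtype, cs.Side.SUBJECT),
        count=count, total=count, rlogf=None, predscal=None, kld_term=None,
        combo=None, score=score, rank=rank,
    )


class TestAnchorSelection:
    def test_occurrence_tie_broken_by_summed_score(self):
        # two semtypes in two patterns each; gngm's summed score is larger
        top = [
            _pattern("ASSOCIATED_WITH", "gngm", 0.592531, 1),
            _pattern("PREDISPOSES", "gngm", 0.205778, 2),
            _pattern("ASSOCIATED_WITH", "aapp", 0.152883, 3),
            _pattern("PREDISPOSES", "aapp", 0.039868, 4),
        ]
        assert cs.select_anchor_semtype(top) == "gngm"

    def test_single_pattern_yields_its_semtype(self):
        assert cs.select_anchor_semtype([_pattern("P", "dsyn", 1.0, 1)]) == "dsyn"

    def test_full_tie_resolved_lexicographically(self):
        top = [
            _pattern("A", "topp", 1.0, 1),
            _pattern("B", "gngm", 1.0, 2),
            _pattern("C", "aapp", 1.0, 3),
        ]
        assert cs.select_anchor_semtype(top) == "aapp"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cs.select_anchor_semtype([])


class TestConnectivitySubset:
    def test_seed_record_excluded_even_with_anchor_type(self):
        corpus = make_corpus([("G gene", "gngm", "ASSOCIATED_WITH", SEED, "neop")])
        assert len(cs.connectivity_subset(corpus, SEED, "gngm")) == 0

    def test_seed_free_anchor_record_included(self):
        corpus = make_corpus(
            [("G gene", "gngm", "ASSOCIATED_WITH", "Neoplasm progression", "neop")]
        )
        assert len(cs.connectivity_subset(corpus, SEED, "gngm")) == 1

    def test_disjoint_from_relevance_subset(self, bundle):
        novel = bundle.foreground
        relevance = cs.filter_by_concept(novel, SEED)
        connectivity = cs.connectivity_subset(novel, SEED, "gngm")
        assert set(relevance.records).isdisjoint(connectivity.records)


class TestComboPipeline:
    def test_planted_relevance_pattern_order(self, combo_summary):
        keys = [
            (p.key.bound_semtype, p.key.predicate) for p in combo_summary.relevance_patterns
        ]
        assert keys == [
            ("gngm", "ASSOCIATED_WITH"),
            ("gngm", "PREDISPOSES"),
            ("aapp", "ASSOCIATED_WITH"),
            ("aapp", "PREDISPOSES"),
        ]
        assert [p.rank for p in combo_summary.relevance_patterns] == [1, 2, 3, 4]

    def test_anchor_and_connectivity_pattern(self, combo_summary):
        assert combo_summary.anchor_semtype == "gngm"
        top = combo_summary.connectivity_patterns[0]
        assert (top.key.predicate, top.key.bound_semtype) == ("ASSOCIATED_WITH", "neop")
        assert top.key.side is cs.Side.OBJECT

    def test_stage_containment_and_disjointness(self, bundle, combo_summary):
        relevance_pool = cs.filter_by_concept(bundle.foreground, SEED)
        assert set(combo_summary.relevance_salient.records) <= set(relevance_pool.records)
        assert all(r.mentions(SEED) for r in combo_summary.relevance_salient)
        assert not any(r.mentions(SEED) for r in combo_summary.connectivity_salient)
        assert all(
            r.has_semtype(combo_summary.anchor_semtype)
            for r in combo_summary.connectivity_salient
        )

    def test_determinism(self, bundle):
        config = cs.SummaryConfig(seed_concept=SEED)
        first = cs.summarize(bundle.foreground, bundle.background, config)
        second = cs.summarize(bundle.foreground, bundle.background, config)
        assert first.to_dict() == second.to_dict()

    def test_seed_absent_names_near_misses(self, bundle):
        config = cs.SummaryConfig(seed_concept="Carcinoma of gallbladder")
        with pytest.raises(cs.SeedNotFoundError, match="Carcinoma of bladder"):
            cs.summarize(bundle.foreground, bundle.background, config)

    def test_degenerate_equal_distributions_flagged(self):
        fg = make_corpus([("G gene", "gngm", "ASSOCIATED_WITH", SEED, "neop")] * 5)
        bg = cs.StageBackgrounds(relevance=cs.PredicateCountTable({"ASSOCIATED_WITH": 7}))
        result = cs.summarize(fg, bg, cs.SummaryConfig(seed_concept=SEED))
        assert all(p.combo == 0.0 for p in result.relevance_patterns)
        assert any("tie rule" in note for note in result.log)

    def test_top_k_configurable(self, bundle):
        config = cs.SummaryConfig(seed_concept=SEED, top_relevance_patterns=1)
        result = cs.summarize(bundle.foreground, bundle.background, config)
        assert len(result.relevance_patterns) == 1
        assert len(result.relevance_salient) == result.relevance_patterns[0].count


class TestStageBackgrounds:
    def _tables(self, bundle):
        relevance = cs.predicate_counts(cs.filter_by_concept(bundle.background, SEED))
        connectivity = cs.predicate_counts(
            cs.connectivity_subset(bundle.background, SEED, "gngm")
        )
        return relevance, connectivity

    def test_preaggregated_tables_match_corpus_route(self, bundle, combo_summary):
        relevance, connectivity = self._tables(bundle)
        tables = cs.StageBackgrounds(relevance, connectivity, connectivity_anchor="gngm")
        result = cs.summarize(
            bundle.foreground, tables, cs.SummaryConfig(seed_concept=SEED)
        )
        assert result.to_dict() == combo_summary.to_dict()

    def test_anchor_mismatch_is_an_error(self, bundle):
        relevance, connectivity = self._tables(bundle)
        tables = cs.StageBackgrounds(relevance, connectivity, connectivity_anchor="aapp")
        with pytest.raises(cs.BackgroundRestrictionError, match="aapp"):
            cs.summarize(bundle.foreground, tables, cs.SummaryConfig(seed_concept=SEED))

    def test_missing_connectivity_table_is_an_error(self, bundle):
        relevance, _ = self._tables(bundle)
        tables = cs.StageBackgrounds(relevance)
        with pytest.raises(cs.BackgroundRestrictionError):
            cs.summarize(bundle.foreground, tables, cs.SummaryConfig(seed_concept=SEED))


class TestMethodArms:
    def test_kld_arm_selects_top_predicates_and_keeps_their_records(self, bundle):
        config = cs.SummaryConfig(seed_concept=SEED, method=cs.Method.KLD_ONLY)
        result = cs.summarize(bundle.foreground, bundle.background, config)
        selected = [p.key.predicate for p in result.relevance_patterns]
        assert len(selected) == 4
        assert selected[:2] == ["ASSOCIATED_WITH", "PREDISPOSES"]
        assert all(p.key.bound_semtype == WILDCARD_SEMTYPE for p in result.relevance_patterns)
        relevance_pool = cs.filter_by_concept(bundle.foreground, SEED)
        expected = [r for r in relevance_pool if r.predicate in set(selected)]
        assert list(result.relevance_salient) == expected
        assert result.anchor_semtype == "gngm"  # most frequent non-seed semtype
        assert len(result.connectivity_patterns) == 1

    def test_rlogf_arm_ranks_side_pooled_pairs_without_background(self, bundle):
        config = cs.SummaryConfig(seed_concept=SEED, method=cs.Method.RLOGF_ONLY)
        result = cs.summarize(bundle.foreground, bundle.background, config)
        assert len(result.relevance_patterns) == 4
        # a saturated binding (all 20 INHIBITS records carry phsu) outranks
        # the strongest frequent binding, as RlogF alone rewards saturation
        top = result.relevance_patterns[0]
        assert (top.key.predicate, top.key.bound_semtype) == ("INHIBITS", "phsu")
        assert top.rlogf == pytest.approx(log2(20), abs=1e-12)
        second = result.relevance_patterns[1]
        assert (second.key.predicate, second.key.bound_semtype) == ("ASSOCIATED_WITH", "gngm")
        assert second.rlogf == pytest.approx(4.218344839, abs=1e-9)
        assert all(p.kld_term is None for p in result.relevance_patterns)
        scores = [p.score for p in result.relevance_patterns]
        assert scores == sorted(scores, reverse=True)

    def test_arm_consistency_on_single_semtype_equal_kld_corpus(self):
        # two predicates, one semtype each, with equal positive KLD terms:
        # COMBO and RLOGF_ONLY must select the same predicates
        rows = [("G gene", "gngm", "ALPHA", SEED, "neop")] * 10 + [
            ("D", "dsyn", "BETA", SEED, "neop")
        ] * 10
        fg = make_corpus(rows)
        bg = cs.StageBackgrounds(
            relevance=cs.PredicateCountTable({"ALPHA": 25, "BETA": 25, "GAMMA": 50})
        )
        combo = cs.summarize(
            fg, bg, cs.SummaryConfig(seed_concept=SEED, top_relevance_patterns=2)
        )
        rlogf = cs.summarize(
            fg,
            bg,
            cs.SummaryConfig(
                seed_concept=SEED, method=cs.Method.RLOGF_ONLY, top_relevance_patterns=2
            ),
        )
        assert {p.key.predicate for p in combo.relevance_patterns} == {
            p.key.predicate for p in rlogf.relevance_patterns
        }

    @pytest.mark.parametrize("method", list(cs.Method))
    def test_salient_output_contained_in_novelty_filtered_input(self, bundle, method):
        config = cs.SummaryConfig(seed_concept=SEED, method=method)
        result = cs.summarize(bundle.foreground, bundle.background, config)
        pool = set(bundle.foreground.records)
        assert set(result.relevance_salient.records) <= pool
        assert set(result.connectivity_salient.records) <= pool
        assert set(result.relevance_salient.records).isdisjoint(
            result.connectivity_salient.records
        )


def test_empty_connectivity_stage_is_logged_not_fatal():
    fg = make_corpus([("G gene", "gngm", "ASSOCIATED_WITH", SEED, "neop")] * 3)
    bg = cs.StageBackgrounds(relevance=cs.PredicateCountTable({"ASSOCIATED_WITH": 9}))
    result = cs.summarize(fg, bg, cs.SummaryConfig(seed_concept=SEED))
    assert result.connectivity_patterns == ()
    assert len(result.connectivity_salient) == 0
    assert any("connectivity" in note for note in result.log)
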