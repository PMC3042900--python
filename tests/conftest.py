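import pytest

import combosum as cs


@pytest.fixture(scope="session")
def bundle() -> cs.PipelineFixture:
    return cs.fixture_full_pipeline()


@pytest.fixture(scope="session")
def relevance_corpus() -> cs.PredicationCorpus:
    return cs.fixture_relevance()


@pytest.fixture(scope="session")
def combo_summary(bundle) -> cs.SummaryResult:
    config = cs.SummaryConfig(seed_concept="Carcinoma of bladder")
    return cs.summarize(bundle.foreground, bundle.background, config)


def make_corpus(rows) -> cs.PredicationCorpus:
    """Build a corpus from (subject, s_st, predicate, object, o_st) tuples."""
    return cs.PredicationCorpus(
        tuple(
            cs.Predication(f"C{i:04d}", s, sst, p, o, ost)
            for i, (s, sst, p, o, ost) in enumerate(rows)
        )
    )


#: Sampling law used by the randomized property tests: a genetic point of
#: view on a neoplasm seed topic, with ASSOCIATED_WITH+gngm enriched in the
#: foreground relative to the flat background below.
SAMPLING_LAW = dict(
    predicate_weights={
        "ASSOCIATED_WITH": 0.35,
        "TREATS": 0.2,
        "ISA": 0.15,
        "AFFECTS": 0.1,
        "COEXISTS_WITH": 0.1,
        "PART_OF": 0.1,
    },
    semtype_pair_weights={
        "ASSOCIATED_WITH": {("gngm", "neop"): 0.7, ("dsyn", "neop"): 0.3},
        "TREATS": {("topp", "neop"): 1.0},
        "ISA": {("dsyn", "neop"): 1.0},
        "AFFECTS": {("dsyn", "neop"): 0.5, ("topp", "neop"): 0.5},
        "COEXISTS_WITH": {("fndg", "neop"): 1.0},
        "PART_OF": {("tisu", "neop"): 1.0},
    },
    entity_vocab={
        "gngm": [f"G{i:02d} gene" for i in range(30)],
        "dsyn": [f"Disorder {i}" for i in range(10)],
        "topp": [f"Therapy {i}" for i in range(10)],
        "fndg": [f"Finding {i}" for i in range(10)],
        "tisu": [f"Tissue {i}" for i in range(10)],
        "neop": ["Neoplasm progression", "Carcinoma in situ"],
    },
)

FLAT_BACKGROUND = cs.PredicateCountTable(
    {
        "ASSOCIATED_WITH": 100,
        "TREATS": 180,
        "ISA": 180,
        "AFFECTS": 180,
        "COEXISTS_WITH": 180,
        "PART_OF": 180,
    },
    restriction="flat background, all points of view",
)
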