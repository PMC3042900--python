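"""Synthetic predication corpora with controlled statistical structure.

Real inputs to pattern scoring are (a) a *foreground* corpus of predications
returned by a slanted literature query — its predicate distribution skewed
toward the point of view — and (b) a flatter *background* corpus
representing all points of view on the same seed topic.  The generator here
emulates exactly that structure: weighted categorical sampling of
predicates, semantic-type pairs and entity names, with a configurable seed
topic inclusion rate.  It does not emulate extractor linguistics or real
MEDLINE frequencies; see the methods note for what that implies.

The ``fixture_*`` functions build fully deterministic corpora and tables
whose declared compositions are self-verifying (recounting them reproduces
the constants they were built from).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .evaluation import DISCARD, NormalizationTable
from .predications import Predication, PredicationCorpus, PredicateCountTable


class ValidationError(ValueError):
    """A SynthConfig field is out of range; the message lists the fields."""


PairWeights = Mapping[tuple[str, str], float]


@dataclass(frozen=True)
class SynthConfig:
    """Sampling law for a synthetic corpus.

    ``predicate_weights`` set the predicate distribution;
    ``semtype_pair_weights`` set (subject, object) semantic-type pairs,
    either globally or per predicate; ``seed_inclusion_rate`` is the
    fraction of records carrying the seed topic, ``seed_side_rate`` the
    probability that the seed occupies the object slot (its semantic type
    then overrides the sampled slot type).  Entity names are drawn
    uniformly per semantic type from ``entity_vocab``.
    """

    n_records: int
    predicate_weights: Mapping[str, float]
    semtype_pair_weights: PairWeights | Mapping[str, PairWeights]
    seed_concept: str = "Carcinoma of bladder"
    seed_semtype: str = "neop"
    seed_inclusion_rate: float = 1.0
    seed_side_rate: float = 1.0
    entity_vocab: Mapping[str, Sequence[str]] = field(default_factory=dict)
    rng_seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_records < 0:
            problems.append("n_records must be >= 0")
        if not self.predicate_weights:
            problems.append("predicate_weights must be non-empty")
        if any(w <= 0 for w in self.predicate_weights.values()):
            problems.append("predicate_weights must all be positive")
        for rate_name in ("seed_inclusion_rate", "seed_side_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                problems.append(f"{rate_name} must be in [0, 1]")
        per_pred = self._per_predicate()
        if per_pred is None:
            problems.append("semtype_pair_weights must be non-empty")
        else:
            for pred, pairs in per_pred.items():
                if not pairs or any(w <= 0 for w in pairs.values()):
                    problems.append(f"semtype pair weights for {pred!r} must be positive")
                for s_st, o_st in pairs:
                    for st in (s_st, o_st):
                        if not self.entity_vocab.get(st):
                            problems.append(f"entity_vocab missing names for semtype {st!r}")
        if problems:
            raise ValidationError("; ".join(sorted(set(problems))))

    def _per_predicate(self) -> dict[str, dict[tuple[str, str], float]] | None:
        if not self.semtype_pair_weights:
            return None
        first_value = next(iter(self.semtype_pair_weights.values()))
        if isinstance(first_value, Mapping):
            table = {p: dict(v) for p, v in self.semtype_pair_weights.items()}
            missing = set(self.predicate_weights) - set(table)
            if missing:
                raise ValidationError(
                    f"semtype_pair_weights missing predicates: {sorted(missing)}"
                )
            return table
        shared = dict(self.semtype_pair_weights)  # type: ignore[arg-type]
        return {p: shared for p in self.predicate_weights}


def generate_corpus(config: SynthConfig) -> PredicationCorpus:
    """Draw ``n_records`` predications; identical configs give identical corpora."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    predicates = sorted(config.predicate_weights)
    pred_p = np.array([config.predicate_weights[p] for p in predicates], dtype=float)
    pred_p /= pred_p.sum()
    per_pred = config._per_predicate()
    assert per_pred is not None

    n = config.n_records
    pred_idx = rng.choice(len(predicates), size=n, p=pred_p) if n else np.empty(0, int)
    seed_mask = rng.random(n) < config.seed_inclusion_rate
    object_side = rng.random(n) < config.seed_side_rate

    # pair sampling, vectorized per predicate group
    subj_st = np.empty(n, dtype=object)
    obj_st = np.empty(n, dtype=object)
    for j, pred in enumerate(predicates):
        mask = pred_idx == j
        k = int(mask.sum())
        if not k:
            continue
        pairs = sorted(per_pred[pred])
        weights = np.array([per_pred[pred][p] for p in pairs], dtype=float)
        drawn = rng.choice(len(pairs), size=k, p=weights / weights.sum())
        subj_st[mask] = [pairs[d][0] for d in drawn]
        obj_st[mask] = [pairs[d][1] for d in drawn]

    seed_on_object = seed_mask & object_side
    seed_on_subject = seed_mask & ~object_side
    subj_st[seed_on_subject] = config.seed_semtype
    obj_st[seed_on_object] = config.seed_semtype

    # name drawing, vectorized per semantic type
    subjects = np.empty(n, dtype=object)
    objects = np.empty(n, dtype=object)
    subjects[seed_on_subject] = config.seed_concept
    objects[seed_on_object] = config.seed_concept
    for slot_st, names, fixed in (
        (subj_st, subjects, seed_on_subject),
        (obj_st, objects, seed_on_object),
    ):
        open_slots = ~fixed
        for st in sorted({s for s in slot_st[open_slots]}):
            mask = open_slots & (slot_st == st)
            vocab = config.entity_vocab[st]
            picks = rng.integers(len(vocab), size=int(mask.sum()))
            names[mask] = [vocab[i] for i in picks]

    records = [
        Predication(
            f"S{i:07d}", subjects[i], subj_st[i], predicates[pred_idx[i]],
            objects[i], obj_st[i],
        )
        for i in range(n)
    ]
    return PredicationCorpus(tuple(records), provenance=f"synthetic(rng_seed={config.rng_seed})")


def fixture_kld_example() -> tuple[PredicateCountTable, PredicateCountTable]:
    """Smallest integer count tables realizing foreground relative frequency
    0.290 and background 0.076 for ASSOCIATED_WITH (29/100 vs 76/1000)."""
    foreground = PredicateCountTable(
        {"ASSOCIATED_WITH": 29, "OTHER": 71},
        restriction="seed-topic predications, single point of view",
    )
    background = PredicateCountTable(
        {"ASSOCIATED_WITH": 76, "OTHER": 924},
        restriction="seed-topic predications, all points of view",
    )
    return foreground, background


_SEED = "Carcinoma of bladder"

#: Reference-standard genes for the curation evaluation fixture, with the
#: eight recovered by the statistical summarizers marked True.
_REFERENCE_RECOVERY = {
    "FGFR3": True, "XPD": True, "RAG1": False, "TP53": True, "MTCYB": False,
    "HRAS": True, "NAT2": True, "RB1": True, "TSC1": True, "ATM": False,
    "TGFB1": False, "MDM2": True, "ERBB3": False,
}


class PipelineFixture(NamedTuple):
    foreground: PredicationCorpus
    background: PredicationCorpus
    reference: set[str]
    validity: dict[str, str]
    normalization: NormalizationTable


def _seeded(cid: str, subject: str, s_st: str, pred: str) -> Predication:
    return Predication(cid, subject, s_st, pred, _SEED, "neop")


def fixture_relevance() -> PredicationCorpus:
    """Deterministic seed-topic corpus with 16 unique predicates in which
    gngm binds ASSOCIATED_WITH 107 times out of 171 non-seed slots, so
    RlogF(gngm, ASSOCIATED_WITH) = log2(107)*(107/171) and PredScal = 1/4."""
    records = []
    cid = iter(range(10_000_000))

    def add(pred: str, semtype: str, count: int, name_stem: str) -> None:
        for i in range(count):
            records.append(
                _seeded(f"R{next(cid):07d}", f"{name_stem} {i % 10}", semtype, pred)
            )

    add("ASSOCIATED_WITH", "gngm", 107, "Gene")
    add("ASSOCIATED_WITH", "aapp", 40, "Protein")
    add("ASSOCIATED_WITH", "cell", 24, "Cell line")
    # 15 further predicates complete the 16-predicate vocabulary
    fillers = [
        ("PREDISPOSES", "gngm", 12), ("TREATS", "topp", 12), ("ISA", "dsyn", 10),
        ("AFFECTS", "celf", 8), ("PART_OF", "tisu", 8), ("COEXISTS_WITH", "dsyn", 6),
        ("CAUSES", "phsu", 6), ("INHIBITS", "phsu", 5), ("STIMULATES", "phsu", 5),
        ("INTERACTS_WITH", "aapp", 4), ("LOCATION_OF", "tisu", 4),
        ("PROCESS_OF", "popg", 3), ("DIAGNOSES", "topp", 3), ("DISRUPTS", "celf", 2),
        ("AUGMENTS", "gngm", 2),
    ]
    for pred, semtype, count in fillers:
        add(pred, semtype, count, semtype.capitalize())
    return PredicationCorpus(tuple(records), provenance="fixture_relevance")


def fixture_full_pipeline() -> PipelineFixture:
    """End-to-end deterministic bundle with planted structure.

    The foreground's seed-containing records are engineered so Combo ranks,
    in order, [gngm] ASSOCIATED_WITH, [gngm] PREDISPOSES,
    [aapp] ASSOCIATED_WITH, [aapp] PREDISPOSES; the anchor semtype is gngm,
    and the top connectivity pattern is gngm ASSOCIATED_WITH [neop].  Gene
    names planted in the salient records normalize to exactly 74 symbols —
    8 reference genes (5 reference genes stay unmentioned), 52 extra genes
    labeled TP and 14 labeled FP — so the curation evaluation yields
    8 TP / 5 FN recall and 60 TP / 14 FP precision.
    """
    recovered = [g for g, hit in _REFERENCE_RECOVERY.items() if hit]
    extra_tp = [f"BCG{i:02d}" for i in range(1, 53)]
    extra_fp = [f"BCF{i:02d}" for i in range(1, 15)]
    asserted = recovered + extra_tp + extra_fp  # 74 symbols

    gene_names = [f"{s} gene" for s in asserted]
    protein_names = [f"{s} protein" for s in asserted]

    mapping = {f"{s} gene": s for s in asserted}
    mapping.update({f"{s} protein": s for s in asserted})
    mapping["Proteins"] = DISCARD
    normalization = NormalizationTable(mapping)
    validity = {**{s: "TP" for s in extra_tp}, **{s: "FP" for s in extra_fp}}

    records = []
    cid = iter(range(10_000_000))

    def add_seeded(pred: str, semtype: str, names: list[str], count: int) -> None:
        for i in range(count):
            records.append(
                _seeded(f"F{next(cid):07d}", names[i % len(names)], semtype, pred)
            )

    # Relevance block: 510 seed-containing records over 14 predicates.
    # ASSOCIATED_WITH is strongly enriched vs the background (0.335 vs
    # 0.100), PREDISPOSES moderately (0.125 vs 0.025); every other
    # predicate is rarer in the foreground, so its KLD term is negative.
    add_seeded("ASSOCIATED_WITH", "gngm", gene_names, 107)
    add_seeded("ASSOCIATED_WITH", "aapp", ["Proteins"] + protein_names, 40)
    add_seeded("ASSOCIATED_WITH", "cell", [f"Cell line {i}" for i in range(8)], 24)
    add_seeded("PREDISPOSES", "gngm", gene_names, 40)
    add_seeded("PREDISPOSES", "aapp", protein_names, 20)
    add_seeded("PREDISPOSES", "cell", [f"Cell line {i}" for i in range(4)], 4)
    add_seeded("TREATS", "topp", [f"Therapy {i}" for i in range(7)], 40)
    add_seeded("TREATS", "phsu", [f"Drug {i}" for i in range(7)], 40)
    add_seeded("AFFECTS", "celf", [f"Cell process {i}" for i in range(5)], 20)
    add_seeded("AFFECTS", "dsyn", [f"Disorder {i}" for i in range(5)], 20)
    add_seeded("PART_OF", "tisu", [f"Tissue {i}" for i in range(5)], 15)
    add_seeded("PART_OF", "cell", [f"Cell line {i}" for i in range(5)], 15)
    add_seeded("ISA", "dsyn", [f"Disorder {i}" for i in range(5)], 15)
    add_seeded("ISA", "neop", [f"Tumor type {i}" for i in range(5)], 15)
    add_seeded("COEXISTS_WITH", "dsyn", [f"Disorder {i}" for i in range(5)], 10)
    add_seeded("COEXISTS_WITH", "fndg", [f"Finding {i}" for i in range(5)], 10)
    add_seeded("INHIBITS", "phsu", [f"Drug {i}" for i in range(5)], 20)
    add_seeded("STIMULATES", "phsu", [f"Drug {i}" for i in range(5)], 15)
    add_seeded("INTERACTS_WITH", "phsu", [f"Drug {i}" for i in range(5)], 10)
    add_seeded("LOCATION_OF", "tisu", [f"Tissue {i}" for i in range(5)], 10)
    add_seeded("PROCESS_OF", "popg", [f"Population {i}" for i in range(5)], 10)
    add_seeded("DIAGNOSES", "topp", [f"Assay {i}" for i in range(5)], 5)
    add_seeded("CAUSES", "phsu", [f"Drug {i}" for i in range(5)], 5)

    # Connectivity block: 165 seed-free gngm records; ASSOCIATED_WITH with
    # a neop partner dominates (60 of 80) and is foreground-enriched.
    neop_partners = ["Neoplasm progression", "Carcinoma, Transitional Cell"]
    for i in range(60):
        records.append(
            Predication(
                f"F{next(cid):07d}", gene_names[i % len(gene_names)], "gngm",
                "ASSOCIATED_WITH", neop_partners[i % 2], "neop",
            )
        )
    for i in range(20):
        records.append(
            Predication(
                f"F{next(cid):07d}", gene_names[i % len(gene_names)], "gngm",
                "ASSOCIATED_WITH", f"Disorder {i % 5}", "dsyn",
            )
        )
    conn_fillers = [
        ("INTERACTS_WITH", 30, "gngm", gene_names),
        ("STIMULATES", 20, "aapp", protein_names),
        ("INHIBITS", 20, "aapp", protein_names),
        ("PART_OF", 15, "cell", [f"Cell line {i}" for i in range(5)]),
    ]
    for pred, count, o_st, names in conn_fillers:
        for i in range(count):
            records.append(
                Predication(
                    f"F{next(cid):07d}", gene_names[(i + 7) % len(gene_names)], "gngm",
                    pred, names[i % len(names)], o_st,
                )
            )
    foreground = PredicationCorpus(tuple(records), provenance="fixture_full_pipeline/foreground")

    # Background: 1000 seed-containing records (flat, all points of view)
    # and 400 seed-free gngm records for the connectivity restriction.
    bg_records = []
    bg_cid = iter(range(10_000_000))
    bg_relevance = [
        ("ASSOCIATED_WITH", 100), ("PREDISPOSES", 25), ("TREATS", 210),
        ("AFFECTS", 120), ("PART_OF", 80), ("ISA", 150), ("COEXISTS_WITH", 100),
        ("INHIBITS", 50), ("STIMULATES", 40), ("INTERACTS_WITH", 30),
        ("LOCATION_OF", 30), ("PROCESS_OF", 30), ("DIAGNOSES", 20), ("CAUSES", 15),
    ]
    for pred, count in bg_relevance:
        for i in range(count):
            bg_records.append(
                _seeded(f"B{next(bg_cid):07d}", f"Background concept {i % 50}", "dsyn", pred)
            )
    bg_connectivity = [
        ("ASSOCIATED_WITH", 50, "neop", neop_partners),
        ("INTERACTS_WITH", 100, "gngm", [f"BG{i:03d} gene" for i in range(40)]),
        ("STIMULATES", 80, "aapp", [f"BG{i:03d} protein" for i in range(40)]),
        ("INHIBITS", 80, "aapp", [f"BG{i:03d} protein" for i in range(40)]),
        ("PART_OF", 90, "cell", [f"Cell line {i}" for i in range(5)]),
    ]
    for pred, count, o_st, names in bg_connectivity:
        for i in range(count):
            bg_records.append(
                Predication(
                    f"B{next(bg_cid):07d}", f"BG{i % 40:03d} gene", "gngm",
                    pred, names[i % len(names)], o_st,
                )
            )
    background = PredicationCorpus(tuple(bg_records), provenance="fixture_full_pipeline/background")

    return PipelineFixture(
        foreground=foreground,
        background=background,
        reference=set(_REFERENCE_RECOVERY),
        validity=validity,
        normalization=normalization,
    )
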