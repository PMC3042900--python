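"""Saliency metrics: per-predicate KLD terms, RlogF, PredScal, and Combo.

The Combo score ranks *predication patterns* — a predicate bound to the
semantic type of its non-anchor argument — by how strongly they express the
point of view of a foreground corpus relative to a background corpus:

* ``KLD term``: one predicate's contribution ``P(x) * log2(P(x)/Q(x))`` to
  the Kullback-Leibler divergence between the foreground predicate
  distribution P and the background distribution Q.  Only predicates shared
  by both distributions are compared; terms may be negative, and no
  renormalization is applied after the restriction.
* ``RlogF``: ``log2(count) * count/total`` where ``count`` is how often a
  semantic type is bound to the predicate and ``total`` pools all non-anchor
  semantic-type occurrences for that predicate.  The log flattens the
  probability space, rewarding types that are strongly bound while still
  rewarding frequent moderately-bound ones.
* ``PredScal``: ``1/log2(c)``, with ``c`` the number of unique predicates in
  the foreground, scales RlogF to the predicate-space size.
* ``Combo = RlogF * PredScal * KLD``.

All logarithms are base 2.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from math import isclose, log2

from .predications import Predication, PredicationCorpus, PredicateCountTable

logger = logging.getLogger(__name__)


class DisjointDistributionsError(ValueError):
    """Two predicate distributions share no predicate."""


class EmptyStageError(ValueError):
    """A scoring stage received an empty foreground corpus."""


class Side(Enum):
    """Which argument slot the bound (non-anchor) semantic type occupies."""

    SUBJECT = "subject"
    OBJECT = "object"

    @property
    def order(self) -> int:  # SUBJECT sorts before OBJECT in tie-breaks
        return 0 if self is Side.SUBJECT else 1


@dataclass(frozen=True)
class PredicateDistribution:
    """Relative predicate frequencies of a (restricted) corpus."""

    rel_freq: dict[str, float]
    support_total: int

    def __post_init__(self) -> None:
        if self.support_total <= 0:
            raise ValueError("support_total must be positive")
        if not self.rel_freq:
            raise ValueError("distribution has no predicates")
        for pred, p in self.rel_freq.items():
            if p <= 0:
                raise ValueError(f"proportion for {pred!r} must be > 0, got {p}")
        if not isclose(sum(self.rel_freq.values()), 1.0, abs_tol=1e-9):
            raise ValueError("proportions must sum to 1 within 1e-9")

    @classmethod
    def from_counts(cls, table: PredicateCountTable) -> "PredicateDistribution":
        total = table.total
        return cls({p: n / total for p, n in table.counts.items()}, support_total=total)


@dataclass(frozen=True)
class Anchor:
    """The argument held fixed while scoring: a seed concept or a semtype.

    In relevance-stage scoring the anchor is the seed topic concept (e.g.
    "Carcinoma of bladder"); in connectivity-stage scoring it is the shared
    semantic type carried over from the top relevance patterns (``gngm`` in
    a genetic point of view).
    """

    kind: str  # "concept" | "semtype"
    value: str

    def __post_init__(self) -> None:
        if self.kind not in ("concept", "semtype"):
            raise ValueError(f"anchor kind must be 'concept' or 'semtype', got {self.kind!r}")
        if not self.value:
            raise ValueError("anchor value must be non-empty")

    @classmethod
    def concept(cls, value: str) -> "Anchor":
        return cls("concept", value)

    @classmethod
    def semtype(cls, value: str) -> "Anchor":
        return cls("semtype", value)


WILDCARD_SEMTYPE = "*"  # bound_semtype of predicate-level (KLD-arm) patterns


@dataclass(frozen=True)
class PatternKey:
    """A (predicate, bound semantic type, side) predication pattern.

    ``side`` records which slot the bound type occupied, for reporting;
    ``side=None`` with ``bound_semtype="*"`` denotes a predicate-level
    pattern (used by the KLD-only arm), and ``side=None`` with a concrete
    semtype a side-pooled pair (RlogF-only arm).
    """

    predicate: str
    bound_semtype: str
    side: Side | None

    def __post_init__(self) -> None:
        if not self.predicate or not self.bound_semtype:
            raise ValueError("pattern key fields must be non-empty")

    def display(self, anchor_semtype: str | None = None) -> str:
        """Report form with the bound type bracketed, e.g. ``[gngm] ASSOCIATED_WITH neop``."""
        other = anchor_semtype or "·"
        if self.bound_semtype == WILDCARD_SEMTYPE:
            return self.predicate
        if self.side is Side.SUBJECT:
            return f"[{self.bound_semtype}] {self.predicate} {other}"
        if self.side is Side.OBJECT:
            return f"{other} {self.predicate} [{self.bound_semtype}]"
        return f"{self.predicate} [{self.bound_semtype}]"


@dataclass(frozen=True)
class PatternScore:
    """A scored pattern.

    ``score`` is the quantity the producing method ranked by; for Combo
    scoring it equals ``combo`` and all components are present.  Components
    a method does not compute (e.g. KLD for the RlogF-only arm) are None.
    """

    key: PatternKey
    count: int
    total: int
    rlogf: float | None
    predscal: float | None
    kld_term: float | None
    combo: float | None
    score: float
    rank: int

    def __post_init__(self) -> None:
        if not (1 <= self.count <= self.total):
            raise ValueError(f"need 1 <= count <= total, got {self.count}/{self.total}")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.combo is not None:
            assert self.rlogf is not None and self.predscal is not None and self.kld_term is not None
            product = self.rlogf * self.predscal * self.kld_term
            if not isclose(self.combo, product, rel_tol=1e-12, abs_tol=1e-15):
                raise ValueError("combo must equal rlogf * predscal * kld_term")


def kld_terms(p: PredicateDistribution, q: PredicateDistribution) -> dict[str, float]:
    """Per-predicate divergence terms ``p(x) * log2(p(x)/q(x))``.

    Predicates absent from either distribution are omitted (the comparison
    is restricted to shared predicates, without renormalizing).  Raises
    :class:`DisjointDistributionsError` if nothing is shared.
    """
    shared = p.rel_freq.keys() & q.rel_freq.keys()
    if not shared:
        raise DisjointDistributionsError(
            "distributions share no predicate; KLD comparison is undefined"
        )
    return {x: p.rel_freq[x] * log2(p.rel_freq[x] / q.rel_freq[x]) for x in sorted(shared)}


def rlogf_score(count: int, total: int) -> float:
    """``log2(count) * (count/total)`` for a type–predicate binding.

    ``count`` is the frequency of one semantic type bound to the predicate,
    ``total`` the frequency of all non-anchor semantic types bound to it.
    """
    if count < 1 or count > total:
        raise ValueError(f"need 1 <= count <= total, got count={count}, total={total}")
    return log2(count) * (count / total)


def predscal(c: int) -> float:
    """``1/log2(c)`` for ``c`` unique predicates; 1.0 for the degenerate c <= 2.

    ``c = 2`` gives 1.0 analytically; ``c = 1`` would divide by zero and is
    defined as 1.0 (no scaling in a near-trivial predicate vocabulary).
    """
    if c <= 0:
        raise ValueError(f"unique predicate count must be positive, got {c}")
    if c <= 2:
        return 1.0
    return 1.0 / log2(c)


def combo_score(rlogf: float, predscal_factor: float, kld_term: float) -> float:
    """``(RlogF * PredScal) * KLD``; the sign follows the KLD term's sign."""
    if predscal_factor <= 0:
        raise ValueError("predscal factor must be positive")
    return rlogf * predscal_factor * kld_term


def bound_slot(record: Predication, anchor: Anchor) -> tuple[str, Side]:
    """The (semantic type, side) of the record's non-anchor argument.

    For a concept anchor, the slot holding the concept is the anchor slot;
    for a semtype anchor, the first slot (subject preferred) carrying the
    type is.  A record where both slots qualify binds the object slot's
    type, so every record maps to exactly one pattern.
    """
    if anchor.kind == "concept":
        if record.subject_name.casefold() == anchor.value.casefold() or (
            record.subject_cui and record.subject_cui.upper() == anchor.value.upper()
        ):
            return record.object_semtype, Side.OBJECT
        if record.mentions(anchor.value):
            return record.subject_semtype, Side.SUBJECT
        raise ValueError(
            f"record {record.citation_id!r} does not mention anchor concept {anchor.value!r}"
        )
    if record.subject_semtype == anchor.value:
        return record.object_semtype, Side.OBJECT
    if record.object_semtype == anchor.value:
        return record.subject_semtype, Side.SUBJECT
    raise ValueError(
        f"record {record.citation_id!r} does not carry anchor semtype {anchor.value!r}"
    )


def pattern_sort_key(score: float, count: int, key: PatternKey) -> tuple:
    """Deterministic rank order: score desc, count desc, predicate asc,
    bound semtype asc, SUBJECT before OBJECT (pooled/None last)."""
    side_order = key.side.order if key.side is not None else 2
    return (-score, -count, key.predicate, key.bound_semtype, side_order)


def score_patterns(
    foreground: PredicationCorpus,
    background_counts: PredicateCountTable,
    anchor: Anchor,
) -> list[PatternScore]:
    """Combo-score every (predicate, non-anchor semtype, side) pattern.

    The foreground must already be restricted to the stage's subset
    (seed-containing records for relevance; seed-free anchor-semtype records
    for connectivity), and the background counts restricted the same way.
    Patterns whose predicate is absent from the background have no KLD term
    and are excluded with a logged warning.
    """
    if not foreground:
        raise EmptyStageError("empty stage input: no foreground predications to score")
    if not background_counts.counts:
        raise ValueError("background count table is empty")

    pattern_counts: Counter[PatternKey] = Counter()
    predicate_totals: Counter[str] = Counter()
    for record in foreground:
        semtype, side = bound_slot(record, anchor)
        pattern_counts[PatternKey(record.predicate, semtype, side)] += 1
        predicate_totals[record.predicate] += 1

    p = PredicateDistribution(
        {pred: n / len(foreground) for pred, n in predicate_totals.items()},
        support_total=len(foreground),
    )
    q = PredicateDistribution.from_counts(background_counts)
    terms = kld_terms(p, q)

    missing = sorted(set(predicate_totals) - set(terms))
    if missing:
        logger.warning(
            "excluding %d predicate(s) absent from the background (no KLD term): %s",
            len(missing),
            ", ".join(missing),
        )

    c = len(predicate_totals)
    scale = predscal(c)
    scored = []
    for key, count in pattern_counts.items():
        if key.predicate not in terms:
            continue
        total = predicate_totals[key.predicate]
        rl = rlogf_score(count, total)
        term = terms[key.predicate]
        scored.append((key, count, total, rl, term, combo_score(rl, scale, term)))

    scored.sort(key=lambda t: pattern_sort_key(t[5], t[1], t[0]))
    return [
        PatternScore(
            key=key, count=count, total=total, rlogf=rl, predscal=scale,
            kld_term=term, combo=combo, score=combo, rank=rank,
        )
        for rank, (key, count, total, rl, term, combo) in enumerate(scored, start=1)
    ]
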