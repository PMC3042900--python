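"""The four-filter summarization pipeline and its three method arms.

Summarization narrows a corpus of semantic predications to the assertions
salient to a user-chosen *seed topic* and point of view in four sequential
filters:

1. **Novelty** — discard assertions about overly general concepts (here an
   explicit concept stoplist, default empty).
2. **Relevance** — keep predications carrying the seed topic as an
   argument, score their patterns against the seed-restricted background,
   and retain records matching the top-k patterns (default 4).
3. **Connectivity** — from the top relevance patterns pick the *anchor*
   semantic type, then repeat the analysis on seed-free predications that
   carry the anchor type, retaining records matching the top pattern
   (default 1).
4. **Saliency** — the pattern scoring itself: the Combo method ranks
   (predicate, non-anchor semtype, side) patterns by RlogF*PredScal*KLD;
   the comparison arms rank bare predicates by their KLD term, or
   side-pooled (predicate, semtype) pairs by RlogF.
"""

from __future__ import annotations

import difflib
import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Union

from .metrics import (
    Anchor,
    DisjointDistributionsError,
    PatternKey,
    PatternScore,
    PredicateDistribution,
    WILDCARD_SEMTYPE,
    bound_slot,
    kld_terms,
    pattern_sort_key,
    rlogf_score,
    score_patterns,
)
from .predications import (
    PredicationCorpus,
    PredicateCountTable,
    filter_by_concept,
    predicate_counts,
)

logger = logging.getLogger(__name__)


class Method(Enum):
    COMBO = "combo"
    KLD_ONLY = "kld"
    RLOGF_ONLY = "rlogf"


class SeedNotFoundError(ValueError):
    """The seed topic appears nowhere in the (novelty-filtered) foreground."""


class BackgroundRestrictionError(ValueError):
    """The background lacks the restriction a stage requires."""


DEFAULT_ENTITY_SEMTYPES = frozenset({"gngm", "aapp"})


@dataclass(frozen=True)
class SummaryConfig:
    """Knobs of the pipeline; defaults follow standard practice of keeping
    the four top relevance patterns and the single top connectivity pattern."""

    seed_concept: str
    method: Method = Method.COMBO
    top_relevance_patterns: int = 4
    top_connectivity_patterns: int = 1
    novelty_stoplist: frozenset[str] = frozenset()
    entity_semtypes: frozenset[str] = DEFAULT_ENTITY_SEMTYPES

    def __post_init__(self) -> None:
        if not self.seed_concept:
            raise ValueError("seed_concept must be non-empty")
        if self.top_relevance_patterns < 1 or self.top_connectivity_patterns < 1:
            raise ValueError("top-k pattern counts must be >= 1")
        object.__setattr__(self, "novelty_stoplist", frozenset(self.novelty_stoplist))
        object.__setattr__(self, "entity_semtypes", frozenset(self.entity_semtypes))


@dataclass(frozen=True)
class StageBackgrounds:
    """Pre-aggregated per-stage background predicate counts.

    For users who cannot share a full background corpus: ``relevance`` holds
    counts over seed-containing background predications; ``connectivity``
    counts over seed-free predications carrying ``connectivity_anchor``.
    """

    relevance: PredicateCountTable
    connectivity: PredicateCountTable | None = None
    connectivity_anchor: str | None = None


Background = Union[PredicationCorpus, StageBackgrounds]


@dataclass(frozen=True)
class SummaryResult:
    seed_concept: str
    method: Method
    relevance_patterns: tuple[PatternScore, ...]
    relevance_salient: PredicationCorpus
    anchor_semtype: str
    connectivity_patterns: tuple[PatternScore, ...]
    connectivity_salient: PredicationCorpus
    log: tuple[str, ...]

    @property
    def seed_semtype(self) -> str | None:
        """Semantic type the seed concept carries in the salient records."""
        for rec in self.relevance_salient:
            if rec.subject_name.casefold() == self.seed_concept.casefold():
                return rec.subject_semtype
            if rec.object_name.casefold() == self.seed_concept.casefold():
                return rec.object_semtype
        return None

    def to_dict(self) -> dict:
        def pattern(ps: PatternScore, anchor: str | None) -> dict:
            return {
                "rank": ps.rank,
                "pattern": ps.key.display(anchor),
                "predicate": ps.key.predicate,
                "bound_semtype": ps.key.bound_semtype,
                "side": ps.key.side.value if ps.key.side else None,
                "count": ps.count,
                "total": ps.total,
                "rlogf": ps.rlogf,
                "predscal": ps.predscal,
                "kld_term": ps.kld_term,
                "combo": ps.combo,
                "score": ps.score,
            }

        seed_st = self.seed_semtype
        return {
            "seed_concept": self.seed_concept,
            "method": self.method.value,
            "anchor_semtype": self.anchor_semtype,
            "relevance_patterns": [pattern(p, seed_st) for p in self.relevance_patterns],
            "relevance_salient": [r.to_line() for r in self.relevance_salient],
            "connectivity_patterns": [
                pattern(p, self.anchor_semtype) for p in self.connectivity_patterns
            ],
            "connectivity_salient": [r.to_line() for r in self.connectivity_salient],
            "log": list(self.log),
        }


def novelty_filter(corpus: PredicationCorpus, stoplist: frozenset[str] | set[str]) -> PredicationCorpus:
    """Drop records whose subject or object name is on the stoplist
    (case-insensitive); an empty stoplist is the identity."""
    if not stoplist:
        return corpus
    folded = {s.casefold() for s in stoplist}
    kept = tuple(
        r
        for r in corpus
        if r.subject_name.casefold() not in folded and r.object_name.casefold() not in folded
    )
    return PredicationCorpus(kept, provenance=corpus.provenance)


def select_anchor_semtype(top_patterns: list[PatternScore] | tuple[PatternScore, ...]) -> str:
    """The non-seed semtype occurring in the most top patterns.

    Ties go to the larger summed pattern score, then lexicographically.
    """
    if not top_patterns:
        raise ValueError("cannot select an anchor semtype from zero patterns")
    occurrences: Counter[str] = Counter()
    summed: Counter[str] = Counter()
    for ps in top_patterns:
        st = ps.key.bound_semtype
        if st == WILDCARD_SEMTYPE:
            continue
        occurrences[st] += 1
        summed[st] += ps.score
    if not occurrences:
        raise ValueError("top patterns carry no concrete bound semantic type")
    return min(occurrences, key=lambda st: (-occurrences[st], -summed[st], st))


def connectivity_subset(
    corpus: PredicationCorpus, seed_concept: str, anchor: str
) -> PredicationCorpus:
    """Seed-free records carrying the anchor semtype on at least one slot."""
    if not anchor:
        raise ValueError("anchor semtype must be non-empty")
    kept = tuple(
        r for r in corpus if not r.mentions(seed_concept) and r.has_semtype(anchor)
    )
    return PredicationCorpus(kept, provenance=corpus.provenance)


def _stage_q(table: PredicateCountTable, stage: str) -> PredicateDistribution:
    if not table.counts:
        raise BackgroundRestrictionError(
            f"background restricted for the {stage} stage is empty"
        )
    return PredicateDistribution.from_counts(table)


def _relevance_background(background: Background, seed: str) -> PredicateCountTable:
    if isinstance(background, PredicationCorpus):
        restricted = filter_by_concept(background, seed)
        if not restricted:
            raise BackgroundRestrictionError(
                f"background corpus has no predication mentioning seed {seed!r}"
            )
        return predicate_counts(restricted, restriction=f"seed {seed!r}")
    return background.relevance


def _connectivity_background(
    background: Background, seed: str, anchor: str
) -> PredicateCountTable | None:
    if isinstance(background, PredicationCorpus):
        restricted = connectivity_subset(background, seed, anchor)
        if not restricted:
            return None
        return predicate_counts(restricted, restriction=f"anchor {anchor!r}, seed-free")
    if background.connectivity is None:
        raise BackgroundRestrictionError(
            "connectivity stage requires an anchor-restricted background count table"
        )
    if background.connectivity_anchor and background.connectivity_anchor != anchor:
        raise BackgroundRestrictionError(
            f"supplied connectivity background is restricted to semtype "
            f"{background.connectivity_anchor!r} but the discovered anchor is {anchor!r}"
        )
    return background.connectivity


def _kld_predicate_patterns(
    subset: PredicationCorpus, q_table: PredicateCountTable, stage: str
) -> list[PatternScore]:
    """KLD-only arm: rank bare predicates by their divergence term."""
    counts = Counter(r.predicate for r in subset)
    p = PredicateDistribution(
        {pred: n / len(subset) for pred, n in counts.items()}, support_total=len(subset)
    )
    terms = kld_terms(p, _stage_q(q_table, stage))
    entries = [
        (PatternKey(pred, WILDCARD_SEMTYPE, None), counts[pred], terms[pred])
        for pred in terms
    ]
    entries.sort(key=lambda t: pattern_sort_key(t[2], t[1], t[0]))
    return [
        PatternScore(
            key=key, count=n, total=n, rlogf=None, predscal=None,
            kld_term=term, combo=None, score=term, rank=rank,
        )
        for rank, (key, n, term) in enumerate(entries, start=1)
    ]


def _rlogf_pair_patterns(subset: PredicationCorpus, anchor: Anchor) -> list[PatternScore]:
    """RlogF-only arm: rank side-pooled (predicate, non-anchor semtype) pairs."""
    pair_counts: Counter[tuple[str, str]] = Counter()
    totals: Counter[str] = Counter()
    for r in subset:
        semtype, _side = bound_slot(r, anchor)
        pair_counts[(r.predicate, semtype)] += 1
        totals[r.predicate] += 1
    entries = []
    for (pred, st), n in pair_counts.items():
        key = PatternKey(pred, st, None)
        entries.append((key, n, totals[pred], rlogf_score(n, totals[pred])))
    entries.sort(key=lambda t: pattern_sort_key(t[3], t[1], t[0]))
    return [
        PatternScore(
            key=key, count=n, total=total, rlogf=rl, predscal=None,
            kld_term=None, combo=None, score=rl, rank=rank,
        )
        for rank, (key, n, total, rl) in enumerate(entries, start=1)
    ]


def _matches(record, key: PatternKey, anchor: Anchor) -> bool:
    if record.predicate != key.predicate:
        return False
    if key.bound_semtype == WILDCARD_SEMTYPE:
        return True
    semtype, side = bound_slot(record, anchor)
    if key.side is None:
        return semtype == key.bound_semtype
    return semtype == key.bound_semtype and side is key.side


def _select_records(
    subset: PredicationCorpus, selected: list[PatternScore], anchor: Anchor
) -> PredicationCorpus:
    keys = [ps.key for ps in selected]
    kept = tuple(r for r in subset if any(_matches(r, k, anchor) for k in keys))
    return PredicationCorpus(kept, provenance=subset.provenance)


def _kld_arm_anchor(salient: PredicationCorpus, seed: str) -> str:
    """Most frequent non-seed semtype among salient relevance records
    (frequency ties broken lexicographically)."""
    anchor = Anchor.concept(seed)
    counts: Counter[str] = Counter(bound_slot(r, anchor)[0] for r in salient)
    return min(counts, key=lambda st: (-counts[st], st))


def summarize(
    foreground: PredicationCorpus,
    background: Background,
    config: SummaryConfig,
) -> SummaryResult:
    """Run the four-filter pipeline for the configured method arm."""
    if not foreground:
        raise ValueError("foreground corpus is empty")
    log: list[str] = []
    seed = config.seed_concept

    novel = novelty_filter(foreground, config.novelty_stoplist)
    log.append(
        f"novelty: {len(foreground)} -> {len(novel)} records "
        f"({len(config.novelty_stoplist)} stoplist concepts)"
    )

    rel_subset = filter_by_concept(novel, seed)
    if not rel_subset:
        names = sorted({r.subject_name for r in novel} | {r.object_name for r in novel})
        near = difflib.get_close_matches(seed, names, n=5, cutoff=0.0)
        raise SeedNotFoundError(
            f"seed topic {seed!r} not found among arguments; nearest names: {near}"
        )
    log.append(f"relevance subset: {len(rel_subset)} seed-containing records")

    rel_bg = _relevance_background(background, seed)
    _stage_q(rel_bg, "relevance")
    seed_anchor = Anchor.concept(seed)

    if config.method is Method.COMBO:
        rel_ranking = score_patterns(rel_subset, rel_bg, seed_anchor)
    elif config.method is Method.KLD_ONLY:
        rel_ranking = _kld_predicate_patterns(rel_subset, rel_bg, "relevance")
    else:
        rel_ranking = _rlogf_pair_patterns(rel_subset, seed_anchor)

    if rel_ranking and all(ps.score == 0 for ps in rel_ranking):
        log.append("relevance: all pattern scores are 0; ranking falls back to the tie rule")

    rel_top = rel_ranking[: config.top_relevance_patterns]
    rel_salient = _select_records(rel_subset, rel_top, seed_anchor)
    log.append(
        f"relevance: kept top {len(rel_top)} of {len(rel_ranking)} patterns "
        f"-> {len(rel_salient)} salient records"
    )

    if config.method is Method.KLD_ONLY:
        anchor_st = _kld_arm_anchor(rel_salient, seed)
    else:
        anchor_st = select_anchor_semtype(rel_top)
    log.append(f"anchor semtype: {anchor_st}")

    conn_subset = connectivity_subset(novel, seed, anchor_st)
    conn_ranking: list[PatternScore] = []
    conn_top: list[PatternScore] = []
    conn_salient = PredicationCorpus()
    if not conn_subset:
        log.append("connectivity: no seed-free records carry the anchor semtype; stage empty")
    else:
        semtype_anchor = Anchor.semtype(anchor_st)
        conn_bg = None
        if config.method is not Method.RLOGF_ONLY:
            conn_bg = _connectivity_background(background, seed, anchor_st)
            if conn_bg is None:
                log.append(
                    "connectivity: background has no anchor-restricted records; stage empty"
                )
        try:
            if config.method is Method.COMBO:
                if conn_bg is not None:
                    conn_ranking = score_patterns(conn_subset, conn_bg, semtype_anchor)
            elif config.method is Method.KLD_ONLY:
                if conn_bg is not None:
                    conn_ranking = _kld_predicate_patterns(conn_subset, conn_bg, "connectivity")
            else:
                conn_ranking = _rlogf_pair_patterns(conn_subset, semtype_anchor)
        except DisjointDistributionsError:
            log.append(
                "connectivity: foreground and background share no predicate; stage empty"
            )
            conn_ranking = []
        if conn_ranking:
            conn_top = conn_ranking[: config.top_connectivity_patterns]
            conn_salient = _select_records(conn_subset, conn_top, semtype_anchor)
            log.append(
                f"connectivity: kept top {len(conn_top)} of {len(conn_ranking)} patterns "
                f"-> {len(conn_salient)} salient records"
            )

    return SummaryResult(
        seed_concept=seed,
        method=config.method,
        relevance_patterns=tuple(rel_top),
        relevance_salient=rel_salient,
        anchor_semtype=anchor_st,
        connectivity_patterns=tuple(conn_top),
        connectivity_salient=conn_salient,
        log=tuple(log),
    )
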