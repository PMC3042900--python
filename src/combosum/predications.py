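"""Semantic predication records and their plain-text dialects.

A *semantic predication* is a normalized subject–PREDICATE–object assertion
distilled from a sentence of biomedical text, e.g.::

    IGF1R gene | gngm | ASSOCIATED_WITH | Carcinoma of bladder | neop

Each argument carries a semantic-type code from the UMLS Semantic Network
(``gngm`` Gene or Genome, ``aapp`` Amino Acid/Peptide/Protein, ``neop``
Neoplastic Process, ``topp`` Therapeutic or Preventive Procedure, ...), and
the whole assertion is tied to the citation it was extracted from.

This module defines the in-memory records and two interchange dialects:

* predication files (suggested extension ``.psv``): UTF-8, pipe-delimited,
  one assertion per line with 6 or 8 fields::

      citation_id|subject_name|subject_semtype|PREDICATE|object_name|object_semtype
      citation_id|subject_name|subject_cui|subject_semtype|PREDICATE|object_name|object_cui|object_semtype

  Lines starting with ``#`` and blank lines are ignored.
* predicate count tables: two-column TSV ``predicate<TAB>count``, ``#``
  comments allowed.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

logger = logging.getLogger(__name__)

_CUI_RE = re.compile(r"^C\d{7}$", re.IGNORECASE)
_SEMTYPE_RE = re.compile(r"^[a-z][a-z0-9]*$")

Source = Union[str, Path, IO[str]]


class ParseError(ValueError):
    """A malformed line in a predication or count-table file."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Predication:
    """One subject–predicate–object assertion from one citation.

    Two predications are equal iff all eight fields (citation included)
    match; duplicates are meaningful, as pattern frequencies drive scoring.
    """

    citation_id: str
    subject_name: str
    subject_semtype: str
    predicate: str
    object_name: str
    object_semtype: str
    subject_cui: str | None = None
    object_cui: str | None = None

    def __post_init__(self) -> None:
        if not self.predicate or "|" in self.predicate:
            raise ValueError(f"invalid predicate {self.predicate!r}")
        for label, st in (("subject", self.subject_semtype), ("object", self.object_semtype)):
            if not _SEMTYPE_RE.match(st):
                raise ValueError(
                    f"{label} semantic type {st!r} must be a non-empty lowercase token"
                )
        for name, value in (
            ("citation_id", self.citation_id),
            ("subject_name", self.subject_name),
            ("object_name", self.object_name),
        ):
            if "|" in value or "\n" in value:
                raise ValueError(f"{name} {value!r} contains a delimiter character")

    def mentions(self, concept: str) -> bool:
        """True if *concept* is an argument of this predication.

        A query of CUI shape (``C`` + 7 digits) is compared against argument
        CUIs; any other string is compared case-insensitively against
        argument names.
        """
        if _CUI_RE.match(concept):
            cui = concept.upper()
            return cui in ((self.subject_cui or "").upper(), (self.object_cui or "").upper())
        folded = concept.casefold()
        return self.subject_name.casefold() == folded or self.object_name.casefold() == folded

    def has_semtype(self, semtype: str) -> bool:
        return semtype in (self.subject_semtype, self.object_semtype)

    def to_line(self) -> str:
        """Serialize in the pipe dialect (8 fields iff both CUIs present)."""
        if self.subject_cui and self.object_cui:
            fields = (
                self.citation_id,
                self.subject_name,
                self.subject_cui,
                self.subject_semtype,
                self.predicate,
                self.object_name,
                self.object_cui,
                self.object_semtype,
            )
        else:
            fields = (
                self.citation_id,
                self.subject_name,
                self.subject_semtype,
                self.predicate,
                self.object_name,
                self.object_semtype,
            )
        return "|".join(fields)

    @classmethod
    def from_line(cls, line: str) -> "Predication":
        parts = [p.strip() for p in line.split("|")]
        if len(parts) == 6:
            cid, sname, sst, pred, oname, ost = parts
            return cls(cid, sname, sst, pred, oname, ost)
        if len(parts) == 8:
            cid, sname, scui, sst, pred, oname, ocui, ost = parts
            return cls(cid, sname, sst, pred, oname, ost, scui or None, ocui or None)
        raise ValueError(f"expected 6 or 8 pipe-delimited fields, got {len(parts)}")


@dataclass(frozen=True)
class PredicationCorpus:
    """An ordered, duplicate-preserving collection of predications."""

    records: tuple[Predication, ...] = ()
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Predication]:
        return iter(self.records)

    def __bool__(self) -> bool:
        return bool(self.records)

    @property
    def unique_predicates(self) -> frozenset[str]:
        return frozenset(r.predicate for r in self.records)

    @property
    def unique_predicate_count(self) -> int:
        """``c`` of the PredScal metric: distinct predicates in the corpus."""
        return len(self.unique_predicates)

    def with_provenance(self, provenance: str) -> "PredicationCorpus":
        return replace(self, provenance=provenance)


@dataclass(frozen=True)
class PredicateCountTable:
    """Raw predicate frequencies over a (restricted) corpus.

    ``restriction`` documents the subset the tally was taken over, e.g.
    "predications containing seed topic Carcinoma of bladder".
    """

    counts: dict[str, int]
    restriction: str = ""

    def __post_init__(self) -> None:
        for pred, n in self.counts.items():
            if not pred:
                raise ValueError("empty predicate in count table")
            if n < 1:
                raise ValueError(f"count for {pred!r} must be >= 1, got {n}")
        # canonical predicate order for deterministic serialization
        object.__setattr__(self, "counts", dict(sorted(self.counts.items())))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, predicate: str) -> bool:
        return predicate in self.counts


def _open_lines(source: Source) -> Iterable[tuple[int, str]]:
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        text = Path(source).read_text(encoding="utf-8")  # type: ignore[arg-type]
    return [(i, line) for i, line in enumerate(text.splitlines(), start=1)]


def read_predications(source: Source, strict: bool = True) -> PredicationCorpus:
    """Parse a predication file into a corpus, preserving record order.

    With ``strict`` on, the first malformed line raises :class:`ParseError`
    naming its line number; with ``strict`` off, malformed lines are
    counted, logged, and skipped.
    """
    records: list[Predication] = []
    skipped = 0
    for lineno, line in _open_lines(source):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        try:
            records.append(Predication.from_line(stripped))
        except ValueError as exc:
            if strict:
                raise ParseError(str(exc), lineno) from exc
            skipped += 1
            logger.warning("skipping malformed line %d: %s", lineno, exc)
    if skipped:
        logger.warning("skipped %d malformed line(s)", skipped)
    provenance = str(source) if not hasattr(source, "read") else ""
    return PredicationCorpus(tuple(records), provenance=provenance)


def write_predications(corpus: PredicationCorpus, sink: str | Path | IO[str]) -> None:
    """Write a corpus in the pipe dialect; deterministic for a given corpus."""
    text = "".join(r.to_line() + "\n" for r in corpus)
    if hasattr(sink, "write"):
        sink.write(text)  # type: ignore[union-attr]
    else:
        Path(sink).write_text(text, encoding="utf-8")


def filter_by_concept(corpus: PredicationCorpus, concept: str) -> PredicationCorpus:
    """Records having *concept* as subject or object argument (order kept)."""
    if not concept:
        raise ValueError("concept must be non-empty")
    kept = tuple(r for r in corpus if r.mentions(concept))
    return PredicationCorpus(kept, provenance=corpus.provenance)


def exclude_concept(corpus: PredicationCorpus, concept: str) -> PredicationCorpus:
    """Complement of :func:`filter_by_concept` over the same corpus."""
    if not concept:
        raise ValueError("concept must be non-empty")
    kept = tuple(r for r in corpus if not r.mentions(concept))
    return PredicationCorpus(kept, provenance=corpus.provenance)


def predicate_counts(corpus: PredicationCorpus, restriction: str = "") -> PredicateCountTable:
    """Tally records per predicate; totals equal the record count."""
    counts = Counter(r.predicate for r in corpus)
    return PredicateCountTable(dict(counts), restriction=restriction or corpus.provenance)


def read_count_table(source: Source, restriction: str = "") -> PredicateCountTable:
    """Read a ``predicate<TAB>count`` table."""
    counts: dict[str, int] = {}
    for lineno, line in _open_lines(source):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t")
        if len(parts) != 2:
            raise ParseError(f"expected 'predicate<TAB>count', got {stripped!r}", lineno)
        pred, raw = parts
        try:
            n = int(raw)
        except ValueError as exc:
            raise ParseError(f"count {raw!r} is not an integer", lineno) from exc
        if pred in counts:
            raise ParseError(f"duplicate predicate {pred!r}", lineno)
        counts[pred] = n
    return PredicateCountTable(counts, restriction=restriction)


def write_count_table(table: PredicateCountTable, sink: str | Path | IO[str]) -> None:
    lines = []
    if table.restriction:
        lines.append(f"# restriction: {table.restriction}")
    lines.extend(f"{pred}\t{n}" for pred, n in table.counts.items())
    text = "".join(line + "\n" for line in lines)
    if hasattr(sink, "write"):
        sink.write(text)  # type: ignore[union-attr]
    else:
        Path(sink).write_text(text, encoding="utf-8")
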