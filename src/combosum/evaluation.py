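"""Genetic-entity extraction and curation-style recall/precision/F scoring.

The evaluation emulates secondary genetic database curation: genetic
entities (gene and protein arguments) are pulled from salient predications,
normalized to gene symbols via a user-supplied table, and compared to a
curated reference gene list.  Asserted genes outside the reference carry an
externally supplied validity label (TP or FP) standing in for manual
review of curated annotations; validity is never computed here.

Printed-figure policy: percentage and F fields are floor-truncated (61.54%
reports as 61%, an F of 0.6959 as 0.69), and the truncated F is computed
from the two-decimal truncated precision and recall.  Exact untruncated
values are always reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Union

from .predications import PredicationCorpus

Source = Union[str, Path, IO[str]]

DISCARD = "DISCARD"


class UnlabeledEntityError(ValueError):
    """An asserted non-reference symbol has no validity label."""


class UnmappedEntityError(ValueError):
    """A raw entity name has no entry in the normalization table."""


@dataclass(frozen=True)
class NormalizationTable:
    """Case-insensitive map from raw entity names to gene symbols.

    A value of :data:`DISCARD` marks names too general to attribute to a
    specific gene; they produce no output symbol.
    """

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        folded: dict[str, str] = {}
        for raw, symbol in self.mapping.items():
            if not raw:
                raise ValueError("empty raw name in normalization table")
            if not symbol:
                raise ValueError(f"empty symbol for raw name {raw!r}")
            key = raw.casefold()
            if key in folded and folded[key] != symbol:
                raise ValueError(f"conflicting entries for {raw!r}")
            folded[key] = symbol
        object.__setattr__(self, "mapping", folded)

    def lookup(self, raw: str) -> str | None:
        return self.mapping.get(raw.casefold())


def _truncate(value: float, decimals: int) -> float:
    scale = 10 ** decimals
    # nudge guards against binary representation of exact decimal ratios
    return math.floor(value * scale + 1e-9) / scale


@dataclass(frozen=True)
class EvaluationResult:
    """Curation-evaluation tallies.

    Recall and precision count true positives differently, mirroring the
    curation protocol: recall is measured against the reference standard
    alone (``reference_tp`` of the reference's genes were asserted), while
    precision credits every asserted gene whose validity review confirmed
    it (``tp = reference_tp + validated extras``).  Hence
    ``reference_tp + fn = |reference|`` and ``tp + fp = |asserted|``.
    """

    tp: int
    fp: int
    fn: int
    reference_tp: int
    recall_pct: int
    precision_pct: int | None
    f_score: float | None
    exact_recall: float
    exact_precision: float | None
    exact_f: float | None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "reference_tp": self.reference_tp,
            "recall_pct": self.recall_pct,
            "precision_pct": self.precision_pct,
            "f_score": self.f_score,
            "exact_recall": self.exact_recall,
            "exact_precision": self.exact_precision,
            "exact_f": self.exact_f,
        }


def extract_entities(
    predications: PredicationCorpus, entity_semtypes: Iterable[str] = ("gngm", "aapp")
) -> set[str]:
    """Unique argument names whose slot carries an entity semantic type."""
    semtypes = frozenset(entity_semtypes)
    if not semtypes:
        raise ValueError("entity_semtypes must be non-empty")
    names: set[str] = set()
    for r in predications:
        if r.subject_semtype in semtypes:
            names.add(r.subject_name)
        if r.object_semtype in semtypes:
            names.add(r.object_name)
    return names


def normalize_entities(
    names: Iterable[str], table: NormalizationTable, strict: bool = False
) -> set[str]:
    """Map raw names to gene symbols; DISCARD-mapped and (non-strict)
    unmapped names are dropped."""
    import logging

    symbols: set[str] = set()
    unmapped: list[str] = []
    for raw in names:
        symbol = table.lookup(raw)
        if symbol is None:
            unmapped.append(raw)
        elif symbol != DISCARD:
            symbols.add(symbol)
    if unmapped:
        if strict:
            raise UnmappedEntityError(
                f"no normalization entry for: {sorted(unmapped)}"
            )
        logging.getLogger(__name__).warning(
            "dropping %d unmapped entity name(s): %s", len(unmapped), sorted(unmapped)
        )
    return symbols


def evaluate(
    asserted: Iterable[str],
    reference: Iterable[str],
    validity: Mapping[str, str] | None = None,
) -> EvaluationResult:
    """Score asserted gene symbols against the curated reference.

    Reference genes that are asserted are true positives by definition;
    every asserted non-reference gene must carry a TP or FP label in
    ``validity`` (curation-review judgment).  False negatives are reference
    genes never asserted.
    """
    asserted_set = set(asserted)
    reference_set = set(reference)
    validity = dict(validity or {})

    extras = asserted_set - reference_set
    unlabeled = sorted(e for e in extras if validity.get(e) not in ("TP", "FP"))
    if unlabeled:
        raise UnlabeledEntityError(
            f"asserted non-reference symbols lack a TP/FP validity label: {unlabeled}"
        )

    reference_tp = len(asserted_set & reference_set)
    tp = reference_tp + sum(1 for e in extras if validity[e] == "TP")
    fp = sum(1 for e in extras if validity[e] == "FP")
    fn = len(reference_set - asserted_set)

    exact_recall = reference_tp / (reference_tp + fn) if (reference_tp + fn) else 0.0
    exact_precision = tp / (tp + fp) if (tp + fp) else None
    recall_pct = int(_truncate(exact_recall * 100, 0))
    precision_pct = (
        int(_truncate(exact_precision * 100, 0)) if exact_precision is not None else None
    )

    if exact_precision is None:
        exact_f = None
        f_score = None
    else:
        denom = exact_precision + exact_recall
        exact_f = 2 * exact_precision * exact_recall / denom if denom else 0.0
        p2, r2 = _truncate(exact_precision, 2), _truncate(exact_recall, 2)
        f_score = _truncate(2 * p2 * r2 / (p2 + r2), 2) if (p2 + r2) else 0.0

    return EvaluationResult(
        tp=tp,
        fp=fp,
        fn=fn,
        reference_tp=reference_tp,
        recall_pct=recall_pct,
        precision_pct=precision_pct,
        f_score=f_score,
        exact_recall=exact_recall,
        exact_precision=exact_precision,
        exact_f=exact_f,
    )


def _read_lines(source: Source) -> list[str]:
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        text = Path(source).read_text(encoding="utf-8")  # type: ignore[arg-type]
    out = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped and not stripped.startswith("#"):
            out.append(stripped)
    return out


def read_normalization_table(source: Source) -> NormalizationTable:
    """Two-column TSV ``raw name<TAB>symbol`` (symbol may be ``DISCARD``)."""
    mapping = {}
    for line in _read_lines(source):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"expected 'raw name<TAB>symbol', got {line!r}")
        mapping[parts[0]] = parts[1]
    return NormalizationTable(mapping)


def read_reference_standard(source: Source) -> set[str]:
    """One gene symbol per line."""
    return set(_read_lines(source))


def read_validity_labels(source: Source) -> dict[str, str]:
    """Two-column TSV ``symbol<TAB>TP|FP``."""
    labels = {}
    for line in _read_lines(source):
        parts = line.split("\t")
        if len(parts) != 2 or parts[1] not in ("TP", "FP"):
            raise ValueError(f"expected 'symbol<TAB>TP|FP', got {line!r}")
        labels[parts[0]] = parts[1]
    return labels


def write_normalization_table(table: NormalizationTable, sink: str | Path) -> None:
    lines = [f"{raw}\t{symbol}" for raw, symbol in sorted(table.mapping.items())]
    Path(sink).write_text("".join(l + "\n" for l in lines), encoding="utf-8")
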