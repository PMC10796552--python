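"""Concept lexicon: the local stand-in for an RxNorm-style drug vocabulary.

A :class:`Concept` plays the role of one RxNorm drug entity — a unique integer
identifier (the RxCUI role), a standardized preferred name (the "RxNorm name"
role) and any number of synonym strings (brand names, generic names, observed
spelling variants).  A :class:`Lexicon` is a validated collection of concepts
with lookup indices, read from / written to a small pipe-delimited file format
that echoes the UMLS/RxNorm RRF style::

    concept_id|term|term_type[|class]

with ``term_type`` one of ``preferred``, ``brand``, ``generic``, ``variant``,
``#``-prefixed comment lines, and UTF-8 text.  The optional fourth column
carries a drug-class annotation (used on the ``preferred`` row).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

__all__ = [
    "TERM_TYPES",
    "Synonym",
    "Concept",
    "Lexicon",
    "LexiconError",
    "LexiconParseError",
    "read_lexicon",
    "write_lexicon",
    "bundled_opioid_lexicon",
]

TERM_TYPES = frozenset({"preferred", "brand", "generic", "variant"})


class LexiconError(ValueError):
    """Invalid lexicon content (duplicate ids, bad term types, ...)."""


class LexiconParseError(LexiconError):
    """Malformed lexicon file; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class Synonym:
    term: str
    term_type: str = "variant"

    def __post_init__(self) -> None:
        if not self.term.strip():
            raise LexiconError("synonym term must be non-empty after trimming")
        if self.term_type not in TERM_TYPES:
            raise LexiconError(
                f"unknown term type {self.term_type!r}; expected one of {sorted(TERM_TYPES)}"
            )


@dataclass
class Concept:
    """One drug entity: integer id, preferred name, synonym terms.

    The preferred name is implicitly a synonym of the concept; ``synonyms``
    holds the *additional* terms.
    """

    concept_id: int
    preferred_name: str
    synonyms: list[Synonym] = field(default_factory=list)
    class_label: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.concept_id, int) or self.concept_id <= 0:
            raise LexiconError(f"concept_id must be a positive integer, got {self.concept_id!r}")
        if not self.preferred_name.strip():
            raise LexiconError(f"concept {self.concept_id}: preferred_name must be non-empty")

    def terms(self) -> Iterator[Synonym]:
        """All synonym terms, preferred name first."""
        yield Synonym(self.preferred_name, "preferred")
        yield from self.synonyms


class Lexicon:
    """Collection of concepts with id and verbatim-term indices.

    Term lookup is case-insensitive and whitespace-trimmed but otherwise
    verbatim (punctuation-sensitive).  Canonical-form indexing lives in
    :mod:`drugnorm.normalize`, which owns the canonicalization rules.
    """

    def __init__(self, concepts: Iterable[Concept] = ()):
        self._concepts: dict[int, Concept] = {}
        self._by_term: dict[str, set[int]] = {}
        for concept in concepts:
            self.add(concept)

    def add(self, concept: Concept) -> None:
        if concept.concept_id in self._concepts:
            raise LexiconError(f"duplicate concept_id {concept.concept_id}")
        self._concepts[concept.concept_id] = concept
        for syn in concept.terms():
            self._by_term.setdefault(_term_key(syn.term), set()).add(concept.concept_id)

    def __len__(self) -> int:
        return len(self._concepts)

    def __iter__(self) -> Iterator[Concept]:
        for cid in sorted(self._concepts):
            yield self._concepts[cid]

    def __contains__(self, concept_id: int) -> bool:
        return concept_id in self._concepts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lexicon):
            return NotImplemented
        return {c.concept_id: (c.preferred_name, sorted((s.term, s.term_type) for s in c.synonyms), c.class_label)
                for c in self} == \
               {c.concept_id: (c.preferred_name, sorted((s.term, s.term_type) for s in c.synonyms), c.class_label)
                for c in other}

    def get(self, concept_id: int) -> Concept:
        try:
            return self._concepts[concept_id]
        except KeyError:
            raise KeyError(f"concept_id {concept_id} not in lexicon") from None

    def lookup_term(self, term: str) -> frozenset[int]:
        """Concept ids whose synonyms contain ``term`` verbatim (case-insensitive)."""
        return frozenset(self._by_term.get(_term_key(term), ()))

    def iter_terms(self) -> Iterator[tuple[str, str, int]]:
        """Yield ``(term, term_type, concept_id)`` over every synonym of every concept."""
        for concept in self:
            for syn in concept.terms():
                yield syn.term, syn.term_type, concept.concept_id

    @property
    def classes(self) -> list[str]:
        """Sorted distinct class labels attached to concepts."""
        return sorted({c.class_label for c in self if c.class_label})


def _term_key(term: str) -> str:
    return term.strip().casefold()


def read_lexicon(source: str | Path | TextIO) -> Lexicon:
    """Parse a pipe-delimited lexicon file into a :class:`Lexicon`.

    Line order is irrelevant: rows are grouped by concept id and each group
    must contain exactly one ``preferred`` row.  Raises
    :class:`LexiconParseError` naming the line for malformed rows and
    :class:`LexiconError` for semantic problems (duplicate preferred names,
    unknown term types, missing preferred row).
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text(encoding="utf-8").splitlines()

    preferred: dict[int, tuple[str, str | None]] = {}
    extra: dict[int, list[Synonym]] = {}
    order_check: dict[int, set[str]] = {}
    for lineno, raw_line in enumerate(lines, start=1):
        line = raw_line.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split("|")]
        if len(fields) < 3:
            raise LexiconParseError(
                f"expected at least 3 pipe-delimited fields, got {len(fields)}: {line!r}",
                lineno,
            )
        cid_text, term, term_type = fields[0], fields[1], fields[2]
        class_label = fields[3] if len(fields) > 3 and fields[3] else None
        try:
            cid = int(cid_text)
        except ValueError:
            raise LexiconParseError(f"concept_id {cid_text!r} is not an integer", lineno) from None
        if cid <= 0:
            raise LexiconParseError(f"concept_id must be positive, got {cid}", lineno)
        if not term:
            raise LexiconParseError("empty term", lineno)
        if term_type not in TERM_TYPES:
            raise LexiconParseError(
                f"unknown term type {term_type!r}; expected one of {sorted(TERM_TYPES)}", lineno
            )
        if term_type == "preferred":
            if cid in preferred:
                raise LexiconError(
                    f"line {lineno}: duplicate preferred name for concept {cid}: "
                    f"{preferred[cid][0]!r} and {term!r}"
                )
            preferred[cid] = (term, class_label)
        else:
            if term_key := _term_key(term):
                seen = order_check.setdefault(cid, set())
                if term_key in seen:
                    continue  # tolerate exact duplicate synonym rows
                seen.add(term_key)
            extra.setdefault(cid, []).append(Synonym(term, term_type))

    missing = sorted(set(extra) - set(preferred))
    if missing:
        raise LexiconError(f"concepts without a preferred row: {missing}")

    lexicon = Lexicon()
    for cid in sorted(preferred):
        name, class_label = preferred[cid]
        synonyms = [s for s in extra.get(cid, []) if _term_key(s.term) != _term_key(name)]
        lexicon.add(Concept(cid, name, synonyms, class_label))
    return lexicon


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write ``lexicon`` in the pipe-delimited format, re-readable by
    :func:`read_lexicon`.  Row order is deterministic: concepts by id,
    preferred row first, then remaining synonyms by (term, term_type)."""
    lines = ["# concept_id|term|term_type[|class]"]
    for concept in lexicon:
        cls = f"|{concept.class_label}" if concept.class_label else ""
        lines.append(f"{concept.concept_id}|{concept.preferred_name}|preferred{cls}")
        for syn in sorted(concept.synonyms, key=lambda s: (s.term, s.term_type)):
            lines.append(f"{concept.concept_id}|{syn.term}|{syn.term_type}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _data_path(name: str):
    return importlib.resources.files("drugnorm") / "data" / name


def bundled_opioid_lexicon() -> Lexicon:
    """The packaged lexicon of 67 FDA-approved prescription-opioid concepts.

    Concepts carry their RxCUI-role identifiers, standardized names and one of
    13 opioid class labels; concepts 214256 (aspirin/oxycodone) and 218337
    (methadone hydrochloride) additionally carry the FAERS name variants
    observed for them, so the bundled lexicon exercises every variant class
    the matcher must handle.
    """
    with importlib.resources.as_file(_data_path("opioid_lexicon.txt")) as path:
        return read_lexicon(path)
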