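"""Tiered drug-name → concept matching with ranked candidate scores.

The matching contract mirrors how terminology services such as the RxNorm API
behave from a client's point of view: a raw name is first tried verbatim
(tier ``exact``), then after canonicalization (tier ``canonical``), and only
then approximately (tier ``approximate``), where every lexicon synonym is
scored against the query and **only the concepts attaining the highest
ranking score are accepted**.  A tie between distinct concepts is reported as
``ambiguous`` rather than resolved silently — residual ambiguity is a matter
for curated overrides (see :func:`map_batch`).

Canonicalization undoes the variation classes that dominate spontaneous
reports: letter case, ingredient order ("oxycodone/aspirin" vs
"aspirin/oxycodone"), conjunction and separator forms ("X and Y", "X-Y",
"X + Y", "X w/Y"), salt abbreviations ("hcl" → "hydrochloride"), bracketed
qualifiers and trailing periods.

The approximate ranking score blends token-set Jaccard similarity with a
normalized character edit distance::

    score = w_tok * J(a, b) + w_edit * (1 - D(a, b) / max(|a|, |b|))

computed on canonical forms; with the default equal weights the score is 1
exactly when the canonical forms coincide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from .lexicon import Lexicon

__all__ = [
    "MatchConfig",
    "MatchCandidate",
    "NormalizationResult",
    "Matcher",
    "canonicalize",
    "score_pair",
    "match_name",
    "map_batch",
    "MATCHED",
    "AMBIGUOUS",
    "UNMATCHED",
]

MATCHED = "matched"
AMBIGUOUS = "ambiguous"
UNMATCHED = "unmatched"

TIER_EXACT = "exact"
TIER_CANONICAL = "canonical"
TIER_APPROXIMATE = "approximate"
TIER_OVERRIDE = "override"
_TIER_ORDER = {TIER_EXACT: 0, TIER_CANONICAL: 1, TIER_APPROXIMATE: 2}

DEFAULT_ABBREVIATIONS: Mapping[str, str] = MappingProxyType(
    {
        "hcl": "hydrochloride",
        "asa": "aspirin",
        "w/": "with",
        "apap": "acetaminophen",
    }
)
DEFAULT_STOPWORDS = frozenset({"and", "with", "de"})

_BRACKETED = re.compile(r"\([^()]*\)|\[[^\[\]]*\]")
_SEPARATORS = re.compile(r"[/+?\-]+")


@dataclass(frozen=True)
class MatchConfig:
    """Tunable knobs of the matcher.

    ``min_score`` is the approximate-tier acceptance floor.  The default 0.40
    is set so that a single-character edit on the shortest names in a typical
    drug lexicon (5 letters, score 0.5·(1−1/5) = 0.40) is still accepted,
    while the nearest cross-concept pairs score well below the winning
    candidate and unrelated strings fall far under the floor; acceptance is
    always restricted to the top-ranked concepts, so the floor only decides
    when *no* concept is credible.
    """

    min_score: float = 0.40
    abbreviations: Mapping[str, str] = field(default_factory=lambda: DEFAULT_ABBREVIATIONS)
    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    weight_token: float = 0.5
    weight_edit: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_score <= 1.0:
            raise ValueError(f"min_score must be in [0, 1], got {self.min_score}")
        if abs(self.weight_token + self.weight_edit - 1.0) > 1e-9:
            raise ValueError("weight_token + weight_edit must equal 1")


DEFAULT_CONFIG = MatchConfig()


@dataclass(frozen=True, order=True)
class MatchCandidate:
    """One scored concept candidate; sorts by tier precedence, score desc, id asc."""

    sort_index: tuple = field(init=False, repr=False, compare=True)
    concept_id: int = field(compare=False)
    score: float = field(compare=False)
    tier: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.tier == TIER_EXACT and self.score != 1.0:
            raise ValueError("exact-tier candidates must have score 1")
        object.__setattr__(
            self, "sort_index", (_TIER_ORDER[self.tier], -self.score, self.concept_id)
        )


@dataclass(frozen=True)
class NormalizationResult:
    raw_name: str
    accepted: tuple[int, ...]
    candidates: tuple[MatchCandidate, ...]
    status: str

    def __post_init__(self) -> None:
        if self.status == MATCHED and len(self.accepted) != 1:
            raise ValueError("matched results carry exactly one accepted concept")
        if self.status == AMBIGUOUS and len(self.accepted) < 2:
            raise ValueError("ambiguous results carry at least two accepted concepts")
        if self.status == UNMATCHED and self.accepted:
            raise ValueError("unmatched results carry no accepted concept")

    @property
    def concept_id(self) -> int | None:
        """The single accepted concept id, or ``None``."""
        return self.accepted[0] if self.status == MATCHED else None

    @property
    def best_score(self) -> float:
        return self.candidates[0].score if self.candidates else 0.0


def canonicalize(raw: str, config: MatchConfig = DEFAULT_CONFIG) -> str:
    """Reduce a raw drug-name string to its canonical form.

    Lowercase; bracketed/parenthesized qualifiers removed; separators
    ``/ - + ?`` collapsed to spaces; trailing periods stripped; abbreviations
    expanded; stopwords dropped; tokens sorted alphabetically and joined by
    single spaces.  Idempotent for any abbreviation table whose values are
    fixed points of the expansion.
    """
    s = raw.strip().lower()
    # peel bracketed qualifiers innermost-out so nested brackets vanish too
    while True:
        stripped = _BRACKETED.sub(" ", s)
        if stripped == s:
            break
        s = stripped
    # abbreviation keys that contain separator characters (e.g. "w/") must be
    # expanded before separators are collapsed
    for key, expansion in config.abbreviations.items():
        if _SEPARATORS.search(key):
            s = re.sub(rf"(?<![a-z0-9]){re.escape(key)}", f" {expansion} ", s)
    s = _SEPARATORS.sub(" ", s)
    tokens: list[str] = []
    for token in s.split():
        # stray unbalanced brackets and trailing periods are noise
        token = token.strip("()[].")
        if not token:
            continue
        token = config.abbreviations.get(token, token)
        if token in config.stopwords:
            continue
        tokens.append(token)
    return " ".join(sorted(tokens))


def score_pair(a: str, b: str, config: MatchConfig = DEFAULT_CONFIG) -> float:
    """Ranking score of two *canonical* strings in [0, 1].

    Symmetric; 0 when both inputs are empty; 1 exactly when ``a == b``
    (non-empty).  Token similarity is set Jaccard; character similarity is
    1 − Levenshtein/maxlen.
    """
    if not a and not b:
        return 0.0
    tokens_a, tokens_b = set(a.split()), set(b.split())
    union = tokens_a | tokens_b
    jaccard = len(tokens_a & tokens_b) / len(union) if union else 0.0
    distance = edlib.align(a, b)["editDistance"]
    maxlen = max(len(a), len(b))
    edit_sim = 1.0 - distance / maxlen
    return config.weight_token * jaccard + config.weight_edit * edit_sim


class Matcher:
    """A lexicon bound to a configuration, with precomputed indices.

    Prefer one :class:`Matcher` (or :func:`map_batch`) for many lookups; the
    module-level :func:`match_name` rebuilds indices per call.
    """

    def __init__(self, lexicon: Lexicon, config: MatchConfig = DEFAULT_CONFIG):
        if len(lexicon) == 0:
            raise ValueError("cannot match against an empty lexicon")
        self.lexicon = lexicon
        self.config = config
        self._canonical_index: dict[str, set[int]] = {}
        self._canonical_terms: list[tuple[str, int]] = []
        seen: set[tuple[str, int]] = set()
        for term, _term_type, cid in lexicon.iter_terms():
            canon = canonicalize(term, config)
            if not canon:
                continue
            self._canonical_index.setdefault(canon, set()).add(cid)
            if (canon, cid) not in seen:
                seen.add((canon, cid))
                self._canonical_terms.append((canon, cid))
        self._cache: dict[str, NormalizationResult] = {}

    def match(self, raw: str) -> NormalizationResult:
        key = raw.strip()
        result = self._cache.get(key)
        if result is None:
            result = self._match_uncached(key)
            self._cache[key] = result
        return replace(result, raw_name=raw)

    def _match_uncached(self, raw: str) -> NormalizationResult:
        if not raw:
            return NormalizationResult(raw, (), (), UNMATCHED)

        ids = self.lexicon.lookup_term(raw)
        if ids:
            return _accept(raw, ids, 1.0, TIER_EXACT)

        canon = canonicalize(raw, self.config)
        ids = self._canonical_index.get(canon, set()) if canon else set()
        if ids:
            return _accept(raw, ids, 1.0, TIER_CANONICAL)

        best_by_concept: dict[int, float] = {}
        score_cache: dict[str, float] = {}
        for term_canon, cid in self._canonical_terms:
            score = score_cache.get(term_canon)
            if score is None:
                score = score_pair(canon, term_canon, self.config)
                score_cache[term_canon] = score
            if score > best_by_concept.get(cid, -1.0):
                best_by_concept[cid] = score
        candidates = tuple(
            sorted(
                MatchCandidate(concept_id=cid, score=score, tier=TIER_APPROXIMATE)
                for cid, score in best_by_concept.items()
                if score >= self.config.min_score
            )
        )
        if not candidates:
            return NormalizationResult(raw, (), (), UNMATCHED)
        top = candidates[0].score
        accepted = tuple(sorted(c.concept_id for c in candidates if c.score == top))
        status = MATCHED if len(accepted) == 1 else AMBIGUOUS
        return NormalizationResult(raw, accepted, candidates, status)


def _accept(raw: str, ids: Iterable[int], score: float, tier: str) -> NormalizationResult:
    accepted = tuple(sorted(ids))
    candidates = tuple(
        MatchCandidate(concept_id=cid, score=score, tier=tier) for cid in accepted
    )
    status = MATCHED if len(accepted) == 1 else AMBIGUOUS
    return NormalizationResult(raw, accepted, candidates, status)


def match_name(
    raw: str, lexicon: Lexicon, config: MatchConfig = DEFAULT_CONFIG
) -> NormalizationResult:
    """Match one raw name against ``lexicon``; see :class:`Matcher`."""
    return Matcher(lexicon, config).match(raw)


MAPPING_COLUMNS = ["raw_name", "concept_id", "preferred_name", "status", "score", "tier"]


def map_batch(
    names: Sequence[str],
    lexicon: Lexicon,
    config: MatchConfig = DEFAULT_CONFIG,
    overrides: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Map a batch of raw names; one row per *distinct* name, first-seen order.

    ``overrides`` (raw name → concept id) realize curated manual corrections
    and take precedence over the matcher; an override naming a concept absent
    from the lexicon raises ``ValueError``.  Returns a DataFrame with columns
    ``raw_name, concept_id, preferred_name, status, score, tier`` where
    ``concept_id`` is nullable.
    """
    overrides = dict(overrides or {})
    for raw, cid in overrides.items():
        if cid not in lexicon:
            raise ValueError(f"override {raw!r} -> {cid}: concept_id not in lexicon")

    rows = []
    seen: set[str] = set()
    matcher = Matcher(lexicon, config) if len(lexicon) else None
    for name in names:
        if name in seen:
            continue
        seen.add(name)
        if name in overrides:
            cid = overrides[name]
            rows.append((name, cid, lexicon.get(cid).preferred_name, MATCHED, 1.0, TIER_OVERRIDE))
            continue
        if matcher is None:
            rows.append((name, None, None, UNMATCHED, 0.0, None))
            continue
        res = matcher.match(name)
        cid = res.concept_id
        rows.append(
            (
                name,
                cid,
                lexicon.get(cid).preferred_name if cid is not None else None,
                res.status,
                res.best_score,
                res.candidates[0].tier if res.candidates else None,
            )
        )
    frame = pd.DataFrame(rows, columns=MAPPING_COLUMNS)
    frame["concept_id"] = frame["concept_id"].astype("Int64")
    return frame
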