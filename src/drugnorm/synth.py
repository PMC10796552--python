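"""Synthetic FAERS-dialect corpora with known ground truth.

Real spontaneous reports corrupt standardized drug names in a handful of
recurring ways: ingredient-order inversion ("oxycodone/aspirin" for
"aspirin/oxycodone"), conjunction forms ("oxycodone and aspirin"), separator
variation ("-", " + ", " w/"), salt abbreviations ("hcl", "asa"), trailing
punctuation, case jitter, and occasional single-character misspellings.  The
generator draws concepts with a Zipf-skewed usage distribution (a handful of
names dominate real corpora), applies each corruption operator independently
with its configured probability, and emits a valid reportset XML document
together with a complete ground-truth table, enabling end-to-end recovery
testing of the matcher without any external download.

Misspellings are single-character edits on one token, never on the first
character, which keeps the recovery behaviour analyzable; all other operators
are exactly inverted by canonicalization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .lexicon import Lexicon
from .normalize import AMBIGUOUS, MATCHED, UNMATCHED

__all__ = [
    "CorruptionModel",
    "RecoveryMetrics",
    "corrupt_name",
    "generate_corpus",
    "write_corpus",
    "recovery_metrics",
    "REACTION_VOCABULARY",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = ["report_id", "raw_name", "concept_id"]

# placeholder MedDRA-PT-like reaction strings; reaction semantics are out of scope
REACTION_VOCABULARY = (
    "Nausea",
    "Vomiting",
    "Dizziness",
    "Somnolence",
    "Respiratory depression",
    "Constipation",
    "Pruritus",
    "Headache",
    "Drug ineffective",
    "Overdose",
)

SALT_ABBREVIATIONS = {"hydrochloride": "hcl", "aspirin": "asa"}
_SWAP_SEPARATORS = ("-", " + ", " w/")
_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class CorruptionModel:
    """Per-operator corruption probabilities plus corpus-shape parameters.

    Defaults make every operator observable in a corpus of a few thousand
    mentions while keeping most mentions recognizable; the identity model
    (all probabilities zero) leaves names unchanged.  ``zipf_exponent``
    controls how strongly usage concentrates on the most-used concepts;
    ``names_per_report`` / ``reactions_per_report`` are inclusive ranges.
    """

    ingredient_inversion: float = 0.15
    conjunction_form: float = 0.15
    separator_swap: float = 0.20
    salt_abbreviation: float = 0.25
    trailing_period: float = 0.10
    case_jitter: float = 0.10
    misspelling: float = 0.05
    zipf_exponent: float = 1.5
    names_per_report: tuple[int, int] = (1, 3)
    reactions_per_report: tuple[int, int] = (0, 3)

    def __post_init__(self) -> None:
        for name in (
            "ingredient_inversion",
            "conjunction_form",
            "separator_swap",
            "salt_abbreviation",
            "trailing_period",
            "case_jitter",
            "misspelling",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} probability must be in [0, 1], got {p}")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        for name in ("names_per_report", "reactions_per_report"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a (lo, hi) range with 0 <= lo <= hi")

    @classmethod
    def identity(cls) -> "CorruptionModel":
        return cls(
            ingredient_inversion=0.0,
            conjunction_form=0.0,
            separator_swap=0.0,
            salt_abbreviation=0.0,
            trailing_period=0.0,
            case_jitter=0.0,
            misspelling=0.0,
        )

    def replace(self, **changes) -> "CorruptionModel":
        return dataclasses.replace(self, **changes)


def _misspell_token(token: str, rng: np.random.Generator) -> str:
    """One random single-character edit, never at position 0."""
    if len(token) < 2:
        return token
    op = rng.choice(("substitute", "delete", "insert"))
    if op == "insert":
        pos = int(rng.integers(1, len(token) + 1))
        return token[:pos] + rng.choice(list(_LETTERS)) + token[pos:]
    pos = int(rng.integers(1, len(token)))
    if op == "delete":
        return token[:pos] + token[pos + 1 :]
    alternatives = [c for c in _LETTERS if c != token[pos]]
    return token[:pos] + rng.choice(alternatives) + token[pos + 1 :]


def corrupt_name(preferred: str, model: CorruptionModel, rng: np.random.Generator) -> str:
    """Corrupt one preferred name; deterministic given the generator state.

    Operators fire independently with their probabilities; multi-ingredient
    operators (inversion, conjunction, separator swap) are no-ops on
    single-ingredient names.  Conjunction and separator swap both rewrite the
    ingredient joiner, so conjunction takes precedence when both fire.
    """
    if not preferred:
        raise ValueError("preferred name must be non-empty")
    parts = [p.strip() for p in preferred.split("/")]
    multi = len(parts) > 1
    fire = {name: rng.random() < getattr(model, name) for name in (
        "ingredient_inversion",
        "conjunction_form",
        "separator_swap",
        "salt_abbreviation",
        "misspelling",
        "case_jitter",
        "trailing_period",
    )}
    if multi and fire["ingredient_inversion"]:
        parts = parts[::-1]
    separator = "/"
    if multi and fire["conjunction_form"]:
        separator = " and "
    elif multi and fire["separator_swap"]:
        separator = str(rng.choice(_SWAP_SEPARATORS))
    name = separator.join(parts)
    if fire["salt_abbreviation"]:
        tokens = name.split(" ")
        name = " ".join(SALT_ABBREVIATIONS.get(t, t) for t in tokens)
    if fire["misspelling"]:
        tokens = name.split(" ")
        editable = [i for i, t in enumerate(tokens) if len(t) >= 2]
        if editable:
            i = int(rng.choice(editable))
            tokens[i] = _misspell_token(tokens[i], rng)
            name = " ".join(tokens)
    if fire["case_jitter"]:
        name = name.upper() if rng.random() < 0.5 else name.title()
    if fire["trailing_period"]:
        name = name + "."
    return name


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    weights = ranks ** -exponent
    return weights / weights.sum()


def generate_corpus(
    lexicon: Lexicon,
    n_reports: int,
    model: CorruptionModel | None = None,
    seed: int = 0,
) -> tuple[str, pd.DataFrame]:
    """Generate a reportset XML document and its ground truth.

    Concepts are drawn with Zipf weights over the lexicon (rank order =
    concept-id order, deterministic and seed-independent); each mention's raw
    name is a corruption of the concept's preferred name.  Returns the XML as
    a string plus a DataFrame with columns ``report_id, raw_name,
    concept_id`` (one row per emitted mention).  Identical seeds produce
    byte-identical corpora.
    """
    if n_reports < 0:
        raise ValueError("n_reports must be >= 0")
    model = model or CorruptionModel()
    if n_reports > 0 and len(lexicon) == 0:
        raise ValueError("cannot generate mentions from an empty lexicon")
    rng = np.random.default_rng(seed)
    concepts = list(lexicon)
    weights = _zipf_weights(len(concepts), model.zipf_exponent) if concepts else None

    lines = ['<?xml version="1.0" encoding="UTF-8"?>', "<reportset>"]
    truth_rows: list[tuple[str, str, int]] = []
    lo_n, hi_n = model.names_per_report
    lo_r, hi_r = model.reactions_per_report
    for i in range(n_reports):
        report_id = f"R{i + 1:07d}"
        lines.append("  <safetyreport>")
        lines.append(f"    <safetyreportid>{report_id}</safetyreportid>")
        lines.append("    <patient>")
        n_names = int(rng.integers(lo_n, hi_n + 1))
        for _ in range(n_names):
            concept = concepts[int(rng.choice(len(concepts), p=weights))]
            raw = corrupt_name(concept.preferred_name, model, rng)
            truth_rows.append((report_id, raw, concept.concept_id))
            lines.append(
                f"      <drug><medicinalproduct>{escape(raw)}</medicinalproduct></drug>"
            )
        n_reactions = int(rng.integers(lo_r, hi_r + 1))
        for _ in range(n_reactions):
            reaction = REACTION_VOCABULARY[int(rng.choice(len(REACTION_VOCABULARY)))]
            lines.append(
                f"      <reaction><reactionmeddrapt>{escape(reaction)}</reactionmeddrapt></reaction>"
            )
        lines.append("    </patient>")
        lines.append("  </safetyreport>")
    lines.append("</reportset>")
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    if truth.empty:
        truth = truth.astype({"concept_id": int})
    return "\n".join(lines) + "\n", truth


def write_corpus(
    lexicon: Lexicon,
    n_reports: int,
    corpus_path: str | Path,
    truth_path: str | Path | None = None,
    model: CorruptionModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a corpus and write the XML (and optionally the truth TSV)."""
    xml, truth = generate_corpus(lexicon, n_reports, model, seed)
    Path(corpus_path).write_text(xml, encoding="utf-8")
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


@dataclass(frozen=True)
class RecoveryMetrics:
    """Mention-level recovery of true concepts by the matcher."""

    accuracy: float
    n_mentions: int
    n_correct: int
    status_counts: dict[str, int]


def recovery_metrics(mapping: pd.DataFrame, truth: pd.DataFrame) -> RecoveryMetrics:
    """Fraction of mentions whose accepted concept equals the true concept.

    ``mapping`` is a batch-mapping table over (at least) the distinct raw
    names of ``truth``; a truth name absent from the mapping raises
    ``KeyError``.  Ambiguous and unmatched mentions count as failures and are
    tallied separately in ``status_counts``.
    """
    by_name = mapping.set_index("raw_name")
    missing = sorted(set(truth["raw_name"]) - set(by_name.index))
    if missing:
        raise KeyError(f"truth names absent from mapping: {missing[:5]}...")
    n_mentions = len(truth)
    if n_mentions == 0:
        return RecoveryMetrics(0.0, 0, 0, {MATCHED: 0, AMBIGUOUS: 0, UNMATCHED: 0})
    joined = truth.rename(columns={"concept_id": "true_concept_id"}).join(
        by_name[["concept_id", "status"]], on="raw_name"
    )
    correct = (joined["status"] == MATCHED) & (
        joined["concept_id"].astype("Int64") == joined["true_concept_id"].astype("Int64")
    )
    status_counts = {
        status: int((joined["status"] == status).sum())
        for status in (MATCHED, AMBIGUOUS, UNMATCHED)
    }
    return RecoveryMetrics(
        accuracy=float(correct.sum() / n_mentions),
        n_mentions=n_mentions,
        n_correct=int(correct.sum()),
        status_counts=status_counts,
    )
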