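"""Reference set of drugs under study (e.g. FDA-approved prescription opioids).

An approved-drug list — rows of ``(name, is_target, class)`` — models the
human step of flagging the drugs of interest on a regulatory list.  Flagged
names are mapped to concepts with the tiered matcher; the resulting
:class:`ReferenceSet` is the membership filter for every downstream statistic.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple

import pandas as pd

from .lexicon import Lexicon
from .normalize import AMBIGUOUS, MATCHED, UNMATCHED, DEFAULT_CONFIG, MatchConfig, Matcher

__all__ = [
    "ReferenceSet",
    "FilterResult",
    "read_approved_list",
    "bundled_approved_list",
    "build_reference_set",
    "filter_to_reference",
]

APPROVED_COLUMNS = ["name", "is_target", "class"]
_TRUE_VALUES = {"true", "1", "yes", "y"}


@dataclass(frozen=True)
class ReferenceSet:
    """Class-annotated concepts under study.

    ``entries`` is a DataFrame with columns ``concept_id, preferred_name,
    class`` (unique concept ids); ``unmatched_names`` records flagged
    approved-list names the matcher could not map, so they are reported
    rather than silently dropped.
    """

    entries: pd.DataFrame
    unmatched_names: tuple[str, ...] = ()
    concept_ids: frozenset[int] = field(init=False)

    def __post_init__(self) -> None:
        ids = self.entries["concept_id"].tolist()
        if len(ids) != len(set(ids)):
            raise ValueError("reference set concept_ids must be unique")
        object.__setattr__(self, "concept_ids", frozenset(int(i) for i in ids))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, concept_id: int) -> bool:
        return concept_id in self.concept_ids

    @property
    def classes(self) -> list[str]:
        return sorted(self.entries["class"].dropna().unique())

    def preferred_names(self) -> dict[int, str]:
        return dict(zip(self.entries["concept_id"], self.entries["preferred_name"]))

    def to_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


class FilterResult(NamedTuple):
    """Partition of a mapping table by reference membership."""

    retained: pd.DataFrame
    out_of_reference: pd.DataFrame
    unresolved: pd.DataFrame  # unmatched + ambiguous rows


def read_approved_list(source: str | Path) -> pd.DataFrame:
    """Read a TSV approved-drug list with columns ``name, is_target, class``."""
    frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in APPROVED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"approved list missing columns: {missing}")
    frame["is_target"] = frame["is_target"].str.strip().str.lower().isin(_TRUE_VALUES)
    frame["class"] = frame["class"].str.strip().replace("", None)
    return frame[APPROVED_COLUMNS]


def bundled_approved_list() -> pd.DataFrame:
    """The packaged approved-drug fixture: 67 flagged opioids plus unflagged decoys."""
    path = importlib.resources.files("drugnorm") / "data" / "approved_drugs.tsv"
    with importlib.resources.as_file(path) as file:
        return read_approved_list(file)


def build_reference_set(
    approved: pd.DataFrame,
    lexicon: Lexicon,
    config: MatchConfig = DEFAULT_CONFIG,
    overrides: Mapping[str, int] | None = None,
) -> ReferenceSet:
    """Map flagged approved-list names to concepts and assemble the reference set.

    Deterministic and insensitive to input row order.  Distinct flagged
    spellings that resolve to one concept are merged into a single entry (the
    first class label by name order wins; in practice labels agree).  An
    ambiguous mapping without an override raises ``ValueError`` listing the
    candidate concepts.
    """
    flagged = approved.loc[approved["is_target"], ["name", "class"]]
    missing_class = flagged.loc[flagged["class"].isna(), "name"].tolist()
    if missing_class:
        raise ValueError(f"flagged approved-list rows lack a class label: {missing_class}")

    overrides = dict(overrides or {})
    matcher = Matcher(lexicon, config) if len(lexicon) else None
    by_concept: dict[int, tuple[str, str]] = {}
    unmatched: list[str] = []
    for name, class_label in sorted(zip(flagged["name"], flagged["class"])):
        if name in overrides:
            cid = overrides[name]
            if cid not in lexicon:
                raise ValueError(f"override {name!r} -> {cid}: concept_id not in lexicon")
        elif matcher is None:
            unmatched.append(name)
            continue
        else:
            result = matcher.match(name)
            if result.status == AMBIGUOUS:
                raise ValueError(
                    f"approved-list name {name!r} is ambiguous between concepts "
                    f"{list(result.accepted)}; resolve it with an override"
                )
            if result.status == UNMATCHED:
                unmatched.append(name)
                continue
            cid = result.accepted[0]
        by_concept.setdefault(cid, (lexicon.get(cid).preferred_name, class_label))

    entries = pd.DataFrame(
        [(cid, name, cls) for cid, (name, cls) in sorted(by_concept.items())],
        columns=["concept_id", "preferred_name", "class"],
    ).astype({"concept_id": int})
    return ReferenceSet(entries, tuple(sorted(unmatched)))


def filter_to_reference(mapping: pd.DataFrame, reference: ReferenceSet) -> FilterResult:
    """Partition a batch-mapping table by reference membership.

    ``retained`` holds rows matched to a reference concept; ``out_of_reference``
    rows matched to some other concept; ``unresolved`` the unmatched and
    ambiguous rows.  The three parts are pairwise disjoint and their union is
    the input.
    """
    matched = mapping["status"] == MATCHED
    in_ref = mapping["concept_id"].isin(sorted(reference.concept_ids)) & matched
    return FilterResult(
        retained=mapping.loc[in_ref].reset_index(drop=True),
        out_of_reference=mapping.loc[matched & ~in_ref].reset_index(drop=True),
        unresolved=mapping.loc[~matched].reset_index(drop=True),
    )
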