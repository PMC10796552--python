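"""Name-heterogeneity statistics over reference-mapped drug mentions.

Given the verbatim name-frequency table and the batch mapping of names to
concepts, this module produces the descriptive statistics that quantify how
heterogeneous drug-name entry is in a spontaneous-reporting corpus:

* a frequency-threshold table — how many distinct raw names survive usage
  thresholds k, versus the constant count and usage of the standardized
  (preferred) names;
* per-concept summaries — number of variant names, usage of the exact
  preferred-name string, total usage, and the percentage of usage carried by
  the preferred name;
* per-concept variant listings ranked by usage; and
* the heterogeneity ratio: distinct raw names per concept.

Percentages and ratios are rounded half-up to one decimal, as printed in
regulatory-style summary tables.  The preferred-name usage counts the exact
preferred string only (case-insensitive but punctuation-sensitive), so
near-duplicates like a trailing-period variant stay separate.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .normalize import MATCHED
from .refdb import ReferenceSet

__all__ = [
    "VariantListing",
    "threshold_table",
    "concept_summaries",
    "variant_listing",
    "heterogeneity_ratio",
    "round_half_up",
]

THRESHOLD_COLUMNS = ["k", "n_names", "total_freq", "n_preferred", "preferred_freq"]
SUMMARY_COLUMNS = [
    "concept_id",
    "preferred_name",
    "class",
    "n_variants",
    "freq_preferred",
    "freq_all",
    "pct_preferred",
]


def round_half_up(value: int | float | Decimal, decimals: int = 1) -> float:
    """Round with ties away from zero (half-up), as printed tables do."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def _pct(numerator: int, denominator: int) -> float:
    if denominator == 0:
        return 0.0
    return float(
        (Decimal(100 * numerator) / Decimal(denominator)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass(frozen=True)
class VariantListing:
    """Ranked variant names of one concept: rows ``raw_name, count`` sorted by
    count descending then name ascending, plus their total."""

    concept_id: int
    rows: pd.DataFrame
    total: int


def _preferred_mask(freqs: pd.DataFrame, reference: ReferenceSet) -> pd.Series:
    preferred = {name.casefold() for name in reference.preferred_names().values()}
    if freqs.empty:
        return pd.Series([], dtype=bool, index=freqs.index)
    return freqs["raw_name"].str.casefold().isin(preferred)


def threshold_table(
    freqs: pd.DataFrame, reference: ReferenceSet, ks: Sequence[int]
) -> pd.DataFrame:
    """Distinct-name and usage totals above each frequency threshold k.

    ``freqs`` must already be restricted to reference-mapped names.  For each
    k, ``n_names``/``total_freq`` count raw names used at least k times and
    their summed usage; ``n_preferred`` (the size of the reference) and
    ``preferred_freq`` (summed usage of exact preferred-name strings) are
    independent of k.
    """
    ks = list(ks)
    if not ks:
        raise ValueError("ks must be non-empty")
    if any(k < 1 for k in ks) or ks != sorted(ks):
        raise ValueError(f"ks must be sorted ascending and all >= 1, got {ks}")
    preferred_freq = int(freqs.loc[_preferred_mask(freqs, reference), "count"].sum())
    rows = []
    for k in ks:
        surviving = freqs.loc[freqs["count"] >= k]
        rows.append((k, len(surviving), int(surviving["count"].sum()), len(reference), preferred_freq))
    return pd.DataFrame(rows, columns=THRESHOLD_COLUMNS)


def _mapped_counts(mapping: pd.DataFrame, freqs: pd.DataFrame) -> pd.DataFrame:
    """Join matched mapping rows with verbatim counts (inner on raw_name)."""
    matched = mapping.loc[mapping["status"] == MATCHED, ["raw_name", "concept_id"]]
    joined = matched.merge(freqs, on="raw_name", how="inner")
    joined["concept_id"] = joined["concept_id"].astype(int)
    return joined


def concept_summaries(
    mapping: pd.DataFrame,
    freqs: pd.DataFrame,
    reference: ReferenceSet,
    min_count: int = 3,
) -> pd.DataFrame:
    """Per-concept variant statistics, restricted to reference concepts.

    Raw names used fewer than ``min_count`` times are excluded before
    aggregation (screening out one-off spelling errors), and only concepts
    with at least two surviving variant names are reported.
    ``pct_preferred`` is 100·freq_preferred/freq_all rounded half-up to one
    decimal (0.0 when freq_all is 0).
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    counts = _mapped_counts(mapping, freqs)
    counts = counts.loc[
        counts["concept_id"].isin(sorted(reference.concept_ids))
        & (counts["count"] >= min_count)
    ]
    preferred = reference.preferred_names()
    classes = dict(zip(reference.entries["concept_id"], reference.entries["class"]))
    rows = []
    for cid, group in counts.groupby("concept_id", sort=True):
        n_variants = group["raw_name"].nunique()
        if n_variants < 2:
            continue
        freq_all = int(group["count"].sum())
        preferred_name = preferred[int(cid)]
        is_preferred = group["raw_name"].str.casefold() == preferred_name.casefold()
        freq_preferred = int(group.loc[is_preferred, "count"].sum())
        rows.append(
            (
                int(cid),
                preferred_name,
                classes[int(cid)],
                int(n_variants),
                freq_preferred,
                freq_all,
                _pct(freq_preferred, freq_all),
            )
        )
    frame = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if not frame.empty:
        frame = frame.sort_values(["class", "concept_id"]).reset_index(drop=True)
    return frame


def variant_listing(
    concept_id: int,
    mapping: pd.DataFrame,
    freqs: pd.DataFrame,
    reference: ReferenceSet | None = None,
) -> VariantListing:
    """All raw names mapped to one concept with their usage counts.

    If ``reference`` is given, a concept outside it raises ``KeyError``.  A
    concept with no mapped names yields an empty listing with total 0; the
    listing total always equals the un-thresholded usage of the concept.
    """
    if reference is not None and concept_id not in reference:
        raise KeyError(f"concept_id {concept_id} is not in the reference set")
    counts = _mapped_counts(mapping, freqs)
    rows = (
        counts.loc[counts["concept_id"] == concept_id, ["raw_name", "count"]]
        .sort_values(["count", "raw_name"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return VariantListing(concept_id, rows, int(rows["count"].sum()))


def heterogeneity_ratio(n_raw: int, n_concepts: int) -> float:
    """Fold-reduction of distinct names achieved by concept mapping:
    ``n_raw / n_concepts`` rounded half-up to one decimal."""
    if n_concepts <= 0:
        raise ValueError(f"n_concepts must be positive, got {n_concepts}")
    if n_raw < 0:
        raise ValueError(f"n_raw must be non-negative, got {n_raw}")
    return float(
        (Decimal(n_raw) / Decimal(n_concepts)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )
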