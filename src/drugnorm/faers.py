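"""Reading adverse-event reports in a FAERS-dialect XML subset.

Spontaneous-report XML (E2B/ICSR style) nests verbatim drug-name strings in
``<medicinalproduct>`` tag pairs and coded reaction terms (MedDRA-PT role) in
``<reactionmeddrapt>`` tags::

    <reportset>
      <safetyreport>
        <safetyreportid>R0001</safetyreportid>
        <patient>
          <drug><medicinalproduct>METHADONE HCL</medicinalproduct></drug>
          <reaction><reactionmeddrapt>Nausea</reactionmeddrapt></reaction>
        </patient>
      </safetyreport>
      ...
    </reportset>

Drug names are kept verbatim (whitespace-trimmed only): counting is always on
the raw strings, so near-duplicates such as "methadone hydrochloride" and
"methadone hydrochloride." remain distinct rows — normalization is a separate,
later stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
from lxml import etree

__all__ = [
    "DrugMention",
    "AdverseEventReport",
    "iter_reports",
    "parse_aer_xml",
    "extract_drug_event_pairs",
    "count_name_frequencies",
    "FREQUENCY_COLUMNS",
]

logger = logging.getLogger(__name__)

FREQUENCY_COLUMNS = ["raw_name", "count"]


@dataclass(frozen=True)
class DrugMention:
    """One verbatim drug-name string from a medicinalproduct tag pair."""

    raw_name: str


@dataclass
class AdverseEventReport:
    report_id: str
    mentions: list[DrugMention] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)


def iter_reports(source: str | Path | IO[bytes]) -> Iterator[AdverseEventReport]:
    """Stream reports from FAERS-dialect XML with bounded memory per report.

    Every ``<medicinalproduct>`` occurrence inside a ``<safetyreport>`` yields
    one :class:`DrugMention` in document order.  Reports without a
    ``<safetyreportid>`` are skipped with a logged warning; malformed XML
    raises ``lxml.etree.XMLSyntaxError`` (which carries the position).
    """
    for _event, element in etree.iterparse(source, events=("end",), tag="safetyreport"):
        report_id = element.findtext(".//safetyreportid", default="").strip()
        if not report_id:
            logger.warning("skipping safetyreport without a safetyreportid")
        else:
            mentions = [
                DrugMention((node.text or "").strip())
                for node in element.iter("medicinalproduct")
            ]
            reactions = [
                (node.text or "").strip() for node in element.iter("reactionmeddrapt")
            ]
            yield AdverseEventReport(report_id, mentions, reactions)
        element.clear(keep_tail=True)
        while element.getprevious() is not None:
            del element.getparent()[0]


def parse_aer_xml(source: str | Path | IO[bytes]) -> list[AdverseEventReport]:
    """Parse a whole FAERS-dialect XML document; see :func:`iter_reports`."""
    return list(iter_reports(source))


def extract_drug_event_pairs(
    reports: Iterable[AdverseEventReport],
) -> list[tuple[str, str]]:
    """Cartesian (drug mention, reaction) pairs per report.

    A report with *m* mentions and *r* reactions contributes ``m * r`` pairs;
    reports without reactions contribute none.
    """
    pairs: list[tuple[str, str]] = []
    for report in reports:
        for mention in report.mentions:
            for reaction in report.reactions:
                pairs.append((mention.raw_name, reaction))
    return pairs


def count_name_frequencies(
    mentions: Iterable[DrugMention | str],
) -> pd.DataFrame:
    """Usage frequency of each distinct verbatim name string.

    Counting is case- and punctuation-sensitive.  Returns a DataFrame with
    columns ``raw_name, count`` ordered by count descending, then name
    ascending; counts sum to the number of input mentions.
    """
    names = [m.raw_name if isinstance(m, DrugMention) else m for m in mentions]
    if not names:
        return pd.DataFrame(columns=FREQUENCY_COLUMNS).astype({"count": int})
    counts = pd.Series(names, dtype=object).value_counts(sort=False)
    frame = counts.rename_axis("raw_name").reset_index(name="count")
    return (
        frame.sort_values(["count", "raw_name"], ascending=[False, True])
        .reset_index(drop=True)
    )
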