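"""Curated FAERS-derived opioid usage fixtures bundled with the package.

Two kinds of tables ship under ``drugnorm/data/``:

* ``opioid_usage_summary.tsv`` — per-concept usage statistics for the 67
  FDA-approved prescription-opioid concepts of the bundled lexicon (number of
  distinct reported names, usage of the standardized name, total usage and
  the printed preferred-name percentage);
* ``variant_frequencies_<rxcui>.tsv`` — complete ranked variant listings for
  two concepts (214256 aspirin/oxycodone, 218337 methadone hydrochloride),
  giving realistic verbatim name-frequency inputs for tests and examples.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

__all__ = ["opioid_usage_summary", "variant_frequency_table", "VARIANT_TABLE_CONCEPTS"]

VARIANT_TABLE_CONCEPTS = (214256, 218337)


def _read_data(name: str) -> pd.DataFrame:
    path = importlib.resources.files("drugnorm") / "data" / name
    with importlib.resources.as_file(path) as file:
        return pd.read_csv(file, sep="\t")


def opioid_usage_summary() -> pd.DataFrame:
    """Per-concept usage statistics of the 67 bundled opioid concepts.

    Columns: ``class, concept_id, preferred_name, n_variants, freq_preferred,
    freq_all, pct_preferred``.
    """
    return _read_data("opioid_usage_summary.tsv")


def variant_frequency_table(concept_id: int) -> pd.DataFrame:
    """Ranked verbatim name-frequency table for one bundled concept.

    Columns: ``raw_name, count``; available for the concepts in
    :data:`VARIANT_TABLE_CONCEPTS`.
    """
    if concept_id not in VARIANT_TABLE_CONCEPTS:
        raise KeyError(
            f"no bundled variant table for concept {concept_id}; "
            f"available: {VARIANT_TABLE_CONCEPTS}"
        )
    return _read_data(f"variant_frequencies_{concept_id}.tsv")
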