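"""Published reference tables for the cannabis health-surveillance study.

Two small count fixtures ship with the package:

- the per-category frequency table over the 353,353-post classified corpus
  (17 categories, with the example keywords that illustrate each), and
- the 1092-post dual-coded validation sample's per-stratum counts of
  motivation / consequence / neither labels.

Only raw counts are stored; every percentage is recomputed by the same
table-building code the pipeline uses, so the fixtures double as an
end-to-end check of the report arithmetic. Files are checksum-verified at
load time.
"""

from __future__ import annotations

import hashlib
import io
from importlib import resources

import pandas as pd

from .classifier import CategoryFrequencyTable
from .errors import FixtureError
from .validation import ValidationTable

#: Total posts in the classified corpus the frequency table describes.
REFERENCE_CORPUS_SIZE = 353_353

_CHECKSUMS = {
    "reference_category_frequencies.csv": (
        "99189b5dea33bc5c2bf2159ea4035e10f025eb50b05bbd9ed67f1d83e981d243"
    ),
    "reference_validation_counts.csv": (
        "11ae49e4084b82bc136214a68edc0bfe04fb3da3bf43201e698ef432a6f0cb52"
    ),
}


def _read_fixture(name: str) -> pd.DataFrame:
    data = resources.files("infoveil").joinpath(f"data/{name}").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureError(f"checksum mismatch for fixture {name}")
    return pd.read_csv(io.BytesIO(data))


def load_reference_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load both count fixtures as DataFrames (frequencies, validation counts)."""
    frequencies = _read_fixture("reference_category_frequencies.csv")
    counts = _read_fixture("reference_validation_counts.csv")
    return frequencies, counts


def reference_frequency_table() -> CategoryFrequencyTable:
    """The published category frequencies as a live frequency table.

    Percentages come out of :class:`CategoryFrequencyTable`, not the file;
    the file's ``pct_printed`` column is retained only so tests can compare
    recomputed against printed values.
    """
    frequencies, _ = load_reference_tables()
    return CategoryFrequencyTable(
        counts=dict(zip(frequencies["category"], frequencies["n"].astype(int))),
        corpus_size=REFERENCE_CORPUS_SIZE,
    )


def reference_validation_table() -> ValidationTable:
    """The published validation counts as a live validation table."""
    _, counts = load_reference_tables()
    return ValidationTable.from_counts(
        {
            row["category"]: {
                "motivation": row["motivation"],
                "consequence": row["consequence"],
                "neither": row["neither"],
            }
            for _, row in counts.iterrows()
        }
    )
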