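"""Rule-based multi-label health-topic classification.

A post's categories are the union of the categories of every lexicon entry
whose surface form occurs as a contiguous whole-token sub-sequence of the
normalized post text. The semantics are deliberately simple and fully
deterministic:

- overlapping matches all count (no longest-match suppression);
- a term matching several times in one post contributes its categories once
  (counts are per post, not per mention);
- medical and colloquial entries carry equal weight.

``classify_corpus`` additionally tabulates per-category frequencies over the
*health subset* — the posts carrying at least one matched term — which is
the denominator the frequency table's percentages use.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import pandas as pd

from .corpus import PostRecord
from .lexicon import Lexicon
from .rounding import percent
from .text import normalize_tokens


@dataclass(frozen=True)
class CategoryAssignment:
    """Categories assigned to one post, with matched terms as evidence."""

    post_id: str
    categories: frozenset[str]
    evidence: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert set(self.evidence) == set(self.categories)
        assert all(self.evidence[c] for c in self.categories)


@dataclass(frozen=True)
class CategoryFrequencyTable:
    """Per-category post counts over the health subset (Frequency, n (%)).

    ``corpus_size`` is the number of posts carrying at least one category;
    because posts may be multi-category, counts can sum past it. Percentages
    are round-half-up to 2 decimals.
    """

    counts: dict[str, int]
    corpus_size: int

    def percentage(self, category: str) -> float:
        return percent(self.counts[category], self.corpus_size, decimals=2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(self.counts),
                "n": list(self.counts.values()),
                "pct": [self.percentage(c) for c in self.counts],
            }
        )


def classify_post(record: PostRecord, lexicon: Lexicon) -> CategoryAssignment:
    """Assign categories to one post by exact whole-token term matching."""
    matched = lexicon.lookup(normalize_tokens(record.text))
    evidence: dict[str, set[str]] = {}
    for entry in matched:
        for category in entry.categories:
            evidence.setdefault(category, set()).add(entry.surface_form)
    return CategoryAssignment(
        post_id=record.post_id,
        categories=frozenset(evidence),
        evidence={c: frozenset(s) for c, s in evidence.items()},
    )


def classify_corpus(
    records: Sequence[PostRecord],
    lexicon: Lexicon,
) -> tuple[list[CategoryAssignment], CategoryFrequencyTable, list[PostRecord]]:
    """Classify every record; tabulate frequencies over the health subset.

    Returns ``(assignments, frequency_table, health_subset)`` where
    ``health_subset`` holds the records with a nonempty category set, in
    corpus order, and the table counts posts per category over that subset.
    """
    assignments = [classify_post(record, lexicon) for record in records]
    health_subset = [
        record for record, a in zip(records, assignments) if a.categories
    ]
    counts = {category: 0 for category in lexicon.category_registry}
    for assignment in assignments:
        for category in assignment.categories:
            counts[category] += 1
    table = CategoryFrequencyTable(counts=counts, corpus_size=len(health_subset))
    return assignments, table, health_subset
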