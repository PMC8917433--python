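"""Post records and the pre-classification filtering cascade.

A corpus is a line-delimited file of JSON objects, one post per line. The
cascade applied before classification mirrors an account-level hygiene
workflow for platform data:

1. retain posts mentioning at least one cannabis seed keyword,
2. drop retweets so each observation is an independent authored post,
3. drop posts from deleted accounts (no bot score can exist for them), then
   posts from accounts whose precomputed bot-likelihood score, on a 1-to-5
   scale, is at or above the threshold (default 4.0, inclusive).

Every filter is a pure subset operation that preserves record order and
returns a :class:`FilterReport` so stage counts can be audited end to end.
Bot scores are consumed, never computed, by this package.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import (
    CorpusError,
    EmptyCorpusError,
    EmptySeedListError,
    MissingBotScoreError,
)
from .registry import SEED_TERMS
from .text import normalize_tokens

logger = logging.getLogger(__name__)

_FIELDS = (
    "post_id",
    "account_id",
    "timestamp",
    "text",
    "is_retweet",
    "bot_score",
    "account_available",
)


@dataclass(frozen=True)
class PostRecord:
    """One social-media post with the account metadata the filters need.

    ``bot_score`` is the precomputed bot-likelihood on a 1-to-5 scale; it is
    ``None`` exactly when no score exists (deleted accounts cannot be scored).
    """

    post_id: str
    account_id: str
    timestamp: str
    text: str
    is_retweet: bool = False
    bot_score: float | None = None
    account_available: bool = True

    def __post_init__(self) -> None:
        if self.bot_score is not None and not 1.0 <= self.bot_score <= 5.0:
            raise CorpusError(
                f"post {self.post_id!r}: bot_score {self.bot_score} outside [1, 5]"
            )


@dataclass(frozen=True)
class FilterReport:
    """Audit record for one cascade stage: input = output + removed."""

    stage: str
    input_count: int
    output_count: int
    removed_count: int
    breakdown: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.input_count != self.output_count + self.removed_count:
            raise CorpusError(f"inconsistent filter report for stage {self.stage!r}")
        if self.breakdown and sum(self.breakdown.values()) != self.removed_count:
            raise CorpusError(f"breakdown does not sum to removed_count in {self.stage!r}")


def read_corpus(path: str | Path) -> Iterator[PostRecord]:
    """Yield records from a JSONL corpus in file order, skipping bad lines."""
    records, _ = load_corpus(path)
    yield from records


def load_corpus(path: str | Path) -> tuple[list[PostRecord], int]:
    """Read a JSONL corpus; return ``(records, n_skipped)``.

    Malformed lines are counted, logged and skipped. A file with zero
    parseable records raises :class:`EmptyCorpusError`.
    """
    path = Path(path)
    records: list[PostRecord] = []
    skipped = 0
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                if not isinstance(obj, dict):
                    raise TypeError("record line is not an object")
                record = PostRecord(**{k: obj[k] for k in _FIELDS if k in obj})
            except (json.JSONDecodeError, TypeError, CorpusError) as exc:
                skipped += 1
                logger.warning("%s:%d: skipping malformed record (%s)", path, lineno, exc)
                continue
            records.append(record)
    if not records:
        raise EmptyCorpusError(f"{path}: no parseable records")
    return records, skipped


def write_corpus(records: Iterable[PostRecord], path: str | Path) -> int:
    """Write records as JSONL; returns the number written."""
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as handle:
        for record in records:
            handle.write(json.dumps(asdict(record), ensure_ascii=False) + "\n")
            n += 1
    return n


def filter_seed_terms(
    records: Sequence[PostRecord],
    seed_terms: Sequence[str] = SEED_TERMS,
) -> tuple[list[PostRecord], FilterReport]:
    """Retain posts containing at least one seed keyword as a whole token.

    Matching runs on the shared normalization, so case, punctuation and
    hashtag prefixes are immaterial, and "weed" inside "seaweed" never hits.
    """
    if not seed_terms:
        raise EmptySeedListError("seed term list is empty")
    seeds = frozenset(seed_terms)
    kept = [r for r in records if seeds.intersection(normalize_tokens(r.text))]
    return kept, FilterReport(
        stage="seed_terms",
        input_count=len(records),
        output_count=len(kept),
        removed_count=len(records) - len(kept),
    )


def remove_retweets(records: Sequence[PostRecord]) -> tuple[list[PostRecord], FilterReport]:
    """Drop records flagged as retweets, preserving order."""
    kept = [r for r in records if not r.is_retweet]
    return kept, FilterReport(
        stage="retweets",
        input_count=len(records),
        output_count=len(kept),
        removed_count=len(records) - len(kept),
    )


def filter_bots(
    records: Sequence[PostRecord],
    threshold: float = 4.0,
) -> tuple[list[PostRecord], FilterReport]:
    """Drop posts from deleted accounts, then from likely-bot accounts.

    Deleted accounts go first: they carry no score, so they cannot face the
    threshold. An *available* account without a score is an input error —
    scores must be precomputed upstream. The threshold is inclusive: a score
    exactly at it is removed.
    """
    if not 1.0 < threshold <= 5.0:
        raise CorpusError(f"bot threshold {threshold} outside (1, 5]")
    kept: list[PostRecord] = []
    n_deleted = 0
    n_bot = 0
    for record in records:
        if not record.account_available:
            n_deleted += 1
            continue
        if record.bot_score is None:
            raise MissingBotScoreError(
                f"post {record.post_id!r}: available account {record.account_id!r} "
                "has no precomputed bot score"
            )
        if record.bot_score >= threshold:
            n_bot += 1
            continue
        kept.append(record)
    return kept, FilterReport(
        stage="bots",
        input_count=len(records),
        output_count=len(kept),
        removed_count=n_deleted + n_bot,
        breakdown={"deleted": n_deleted, "bot": n_bot},
    )


def count_unique_accounts(records: Iterable[PostRecord]) -> int:
    """Number of distinct account ids in the corpus."""
    return len({r.account_id for r in records})
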