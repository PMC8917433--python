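"""Shared fixtures: the demo lexicon, record builders, random corpora and
the brute-force matching oracle used to check the classifier."""

from __future__ import annotations

import numpy as np
import pytest

from infoveil import Lexicon, LexiconEntry, PostRecord, demo_lexicon
from infoveil.registry import CATEGORY_REGISTRY


@pytest.fixture(scope="session")
def demo_lex() -> Lexicon:
    return demo_lexicon()


def make_record(
    post_id: str = "p1",
    text: str = "cbd helps",
    *,
    account_id: str = "a1",
    is_retweet: bool = False,
    bot_score: float | None = 2.0,
    account_available: bool = True,
) -> PostRecord:
    return PostRecord(
        post_id=post_id,
        account_id=account_id,
        timestamp="2020-03-01T00:00:00Z",
        text=text,
        is_retweet=is_retweet,
        bot_score=bot_score,
        account_available=account_available,
    )


@pytest.fixture
def record_factory():
    return make_record


def oracle_match(entries, tokens) -> set[LexiconEntry]:
    """Brute force: enumerate every contiguous sub-sequence, test membership."""
    max_len = max((len(e.tokens) for e in entries), default=0)
    ngrams = {
        tuple(tokens[i : i + k])
        for i in range(len(tokens))
        for k in range(1, max_len + 1)
        if i + k <= len(tokens)
    }
    return {e for e in entries if e.tokens in ngrams}


def random_lexicon(rng: np.random.Generator, n_entries: int) -> Lexicon:
    """Random single/multi-token lexicon over a small synthetic vocabulary."""
    vocab = [f"w{i}" for i in range(40)]
    entries: dict[str, LexiconEntry] = {}
    while len(entries) < n_entries:
        length = int(rng.integers(1, 4))
        surface = " ".join(rng.choice(vocab, size=length))
        if surface in entries:
            continue
        n_cats = int(rng.integers(1, 4))
        categories = frozenset(rng.choice(CATEGORY_REGISTRY, size=n_cats, replace=False))
        entries[surface] = LexiconEntry(
            surface_form=surface, categories=categories, source="medical"
        )
    return Lexicon(entries.values())


def random_texts(rng: np.random.Generator, n_posts: int) -> list[str]:
    """Token soup over the same vocabulary the random lexica draw from."""
    vocab = [f"w{i}" for i in range(40)] + [f"x{i}" for i in range(20)]
    return [
        " ".join(rng.choice(vocab, size=int(rng.integers(3, 25))))
        for _ in range(n_posts)
    ]
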