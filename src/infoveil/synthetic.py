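"""Synthetic corpora, bot scores and coder annotations with known truth.

The generator emulates the statistical structure the pipeline assumes, so
every stage is testable without platform data:

- **Accounts.** Posts are grouped into accounts whose post counts follow a
  shifted geometric distribution with configurable mean; bot and deleted
  status are drawn per account, mirroring account-level filtering. Bot
  accounts receive a bot score uniform in [4, 5], non-bots uniform in
  [1, 4); deleted accounts carry no score.
- **Text.** Every post contains one cannabis seed keyword (sometimes as a
  hashtag) plus filler drawn from a generated nonsense vocabulary that is
  disjoint from the lexicon and the seed list, so no category match can
  happen by accident. A post is a *health candidate* with probability
  ``1 - no_health_fraction``; candidates then carry each category
  independently with its configured prevalence, realized by planting a
  uniformly chosen lexicon term of that category. The marginal chance a
  post carries category ``c`` is therefore
  ``(1 - no_health_fraction) * category_prevalence[c]``.
- **Labels and coders.** Every post has a true codebook label drawn from
  ``true_label_distribution``; each simulated coder reproduces the true
  label with probability ``coder_accuracy`` and otherwise errs uniformly
  over the two remaining labels, independently of the other coder.

An optional ambiguity-injection mode additionally fuses a lexicon term into
a longer nonsense token (the "seaweed" hazard) to exercise whole-token
boundary handling; fused terms are *not* part of the ground truth.

Identical config and seed give byte-identical output.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .corpus import PostRecord
from .errors import SimulationError
from .lexicon import Lexicon
from .registry import CATEGORY_REGISTRY, CODEBOOK_LABELS, SEED_TERMS
from .validation import Annotation

# Default study conditions. Prevalences are the published per-category
# shares of the classified corpus; account-level fractions come from the
# published filtering flow (bots among available accounts, deleted among
# all accounts, posts per retained account); the no-health fraction is the
# share of seed-keyword posts that matched no lexicon term.
DEFAULT_CATEGORY_PREVALENCE: dict[str, float] = {
    "Cancer": 0.0392,
    "Cardiovascular": 0.0052,
    "Cognitive": 0.0249,
    "Death": 0.0895,
    "Dermatological": 0.0044,
    "Gastrointestinal": 0.0295,
    "Immune System": 0.0346,
    "Injury": 0.0552,
    "Mental health": 0.2834,
    "Neurological": 0.1595,
    "Other": 0.1248,
    "Pain": 0.1085,
    "Poisoning": 0.0236,
    "Pregnancy or in utero": 0.0135,
    "Respiratory": 0.0470,
    "Stress": 0.0378,
    "Weight": 0.0167,
}
DEFAULT_NO_HEALTH_FRACTION = 1.0 - 609_227 / 16_703_751  # ~0.9635
DEFAULT_BOT_FRACTION = 15_245 / 261_134  # ~0.0584
DEFAULT_DELETED_FRACTION = 127_140 / 388_274  # ~0.3275
DEFAULT_POSTS_PER_ACCOUNT_MEAN = 353_353 / 245_889  # ~1.44
DEFAULT_TRUE_LABEL_DISTRIBUTION = (0.204, 0.108, 0.688)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic corpus; defaults encode the study conditions."""

    n_posts: int = 5000
    seed: int = 0
    category_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PREVALENCE)
    )
    no_health_fraction: float = DEFAULT_NO_HEALTH_FRACTION
    retweet_fraction: float = 0.4
    bot_fraction: float = DEFAULT_BOT_FRACTION
    deleted_fraction: float = DEFAULT_DELETED_FRACTION
    posts_per_account_mean: float = DEFAULT_POSTS_PER_ACCOUNT_MEAN
    coder_accuracy: float = 0.93
    true_label_distribution: tuple[float, float, float] = DEFAULT_TRUE_LABEL_DISTRIBUTION
    ambiguity_injection: bool = False
    filler_tokens_range: tuple[int, int] = (5, 15)

    def __post_init__(self) -> None:
        if self.n_posts <= 0:
            raise SimulationError("n_posts must be positive")
        probs = [
            self.no_health_fraction,
            self.retweet_fraction,
            self.bot_fraction,
            self.deleted_fraction,
            self.coder_accuracy,
            *self.category_prevalence.values(),
            *self.true_label_distribution,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise SimulationError("all probabilities must lie in [0, 1]")
        if abs(sum(self.true_label_distribution) - 1.0) > 1e-9:
            raise SimulationError("true_label_distribution must sum to 1")
        if self.posts_per_account_mean < 1.0:
            raise SimulationError("posts_per_account_mean must be >= 1")


@dataclass
class GroundTruth:
    """What the generator planted, keyed by post and account id."""

    categories: dict[str, frozenset[str]]
    labels: dict[str, str]
    bot_accounts: set[str]
    deleted_accounts: set[str]
    retweet_posts: set[str]

    def expected_survivors(self, records: Sequence[PostRecord]) -> list[str]:
        """Post ids that should survive the full filtering cascade."""
        return [
            r.post_id
            for r in records
            if r.post_id not in self.retweet_posts
            and r.account_id not in self.deleted_accounts
            and r.account_id not in self.bot_accounts
        ]


_CONSONANTS = np.array(list("bcdfghjklmnpqrstvwxz"))


def _nonsense_vocabulary(
    rng: np.random.Generator, size: int, forbidden: frozenset[str]
) -> list[str]:
    """Pronounceable-ish nonsense words disjoint from ``forbidden`` tokens."""
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < size:
        length = int(rng.integers(6, 10))
        word = "".join(rng.choice(_CONSONANTS, size=length))
        if word not in forbidden and word not in seen:
            seen.add(word)
            words.append(word)
    return words


def generate_corpus(
    config: SimulationConfig,
    lexicon: Lexicon,
    seed_terms: Sequence[str] = SEED_TERMS,
) -> tuple[list[PostRecord], GroundTruth]:
    """Generate a corpus of posts plus the ground truth behind it."""
    if len(lexicon) == 0:
        raise SimulationError("lexicon is empty")
    for category in config.category_prevalence:
        if config.category_prevalence[category] > 0 and not lexicon.entries_for_category(
            category
        ):
            raise SimulationError(f"prevalence set for {category!r}, but no lexicon entry")
    rng = np.random.default_rng(config.seed)
    lexicon_tokens = frozenset(
        token for entry in lexicon for token in entry.tokens
    )
    filler = _nonsense_vocabulary(
        rng, 200, lexicon_tokens | frozenset(seed_terms)
    )
    by_category = {
        category: lexicon.entries_for_category(category)
        for category in lexicon.category_registry
    }
    categories_order = [
        c for c in CATEGORY_REGISTRY if config.category_prevalence.get(c, 0.0) > 0
    ]

    # account structure: shifted-geometric post counts, status per account
    account_of_post: list[str] = []
    bot_accounts: set[str] = set()
    deleted_accounts: set[str] = set()
    bot_score_of: dict[str, float | None] = {}
    account_index = 0
    p_stop = 1.0 / config.posts_per_account_mean
    while len(account_of_post) < config.n_posts:
        account_id = f"acct{account_index:06d}"
        account_index += 1
        n_from_account = int(rng.geometric(p_stop))
        if rng.random() < config.deleted_fraction:
            deleted_accounts.add(account_id)
            bot_score_of[account_id] = None
        elif rng.random() < config.bot_fraction:
            bot_accounts.add(account_id)
            bot_score_of[account_id] = float(rng.uniform(4.0, 5.0))
        else:
            bot_score_of[account_id] = float(rng.uniform(1.0, 4.0))
        account_of_post.extend([account_id] * n_from_account)
    account_of_post = account_of_post[: config.n_posts]

    label_probs = np.asarray(config.true_label_distribution)
    records: list[PostRecord] = []
    truth_categories: dict[str, frozenset[str]] = {}
    truth_labels: dict[str, str] = {}
    retweet_posts: set[str] = set()
    for i in range(config.n_posts):
        post_id = f"post{i:07d}"
        account_id = account_of_post[i]
        is_retweet = bool(rng.random() < config.retweet_fraction)
        if is_retweet:
            retweet_posts.add(post_id)
        true_cats: set[str] = set()
        units: list[str] = []
        seed_term = str(rng.choice(seed_terms))
        units.append("#" + seed_term if rng.random() < 0.3 else seed_term)
        if rng.random() >= config.no_health_fraction:
            for category in categories_order:
                if rng.random() < config.category_prevalence[category]:
                    entries = by_category[category]
                    entry = entries[int(rng.integers(len(entries)))]
                    units.append(entry.surface_form)
                    true_cats |= entry.categories
        n_filler = int(rng.integers(*config.filler_tokens_range))
        units.extend(str(w) for w in rng.choice(filler, size=n_filler))
        if config.ambiguity_injection and rng.random() < 0.2:
            # fuse a lexicon token into a longer word: must never match
            entry = list(lexicon)[int(rng.integers(len(lexicon)))]
            units.append(str(rng.choice(filler)) + entry.tokens[0])
        order = rng.permutation(len(units))
        text = " ".join(units[j] for j in order)
        records.append(
            PostRecord(
                post_id=post_id,
                account_id=account_id,
                timestamp=f"2020-0{1 + (i % 8)}-15T12:00:00Z",
                text=text,
                is_retweet=is_retweet,
                bot_score=bot_score_of[account_id],
                account_available=account_id not in deleted_accounts,
            )
        )
        truth_categories[post_id] = frozenset(true_cats)
        truth_labels[post_id] = CODEBOOK_LABELS[int(rng.choice(3, p=label_probs))]
    truth = GroundTruth(
        categories=truth_categories,
        labels=truth_labels,
        bot_accounts=bot_accounts,
        deleted_accounts=deleted_accounts,
        retweet_posts=retweet_posts,
    )
    return records, truth


def generate_annotations(
    truth: GroundTruth,
    sample_ids: Sequence[str],
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[list[Annotation], list[Annotation]]:
    """Simulate two independent coders over ``sample_ids``.

    Each coder emits the true label with probability ``coder_accuracy`` and
    otherwise a uniform choice among the other two labels. ``seed`` defaults
    to a derivation of ``config.seed`` distinct from the corpus stream.
    """
    unknown = [p for p in sample_ids if p not in truth.labels]
    if unknown:
        raise SimulationError(f"unknown post ids in sample: {unknown[:3]}")
    if seed is None:
        seed = np.random.SeedSequence(config.seed, spawn_key=(1,))
    rng = np.random.default_rng(seed)
    coders: list[list[Annotation]] = []
    for coder_id in ("coder_a", "coder_b"):
        annotations = []
        for post_id in sample_ids:
            true_label = truth.labels[post_id]
            if rng.random() < config.coder_accuracy:
                label = true_label
            else:
                others = [l for l in CODEBOOK_LABELS if l != true_label]
                label = others[int(rng.integers(2))]
            annotations.append(Annotation(post_id, coder_id, label))
        coders.append(annotations)
    return coders[0], coders[1]
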