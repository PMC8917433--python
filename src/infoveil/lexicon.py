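"""The two-dictionary term resource that defines the 17 health categories.

A lexicon merges two kinds of entries: *medical* terms (consumer health
vocabulary: symptoms and diseases as lay people and clinicians write them)
and *colloquial* synonyms, each of which points at the canonical medical
term it stands for (e.g. "drunk" for "inebriation"). Every entry maps one
normalized surface form — one or more whole tokens — to a nonempty set of
categories from the fixed 17-name registry.

Matching is exact whole-token sub-sequence matching: a multi-word term
matches only where its tokens appear contiguously in the normalized post
text. There is no stemming, spelling correction or substring matching.

The on-disk format is UTF-8 TSV with header
``surface_form  categories  source  canonical``; multi-category terms list
their categories pipe-separated; ``canonical`` is empty for medical rows.
Duplicate rows for one surface form are merged by category-set union.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import (
    EmptyLexiconError,
    LexiconFormatError,
    UnknownCategoryError,
    UnresolvedCanonicalError,
)
from .registry import CATEGORY_REGISTRY, canonical_category
from .text import normalize_term

_COLUMNS = ("surface_form", "categories", "source", "canonical")
_SOURCES = ("medical", "colloquial")


@dataclass(frozen=True)
class LexiconEntry:
    """One surface form mapped to its categories.

    ``canonical`` is the medical term a colloquial synonym stands for; it is
    required for colloquial entries and absent for medical ones.
    """

    surface_form: str
    categories: frozenset[str]
    source: str
    canonical: str | None = None

    def __post_init__(self) -> None:
        if not self.surface_form or self.surface_form != normalize_term(self.surface_form):
            raise LexiconFormatError(f"surface form not normalized: {self.surface_form!r}")
        if not self.categories:
            raise LexiconFormatError(f"entry {self.surface_form!r} has no categories")
        if self.source not in _SOURCES:
            raise LexiconFormatError(f"unknown source {self.source!r}")
        if (self.source == "colloquial") != (self.canonical is not None):
            raise LexiconFormatError(
                f"entry {self.surface_form!r}: canonical is required for colloquial "
                "entries and forbidden for medical ones"
            )

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(self.surface_form.split(" "))


class Lexicon:
    """Immutable collection of entries with token-sequence lookup."""

    def __init__(
        self,
        entries: Iterable[LexiconEntry],
        category_registry: Sequence[str] = CATEGORY_REGISTRY,
    ):
        self.category_registry: tuple[str, ...] = tuple(category_registry)
        registry_set = set(self.category_registry)
        by_surface: dict[str, LexiconEntry] = {}
        for entry in entries:
            if not entry.categories <= registry_set:
                bad = sorted(entry.categories - registry_set)
                raise UnknownCategoryError(
                    f"entry {entry.surface_form!r} uses unknown categories {bad}"
                )
            if entry.surface_form in by_surface:
                raise LexiconFormatError(f"duplicate surface form {entry.surface_form!r}")
            by_surface[entry.surface_form] = entry
        self._by_surface = by_surface
        for entry in by_surface.values():
            if entry.source == "colloquial":
                target = by_surface.get(entry.canonical or "")
                if target is None or target.source != "medical":
                    raise UnresolvedCanonicalError(
                        f"colloquial entry {entry.surface_form!r} points at "
                        f"{entry.canonical!r}, which is not a medical entry"
                    )
        # first-token index so lookup only scans candidate entries
        index: dict[str, list[LexiconEntry]] = {}
        for entry in by_surface.values():
            index.setdefault(entry.tokens[0], []).append(entry)
        self._index = index

    def __len__(self) -> int:
        return len(self._by_surface)

    def __iter__(self):
        return iter(sorted(self._by_surface.values(), key=lambda e: e.surface_form))

    def __contains__(self, surface_form: str) -> bool:
        return normalize_term(surface_form) in self._by_surface

    def get(self, surface_form: str) -> LexiconEntry | None:
        return self._by_surface.get(normalize_term(surface_form))

    def entries_for_category(self, category: str) -> list[LexiconEntry]:
        name = canonical_category(category)
        return [e for e in self if name in e.categories]

    def lookup(self, token_seq: Sequence[str]) -> set[LexiconEntry]:
        """All entries whose token sequence occurs contiguously in ``token_seq``."""
        found: set[LexiconEntry] = set()
        for i, token in enumerate(token_seq):
            for entry in self._index.get(token, ()):
                tokens = entry.tokens
                if entry not in found and tokens == tuple(token_seq[i : i + len(tokens)]):
                    found.add(entry)
        return found


def _merge_row(
    rows: dict[str, dict],
    surface: str,
    categories: frozenset[str],
    source: str,
    canonical: str | None,
) -> None:
    existing = rows.get(surface)
    if existing is None:
        rows[surface] = {"categories": set(categories), "source": source, "canonical": canonical}
        return
    if existing["source"] != source or existing["canonical"] != canonical:
        raise LexiconFormatError(
            f"duplicate rows for {surface!r} disagree on source/canonical"
        )
    existing["categories"] |= categories


def load_lexicon(
    path: str | Path,
    registry: Sequence[str] = CATEGORY_REGISTRY,
) -> Lexicon:
    """Load and validate a TSV lexicon file.

    Surface forms and canonical terms are normalized exactly as post text is;
    duplicate rows for one surface form merge by category-set union. Raises
    FileNotFoundError, LexiconFormatError, UnknownCategoryError,
    UnresolvedCanonicalError or EmptyLexiconError.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != _COLUMNS:
            raise LexiconFormatError(
                f"{path}: expected header {list(_COLUMNS)}, got {reader.fieldnames}"
            )
        rows: dict[str, dict] = {}
        for lineno, row in enumerate(reader, start=2):
            surface = normalize_term(row["surface_form"] or "")
            if not surface:
                raise LexiconFormatError(f"{path}:{lineno}: empty surface form")
            raw_categories = [c for c in (row["categories"] or "").split("|") if c.strip()]
            if not raw_categories:
                raise LexiconFormatError(f"{path}:{lineno}: no categories")
            try:
                categories = frozenset(canonical_category(c) for c in raw_categories)
            except KeyError as exc:
                raise UnknownCategoryError(f"{path}:{lineno}: unknown category {exc}") from exc
            source = (row["source"] or "").strip().lower()
            if source not in _SOURCES:
                raise LexiconFormatError(f"{path}:{lineno}: unknown source {row['source']!r}")
            canonical = normalize_term(row["canonical"] or "") or None
            if source == "medical" and canonical is not None:
                raise LexiconFormatError(
                    f"{path}:{lineno}: medical row must leave canonical empty"
                )
            if source == "colloquial" and canonical is None:
                raise LexiconFormatError(
                    f"{path}:{lineno}: colloquial row needs a canonical term"
                )
            _merge_row(rows, surface, categories, source, canonical)
    if not rows:
        raise EmptyLexiconError(f"{path}: no entries")
    entries = [
        LexiconEntry(
            surface_form=surface,
            categories=frozenset(spec["categories"]),
            source=spec["source"],
            canonical=spec["canonical"],
        )
        for surface, spec in rows.items()
    ]
    return Lexicon(entries, registry)


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write a lexicon back to the TSV format ``load_lexicon`` reads."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for entry in lexicon:
            ordered = [c for c in lexicon.category_registry if c in entry.categories]
            writer.writerow(
                [entry.surface_form, "|".join(ordered), entry.source, entry.canonical or ""]
            )


def demo_lexicon() -> Lexicon:
    """The packaged demonstration lexicon (example keywords per category)."""
    ref = resources.files("infoveil").joinpath("data/demo_lexicon.tsv")
    with resources.as_file(ref) as path:
        return load_lexicon(path)
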