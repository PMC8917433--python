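"""Validation of the rule-based classifier by dual human coding.

The workflow this module supports: draw a stratified random sample of
classified posts (one stratum per post, derived from its assigned
categories), have two coders independently label each sampled post as
``motivation`` (a health-related reason for cannabis use), ``consequence``
(a perceived adverse health effect of use) or ``neither``, quantify
agreement with Cohen's kappa, adjudicate disagreements, and tabulate the
adjudicated labels per stratum.

Cohen's kappa is computed from the 3x3 contingency table: observed
agreement is the diagonal mass, expected agreement the inner product of the
two coders' marginal label proportions, and
``kappa = (p_o - p_e) / (1 - p_e)`` (defined as 1 when both are exactly 1).
"""

from __future__ import annotations

import csv
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import CategoryAssignment
from .errors import (
    AllocationError,
    AnnotationMismatchError,
    MissingResolutionError,
    MissingStratumError,
    ValidationError,
)
from .registry import CODEBOOK_LABELS
from .rounding import percent


@dataclass(frozen=True)
class Annotation:
    """One coder's label for one sampled post."""

    post_id: str
    coder_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in CODEBOOK_LABELS:
            raise ValidationError(f"unknown codebook label {self.label!r}")


@dataclass(frozen=True)
class AgreementResult:
    """Two-coder agreement summary over ``n_items`` posts."""

    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_items: int


def _as_label_map(annotations) -> dict[str, str]:
    if isinstance(annotations, Mapping):
        return dict(annotations)
    return {a.post_id: a.label for a in annotations}


def cohens_kappa(annotations_a, annotations_b) -> AgreementResult:
    """Cohen's kappa between two coders over the same post set.

    Accepts either mappings ``post_id -> label`` or sequences of
    :class:`Annotation`. Raises if the post sets differ or fewer than two
    posts are shared.
    """
    a = _as_label_map(annotations_a)
    b = _as_label_map(annotations_b)
    if set(a) != set(b):
        raise AnnotationMismatchError("coders annotated different post sets")
    if len(a) < 2:
        raise ValidationError("kappa needs at least 2 items")
    posts = sorted(a)
    labels_a = pd.Categorical([a[p] for p in posts], categories=CODEBOOK_LABELS)
    labels_b = pd.Categorical([b[p] for p in posts], categories=CODEBOOK_LABELS)
    table = pd.crosstab(labels_a, labels_b, dropna=False).to_numpy()
    n = table.sum()
    observed = np.trace(table) / n
    expected = float(table.sum(axis=1) @ table.sum(axis=0)) / (n * n)
    kappa = 1.0 if expected == 1.0 else (observed - expected) / (1.0 - expected)
    return AgreementResult(
        kappa=float(kappa),
        observed_agreement=float(observed),
        expected_agreement=float(expected),
        n_items=int(n),
    )


def stratified_sample(
    assignments: Sequence[CategoryAssignment],
    allocation: Mapping[str, int],
    seed: int,
) -> pd.DataFrame:
    """Draw a stratified random sample of classified posts.

    Each post with at least one category is placed in exactly one stratum,
    chosen uniformly at random among its assigned categories (multi-label
    posts cannot occupy two strata in the sample); the choice and the
    within-stratum draws share one seeded generator, so the whole sample is
    reproducible from ``seed``. Within each allocated stratum, posts are
    drawn uniformly without replacement.

    Returns a DataFrame with columns ``post_id`` and ``stratum``.
    """
    rng = np.random.default_rng(seed)
    strata: dict[str, list[str]] = {}
    for assignment in sorted(assignments, key=lambda a: a.post_id):
        categories = sorted(assignment.categories)
        if not categories:
            continue
        stratum = categories[rng.integers(len(categories))]
        strata.setdefault(stratum, []).append(assignment.post_id)
    rows: list[tuple[str, str]] = []
    for stratum, size in allocation.items():
        population = strata.get(stratum)
        if population is None:
            raise AllocationError(f"unknown or empty stratum {stratum!r}")
        if size > len(population):
            raise AllocationError(
                f"allocation {size} exceeds stratum {stratum!r} population "
                f"{len(population)}"
            )
        chosen = rng.choice(len(population), size=size, replace=False)
        rows.extend((population[i], stratum) for i in sorted(chosen))
    return pd.DataFrame(rows, columns=["post_id", "stratum"])


def adjudicate(
    annotations_a,
    annotations_b,
    resolutions: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Resolve dual coding into one final label per post.

    Agreed posts keep the common label; disagreements take the label from
    ``resolutions`` and raise if none is supplied.
    """
    a = _as_label_map(annotations_a)
    b = _as_label_map(annotations_b)
    if set(a) != set(b):
        raise AnnotationMismatchError("coders annotated different post sets")
    resolutions = dict(resolutions or {})
    final: dict[str, str] = {}
    for post_id in a:
        if a[post_id] == b[post_id]:
            final[post_id] = a[post_id]
        elif post_id in resolutions:
            label = resolutions[post_id]
            if label not in CODEBOOK_LABELS:
                raise ValidationError(f"unknown resolution label {label!r}")
            final[post_id] = label
        else:
            raise MissingResolutionError(f"no resolution for disagreement on {post_id!r}")
    return final


@dataclass(frozen=True)
class ValidationTable:
    """Per-stratum counts of adjudicated motivation/consequence/neither.

    ``counts`` maps each stratum, in report order, to a label->count dict.
    Percentages are round-half-up to 1 decimal of the row total; the
    headline health-related share is (motivation + consequence) / total.
    """

    counts: dict[str, dict[str, int]]

    def row_total(self, stratum: str) -> int:
        return sum(self.counts[stratum].values())

    def column_total(self, label: str) -> int:
        return sum(row[label] for row in self.counts.values())

    @property
    def n_annotated(self) -> int:
        return sum(self.row_total(s) for s in self.counts)

    def row_percent(self, stratum: str, label: str) -> float:
        return percent(self.counts[stratum][label], self.row_total(stratum))

    def total_percent(self, label: str) -> float:
        return percent(self.column_total(label), self.n_annotated)

    @property
    def health_related_count(self) -> int:
        return self.column_total("motivation") + self.column_total("consequence")

    @property
    def health_related_percent(self) -> float:
        return percent(self.health_related_count, self.n_annotated)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stratum in self.counts:
            total = self.row_total(stratum)
            row: dict[str, object] = {"stratum": stratum, "total": total}
            for label in CODEBOOK_LABELS:
                row[f"{label}_n"] = self.counts[stratum][label]
                row[f"{label}_pct"] = self.row_percent(stratum, label)
            rows.append(row)
        total_row: dict[str, object] = {"stratum": "Total", "total": self.n_annotated}
        for label in CODEBOOK_LABELS:
            total_row[f"{label}_n"] = self.column_total(label)
            total_row[f"{label}_pct"] = self.total_percent(label)
        rows.append(total_row)
        columns = ["stratum"]
        for label in CODEBOOK_LABELS:
            columns += [f"{label}_n", f"{label}_pct"]
        columns.append("total")
        return pd.DataFrame(rows)[columns]

    @classmethod
    def from_counts(cls, counts: Mapping[str, Mapping[str, int]]) -> "ValidationTable":
        return cls(
            counts={
                stratum: {label: int(row[label]) for label in CODEBOOK_LABELS}
                for stratum, row in counts.items()
            }
        )


def build_validation_table(
    adjudicated: Mapping[str, str],
    strata: Mapping[str, str],
) -> ValidationTable:
    """Tabulate adjudicated labels per sampling stratum.

    Every adjudicated post must have a recorded stratum. Strata appear in
    first-seen order of ``strata``.
    """
    counts: dict[str, dict[str, int]] = {}
    for stratum in strata.values():
        counts.setdefault(stratum, {label: 0 for label in CODEBOOK_LABELS})
    for post_id, label in adjudicated.items():
        stratum = strata.get(post_id)
        if stratum is None:
            raise MissingStratumError(f"post {post_id!r} has no sampling stratum")
        counts[stratum][label] += 1
    return ValidationTable(counts=counts)


def kappa_by_stratum(
    annotations_a,
    annotations_b,
    strata: Mapping[str, str],
) -> dict[str, AgreementResult]:
    """One Cohen's kappa per sampling stratum (strata with >= 2 posts)."""
    a = _as_label_map(annotations_a)
    b = _as_label_map(annotations_b)
    groups: dict[str, list[str]] = {}
    for post_id in a:
        stratum = strata.get(post_id)
        if stratum is None:
            raise MissingStratumError(f"post {post_id!r} has no sampling stratum")
        groups.setdefault(stratum, []).append(post_id)
    return {
        stratum: cohens_kappa(
            {p: a[p] for p in posts}, {p: b[p] for p in posts}
        )
        for stratum, posts in groups.items()
        if len(posts) >= 2
    }


def kappa_range(per_stratum: Mapping[str, AgreementResult]) -> tuple[float, float]:
    """(min, max) kappa across strata."""
    values = [r.kappa for r in per_stratum.values()]
    if not values:
        raise ValidationError("no stratum had enough items for kappa")
    return min(values), max(values)


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read a ``post_id,coder_id,label`` CSV of annotations."""
    with Path(path).open(newline="", encoding="utf-8") as handle:
        return [
            Annotation(row["post_id"], row["coder_id"], row["label"])
            for row in csv.DictReader(handle)
        ]


def write_annotations(annotations: Sequence[Annotation], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["post_id", "coder_id", "label"])
        for annotation in annotations:
            writer.writerow([annotation.post_id, annotation.coder_id, annotation.label])


def read_resolutions(path: str | Path) -> dict[str, str]:
    """Read a ``post_id,label`` CSV of adjudication resolutions."""
    with Path(path).open(newline="", encoding="utf-8") as handle:
        return {row["post_id"]: row["label"] for row in csv.DictReader(handle)}
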