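"""Fixed vocabularies shared across the pipeline.

The 17 health-topic categories and the 16 cannabis seed keywords are part of
the study design, not configuration: every lexicon, classifier output and
validation stratum refers to the same category registry, and the corpus
filter retains exactly the posts mentioning at least one seed keyword.
"""

from __future__ import annotations

#: The 17 a priori health-topic categories, in canonical report order.
CATEGORY_REGISTRY: tuple[str, ...] = (
    "Cancer",
    "Cardiovascular",
    "Cognitive",
    "Death",
    "Dermatological",
    "Gastrointestinal",
    "Immune System",
    "Injury",
    "Mental health",
    "Neurological",
    "Other",
    "Pain",
    "Poisoning",
    "Pregnancy or in utero",
    "Respiratory",
    "Stress",
    "Weight",
)

#: Cannabis-related seed keywords used to retain candidate posts.
SEED_TERMS: tuple[str, ...] = (
    "blunt",
    "bong",
    "budder",
    "cannabis",
    "cbd",
    "ganja",
    "hash",
    "hemp",
    "indica",
    "kush",
    "marijuana",
    "marihuana",
    "reefer",
    "sativa",
    "thc",
    "weed",
)

#: The three codebook labels assigned during manual validation.
CODEBOOK_LABELS: tuple[str, ...] = ("motivation", "consequence", "neither")

_CANONICAL = {name.casefold(): name for name in CATEGORY_REGISTRY}


def canonical_category(name: str) -> str:
    """Map a case-insensitive category name onto its registry spelling.

    Raises KeyError if the name is not one of the 17 registry categories.
    """
    return _CANONICAL[name.strip().casefold()]
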