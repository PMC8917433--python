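"""Text normalization shared by the seed filter and the classifier.

One convention everywhere: Unicode NFKC, casefold to lowercase, then split
into maximal runs of ASCII alphanumerics. Splitting on non-alphanumeric
boundaries makes hashtag prefixes vanish ("#cannabis" tokenizes to
"cannabis") and keeps matching strictly whole-token ("seaweed" never yields
the token "weed").
"""

from __future__ import annotations

import re
import unicodedata

_TOKEN_RE = re.compile(r"[0-9a-z]+")


def normalize_tokens(text: str) -> tuple[str, ...]:
    """Tokenize ``text`` into the pipeline's normalized token sequence."""
    folded = unicodedata.normalize("NFKC", text).lower()
    return tuple(_TOKEN_RE.findall(folded))


def normalize_term(term: str) -> str:
    """Normalize a lexicon surface form: lowercase tokens joined by one space."""
    return " ".join(normalize_tokens(term))
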