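"""Term/keyword matching semantics shared by the offline engine,
keyword verification and the SuperMatch flag.

Definition (mirrors the quoted-phrase behaviour of the live dialects):

* matching is case-insensitive;
* Unicode hyphen variants are unified to ASCII ``-`` and runs of
  whitespace are collapsed to a single space, on both sides;
* a term matches iff its normalized form occurs in the normalized text
  with no alphanumeric character immediately before or after it, i.e.
  single-token terms match at token boundaries and multi-word terms
  match as contiguous phrases.

The brute-force oracle in :mod:`litscreen.fixtures` re-implements the
same definition with an independent character-scanning loop and shares
no code with this module.
"""

from __future__ import annotations

import re
from functools import lru_cache

# U+2010 hyphen, U+2011 non-breaking hyphen, U+2012 figure dash,
# U+2013 en dash, U+2212 minus — all seen in copy-pasted protein names.
_HYPHENS = dict.fromkeys(map(ord, "‐‑‒–−"), "-")
_WS_RE = re.compile(r"\s+")


@lru_cache(maxsize=65536)
def normalize_text(text: str) -> str:
    """Lowercase, unify hyphens, collapse whitespace, trim."""
    return _WS_RE.sub(" ", text.translate(_HYPHENS)).strip().casefold()


@lru_cache(maxsize=65536)
def _boundary_pattern(term: str) -> re.Pattern[str]:
    norm = normalize_text(term)
    # spaces inside the phrase were already collapsed; escape the rest
    return re.compile(
        r"(?<![0-9a-z])" + re.escape(norm) + r"(?![0-9a-z])"
    )


def contains_term(text: str, term: str) -> bool:
    """True iff ``term`` occurs in ``text`` under the module semantics."""
    if not term.strip():
        return False
    return _boundary_pattern(term).search(normalize_text(text)) is not None


def count_term_hits(text: str, terms: list[str] | tuple[str, ...]) -> int:
    """Number of distinct terms that occur in ``text`` (used by the
    offline relevance sort)."""
    return sum(1 for t in terms if contains_term(text, t))
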