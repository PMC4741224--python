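"""Name normalization used for deduplication and author matching.

Registries match incoming author names against already-registered ones, so
spelling variation (diacritics, case, punctuation, initials vs. full given
names) must collapse onto a single key. The rules here are deliberately
mechanical — no fuzzy scoring — so that two names either share a key or they
do not.
"""

from __future__ import annotations

import re
import unicodedata

_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)
_WS = re.compile(r"\s+")


def strip_diacritics(text: str) -> str:
    """Decompose to NFKD and drop combining marks (é -> e, ø stays ø)."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def normalize_text(text: str) -> str:
    """Casefold, strip diacritics and punctuation, collapse whitespace."""
    text = strip_diacritics(text).casefold()
    text = _PUNCT.sub(" ", text)
    return _WS.sub(" ", text).strip()


def author_key(surname: str, given_names: str) -> str:
    """Normalized dedup key for an author name.

    Given names are reduced to initials so that "J." and "John" produce the
    same key — the prefix-matching behaviour registries apply to initials.
    The key is a pure function of (surname, given_names).
    """
    s = normalize_text(surname)
    initials = " ".join(tok[0] for tok in normalize_text(given_names).split() if tok)
    return f"{s} {initials}".strip()
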