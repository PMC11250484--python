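"""Surface-form and label normalization shared across the pipeline.

Phrase-level comparison of conversational model output needs a single,
deliberately mild normalization: case-fold, collapse internal whitespace,
strip outer punctuation. Anything stronger (stemming, stopword removal)
would blur genuinely distinct clinical phrases.
"""

from __future__ import annotations

import re

_WS = re.compile(r"\s+")
_OUTER_PUNCT = re.compile(r"^[\s\"'`.,;:!?()\[\]{}*•-]+|[\s\"'`.,;:!?()\[\]{}*•-]+$")
_CAMEL = re.compile(r"(?<=[a-z0-9])(?=[A-Z])")


def normalize_ws(text: str) -> str:
    """Collapse runs of whitespace to single spaces and trim."""
    return _WS.sub(" ", text).strip()


def normalize_surface(text: str) -> str:
    """Canonical form of an entity surface for identity and matching."""
    return normalize_ws(_OUTER_PUNCT.sub("", text)).casefold()


def normalize_label(label: str) -> str:
    """Canonical form of a relation/type label: case- and separator-insensitive.

    ``TreatedByMedication``, ``treated_by_medication`` and ``treated by
    medication`` all map to the same key.
    """
    spaced = _CAMEL.sub(" ", label).replace("_", " ").replace("-", " ")
    return normalize_ws(spaced).casefold()


def verbalize_label(label: str) -> str:
    """Human-readable rendering of a relation label for prompt text.

    ``increases_risk_of`` -> ``increases risk of``;
    ``TreatedByMedication`` -> ``treated by medication``.
    """
    return normalize_label(label)


def word_count(text: str) -> int:
    """Whitespace-token count."""
    return len(text.split())
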