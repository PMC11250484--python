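"""Split long documents into model-sized chunks along natural boundaries.

Guidelines, consensus statements and papers are far longer than a chat
model's input window, so documents are cut into passages of a target word
range (500-700 by default) before extraction. Cuts are only made at
natural boundaries, preferred in the order paragraph break > sentence
terminator > line break; a cut never falls inside a sentence unless a
single sentence alone exceeds the maximum, in which case that sentence
becomes its own oversized chunk.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from ._text import word_count

__all__ = ["TextChunk", "ChunkPolicy", "split_document"]

_PARA = re.compile(r"\n[ \t]*\n\s*")
_SENT_OR_LINE = re.compile(r"(?<=[.!?])\s+|\n+")

_RANK_PARA, _RANK_SENT, _RANK_LINE = 3, 2, 1


@dataclass(frozen=True)
class TextChunk:
    id: str
    doc_id: str
    text: str
    word_count: int


@dataclass(frozen=True)
class ChunkPolicy:
    min_words: int = 500
    max_words: int = 700
    #: advisory model-input budget; not enforced beyond the word bounds
    hard_cap_tokens: int = 16000

    def __post_init__(self) -> None:
        if not (0 < self.min_words <= self.max_words):
            raise ValueError("require 0 < min_words <= max_words")


@dataclass(frozen=True)
class _Atom:
    text: str  # raw slice, no surrounding separators
    sep_before: str  # separator text between previous atom and this one
    rank: int  # boundary rank of sep_before (higher = better cut point)
    words: int


def _atoms(text: str) -> list[_Atom]:
    atoms: list[_Atom] = []

    def push(piece: str, sep: str, rank: int) -> None:
        if piece.strip():
            atoms.append(_Atom(piece, sep if atoms else "", rank, word_count(piece)))

    last_sep, last_rank = "", _RANK_PARA
    for para, para_sep in _split_keep(_PARA, text):
        sep, rank = last_sep, last_rank
        for piece, piece_sep in _split_keep(_SENT_OR_LINE, para):
            # rank of the boundary *after* this piece
            after_rank = (
                _RANK_SENT
                if piece.rstrip()[-1:] in ".!?"
                else _RANK_LINE
            )
            push(piece, sep, rank)
            sep, rank = piece_sep, after_rank
        last_sep = sep + para_sep
        last_rank = _RANK_PARA
    return atoms


def _split_keep(regex: re.Pattern, text: str) -> list[tuple[str, str]]:
    """Split, returning (piece, following separator) pairs covering text."""
    out: list[tuple[str, str]] = []
    last = 0
    for m in regex.finditer(text):
        out.append((text[last : m.start()], m.group(0)))
        last = m.end()
    out.append((text[last:], ""))
    return out


def _emit(atoms: list[_Atom]) -> str:
    parts = [atoms[0].text]
    for a in atoms[1:]:
        parts.append(a.sep_before or " ")
        parts.append(a.text)
    return "".join(parts)


def split_document(
    doc_id: str, text: str, policy: ChunkPolicy = ChunkPolicy()
) -> list[TextChunk]:
    """Partition ``text`` into chunks honouring ``policy``.

    Greedy fill toward ``max_words``; when the next unit would overflow,
    the cut backtracks to the best boundary (highest rank, then latest)
    whose prefix already holds ``min_words``. Concatenating the chunks
    reproduces the document up to whitespace at chunk boundaries.
    """
    if not text or not text.strip():
        raise ValueError("cannot chunk empty text")
    atoms = _atoms(text)
    chunks: list[list[_Atom]] = []
    current: list[_Atom] = []
    current_words = 0

    def flush_at(cut: int) -> None:
        nonlocal current, current_words
        chunks.append(current[:cut])
        current = current[cut:]
        current_words = sum(a.words for a in current)

    for atom in atoms:
        while current and current_words + atom.words > policy.max_words:
            best = None  # (rank, index)
            prefix = 0
            for i in range(1, len(current)):
                prefix += current[i - 1].words
                if prefix < policy.min_words:
                    continue
                rank = current[i].rank
                if best is None or rank >= best[0]:
                    best = (rank, i)
            flush_at(best[1] if best else len(current))
        current.append(atom)
        current_words += atom.words
    if current:
        chunks.append(current)

    return [
        TextChunk(
            id=f"{doc_id}-c{i:04d}",
            doc_id=doc_id,
            text=_emit(group),
            word_count=sum(a.words for a in group),
        )
        for i, group in enumerate(chunks)
    ]


def chunks_to_records(chunks: Iterable[TextChunk]) -> list[dict]:
    return [
        {"id": c.id, "doc_id": c.doc_id, "text": c.text, "word_count": c.word_count}
        for c in chunks
    ]


def chunks_from_records(records: Iterable[dict]) -> list[TextChunk]:
    return [
        TextChunk(
            id=r["id"],
            doc_id=r.get("doc_id", ""),
            text=r["text"],
            word_count=r.get("word_count", word_count(r["text"])),
        )
        for r in records
    ]
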