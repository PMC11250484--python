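"""Phrase-level scoring, expert-consensus gold, and inter-annotator agreement.

Extraction quality is scored at the *phrase* level: an extracted item
counts as correct only if its whole surface string (normalized) matches a
gold item — "100 mg" is one phrase, not the tokens "100" and "mg". NER
items are (surface, type) pairs, RE items (head, relation, tail) triples;
counts are accumulated per chunk and summed, so the metrics are additive
across disjoint chunk sets.

Gold construction mirrors incremental three-annotator consensus: a label
two of three annotators agree on becomes ground truth; a three-way split
is left disputed. Agreement is quantified by Cohen's kappa,
(p_o - p_e) / (1 - p_e), a two-rater statistic reported pairwise plus the
pairwise mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Iterable, Mapping, Sequence

from ._text import normalize_label, normalize_surface

__all__ = [
    "PhraseMatchReport",
    "AnnotationVote",
    "phrase_prf",
    "consensus_gold",
    "cohens_kappa",
    "pairwise_kappa",
]


@dataclass(frozen=True)
class PhraseMatchReport:
    task: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    vacuous: bool = False  # no gold and no predictions anywhere

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "vacuous": self.vacuous,
        }


def _norm_ner(item: tuple[str, str]) -> tuple[str, str]:
    surface, type_name = item
    return (normalize_surface(surface), normalize_label(type_name))


def _norm_re(item: tuple[str, str, str]) -> tuple[str, str, str]:
    h, r, t = item
    return (normalize_surface(h), normalize_label(r), normalize_surface(t))


def phrase_prf(
    pred: Mapping[str, Iterable[tuple]],
    gold: Mapping[str, Iterable[tuple]],
    task: str = "ner",
) -> PhraseMatchReport:
    """Phrase-level precision/recall/F1 over chunk-keyed item collections.

    A chunk present on only one side contributes all-false-positives (or
    all-false-negatives). The doubly-empty case is vacuously perfect
    (P = R = F1 = 1) and flagged; one-sided emptiness scores 0.
    """
    if task not in ("ner", "re"):
        raise ValueError("task must be 'ner' or 're'")
    norm = _norm_ner if task == "ner" else _norm_re
    tp = fp = fn = 0
    for chunk_id in set(pred) | set(gold):
        p = {norm(tuple(i)) for i in pred.get(chunk_id, ())}
        g = {norm(tuple(i)) for i in gold.get(chunk_id, ())}
        tp += len(p & g)
        fp += len(p - g)
        fn += len(g - p)
    vacuous = tp == fp == fn == 0
    precision = 1.0 if vacuous else (tp / (tp + fp) if tp + fp else 0.0)
    recall = 1.0 if vacuous else (tp / (tp + fn) if tp + fn else 0.0)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return PhraseMatchReport(task, tp, fp, fn, precision, recall, f1, vacuous)


@dataclass(frozen=True)
class AnnotationVote:
    """One item's judgments from exactly three annotators."""

    item: Hashable
    labels: tuple

    def __post_init__(self) -> None:
        if len(self.labels) != 3:
            raise ValueError(f"expected exactly 3 labels, got {len(self.labels)}")


def consensus_gold(votes: Iterable[AnnotationVote]) -> tuple[dict, list]:
    """Majority-of-three gold: a label >= 2 annotators share is adopted.

    Returns (item -> consensus label, disputed items). Three distinct
    labels leave the item disputed — impossible for binary labels.
    """
    gold: dict = {}
    disputed: list = []
    for vote in votes:
        a, b, c = vote.labels
        if a == b or a == c:
            gold[vote.item] = a
        elif b == c:
            gold[vote.item] = b
        else:
            disputed.append(vote.item)
    return gold, disputed


def cohens_kappa(a: Sequence, b: Sequence) -> float:
    """Chance-corrected two-rater agreement, kappa = (p_o - p_e)/(1 - p_e).

    p_o is the observed agreement rate; p_e the expected agreement from
    the raters' marginal label frequencies. Two constant, identical raters
    give p_e = 1, defined here as perfect agreement (kappa = 1).
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    n = len(a)
    if n == 0:
        raise ValueError("sequences are empty")
    p_o = sum(x == y for x, y in zip(a, b)) / n
    labels = set(a) | set(b)
    p_e = sum((list(a).count(l) / n) * (list(b).count(l) / n) for l in labels)
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def pairwise_kappa(annotations: Sequence[Sequence]) -> dict:
    """Cohen's kappa for every annotator pair, plus their mean.

    Kappa is inherently two-rater; a panel of three is summarized by the
    three pairwise coefficients and their unweighted mean.
    """
    pairs = {}
    for i, j in combinations(range(len(annotations)), 2):
        pairs[f"{i}-{j}"] = cohens_kappa(annotations[i], annotations[j])
    mean = sum(pairs.values()) / len(pairs) if pairs else float("nan")
    return {"pairwise": pairs, "mean": mean}
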