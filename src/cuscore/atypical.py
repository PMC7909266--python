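"""Classification of the five task-irrelevant ("atypical") output types:
self-referential speech, statements of inability, tangential speech, empty
speech, and false starts — reported as word-level proportions of total
utterances — plus word-level inter-rater percent agreement.

Rater annotation spans are authoritative. In ``rules+annotation`` mode,
unannotated tokens are additionally classified by deterministic rules:
false-start fragments by token kind; fillers, unrecognizable words and
packaged empty-phrase patterns as empty speech; packaged cue phrases as
inability. Self-referential and tangential speech require pragmatic judgment
and have no reliable rule, so they remain annotation-only (an optional
first-person-pronoun heuristic is provided separately and is never merged
into the main profile). Precedence on collisions:
annotation > false_start > empty > inability cue.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from ._text import load_word_list, normalize_token
from .transcripts import (
    FALSE_START,
    FILLER,
    REFERENT_TAG,
    Transcript,
    UNRECOGNIZABLE,
    count_total_utterances,
)

CATEGORIES = (
    "self_referential",
    "inability",
    "tangential",
    "empty",
    "false_start",
)

DEFAULT_CUES = "inability_cues.txt"
DEFAULT_EMPTY_PHRASES = "empty_phrases.txt"

_FIRST_PERSON = {"i", "i'm", "i've", "i'd", "my", "me", "mine", "we", "our", "us"}


class AtypicalCodingError(ValueError):
    """Conflicting authoritative annotation spans."""


class UndefinedProportionError(ZeroDivisionError):
    """Proportions undefined (zero utterances)."""


@dataclass
class AtypicalProfile:
    counts: dict[str, int]
    proportions: dict[str, float]
    total_utterances: int


def _load_phrases(source) -> list[tuple[str, ...]]:
    phrases = [
        tuple(normalize_token(w) for w in entry.split())
        for entry in load_word_list(source)
    ]
    return sorted(phrases, key=len, reverse=True)  # longest first


def _apply_phrases(
    tokens, labels: list[Optional[str]], phrases: list[tuple[str, ...]], label: str
) -> None:
    n = len(tokens)
    i = 0
    while i < n:
        if labels[i] is not None:
            i += 1
            continue
        hit = None
        for phrase in phrases:
            j = i + len(phrase)
            if j > n:
                continue
            window = tokens[i:j]
            if any(labels[k] is not None for k in range(i, j)):
                continue
            if tuple(w.normalized for w in window) == phrase:
                hit = j
                break
        if hit is not None:
            for k in range(i, hit):
                labels[k] = label
            i = hit
        else:
            i += 1


def label_tokens(
    t: Transcript,
    mode: str = "rules+annotation",
    cue_phrases=DEFAULT_CUES,
    empty_phrases=DEFAULT_EMPTY_PHRASES,
) -> list[Optional[str]]:
    """Per-token category labels (None = no category).

    Every token receives at most one label; the precedence order makes the
    labeling total and deterministic.
    """
    if mode not in ("annotation-only", "rules+annotation"):
        raise ValueError(f"unknown mode {mode!r}")
    labels: list[Optional[str]] = [None] * len(t.tokens)
    spans = [a for a in t.annotations if a.label in CATEGORIES]
    for a in spans:
        for b in spans:
            if a is not b and a.label != b.label and a.start < b.end and b.start < a.end:
                raise AtypicalCodingError(
                    f"overlapping spans {a.label} and {b.label} at tokens "
                    f"{max(a.start, b.start)}..{min(a.end, b.end)}"
                )
    for a in spans:
        for i in range(a.start, a.end):
            labels[i] = a.label
    if mode == "rules+annotation":
        for i, tok in enumerate(t.tokens):
            if labels[i] is not None:
                continue
            if tok.kind == FALSE_START:
                labels[i] = "false_start"
            elif tok.kind in (FILLER, UNRECOGNIZABLE):
                labels[i] = "empty"
        _apply_phrases(t.tokens, labels, _load_phrases(empty_phrases), "empty")
        _apply_phrases(t.tokens, labels, _load_phrases(cue_phrases), "inability")
    return labels


def atypical_proportions(counts: dict[str, int], total_utterances: int) -> AtypicalProfile:
    """Divide per-category token counts by the total utterance count."""
    if total_utterances <= 0:
        raise UndefinedProportionError("proportions undefined for zero utterances")
    counts = {cat: int(counts.get(cat, 0)) for cat in CATEGORIES}
    props = {cat: counts[cat] / total_utterances for cat in CATEGORIES}
    return AtypicalProfile(counts, props, total_utterances)


def classify_atypical(t: Transcript, mode: str = "rules+annotation") -> AtypicalProfile:
    """Word-level atypical-speech profile of one transcript."""
    labels = label_tokens(t, mode=mode)
    counts = {cat: 0 for cat in CATEGORIES}
    for lab in labels:
        if lab is not None:
            counts[lab] += 1
    return atypical_proportions(counts, count_total_utterances(t))


def percent_agreement(
    ratings_a: Sequence[Optional[str]], ratings_b: Sequence[Optional[str]]
) -> float:
    """Word-level percent agreement between two raters.

    A token agrees only when the presence of a rating AND the category are
    identical (both unrated also agrees).
    """
    if len(ratings_a) != len(ratings_b):
        raise ValueError(
            f"rating length mismatch: {len(ratings_a)} vs {len(ratings_b)}"
        )
    if not ratings_a:
        raise ValueError("cannot compute agreement over zero tokens")
    hits = sum(a == b for a, b in zip(ratings_a, ratings_b))
    return 100.0 * hits / len(ratings_a)


def cohens_kappa(
    ratings_a: Sequence[Optional[str]], ratings_b: Sequence[Optional[str]]
) -> float:
    """Chance-corrected agreement; an extra output beyond the primary percent
    agreement, provided for completeness."""
    if len(ratings_a) != len(ratings_b) or not ratings_a:
        raise ValueError("ratings must be non-empty and equal length")
    n = len(ratings_a)
    po = sum(a == b for a, b in zip(ratings_a, ratings_b)) / n
    cats = set(ratings_a) | set(ratings_b)
    pe = sum(
        (sum(a == c for a in ratings_a) / n) * (sum(b == c for b in ratings_b) / n)
        for c in cats
    )
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


def heuristic_self_referential(t: Transcript) -> list[bool]:
    """Optional first-person-pronoun flag per token, reported separately from
    the annotation-driven profile (never silently merged)."""
    return [tok.normalized in _FIRST_PERSON for tok in t.tokens]
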