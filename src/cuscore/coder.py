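"""Content-unit detection, de-duplication and informativeness.

Matching is surface-lexicon-based: greedy longest-match, left-to-right, over
normalized tokens, with overlap resolved longest-then-leftmost. False-start
fragments and unrecognizable words never participate in matches. Raw CU
counting is once-per-concept (later re-mentions of a concept, even with a
different verbal description, add nothing); there is no penalty for absent
CUs. Informativeness is the raw CU count divided by the total number of
utterances (all tokens), a normalized content-efficiency measure.

Under the unique-referent scheme, mentions of a subdivided CU resolve to a
(cu_id, referent) identity via explicit referent tags; untagged mentions of
one CU collapse to a single "referent unknown" identity rather than being
guessed from context.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .atypical import classify_atypical
from .lexicon import CULexicon
from .transcripts import (
    FALSE_START,
    REFERENT_TAG,
    Transcript,
    UNRECOGNIZABLE,
    count_total_utterances,
)

_EXCLUDED_KINDS = (FALSE_START, UNRECOGNIZABLE)


class UndefinedScoreError(ZeroDivisionError):
    """Score undefined (zero utterances)."""


class CodingError(ValueError):
    """Inconsistent referent tagging."""


@dataclass(frozen=True)
class CUMatch:
    start: int  # 0-based half-open token span
    end: int
    cu_id: int
    sub_id: Optional[str] = None  # referent letter, uniqueref method only
    method: str = "original"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def match_cus(t: Transcript, lex: CULexicon) -> list[CUMatch]:
    """Greedy longest-match left-to-right CU detection."""
    table = lex.match_table
    max_len = lex.max_phrase_len
    tokens = t.tokens
    matches: list[CUMatch] = []
    i = 0
    n = len(tokens)
    while i < n:
        if tokens[i].kind in _EXCLUDED_KINDS:
            i += 1
            continue
        advanced = False
        for length in range(min(max_len, n - i), 0, -1):
            window = tokens[i : i + length]
            if any(w.kind in _EXCLUDED_KINDS for w in window):
                continue
            key = tuple(w.normalized for w in window)
            if key in table:
                matches.append(CUMatch(i, i + length, table[key]))
                i += length
                advanced = True
                break
        if not advanced:
            i += 1
    return matches


def raw_cu_count_original(matches: list[CUMatch]) -> int:
    """Number of distinct CUs mentioned at least once."""
    return len({m.cu_id for m in matches})


def resolve_referents(
    matches: list[CUMatch], t: Transcript, lex: CULexicon
) -> list[CUMatch]:
    """Attach referent letters to matches of subdivided CUs from [CUnn:x] tags."""
    tags = [a for a in t.annotations if a.label == REFERENT_TAG]
    resolved: list[CUMatch] = []
    subdivided = set(lex.subdivided_ids)
    for m in matches:
        sub_id = None
        if m.cu_id in subdivided:
            for tag in tags:
                if m.start <= tag.start < m.end:
                    tagged_cu = int("".join(ch for ch in tag.payload if ch.isdigit()))
                    letter = tag.payload[len(str(tagged_cu)):]
                    if tagged_cu != m.cu_id:
                        raise CodingError(
                            f"referent tag CU{tagged_cu}:{letter} on a mention "
                            f"of CU {m.cu_id}"
                        )
                    if letter not in lex.sub_letters(m.cu_id):
                        raise CodingError(
                            f"CU {m.cu_id} has no referent sub-unit {letter!r}"
                        )
                    sub_id = letter
                    break
        resolved.append(CUMatch(m.start, m.end, m.cu_id, sub_id, "uniqueref"))
    return resolved


def raw_cu_count_uniqueref(
    matches: list[CUMatch], t: Transcript, lex: CULexicon
) -> int:
    """Distinct scoreable identities under the unique-referent scheme.

    Splitting by referent can only add identities, so this count is always
    >= the original-method count on the same matches.
    """
    subdivided = set(lex.subdivided_ids)
    identities = set()
    for m in resolve_referents(matches, t, lex):
        if m.cu_id in subdivided:
            identities.add((m.cu_id, m.sub_id or "unknown"))
        else:
            identities.add((m.cu_id, None))
    return len(identities)


def informativeness(raw_cu: int, total_utterances: int) -> float:
    """raw CU count / all utterances, as a proportion in [0, 1]."""
    if total_utterances <= 0:
        raise UndefinedScoreError("informativeness undefined for zero utterances")
    return raw_cu / total_utterances


@dataclass
class ParticipantScore:
    participant_id: str
    group: str
    total_utterances: int
    raw_cu_original: int
    raw_cu_uniqueref: int
    informativeness_original: float
    informativeness_uniqueref: float
    atypical_counts: dict[str, int] = field(default_factory=dict)
    atypical_proportions: dict[str, float] = field(default_factory=dict)
    matches: list[CUMatch] = field(default_factory=list)


def score_participant(
    t: Transcript, lex: CULexicon, atypical_mode: str = "rules+annotation"
) -> ParticipantScore:
    """Full per-participant scoring under both coding schemes."""
    total = count_total_utterances(t)
    if total == 0:
        raise UndefinedScoreError(
            f"participant {t.participant_id!r}: empty transcript"
        )
    matches = match_cus(t, lex)
    raw_orig = raw_cu_count_original(matches)
    raw_uniq = raw_cu_count_uniqueref(matches, t, lex)
    profile = classify_atypical(t, mode=atypical_mode)
    return ParticipantScore(
        participant_id=t.participant_id,
        group=t.group,
        total_utterances=total,
        raw_cu_original=raw_orig,
        raw_cu_uniqueref=raw_uniq,
        informativeness_original=informativeness(raw_orig, total),
        informativeness_uniqueref=informativeness(raw_uniq, total),
        atypical_counts=dict(profile.counts),
        atypical_proportions=dict(profile.proportions),
        matches=resolve_referents(matches, t, lex),
    )


def scores_to_frame(scores: list[ParticipantScore]) -> pd.DataFrame:
    """Per-participant score table (one row each), ready for CSV export."""
    rows = []
    for s in scores:
        row = {
            "participant_id": s.participant_id,
            "group": s.group,
            "total_utterances": s.total_utterances,
            "raw_cu_original": s.raw_cu_original,
            "raw_cu_uniqueref": s.raw_cu_uniqueref,
            "informativeness_original": s.informativeness_original,
            "informativeness_uniqueref": s.informativeness_uniqueref,
        }
        for cat, prop in s.atypical_proportions.items():
            row[f"p_{cat}"] = prop
        rows.append(row)
    return pd.DataFrame(rows)


def matches_to_frame(scores: list[ParticipantScore]) -> pd.DataFrame:
    """Match audit log (one row per CU mention) for coder review."""
    rows = []
    for s in scores:
        for m in s.matches:
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "start": m.start,
                    "end": m.end,
                    "cu_id": m.cu_id,
                    "sub_id": m.sub_id or "",
                    "method": m.method,
                }
            )
    return pd.DataFrame(
        rows, columns=["participant_id", "start", "end", "cu_id", "sub_id", "method"]
    )
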