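"""Transcript parsing under the study's transcription conventions.

File grammar (UTF-8 plain text, one breath-group per line):

* whitespace-delimited tokens; punctuation other than apostrophes is dropped
  in the normalized form, matching is case-insensitive;
* ``&``-prefixed and/or ``-``-suffixed tokens are false-start fragments
  (phonemic clusters followed by self-correction or rerouting);
* ``xxx`` is an unrecognizable word (counts as empty speech);
* ``{heard→intended}`` records a corrected phonemic error: the intended word
  replaces the surface form, the raw form is kept for round-tripping;
* inline span tags ``<sr>…</sr>`` (self-referential), ``<in>…</in>``
  (inability), ``<tg>…</tg>`` (tangential), ``<em>…</em>`` (empty),
  ``<fs>…</fs>`` (false start) mark rater judgments; spans close on the line
  they open;
* ``[CU45:b]`` immediately after a token assigns a referent tag for the
  unique-referent coding scheme;
* lines starting with ``#`` are comments.

An "utterance" here is any verbalization attempt at the token level — single
words, fillers, and false starts all count — so the total utterance count is
simply the number of tokens. This is the informativeness denominator.
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from ._text import load_word_list, normalize_token

GROUPS = ("svPPA", "lvPPA", "nfvPPA", "HC")

WORD = "word"
FILLER = "filler"
FALSE_START = "false_start_fragment"
UNRECOGNIZABLE = "unrecognizable"

REFERENT_TAG = "referent_tag"
SPAN_LABELS = {
    "sr": "self_referential",
    "in": "inability",
    "tg": "tangential",
    "em": "empty",
    "fs": "false_start",
}
_LABEL_TO_TAG = {v: k for k, v in SPAN_LABELS.items()}

_TAG_RE = re.compile(r"(</?(?:sr|in|tg|em|fs)>)")
_REF_RE = re.compile(r"^(?P<base>.*?)\[CU(?P<cu>\d+):(?P<sub>[A-Za-z0-9]+)\]$")
_CORR_RE = re.compile(r"^\{(?P<heard>[^{}]+?)(?:→|->)(?P<intended>[^{}]+?)\}(?P<trail>\W*)$")

DEFAULT_FILLERS = "fillers.txt"


class TranscriptParseError(ValueError):
    """Malformed transcript file."""


class ManifestError(KeyError):
    """Participant missing from, or malformed, cohort manifest."""


@dataclass
class Token:
    surface: str
    normalized: str
    kind: str
    index: int
    line: int = 0
    raw: str = ""  # original file form, for loss-less serialization


@dataclass(frozen=True)
class AnnotationSpan:
    start: int  # 0-based half-open token range
    end: int
    label: str
    payload: Optional[str] = None  # sub_id for referent tags, e.g. "45b"


@dataclass
class Transcript:
    participant_id: str
    group: str
    tokens: list[Token] = field(default_factory=list)
    annotations: list[AnnotationSpan] = field(default_factory=list)


def load_fillers(source=DEFAULT_FILLERS) -> set[tuple[str, ...]]:
    """Filler list as normalized token tuples (unigrams and bigrams)."""
    return {
        tuple(normalize_token(w) for w in entry.split())
        for entry in load_word_list(source)
    }


_DEFAULT_FILLER_SET = None


def default_fillers() -> set[tuple[str, ...]]:
    global _DEFAULT_FILLER_SET
    if _DEFAULT_FILLER_SET is None:
        _DEFAULT_FILLER_SET = load_fillers()
    return _DEFAULT_FILLER_SET


def _mark_fillers(tokens: list[Token], fillers: set[tuple[str, ...]]) -> None:
    unigrams = {f[0] for f in fillers if len(f) == 1}
    bigrams = {f for f in fillers if len(f) == 2}
    for tok in tokens:
        if tok.kind == WORD and tok.normalized in unigrams:
            tok.kind = FILLER
    for i in range(len(tokens) - 1):
        a, b = tokens[i], tokens[i + 1]
        if (
            a.line == b.line
            and a.kind in (WORD, FILLER)
            and b.kind in (WORD, FILLER)
            and (a.normalized, b.normalized) in bigrams
        ):
            a.kind = FILLER
            b.kind = FILLER


def _make_token(piece: str, index: int, line: int) -> Optional[Token]:
    raw = piece
    corr = _CORR_RE.match(piece)
    if corr:
        surface = corr.group("intended")
        norm = normalize_token(surface)
        if not norm:
            return None
        return Token(surface, norm, WORD, index, line, raw)
    stripped = normalize_token(piece)
    if stripped == "xxx":
        return Token(piece, "", UNRECOGNIZABLE, index, line, raw)
    bare = piece
    is_false_start = False
    if bare.startswith("&"):
        is_false_start = True
        bare = bare[1:]
    if bare.rstrip(".,!?;:").endswith("-"):
        is_false_start = True
        bare = bare.rstrip(".,!?;:")[:-1]
    norm = normalize_token(bare)
    if not norm:
        return None  # punctuation-only piece
    kind = FALSE_START if is_false_start else WORD
    return Token(bare if is_false_start else piece.strip(), norm, kind, index, line, raw)


def tokenize(line: str, fillers: Optional[set] = None) -> list[Token]:
    """Tokenize a plain line (no span tags) into Tokens."""
    if fillers is None:
        fillers = default_fillers()
    tokens: list[Token] = []
    for piece in line.split():
        tok = _make_token(piece, len(tokens), 0)
        if tok is not None:
            tokens.append(tok)
    _mark_fillers(tokens, fillers)
    return tokens


def parse_transcript_text(
    text: str,
    participant_id: str = "",
    group: str = "",
    fillers: Optional[set] = None,
) -> Transcript:
    """Parse transcript text into tokens and annotation spans."""
    if fillers is None:
        fillers = default_fillers()
    tokens: list[Token] = []
    annotations: list[AnnotationSpan] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        open_tag: Optional[tuple[str, int]] = None
        for segment in _TAG_RE.split(line):
            if not segment:
                continue
            if _TAG_RE.fullmatch(segment):
                closing = segment.startswith("</")
                label = SPAN_LABELS[segment.strip("</>").lower()]
                if closing:
                    if open_tag is None or open_tag[0] != label:
                        raise TranscriptParseError(
                            f"line {lineno}: stray closing tag {segment}"
                        )
                    start = open_tag[1]
                    if start == len(tokens):
                        raise TranscriptParseError(f"line {lineno}: empty span {segment}")
                    annotations.append(AnnotationSpan(start, len(tokens), label))
                    open_tag = None
                else:
                    if open_tag is not None:
                        raise TranscriptParseError(
                            f"line {lineno}: nested tag {segment} inside open span"
                        )
                    open_tag = (label, len(tokens))
                continue
            for piece in segment.split():
                payload = None
                ref = _REF_RE.match(piece)
                if ref:
                    payload = f"{ref.group('cu')}{ref.group('sub').lower()}"
                    piece = ref.group("base")
                elif "[CU" in piece:
                    raise TranscriptParseError(
                        f"line {lineno}: malformed referent tag in {piece!r}"
                    )
                if piece:
                    tok = _make_token(piece, len(tokens), lineno)
                    if tok is None:
                        if payload is not None:
                            raise TranscriptParseError(
                                f"line {lineno}: referent tag on empty token"
                            )
                        continue
                    tokens.append(tok)
                    target = tok.index
                else:
                    if not tokens:
                        raise TranscriptParseError(
                            f"line {lineno}: referent tag with no preceding token"
                        )
                    target = len(tokens) - 1
                if payload is not None:
                    annotations.append(
                        AnnotationSpan(target, target + 1, REFERENT_TAG, payload)
                    )
        if open_tag is not None:
            raise TranscriptParseError(
                f"line {lineno}: span <{_LABEL_TO_TAG[open_tag[0]]}> not closed"
            )
    _mark_fillers(tokens, fillers)
    return Transcript(participant_id, group, tokens, annotations)


def load_manifest(path) -> dict[str, str]:
    """Cohort manifest CSV (header participant_id,group) -> mapping."""
    mapping: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) < {"participant_id", "group"}:
            raise ManifestError(f"manifest {path} lacks participant_id/group header")
        for row in reader:
            group = row["group"].strip()
            if group not in GROUPS:
                raise ManifestError(f"unknown group {group!r} in manifest {path}")
            mapping[row["participant_id"].strip()] = group
    return mapping


def write_manifest(mapping: dict[str, str], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "group"])
        for pid, group in mapping.items():
            writer.writerow([pid, group])


def parse_transcript(path, manifest, fillers: Optional[set] = None) -> Transcript:
    """Parse a transcript file; the participant id is the file stem."""
    if not isinstance(manifest, dict):
        manifest = load_manifest(manifest)
    path = Path(path)
    pid = path.stem
    if pid not in manifest:
        raise ManifestError(f"participant {pid!r} not in cohort manifest")
    transcript = parse_transcript_text(
        path.read_text(encoding="utf-8"), pid, manifest[pid], fillers
    )
    return transcript


def count_total_utterances(t: Transcript) -> int:
    """Every token — word, filler, false start, unrecognizable — is one
    verbalization attempt; this is the informativeness denominator."""
    return len(t.tokens)


def _render_token(tok: Token) -> str:
    if tok.raw:
        return tok.raw
    if tok.kind == UNRECOGNIZABLE:
        return "xxx"
    if tok.kind == FALSE_START:
        return f"&{tok.normalized}-"
    return tok.surface


def write_transcript(t: Transcript, path=None) -> str:
    """Serialize to the canonical file form; optionally write to ``path``."""
    ref_by_index: dict[int, str] = {}
    opens: dict[int, list[str]] = {}
    closes: dict[int, list[str]] = {}
    for ann in t.annotations:
        if ann.label == REFERENT_TAG:
            m = re.match(r"(\d+)([a-z0-9]+)", ann.payload)
            ref_by_index[ann.start] = f"[CU{m.group(1)}:{m.group(2)}]"
        else:
            tag = _LABEL_TO_TAG[ann.label]
            opens.setdefault(ann.start, []).append(f"<{tag}>")
            closes.setdefault(ann.end - 1, []).append(f"</{tag}>")
    lines: list[str] = []
    current_line = None
    parts: list[str] = []
    for tok in t.tokens:
        if tok.line != current_line and parts:
            lines.append(" ".join(parts))
            parts = []
        current_line = tok.line
        rendered = _render_token(tok) + ref_by_index.get(tok.index, "")
        for tag in opens.get(tok.index, []):
            parts.append(tag)
        parts.append(rendered)
        for tag in closes.get(tok.index, []):
            parts.append(tag)
    if parts:
        lines.append(" ".join(parts))
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
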