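"""Low-level text normalization shared by the lexicon and transcript layers."""
from __future__ import annotations

import re
from importlib import resources

_KEEP = re.compile(r"[^a-z0-9']")


def normalize_token(piece: str) -> str:
    """Lowercase and strip punctuation except apostrophes.

    Markers (leading ``&``, trailing ``-``, braces) are handled upstream by
    the tokenizer; this is the final surface normalization, so ``Can't,`` ->
    ``can't`` and ``t-shirt`` -> ``tshirt``.
    """
    return _KEEP.sub("", piece.lower())


def normalize_phrase(phrase: str) -> tuple[str, ...]:
    """Normalize a whitespace-delimited phrase into a token tuple."""
    out = []
    for piece in phrase.split():
        norm = normalize_token(piece)
        if norm:
            out.append(norm)
    return tuple(out)


def inflections(word: str) -> set[str]:
    """Deterministic English-lite inflection table: plural s/es, -ing, -ed.

    Intentionally small (no lemmatizer dependency); applied only to
    single-token lexicon variants when the match table is built.
    """
    out: set[str] = set()
    if word.endswith(("s", "x", "z", "ch", "sh")):
        out.add(word + "es")
    elif word.endswith("y") and len(word) > 2 and word[-2] not in "aeiou":
        out.add(word[:-1] + "ies")
    else:
        out.add(word + "s")
    if word.endswith("e"):
        out.add(word[:-1] + "ing")
        out.add(word + "d")
    else:
        out.add(word + "ing")
        out.add(word + "ed")
    return out


def packaged_path(name: str):
    """Path to a packaged data file."""
    return resources.files("cuscore.data").joinpath(name)


def load_word_list(name_or_path) -> list[str]:
    """Read a packaged or user word/phrase list (one entry per line,
    ``#`` comments and blank lines ignored)."""
    if isinstance(name_or_path, str) and "/" not in name_or_path and not name_or_path.endswith((".txt",)):
        raise ValueError(f"not a word-list path: {name_or_path!r}")
    try:
        text = packaged_path(name_or_path).read_text(encoding="utf-8") \
            if isinstance(name_or_path, str) and "/" not in name_or_path else None
    except FileNotFoundError:
        text = None
    if text is None:
        with open(name_or_path, encoding="utf-8") as fh:
            text = fh.read()
    entries = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            entries.append(line)
    return entries
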