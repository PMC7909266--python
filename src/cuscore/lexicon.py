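"""Content-unit (CU) lexicon for picture-description scoring.

A CU is a unique picture-relevant concept, operationalized as the set of
verbal descriptions ("variants") healthy controls used for it. The packaged
fixture is the 64-concept dictionary for the WAB-R "Picnic Scene" stimulus;
ambiguous CUs additionally carry referent sub-units used by the
unique-referent (uniqueref) coding scheme, under which the same word applied
to a different picture entity counts as a new CU.
"""
from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Optional, Union

from ._text import inflections, normalize_phrase, packaged_path

NO_PATTERN = "no-pattern"
PACKAGED_LEXICON = "picnic_lexicon.tsv"
PACKAGED_LEXICON_JSON = "picnic_lexicon.json"

CATEGORIES = frozenset(
    {
        "unambiguous-entity",
        "unambiguous-action",
        "unambiguous-property",
        "ambiguous-entity",
        "ambiguous-action",
        "ambiguous-property",
        "inferred",
        "spatial-relation",
    }
)

_TSV_COLUMNS = ("cu_id", "sub_id", "category", "variant", "control_count", "referents")


class LexiconError(ValueError):
    """Malformed lexicon file or inconsistent lexicon content."""


@dataclass(frozen=True)
class ReferentSubCU:
    """A referent-disambiguated identity of an ambiguous parent CU.

    ``referents`` is either a frozenset of entity cu_ids (possibly composite,
    e.g. {11, 12, 8, 42} for "family" construed as the whole group) or the
    :data:`NO_PATTERN` sentinel when control speech showed no referent
    pattern.
    """

    sub_id: str
    parent_cu: int
    referents: Union[frozenset, str]
    control_count: Optional[int] = None

    @property
    def letter(self) -> str:
        return self.sub_id[len(str(self.parent_cu)):]


@dataclass
class ContentUnit:
    """One concept: id, category, variant phrases and referent sub-units."""

    cu_id: int
    category: str
    variants: list[tuple[str, ...]]
    control_count: int
    sub_cus: list[ReferentSubCU] = field(default_factory=list)
    referent_note: Optional[str] = None  # parent-level referent info (#44, #54)

    @property
    def subdivided(self) -> bool:
        return bool(self.sub_cus)


@dataclass
class CULexicon:
    """The full concept dictionary, keyed by cu_id."""

    units: dict[int, ContentUnit]

    @property
    def n_parents(self) -> int:
        return len(self.units)

    @property
    def n_sub_cus(self) -> int:
        return sum(len(u.sub_cus) for u in self.units.values())

    @property
    def subdivided_ids(self) -> list[int]:
        return sorted(cid for cid, u in self.units.items() if u.subdivided)

    def sub_letters(self, cu_id: int) -> list[str]:
        return [s.letter for s in self.units[cu_id].sub_cus]

    @cached_property
    def match_table(self) -> dict[tuple[str, ...], int]:
        """Normalized phrase tuple -> owning cu_id.

        Exact variant phrases are authoritative and must be globally unique.
        Inflected forms (single-token variants only) are added unless the form
        is already an exact variant elsewhere; inflected forms claimed by two
        different CUs are dropped as ambiguous.
        """
        exact: dict[tuple[str, ...], int] = {}
        for unit in self.units.values():
            for variant in unit.variants:
                if variant in exact and exact[variant] != unit.cu_id:
                    raise LexiconError(
                        f"variant {' '.join(variant)!r} owned by both CU "
                        f"{exact[variant]} and CU {unit.cu_id}"
                    )
                exact[variant] = unit.cu_id
        table = dict(exact)
        inflected: dict[tuple[str, ...], int] = {}
        ambiguous: set[tuple[str, ...]] = set()
        for unit in self.units.values():
            for variant in unit.variants:
                if len(variant) != 1:
                    continue
                for form in inflections(variant[0]):
                    key = (form,)
                    if key in exact:
                        continue  # exact claim wins
                    if key in inflected and inflected[key] != unit.cu_id:
                        ambiguous.add(key)
                    else:
                        inflected[key] = unit.cu_id
        for key, cid in inflected.items():
            if key not in ambiguous:
                table[key] = cid
        return table

    @property
    def max_phrase_len(self) -> int:
        return max(len(k) for k in self.match_table)


def _parse_referents(text: str) -> Union[frozenset, str]:
    text = text.strip()
    if text.lower() in (NO_PATTERN, "no pattern"):
        return NO_PATTERN
    ids = [p for p in re.split(r"[,+]", text) if p.strip()]
    return frozenset(int(p) for p in ids)


def load_lexicon(path=None) -> "CULexicon":
    """Load a lexicon from TSV or JSON (packaged fixture by default)."""
    if path is None:
        path = packaged_path(PACKAGED_LEXICON)
    suffix = str(path).rsplit(".", 1)[-1].lower()
    text = Path(path).read_text(encoding="utf-8") if isinstance(path, (str, Path)) \
        else path.read_text(encoding="utf-8")
    if suffix == "json":
        return _lexicon_from_json(text)
    return _lexicon_from_tsv(text)


def _lexicon_from_tsv(text: str) -> CULexicon:
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    rows = list(reader)
    if not rows:
        raise LexiconError("empty lexicon file")
    header = tuple(h.strip() for h in rows[0])
    if header != _TSV_COLUMNS:
        raise LexiconError(f"bad header {header!r}; expected {_TSV_COLUMNS!r}")
    units: dict[int, ContentUnit] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        row = list(row) + [""] * (len(_TSV_COLUMNS) - len(row))
        cu_raw, sub_id, category, variant, count_raw, referents = (c.strip() for c in row[:6])
        try:
            cu_id = int(cu_raw)
        except ValueError:
            raise LexiconError(f"line {lineno}: bad cu_id {cu_raw!r}") from None
        if category not in CATEGORIES:
            raise LexiconError(f"line {lineno}: unknown category {category!r}")
        count = None
        if count_raw:
            try:
                count = int(count_raw)
            except ValueError:
                raise LexiconError(f"line {lineno}: bad control count {count_raw!r}") from None
        if sub_id:  # referent sub-unit row
            if cu_id not in units:
                raise LexiconError(f"line {lineno}: sub-CU {sub_id} before parent {cu_id}")
            if not referents:
                raise LexiconError(f"line {lineno}: sub-CU {sub_id} lacks referents")
            units[cu_id].sub_cus.append(
                ReferentSubCU(sub_id, cu_id, _parse_referents(referents), count)
            )
            continue
        if not variant:
            raise LexiconError(f"line {lineno}: parent row without a variant")
        if count is None:
            raise LexiconError(f"line {lineno}: parent row without a control count")
        phrase = normalize_phrase(variant)
        if not phrase or len(phrase) > 4:
            raise LexiconError(f"line {lineno}: bad variant {variant!r}")
        if cu_id in units:
            unit = units[cu_id]
            if unit.category != category or unit.control_count != count:
                raise LexiconError(
                    f"line {lineno}: CU {cu_id} redefined with conflicting "
                    "category or control count"
                )
            unit.variants.append(phrase)
            if referents and unit.referent_note is None:
                unit.referent_note = referents
        else:
            units[cu_id] = ContentUnit(
                cu_id, category, [phrase], count,
                referent_note=referents or None,
            )
    if not units:
        raise LexiconError("lexicon file contains no content units")
    return CULexicon(units)


def _lexicon_from_json(text: str) -> CULexicon:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise LexiconError(f"bad lexicon JSON: {exc}") from exc
    units: dict[int, ContentUnit] = {}
    for entry in payload["units"]:
        cu_id = int(entry["cu_id"])
        if cu_id in units:
            raise LexiconError(f"duplicate cu_id {cu_id}")
        subs = [
            ReferentSubCU(
                s["sub_id"], cu_id,
                NO_PATTERN if s["referents"] == NO_PATTERN else frozenset(s["referents"]),
                s.get("control_count"),
            )
            for s in entry.get("sub_cus", [])
        ]
        units[cu_id] = ContentUnit(
            cu_id,
            entry["category"],
            [tuple(v.split()) for v in entry["variants"]],
            int(entry["control_count"]),
            subs,
            entry.get("referent_note"),
        )
    if not units:
        raise LexiconError("lexicon file contains no content units")
    return CULexicon(units)


def lexicon_to_json(lex: CULexicon) -> str:
    payload = {
        "units": [
            {
                "cu_id": u.cu_id,
                "category": u.category,
                "variants": [" ".join(v) for v in u.variants],
                "control_count": u.control_count,
                "referent_note": u.referent_note,
                "sub_cus": [
                    {
                        "sub_id": s.sub_id,
                        "referents": (
                            NO_PATTERN if s.referents == NO_PATTERN
                            else sorted(s.referents)
                        ),
                        "control_count": s.control_count,
                    }
                    for s in u.sub_cus
                ],
            }
            for _, u in sorted(lex.units.items())
        ]
    }
    return json.dumps(payload, indent=1)


def write_lexicon(lex: CULexicon, path) -> None:
    """Serialize to TSV or JSON (by file suffix); round-trips exactly."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(lexicon_to_json(lex), encoding="utf-8")
        return
    lines = ["\t".join(_TSV_COLUMNS)]
    for _, u in sorted(lex.units.items()):
        for i, variant in enumerate(u.variants):
            note = u.referent_note or ""
            lines.append(
                f"{u.cu_id}\t\t{u.category}\t{' '.join(variant)}\t{u.control_count}\t{note}"
            )
        for s in u.sub_cus:
            ref = s.referents if s.referents == NO_PATTERN else ",".join(
                str(r) for r in sorted(s.referents)
            )
            cc = "" if s.control_count is None else str(s.control_count)
            lines.append(f"{u.cu_id}\t{s.sub_id}\t{u.category}\t\t{cc}\t{ref}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def validate_lexicon(lex: CULexicon, min_controls: int = 3) -> list[str]:
    """Return human-readable violations (empty list when the lexicon is valid).

    Checks the corpus rule (every CU produced by >= ``min_controls``
    controls), global variant uniqueness, and referent resolvability.
    """
    violations: list[str] = []
    seen: dict[tuple[str, ...], int] = {}
    for cu_id, unit in sorted(lex.units.items()):
        if unit.control_count < min_controls:
            violations.append(
                f"CU {cu_id}: control count {unit.control_count} < {min_controls}"
            )
        if not unit.variants:
            violations.append(f"CU {cu_id}: no variant phrases")
        for variant in unit.variants:
            if variant in seen and seen[variant] != cu_id:
                violations.append(
                    f"variant {' '.join(variant)!r} duplicated across CU "
                    f"{seen[variant]} and CU {cu_id}"
                )
            seen[variant] = cu_id
        for sub in unit.sub_cus:
            if sub.parent_cu != cu_id:
                violations.append(f"sub-CU {sub.sub_id}: parent mismatch")
            if sub.referents != NO_PATTERN:
                for ref in sub.referents:
                    if ref not in lex.units:
                        violations.append(
                            f"sub-CU {sub.sub_id}: referent CU {ref} does not exist"
                        )
    return violations


@dataclass
class UniquerefExpansion:
    """Scoreable identities under the unique-referent coding scheme."""

    identities: dict[int, list[Optional[str]]]  # cu_id -> sub letters (None = parent)
    n_identities: int
    n_sub_identities: int
    n_additional: int  # identities beyond the original one-per-CU scheme


def expand_uniqueref(lex: CULexicon) -> UniquerefExpansion:
    """Enumerate scoreable identities for the uniqueref scheme.

    Subdivided CUs contribute one identity per referent sub-unit plus a
    parent-level "referent unknown" fallback; all other CUs contribute their
    single parent identity.
    """
    identities: dict[int, list[Optional[str]]] = {}
    for cu_id, unit in sorted(lex.units.items()):
        if unit.subdivided:
            identities[cu_id] = [s.letter for s in unit.sub_cus] + ["unknown"]
        else:
            identities[cu_id] = [None]
    n_ident = sum(len(v) for v in identities.values())
    n_subs = lex.n_sub_cus
    return UniquerefExpansion(
        identities=identities,
        n_identities=n_ident,
        n_sub_identities=n_subs,
        n_additional=n_ident - lex.n_parents,
    )


def lookup_variant(lex: CULexicon, phrase) -> Optional[int]:
    """Map a normalized phrase (string or token tuple) to its owning cu_id."""
    if isinstance(phrase, str):
        phrase = tuple(phrase.split())
    return lex.match_table.get(tuple(phrase))
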