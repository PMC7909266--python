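"""Seeded synthetic picnic-scene transcript generator with known ground truth.

Real patient transcripts are not public, so every pipeline stage is exercised
on synthetic cohorts that reproduce the statistical structure of the study
groups: per-group utterance-count distributions, informativeness
distributions, and qualitative atypical-speech profiles (svPPA dominated by
self-referential tangents and inability statements; lvPPA by empty speech and
false starts; nfvPPA and controls low on all five).

Per participant the generator draws a total utterance count U (truncated
normal, >= 10 tokens) and an informativeness proportion p (truncated normal
on [0, 1]), targets C = round(p*U) distinct content units (clamped to [0, 64]),
realizes each CU once through a randomly chosen lexicon variant, embeds
atypical material at the profile's per-category token rates, and fills the
rest with distractor words screened to never match the lexicon. Because each
CU appears exactly once and nothing else can match, the pipeline's raw CU
count recovers C exactly — the generator's ground truth is a strict oracle.

Fixed seed implies byte-identical output. The generator does not attempt
linguistically realistic syntax.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy.stats import truncnorm

from . import reference
from ._text import load_word_list, normalize_token
from .atypical import DEFAULT_CUES, DEFAULT_EMPTY_PHRASES
from .lexicon import CULexicon, load_lexicon
from .transcripts import (
    GROUPS,
    Transcript,
    default_fillers,
    parse_transcript_text,
    write_manifest,
)

DEFAULT_DISTRACTORS = "distractors.txt"
MIN_UTTERANCES = 10

# Qualitative per-category token rates (proportion of all utterances).
# The study reports these only as group contrasts (no printed rates), so the
# defaults are free parameters chosen to realize the reported ordering:
# svPPA highest on self-referential/inability, lvPPA highest on empty speech
# and false starts, controls and nfvPPA low throughout.
DEFAULT_ATYPICAL_RATES = {
    "HC": {"self_referential": 0.01, "inability": 0.01, "tangential": 0.01,
           "empty": 0.04, "false_start": 0.01},
    "svPPA": {"self_referential": 0.10, "inability": 0.08, "tangential": 0.04,
              "empty": 0.06, "false_start": 0.02},
    "lvPPA": {"self_referential": 0.02, "inability": 0.08, "tangential": 0.02,
              "empty": 0.14, "false_start": 0.08},
    "nfvPPA": {"self_referential": 0.01, "inability": 0.02, "tangential": 0.01,
               "empty": 0.05, "false_start": 0.02},
}


class GeneratorConfigError(ValueError):
    """Invalid generator configuration or distractor/lexicon collision."""


@dataclass
class GroupProfile:
    """Distributional parameters for one group."""

    group: str
    n: int
    utterance_mean: float
    utterance_sd: float
    informativeness_mean: float  # proportion in (0, 1)
    informativeness_sd: float
    atypical_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n < 2:
            raise GeneratorConfigError(f"group {self.group}: n must be >= 2")
        if not (0 < self.informativeness_mean < 1):
            raise GeneratorConfigError(
                f"group {self.group}: informativeness mean must be in (0, 1)"
            )
        if min(self.utterance_sd, self.informativeness_sd) < 0:
            raise GeneratorConfigError(f"group {self.group}: negative SD")


@dataclass
class CohortConfig:
    profiles: list[GroupProfile]
    seed: int = 0
    lexicon_path: Optional[str] = None

    def lexicon(self) -> CULexicon:
        return load_lexicon(self.lexicon_path)


@dataclass
class TruthRecord:
    """Ground truth for one generated participant."""

    participant_id: str
    group: str
    total_utterances: int
    n_cus: int  # distinct CUs realized (== pipeline raw CU count)
    informativeness: float  # realized C/U, proportion
    drawn_informativeness: float  # the sampled target proportion
    atypical_counts: dict[str, int] = field(default_factory=dict)
    clamped: bool = False


def default_profiles() -> list[GroupProfile]:
    """Profiles matching the study conditions: group sizes 19/26/25/31,
    utterance moments per group, informativeness moments from the
    original-scheme group table (converted from percent to proportion)."""
    profiles = []
    for group in GROUPS:
        u_mean, u_sd = reference.UTTERANCE_PARAMS[group]
        info = reference.INFORMATIVENESS_ORIGINAL[group]
        profiles.append(
            GroupProfile(
                group=group,
                n=reference.GROUP_SIZES[group],
                utterance_mean=u_mean,
                utterance_sd=u_sd,
                informativeness_mean=info.mean / 100.0,
                informativeness_sd=info.sd / 100.0,
                atypical_rates=dict(DEFAULT_ATYPICAL_RATES[group]),
            )
        )
    return profiles


def default_config(seed: int = 0) -> CohortConfig:
    return CohortConfig(default_profiles(), seed=seed)


def load_cohort_config(path) -> CohortConfig:
    """Read a cohort config from YAML (keys mirror GroupProfile fields)."""
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    profiles = [GroupProfile(**entry) for entry in payload["profiles"]]
    return CohortConfig(
        profiles, seed=int(payload.get("seed", 0)),
        lexicon_path=payload.get("lexicon_path"),
    )


def write_cohort_config(config: CohortConfig, path) -> None:
    payload = {
        "seed": config.seed,
        "lexicon_path": config.lexicon_path,
        "profiles": [asdict(p) for p in config.profiles],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def _phrase_tokens(entries: list[str]) -> list[tuple[str, ...]]:
    return [tuple(normalize_token(w) for w in e.split()) for e in entries]


def screen_vocabulary(lex: CULexicon, distractors: list[str]) -> None:
    """Verify the generator's non-CU material can never match the lexicon.

    Raises when (a) any distractor, filler, cue or empty-phrase token window
    is a match-table key, or (b) a multi-token match-table key starts with a
    word that non-CU material could emit (which would allow a spurious match
    to begin inside filler/distractor text).
    """
    table = lex.match_table
    non_cu_vocab: set[str] = set()
    phrases = [(w,) for w in distractors]
    phrases += [tuple(f) for f in default_fillers()]
    phrases += _phrase_tokens(load_word_list(DEFAULT_CUES))
    phrases += _phrase_tokens(load_word_list(DEFAULT_EMPTY_PHRASES))
    for phrase in phrases:
        non_cu_vocab.update(phrase)
        for i in range(len(phrase)):
            for j in range(i + 1, min(i + 5, len(phrase) + 1)):
                if phrase[i:j] in table:
                    raise GeneratorConfigError(
                        f"vocabulary collision: {' '.join(phrase[i:j])!r} "
                        "matches the lexicon"
                    )
    for key in table:
        if len(key) > 1 and key[0] in non_cu_vocab:
            raise GeneratorConfigError(
                f"multi-token lexicon phrase {' '.join(key)!r} can start "
                "inside distractor material"
            )


def _draw_truncnorm(rng, mean, sd, lower, upper=np.inf) -> float:
    """Normal draw clamped to [lower, upper].

    Clamping (rather than renormalized truncation) keeps the expectation
    essentially at ``mean`` when the bounds sit in the far tails, which they
    do for every default profile; the recovery checks compare against the
    configured mean.
    """
    return float(np.clip(rng.normal(mean, sd), lower, upper))


_CONSONANTS = "bcdfgklmnprst"


@dataclass
class _Chunk:
    kind: str  # "cu" | "span" | "token"
    text: str
    n_tokens: int
    category: Optional[str] = None  # atypical category, if any


def _cu_chunk(cu_id: int, lex: CULexicon, rng, shortest: bool = False) -> _Chunk:
    unit = lex.units[cu_id]
    variants = [min(unit.variants, key=len)] if shortest else unit.variants
    variant = variants[rng.integers(len(variants))]
    text = " ".join(variant)
    if unit.subdivided:
        letters = lex.sub_letters(cu_id)
        letter = letters[rng.integers(len(letters))]
        text += f"[CU{cu_id}:{letter}]"
    return _Chunk("cu", text, len(variant))


def _span_chunk(tag: str, category: str, words: list[str]) -> _Chunk:
    return _Chunk("span", f"<{tag}> {' '.join(words)} </{tag}>", len(words), category)


def generate_participant(
    profile: GroupProfile,
    rng: np.random.Generator,
    lex: Optional[CULexicon] = None,
    participant_id: str = "P000",
    distractors: Optional[list[str]] = None,
) -> tuple[Transcript, TruthRecord]:
    """Generate one transcript plus its ground-truth record."""
    if lex is None:
        lex = load_lexicon()
    if distractors is None:
        distractors = load_word_list(DEFAULT_DISTRACTORS)
    cues = [c.split() for c in load_word_list(DEFAULT_CUES)]

    U = int(round(_draw_truncnorm(
        rng, profile.utterance_mean, profile.utterance_sd, MIN_UTTERANCES)))
    p = _draw_truncnorm(
        rng, profile.informativeness_mean, profile.informativeness_sd, 0.0, 1.0)
    C = int(np.clip(round(p * U), 0, lex.n_parents))
    clamped = round(p * U) > lex.n_parents

    # Realize C distinct CUs; fall back to shortest variants, then fewer CUs,
    # if the token budget cannot accommodate them.
    cu_ids = list(rng.choice(sorted(lex.units), size=C, replace=False))
    chunks = [_cu_chunk(cid, lex, rng) for cid in cu_ids]
    if sum(c.n_tokens for c in chunks) > U:
        chunks = [_cu_chunk(cid, lex, rng, shortest=True) for cid in cu_ids]
    while chunks and sum(c.n_tokens for c in chunks) > U:
        chunks.pop()
        cu_ids.pop()
        clamped = True
    C = len(cu_ids)
    cu_cost = sum(c.n_tokens for c in chunks)

    remaining = U - cu_cost
    # per-participant atypical rates jitter around the group rate (CV 0.4)
    # so category proportions carry realistic between-subject variance
    targets = {
        cat: int(round(float(np.clip(rng.normal(rate, 0.4 * rate), 0.0, 0.5)) * U))
        for cat, rate in profile.atypical_rates.items()
    }
    total_target = sum(targets.values())
    if total_target > remaining and total_target > 0:
        scale = remaining / total_target
        targets = {cat: int(np.floor(k * scale)) for cat, k in targets.items()}

    counts = {cat: 0 for cat in
              ("self_referential", "inability", "tangential", "empty", "false_start")}

    for category, tag in (("self_referential", "sr"), ("tangential", "tg")):
        todo = targets.get(category, 0)
        while todo >= 1:
            size = int(min(todo, rng.integers(2, 7))) if todo > 1 else 1
            words = [distractors[rng.integers(len(distractors))] for _ in range(size)]
            chunks.append(_span_chunk(tag, category, words))
            counts[category] += size
            todo -= size

    todo = targets.get("inability", 0)
    usable = [c for c in cues if len(c) >= 2]
    while todo >= 2:
        options = [c for c in usable if len(c) <= todo]
        cue = options[rng.integers(len(options))]
        chunks.append(_span_chunk("in", "inability", cue))
        counts["inability"] += len(cue)
        todo -= len(cue)

    filler_words = sorted({f[0] for f in default_fillers() if len(f) == 1})
    for _ in range(targets.get("empty", 0)):
        word = filler_words[rng.integers(len(filler_words))]
        chunks.append(_Chunk("token", word, 1, "empty"))
        counts["empty"] += 1

    for _ in range(targets.get("false_start", 0)):
        frag = "".join(_CONSONANTS[rng.integers(len(_CONSONANTS))]
                       for _ in range(int(rng.integers(2, 4))))
        chunks.append(_Chunk("token", f"&{frag}-", 1, "false_start"))
        counts["false_start"] += 1

    n_distract = U - sum(c.n_tokens for c in chunks)
    for _ in range(n_distract):
        chunks.append(_Chunk("token", distractors[rng.integers(len(distractors))], 1))

    order = rng.permutation(len(chunks))
    lines: list[str] = []
    line: list[str] = []
    line_tokens = 0
    for idx in order:
        chunk = chunks[idx]
        line.append(chunk.text)
        line_tokens += chunk.n_tokens
        if line_tokens >= 10:
            lines.append(" ".join(line))
            line, line_tokens = [], 0
    if line:
        lines.append(" ".join(line))
    text = "\n".join(lines) + "\n"

    transcript = parse_transcript_text(text, participant_id, profile.group)
    assert len(transcript.tokens) == U, "generator token accounting broke"
    truth = TruthRecord(
        participant_id=participant_id,
        group=profile.group,
        total_utterances=U,
        n_cus=C,
        informativeness=C / U,
        drawn_informativeness=p,
        atypical_counts=counts,
        clamped=clamped,
    )
    return transcript, truth


def generate_group(
    profile: GroupProfile,
    rng: np.random.Generator,
    lex: Optional[CULexicon] = None,
    prefix: Optional[str] = None,
) -> list[tuple[Transcript, TruthRecord]]:
    """Generate one whole group in memory."""
    if lex is None:
        lex = load_lexicon()
    distractors = load_word_list(DEFAULT_DISTRACTORS)
    screen_vocabulary(lex, distractors)
    prefix = prefix or profile.group
    return [
        generate_participant(profile, rng, lex, f"{prefix}_{i+1:03d}", distractors)
        for i in range(profile.n)
    ]


def generate_cohort_memory(
    config: CohortConfig,
) -> list[tuple[Transcript, TruthRecord]]:
    rng = np.random.default_rng(config.seed)
    lex = config.lexicon()
    out: list[tuple[Transcript, TruthRecord]] = []
    for profile in config.profiles:
        out.extend(generate_group(profile, rng, lex))
    return out


def generate_cohort(config: CohortConfig, out_dir) -> Path:
    """Write a full corpus: transcripts/, manifest.csv, truth.csv."""
    out_dir = Path(out_dir)
    (out_dir / "transcripts").mkdir(parents=True, exist_ok=True)
    pairs = generate_cohort_memory(config)
    manifest = {}
    from .transcripts import write_transcript

    for transcript, truth in pairs:
        manifest[truth.participant_id] = truth.group
        write_transcript(
            transcript, out_dir / "transcripts" / f"{truth.participant_id}.txt"
        )
    write_manifest(manifest, out_dir / "manifest.csv")
    with open(out_dir / "truth.csv", "w", newline="", encoding="utf-8") as fh:
        cats = ("self_referential", "inability", "tangential", "empty", "false_start")
        writer = csv.writer(fh)
        writer.writerow(
            ["participant_id", "group", "total_utterances", "n_cus",
             "informativeness", "drawn_informativeness"]
            + [f"n_{c}" for c in cats] + ["clamped"]
        )
        for _, truth in pairs:
            writer.writerow(
                [truth.participant_id, truth.group, truth.total_utterances,
                 truth.n_cus, f"{truth.informativeness:.6f}",
                 f"{truth.drawn_informativeness:.6f}"]
                + [truth.atypical_counts[c] for c in cats]
                + [int(truth.clamped)]
            )
    write_cohort_config(config, out_dir / "cohort_config.yaml")
    return out_dir


@dataclass
class RecoveryReport:
    violations: list[str]
    exact_cu_recovery: bool
    group_mean_utterances: dict[str, float]
    group_mean_informativeness: dict[str, float]  # proportion

    @property
    def ok(self) -> bool:
        return not self.violations


def recovery_check(
    scores, truths: list[TruthRecord], config: CohortConfig
) -> RecoveryReport:
    """Validate a scored synthetic corpus against its ground truth.

    Checks exact per-participant CU recovery, group means within two standard
    errors of the configured means, and the qualitative atypical ordering
    (svPPA highest self-referential mean; lvPPA highest empty and
    false-start means).
    """
    violations: list[str] = []
    truth_by_pid = {t.participant_id: t for t in truths}
    exact = True
    for s in scores:
        t = truth_by_pid[s.participant_id]
        if s.raw_cu_original != t.n_cus:
            exact = False
            violations.append(
                f"{s.participant_id}: raw CU {s.raw_cu_original} != truth {t.n_cus}"
            )
        if s.total_utterances != t.total_utterances:
            exact = False
            violations.append(
                f"{s.participant_id}: utterances {s.total_utterances} "
                f"!= truth {t.total_utterances}"
            )
    by_group: dict[str, list] = {}
    for s in scores:
        by_group.setdefault(s.group, []).append(s)
    mean_u: dict[str, float] = {}
    mean_info: dict[str, float] = {}
    for profile in config.profiles:
        members = by_group.get(profile.group, [])
        if not members:
            violations.append(f"group {profile.group}: no scored participants")
            continue
        n = len(members)
        mu = float(np.mean([s.total_utterances for s in members]))
        mi = float(np.mean([s.informativeness_original for s in members]))
        mean_u[profile.group] = mu
        mean_info[profile.group] = mi
        se_u = profile.utterance_sd / np.sqrt(n)
        se_i = profile.informativeness_sd / np.sqrt(n)
        if abs(mu - profile.utterance_mean) > 2 * se_u:
            violations.append(
                f"group {profile.group}: mean utterances {mu:.1f} outside "
                f"2 SE of {profile.utterance_mean}"
            )
        if abs(mi - profile.informativeness_mean) > 2 * se_i:
            violations.append(
                f"group {profile.group}: mean informativeness {mi:.3f} outside "
                f"2 SE of {profile.informativeness_mean}"
            )
    def group_mean(group: str, cat: str) -> float:
        members = by_group.get(group, [])
        return float(np.mean([s.atypical_proportions[cat] for s in members])) \
            if members else float("nan")

    if set(by_group) >= set(GROUPS):
        sr = {g: group_mean(g, "self_referential") for g in GROUPS}
        if max(sr, key=sr.get) != "svPPA":
            violations.append("svPPA is not highest on self-referential speech")
        for cat in ("empty", "false_start"):
            vals = {g: group_mean(g, cat) for g in GROUPS}
            if max(vals, key=vals.get) != "lvPPA":
                violations.append(f"lvPPA is not highest on {cat}")
    return RecoveryReport(violations, exact, mean_u, mean_info)
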