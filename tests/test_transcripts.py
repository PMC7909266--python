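"""Transcript grammar: tokenization, markers, annotation spans, round-trip."""
import pytest
from hypothesis import given, settings, strategies as st

from cuscore.transcripts import (
    FALSE_START,
    FILLER,
    ManifestError,
    TranscriptParseError,
    UNRECOGNIZABLE,
    WORD,
    count_total_utterances,
    load_manifest,
    parse_transcript,
    parse_transcript_text,
    tokenize,
    write_manifest,
    write_transcript,
)


def test_phonemic_correction_replaces_surface():
    t = parse_transcript_text("they are sitting on a {splanket→blanket}", "p", "HC")
    assert len(t.tokens) == 6
    assert t.tokens[5].surface == "blanket"
    assert t.tokens[5].normalized == "blanket"
    assert t.tokens[5].kind == WORD


def test_false_start_markers():
    t = parse_transcript_text("&sp- &spl- blanket", "p", "HC")
    kinds = [tok.kind for tok in t.tokens]
    assert kinds == [FALSE_START, FALSE_START, WORD]


def test_unrecognizable_word():
    t = parse_transcript_text("xxx", "p", "HC")
    assert [tok.kind for tok in t.tokens] == [UNRECOGNIZABLE]


def test_total_utterances_counts_every_attempt():
    t = parse_transcript_text("um the boy is run- running", "p", "HC")
    assert count_total_utterances(t) == 6
    assert t.tokens[0].kind == FILLER
    assert t.tokens[4].kind == FALSE_START


def test_empty_transcript_has_zero_utterances():
    t = parse_transcript_text("", "p", "HC")
    assert count_total_utterances(t) == 0


def test_tokenize_fillers_and_punctuation():
    toks = tokenize("Uh no, yeah I guess")
    assert len(toks) == 5
    assert toks[0].kind == FILLER
    assert toks[1].normalized == "no"
    toks2 = tokenize("um, uh")
    assert [t.kind for t in toks2] == [FILLER, FILLER]
    assert tokenize("") == []


def test_bigram_filler_marks_both_tokens():
    toks = tokenize("well you know the")
    assert [t.kind for t in toks] == [WORD, FILLER, FILLER, WORD]


def test_apostrophes_kept_case_folded():
    toks = tokenize("Can't SWIM")
    assert [t.normalized for t in toks] == ["can't", "swim"]


def test_annotation_spans_and_referent_tags():
    t = parse_transcript_text(
        "<sr> i hate fish </sr> the fellow[CU45:a] runs", "p", "svPPA"
    )
    spans = {a.label: (a.start, a.end) for a in t.annotations}
    assert spans["self_referential"] == (0, 3)
    ref = [a for a in t.annotations if a.label == "referent_tag"][0]
    assert ref.payload == "45a"
    assert t.tokens[ref.start].normalized == "fellow"


@pytest.mark.parametrize(
    "text",
    [
        "<sr> oops no close",
        "</sr> stray close",
        "<sr> nested <in> tags </in> </sr>",
        "word [CU45malformed]",
    ],
)
def test_malformed_markup_raises(text):
    with pytest.raises(TranscriptParseError):
        parse_transcript_text(text, "p", "HC")


def test_round_trip_is_canonical(tmp_path):
    original = (
        "um the {splanket→blanket} is &bl- nice\n"
        "<in> can't think of that </in> fellow[CU45:d] reading\n"
        "xxx <sr> we have one of these </sr>\n"
    )
    t1 = parse_transcript_text(original, "p", "lvPPA")
    canonical = write_transcript(t1)
    t2 = parse_transcript_text(canonical, "p", "lvPPA")
    assert [tok.normalized for tok in t2.tokens] == [tok.normalized for tok in t1.tokens]
    assert [tok.kind for tok in t2.tokens] == [tok.kind for tok in t1.tokens]
    assert t2.annotations == t1.annotations
    # serializing the canonical form is a fixed point
    assert write_transcript(t2) == canonical


def test_manifest_round_trip_and_unknown_participant(tmp_path):
    mapping = {"P1": "HC", "P2": "svPPA"}
    mpath = tmp_path / "manifest.csv"
    write_manifest(mapping, mpath)
    assert load_manifest(mpath) == mapping
    tpath = tmp_path / "P9.txt"
    tpath.write_text("hello there\n")
    with pytest.raises(ManifestError):
        parse_transcript(tpath, mpath)
    tpath2 = tmp_path / "P1.txt"
    tpath2.write_text("hello there\n")
    t = parse_transcript(tpath2, mpath)
    assert t.participant_id == "P1" and t.group == "HC"


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.sampled_from(
            ["the", "boy", "um", "&fr-", "xxx", "run-", "Nice,", "can't"]
        ),
        max_size=25,
    )
)
def test_token_count_equals_utterance_count(pieces):
    """The utterance count is by definition the token count."""
    t = parse_transcript_text(" ".join(pieces), "p", "HC")
    assert count_total_utterances(t) == len(t.tokens)
    for i, tok in enumerate(t.tokens):
        assert tok.index == i
        if tok.kind in (WORD, FILLER):
            assert tok.normalized
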