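"""CU matching, de-duplication, both coding schemes, informativeness."""
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_matches
from cuscore.coder import (
    CodingError,
    UndefinedScoreError,
    informativeness,
    match_cus,
    raw_cu_count_original,
    raw_cu_count_uniqueref,
    score_participant,
)
from cuscore.transcripts import Transcript, parse_transcript_text


def _parse(text, group="HC"):
    return parse_transcript_text(text, "p", group)


def test_basic_matching(lexicon):
    t = _parse("the man is fishing on the dock")
    assert sorted({m.cu_id for m in match_cus(t, lexicon)}) == [13, 33, 43]


def test_longest_match_wins(lexicon):
    t = _parse("they were having a good time there")
    ms = match_cus(t, lexicon)
    assert [(m.cu_id, m.span) for m in ms] == [(38, (2, 6))]


def test_repeated_concept_different_words_counts_once(lexicon):
    t = _parse("a dog chased and then the puppy sat")
    ms = match_cus(t, lexicon)
    assert [m.cu_id for m in ms if m.cu_id == 4] == [4, 4]
    assert raw_cu_count_original(ms) == 2  # dog + chased


def test_excluded_kinds_never_match(lexicon):
    t = _parse("&fi- xxx")
    assert match_cus(t, lexicon) == []
    # a false start cannot sit inside a multi-token match either
    t2 = _parse("next &uh- to")
    assert match_cus(t2, lexicon) == []


def test_uniqueref_splits_tagged_referents(lexicon):
    t = _parse("fellow[CU45:a] and then that fellow[CU45:d]")
    ms = match_cus(t, lexicon)
    assert raw_cu_count_original(ms) == 1
    assert raw_cu_count_uniqueref(ms, t, lexicon) == 2


def test_uniqueref_untagged_mentions_collapse(lexicon):
    t = _parse("fellow and then that fellow again")
    ms = match_cus(t, lexicon)
    assert raw_cu_count_uniqueref(ms, t, lexicon) == 1


def test_uniqueref_equals_original_without_ambiguous_cus(lexicon):
    t = _parse("the dog and the kite by the sailboat")
    ms = match_cus(t, lexicon)
    assert raw_cu_count_uniqueref(ms, t, lexicon) == raw_cu_count_original(ms) == 3


def test_wrong_referent_tag_is_a_coding_error(lexicon):
    t = _parse("fellow[CU43:a]")  # tag claims CU 43 on a CU 45 mention
    ms = match_cus(t, lexicon)
    with pytest.raises(CodingError):
        raw_cu_count_uniqueref(ms, t, lexicon)
    t2 = _parse("fellow[CU45:z]")  # no such sub-unit
    ms2 = match_cus(t2, lexicon)
    with pytest.raises(CodingError):
        raw_cu_count_uniqueref(ms2, t2, lexicon)


def test_informativeness_ratio():
    assert informativeness(15, 100) == pytest.approx(0.15)
    assert informativeness(0, 50) == 0.0
    with pytest.raises(UndefinedScoreError):
        informativeness(3, 0)


def test_score_participant_worked_example(lexicon):
    """Hand-scored toy description: 11 utterances (word, filler and false
    start each count), 4 CUs (boy, flying, kite, beach), informativeness
    4/11 under both schemes."""
    t = _parse("um the boy is &fl- flying a kite at the beach")
    s = score_participant(t, lexicon)
    assert s.total_utterances == 11
    assert s.raw_cu_original == 4
    assert s.raw_cu_uniqueref == 4
    assert s.informativeness_original == pytest.approx(4 / 11)
    assert s.atypical_counts["empty"] == 1  # um
    assert s.atypical_counts["false_start"] == 1  # &fl-


def test_score_empty_transcript_errors(lexicon):
    with pytest.raises(UndefinedScoreError):
        score_participant(_parse(""), lexicon)


def test_all_filler_transcript_scores_zero(lexicon):
    s = score_participant(_parse("um uh er um"), lexicon)
    assert s.raw_cu_original == 0
    assert s.informativeness_original == 0.0


def test_scoring_is_idempotent(lexicon):
    t = _parse("the man is fishing on the dock next to the sailboat")
    s1, s2 = score_participant(t, lexicon), score_participant(t, lexicon)
    assert s1 == s2


def test_match_cus_agrees_with_brute_force(lexicon, random_token_transcripts):
    table = lexicon.match_table
    for t in random_token_transcripts:
        got = [(m.start, m.end, m.cu_id) for m in match_cus(t, lexicon)]
        assert got == brute_force_matches(t.tokens, table)


def test_line_permutation_leaves_counts_unchanged(lexicon):
    lines = [
        "the boy is flying a kite",
        "a dog chasing the boy",
        "someone fishing off the pier",
        "um the picnic basket and wine",
    ]
    base = None
    for perm in ([0, 1, 2, 3], [3, 2, 1, 0], [2, 0, 3, 1]):
        t = _parse("\n".join(lines[i] for i in perm))
        ms = match_cus(t, lexicon)
        counts = (raw_cu_count_original(ms), raw_cu_count_uniqueref(ms, t, lexicon))
        base = base or counts
        assert counts == base


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.sampled_from(
            ["dog", "puppy", "fellow", "man", "running", "the", "a", "nice",
             "kite", "castle", "next", "to", "um", "people"]
        ),
        min_size=1, max_size=20,
    )
)
def test_uniqueref_never_below_original(lexicon, words):
    """Splitting identities by referent can only add, never remove."""
    t = _parse(" ".join(words))
    ms = match_cus(t, lexicon)
    orig = raw_cu_count_original(ms)
    uniq = raw_cu_count_uniqueref(ms, t, lexicon)
    assert uniq >= orig
    assert orig <= len(ms) and orig <= 64
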