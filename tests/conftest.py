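import numpy as np
import pytest

from cuscore.lexicon import load_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def seeded_cohort():
    """One default synthetic cohort (seed 1), generated and scored once."""
    from cuscore.coder import score_participant
    from cuscore.simulate import default_config, generate_cohort_memory

    lex = load_lexicon()
    config = default_config(seed=1)
    pairs = generate_cohort_memory(config)
    scores = [score_participant(t, lex) for t, _ in pairs]
    truths = [truth for _, truth in pairs]
    return config, pairs, scores, truths


def brute_force_matches(tokens, table, max_len=4):
    """Independent matcher: enumerate every eligible token window <= max_len
    that hits the lexicon, then resolve overlaps longest-then-leftmost."""
    excluded = ("false_start_fragment", "unrecognizable")
    n = len(tokens)
    candidates = []
    for i in range(n):
        for j in range(i + 1, min(i + max_len, n) + 1):
            window = tokens[i:j]
            if any(w.kind in excluded for w in window):
                continue
            if tuple(w.normalized for w in window) in table:
                candidates.append((i, j))
    chosen = []
    cursor = 0
    while True:
        avail = [c for c in candidates if c[0] >= cursor]
        if not avail:
            break
        start = min(c[0] for c in avail)
        best = max((c for c in avail if c[0] == start), key=lambda c: c[1])
        chosen.append(best + (table[tuple(w.normalized for w in tokens[best[0]:best[1]])],))
        cursor = best[1]
    return chosen


@pytest.fixture(scope="session")
def random_token_transcripts(lexicon):
    """200 random transcripts (<= 30 tokens) mixing lexicon words, function
    words and excluded-kind tokens, for matcher oracle comparison."""
    from cuscore.transcripts import Token, Transcript

    rng = np.random.default_rng(20240917)
    words = sorted({w for key in lexicon.match_table for w in key})
    extras = ["the", "a", "and", "is", "was", "so", "there", "then", "very"]
    transcripts = []
    for t_idx in range(200):
        n = int(rng.integers(0, 31))
        tokens = []
        for i in range(n):
            roll = rng.random()
            if roll < 0.05:
                tokens.append(Token("xxx", "", "unrecognizable", i))
            elif roll < 0.12:
                w = words[rng.integers(len(words))]
                tokens.append(Token(w, w, "false_start_fragment", i))
            elif roll < 0.7:
                w = words[rng.integers(len(words))]
                tokens.append(Token(w, w, "word", i))
            else:
                w = extras[rng.integers(len(extras))]
                tokens.append(Token(w, w, "word", i))
        transcripts.append(Transcript(f"R{t_idx}", "HC", tokens, []))
    return transcripts
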