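"""Synthetic cohort generator: determinism, ground-truth recovery,
calibration."""
import numpy as np
import pytest

from cuscore.coder import score_participant
from cuscore.simulate import (
    GeneratorConfigError,
    GroupProfile,
    default_config,
    default_profiles,
    generate_cohort,
    generate_group,
    generate_participant,
    recovery_check,
    screen_vocabulary,
    DEFAULT_DISTRACTORS,
)
from cuscore._text import load_word_list
from cuscore.transcripts import write_transcript


def _profile(**kw):
    base = dict(
        group="HC", n=5, utterance_mean=80, utterance_sd=10,
        informativeness_mean=0.2, informativeness_sd=0.04,
        atypical_rates={"self_referential": 0.02, "inability": 0.02,
                        "tangential": 0.01, "empty": 0.05, "false_start": 0.02},
    )
    base.update(kw)
    return GroupProfile(**base)


def test_fixed_seed_reproduces_bytes(lexicon):
    texts = []
    for _ in range(2):
        rng = np.random.default_rng(11)
        t, _truth = generate_participant(_profile(), rng, lexicon)
        texts.append(write_transcript(t))
    assert texts[0] == texts[1]


def test_different_seeds_differ(lexicon):
    t1, _ = generate_participant(_profile(), np.random.default_rng(1), lexicon)
    t2, _ = generate_participant(_profile(), np.random.default_rng(2), lexicon)
    assert write_transcript(t1) != write_transcript(t2)


def test_zero_atypical_rates_gives_cu_and_distractors_only(lexicon):
    prof = _profile(atypical_rates={})
    t, truth = generate_participant(prof, np.random.default_rng(5), lexicon)
    assert all(v == 0 for v in truth.atypical_counts.values())
    s = score_participant(t, lexicon)
    assert all(v == 0 for v in s.atypical_counts.values())
    assert s.raw_cu_original == truth.n_cus


def test_ground_truth_recovered_exactly(lexicon, seeded_cohort):
    config, pairs, scores, truths = seeded_cohort
    for s, truth in zip(scores, truths):
        assert s.raw_cu_original == truth.n_cus
        assert s.total_utterances == truth.total_utterances
        assert s.raw_cu_uniqueref >= s.raw_cu_original
        for cat, count in truth.atypical_counts.items():
            assert s.atypical_counts[cat] == count


def test_default_cohort_structure(seeded_cohort):
    config, pairs, scores, truths = seeded_cohort
    assert len(pairs) == 101
    sizes = {g: sum(t.group == g for t in truths) for g in
             ("svPPA", "lvPPA", "nfvPPA", "HC")}
    assert sizes == {"svPPA": 19, "lvPPA": 26, "nfvPPA": 25, "HC": 31}


def test_recovery_report_on_seeded_cohort(seeded_cohort):
    config, pairs, scores, truths = seeded_cohort
    report = recovery_check(scores, truths, config)
    assert report.exact_cu_recovery
    assert report.ok, report.violations


def test_atypical_ordering_matches_group_profiles(seeded_cohort):
    """lvPPA leads on empty speech and false starts, svPPA on
    self-referential speech (one-sided group contrasts)."""
    _, _, scores, _ = seeded_cohort

    def mean(group, cat):
        vals = [s.atypical_proportions[cat] for s in scores if s.group == group]
        return float(np.mean(vals))

    assert mean("lvPPA", "empty") > mean("HC", "empty")
    assert mean("lvPPA", "false_start") > mean("HC", "false_start")
    assert mean("svPPA", "self_referential") > max(
        mean(g, "self_referential") for g in ("HC", "lvPPA", "nfvPPA")
    )


def test_written_corpus_round_trips(tmp_path, lexicon):
    config = default_config(seed=3)
    config.profiles = [p for p in config.profiles if p.group in ("HC", "svPPA")]
    for p in config.profiles:
        p.n = 3
    out = generate_cohort(config, tmp_path / "corpus")
    transcripts = sorted((out / "transcripts").glob("*.txt"))
    assert len(transcripts) == 6
    assert (out / "manifest.csv").exists() and (out / "truth.csv").exists()
    # regenerating with the same seed is byte-identical
    out2 = generate_cohort(config, tmp_path / "corpus2")
    for p1, p2 in zip(transcripts, sorted((out2 / "transcripts").glob("*.txt"))):
        assert p1.read_text() == p2.read_text()


def test_distractors_screened_against_lexicon(lexicon):
    screen_vocabulary(lexicon, load_word_list(DEFAULT_DISTRACTORS))
    with pytest.raises(GeneratorConfigError):
        screen_vocabulary(lexicon, ["dog"])


def test_infeasible_profile_clamps_and_records(lexicon):
    prof = _profile(utterance_mean=12, utterance_sd=0,
                    informativeness_mean=0.99, informativeness_sd=0.0,
                    atypical_rates={})
    t, truth = generate_participant(prof, np.random.default_rng(0), lexicon)
    assert truth.total_utterances == 12
    assert truth.n_cus <= 12
    s = score_participant(t, lexicon)
    assert s.raw_cu_original == truth.n_cus


def test_calibration_improves_with_n(lexicon):
    """Mean absolute deviation of recovered group means shrinks with n."""
    devs = {}
    for n in (10, 31, 100):
        acc = []
        for seed in range(20):
            prof = _profile(n=n)
            rng = np.random.default_rng(1000 + seed)
            pairs = generate_group(prof, rng, lexicon)
            mean_info = float(np.mean([tr.informativeness for _, tr in pairs]))
            acc.append(abs(mean_info - prof.informativeness_mean))
        devs[n] = float(np.mean(acc))
    assert devs[100] < devs[10]
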