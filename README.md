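# cuscore

Content-unit scoring and informativeness analysis of naturalistic
picture-description speech, built for research on primary progressive
aphasia (PPA) and usable for any picture-elicited connected-speech sample
with a suitable concept lexicon.

## The problem and the measures

Clinicians elicit connected speech by asking a participant to describe a
standard picture (here, the WAB-R "Picnic Scene"). A **content unit (CU)**
is a unique picture-relevant concept, operationalized as the set of verbal
descriptions healthy controls used for it (e.g. *man / dad / gentleman* are
one CU); the packaged lexicon holds the 64 concepts mentioned by at least
three of 31 controls. Each transcript is scored:

- **raw CU count** — number of distinct CUs mentioned; re-mentions of a
  concept, even with a different word, count once; absent CUs carry no
  penalty;
- **unique-referent (uniqueref) CU count** — ambiguous CUs (e.g. *fellow*,
  which may denote the boy, the girl, the man reading, or the fisherman)
  are split by referent, so the same word applied to a new picture entity
  is a new CU; untagged ambiguous mentions collapse to a single
  "referent unknown" identity;
- **informativeness** — raw CU count divided by total utterances, where an
  *utterance* is any verbalization attempt at the token level (words,
  fillers, false starts, unrecognizable words). This is a normalized
  content-efficiency measure: form errors are not penalized, but empty and
  task-irrelevant output dilutes the score;
- **atypical-speech proportions** — word-level proportions of five
  task-irrelevant output types: self-referential speech, statements of
  inability, tangential speech, empty speech, and false starts.

Group contrasts use one-way ANOVA (from raw scores or directly from
printed group summaries), pairwise pooled-variance t-tests at a
Bonferroni-adjusted alpha (0.05/6 ≈ 0.008 for four groups), and Hedges'
g = J·(m̄₁−m̄₂)/s_pooled with J = 1 − 3/(4N−9). Participants are flagged
impaired when informativeness falls below the control normal range
(HC mean − 1.96·SD).

Because the patient transcripts are private, the package ships a seeded
synthetic-cohort generator that reproduces the study's group structure
(svPPA n=19, lvPPA n=26, nfvPPA n=25, HC n=31; per-group utterance and
informativeness distributions; qualitative atypical profiles) with exact
ground truth, so the whole pipeline is testable end to end.

## Worked example

```python
from cuscore import load_lexicon, parse_transcript_text, score_participant

lex = load_lexicon()
text = """um the boy is &fl- flying a kite at the beach
<in> can't think of that </in> the fellow[CU45:d] is fishing
<sr> we have one of these at home </sr>
"""
t = parse_transcript_text(text, participant_id="demo", group="svPPA")
s = score_participant(t, lex)
print("total utterances:", s.total_utterances)
print("raw CU count (original):", s.raw_cu_original)
print("raw CU count (uniqueref):", s.raw_cu_uniqueref)
print(f"informativeness: {s.informativeness_original:.3f}")
```

prints

```
total utterances: 26
raw CU count (original): 7
raw CU count (uniqueref): 7
informativeness: 0.269
```

All 26 tokens count as utterances (including the filler *um* and the false
start *&fl-*). Seven concepts match — boy, flying, kite, beach, fellow,
fishing, home — so informativeness is 7/26 ≈ 0.27. The `[CU45:d]` tag
resolves *fellow* to the fisherman referent; with a single mention the
uniqueref count equals the original count. The self-referential span and
the inability span contribute to the atypical proportions
(`s.atypical_proportions`), not to content.

The transcript grammar (markers `&…-`, `xxx`, `{heard→blanket}` corrections,
`<sr>/<in>/<tg>/<em>/<fs>` spans, `[CUnn:x]` referent tags) is documented in
`cuscore.transcripts`.

## Command line and analysis scripts

```sh
cuscore simulate --seed 1 --out results/cohort
cuscore score --transcripts results/cohort/transcripts \
              --manifest results/cohort/manifest.csv --out results/scores
cuscore analyze --scores results/scores/scores.csv --out results/analysis
cuscore validate-lexicon
```

The numbered drivers under `analysis/` run the same steps as a narrative
(`01_simulate_cohort.py`, `02_score_cohort.py`, `03_group_statistics.py`,
`04_published_summary_checks.py`) and write their tables under `results/`.
On the default seed-1 cohort, scoring recovers every generated CU count
exactly, and the informativeness ANOVA comes out at F(3, 97) ≈ 20.4 with
svPPA/lvPPA below controls and nfvPPA preserved — the published pattern.

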