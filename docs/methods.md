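# Methods

## Scoring model

A transcript is an ordered list of token-level *utterances*: every
verbalization attempt counts, including fillers (*um*, *uh*, …),
false-start fragments (`&bl-`), and unrecognizable words (`xxx`). This
token-level definition is the only one consistent with the study
conditions the package emulates (control means near 150 utterances in
under a minute of speech) and makes the denominator of every normalized
measure the plain token count. Phonemic errors corrected during
transcription (`{splanket→blanket}`) are scored on the intended word, so
form errors are never penalized.

Content-unit (CU) detection is lexicon-driven: greedy longest-match,
left-to-right, over normalized tokens (lowercased, punctuation stripped
except apostrophes), with phrases up to four tokens. A small deterministic
inflection table (plural *s/es*, *-ing*, *-ed*, with *y→ies* and final-*e*
handling) extends single-token variants; an exact variant listed elsewhere
always outranks an inflected form, and inflected forms claimed by two CUs
are dropped as ambiguous. False-start fragments and unrecognizable tokens
never participate in matches. This replaces the study's human coders with
an exact, auditable operationalization; the match audit log (one row per
mention) is the hand-checkable artifact.

Raw CU count is the number of distinct CUs (once-per-concept
de-duplication, no penalty for omissions). Under the unique-referent
scheme, the twelve ambiguous CUs with referent patterns are split into
(cu, referent) identities resolved from explicit `[CUnn:x]` tags; untagged
mentions collapse to one "referent unknown" identity per CU rather than
being guessed from context, because the original disambiguation relied on
human judgment of surrounding context and any automatic guess would be
unverifiable. A consequence used as a property test: the uniqueref count
can never fall below the original count. The packaged lexicon expands to
46 referent sub-identities over those twelve parents (110 scoreable
identities including the unknown fallbacks); the lexicon file records its
provenance notes, including one typo correction, in
`src/cuscore/data/lexicon_notes.md`.

Atypical speech is classified per token into at most one of five
categories with precedence annotation > false-start (token kind) > empty
(fillers, unrecognizable words, packaged empty phrases) > inability
(packaged cue phrases). Self-referential and tangential speech are
annotation-only: their published examples require pragmatic judgment, and
a first-person-pronoun heuristic is provided but reported separately,
never merged. CU matches inside self-referential or tangential spans still
count as content — nothing in the scoring rules excludes content produced
inside a tangent. Inter-rater agreement is word-level percent agreement
(presence and category both required); Cohen's kappa is available as a
clearly-labelled extra.

## Group statistics

Group summaries use the sample SD (n−1). The summary-statistic one-way
ANOVA, F = [Σnᵢ(m̄ᵢ−m̄)²/(k−1)] / [Σ(nᵢ−1)sᵢ²/(N−k)], is algebraically
identical to the raw-score ANOVA and is verified against it to 1e-10 on
random data; this lets printed group tables be re-analyzed directly.
Hedges' g uses the pooled SD with J = 1 − 3/(4N−9), control group first so
deficits are positive. Post hoc tests are pooled-variance Student t-tests
(matching the pooled-SD convention of g; Welch behind a flag), two-sided,
judged against the unrounded Bonferroni alpha (0.05/6) and displayed at
three decimals (0.008). Degenerate inputs are defined, not crashed:
all-equal groups give F = 0 and p = 1; zero within-group variance with
unequal means flags an infinite F / effect size.

Impairment classification uses the control *normal range*, mean ± 1.96·SD
of the control distribution, flagging a participant only when strictly
below the lower bound (low informativeness is the deficit direction). The
confidence interval *of the mean* would be ~5 times narrower and would
flag nearly every patient, contradicting the reported prevalence of
impairment; the z multiplier is a parameter for sites preferring another
convention. The published count of impaired cases is not claimed to be
reproduced, since the original wording of the criterion is ambiguous.

## Synthetic cohorts

The generator emulates the study's four groups — svPPA n=19, lvPPA n=26,
nfvPPA n=25, controls n=31 — with, per group: utterance-count mean/SD
(135/53.6, 135/60.3, 97.1/34.1, 150/65.9 tokens), informativeness mean/SD
(proportions 0.111/0.0646, 0.117/0.0518, 0.231/0.0945, 0.209/0.0567), and
per-category atypical token rates. The atypical defaults are free
parameters: the source reports only group contrasts, so the rates were
chosen once to realize the qualitative ordering (svPPA highest on
self-referential and inability speech, lvPPA highest on empty speech and
false starts, controls and nfvPPA low) and are listed in
`cuscore.simulate.DEFAULT_ATYPICAL_RATES`. Each participant's rates jitter
around the group rate with coefficient of variation 0.4 so the category
proportions carry between-subject variance.

Per participant, the utterance count U is a normal draw clamped to ≥ 10
and the target informativeness p a normal draw clamped to [0, 1] (clamping
rather than renormalized truncation keeps the expectation essentially at
the configured mean, since the bounds lie in the far tails for every
default profile). The generator realizes C = round(p·U) (capped at 64)
distinct CUs, each through one randomly chosen variant, embeds atypical
spans and fills the remainder with distractor function words. The
distractor, filler, cue-phrase and empty-phrase vocabularies are screened
at load time against every lexicon variant and inflection — including
window checks that no multi-token lexicon phrase can begin inside non-CU
material — so a collision is a build error rather than a silent scoring
artifact. Consequently the pipeline's raw CU count equals the generated C
for every participant, an exact oracle asserted over the whole cohort.

Draws of U and p are independent, so the configured CU-count moments are
not simultaneously matched (ratio of means ≠ mean of ratios); the
generator targets utterances and informativeness, the headline measures,
and derives C. Known small biases: the 64-CU cap slightly depresses
recovered informativeness for profiles whose tail crosses p·U > 64
(visible for the nfvPPA profile, mean recovery ~1 point below the
configured 23.1%), and rounding C adds ±0.5/U noise per participant.
Since every generated CU appears exactly once, the uniqueref and original
counts coincide on synthetic data; transcripts exercising a genuine
uniqueref increase are covered by targeted tests instead. Synthetic
transcripts have no syntax; what passing tests show is that the scoring,
classification and statistical machinery is correct on inputs with known
truth, not that the lexicon matcher approximates human coders on real
disfluent speech.

## Problem sizes and determinism

All randomness flows through one seeded NumPy generator per run; a fixed
seed reproduces corpora byte-identically. The default test suite generates
and scores one 101-participant cohort (seconds). The acceptance script
averages recovered group means over 20 replicate cohorts at the study
group sizes — about 12,000 scored synthetic utterance tokens per
replicate — chosen so that Monte Carlo error on the reported means is a
fraction of a percentage point while the whole run stays under ten
seconds.
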