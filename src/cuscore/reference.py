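"""Published summary statistics of the original clinical cohort.

These are inputs, not results: the group sizes, utterance-count moments and
group summary tables printed in the original study of picnic-scene picture
descriptions in primary progressive aphasia (svPPA n=19, lvPPA n=26,
nfvPPA n=25, plus 31 age-matched healthy controls). They parameterize the
synthetic cohort generator and let the summary-statistic routines
(ANOVA-from-summary, Hedges' g) be exercised against the published numbers.
Informativeness is stored in percent, as printed.
"""
from __future__ import annotations

from .stats import GroupSummary

GROUP_SIZES = {"svPPA": 19, "lvPPA": 26, "nfvPPA": 25, "HC": 31}

# Utterance counts (all verbalization attempts) per group: mean, SD.
UTTERANCE_PARAMS = {
    "svPPA": (135.0, 53.6),
    "lvPPA": (135.0, 60.3),
    "nfvPPA": (97.1, 34.1),
    "HC": (150.0, 65.9),
}

# Raw CU counts, original coding scheme: group -> (n, mean, SD).
CU_ORIGINAL = {
    "HC": GroupSummary("HC", "raw_cu_original", 31, 28.5, 6.46),
    "lvPPA": GroupSummary("lvPPA", "raw_cu_original", 26, 14.5, 5.81),
    "nfvPPA": GroupSummary("nfvPPA", "raw_cu_original", 25, 20.3, 6.07),
    "svPPA": GroupSummary("svPPA", "raw_cu_original", 19, 13.0, 5.67),
}

# Raw CU counts, unique-referent scheme.
CU_UNIQUEREF = {
    "HC": GroupSummary("HC", "raw_cu_uniqueref", 31, 30.0, 7.99),
    "lvPPA": GroupSummary("lvPPA", "raw_cu_uniqueref", 26, 14.8, 6.07),
    "nfvPPA": GroupSummary("nfvPPA", "raw_cu_uniqueref", 25, 20.8, 6.19),
    "svPPA": GroupSummary("svPPA", "raw_cu_uniqueref", 19, 13.7, 6.24),
}

# Informativeness (raw CU / utterances), percent, original scheme.
INFORMATIVENESS_ORIGINAL = {
    "HC": GroupSummary("HC", "informativeness_original", 31, 20.9, 5.67),
    "lvPPA": GroupSummary("lvPPA", "informativeness_original", 26, 11.7, 5.18),
    "nfvPPA": GroupSummary("nfvPPA", "informativeness_original", 25, 23.1, 9.45),
    "svPPA": GroupSummary("svPPA", "informativeness_original", 19, 11.1, 6.46),
}

# Informativeness, percent, unique-referent scheme.
INFORMATIVENESS_UNIQUEREF = {
    "HC": GroupSummary("HC", "informativeness_uniqueref", 31, 21.9, 5.87),
    "lvPPA": GroupSummary("lvPPA", "informativeness_uniqueref", 26, 11.9, 5.26),
    "nfvPPA": GroupSummary("nfvPPA", "informativeness_uniqueref", 25, 23.5, 9.31),
    "svPPA": GroupSummary("svPPA", "informativeness_uniqueref", 19, 11.7, 7.02),
}

# Published Hedges' g versus controls (original scheme, CU counts and
# informativeness) — the values the effect-size routine is checked against.
PUBLISHED_G_CU_ORIGINAL = {"lvPPA": 2.25, "nfvPPA": 1.28, "svPPA": 2.47}
PUBLISHED_G_INFORMATIVENESS_NFV = -0.29

# Published omnibus F for raw CU counts, original scheme, on df (3, 97).
PUBLISHED_F_CU_ORIGINAL = 36.2
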