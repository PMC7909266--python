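#!/usr/bin/env python
"""Group-level analysis of the scored synthetic cohort: per-group summaries,
one-way ANOVAs, Bonferroni-corrected pairwise t-tests with Hedges' g, and
control-range impairment flags, for both coding schemes and the five
atypical-speech proportions. Outputs under results/analysis/."""
import argparse
from pathlib import Path

import pandas as pd

from cuscore.pipeline import RunConfig, run_analyze


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scores", type=Path, default=Path("results/scores/scores.csv"))
    parser.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = parser.parse_args()
    outputs = run_analyze(args.scores, RunConfig(method="both"), args.out)
    anova = pd.read_csv(outputs["anova"]).set_index("measure")
    print("one-way ANOVA, df ({:.0f}, {:.0f}):".format(
        anova["df_between"].iloc[0], anova["df_within"].iloc[0]))
    print(anova[["F", "p"]].round(4))
    impair = pd.read_csv(outputs["impairment"])
    scores = pd.read_csv(args.scores)
    flagged = impair[impair.impaired].merge(
        scores[["participant_id", "group"]], on="participant_id")
    print("\nimpaired (below control normal range), by group and method:")
    print(flagged.groupby(["method", "group"]).size())


if __name__ == "__main__":
    main()
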