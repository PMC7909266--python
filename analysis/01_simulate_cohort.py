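#!/usr/bin/env python
"""Generate the default synthetic four-group cohort (svPPA 19, lvPPA 26,
nfvPPA 25, HC 31) with ground truth, under results/cohort/.

The generator draws per-participant utterance counts and informativeness
from the published group distributions and embeds each target content unit
exactly once, so the corpus comes with an exact scoring oracle
(results/cohort/truth.csv)."""
import argparse
from pathlib import Path

from cuscore.pipeline import RunConfig, run_simulate


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = parser.parse_args()
    out = run_simulate(RunConfig(seed=args.seed), args.out)
    n = len(list((out / "transcripts").glob("*.txt")))
    print(f"wrote {n} transcripts, manifest and ground truth to {out}")


if __name__ == "__main__":
    main()
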