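"""End-to-end runs: score a transcript directory, analyze a score table,
simulate a cohort — each writing reproducible outputs plus a machine-readable
run manifest (config echo, package version, seed)."""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .atypical import CATEGORIES
from .coder import matches_to_frame, score_participant, scores_to_frame
from .lexicon import load_lexicon
from .simulate import CohortConfig, default_config, generate_cohort, load_cohort_config
from .stats import (
    GroupSummary,
    anova_oneway,
    classify_impairment,
    pairwise_ttests,
    summarize_groups,
)
from .transcripts import load_manifest, parse_transcript

METHODS = ("original", "uniqueref")


@dataclass
class RunConfig:
    lexicon_path: Optional[str] = None
    method: str = "both"  # original | uniqueref | both
    atypical_mode: str = "rules+annotation"
    alpha: float = 0.05
    seed: int = 0
    skip_bad: bool = False

    def __post_init__(self):
        if self.method not in ("original", "uniqueref", "both"):
            raise ValueError(f"unknown method {self.method!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @property
    def methods(self) -> tuple[str, ...]:
        return METHODS if self.method == "both" else (self.method,)


def _write_run_manifest(out_dir: Path, config: RunConfig, command: str) -> None:
    payload = {
        "command": command,
        "version": __version__,
        "config": {
            "lexicon_path": config.lexicon_path,
            "method": config.method,
            "atypical_mode": config.atypical_mode,
            "alpha": config.alpha,
            "seed": config.seed,
            "skip_bad": config.skip_bad,
        },
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(payload, indent=1), encoding="utf-8"
    )


def run_score(transcripts_dir, manifest_path, config: RunConfig, out_dir) -> Path:
    """Score every transcript in a directory; write scores.csv + audit log."""
    transcripts_dir = Path(transcripts_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = load_manifest(manifest_path)
    lex = load_lexicon(config.lexicon_path)
    paths = sorted(transcripts_dir.glob("*.txt"))
    if not paths:
        raise FileNotFoundError(f"no transcripts (*.txt) in {transcripts_dir}")
    scores, skipped = [], []
    for path in paths:
        try:
            t = parse_transcript(path, manifest)
            scores.append(score_participant(t, lex, config.atypical_mode))
        except Exception as exc:
            if config.skip_bad:
                skipped.append((path.name, str(exc)))
                continue
            raise RuntimeError(f"failed to score {path}: {exc}") from exc
    frame = scores_to_frame(scores)
    frame.to_csv(out_dir / "scores.csv", index=False)
    matches_to_frame(scores).to_csv(out_dir / "matches.tsv", sep="\t", index=False)
    if skipped:
        pd.DataFrame(skipped, columns=["file", "error"]).to_csv(
            out_dir / "skipped.csv", index=False
        )
    _write_run_manifest(out_dir, config, "score")
    return out_dir / "scores.csv"


def _analysis_measures(config: RunConfig) -> list[str]:
    measures = []
    for method in config.methods:
        measures += [f"raw_cu_{method}", f"informativeness_{method}"]
    measures += [f"p_{cat}" for cat in CATEGORIES]
    return measures


def run_analyze(score_table, config: RunConfig, out_dir) -> dict[str, Path]:
    """Group summaries, one-way ANOVAs, Bonferroni pairwise t-tests with
    Hedges' g, and control-range impairment flags, per coding method."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = pd.read_csv(score_table) if not isinstance(score_table, pd.DataFrame) \
        else score_table
    groups = sorted(frame["group"].unique())
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups, found {groups}")
    summary_rows, anova_rows, pair_rows, impair_rows = [], [], [], []
    for measure in _analysis_measures(config):
        if measure not in frame.columns:
            continue
        for s in summarize_groups(frame, measure):
            summary_rows.append(
                {"measure": measure, "group": s.group, "n": s.n,
                 "mean": s.mean, "sd": s.sd}
            )
        by_group = {g: frame.loc[frame.group == g, measure].to_numpy()
                    for g in groups}
        a = anova_oneway(by_group)
        anova_rows.append(
            {"measure": measure, "F": a.F, "df_between": a.df_between,
             "df_within": a.df_within, "p": a.p}
        )
        report = pairwise_ttests(by_group, alpha=config.alpha, measure=measure)
        for r in report.results:
            pair_rows.append(
                {"measure": measure, "group_a": r.pair[0], "group_b": r.pair[1],
                 "t": r.t, "df": r.df, "p": r.p,
                 "alpha_adjusted_displayed": report.alpha_displayed,
                 "significant": r.significant, "hedges_g": r.g}
            )
    if "HC" in groups:
        for method in config.methods:
            measure = f"informativeness_{method}"
            hc_values = frame.loc[frame.group == "HC", measure]
            hc = GroupSummary("HC", measure, len(hc_values),
                              float(hc_values.mean()), float(hc_values.std(ddof=1)))
            flags = classify_impairment(
                hc, dict(zip(frame["participant_id"], frame[measure]))
            )
            for pid, impaired in flags.items():
                impair_rows.append(
                    {"participant_id": pid, "method": method, "impaired": impaired}
                )
    outputs = {}
    for name, rows in (
        ("group_summary", summary_rows),
        ("anova", anova_rows),
        ("pairwise", pair_rows),
        ("impairment", impair_rows),
    ):
        path = out_dir / f"{name}.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        outputs[name] = path
    _write_run_manifest(out_dir, config, "analyze")
    return outputs


def run_simulate(config: RunConfig, out_dir, cohort_config=None) -> Path:
    """Generate a synthetic corpus (default: the four study groups)."""
    if cohort_config is None:
        cohort = default_config(seed=config.seed)
    elif isinstance(cohort_config, CohortConfig):
        cohort = cohort_config
    else:
        cohort = load_cohort_config(cohort_config)
        cohort.seed = config.seed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    generate_cohort(cohort, out_dir)
    _write_run_manifest(out_dir, config, "simulate")
    return out_dir
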