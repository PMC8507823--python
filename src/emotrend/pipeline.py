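"""End-to-end orchestration: simulate -> score -> aggregate -> itsa -> report."""

from __future__ import annotations

import json
import logging
import sys
import tomllib
from importlib.metadata import version
from pathlib import Path
from typing import Optional

import pandas as pd

from . import aggregate as agg
from .config import MH, NMH, PipelineConfig, SimConfig
from .emotion import Lexicon, load_lexicon, score_frame
from .itsa import fit_itsa
from .report import export_tables, load_events, plot_series
from .synthetic import generate_corpus, write_ledger, write_ndjson

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_pipeline"]


def load_config(path) -> PipelineConfig:
    """Read a TOML pipeline configuration."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    if "sim" in data:
        data["sim"] = SimConfig(**data["sim"])
    return PipelineConfig(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir, input_path: Optional[str] = None) -> dict:
    """Run the configured stages, writing all artifacts plus a manifest.

    With ``simulate`` enabled the corpus is generated; otherwise
    ``input_path`` must point to an existing NDJSON/CSV corpus. Returns the
    manifest (also written to ``manifest.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": {},
        "versions": {
            "python": sys.version.split()[0],
            "emotrend": version("emotrend"),
            "pandas": pd.__version__,
        },
        "decisions": {
            "week_convention": "thursday-start complete weeks; partial first/last excluded",
            "emotion_mean_weighting": "items",
            "score_denominator": "tokens after preprocessing",
            "post_time_origin": "P = 0 at the interruption week",
        },
    }
    stages = set(config.stages)
    records = None
    lexicon = (
        Lexicon.from_tsv(config.lexicon_path) if config.lexicon_path else load_lexicon()
    )

    def _run(stage, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = result
        return result

    if "simulate" in stages:
        def _simulate():
            sim = config.sim.model_copy(update={"seed": config.seed})
            recs, ledger = generate_corpus(sim)
            write_ndjson(recs, out_dir / "corpus.ndjson")
            write_ledger(ledger, out_dir / "ledger.json")
            nonlocal records
            records = recs
            return {"n_records": len(recs), "n_deleted_marked": ledger["n_deleted_marked"]}
        _run("simulate", _simulate)

    if records is None:
        if input_path is None:
            raise ValueError("no input: enable the simulate stage or pass input_path")
        records, report = agg.ingest_records(input_path)
        manifest["stages"]["ingest"] = vars(report)
    elif "score" in stages or "aggregate" in stages:
        # simulated corpora still pass through ingest so deleted markers drop
        write_path = out_dir / "corpus.ndjson"
        records, report = agg.ingest_records(write_path)
        manifest["stages"]["ingest"] = vars(report)

    if "score" in stages:
        def _score():
            nonlocal records
            records = score_frame(records, lexicon)
            records.to_json(out_dir / "scored.ndjson", orient="records", lines=True)
            return {"n_scored": len(records), "lexicon": lexicon.provenance}
        _run("score", _score)

    community_series = cohort_series = None
    if "aggregate" in stages:
        def _aggregate():
            nonlocal community_series, cohort_series
            year, n_weeks = config.sim.year, config.sim.n_weeks
            assignment = agg.identify_cohort(records)
            community_series = agg.weekly_series(records, "community", assignment, n_weeks, year)
            cohort_series = agg.weekly_series(records, "cohort", assignment, n_weeks, year)
            community_series.to_csv(out_dir / "weekly_by_community.csv", index=False)
            cohort_series.to_csv(out_dir / "weekly_by_cohort.csv", index=False)
            assignment.to_frame().to_csv(out_dir / "cohorts.csv", index=False)
            return {
                "n_mh": assignment.n_mh,
                "n_nmh": assignment.n_nmh,
                "mh_fraction": assignment.mh_fraction,
                "n_excluded_mh_only": assignment.n_excluded_mh_only,
            }
        _run("aggregate", _aggregate)

    fit = None
    if "itsa" in stages:
        def _itsa():
            nonlocal fit
            series = {
                0: cohort_series.loc[cohort_series["key"] == NMH]
                .sort_values("week")["posts_per_participant"].to_numpy(),
                1: cohort_series.loc[cohort_series["key"] == MH]
                .sort_values("week")["posts_per_participant"].to_numpy(),
            }
            fit = fit_itsa(series, t0=config.t0, lag=config.lag)
            fit.to_json(out_dir / "itsa_frequency.json")
            out = {"frequency_r_square": fit.r_square}
            if cohort_series["mean_compound"].notna().any():
                emo = {
                    g: cohort_series.loc[cohort_series["key"] == k]
                    .sort_values("week")["mean_compound"].to_numpy()
                    for g, k in ((0, NMH), (1, MH))
                }
                emo_fit = fit_itsa(emo, t0=config.t0, lag=config.lag)
                emo_fit.to_json(out_dir / "itsa_emotion.json")
                out["emotion_r_square"] = emo_fit.r_square
            return out
        _run("itsa", _itsa)

    if "report" in stages:
        def _report():
            events = load_events(config.events_path)
            figures = plot_series(
                community_series, cohort_series, out_dir / "figures",
                annotations=events, display_scale=config.display_scale,
            )
            tables = export_tables(fit, community_series, cohort_series, out_dir / "tables")
            return {
                "figures": {k: str(v) for k, v in figures.items()},
                "tables": {k: str(v) for k, v in tables.items()},
            }
        _run("report", _report)

    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
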