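# emotrend

Weekly social-media engagement and emotion analysis with a two-group
interrupted time series model, plus a synthetic corpus generator with planted
ground truth.

The package implements a complete, testable pipeline:

1. **synthetic corpus** (`emotrend.synthetic`) — Reddit-like post/comment
   events over four communities (one general teen community, three
   mental-health communities) with two latent user cohorts (default 3.5%
   overlap), per-user Poisson–gamma weekly activity following a segmented
   linear trend with a level/slope break at the interruption week, and
   bag-of-words texts mixing emotion-lexicon and neutral words. Every planted
   parameter is written to a separate ground-truth ledger.
2. **emotion scoring** (`emotrend.emotion`) — preprocessing (emoji
   replacement, contraction/shortcut expansion, URL and punctuation
   stripping, stopword removal), dictionary lookup against a bundled
   five-emotion word list, per-token-count normalization into five scores in
   [0, 1], and the compound negative-emotion scale
   `anger + fear − happiness + sadness` (surprise excluded).
3. **cohort aggregation** (`emotrend.aggregate`) — NDJSON/CSV ingest with
   deleted-account filtering, complete-calendar-week assignment (Thursday
   -start blocks; 2020 has exactly 52 complete weeks with both partial end
   weeks excluded), MH/NMH cohort identification by username matching, weekly
   participant/item/frequency/emotion series, percent-change arithmetic, and
   display scaling.
4. **interrupted time series** (`emotrend.itsa`) — stacked two-group
   segmented OLS with design columns `[1, t, D, P, g, g·t, g·D, g·P]`,
   Newey–West (Bartlett kernel) autocorrelation-adjusted standard errors
   computed within group boundaries, a residual-autocorrelation lag
   diagnostic, and Student-t inference with `n − 8` degrees of freedom.
5. **reporting/CLI** (`emotrend.report`, `emotrend.pipeline`,
   `emotrend.cli`) — the five standard figures, coefficient and summary
   tables, and an end-to-end orchestrator with a run manifest.

## Command line

The console script `emotrend` (equivalently `python -m emotrend.cli`)
provides:

```sh
emotrend simulate  --out runs/sim --seed 7            # corpus + ledger
emotrend score     --in runs/sim/corpus.ndjson --out runs/scored.ndjson
emotrend aggregate --in runs/scored.ndjson --out runs/agg
emotrend itsa      --in series.csv --t0 11 --lag 12 --out runs/fit
emotrend report    --community runs/agg/weekly_by_community.csv \
                   --cohort runs/agg/weekly_by_cohort.csv --out runs/report
emotrend run-all   --out runs/full --seed 7           # all five stages
```

`run-all` uses the shipped default profile (52 weeks, interruption at week
11, 12-week Newey–West lag, 3.5% MH fraction, display scale ×30) unless a
TOML config is given; see `emotrend.config.PipelineConfig`.

## Data formats

Corpora are NDJSON (one record per line) or CSV with fields
`id, author, community, created_utc, title, body, kind`; weekly series are
tidy CSV (one row per key × week); fits are JSON plus a fixed-width text
table. Lexicon, stopword, contraction, and emoji resources are plain
text/TSV under `src/emotrend/resources/` with one entry per line
(`word<TAB>emotion`, `key<TAB>expansion`).
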