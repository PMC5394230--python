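# herbtrends

A pipeline for analysing long-term herbicide use intensity and relative
mammalian toxicity from agricultural pesticide-use surveys.

Given three delimited-text inputs — a use survey (crop, year, ingredient
label, total amount applied, average application rate), a toxicity
reference table per active ingredient (acute oral rat LD50, chronic
24-month rat NOEL, WSSA site-of-action group), and annual planted-area
tables — the pipeline computes:

- **Area-treatments (AT)** — amount applied ÷ average rate ÷ planted
  area: a dimensionless use-intensity metric equal to the number of
  whole-field passes at the average rate, summed per crop-year.
- **Hazard quotients (HQ)** — Σ amount (mg/ha) ÷ toxicity, for chronic
  (NOEL) and acute (LD50) endpoints, with per-ingredient contribution
  shares.  LD50 values reported only as a bound (`>5,000`) enter at the
  bound, which conservatively overestimates hazard.
- **Label consolidation** — formulation/salt-specific ingredient labels
  (e.g. seven glyphosate salts) are merged into canonical active
  ingredients before any arithmetic.
- **Trend statistics** — Mann-Kendall monotonic-trend tests (tau-b,
  exact null for tie-free n ≤ 10, tie-corrected normal approximation
  otherwise), OLS slope vs calendar year, and Pearson correlation.

A synthetic survey-data generator (`herbtrends.synthetic_data`) builds
all three tables from configured ground truth — per-crop AT trends,
dominance weights, log-spread toxicity values with a censoring mass —
so the full pipeline is testable without any downloads.

## CLI

```bash
# generate synthetic tables + ground truth + a ready-made run config
herbtrends simulate --config sim.yaml --out-dir out/sim --seed 1

# full pipeline: area-treatments, hazard quotients, contributions, trends
herbtrends compute --config out/sim/run.yaml

# re-run trend tests on existing outputs
herbtrends trend --out-dir out/sim/results

# per-crop text summaries (first/last-year HQ, % change, top contributors)
herbtrends report --config out/sim/run.yaml --crop maize
```

The run configuration is a small YAML file naming input paths, column
maps, source units (lb/acre or kg/ha — converted once at read time),
the crop list, the year range, and the output directory; `simulate`
emits a complete example (`run.yaml`).  Outputs are plain CSV plus a
`manifest.json` recording input checksums, configuration, per-stage row
counts, and warnings.  Re-runs are byte-identical.

## Layout

```
src/herbtrends/
  survey_io.py        input/output tables, unit normalization, validation
  normalize.py        salt/formulation -> active-ingredient consolidation
  intensity.py        area-treatments and per-crop annual series
  hazard.py           hazard quotients, censoring, contribution shares
  trends.py           Mann-Kendall, OLS slope, Pearson correlation
  synthetic_data.py   ground-truth-driven survey-data generator
  cli_report.py       pipeline orchestration, summaries, CLI
```
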