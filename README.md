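# ahpgroup

Group preference elicitation from pairwise-comparison questionnaires via the
analytic hierarchy process (AHP), built for health-information prioritization
studies with multiple stakeholder subgroups.

The pipeline takes per-respondent pairwise judgments over a three-level
decision hierarchy and produces:

- per-respondent priority weights (principal eigenvector of each reciprocal
  judgment matrix, by power iteration) with consistency index/ratio
  diagnostics and a CR-threshold inclusion filter (default CR ≤ 0.2);
- group weights per subgroup via geometric-mean aggregation of individual
  priorities (optionally exponent-weighted), with per-item standard
  deviations, global leaf weights (level-2 × level-3 locals), and tie-aware
  local/global rankings;
- percentile bootstrap confidence intervals for the aggregated weights;
- Welch (or pooled) two-sample t tests of local weights between every pair
  of subgroups, with a supplementary Holm-adjusted column;
- sensitivity analysis: Tukey-fence (boxplot-rule) outlier detection per
  item and rank-reversal checks after excluding flagged respondents.

Because raw questionnaire data for such studies are rarely shared, the
package includes a synthetic-cohort generator (`ahpgroup.simulate`) that
produces judgments from latent priority vectors under multiplicative
log-normal noise — with optional snapping to the 1/9…9 verbal scale and a
controllable fraction of highly inconsistent respondents — and keeps the
generating truth for parameter-recovery validation.

## CLI

```bash
# generate a synthetic cohort (judgments.csv, demographics.csv, truth.json)
ahpgroup simulate --seed 1 --sigma 0.15 --out scratch/sim

# run the full analysis and write the report tables
ahpgroup run --input scratch/sim/judgments.csv \
             --demographics scratch/sim/demographics.csv \
             --bootstrap-b 1000 --seed 1 --out scratch/report

# re-render ranking tables from a previous run's structured summary
ahpgroup report --summary scratch/report/summary.json --out scratch/tables
```

`ahpgroup run` accepts `--hierarchy` (a YAML tree; the packaged default is
the four-category rare-disease information hierarchy with 15 pairwise
comparisons), `--cr-threshold`, `--cr-rule {mean,max}`,
`--aggregation {gm,wgm-uniform,wgm-bias}`, `--ci-level`,
`--test {welch,pooled}`, `--outlier-k`, `--precision`, and `--config`
(YAML overriding defaults; explicit flags win). The report directory
contains per-subgroup ranking tables (item, local weight, SD, global
weight, local/global rank), bootstrap intervals, the significance table,
outlier and rank-reversal reports, a machine-readable `summary.json`, and
a `config.json` echo. Runs are fully reproducible given `--seed`.

## Input formats

Judgments CSV: `respondent_id, subgroup, block_id, item_a, item_b, value`
with one row per comparison; `value` is the ratio by which `item_a`
outweighs `item_b`, as a decimal or a `1/k` fraction literal.
Demographics CSV: `respondent_id, subgroup, sex, age, …`.

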