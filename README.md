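# srsignal

Pharmacovigilance signal mining for spontaneous-reporting-system (SRS) data,
built around antipsychotic adverse-drug-reaction surveillance:

* **Ingestion & validation** of a long-format delimited dataset
  (`reports.csv` / `drugs.csv` / `reactions.csv`) with row-level error
  logging — no record is ever dropped silently.
* **Preprocessing**: study inclusion/exclusion (report-year window, at least
  one suspected antipsychotic, accepted causality), drug/reaction name
  standardization through ATC- and MedDRA-style dictionaries, and expansion
  of each report into deduplicated drug-event combinations.
* **Disproportionality analysis** per (drug, preferred term) pair: ROR and
  PRR with log-scale Wald CIs, the MHRA rule (PRR + chi-squared, Yates or
  Pearson variant), and the BCPNN information component with shrinkage;
  per-method flags, a consensus flag, and PRR-ranked signal lists.
* **Off-label annotation** of consensus signals against a curated
  drug-label knowledge base (labeled / off-label / undetermined).
* **Descriptive outputs**: yearly report counts with serious proportions,
  onset-delay distribution, per-drug/per-class seriousness tallies, SOC and
  PT frequency tables, outcome tallies — all percentages computed with
  exact 2-dp half-up decimal arithmetic.
* **Risk-factor model**: logistic regression of serious vs non-serious
  reports (sex, age bins, season, antipsychotic class, hospital level/type,
  multiple disease, polypharmacy) with adjusted ORs, Wald CIs/p-values and
  per-factor likelihood-ratio tests.
* **Synthetic SRS generator** with injected disproportionality pairs,
  covariate-driven seriousness and closed-form expected fourfold tables,
  used as ground truth for recovery testing.

## CLI

All stages are exposed through the `srsignal` command:

```bash
# generate a synthetic dataset (bundled default configuration)
srsignal simulate --seed 1 --n-reports 20000 --outdir run/

# filter + expand into drug-event combinations
srsignal preprocess --reports run/reports.csv --drugs run/drugs.csv \
    --reactions run/reactions.csv --outdir run/

# disproportionality statistics and flags
srsignal signal --combinations run/combinations.csv --out run/signals.csv

# descriptive report, risk factors, off-label annotation
srsignal describe --reports run/reports.csv --drugs run/drugs.csv \
    --reactions run/reactions.csv --combinations run/combinations.csv \
    --out run/descriptive_report.json
srsignal riskfactors --reports run/reports.csv --drugs run/drugs.csv \
    --reactions run/reactions.csv --out run/risk_factors.csv
srsignal offlabel --signals run/signals.csv --out run/offlabel_signals.csv
```

or end-to-end from a YAML config (see
`src/srsignal/resources/demo_pipeline.yaml`):

```bash
srsignal run --config src/srsignal/resources/demo_pipeline.yaml --outdir run/
```

Every run writes `exclusions.csv`, `combinations.csv`, `signals.csv`,
`descriptive_report.json`, `risk_factors.csv`, `offlabel_signals.csv`, and a
`run_manifest.json` (config hash, seed, versions, per-stage record counts);
identical config + seed reproduce all outputs byte-for-byte. Method variants
(`--chi2 {yates,pearson}`, `--ic-variant {n4,plain}`) and all thresholds are
configurable and logged.

Bundled fixtures (`src/srsignal/resources/`): a 15-drug antipsychotic roster
(7 typical, 8 atypical) with ATC codes, a ~40-term reaction vocabulary with
primary SOCs, and a miniature label knowledge base. These are test/demo
fixtures, not real terminologies.

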