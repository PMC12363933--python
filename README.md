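# morbiditrail

Comorbidity pattern mining and multi-state progression modelling for
obese cohorts.

People with obesity (BMI ≥ 30 kg/m²) accumulate chronic diseases in
sequences, not at random. This package asks two questions of
longitudinal survey panels: *which disease systems cluster together?*
and *how fast do people move from health, through single and dual
disease states, to a triple-comorbidity endpoint — and does the first
disease acquired change that speed or the burden it brings?* It is
aimed at epidemiologists and biostatisticians working with
interval-censored panel data (disease status observed only at biennial
survey waves).

## What it computes

**Pattern mining.** Each participant's set of affected disease systems
(cardiovascular CVD, metabolic MTD, respiratory RPD, skeletal-muscular
SMD, neurological NRD, mental MD, cancer CC) is a transaction; Apriori
enumerates frequent itemsets (support ≥ 0.005) and association rules
(confidence ≥ 0.07, with lift = conf(A→B)/supp(B)), stratified by sex
and age band. The highest-support trio becomes the modelling target.

**Progression modelling.** A nine-state continuous-time Markov chain on
the progressive graph

    1 healthy → {2 non-trio, 3 CVD, 4 MTD, 5 SMD} → duals {6,7,8} → 9 all three (absorbing)

is fitted to the panel by maximising the interval-censored likelihood
∏ᵢ [exp(QΔtᵢ)]_{sᵢ,sᵢ₊₁} over the log-intensities of allowed edges.
From the fitted generator Q the package derives transition-probability
matrices P(t) = exp(Qt) at 5/10/20 years, expected first-passage times
to state 9 (solving −Q_TT τ = 1), and a seeded parametric-bootstrap
test of whether progression speed differs by onset disease. Burden
measures (depression, work limitation, sleep, self-rated health) are
compared across onset groups with chi-square/ANOVA.

Because the motivating survey data are access-restricted, a synthetic
cohort generator with known ground truth (planted trio, known Q, known
burden conditionals) stands in for them; see `docs/methods.md`.

## Worked example

Run the numbered analysis steps (each regenerates its inputs'
downstream tables under `results/`):

```bash
python analysis/01_simulate.py        # synthetic cohort + cross-section
python analysis/02_describe_cohort.py
python analysis/03_mine_patterns.py
python analysis/04_fit_markov.py
python analysis/05_burden_by_onset.py
```

Step 03 prints

```
selected trio: ['CVD', 'MTD', 'SMD'] (support 0.119)
```

— the planted trio is recovered from the mined pattern tables. Step 04
prints (abridged)

```
P(5y): healthy->any disease 0.411; healthy->trio 0.010; MTD->trio 0.117
P(10y): healthy->any disease 0.653; healthy->trio 0.060; MTD->trio 0.320
expected years to trio from state 3 (CVD): 23.09
expected years to trio from state 4 (MTD): 18.14
expected years to trio from state 5 (SMD): 25.19
global test: F = 45.04, p = 7.546e-17
  state 3 vs 4: diff +4.95y, Bonferroni p = 3.797e-10
  state 4 vs 5: diff -7.04y, Bonferroni p = 2.849e-15
```

Read: ~41% of healthy obese participants acquire some chronic disease
within 5 years; a participant starting with metabolic disease is
expected to reach triple comorbidity ~5 years sooner than one starting
with cardiovascular disease (and ~7 years sooner than skeletal-
muscular onset), and the bootstrap rejects equal progression speeds.
These estimates recover the generator's ground truth (true expected
times 23.0 / 17.9 / 25.3 years). Step 05 tabulates burden by onset
group and flags work limitation and sleep quality as most elevated
after SMD onset.

The same pipeline is scriptable end-to-end:

```bash
morbiditrail run --out run_dir --seed 42      # or: --config cfg.yaml
morbiditrail simulate|summarize|mine|fit|burden --help
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch at the given seed — simulating
the cohort, mining the trio, fitting the multi-state model and the
bootstrap comparison — and writes the result-metrics JSON to `--out`.

## Layout

- `src/morbiditrail/` — library: `conditions`/`panel` (I/O, samples,
  summaries), `arm` (Apriori), `states`/`markov` (state space,
  likelihood, bootstrap), `synthetic` (generator), `burden`,
  `pipeline`/`cli`.
- `analysis/` — numbered narrative drivers writing `results/`.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — model, assumptions, numerical choices, limits.
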