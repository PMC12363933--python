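# Methods

`morbiditrail` implements a two-part analysis of chronic-disease
comorbidity in an obese cohort: cross-sectional association-rule mining
of disease-system co-occurrence, and a nine-state multi-state Markov
model of longitudinal progression from health to triple comorbidity.
Because the motivating cohort (an English ageing panel survey) is
access-restricted, the package ships a synthetic-cohort generator with
a fully known generating process; every claim a green test makes is a
claim about recovering that known process, not about the restricted
data.

## Disease systems and panel coding

Self-reported conditions are grouped into seven body systems —
cardiovascular (CVD), metabolic (MTD), respiratory (RPD),
skeletal-muscular (SMD), neurological (NRD), mental disorders (MD) and
cancer (CC). A group flag is set as soon as any member condition is
reported. Because the survey asks about conditions ever diagnosed and
the progression graph has no backward arrows, group indicators are made
monotone within participant (running maximum over waves); apparent
remission in raw self-report is thereby coded as persistence. This is a
deliberate modelling choice (`carry_forward_diseases`), switchable by
simply not applying it.

Obesity is classified once per participant, at the first non-missing
BMI (threshold 30 kg/m², inclusive), because entry anthropometry is
what defines cohort membership and later BMI drifts downward in ageing
cohorts; `rule="any"` is available. The cross-sectional ("independent")
sample takes each participant's last observed wave; the longitudinal
sample keeps participants with at least two records complete on the key
variables. Percentage denominators: stratum n for stratified
descriptive tables, the full sample n for follow-up composition tables.

## Association-rule mining

The miner is classic levelwise Apriori with prefix-join candidate
generation and the anti-monotone support prune; with seven items the
lattice has 127 itemsets, so correctness, not speed, is the point, and
tests compare the output against exhaustive enumeration. Support,
confidence and lift use their standard definitions. Defaults: minimum
support 0.005, minimum confidence 0.07.

Ranked pattern tables group itemsets by order (singleton/pair/trio)
within strata (sex; age bands 19–37, 38–56, 57–75, 76–94, closed on
both ends, other ages excluded from age stratification only). The
printed `pct` is the within-order relative frequency — the share of an
itemset's support among all frequent itemsets of the same order in the
stratum — with raw support also emitted; the reported lift of a pair or
trio is the maximum over its binary partitions (lift is symmetric in
antecedent/consequent, so direction is immaterial). Ties break by
support desc, lift desc, then lexicographic, making output
deterministic. The modelling trio is the highest-support frequent
3-itemset under those tie-breaks.

## State space

Nine states over an ordered trio (first, second, third) = (CVD, MTD,
SMD): 1 healthy, 2 non-trio disease only, 3/4/5 single trio disease,
6 = first+second, 7 = first+third, 8 = second+third, 9 all three.
States 3–9 are defined by the trio-component subset alone — a non-trio
disease never moves someone out of them; state 2 requires no trio
component. Otherwise the "single disease" states would be unreachable
for most participants and the state-2 comparisons undefined.

Allowed transitions add one disease at a time: 1→{2,3,4,5}, 2→{3,4,5},
each single state to the two duals containing it, each dual to 9
(16 directed edges). State 9 is absorbing. Direct edges such as 1→6
(two simultaneous acquisitions) are excluded; the adjacency is a
constructor argument for anyone who disagrees.

## Interval-censored likelihood

States are seen only at waves, so the data are independent
wave-to-wave jumps. We fit a time-homogeneous continuous-time Markov
chain: for observation pair (s at t, s' at t+Δ) the likelihood factor
is `expm(QΔ)[s, s']`, maximised over the log-intensities of allowed
edges (L-BFGS-B, bounds on log-rates of [−12, 3] per year). Observation
pairs are aggregated into per-Δ count matrices, so one likelihood
evaluation costs one matrix exponential per distinct interval length.
Initialisation is the crude occurrence/exposure rate; by default three
seeded starts (crude + perturbations) guard against local optima;
convergence requires the optimiser's own criterion plus no likelihood
loss against the start. A fit whose rates sit at the lower bound is
flagged as a boundary solution (typical when no transitions of a type
were observed). Standard errors come from a finite-difference observed
information matrix in log-rate coordinates, delta-method transformed.
A discrete-time row-normalised-counts estimator (`fit_discrete`) is
retained purely as a cross-check mode.

Observed pairs impossible under the transitive closure of the adjacency
(e.g. state 9 → state 3) raise a data error naming the participant and
observation, rather than silently getting zero likelihood.

Derived quantities: `transition_probabilities(Q, t) = expm(Qt)`
(scaling-and-squaring Padé, via SciPy); expected first-passage times to
state 9 solve `(−Q_TT) τ = 1` on the transient block, with +inf for
states from which 9 is unreachable.

## Comparing progression times by onset disease

The sampling uncertainty of the fitted absorption times is estimated by
a parametric bootstrap: simulate panels from the fitted Q on the
original observation schedule (drawing wave-to-wave jumps from
`expm(QΔ)`, which is exactly the observed-data law), refit each
(warm-started at the point estimate), and recompute the absorption-time
vector for the three single-disease states. The global test of equal
progression speed is a Hotelling-corrected Wald statistic on the
successive contrasts — `T² (B−p)/(p(B−1)) ~ F(p, B−p)` with p = 2
contrasts and B retained replicates — which keeps the test calibrated
at moderate bootstrap sizes; pairwise contrasts use bootstrap SEs with
a t reference (df = B−1) and Bonferroni adjustment over the three
pairs. All p-values are labelled with this method; the original
analysis does not state its test, so this is the package's own choice.
Refits that fail to converge are dropped; more than 20% failures aborts
with diagnostics.

## Synthetic cohort: what it emulates, and what not

* **Cross-section** (default n = 20,000): items drawn independently at
  marginal prevalences (CVD 0.32, MTD 0.14, RPD 0.14, SMD 0.22, NRD
  0.12, MD 0.05, CC 0.05 — ordered like the published singleton table)
  except inside planted itemsets. Planting forces all items of a set on
  with mixture weight π chosen (by root finding) so the joint
  probability equals boost × ∏ marginals while marginals are preserved;
  the default plants {CVD, MTD, SMD} at lift 12, the order of magnitude
  of the reported trio lift. Planted sets must be disjoint and
  infeasible boosts (implied joint above the smallest marginal) raise.
* **Panel** (default n = 2,000, 11 biennial waves): continuous-time
  trajectories by competing exponential clocks (Gillespie) under the
  ground-truth Q, observed only at wave times — exactly the interval
  censoring the estimator must invert. The default Q gives the healthy
  state an exit rate of 0.105/yr (≈ 40% acquire a disease within 5
  years), makes every rate out of state 2 faster than out of state 1,
  and makes the metabolic route the fastest to triple comorbidity
  (true expected years from CVD/MTD/SMD: 23.0 / 17.9 / 25.3). A
  discrete mode draws jumps from `expm(QΔ)` directly (same observed
  law, faster) and is used in simulation-heavy tests.
* **Burden**: drawn at each participant's last wave from
  onset-conditional tables; defaults plant SMD onset as worst for
  depression (0.063 vs 0.035/0.045), adverse sleep (0.77) and work
  limitation (0.74), and MTD onset worst for adverse self-rated health
  (0.45). Five-level ordinals put 60/40 of the adverse mass on
  fair/poor and 50/30/20 of the rest on good/very good/excellent.

Not emulated: mortality and informative attrition (an optional
memoryless per-wave dropout knob exists, default off), age- or
sex-dependent intensities (the model is time-homogeneous, ages only
feed the mining strata), BMI dynamics beyond a small random walk, and
diagnostic misclassification. A green recovery test therefore
establishes estimator correctness under the stated model, not
robustness to these violations.

## Numerical choices and degenerate inputs

* Interval lengths are rounded to 1e-6 years when grouping; transition
  probabilities are floored at 1e-300 inside logs.
* Absorption-time systems use dense `solve`; unreachable states are
  detected from the positive-rate graph, not from singular-matrix
  failure.
* Empty transaction lists, empty panels with < 2 records everywhere,
  non-3-subset trios, negative horizons, n_boot < 1 and infeasible
  plantings raise immediately with actionable messages.
* Ordinal collapse for "poor sleep"/"poor health" prevalence is
  adverse = {fair, poor}, configurable; burden is assessed at the last
  observed wave (configurable to the onset wave). Participants without
  an identifiable single onset ("none"/"ambiguous") are excluded from
  burden tests.

## Known limitations

The fitted model assumes time homogeneity; cohorts ageing 20 years
surely violate it, and estimates are period averages. Interval
censoring means progression-time estimates are upper-biased relative to
continuous observation (participants "wait" for the next wave). The
bootstrap test's calibration was verified at n = 500 participants /
50–200 replicates under the default design; severe boundary fits
(sparse transitions) would degrade it.
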