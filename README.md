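# reproage

Decomposition of reproductive ageing in longitudinal breeding histories.

Long-term monitoring studies of long-lived animals — the motivating system
is three sympatric albatross species (an annual breeder, BBA, and two
biennial breeders, GHA and WA) followed over ~40 breeding seasons — record,
for each bird and season, whether a single-egg breeding attempt fledged a
chick. The population-level relationship between age and breeding success
in such data confounds three processes:

* **within-individual change** — improvement through early adulthood and
  senescent decline in late adulthood;
* **selective appearance** — birds that recruit late may differ in average
  quality from early recruits;
* **selective disappearance** — birds that die young may differ in average
  quality from long-lived ones.

`reproage` implements the full analysis chain used to separate these
processes, plus an individual-based simulator that generates synthetic
populations with known structure so every estimator can be validated
against ground truth.

## The models

All models are Bernoulli GLMMs with logit link and two crossed random
intercepts, fitted by a Laplace-approximated marginal likelihood maximised
with nested penalised-IRLS / quasi-Newton optimisation (written from
scratch in this package; see `reproage.glmm`):

```
y_ij ~ Bernoulli(p_ij),   logit(p_ij) = x_ij' b + u_i + v_j
u_i ~ N(0, s2_ind),  v_j ~ N(0, s2_year)      (individual i, season j)
```

**Population-level age trajectory.** For each species x sex the age term
`f(age)` is chosen among: none (null), linear, quadratic, and continuous
piecewise-linear (hinge) functions with one or two breakpoints. Single
breakpoints are scanned over every adequately supported integer age; the
95% CI for the breakpoint is the contiguous set of candidates whose
deviance is within 3.841 of the minimum. Models within 2 AIC units of the
best form the top set and their predictions are averaged with Akaike
weights `w_i = exp(-d_i/2) / sum_j exp(-d_j/2)`.

**Within/among decomposition.** Records are split at the selected
breakpoint. Early adulthood (known recruits only):

```
logit p = b0 + b_w * years_since_first + b_a * age_first + b_f * is_first_attempt + u + v
```

Late adulthood (birds presumed dead under a species-specific
unseen-for-k-years rule, k = 4 for the annual species and 5 for the
biennial ones):

```
logit p = b0 + b_d * years_before_death + b_s * age_last + b_t * is_last_attempt + u + v
```

`b_w` measures within-individual improvement, `b_a` selective appearance,
`b_d > 0` a decline approaching death, `b_s < 0` selective disappearance of
good breeders, and `b_t` a terminal effect at the final attempt. Each
term's importance is scored by the AIC change when it is removed and the
model refitted (positive = the term improves fit).

## Worked example

Simulate a wandering-albatross-like population (600 birds, improvement
+0.15 logits/yr to a breakpoint at age 20 then -0.10 logits/yr, a -0.8
first-attempt penalty, a +0.7 terminal effect, and quality-dependent
mortality) and run the full pipeline:

```python
from reproage import AnalysisConfig, run_analysis

bundle = run_analysis(AnalysisConfig(
    simulation={"seed": 7, "n_individuals": 600},
    seed=7, out_dir="demo_out",
))
print(bundle["groups"][("WA", "F")]["threshold"])
print(bundle["decomposition"])
```

prints (females shown):

```
{'best': 19, 'ci_low': 19, 'ci_high': 20, 'cutoff_used': 19}
phase species sex               term  estimate    se  delta_aic    n
early      WA   F  years_since_first     0.146 0.026     31.774 1309
early      WA   F          age_first     0.179 0.033     27.799 1309
early      WA   F   is_first_attempt    -0.674 0.180     12.389 1309
 late      WA   F years_before_death     0.309 0.082     16.314  178
 late      WA   F           age_last    -0.063 0.044     -0.004  178
 late      WA   F    is_last_attempt     2.802 0.611     24.893  178
```

The breakpoint scan lands one year below the generative threshold with a
tight profile CI. In early adulthood the within-individual improvement
(+0.146 logits/yr, vs +0.15 simulated) dominates, with the expected
first-attempt penalty; in late adulthood success declines approaching death
(positive `years_before_death`), and the last-attempt contrast is positive —
inflated beyond the generative +0.7 because under a biennial schedule a
success lengthens the gap to the next attempt and thereby raises the chance
that death intervenes, a mechanical enrichment discussed in
`docs/methods.md`.

The same pipeline is available from the shell:

```
reproage simulate --profile biennial_yearlong --seed 7 --out records.csv
reproage analyze --input records.csv --seed 7 --out-dir demo_out
reproage demo --seed 1            # all three breeding-tactic profiles
```

Input CSVs need the columns `individual_id, species, sex, season, age,
outcome` (optionally `partner_id`, `known_recruit`); every output table is
CSV.

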