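# raschdif

Rasch-model analysis of **differential item functioning (DIF)** in ordinal
questionnaire data — built for the situation epidemiologists face when
comparing groups (e.g. boys vs girls, or girls before vs after menarche)
on a composite symptom scale: before trusting a group difference in mean
scores, you must check that the items work the same way in every group,
and when they do not, decide what to do about it.

The package fits the polytomous Rasch (partial credit) model

    Pr{x_vi = x} ∝ exp(−τ_1i − … − τ_xi + x(β_v − δ_i)),   x = 0..m_i,

places persons (β) and items (δ, thresholds τ) on a common logit scale,
and then:

- **diagnoses the category structure** — disordered thresholds, suggested
  category collapses, conditional item-fit chi-square, expected value
  curve (EVC) data;
- **detects DIF** by a two-way ANOVA of standardized response residuals on
  group × class interval: the group main effect is *uniform* DIF (constant
  offset along the trait), the interaction is *non-uniform* DIF;
- **separates real from artificial DIF**: real DIF in one item induces
  compensating, opposite-signed DIF in the others, so significant items
  are resolved *sequentially* — the worst item is split into
  group-specific items (other groups structurally missing), the model is
  refitted, and the test repeated until nothing is significant;
- **quantifies the consequences** — group-specific item locations and EVC
  slopes of resolved items, person-mean group differences and
  difference-in-differences across item sets, person separation index
  (PSI), and overall fit probability per item set.

A fully seeded synthetic-data generator produces survey-scale response
matrices with known injected uniform/non-uniform DIF, so the whole
workflow is testable end to end.

## Worked example

Run the built-in survey-scale scenario — three groups of 3 500 persons,
eight 3-category items, uniform DIF of 0.8 and 0.5 logits injected into
`felt_low` and `stomach_ache` for the post-menarche group:

```python
from raschdif.pipeline import PipelineConfig, run_pipeline
run_pipeline(PipelineConfig(preset="hbsc_like", seed=5, output_dir="out"))
```

`out/group_comparison.txt` then contains (this run's actual output):

```
Group comparison (person means; higher = better health)

                                            set1     set2     set3
boys                                     0.51874  0.58266  0.55339
girls_no_period                          0.34736  0.41625  0.38783
girls_period                            -0.69594 -0.54624 -0.49040
Difference boys-girls_no_period          0.17139  0.16642  0.16556
Difference girls_no_period-girls_period  1.04329  0.96249  0.87823
PSI                                      0.74563  0.74059  0.73559
Overall item fit p                       0.88490  0.99999  1.00000
```

Reading it: the loop resolved `felt_low` then `stomach_ache` (sets 2 and
3; see `resolution_trace.json`), exactly the two injected items in
magnitude order. Resolving them shrinks the girls-before vs girls-after
mean difference from 1.043 to 0.878 logits — the 0.165 removed is the
spurious part contributed by the DIF items — while a large true group
difference remains. The boys vs girls-before difference, where no DIF was
injected, barely moves. PSI stays essentially constant (reliability is
retained) and the overall fit probability rises with each resolution.
`resolved_item_comparison.json` shows the recovered group-specific item
locations: for `felt_low` the boys–girls_period location difference is
0.80 logits, matching the injected shift.

The same workflow runs from the shell:

```
raschdif simulate --preset hbsc_like --seed 5 -o responses.csv
raschdif run --preset hbsc_like --seed 5 -o out
raschdif report out
```

or on your own CSV (`person_id,group,item…` columns, empty cell =
missing) via `raschdif run --input responses.csv` or the library calls
(`read_responses`, `fit`, `sequential_resolution`, `group_comparison`).

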