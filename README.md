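# greykappa

Weighted inter-rater agreement coefficients for ordinal contingency tables,
and a simulation framework for studying **grey zones** — the systematic
migration of one rater's borderline ratings into an adjacent category.

## Who this is for

When two raters (pathologists grading tumours, radiologists classifying
films, examiners scoring tests) classify the same N subjects into q ordered
categories, their agreement is summarised by a chance-corrected coefficient

```
delta = (p_a - p_e) / (1 - p_e),
```

where `p_a = sum_ij w_ij p_ij` is the weighted observed agreement and `p_e`
a chance term. The package implements the five standard choices of `p_e` —
Cohen's weighted kappa, Scott's pi, Gwet's AC2, Brennan–Prediger's S and
Krippendorff's alpha — each combined with five weighting schemes
(unweighted, linear, quadratic, radical, ordinal) that grade partial credit
for near-diagonal disagreement.

A *grey zone* arises when one rater cannot sharply separate two adjacent
categories and over-uses one of them (e.g. calling borderline films "benign
disease" rather than "suspected cancer"). This distorts the table's margins
and biases every coefficient. The package provides:

- **measures** — the 5 x 5 coefficient grid and a cross-table
  coefficient-of-variation sensitivity summary;
- **tablegen** — generation of ordinal agreement tables by discretizing a
  standard bivariate normal latent pair (correlation rho, cutoffs on the
  normal scale) and sampling multinomial counts;
- **greyzone** — injection of a grey zone at category g by moving a fraction
  `lambda` of the adjacent diagonal mass into column g, plus two searches
  (PA, from the perfect-agreement table; CP, from a given table with
  diagonal-step compensation) that hit a prescribed *true* agreement within
  a tolerance, so grey and non-grey tables can be compared at matched truth;
- **simulate** — the paired Monte Carlo study: MAE/MSE/MAPE of each
  coefficient with and without a grey zone across table structures
  (balanced, slightly/heavily unbalanced), sample sizes, table sizes and
  agreement levels.

## Worked example

The packaged fixture `original` is a classic 4 x 4 table of two
radiologists' diagnostic classification of 85 xeromammography films
(Normal / Benign disease / Suspected cancer / Cancer). Rater A over-uses
"Suspected cancer" (29 vs 16) while rater B over-uses "Benign disease"
(38 vs 22) — a grey zone between the two middle categories.

```bash
greykappa fixtures --dump fx
greykappa compute --table fx/original.csv --all | head -8
```

```
table,measure,scheme,value
fx/original.csv,cohen,unweighted,0.473
fx/original.csv,cohen,linear,0.568
fx/original.csv,cohen,quadratic,0.671
fx/original.csv,cohen,radical,0.518
fx/original.csv,cohen,ordinal,0.631
fx/original.csv,scott,unweighted,0.461
fx/original.csv,scott,linear,0.564
```

Cohen's kappa rises from 0.473 (unweighted) to 0.671 (quadratic): the
heavier the partial credit for one-step disagreements, the less the grey
zone between the middle categories is penalised.

Passing several tables adds a coefficient-of-variation row — how much a
measure/weight pair moves across hypothetical realizations of the grey
zone. Gwet's AC2 with quadratic weights is the most stable pair:

```bash
greykappa compute --table fx/original.csv --table fx/scenario1_additive.csv \
  --table fx/scenario2_additive.csv --table fx/scenario3_additive.csv \
  --measure gwet_ac2 --weight quadratic
```

```
table,measure,scheme,value
fx/original.csv,gwet_ac2,quadratic,0.85
fx/scenario1_additive.csv,gwet_ac2,quadratic,0.84
fx/scenario2_additive.csv,gwet_ac2,quadratic,0.869
fx/scenario3_additive.csv,gwet_ac2,quadratic,0.863
CV,gwet_ac2,quadratic,0.015
```

A matched-truth grey-zone table and a small paired study:

```bash
greykappa greyzone --q 4 --structure balanced --target-kappa 0.8 \
  --approach pa --epsilon 0.01 --out grey.json
greykappa simulate --config study.yaml --out results.csv
```

where `study.yaml` lists factor levels (`structure`, `n`, `q`, `level`,
`measure`, `scheme`), `replications`, `epsilon` and `seed`. The output CSV
has one row per (scenario, grey-status) with `mae`, `mse`, `mape`,
`true_kappa`, effective replication counts and seeds.

Python API mirrors the CLI:

```python
import greykappa as gk

t = gk.load_fixture("original")
gk.coefficient(t, "gwet_ac2", "quadratic").round3()   # 0.85
p, search = gk.scenario_tables("BL", 4, "M")          # latent table + grey zone
search.spec.lambda1, search.achieved                  # (0.05, 0.0075)
```

## Layout

```
src/greykappa/
  weights.py    # the five weight matrices
  measures.py   # tables, coefficients, CV
  tablegen.py   # latent bivariate-normal table generation
  greyzone.py   # grey-zone injection, PA and CP searches
  simulate.py   # paired Monte Carlo accuracy study
  fixtures.py   # packaged worked-example tables (with provenance notes)
  io.py, cli.py # CSV/JSON I/O and the command-line interface
docs/methods.md # model, assumptions, design choices, limitations
```
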