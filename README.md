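# smmsurv — severe-maternal-morbidity surveillance for administrative hospital data

Maternal deaths are too rare for most municipalities to learn anything from
them, so surveillance programmes track **severe maternal morbidity (SMM)**
instead: the WHO's *potentially life-threatening conditions* (PLTC), a layer
of 26 diagnosis-, condition- and management-based criteria sitting below
maternal near miss in the severity spectrum. `smmsurv` operationalizes those
criteria over the two Brazilian hospital-discharge dialects — the public
SIH/SUS schema (AIH admission forms, ICD-10 diagnoses, SIGTAP procedures)
and the private ANS schema (hospitalization events, four ICD fields, TUSS
procedures) — and reproduces the standard analysis surfaces of an
administrative-claims validity study. It is written for epidemiologists and
health-information analysts who need a reusable, editable phenotyping
pipeline rather than a one-off script.

## What it computes

For each hospitalization episode *e* and criterion *c* with ICD set
*I(c)*, schema procedure set *P(c)* and optional derived rule *r(c)*:

```
meets(e, c)  =  [ diagnoses(e) ∩ I(c) ≠ ∅ ]  ∨  [ procedures(e) ∩ P(c) ≠ ∅ ]  ∨  r(c)(e)
```

with 3-character ICD entries acting as category prefixes, 4-character
entries exact, and ranges (`Z34–Z39`) inclusive on the 3-character stem.
22 of the 26 criteria are operationalizable this way; the remaining four
(placenta accreta/increta/percreta, HELLP syndrome, thrombocytopenia
<100,000, return to operating room) are declared in the registry but carry
no observable signature in either schema.

Episodes, not forms, are the unit of analysis: public-schema admission
forms chain into one episode of care when they share person and hospital
keys and the next admission starts at most `max_gap_days` (default 1) after
the previous discharge.

Convergent validity is assessed with the odds ratio of in-hospital death.
For criterion *c*, over known-outcome episodes (live discharge or death),

```
OR(c) = (a·d) / (b·c),    a = deaths with c,  b = alive with c,
                          c = deaths without, d = alive without
```

with the complement — including episodes meeting *other* criteria — as the
reference, no continuity correction, `OR = 0` when a = 0 and undefined when
b = 0 or c = 0. The package also produces the per-criterion frequency table
(shares of obstetric hospitalizations and of SMM cases, group totals by
episode-level union) and the deaths-by-criterion-count table.

Because the national microdata cannot be redistributed, a synthetic-cohort
generator (`smmsurv.simulate`) emulates both schema pairs — multi-form
public episodes, ~30% record-level ICD missingness on the private side,
planted per-criterion prevalences, and a logistic death model on the number
of observable criteria — so the whole pipeline is testable end to end
against a known truth table.

## Worked example

```python
import pandas as pd
import smmsurv as s

cfg = s.SimConfig(n_episodes=20_000, seed=42)
s.simulate_cohort(cfg, "demo")              # writes both schema pairs + truth
result = s.run_pipeline("demo")             # read -> assemble -> identify -> classify

pub = result.public
print(pub.n_records, pub.n_episodes, pub.n_obstetric)
#> 17406 16634 14972
freq = pub.frequency.set_index("name")
print(freq.loc[["severe_hypertension", "prolonged_stay", "blood_transfusion"],
               ["n_cases", "pct_hospitalizations", "pct_smm_cases"]].round(2))
#>                      n_cases  pct_hospitalizations  pct_smm_cases
#> name
#> severe_hypertension      542                  3.62          36.25
#> prolonged_stay           223                  1.49          14.92
#> blood_transfusion        151                  1.01          10.10
```

17,406 admission forms collapse into 16,634 episodes (the multi-form
continuation chains), of which 14,972 are obstetric; severe hypertension is
the most frequent criterion, at 3.62% of obstetric hospitalizations and
36.25% of SMM cases — the same shape as the national tables the generator's
defaults emulate.

The validity arithmetic works directly on published margins, too. Shock in
the public schema, from its printed (death, alive) cells against the
cohort totals:

```python
table = s.TwoByTwo.from_margins(269, 1006, 7_456, 18_621_293)
print(s.round2(table.odds_ratio()))
#> 692.78
```

A command-line interface wraps the same steps:

```bash
smmsurv simulate --n-episodes 100000 --seed 1 --out-dir cohort/
smmsurv classify --data-dir cohort/ --out profiles.csv
smmsurv report   --data-dir cohort/ --out-dir report/
```

`report/` then holds `frequency.csv`, `odds_ratios.csv`,
`deaths_by_count.csv` and `cross_schema_ratio.csv`.

## Layout

- `smmsurv/codebook.py` — code-set registry (editable YAML), normalization
  and matching semantics
- `smmsurv/records.py` — data model + CSV readers/writers for both dialects
- `smmsurv/episodes.py` — episode-of-care assembly
- `smmsurv/obstetric.py` — obstetric-hospitalization identification
- `smmsurv/classify.py` — the 22-criterion classification and derived rules
- `smmsurv/stats.py` — 2x2 tables, odds ratios, frequency surfaces
- `smmsurv/simulate.py` — synthetic cohorts and parameter recovery
- `smmsurv/pipeline.py`, `smmsurv/report.py`, `smmsurv/cli.py` — orchestration
- `docs/methods.md` — modelling assumptions, defaults and limitations
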