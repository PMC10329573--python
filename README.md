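# uroscreen

Reflex urine-culture screening evaluation for clinical microbiology and
urology laboratories.

Many urine cultures ordered for outpatients grow nothing of clinical
significance. A *reflex screening* policy cultures a sample only when its
automated sediment analysis — leukocytes/µL and bacteria/µL from an automated
microscopy analyzer — exceeds fixed cut-offs. `uroscreen` implements the full
evaluation loop a laboratory needs to adjust those cut-offs:

- **Rule-based adjudication** of each culture as positive or negative from
  growth status, organism class (classic vs non-classic uropathogen),
  cfu/ml, pyuria and the need for antibiotics.
- **A screening-rule grammar** (`leuk>20 OR band>=++`) over leukocyte counts,
  raw bacteria counts, and the banded bacteria result
  (`neg` < 130/µL ≤ `+` ≤ 330/µL < `++`).
- **Diagnostic evaluation**: confusion matrices against the adjudicated
  labels, sensitivity/specificity sweeps across candidate rules, and a
  breakdown of the positive cultures a rule would miss.
- **Workup-cost savings**: avoided cultures priced by laboratory workup
  category (negative, Gram-positive, Gram-negative, both), with exact
  decimal currency arithmetic and annualization.
- **A calibrated synthetic cohort** of 2,821 urology-outpatient samples
  whose raw attributes re-derive, through the analysis code itself, the
  published-scale marginals this package is validated against.

## The model

A culture is adjudicated **negative** iff one of five clauses holds:

1. no bacterial growth;
2. growth of mixed contaminants;
3. non-classic uropathogen at < 10⁵ cfu/ml;
4. non-classic uropathogen at ≥ 10⁵ cfu/ml with < 20 leukocytes/µL and no
   need for antibiotics;
5. classic uropathogen at ≤ 10⁴ cfu/ml with < 20 leukocytes/µL and no need
   for antibiotics;

otherwise positive. For a screening rule *R*, with screen-positive meaning
"reflex to culture",

- sensitivity = TP/(TP+FN) · 100 (positive cultures the screen retains),
- specificity = TN/(TN+FP) · 100 (negative cultures the screen avoids),
- cultures saved = TN + FN, priced per workup category and annualized as
  `total · 12 / months_observed`.

## Worked example

```python
from uroscreen import (
    default_spec, generate_cohort, adjudicate_cohort,
    confusion_matrix, sens_spec, missed_report, savings_breakdown, annualize,
    ADOPTED_RULE_TEXT,
)

samples = adjudicate_cohort(generate_cohort(default_spec(), seed=1))
cm = confusion_matrix(samples, ADOPTED_RULE_TEXT)   # leuk>20 OR band>=++
print(cm.to_frame())
#                     culture_negative  culture_positive  total
# sediment_negative               1019                32   1051
# sediment_positive               1079               691   1770
# total                           2098               723   2821
print(sens_spec(cm))
# {'sensitivity_pct': 96.0, 'specificity_pct': 49.0}

report = missed_report(samples, ADOPTED_RULE_TEXT)
print(report.total_missed, report.clinically_relevant_count)
# 32 11

sb = savings_breakdown(samples, ADOPTED_RULE_TEXT)
print(sb.total_count, sb.total_cost_eur, annualize(sb.total_cost_eur, 8))
# 1051 31470 47205
```

Reading: under the `leuk>20 OR band>=++` cut-off, 1,051 of 2,821 cultures
(37%) would not have been performed; 32 positive cultures would be missed, of
which 11 were clinically relevant (antibiotics given for symptomatic UTI or
as pre-procedure prophylaxis); the avoided laboratory workups are worth
€31,470 over 8 months, €47,205 annualized.

The same pipeline runs from a shell:

```bash
uroscreen generate --seed 1 --out cohort.csv
uroscreen evaluate --cohort cohort.csv --months 8 --out-dir report/
uroscreen sweep --cohort cohort.csv
```

`evaluate` writes the cohort overview, species table, rule sweep, 2×2 matrix,
savings table, missed-culture table and a plain-text summary with
deterministic bytes.

## Rule grammar

Atoms compare one quantity with a threshold: `leuk>20`, `bact>330`,
`band>=+`, `band==neg` (band order `neg` < `+` < `++`; comparators `>`,
`>=`, `<`, `<=`, `==`). Atoms combine with `AND`/`OR` and parentheses:

```
(leuk>20 AND band>=+) OR (leuk>100 AND band==neg)
```

Rules can also be given as structured clauses in a YAML run config; see
`uroscreen.cli_io.RunConfig`.

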