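# Methods

## Problem setting

A urology outpatient clinic sends midstream urine samples to automated
sediment analysis (leukocytes/µL, bacteria/µL). Under the legacy policy a
culture is performed only when the sediment shows more than 130 bacteria/µL
(band `+` or higher) and/or more than 50 leukocytes/µL. The question the
package answers: if the reflex cut-off were tightened (e.g. to
`leuk>20 OR band>=++`), how many cultures would be avoided, at what cost in
missed positive cultures, and what laboratory spending would be saved?

## Culture adjudication

Ground truth is not raw growth: low-count growth of skin or mucosal flora is
clinically negative. A culture is adjudicated negative iff one of five
clauses holds (see README). Implementation details that matter:

- `10^5` and `10^4` cfu/ml are the conventional significant-bacteriuria
  thresholds; both live in `AdjudicationPolicy` and are configurable.
- Boundary semantics follow the clauses as stated: the non-classic low-count
  clause is strict (`< 10^5`), the classic low-count clause is inclusive
  (`<= 10^4`), pyuria comparisons are strict (`< 20` leukocytes/µL).
- Classic uropathogens with cfu strictly between 10^4 and 10^5 are covered by
  no negative clause and are therefore positive regardless of pyuria. This is
  a deliberate, faithful reading of the clause set; it is the regime the
  missed-culture stratum of the default cohort occupies.
- Multi-isolate cultures are negative only if every isolate individually
  satisfies a negative clause; "all other cultures are positive" is read at
  the sample level.
- The classic/non-classic catalog is configurable because laboratories
  disagree at the margins; the shipped default covers every species of the
  default cohort. Missing treatment flags default to `False`, which is
  conservative toward the negative clauses (a missing flag can only make a
  culture negative, never positive).
- "Mixed contaminants" and named-isolate growth are modelled as mutually
  exclusive statuses.

Monotonicity follows from the clause structure: leukocytes appear only in
negative clauses as `< 20`, so raising leukocytes can never turn a positive
culture negative (property-tested).

## Banding, trigger, rule grammar

Bacteria bands partition [0, ∞): `[0,130) -> neg`, `[130,330] -> +`,
`(330,∞) -> ++`. The legacy trigger's bacteria arm is implemented as
`band >= +` (i.e. ≥ 130) so banding and triggering share one boundary; the
alternative strict `> 130` reading differs only at the single value 130.
Leukocyte comparators are strict `>` throughout, matching the printed rules.
Counts are non-negative reals (analyzers report non-integers).

Rules are ASTs of atoms (`quantity comparator threshold`) combined with
AND/OR; the parser and canonical formatter round-trip (property-tested).
Threshold rules of the form used here are monotone: lowering a leukocyte
threshold or relaxing a band comparator can only add screen-positives, hence
sensitivity is non-decreasing and specificity non-increasing along a
relaxation sweep (asserted on any cohort).

## Evaluation conventions

- The screen-vs-adjudication 2×2 conserves the cohort size; `cultures_saved`
  is the screen-negative margin TN + FN.
- Percentages round half-away-from-zero (`round_half_up`), not banker's
  rounding — the convention that reproduces clinical-report percentages such
  as 74.4% (2098/2821) and 59.4% (19/32); sensitivity/specificity default to
  integer precision, cohort-summary percentages to one decimal.
- Known discrepancy: the adopted rule's specificity computed from the 2×2
  (1019/2098 = 48.6 → 49) differs from the 47 sometimes quoted alongside it;
  `sens_spec` always returns the arithmetic value of the matrix it is given.
- The missed-culture report tabulates species by first-listed isolate
  (`species_mode="all"` multi-counts deliberately); "clinically relevant"
  means antibiotic treatment was actually given, for symptomatic UTI or as
  pre-procedure prophylaxis.

## Cost model

Cost category reflects the laboratory workup actually performed, not the
adjudicated label: no-growth and mixed-contaminant cultures take the
negative workup, growth cultures the Gram class of their isolates
(`both` when mixed). This is why the avoided-culture cost rows of the
default cohort (957 negative workups + 38 + 53 + 3 identification workups)
exceed the 1,019 adjudicated negatives' negative share — 94 avoided cultures
grew organisms, only 32 of them adjudicated positive. Yeast-only cultures are
priced as Gram-positive workups by default; a separate yeast price slot is
available. Currency arithmetic is exact `decimal.Decimal`: each row is
count × unit price rounded half-up to whole euros and the total is the sum of
the rounded rows (957 × €24.66 = €23,599.62 → €23,600; grand total €31,470,
not the unrounded €31,469.45). Annualization is linear:
`total × 12 / months`, rounded to whole euros. Prices are stored and parsed
as plain dot-decimal numbers; locale variants (decimal commas) are rejected,
never guessed.

## The calibrated synthetic cohort

No per-sample data accompany the published marginals, so the default spec
encodes them as a count-exact stratified design (exact counts, not
multinomial rates): n = 2,821; growth status 1,356 / 600 / 865; adjudication
2,098 negative / 723 positive; adopted-rule cells TN 1019, FN 32, FP 1079,
TP 691; avoided-culture workup categories 957 / 38 / 53 / 3; species mix
with E. coli 408 of 865; missed cultures 19 E. coli + 5 E. faecalis +
3 P. mirabilis + 5 various, split 21 untreated / 6 symptomatic /
5 prophylaxis.

Each stratum carries an admissible attribute region chosen so that the
analysis code itself re-derives the stratum: e.g. a missed positive needs
leukocytes ≤ 20 and (via the legacy trigger) bacteria in [130, 330], with a
classic uropathogen above 10⁴ cfu/ml. Validation certifies each region by
corner evaluation (the clauses and threshold rules are monotone in
leukocytes and cfu) and raises an explicit infeasibility error naming any
stratum whose region is empty or lands on the wrong side of the rule.
Generation never trusts construction labels: with checking enabled every
sample is pushed back through the trigger, the adopted rule and the
adjudication clauses.

Free choices the marginals do not determine, fixed once as package defaults:

- The species table's individual rows sum to 858 of 865 growth cultures; the
  remaining 7 are modelled as polymicrobial mixed-Gram cultures
  (*S. epidermidis* + *Acinetobacter*), which simultaneously supplies the
  `both` workup category (3 avoided + 4 cultured). The cohort summary lists
  them as a "Polymicrobial" row so every individual species cell keeps its
  exact count and percentage against the 865 denominator.
- The "Other" species group (90 cultures) is realised as named non-classic
  flora (Corynebacterium, viridans streptococci, Lactobacillus,
  Acinetobacter, Stenotrophomonas) so that Gram classes can satisfy the
  avoided-culture category counts.
- The 5 "various" missed species are 2 K. pneumoniae, 1 group-B
  streptococcus, 1 S. aureus, 1 P. aeruginosa — classic uropathogens chosen
  so the missed Gram classes remain consistent with the cost strata.
- Within-stratum sediment counts are log-normal (right-skewed, as analyzer
  counts are), truncated to the admissible region by rejection with the
  location at the region's log-midpoint and σ = 0.6, giving high acceptance;
  after 200 rejections the draw falls back to uniform on the region, keeping
  generation total. cfu values are log-uniform within each clause's
  admissible interval. A fifth of the screen-positive non-growth, mixed and
  true-positive cultures enter through the trigger's leukocyte arm only
  (leukocytes > 50, band-negative bacteriuria), since both trigger arms occur
  in practice.
- Randomness: every sample has its own keyed stream
  (`SeedSequence([seed, stratum, index])`), so a (spec, seed) pair
  regenerates the identical cohort on any platform, and the count structure
  is seed-invariant by design.

An optional multinomial mode draws stratum membership stochastically with the
spec's proportions (tested to recover them within 3 standard errors at 10× n).

**What passing tests do and do not show.** The generator reproduces the
printed *marginals* exactly and places raw values in *admissible* regions; it
does not model the real joint distribution of sediment counts, repeat
samples from the same patient, seasonal case mix, or measurement error in
the analyzer. Sweep rows for rules other than the adopted one therefore
depend on the within-region distribution conventions above and are
illustrative, not calibrated; only the adopted rule's cells are pinned by
the design.

## Problem sizes

The default cohort is 2,821 samples; the full test suite (including a
28,210-sample multinomial-recovery check and several hundred property-test
cases) runs in well under a minute on one CPU, and the acceptance script in
a few seconds.

## Known limitations

- Single-center urology-outpatient case mix; the calibrated cohort should
  not be read as representative of other departments or primary care.
- No erythrocyte or other particle channels; no antimicrobial
  susceptibility; no downstream treatment-cost or resistance economics.
- The adjudication leaves classic uropathogens between 10⁴ and 10⁵ cfu/ml
  positive irrespective of pyuria (see above); laboratories wanting a
  different convention can change `AdjudicationPolicy`.
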