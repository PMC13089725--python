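# Methods

## The surveillance problem

Administrative hospitalization databases record diagnoses (ICD-10) and
billed procedures, not clinical measurements. Identifying severe maternal
morbidity (SMM) in them therefore means translating each WHO potentially
life-threatening condition (PLTC) criterion into code sets the data can
actually express. `smmsurv` implements that translation for two Brazilian
dialects: the public SIH/SUS schema and the private ANS schema. Four of the
26 criteria (placenta accreta/increta/percreta, HELLP syndrome,
thrombocytopenia <100,000, return to operating room) have no ICD-10 code or
billable procedure in either terminology; they are kept in the registry as
declared-but-unoperationalized entries, and asking the classifier to
evaluate one raises an error rather than silently returning false.

## Code matching

ICD entries follow three semantics: 4-character codes match exactly,
3-character codes are category prefixes (the source tables list, e.g., both
a category and its subcodes; prefix semantics reproduces those redundant
listings without double counting), and ranges match on the 3-character stem
(4-character bounds clip the edges). Malformed recorded values — anything
that does not normalize to letter + 2 digits + optional digit — are flagged
and never matched. Procedure codes are fixed-width digit strings: SIGTAP
10 digits, TUSS 8; shorter printed forms are left-zero-padded, which is how
the 9-digit entries in the source material (e.g. the ectopic-pregnancy
procedure 411020048 and the blood-transfusion block) are stored.

Two transcription decisions in the shipped registry deserve a note. The
sepsis enumeration contains a bare "413" between A412 and A414; it is
stored as A413. The hysterectomy criterion lists O822 (delivery by
caesarean hysterectomy) as printed, without reinterpretation. The severe
hypertension entries I10–I15 are 3-character prefixes, so all fourth
characters match; I14 is not listed and does not match.

The registry is data, not code: `smmsurv/data/codebook.yaml` can be edited
or replaced (`Codebook.from_yaml`) to load an alternative
operationalization, and serialization round-trips losslessly.

## Episodes of care

A public-schema hospitalization can span several AIH admission forms (care
type changes mid-stay). The national linkage algorithm behind the published
episode construction is not reproducible from its public description, so
the package uses a documented replacement: forms chain transitively when
they share person key and hospital key and each admission starts no more
than `max_gap_days` after the latest previous discharge in the chain
(default 1 day — same-day or next-day continuation; overlapping stays also
chain). The replacement is deliberately conservative: no probabilistic
linkage, no cross-facility transfer chaining. This rule is *not* identical
to the published algorithm (whose essential keys are the hospital number
and the woman's date of birth); sensitivity to the gap threshold is exposed
as configuration. Private-schema events pass through one-to-one — the ANS
release lacks both keys, so multi-event stays there (the "hospital
permanence"/"administrative discharge" reasons) cannot be linked, only
counted.

Episode diagnosis and procedure sets are unions over member forms, because
a criterion anywhere in the episode marks the episode. The outcome is the
final form's discharge reason; death on a non-final form is a validation
error.

## Obstetric identification

Public: ICD chapter O in any of the 14 diagnosis fields, or an obstetric
SIGTAP procedure. Private: the type-of-hospitalization field (3 =
obstetric) is combined with diagnoses and procedures because it both
under-captures (abortion, some cesareans) and over-captures (newborns
billed under the mother). A type-3 record is vetoed when it carries a
chapter-P diagnosis outside the maternal-relevant allow-list — read as a
neonatal admission under the mother's event — which is the single
non-monotone clause in the rule and is tested explicitly. The printed
allow-list shorthand ("P0, P1, …") is ambiguous between 2- and 3-character
stems; the package stores the fully enumerated allow-list printed alongside
it and matches by stem prefix, nothing more. Because ICD registration is
not mandatory in the private system (~30% of records carry none), the
type-3 clause must and does fire on type alone when all ICD fields are
empty. The 10–49 age filter is a cohort-construction step upstream of these
predicates (neither schema's age field is modelled here).

## Derived rules

* **Prolonged stay** — delivery episode (configurable delivery-procedure
  subset; default: the normal-delivery and cesarean entries of the
  obstetric lists) with discharge − admission strictly greater than 7 days;
  public episodes billed for newborn care (0802010024) are excluded.
* **ICU admission** — public: the ICU-days counter > 0 or an ICU SIGTAP
  code; private: the ICU TUSS codes.
* **Surgical intervention / conditional curettage** — the public curettage
  code 0411020013 cannot distinguish post-abortion from puerperal
  curettage, so it counts only when the episode also contains a delivery
  procedure or a puerperal-complication diagnosis (default stems O85–O92,
  configurable); the direct surgical codes count unconditionally.

## Analysis surfaces

Frequency tables use the full obstetric cohort as denominator; the death
analyses (odds ratios, deaths by criterion count) use only known-outcome
episodes (live discharge or in-hospital death) — the two denominators are
explicit parameters because surveillance practice switches between them.
Group totals are episode-level unions (an episode with two haemorrhagic
criteria counts once for the group), which is why group totals are below
column sums. The odds ratio is the plain cross-product with the complement
as reference; a = 0 gives 0, b = 0 or c = 0 gives NaN, and printed-scale
comparisons round half-up to 2 decimals (this convention reproduces every
published row that has four positive cells). Woolf confidence intervals are
implemented but off by default — the reference tables print none.
Cross-schema ratios are computed from unrounded shares (rounding first
would zero out the rare-criterion rows).

### Shipped reference counts

`data/reference_counts.yaml` carries the national 2015–2022 margins: per
criterion, cases and (death, alive) cells; per schema, the obstetric,
known-outcome, death and SMM totals; and deaths by criterion count. They
are the inputs to the validity reconstruction in `smmsurv.reference` and
`scripts/acceptance.py`. One internal inconsistency in the published
private-schema material is preserved rather than resolved: the death-table
header total (3,545,882; overall SMM deaths 1,016) disagrees with the
deaths-by-count table (3,580,965 known-outcome episodes; 4,276 deaths;
956 SMM deaths). Reconstruction against the deaths-by-count margins is
therefore only asserted for private rows consistent with them (blood
transfusion, central venous access); the others are reported but not
certified.

## Synthetic cohorts

The generator's defaults are the national study conditions: 83% public
episodes (18.8M vs 3.78M), per-criterion prevalences at the public-schema
rates, 30% private ICD missingness, known-outcome rates of 99% (public)
and 94.8% (private), and a 2015–2022 admission window. Criterion hits are
independent Bernoulli draws (the source provides no joint distribution; a
correlation hook is out of the default surface) — so the synthetic overall
SMM share (~9.5%) sits slightly above the national 8.51%, where criteria
co-occur. Every planted hit is realized as a triggering code drawn from the
registry; when private missingness masks an ICD trigger, a TUSS procedure
is substituted if the criterion has one, otherwise the hit is
planted-but-unobservable and the truth table says so. Death follows
logit(p) = β₀ + β₁·k on the number of observable hits, β₀ = −8, β₁ = 1.1 —
explicitly synthetic values that land near the magnitude ordering of the
national deaths-by-count gradient, not estimates. Multi-form public
episodes (5% by default) split a stay into 2–3 segments with 0–1-day
handoff gaps, so default assembly recovers the planted grouping exactly.

What the generator does **not** emulate: criterion correlation, schema-
specific prevalence profiles, coding error and miscoded discharge reasons,
person attributes, geography, and seasonality. Passing tests therefore
demonstrate the pipeline's mechanics (matching, linkage, accounting,
arithmetic) under controlled conditions — not the field accuracy of the
operationalization on real claims, which depends on recording quality the
synthetic data idealizes.

`recover_parameters` reports per-criterion sensitivity and specificity
against planted truth (sensitivity is measured against *all* planted hits,
so full masking yields exactly the procedure-fallback share), prevalence
bias, and the sign of a logistic death-gradient fit (statsmodels).

## Numerical and scale choices

Deterministic throughout: a single seeded generator produces byte-identical
cohort files. The default test suite exercises cohorts up to 50,000
episodes and the end-to-end smoke test 100,000 (≈half a minute on one
core), sizes at which the binomial 3-SE prevalence checks are informative
for criteria with expected counts above ~5; rarer criteria are excluded
from that bound rather than pretending power exists. Ties in episode
assembly are broken by (admission date, discharge date, form id); matching
is order-independent over code-set entries by construction.

## Known limitations

* The episode-linkage heuristic is a stated replacement, not the published
  algorithm; episode counts on real public-schema data will differ near the
  gap threshold.
* The private discharge-reason code map covers only the categories named in
  the public documentation; unmapped codes load as UNKNOWN and drop out of
  the death analyses.
* Criteria based solely on ICD (13 in the private schema) are structurally
  under-ascertained there; the generator reproduces the mechanism, and the
  missingness-monotonicity test pins the direction, but the magnitude on
  real data is unknowable from within this package.
* No regression adjustment, no confidence intervals by default, no
  maternal-near-miss layer — the analysis surface is deliberately the
  descriptive validity triad.
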