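# Methods

## Scope and data model

The package analyses spontaneous-report line-lists: one row per
Individual Case Safety Report (ICSR) with the suspected drug(s), the
reaction preferred terms (PTs), coarse demographics and a case-level
fatal-outcome flag. This mirrors what public ADR portals expose — in
particular, age arrives pre-binned in the EMA bands (0–1 month,
2 months–2 years, 3–11, 12–17, 18–64, 65–85, >85 years), never as a
numeric age, and origin is only EEA / non-EEA. PTs are flat,
case-insensitive, whitespace-normalised strings; no MedDRA hierarchy
(SOC/HLT) is modelled and no live database connector exists.

The built-in query sets are the three resistance PTs (DR: "drug
resistance", "multiple-drug resistance", "pathogen resistance") and the
nine ineffectiveness PTs (DI: "therapeutic product effect decreased",
"therapeutic product effect incomplete", "decreased activity", "drug
ineffective for unapproved indication", "therapeutic product
ineffective", "therapeutic response decreased", "treatment failure",
"therapy non-responder", "drug ineffective"). "multi-drug resistance"
is registered as a spelling alias of "multiple-drug resistance": both
forms circulate for the same PT, and either counts toward the same
member in matching and in per-PT breakdowns.

**Counting unit.** Every statistic counts cases, not drug–reaction
pairs. A case with two member PTs of one category is one category case
(it does increment both rows of the per-PT breakdown). A case naming
both drugs of a screened pair contributes to both margins of the 2×2
table; whether such cases should instead be excluded is a genuinely
open design point in disproportionality practice — inclusion was chosen
because it needs no extra information and is symmetric in the pair.
The fatal fraction of a category uses the category's case count as
denominator (fatal DR cases / DR cases).

## The ROR screen

For target/comparator cells (a, b, c, d): ROR = ad/bc, SE on the log
scale sqrt(1/a+1/b+1/c+1/d), CI exp(ln ROR ± z·SE). z is fixed at
exactly 1.96 for α = 0.05, the convention of the field's formula
sheets; any other α uses the exact normal quantile. The p-value is the
two-sided normal tail of ln(ROR)/SE — the test behind the significance
stars (\* p<0.05, \*\* p≤0.01, \*\*\* p≤0.001, \*\*\*\* p≤0.0001) is
isolated in one function (`stars_for`) should a different test ever be
preferred.

A **signal of disproportionate reporting** requires n ≥ 5 target
category reports *and* CI lower bound > 1.0. "Lower bound ≤ 1 ⇒ no
signal" is the standard SDR convention: an ROR below 1 with a tight CI
(e.g. 0.68, CI 0.48–0.96) is a lower reporting probability, not a
signal. The report count tested is the *uncorrected* a-cell.

**Zero cells.** Default policy is Haldane–Anscombe: +0.5 on all four
cells, flagged `corrected` in every output so downstream consumers can
see which rows were shrunk. The alternative `error` policy refuses the
pair; the screen logs and marks such rows unavailable rather than
aborting, because a surveillance screen over many comparators must not
die on one rare-event drug. Corrected cells make the ROR slightly
conservative for large effects; with a = 0 the CI is driven entirely by
the correction and should be read qualitatively.

Percent rendering is full-precision internally, two decimals
half-away-from-zero at the boundary (Python's Decimal ROUND_HALF_UP),
which reproduces portal-style printed percentages exactly.

## The synthetic generator

`generate_frame`/`generate_cases` emulate a multi-drug spontaneous-
report database. Per drug profile: the report count; independent
Bernoulli membership per ADR category; one member PT per membership,
drawn by configurable weights; 1–3 background PTs per case, uniform,
from a vocabulary disjoint from all category members; categorical
demographics; and a fatality flag whose probability is the category
conditional (the max across categories when a case is in several — any
rule mixes the conditionals on the overlap, so convergence tests use
single-category scenarios) or the background rate otherwise.

Randomness: one NumPy substream per profile, keyed by the scenario seed
and a CRC-32 of the drug name, so adding or removing a drug never
perturbs another drug's draws — this keeps regression outputs stable
as scenarios grow. Replicated studies derive per-replicate seeds by
`SeedSequence.spawn`, which decorrelates replicates for any root seed.

What the generator does **not** model: reporting-time dynamics,
duplicate reports, under-reporting, correlation between DR and DI
membership (sampled independently — no joint distribution is published),
or correlation between demographics and outcome. Passing tests
therefore certify the estimator and the pipeline on a well-specified
sampling model, not robustness to real-world reporting artefacts.

### The reference scenario

`reference_scenario()` is a 13-profile scenario shaped like the
EudraVigilance antimicrobial landscape at the 31 December 2022 data
lock: colistin (986 reports, DR 8.42%, DI 10.14%), meropenem (8,864;
3.56%, 9.45%) and linezolid (13,381; 2.38%, 4.15%), with the published
per-PT weights, fatal conditionals (DR 24/20/6%, DI 35/28/19%) and
demographic margins (e.g. male 52.9/55.3/54.4%, EEA 75/40/38%, HCP
89/96/89%). Ten comparator profiles (MOX, TIG, PIP/TAZ, CEF/AVI, VAN,
FLU, ISA, CAP, AMF, VOR) complete the screen design. Comparator DR/DI
rates were back-solved from published target-vs-comparator RORs where
those pin the comparator's odds down — the same MOX rate is recovered
independently from the colistin and the meropenem comparison, a useful
consistency check — and set to plausible mid-range values where nothing
pins them (AMF and VAN resistance; most comparator DI rates). Comparator
report counts are not published at all, so the profile sizes (600 to
15,000) are the package's own choices, spanning the target sizes;
all are overridable per run. Consequently the reference scenario
reproduces the published *descriptive* margins in expectation, but its
screen RORs are only qualitatively comparable to the published ones.

Demographic mass not pinned by a published margin (the six age bands
besides 18–64 and 65–85; the not-specified remainders) is spread in
small, fixed, plausible fractions; the linezolid DI case count is
carried as the probability 0.0415, never as a count, because the
published percentage and per-PT denominators disagree by one case.

## Numerical and validation choices

- Exact arithmetic where exactness is claimed: the worked table
  (4, 6, 2, 18) yields ROR 6 and SE sqrt(35/36) to machine precision,
  and the engine is cross-checked against an independent contingency-
  table implementation (statsmodels `Table2x2`) on random tables in the
  test suite.
- Invariants tested as properties: reciprocity (swapping the rows
  inverts the ROR and mirrors the CI), strict monotonicity in a, CI
  containing the point estimate, CI width shrinking under cell scaling,
  and write∘read identity on the line-list store.
- Operating characteristics at fixed study sizes, chosen to give tight
  binomial bounds while staying desk-sized: parameter recovery with 200
  replicates of 20,000 reports per arm at true ROR 2.111 (mean within
  2%, coverage within [91%, 98%]), and the null false-signal rate with
  400 replicates of 5,000 per arm (≤ 5%; expected ≈ 2.5% since only the
  lower CI bound can fire the rule).
- Degenerate inputs: empty datasets yield all-zero descriptive tables;
  a drug with no reports is an explicit error in summaries and a
  logged, non-fatal unavailable row in screens; a category with zero
  cases has an empty PT breakdown and an undefined (absent) fatal
  fraction rather than a 0/0.

## Known limitations

PRR, Bayesian shrinkage measures (IC/BCPNN, EBGM) and any
multiple-comparison control across the screen grid are out of scope;
the screen reports one frequentist ROR per pair, as surveillance
practice does, and leaves grid-level error control to the reader. The
published screen values for real EudraVigilance data are not
reproducible from first principles — comparator contingency cells are
not published and the database is live — so validation rests on the
synthetic ground-truth studies above.
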