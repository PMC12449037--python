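# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the design decisions behind `kounispv`.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Cohort selection

A case enters the analysis cohort when its reaction set intersects the
union of the *Anaphylactic reaction* (20000021) and *Hypersensitivity*
(20000214) SMQ memberships **and** intersects the *Myocardial infarction*
(20000047) SMQ membership.  All three SMQs contain the PT *Kounis
syndrome* (10069167), so that PT alone qualifies a case; included cases
carrying it form the KS group and the remainder the non-KS group.

SMQ membership is modelled as flat PT sets without the narrow/broad scope
distinction.  Real SMQs carry scopes, but the selection rule here is a
plain membership test, and the dictionary format can be populated with
either scope by whoever builds the bundle.

Exclusion for "missing data on clinical outcomes or underlying diseases"
is operationalised on the four-table structure: a case is excluded when
its outcome field is empty **or** it has no row at all in the history
table.  A history row with a blank PT code means "history recorded,
nothing to report" and does not exclude.  This is the only reading
implementable from the table layout; a database that encodes an explicit
"unknown" outcome value would need a preprocessing step mapping it to the
empty field.

Age, height and weight are categorical bands.  Age is dichotomised at 60
and at 70 years (`dichotomize_age`), but these variables carry heavy
missingness and are excluded from inferential comparisons and from the
candidate set of the model; they are reported descriptively only.

## Disproportionality statistics

For each suspected-drug ingredient the 2×2 table against the **whole**
database is

|              | target event | other events |
|--------------|--------------|--------------|
| target drug  | a            | b            |
| other drugs  | c            | d            |

with ROR = ad/bc and 95% CI exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)),
z = 1.959964.  The comparator is the entire report database rather than
the cohort complement: the extreme RORs such an analysis reports are only
attainable against the full-database denominator.  Each case counts once
per (drug, event) pair regardless of record multiplicity; exposure means
involvement "suspected"; ingredients with no ATC 5th-level code are
excluded from the tally, and ingredients with several codes (e.g.
epinephrine) aggregate by ingredient name.

**Haldane–Anscombe correction.** When at least one cell is zero, 0.5 is
added to all four cells, and both the estimate and the CI use the
corrected cells.  The correction is conditional — applied only in the
presence of a zero — which is the standard reading of the rule; an
unconditional correction would bias every finite-sample estimate toward 1.

**Fisher's exact test.** Two-sided p-values use the point-probability
(minimum-likelihood) rule: with margins fixed, the p-value sums the
hypergeometric probabilities of all tables whose point probability does
not exceed the observed one (within ~1e-7 relative slack for
floating-point ties).  The doubling rule was rejected because the
point-probability convention is the mainstream default in statistical
software; the original convention cannot be determined from published
output, so the choice is recorded here as open.  The implementation
delegates to `scipy.stats.fisher_exact`; the test suite checks it against
full hypergeometric enumeration on every table with N ≤ 30.

**Signal rule.** `signal = ci_low > 1`, a one-sided rule at nominal 2.5%.
Under independence the flag rate measured by the acceptance study stays
near that level (Monte-Carlo slack included, bound 3.5%).

## Group contrasts

Each binary feature is tested on its group-by-feature 2×2 table with
Pearson's chi-squared statistic N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), df = 1,
**without** Yates continuity correction, or with Fisher's exact test when
any of the four expected cell counts is below 5.  The no-correction
choice is validated by recomputing published statistics from their
printed counts: the cardiac-disorders row gives 6.110 against a printed
6.11, whereas the Yates-corrected value would be ≈5.5.  Recomputed values
agree with the printed ones to ±0.05; the published rounding itself
wobbles by up to ~0.03 on some rows (e.g. 34.83 vs 34.84 for the B01 row,
52.27 vs 52.30 for the HIT row), so exact two-decimal equality is not a
meaningful target and is not chased.

The co-reported-PT table is seeded from the KS group: a PT belonging to
any of the three SMQs (other than the KS PT itself) becomes a candidate
when it co-occurs with the KS PT in at least one KS case; counts per
group are cases reporting the PT, plus a row counting cases with at
least one listed PT.  PTs occurring only in non-KS cases never enter the
list — the literal reading of the published aggregation procedure.

No multiple-testing adjustment is applied anywhere, matching the
published analysis.

## Logistic modelling

The dependent variable codes non-KS as 1.  Candidate variables are the
seven disease flags, fatal outcome, ATC-2 class use flags, and the
co-reported PT flags — all binary and defined for every included case.

* **Univariate screen:** the chi-squared/Fisher choice above against the
  label; candidates are variables with p < 0.05.  Constant columns are
  excluded with a warning.
* **VIF screen:** VIF_j = 1/(1−R²_j) from an intercept-included
  least-squares regression of column j on the other candidates; the
  worst column with VIF ≥ 5 is removed and VIFs recomputed, iteratively.
  Perfect collinearity gives infinite VIF and is removed first.  Whether
  the original analysis computed VIF once or iteratively is unstated;
  the iterative variant is chosen because it cannot strand a
  still-collinear pair.
* **Stepwise selection:** the published analysis reports AICc but not its
  entry/stay rule, so the selection criterion is AICc-minimising
  bidirectional search — from the intercept-only model, take the single
  add or drop move with the largest AICc improvement, stop when none
  improves.  Ties break by move type then variable name, making the
  result invariant to candidate order.  Moves whose fit separates or is
  rank-deficient are skipped with a warning.
* **Fit:** maximum likelihood by IRLS (`statsmodels` GLM/binomial) with a
  post-fit score check ‖X'(y−p̂)‖ < 1e-6.  AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)
  and BIC = −2ℓ + k·ln n with k counting the intercept; pseudo R² is
  McFadden's 1 − ℓ/ℓ₀.
* **Intervals:** the primary odds-ratio CIs invert the likelihood-ratio
  test at χ²₁(0.95) = 3.841459 (profile likelihood, nuisance parameters
  re-maximised via offset fits, bounds located by bracketing plus Brent's
  method at 1e-8).  Profile intervals are primary because published
  intervals of this analysis type are far from log-symmetric about the OR
  for near-sparse variables, which pure Wald intervals cannot produce.
  Wald intervals are reported alongside.
* **Separation:** a constant predictor, a rank-deficient design, or a
  diverged coefficient (|β| > 15 on binary data, i.e. OR beyond ~3×10⁶)
  raises an explicit error naming the column.  A quasi-separating
  predictor — present in only one group — must surface this way rather
  than yield a silent huge estimate; the stepwise search treats such
  moves as unavailable.
* **Discrimination:** AUC is the Mann–Whitney statistic of fitted
  probabilities versus labels with half credit for ties; the ROC curve
  (via `scikit-learn`, all thresholds retained) integrates to the same
  number by the trapezoid rule, and both equal brute-force pair counting
  in the tests.

## Synthetic-data generator

The generator emulates what the pipeline consumes: case-linked four-table
structure, multi-PT and multi-drug cases, suspected/concomitant roles,
banded demographics with heavy missingness, a binary fatal outcome, and
drug–event pairs with known RORs.  Its default condition values mirror
the published cohort structure:

* ~2% of cases are cohort-eligible; 53% of eligible cases carry the KS
  PT (the published included cohort splits 130:115).
* Disease-flag prevalences, death probabilities (5.4% KS, 32.2% non-KS),
  ATC-2 class use, and co-reported PT carriage probabilities per group
  are the published per-group proportions; the background population uses
  unremarkable rates (e.g. death 5%).
* Band distributions for age/height/weight follow the published pooled
  tables; missingness (height ~60%, weight ~58%, history 20%, outcome
  15%) is applied after sampling, so ~1/3 of eligible cases are excluded,
  matching the published attrition fraction (123/368).
* Planted drug–event pairs: exposure and event are drawn per case from
  the unique 2×2 joint distribution with the configured margins and odds
  ratio.  The joint is solved in closed form — the OR constraint
  p₁₁p₀₀ = θ·p₁₀p₀₁ is a quadratic in p₁₁ with exactly one root in the
  Fréchet interval — and verified to reproduce margins and OR to 1e-10.
  Planted ingredients are reserved (never drawn as background or cohort
  drugs), so ground-truth cell counts equal a recount from the emitted
  tables exactly.

All randomness flows through one `numpy` generator keyed by the seed,
with draws made in a fixed vectorised order before cases are assembled,
so identical configurations give byte-identical databases.

What the generator does **not** emulate: reporting bias, duplicate
reports, temporal (quarterly) structure, dose/duration, or any real
pathophysiology — group membership and event carriage are independent
coin flips at the configured rates.  Passing tests therefore demonstrate
that the statistical machinery recovers known structure from data of the
right shape, not that it would reproduce real-database estimates.  In
particular the real attrition counts, the published drug-level RORs, and
the published model ORs/AUC require the licensed database and are out of
numeric scope; they are covered structurally (parameter recovery,
coverage, separation diagnostics) instead.

The dictionary bundle shipped in code reuses the genuine MedDRA PT/ATC
codes that appear in published tables; codes at or above 90000000 are
synthetic stand-ins (marked "(synthetic)" in their labels) for terms
whose real codes are licensed.  SMQ memberships are restricted to the
PTs the published tables name plus two generic qualifying terms — the
full licensed memberships are intentionally not reproduced.

## Problem sizes

The default synthetic study uses 20,000 cases (cohort ≈ 250, mirroring
the published 245 at 1/34 of the real database size).  The
parameter-recovery study uses a planted ROR of 4.0 with margins 0.1/0.05
at n = 50,000 over 200 seeds, sampled at the count level (multinomial
over the solved joint cells — distributionally identical to per-case
draws) so the study measures estimator behaviour rather than data
plumbing; CI coverage lands near the nominal 95% and the null flag rate
near 2.5%.  Oracle equivalence for Fisher's test is exhaustive over all
46,375 tables with N ≤ 30.

## Known limitations

* The stepwise criterion, Fisher two-sided convention, and VIF recipe are
  documented choices where the original software's behaviour is
  unstated; alternatives (p-to-enter rules, doubling-rule Fisher) would
  give slightly different selections on borderline data.
* Profile-likelihood bounds are searched within |β| ≤ 60; a bound beyond
  that is reported as infinite (practically, such fits are rejected as
  separated first).
* The reader accepts any delimiter/encoding but expects the package's
  canonical column names; adapting a real PMDA export requires renaming
  columns upstream.
* Duplicate spontaneous reports are retained by design (consistent with
  the published handling); the reader only enforces case-ID uniqueness.
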