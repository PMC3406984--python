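# Methods

## Problem and model

Administrative health data — physician billing claims and hospital discharge
abstracts — are often the only timely source of cancer-treatment information,
but they are collected for payment and administration, not research. Before
such data are used to measure, say, surgical treatment rates, their ability
to identify the treatment must be validated against a gold standard. This
package implements that validation for colorectal cancer surgery, with a
population-based cancer registry (which records the single date of the
surgery that removed the primary tumor) treated as truth.

The analysis is a classical diagnostic-accuracy design. For each patient in
the cohort, truth is the binary indicator "registry records a surgery date";
the test is "the administrative source contains a qualifying colorectal
surgery claim in the extraction window". Cross-tabulating gives a 2×2 table
(TP, FP, FN, TN) per source and stratum, from which the package computes

    sensitivity = TP/(TP+FN)        specificity = TN/(TN+FP)
    PPV         = TP/(TP+FP)        NPV         = TN/(TN+FN)
    agreement   = (TP+TN)/N

Observed agreement is used instead of Cohen's κ: κ collapses under extreme
trait prevalence, and surgery prevalence exceeds 98% in the stage I–III
strata of this problem. Two identities tie the measures together and are
enforced as invariants (to 1e-12): with prevalence π = (TP+FN)/N,

    PPV = sens·π / (sens·π + (1−spec)(1−π))
    agreement = sens·π + spec·(1−π)

### Cohort rules

Qualifying diagnoses are ICD-O topography c18.0, c18.2–c18.9 (colon) and
c19.9, c20.9 (rectum); note c18.1 (appendix) is deliberately absent. Records
are excluded if the linkage identifier (ULI) is missing, the histology is
flagged unstageable, or the disease is stage 0; patients whose stage is
missing for any other reason stay in the cohort and form their own stratum.
The exclusion priority order (missing ULI → unstageable → stage 0) is a
package convention so that overlapping conditions are counted once,
deterministically; non-colorectal site codes are tallied in a separate
out-of-scope bucket.

### Linkage rules

Per patient and source, the surgery event is the earliest claim whose
procedure code is on the configured code list and whose service date lies in
the closed window [diagnosis − 7 days, diagnosis + 548 days]. The lower
bound absorbs small date inaccuracies in billing; the upper bound is the
maximum plausible diagnosis-to-surgery delay (1.5 years). Same-date ties
break by procedure code lexicographically — the date is all that matters
downstream; the tie-break only guarantees permutation invariance. The
combined administrative dataset is the union of the two sources, keeping the
earlier date when both have one. Registry truth is *not* windowed: the
registry date is the gold standard wherever it falls.

Procedure-code vocabularies are configuration (a CSV of
`coding_system, code`), because real code lists are jurisdiction-specific:
billing uses CCP; hospital data use ICD-9-CM before April 2002 and CCI
after. The synthetic vocabulary is a single code `SURG01` present in all
three systems, plus a non-qualifying `OTHER99` used for noise claims.

### Confidence intervals and instability

The 95% CIs are Wilson score intervals (statsmodels), chosen because several
strata sit at or near 0%/100% where Wald intervals degenerate; Wald is
available behind `ci_method="wald"` for comparison. An estimate is flagged
unstable when its CI is wider than 15 percentage points (strict) or its
width is ≥ 40% of the estimate (inclusive). Zero-denominator measures are
reported as *undefined*, never as 0 or 100. Empirical coverage of the Wilson
interval is property-tested (93–97% at p = 0.8, n = 100 over 1,500
replicates).

### Rounding

Published tables print whole percents, so matching them requires an explicit
convention. The package default is round-half-up, implemented in exact
rational arithmetic (`fractions.Fraction`) so ties are decided by
convention, never by binary float representation; round-half-even is
available to probe sensitivity of feasibility findings to the convention.

## Reconstruction of published tables

Published rows give the marginals (N, truth-positives, test-positives) and
rounded measures but not the cells. Since the table has one degree of
freedom given its marginals, `reconstruct_from_seed` inverts a single
printed measure into a count (e.g. specificity seed → TN =
round(seed/100 × (N − truth_pos))) and derives the rest by subtraction; an
agreement seed fixes TP+TN and splits it using TP − TN = test_pos −
(N − truth_pos), flooring TP's half when the split is odd. A seed implying a
negative cell is reported as infeasible, not crashed on.

`feasible_tp_set` is the audit companion: exhaustive enumeration of every TP
whose implied table reproduces *all* printed measures after exact rounding.
On the overall billing row it returns a contiguous non-empty range
(tp ∈ [6822, 6831]), confirming the printed row is self-consistent; on the
overall hospital row it returns the empty set under half-up rounding — every
reconstruction yields NPV 71% against the printed 72%, so the printed NPV is
inconsistent with the other four cells at those marginals. The package
reports this finding; whether it reflects a different rounding convention, a
slightly different denominator, or a typographical slip in the source cannot
be decided from the printed numbers.

## Synthetic cohort generator

Real registry/claims linkages are confidential, so the pipeline is exercised
on synthetic cohorts with the same statistical structure. The observation
model, per patient: stage and site from categorical distributions; a latent
registry-surgery indicator per stage (≈0.99/0.98/0.99 for I–III, 0.60 for
IV, 0.56 for missing — prevalences mirroring a provincial cohort); surgery
date = diagnosis + a discretised gamma(2, 15) delay clipped to [0, 548]
(median ≈ 25 days; only the 548-day maximum is externally given, the shape
is a package choice). Three mechanisms decouple administrative capture from
registry truth:

- **registry-only events** (per-stage probability, default 0.07 for stage I,
  0.05 for missing): the polypectomy mechanism — an excision the registry
  counts as surgery that generates no inpatient/billing surgery code;
  suppresses the administrative counterpart in *both* sources;
- **per-source capture** (0.97 billing, 0.945 hospital): a non-suppressed
  registry surgery yields a claim in each source independently;
- **false positives** (per source per stage; largest for stage IV, e.g. 0.31
  billing / 0.21 hospital): the palliative de-bulking/stoma mechanism — the
  underlying event is shared between sources (correlation parameter, default
  1 = comonotone coupling) while capture follows each source's probability.

Captured dates are jittered with probability 0.05 by a nonzero offset in
±3 days, clamped inside the extraction window (window-boundary behaviour is
tested by explicit fixtures instead). Exclusion seeding (missing ULI,
unstageable, stage 0) happens at rates 2/8533, 140/8533 and 83/8533 before
linkage, so cohort construction has real work to do;
`registry_with_exact_exclusions` fixes those counts exactly for
deterministic arithmetic checks. Noise claims with a non-qualifying code
(probability 0.10 per source) exercise the code filter.

The generator consumes a fixed block of RNG draws per patient regardless of
which branches fire. Outputs are therefore bit-for-bit reproducible per
seed, and changing one probability parameter perturbs only the outcomes that
parameter governs (common random numbers), which makes mechanism-isolation
tests sharp.

**What the generator does not emulate:** code-list errors (miscoded or
ambiguous procedure codes), readmissions and multiple surgeries per patient,
inter-annual drift, dependence of capture on stage or site, registry
under-registration of diagnoses, and any privacy/linkage failure other than
a missing ULI. Passing tests therefore demonstrate that the *pipeline*
computes the intended quantities and recovers known generating parameters —
not that any real administrative database has these properties.

## Problem sizes and numerical choices

Parameter-recovery tests run at 20,000 patients, where a 3-binomial-SE band
around a capture probability of 0.97 is about ±0.4 percentage points — wide
enough to be stable across seeds, tight enough to catch systematic errors.
Pipeline-behaviour tests use 200–5,000 patients. Wilson coverage uses 1,500
replicates at n = 100. The whole suite runs in well under a minute; the
feasibility enumerations over ~7,000 TP values are exact and take
milliseconds.

Degenerate inputs are handled by contract: empty cohorts produce empty
reports; n = 0 contingency tables raise; undefined measures propagate as
absent values in the tidy report (`defined = False`); claims of patients
outside the cohort are logged and dropped.

## Known limitations

- The reconstruction oracle assumes the published marginals are exact counts
  and only the measures were rounded; if a published row used a slightly
  different denominator the feasibility verdict refers to the stated
  marginals.
- Stage-specific validation values from the confidential source data cannot
  be reproduced, only structurally emulated; the acceptance surface is
  restricted to arithmetic the publication itself pins down.
- The generator's stage-IV false-positive probabilities are calibrated to
  overall published specificities at default prevalences; they are not
  estimates of any real-world coding process.
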