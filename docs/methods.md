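# Methods

## The phenotyping problem and the gold standard

Administrative claims identify lung cancer through ICD-10-CM C34 diagnosis
codes, which do not distinguish small cell (SCLC) from non-small cell
(NSCLC) disease. Where claims are linked to a tumor registry, the registry's
ICD-O-3 histology provides a gold standard: codes 8002 and 8041–8045 define
SCLC, every other lung-cancer histology is NSCLC. A computable phenotype is
a deterministic boolean rule over coded claims events, evaluated in a time
window anchored at the diagnosis date, whose prediction (SCLC if the rule
fires) is scored against that gold standard with sensitivity, specificity,
PPV and NPV. The package deliberately produces binary, deterministic
predictions — no probabilistic scores — so that downstream users can audit
exactly which patients a rule selects.

## Cohort model

* **Index date.** Registries report only the month and year of diagnosis, so
  the index date is the first day of the diagnosis month. When a patient has
  more than one registry lung-tumor record, the record whose month is
  closest to the month of the earliest claims lung-cancer diagnosis is used;
  ties go to the earlier month, then the smaller histology code. The
  "earliest qualifying claim" operationalization of the claims diagnosis
  month is this package's choice; the convention only matters for the rare
  duplicate-record patients.
* **Inclusion.** A claims lung-cancer diagnosis in the study years (default
  2016–2017), completed age within bounds at index (default ≥ 66, so a full
  year of fee-for-service history exists), and Parts A, B and D with no HMO
  coverage in each of the 12 calendar months strictly before the index
  month. Enrollment is month-granular, as in Medicare enrollment files.
* **Observation and censoring.** Observation runs to the earliest of
  index + 180 days, the start of the first non-enrolled month at or after
  the index month, or death (tie priority: death, then disenrollment).
  Exposure *capture*, however, is defined purely by the window — flags are
  computed over [index, index+180) regardless of the censoring date, since a
  claim cannot postdate death and truncation by disenrollment is a property
  of the data source, not of the code search.
* **Windows.** All windows are half-open on the right: `post180` is
  [index, index+180) and the pre-diagnosis sensitivity window
  `pre30_post180` is [index−30, index+180). Whether day 180 itself counts is
  undocumented in the published protocol; the half-open convention is pinned
  by unit tests.
* **Treated subset.** A patient is "treated" with at least one
  outpatient-setting claim matching any individual systemic-therapy code set
  within [index, index+180). Fosaprepitant (an antiemetic) and EGFR testing
  are deliberately not systemic therapy. Systemic-therapy exposure
  predicates search outpatient, Part D and DME settings; the EGFR-testing
  predicate searches every setting (the published protocol does not restrict
  it; this is configurable).
* **Split.** The exploration/validation split is an exact-size partition:
  round(0.25·N) exploration members drawn by seeded permutation, e.g.
  7,978 / 23,934 for N = 31,912.

## Code sets

Code sets are single-system named sets with exact matching, except the
ICD-10 lung-cancer family which prefix-matches "C34" dot-insensitively. NDC
codes are normalized by hyphen removal and leading-zero stripping only. The
exact HCPCS/NDC contents of the drug definitions used in practice are
site-specific; the built-ins carry one representative HCPCS J-code per agent
and are meant to be overridden from a CSV file for real data. The union sets
`platinum` (carboplatin ∪ cisplatin ∪ oxaliplatin) and `gcsf`
(filgrastim ∪ pegfilgrastim) are recomputed whenever their components are
overridden. Oxaliplatin is included in the platinum union for completeness
("all platinum agents") even though it is rare in lung cancer.

## Synthetic-data generator

The generator emulates the joint structure a linked registry-claims study
observes; it is first-class, tested code, not a fixture. Per patient it
draws:

| quantity | default | basis |
|---|---|---|
| SCLC prevalence | 0.094 | observed share among diagnosed lung cancer |
| treated \| SCLC | 1,762/3,000 ≈ 0.587 | treated-subset label counts |
| treated \| NSCLC | 8,244/28,912 ≈ 0.285 | treated-subset label counts |
| diagnosis month | uniform over 2016-01…2017-12 | study window |
| age bands 66–69…85+ | 18.9/26.9/23.9/16.0/14.3% | population table |
| agent exposure \| (label, treated) | per-agent table below | exploration treated-subset confusion matrices |

Treated-conditional exposure probabilities (SCLC, NSCLC): carboplatin
368/447, 1410/2121; cisplatin 92/447, 228/2121; etoposide 431/447,
116/2121; pegfilgrastim 297/447, 471/2121; filgrastim 22/150, 141/1650
(derived from the G-CSF union row under independence,
p_f = (p_g − p_p)/(1 − p_p)); nivolumab 17/447, 157/2121; ipilimumab 5/447,
2/2121, irinotecan 7/447, 2/2121 and topotecan 11/447, 2/2121 (sub-threshold
stand-ins reconstructed from published PPVs of privacy-masked rows — their
counts are synthetic by necessity); oxaliplatin 0.005/0.01 (nominal).
Diagnosed-level exposures, independent of treatment: fosaprepitant
0.29/0.077; EGFR testing 0.005/0.104. The EGFR NSCLC rate is set a fraction
of a point above the 10% false-positive-reducer threshold because the
discovery procedure demonstrably retained it — its observed rate was
strictly above 10% — while 10.4% still displays as the reported (rounded)
10%.

Untreated patients have no systemic-therapy claims by construction. A
patient drawn "treated" has their exposure vector rejection-sampled until at
least one systemic agent is positive, making the generated treatment status
exactly consistent with the claims-derived treated flag; the conditioning
inflates each conditional rate by 1/(1−P₀), where P₀ is the all-negative
probability, and `analytic_expectations()` returns the exact model-implied
marginals, treated-subset sensitivity and full-cohort specificity that the
stochastic tests compare against. The implied diagnosed-level etoposide
marginal in SCLC is ≈ 56.6%, consistent with the reported ~58% given the
internal inconsistencies of a few percent among the published marginal
tables.

What the generator does **not** model, hence what passing tests cannot
show: agents are conditionally independent given (label, treated) — no
regimen structure (an optional flag forces etoposide users onto a platinum
agent), no line-of-therapy sequencing, no dose or duration, no correlation
between EGFR testing and treatment choice, no stage- or age-dependence of
treatment, no realistic attrition (death, enrollment dropout and duplicate
tumor records default to 0, 0 and 0.002 and exist to exercise censoring and
tie-breaking logic), uniform diagnosis months, and single-code drug claims.
Accuracy estimates on synthetic data validate the *pipeline*, not the
clinical performance of any rule on real claims.

## Screening

Per-code utilization profiles count each patient once per distinct
(code, system) pair, with label totals as denominators; patients with no
in-window claims stay in denominators. The candidate filter is non-strict
(difference ≥ 20 percentage points, read as an absolute difference in
proportions) while both reducer filters are strict (< 5% / > 10% and
> 20% / < 5%), matching the published wording; boundary behaviour is pinned
by tests. By default only HCPCS/CPT codes are screened (the published
procedure screened HCPCS/CPT); other systems are configurable. Evaluating
whole therapies rather than individual codes is done by running the
evaluation module on the built-in rule battery over the exploration split —
no separate screening operation is needed.

## Evaluation and disclosure masking

Metrics are exact integer ratios; undefined (0/0) metrics are carried as
`None` and rendered as empty cells, never 0. Display rounding is half-up at
3 decimals, computed with `decimal` on the integer counts — float-first
rounding fails on exact-half ratios such as 92/320 = 0.2875. Whole-percent
summaries round half-up. The case-mix ratio TP/FP is displayed at 1 decimal
as computed.

Small-cell suppression replaces any cell below the threshold (default 11)
with "NR". Complementary suppression is margin-aware: when a gold-label
margin is public (the default assumption, since population tables publish
label counts), the complement cell within that margin is suppressed too,
otherwise a reader could recover the masked cell by subtraction. With the
margin-aware default, a brute-force inversion test confirms that every
suppressed cell admits at least two values consistent with all displayed
integers and public margins. Two interpretive choices are documented rather
than derived from a published rule: (1) when TP is masked, sensitivity
displays as "< threshold/(TP+FN)" rounded up to 2 decimals, and when FP is
masked, specificity displays as "> 1 − threshold/(FP+TN)" rounded down —
formulae that reproduce the published bound patterns for fully masked rows;
(2) PPV and NPV are displayed as computed even for masked rows, as published
tables do, although exact-ratio inversion of a displayed PPV can in
principle narrow a masked TP — the safety guarantee is stated for displayed
integers and margins, not for displayed rounded ratios.

## Numerical and testing choices

Everything random flows from one `numpy.random.Generator`; a fixed config
reproduces byte-identical tables, and the split is deterministic in its own
seed. Stochastic calibration tests run at the full study scale (n = 31,912)
against `analytic_expectations()` with standard-error-scaled bounds. The
screening-discovery test is replicate-based: the EGFR retention event sits
by design a fraction of a percentage point above a strict threshold, so it
is asserted as a majority across five replicate populations of n = 20,000
rather than on one binomial draw, while far-from-boundary discoveries
(etoposide rank 1, pegfilgrastim candidacy) must hold in every replicate.
Expression-tree evaluation is checked against a brute-force truth-table
oracle, confusion matrices against both a per-patient loop and
scikit-learn's `confusion_matrix`, and cohort inclusion against a slow
per-patient re-evaluation of every predicate on a deliberately messy
population (dropout, deaths, duplicate tumors, under-age patients).

## Known limitations

Inpatient drug administrations are not identifiable in the modelled data,
so "treated" means outpatient-treated; rules cannot find SCLC patients who
receive no (outpatient) systemic therapy, and the full-cohort sensitivity
of any treatment-based rule is bounded by the treated fraction. Stage- and
subgroup-specific performance is out of scope. The placeholder drug code
lists are not the study lists; on real data users must supply their own
code-set file. The masking module protects single tables — cross-table
consistency (the same cell visible in one table and masked in another) is
the caller's responsibility.
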