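# Methods

## The estimand and the data model

The package estimates *period prevalence of cardiovascular disease (CVD)
among prevalent type 2 diabetes (T2D) patients* in claims data shaped like
a German statutory-health-insurance (SHI) research extract: person-level
enrollment spans with death dates, quarter-stamped ambulatory diagnoses
carrying certainty qualifiers (G/V/A/Z), hospital main/secondary discharge
diagnoses, ATC-coded pharmacy dispensations with a prescriber identifier,
OPS-coded hospital procedures, and EBM-coded lab billings with a physician
identifier. Claims are evidence of *documentation*, not of disease: every
rule in the pipeline is explicitly a rule about codes, and the simulator
models the gap between latent disease and coded disease.

Diagnoses count as evidential when they are confirmed ambulatory
(qualifier G) or hospital main/secondary; suspected (V), excluded (A) and
status-post (Z) ambulatory codes never count. Ambulatory events are
anchored by service date, hospital events by admission date — claims
extracts date discharge diagnoses either way, and admission places an event
in the window in which care began.

## Case identification

Eligibility: age ≥ 18 at 1 January of the index year (computed from birth
year, the only resolution claims extracts carry) and continuous enrollment
from the start of the look-back (1 Jan 2010) through the index year.
Death during the index year does not break continuity — excluding decedents
would bias a prevalence estimate of a disease that kills — but the evidence
window truncates at death.

The four T2D criteria (README) are evaluated independently and all recorded,
so the output distinguishes *why* someone is a case. Deliberate choices:

- **Distinct-quarter counting** for the two-quarter drug criterion and the
  three-of-four-quarters diagnosis criterion: the criteria are about
  persistence across quarters, not prescription volume.
- **Criterion 2 accepts any A10 agent** (insulins included); criteria 1
  and 3 require non-insulin agents (A10B), since insulin alone cannot
  separate type 1 from type 2 diabetes.
- **The E14 exclusion applies only to drug-only cases** (criteria 1/3):
  anyone qualifying via criteria 2/4 necessarily has an E11 code, so
  "unspecific diabetes only" can occur only in the drug-based path.
- **Drug-only cases with no diabetes code at all are retained** and flagged
  (`drug_only_no_diabetes_dx`): the rule as written admits them, and the
  flag lets an analyst drop them in sensitivity analyses.

Diabetes duration is bucketed from the earliest look-back year with any E11
diagnosis or A10 dispensation: no earlier evidence → incident; evidence in
the first look-back year → "5plus" (left-censored — true onset may be far
earlier, which is why the bucket is open-ended).

## CVD definitions and matching

Code sets are prefix-inclusion/exclusion rules over dot-free codes;
exclusion overrides inclusion regardless of prefix length, which is how
printed lists of the form "I25 excluding I25.3/.4/.10/.19" behave. The
"x" suffix convention in printed lists ("8-84x", "I70.2x") is read as
prefix coverage of all children. The wide definition deliberately drops
the narrow set's ischemic-heart-disease exclusions: it is defined as *all*
of I20–I25.

Two structural properties are enforced by construction and asserted in
tests over a bundled synthetic code universe (a plausible slice of the
ICD-10-GM circulatory/metabolic chapters plus the relevant OPS families):

- *definition monotonicity*: narrow ⊂ narrow+CHF ⊂ wide as coverage sets,
  hence classification implies classification under any broader definition;
- *window monotonicity*: a hit in a window is a hit in any containing
  window, hence the prevalence grid is non-decreasing in window length.

Both monotonicities therefore hold on **any** dataset; only the *size* of
the gradient is an empirical result.

Therapy classes partition the cohort by the set of distinct non-insulin
ATC subclasses dispensed in the index year plus insulin presence. The
subclass map (metformin A10BA, sulfonylureas A10BB, DPP-4 A10BH, GLP-1
A10BJ, SGLT-2 A10BK, glinides A10BX02/03, α-glucosidase inhibitors A10BF)
and the expansion of A10BD fixed combinations into components are plain
module-level tables meant to be overridden as the ATC index evolves; an
unmapped A10B code becomes an "other" subclass rather than being dropped,
preserving the partition property.

## Statistics

- Point estimates: percent = 100·n/N computed on exact rationals and
  rounded half-up to two decimals (one decimal for running text). Half-up
  is the convention of the published tables this mirrors; Python's default
  banker's rounding would differ on exact halves.
- Intervals: Wald on the unrounded proportion, z = 1.96, bounds rounded
  then clamped to [0, 100] and to bracket the point estimate (relevant only
  at degenerate p). Wald is the default because it is what descriptive
  claims studies print; Wilson and Clopper–Pearson are available via
  `method=` and delegate to statsmodels. Wald coverage at the cohort sizes
  involved (N ≈ thousands, p far from the boundary) is within half a point
  of nominal — checked by simulation in the test suite.
- Extrapolation multiplies count × reference/N as an exact `Fraction` and
  rounds half-up, so no floating-point intermediate can move the integer
  result.

## The synthetic population

The generator emulates the *structure* that the pipeline consumes, with
latent truth emitted separately and never read by the analysis. Defaults
(all configurable in `SimulationConfig`):

| parameter | default | what it encodes |
|---|---|---|
| age band weights | 16/26/29/22/7 % (under-18/18–39/40–59/60–79/80+) | roughly German age structure |
| T2D prevalence by band | 0/1/7/20/24 % | ~10% of adults overall |
| CVD given T2D / not | 50% / 8% | six-year CVD burden of a diabetic cohort |
| `doc_prob` | 0.5 | per-year coding probability of a prevalent chronic condition |
| churn | 2% | join/leave strictly inside the study period |
| death rate by band | 0.05–25% over six years | enrollment truncation, decedent handling |
| therapy mix | ~70% treated; metformin-mono the largest class | a realistic regimen distribution |
| onset-year mix | 72% before the look-back | left-censored duration structure |
| E14 miscoding | 2.5% of treated | the unspecific-diabetes exclusion path |
| lab pathway | 50% of treated | prescriber-linked HbA1c billing (criterion 3) |

Documentation is independent Bernoulli(`doc_prob`) per condition-year; a
documented diabetes year produces codes in 1–4 quarters (quarterly-contact
model), so untreated diabetics can satisfy the three-quarter criterion.
CVD component codes are drawn across all three definition tiers, which is
what makes the definition gradient strictly positive; about 12% of
documented CVD years are procedure-only admissions, giving the OPS toggle
observable effect. Noise diagnoses and suspected-only (qualifier V) E11
rows exercise the negative paths.

What the generator does **not** model — and hence what passing tests do not
establish about real data: care-seeking correlation across years (documentation
is memoryless), coding intensity differences across regions and physician
specialties, incident CVD during the study period (CVD state is fixed;
the study measures history, not incidence), multi-span enrollment (churn is
a single early-leave/late-join, since a person record holds one span),
seasonality within quarters, and any cost or provider-network structure.
Recovered quantities (e.g. case-algorithm sensitivity ≈ 0.75 at the default
mix, driven by untreated diabetics without persistent coding) describe the
simulation, not German practice.

## Problem sizes and numerical choices

The shipped study runs 20,000 persons (seed 1), yielding ≈ 1,100 identified
cases and ≈ 550 true-CVD cases — enough that the mechanism check
(`1 − 0.5^y`, six windows) resolves within 3 Monte-Carlo standard errors
while the whole pipeline runs in seconds. The coverage simulation uses
2,000 binomial replicates at p = 0.45, N = 5,000. Determinism: a single
seeded `random.Random` drives generation in fixed person order; identical
configs produce byte-identical claims files, and the run manifest records a
cohort hash.

Degenerate inputs are defined rather than accidental: an empty cohort
raises with context (a denominator of zero is an analysis error, not a
zero); prevalence at p ∈ {0, 1} yields clamped zero-width intervals;
an empty person table reads as an empty bundle with a warning.

## Known limitations

- The case algorithm's operating characteristics on real SHI data are
  unknowable from simulation; the sensitivity/specificity report is a
  consistency check, not a validation study.
- The one-year "database prevalence" table reflects `doc_prob`-thinned
  visibility, so its values sit below the latent prevalences by design.
- ICD-10-GM and OPS evolve across years; the shipped code sets are frozen
  snapshots and the code-universe fixture is synthetic.
- Hospital diagnoses accept main or secondary position for CVD; if a
  stricter main-only reading is wanted it is a one-line code-set change,
  but it is not exposed as a config switch.
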