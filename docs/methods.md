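# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the package. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Synthetic record universe

Real HIV laboratory and cancer-registry extracts are restricted, so the
package is developed and validated against a generator
(`hivcanlink.synthgen`) with full ground truth.

**Population.** `n_entities` persons with: sex (female fraction 0.709,
matching the female share of the HIV–cancer comorbid population the
fixtures describe); population group sampled proportionally to the fixture
demographics (Black 0.881, Coloured 0.049, White 0.047, Asian 0.006);
home province sampled from approximate provincial population shares; names
drawn from a packaged bank of 567 given names and 553 surnames spanning
South Africa's naming traditions, with harmonic rank weights
w_k ∝ 1/(k+21) so the most common surname covers ≈1.4% of the population —
realistic name-collision rates are essential, because name collisions are
exactly what stresses a linkage classifier.

**Ages.** Age is log-normal, exp N(log 40, 0.28²), clipped to [15, 90].
The median 40 and σ = 0.28 (fitted to an interquartile range of 33–48 via
σ ≈ (log 48 − log 33)/(2 × 0.6745)) describe age *at cancer diagnosis*.
Dates of birth are therefore anchored at the expected diagnosis date of an
eligible case under the default date model (≈ 8 years into the 2004–2014
window; derivation in the source): the first of ~2.5 uniform test dates
falls ≈ 3.5 y in, diagnoses are uniform after the first positive test, and
the eligibility filters keep only diagnoses at or after it.

**Records.** Each person receives 1 + Poisson(1.5) HIV records (mean 2.5,
emulating prevalent re-testing) at uniform dates in 2004–2014; 10%
(`hiv_away_province_rate`) are issued outside the home province so that
modal-province inference is genuinely exercised. A fraction
`cancer_fraction` (default 0.3) receives one pathology record whose
diagnosis province is drawn from the mobility row of the home province;
the default mobility matrix is the column-normalised packaged OD table,
i.e. the generator reproduces, in expectation, the flow structure the
analysis is meant to estimate. 90% of diagnoses postdate the person's
first HIV test; the remainder exercise the temporal filter. HIV result
labels are positive/negative/unknown at 0.7/0.2/0.1.

**Identifier noise** (`CorruptionModel`, per-field): one single-character
edit (substitution 0.4 / transposition 0.3 / deletion 0.15 / insertion
0.15) with probability 0.05; truncation-style nickname substitution 0.02;
day/month perturbation or swap of the date of birth 0.03; episode number,
folder number and date of birth each independently missing with
probability 0.15 (a record losing its date of birth carries a floored age
instead). No published noise characterisation of the real identifiers
exists; these rates are asserted defaults, chosen once as plausible for
administrative data, not estimated.

**Stable identifiers.** Episode numbers are generated person-stable and
folder numbers person-stable within the person's primary facility. Episode
numbers in a raw laboratory feed would be visit-scoped; they are modelled
as person-scoped here because the linkage design treats them as strong
person keys, which is only coherent for a stable identifier.

**Determinism.** All randomness flows from one `numpy` generator seeded by
the config; identical (config, seed) gives byte-identical CSV outputs.

**What the generator does not emulate.** Test-volume seasonality, facility
catchment geography, HIV incidence dynamics, within-person mobility over
time, multiple primaries, and any correlation between cancer type and
demographics (types are drawn independently). Passing tests therefore
demonstrate correctness of the pipeline's machinery and its behaviour
under controlled noise — not linkage accuracy on real registry data.

## 2. Standardisation and blocking

Names are upper-cased, diacritics folded to ASCII, punctuation and digits
deleted, whitespace collapsed; the result is idempotent, and an empty
result is a missing value. Birth year comes from the date of birth when
present, else from (record year − age); an age-derived year is ambiguous
by one because ages are floored, so such records emit blocking keys for
both candidate years.

Blocking keys per record: `Soundex(surname)+birth year`,
`first two letters(first name)+birth year`, and the episode number when
present. A pair is compared iff key sets intersect (union-of-keys: one
corrupted field cannot sever a true pair; recall dominates at this stage,
precision is the classifier's job). Measured on the default configuration
the blocking stage retains ≥ 99% of true pairs while discarding ≈ 99.9% of
the quadratic comparison space (asserted in the test suite).

## 3. Pair classification and clustering

Features are the six-vector described in the README, all in [0, 1], with
missing comparisons at 0.5: absence of an episode number is not evidence
against a match, whereas two *different* episode numbers are (encoded 0).

**Classifier.** A linear SVM (`LinearSVC`, primal liblinear, C = 1,
tol = 1e-6), deterministic for fixed input; the model is serialised as
JSON (weights, bias, threshold, feature order). The decision threshold is
the margin zero-point; it can be overridden to trade precision against
recall. Linear kernel only: six bounded features, interpretable weights,
deterministic training.

**Training set.** Labels come from the generator truth table (on real data
they would come from clerical review). Sampling is stratified: one half
true matches, one quarter random non-matches, one quarter *ambiguous*
non-matches (pairs agreeing on canonical surname and first-name prefix).
Ambiguous non-matches — different people sharing a name and birth year —
are on the order of 10⁻³ of blocked pairs, so a uniform sample never
represents the region where the decision boundary lives.

**Asymmetric loss.** The hinge penalty for misclassifying a non-match is
weighted 10:1. Persons are formed by transitive closure, so one false
match fuses two entire persons (and chains: with ~10⁵ persons, a boundary
that accepts "identical name + year, everything else silent" produces
components of hundreds of records), while a false non-match usually costs
a single pair because the remaining pairs still connect the cluster. The
10:1 weight encodes that cost asymmetry; it is a design constant of the
package, not a per-dataset tuning knob.

**Clustering.** Matches feed a union–find (path-halving, union by size);
clusters are connected components — standard deduplication practice,
documented because closure inflates clusters under high noise. The cluster
id is the lexicographically smallest member record id, making ids stable
and tie-breaks well defined. Equivalence with a brute-force graph
traversal is asserted on random instances.

**Linking.** Cancer records are blocked against HIV records with the same
keys; each cancer record links to the cluster of its highest-scoring
matching pair (ties to the smaller cluster id), or stays unlinked if no
pair clears the threshold.

## 4. Cohort construction

Candidate persons are clusters with a linked cancer record. In order:

1. drop clusters with no laboratory record documented HIV-positive;
2. keep the *incident* cancer: earliest diagnosis date, ties to the
   smallest record id;
3. drop cases whose cancer diagnosis predates the first positive HIV
   record — strictly predates: same-day diagnoses are retained, reading
   "prior to" as strict and resolving the ambiguity between the stricter
   and looser phrasings of the eligibility rule in favour of retention;
4. drop cases with a missing province of diagnosis.

An attrition log records the count removed at each step and must sum to
input minus output (asserted). Home province is the modal province over
the person's positive HIV records; ties break to the province of the
earliest record, then alphabetically. Age at diagnosis is floor(years
between date of birth and diagnosis date) — registry convention — using
the modal date of birth over positive records, falling back to the
recorded age at the HIV test nearest the diagnosis. Sex and population
group come from the incident cancer record, falling back to the modal HIV
values.

## 5. Analytical outputs and numerical conventions

**OD matrix.** Rows = province of cancer diagnosis, columns = province of
HIV care, matching the printed layout of the fixture table. Column
percentages always use the column's *cell sum*, never an externally
printed total — the fixture's printed TOTAL row is internally inconsistent
for two columns (its NW and NC entries are swapped relative to the cell
sums), while every checkable printed cell percentage is consistent with
cell sums. Percentages are re-derived from counts on demand, never stored,
and rounded half away from zero to one decimal — the convention that
reproduces every checkable printed percentage.

**Known fixture inconsistencies** (reported, not "corrected"): the EC row
cells sum to 4,604 against a printed row total of 4,606, so the cell total
is 65,143 rather than the printed 65,284; the share of travellers
diagnosed in Gauteng is 61.5% from the cells ((27,660 − 17,682)/16,225)
against a narrative figure of 60.7%; and one printed female percentage
(26.2%) disagrees with its own counts (12,110/46,313 = 26.1%). The
package always reports cell-derived values.

**χ² test.** Pearson statistic without continuity correction,
df = (r−1)(c−1), upper-tail p; a zero expected count is an error. The
implementation delegates to `scipy.stats.chi2_contingency`; tests assert
equality with an independently coded Σ(O−E)²/E to 1e-9.

**Logistic regression.** Outcome 1 = diagnosed outside the home province.
Age enters continuously per year; sex as male vs female (reference
female); population group as Black vs non-Black (reference non-Black);
cancer type dummy-coded against the most frequent type (recorded in the
result's metadata, overridable). Maximum likelihood via `statsmodels`
Logit; Wald 95% CIs as exp of the coefficient interval; non-convergence
and separation raise with a diagnostic. The one-covariate fit equals the
2×2 cross-product ratio ad/bc to 1e-6 (asserted). In the orchestrated
pipeline a cancer-type stratum too thin to fit triggers a recorded
fallback to the demographic covariates alone.

**Quartiles.** Median/IQR use linear interpolation (the inclusive
convention, `numpy.percentile(method="linear")`).

**Flows.** Off-diagonal OD cells export as GeoJSON LineStrings between
approximate provincial centroids (synthetic rounded coordinates packaged
with the code, not an official boundary product), with origin, destination
and count properties. Map rendering is out of scope.

## 6. Validation design and problem sizes

The acceptance checks run at the sizes the validation design calls for:
linkage quality on 50,000 entities (≈ 125,000 HIV records) at default
corruption, with pairwise precision and recall ≥ 0.95 and exact recovery
(1.0/1.0) at zero corruption; mobility recovery on 30,000 entities with
`cancer_fraction` 1.0, yielding > 20,000 cases, where the estimated
out-of-province proportion must fall within 3 binomial standard errors of
the generating 0.25. The mobility run keeps HIV records in the home
province (`hiv_away_province_rate = 0`) so the check isolates the mobility
signal from residence-proxy noise, which is a separate, documented error
source. Confidence-interval coverage of a known odds ratio 2.0 uses 100
replicates of n = 20,000 simulated directly from the logistic model — the
property under test is the regression machinery, not the linkage.
Smaller configurations (700–10,000 entities) back the unit and property
tests; monotonicity of linkage quality in the typo rate is averaged over
five replicate seeds.

## 7. Known limitations

* The home province is a residence *proxy*; with 10% away-from-home HIV
  records and a modal rule over few records, some persons are
  misassigned, which inflates the apparent out-of-province rate in
  synthetic defaults. On real data the same caveat applies and cannot be
  checked against truth.
* Transitive closure can chain distinct persons through borderline pairs;
  the asymmetric loss suppresses but cannot eliminate this, and true pairs
  with no positive identifier evidence are deliberately sacrificed.
* The probabilistic Fellegi–Sunter framework, active-learning labelling
  and privacy-preserving (hashed) linkage are out of scope.
* The regression on synthetic defaults estimates near-null effects
  (covariates are generated independently of mobility); it validates
  machinery, not epidemiology.
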