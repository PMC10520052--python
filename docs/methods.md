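# Methods

## Scope and model

`ecigrisk` implements a screening-level, steady-state human health risk
assessment for eleven chemicals measured in e-cigarette aerosols
(µg/puff) and e-liquids (mg/ml).  Risks are modelled per chemical, per
route (inhalation / oral / dermal) and per endpoint (chronic non-cancer,
cancer, acute), then summed within routes with no chemical-interaction
terms: the model deliberately assumes independent, additive risks, so
route totals are upper-bound screening numbers, not predictions of joint
toxicity.  Absorption of inhaled or ingested material is assumed complete
(100 %), and chromium is treated as hexavalent throughout because the
source measurements do not speciate it — both conservative choices.

## Exposure equations and parameters

Chronic daily doses (mg/kg·day):

| route | equation |
|---|---|
| inhalation | `DD = P_mg × T × EF × ED / (BW × AT)` |
| oral | `DD = P × CI × CF × EF × ED / (BW × AT)` |
| dermal | `DD = P × CI × CF × SA × AF × ABS × EF × ED / (BW × AT)` |

Acute single-event intake (mg/kg): `I = P × AI / BW`.

Default scenario (`scenarios/paper_default.yaml`): BW = 70 kg,
T = 163 puffs/day, breathing volume 20 m³/day, CI = 0.05 ml/day (chronic
leakage contact, both oral and dermal), AI = 10 ml (one accidental
ingestion), EF = 365 day/yr, ED = 70 yr, AT = 25550 day, SA = 5700 cm²,
AF = 0.2 mg/(cm²·day), CF = 1.  With these values EF·ED/AT = 1 exactly;
ED is kept in years with AT in days precisely so that this lifetime
cancellation holds, which is the reading consistent with every published
chronic dose.

Two deliberate modelling notes:

* **Dermal dimensional convention.**  The dermal product CI·SA·AF·ABS
  mixes units (ml × cm² × mg/(cm²·day)); treated literally as a single
  multiplier with CF = 1 it reproduces every published dermal dose, so the
  package adopts that literal reading and documents it rather than
  inventing a unit repair that would change the numbers.
* **Dermal absorption modes.**  Back-solving the published dermal doses
  shows they all used ABS = 0.03, although the stated parameterization is
  0.03 for As and 0.001 for the rest.  `paper_replication` (default)
  applies 0.03 to every chemical; `as_stated` applies the per-chemical
  map.  The two differ by the constant factor 0.001/0.03 for non-As
  chemicals.
* **No acute inhalation.**  A vaper cannot plausibly inhale a bolus of
  aerosol comparable to swallowing 10 ml of liquid, so the acute endpoint
  exists only for the oral and dermal routes.

## Reference values

Route-specific toxicity constants live in three packaged CSV tables
(inhalation: REL, RfC, CPV; dermal: RfD, SF, LD50; oral: RfD, CPV, LD50).
Missing cells are explicit nulls and propagate as "not assessed" — never
as zero risk — so e.g. acetone contributes nothing to the inhalation
hazard index rather than a spurious 0.

For non-cancer inhalation risk, each available air-concentration
threshold c (µg/m³) is converted to a dose via
`c × breathing_volume / BW / 1000` and the **minimum** across REL and RfC
is used (the conservative choice when agencies disagree).  Oral and
dermal HQs use the route's RfD directly, with no additional
absorption adjustment of the reference dose.

Several source-table entries required resolution because the published
digits are concatenated ambiguously; the resolutions were fixed by
back-solving against the downstream dose/risk tables and are recorded in
`tables/inhalation_print_resolution.csv` (e.g. Cr = REL 0.2 / CPV 510 /
RfC 0.0083; acetaldehyde CPV = 0.01, the OEHHA value, the only potency
consistent with the published acetaldehyde cancer risk).

Two published inconsistencies are documented but *not* reproduced: the
published Pb inhalation HQ implies a reference near 0.465 µg/m³ rather
than the tabulated REL 0.5 (the package keeps REL 0.5), and the published
acute-risk cells for acetone and acrolein each reproduce only with the
*other* chemical's LD50 (the package evaluates `AR = I / LD50`
faithfully).  Similarly, the published aerosol summary rows for acetone
and acrolein are transposed relative to every downstream table; the
packaged summaries adopt the downstream-consistent values
(acrolein 0.373 µg/puff, acetone 0.242 µg/puff) and keep the as-printed
rows loadable behind a warning.

## Data harmonization

Literature reports are normalized into per-sample records: individual
results count one sample each, a reported mean counts as one sample, a
reported range contributes its minimum and maximum as two samples, and
per-power-setting replicates contribute their arithmetic mean.  Units
convert to µg/puff (aerosol) and mg/ml (liquid; mg/g assumes density
1 g/ml).  Non-detects are encoded as 0 with no LOD/2 substitution — the
downstream model assumes complete absorption of what is present and no
censoring model is attempted.  Summaries use the sample (n−1) standard
deviation, defined as 0 for a single sample so summaries are total; the
packaged summary tables carry the published SDs verbatim, whose
sample-vs-population convention is unknown.

Sample-level source data are not part of the package (only the summary
tables are published); the probabilistic layer therefore fits either
user-supplied sample files, synthetic data (below), or a surrogate sample
set reconstructed from (mean, sd, min, max) — a moment-matched lognormal
with a zero mass when the reported minimum is 0, clipped to the reported
range.  The surrogate construction is a device of this package and is
labelled as such.

## Distribution fitting

Candidate families: normal, lognormal, gamma, Weibull, uniform,
triangular — the common set of spreadsheet risk tools — with an empirical
(resampling) fallback for samples with fewer than 8 observations and a
point mass for degenerate samples.  Positive-support families are fitted
by maximum likelihood to the positive part with location pinned at 0 and
a zero point-mass weight equal to the observed zero fraction; the
remaining families fit the full sample (uniform by its min/range MLE,
triangular by MLE from a moment-based starting point).  Selection is by
minimum Anderson–Darling statistic computed against each fitted
(mixture) CDF with CDF values clipped to [10⁻¹², 1−10⁻¹²]; a chi-square
statistic on near-equiprobable empirical-quantile bins is recorded as a
secondary diagnostic but never drives selection, since no principled
combination rule exists.  Values are sorted before fitting, making the
result independent of input order.

## Monte Carlo propagation

Only concentrations are stochastic by default — consistent with the
sensitivity results, which attribute essentially all output variance to
concentrations — while scenario parameters stay fixed; callers can pass
distributions for any variable.  One seeded `numpy` generator drives the
run; variables are drawn in sorted name order, so a fixed seed fixes
every reported number bit for bit.  Negative draws (possible under the
normal family) truncate at 0.  Each of the n = 10,000 iterations
evaluates the full vectorized exposure→risk pipeline; per-target outputs
are summarized by the mean, percentiles {1, 5, 25, 50, 75, 95, 99}, and
the exceedance probability (fraction of draws strictly above the
endpoint's acceptability threshold; "certainty" is its complement).
Below 1,000 iterations the package warns that tail estimates are
unstable.

Sensitivity contributions are normalized squared Spearman rank
correlations: `contribution_i = r_i² / Σ_j r_j² × 100` — the standard
"contribution to variance" of spreadsheet Monte Carlo tools, which is how
the source description ("contribution calculated by the square of the
variance") is interpreted here.  Constant inputs contribute 0 %; a
constant output yields all-zero contributions with a warning.

Because the underlying sample-level concentration data are unpublished,
exact published exceedance percentages are not reproducible; the test
suite instead checks structural properties (point-mass degeneracy
collapses Monte Carlo to the deterministic result; lognormal exceedance
matches its closed normal-CDF form; fit→sample→fit recovers parameters)
and qualitative concordance of the exceedance ordering on synthetic data.

## Synthetic data generator

The generator emulates the *shape* of the literature: per-study records
drawn from a configurable ground-truth family (default lognormal —
concentrations are non-negative and right-skewed, with reported SDs
exceeding means for most chemicals), zero-inflated at a configurable
non-detect fraction, and packaged into report kinds with fixed
conventions (mean-only = mean of 3 draws; range-only = min/max of a
5-draw batch; power series = 3 replicates) in a default mix of
50 % individual / 20 % mean / 20 % range / 10 % power-series.
`generate_paper_like_study` moment-matches the lognormal truth to each
packaged summary mean (rescaling the positive part when a 10 % zero mass
is added for chemicals whose reported minimum is 0) and uses the
published per-chemical study counts.

What the generator does **not** emulate: device physics (power and
coil effects on carbonyl yield), between-study heterogeneity in
measurement protocols, correlations between chemicals, and reporting
biases.  Passing tests on synthetic data therefore demonstrate that the
pipeline machinery is correct under known ground truth, not that the
fitted families describe real e-cigarette measurements.

## Numerical and testing choices

Deterministic benchmark checks compare recomputed values against the
published ones at 1 % relative tolerance, absorbing the publication's own
rounding of intermediate values (all recomputed values agree within
0.4 %).  Stochastic tests run at 10,000 iterations with fixed seeds and
3-standard-error bands; the whole suite runs in a few seconds on one CPU.
Report CSVs print 3 significant digits; JSON keeps full precision.

## Known limitations

* Screening model only: single 70-kg adult, no age stratification, no
  pharmacokinetics, no particle-size or deposition modelling.
* Additivity: no synergistic or antagonistic interactions.
* Worst-case totals combine every chemical's maximum simultaneously — a
  physically improbable co-occurrence, reported as such.
* The zero-inflated mixture and the summary-statistics surrogate are
  modelling devices of this package, not published procedures.
* No correlated sampling across chemicals and no Latin hypercube /
  Bayesian uncertainty over the fitted parameters.
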