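# Methods

## The assay and its unit of replication

The sediment bioassay places 10 synchronized, freshly hatched larvae in
each well of a 12-well plate containing 1 mL of test sediment (or spiked
water) and killed-bacteria food. After one life cycle (96 h for
*C. elegans*, 120 h for *P. pacificus*) wells are harvested and live
adults, dead larvae, and F1 progeny are counted. Six replicate wells per
trial and at least two trials per treatment give n = 12 wells, i.e. a
minimum of 120 animals per treatment. All statistics in this package treat
the **well** as the experimental unit: per-well counts, per-well fecundity
indices, means over wells. Doubling every count in every well changes no
fraction or index (a tested invariant).

Corpse recovery from sediment is incomplete, so dead counts are stored but
never used as a survival denominator; all analyses work from live
recoveries against animals added.

## Endpoints

- **P0 recovery**: live adults recovered per well (0–10), also expressed
  as a fraction of animals added.
- **F1 progeny**: larvae recovered per well.
- **Fecundity index**: progeny per recovered live adult, per well. A well
  with no surviving adults and no progeny scores 0 (configurable to
  exclusion); a well with progeny but no surviving adults has no
  denominator — the index is undefined and the well is excluded listwise
  from group tests (treating it as infinite would let a single corpse-loss
  artifact dominate an ANOVA). The conservation identity
  Σ(index × adults) + Σ(progeny of undefined wells) = total progeny
  is enforced by a property test.

## Concentration-response models and the LC50

Live recovery y (animals/well) is modelled against total-recoverable
sediment nickel x (µg/g dry weight), using **per-well points** rather than
treatment means — the scatter of individual wells is the replication
structure, and means-based fitting is available only as a sensitivity
mode. Controls enter at their measured background nickel (59.7 µg/g for
WB, 8.9 for SR), never at x = 0; this is what keeps ln x defined and
reflects that "un-spiked" sediment is not nickel-free.

Four families are fitted, matching spreadsheet-trendline conventions:

1. quadratic and cubic polynomials by OLS on the Vandermonde design
   ("binomial"/"trinomial" in trendline parlance — degree, not the
   binomial distribution; the aliases are accepted);
2. logarithmic, OLS of y on (ln x, 1);
3. shifted exponential: OLS of ln(y + 1) on (x, 1), back-transformed to
   A·e^(kx). The +1 shift keeps the logarithm defined at y = 0 wells and
   gives a decay that never crosses zero. R² is reported on the fitting
   scale, i.e. ln(y + 1) for this family (the trendline convention); the
   raw-scale R² is computed alongside for comparison.

The **LC50** is defined by intersection, not by a parametric quantile: the
smallest x > 0 where the fitted curve equals the target y*, with
y* = 0.5 × mean control recovery. In replication mode the target is
rounded half-away-from-zero to a whole animal (5 for *C. elegans* and 4
for *P. pacificus* in the WB series, 3 for *P. pacificus* in SR),
reproducing the integer target lines used when the published curves were
read. For the shifted-exponential family the intersection is taken on the
y + 1 scale against y* + 1.

Quadratic, logarithmic, and exponential intersections use closed forms;
cubics use a sign-change scan (20 001 grid points) plus Brent's method to
an absolute tolerance of 1e-6 µg/g. The search range is (0, 1.5 × the
highest fitted concentration]; crossings beyond it report "not attained".
The smallest positive root is always taken — polynomial fits are
non-monotone and can re-cross the target line at high doses where the
model is extrapolating anyway. Reported toxicity **ranges** use the
polynomial families only, which consistently carry the highest R² on this
design; log/exponential LC50s are reported individually but excluded from
the range.

A +1 shift of all responses together with a +1 shift of the target leaves
polynomial LC50s unchanged (the intercept absorbs the shift) — a tested
invariant that justifies comparing shifted-exponential LC50s with the
unshifted polynomial ones.

## Survivorship and the LT50

Longevity assays sacrifice one whole well per treatment per day over a
22-day window (~55–75 animals per well, tracked per well, never as a
global constant), so each day's fraction alive is an independent binomial
cohort. Kaplan–Meier or Cox machinery is deliberately not used: there is
no censoring structure to exploit, and the published survivorship curves
are trendline cubics. The package fits an OLS cubic of fraction alive vs
day and takes the **LT50** as the first crossing of 0.5 within the
observation window (tolerance 1e-4 day). A fitted cubic that only reaches
0.5 beyond the window reports "beyond window"; the extrapolated crossing
is logged (searched out to 3× the window) but never returned as a result.
Fitted values outside [−0.1, 1.1] at observed days trigger a diagnostic
warning, not an error — a trendline cubic is a summary, not a probability
model.

## Group comparison

One-way fixed-effects ANOVA (all wells, outliers included) with Tukey HSD
pairwise comparisons at α = 0.05; unbalanced groups use the Tukey–Kramer
harmonic-mean adjustment (scipy's studentized-range implementation; the
test suite cross-checks it against the q = t√2 identity for two groups and
a longhand sums-of-squares F oracle). Homogeneity of variance is an
assumption of the design, so Levene's test is logged as a diagnostic and
never gates. Letters come from the insert-and-absorb algorithm: start with
one column holding all groups; for each significant pair, split every
column containing both and absorb subset columns; assign letters by
descending group mean. The resulting display satisfies, exactly: two
groups share a letter **iff** their adjusted p exceeds α — including
non-transitive patterns (A≈B, B≈C, A≠C → a, ab, b), which are
representable, never an error. The invariant is property-tested on 1000
random significance patterns.

## Covariate screen

Mean recovery per un-spiked sediment is regressed on every subset of at
most three of {TOC, AVS, CEC, pH, ORP, clay, silt, sand}; each subset's R²
is reported, sorted descending. With only eight sediments this is a screen
for obvious structure, not model selection — no p-values or information
criteria are attached. Collinear subsets are flagged and skipped.

## Synthetic data generator

The generator emulates the assay's stochastic skeleton, with defaults set
to the study design: the measured WB dose grid (59.7, 156, 369, 1040,
2680, 7660 µg/g), 12 wells/dose (6 wells × 2 trials), 10 animals/well.

- **Survival**: live adults ~ Binomial(n_added, p(dose)). Two truth
  families: logistic p(d) = p0/(1 + (d/LC50)^s), whose half-of-control
  dose is the LC50 parameter itself by construction; or an explicit
  polynomial on the animals scale, whose true LC50 is delegated to the
  same root-finder the analysis uses. Survival probabilities are clamped
  to [0, 1]; a configuration whose unclamped values leave [−0.25, 1.25]
  at any dose is rejected as not credibly a survival curve.
- **Progeny**: per-well mean = live adults × λ(dose); counts are drawn
  from a gamma–Poisson mixture with variance = 2 × mean by default.
  λ defaults to 3 progeny per adult — sediment assays yield few larvae in
  one life cycle because growth is slower in sediment than in water. No
  distributional data on brood counts exist for this design, so both λ
  and the dispersion are exposed in the config.
- **Longevity**: constant daily hazard h per treatment,
  n_live ~ Binomial(n_initial, e^(−h·day)) independently per day,
  mimicking destructive sampling. True LT50 = ln 2 / h.
- **Determinism**: every well and every daily harvest draws from its own
  `default_rng((seed, index))` substream, so outputs are byte-identical
  for a given seed and independent of generation order.

### What passing recovery tests do and do not show

The parameter-recovery tests generate from a **quadratic truth whose
survival stays strictly inside (0, 1) on the dose grid** and whose
half-of-control crossing is exactly 1200 µg/g, then require the fitted
pipeline to recover it within 5% at 200 wells/dose (and LT50 within 10%
at 500 animals/day). This demonstrates estimator consistency when the
fitted family contains the truth. It deliberately does not claim
robustness to model misspecification: fitting polynomials to data
generated from a logistic curve leaves a bias of order 10% that no amount
of replication removes, because the polynomial's intersection with the
target line is then a different estimand. Real assays are in the
misspecified regime, which is exactly why the analysis reports a range
across families rather than a single curve's LC50. Synthetic data also
omit between-trial variance and dose-dependent corpse-recovery artifacts;
group-test behaviour on real sediments may be noisier than these tests
suggest.

## Reference replication

The packaged reference tables carry the published best-fit coefficients,
targets, and reported LC50/LT50 values for the WB and SR spiked series.
`replicate_reference()` re-derives all 16 values through the package's
intersection code; every value reproduces within 0.5% (most within
0.005%, i.e. to the precision the values were printed at). The raw
well-level data behind the published coefficients were never deposited, so
the coefficients themselves and their R² values are inputs here, not
outputs — what is independently recomputable is every intersection-derived
quantity, and that is what the acceptance script reports.

## Numerical choices, in one place

- Root-finding: Brent bracketing after a 20 001-point sign scan; 1e-6 µg/g
  (LC50) and 1e-4 day (LT50) absolute tolerances; smallest positive root.
- OLS via `numpy.linalg.lstsq`; R² = 1 − SS_res/SS_tot on the fitting
  scale; zero-variance responses give R² = 1 when residuals vanish and are
  rejected otherwise.
- Target rounding: half away from zero (3.95 → 4).
- LC50 search cap: 1.5 × the highest tested concentration — beyond that a
  fitted trendline is extrapolation, not an estimate.
- Tie-breaks in the letter display: columns lettered by the position of
  their first member in the mean-descending group order, so output is
  reproducible across runs.
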