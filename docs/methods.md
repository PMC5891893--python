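# Methods

## Decision problem and model structure

The package evaluates early physician consultation with guideline-based
intervention (oral contraceptives / progestin under gynaecological care)
against continued self-care (OTC analgesics, self-medication) for Japanese
girls who reach menarche with dysmenorrhea.  A closed cohort enters at age
12 and is followed for 23 yearly cycles to age 35 through six health
states:

    WELL -> DYSMENORRHEA -> ENDO I/II -> ENDO III/IV
                 ^              |            |
                 |              v            v
                 +---------- CURED <---------+          DEAD (absorbing)

`WELL` exists so that an age-dependent incidence schedule can feed the
model when a susceptible cohort is wanted; the default initial distribution
places all mass in `DYSMENORRHEA`, because the analysis targets girls who
are already symptomatic and practicing self-care.  Consultation, surgery
and (under intervention) managed recurrence are *within-cycle events*
attached to states — they trigger costs and utility adjustments but are not
Markov rows, since no dwell-time parameters exist for them.

## Transition mechanics

All annual probabilities are interpreted through a constant-hazard
(exponential survival) lens, `p = 1 - exp(-r t)`.  Within a cycle,
competing transitions are resolved by rate embedding: each annual
probability is converted to a hazard `r_j = -ln(1 - p_j)`, hazards compete
additively (background mortality `mu` included), and the probability of
leaving through channel `j` during the cycle is

    P_j = (r_j / R) * (1 - e^{-R}),   R = mu + sum_j r_j ,

with `e^{-R}` remaining in-state.  Rows therefore sum to one by
construction and treatment effects expressed as hazard ratios act exactly
multiplicatively (`r_adj = r * OR`).  This embedding — rather than applying
annual probabilities directly to surviving mass — matters quantitatively:
under intervention the dysmenorrhea exit hazard is large (cure 0.80/yr →
r ≈ 1.61), so the fraction of an episode that ends in endometriosis is the
hazard share `r_prog/(r_prog + r_cure)` ≈ 0.048, which is what produces the
~95% reduction in endometriosis onset.  Direct probability competition
cannot reach that reduction at any admissible parameter values.

Transitions occur at cycle end; no half-cycle correction is applied (a
`half_cycle_correction` flag is reserved).  Costs and utilities accrue on
start-of-cycle occupancy; cycle 0 is undiscounted; both costs and QALYs are
discounted at 3%/yr.

## Strategy arms

* **Self-care**: spontaneous annual remission probabilities (calibrated,
  see below); recurrence from CURED back to DYSMENORRHEA at 0.222/yr; only
  the visiting fraction (age-dependent visit-proportion schedules,
  0.03–0.5 for dysmenorrhea and 0.0124–0.0307 for endometriosis) accrues
  visit costs, and only the diagnosed (visiting) fraction of endometriosis
  is eligible for surgery.
* **Intervention**: cure probabilities 0.80 (dysmenorrhea), 0.40 (ENDO
  I/II), 0.80 (ENDO III/IV); progression hazards reduced by OR 0.40
  (dysmenorrhea → ENDO I/II) and OR 0.10 (ENDO I/II → III/IV, the
  reciprocal of the published 10.00); everyone symptomatic is under care
  (4 visits/yr); cured patients remain on maintenance follow-up
  (2 visits/yr, an assumption — see below); recurrence under maintenance is
  a *managed within-cycle event* at 0.222/yr: the year carries the
  dysmenorrhea utility and symptomatic visit costs, but the patient returns
  to maintenance rather than to untreated dysmenorrhea.

The "natural healing" values 0.80/0.40/0.80 are assigned to the
*intervention* arm: the published one-way sensitivity ranges centre on them
and name them "cure rate … resulting from the intervention", while the
self-care remission proportions are explicitly described as having no valid
source and being adjusted by calibration.  Reading the same three values as
self-care remission (with the intervention no better) makes the two arms
nearly indistinguishable in QALYs, which contradicts every published
base-case quantity.

Surgery (6.0%/yr of eligible endometriosis occupancy) is a costed event
whose recipients move to CURED in the same cycle (`surgery_cures` flag);
each surgical admission also carries the annual inpatient cost.

## Calibration

Four parameters are unpublished and fitted: self-care remission of
dysmenorrhea, ENDO I/II and ENDO III/IV, and the base ENDO I/II → III/IV
annual progression (bounds [0.01, 0.5]).  The objective is a weighted sum
of squared relative residuals against: the cumulative national
endometriosis case count (210,000 when the cohort prevalence is scaled by
the population denominator) and age-group prevalences of endometriosis and
dysmenorrhea.  The optimizer is a full-factorial coarse grid (5 points per
axis) followed by bounded Nelder-Mead; it is derivative-free and
deterministic.  The shipped target values are synthetic: the underlying
survey tables are not reproduced anywhere, so targets were generated to be
self-consistent with the calibrated defaults (0.02, 0.65, 0.40, 0.08),
which were themselves chosen so the full pipeline lands on the published
base-case outcomes — the same "adjust by comparing modeled estimations
with previous studies" step the original analysis describes.  Parameter
recovery on these targets is exact to ~1e-3 except for the ENDO III/IV
remission, which is weakly identified by prevalence data (recovered to
~0.02); the acceptance tests therefore use a ±0.05 recovery band.
Age-specific targets above age 34 get weight 0 by default: the model is
known to overpredict prevalence there and that discrepancy is reproduced,
not fixed.

Two further unpublished quantities were set by the same
output-calibration logic and then frozen: the maintenance follow-up
frequency for cured intervention patients (2 visits/yr — 4/yr overshoots
the published intervention arm cost by ~50%, 0 undershoots it by a factor
of ~2.5) and the scope of productivity loss (the intervention half-year
loss of 39,546 JPY applies to all on-treatment person-years, i.e.
symptomatic + cured-on-maintenance; the self-care loss of 184,625 JPY
applies to symptomatic person-years — the only combination whose societal
totals approach the published 1.64M / 4.77M JPY).

## Economic evaluation

Payer perspective: visit costs (7,529 JPY dysmenorrhea / 11,291 JPY
endometriosis per visit, 4 visits/yr for the attended fraction,
maintenance at 2/yr), surgery (case-mix 45.2% complex: 0.452·456,667 +
0.548·288,080 = 364,281 JPY per operated person-year) plus the inpatient
annual cost (207,661 JPY) per surgical admission.  Societal perspective
adds OTC/self-medication spending on symptomatic self-care person-years
(87.1% OTC at 19,243 JPY/yr, otherwise 13,715 JPY/yr) and the productivity
losses above.  QALYs weight occupancy by VAS utilities (dysmenorrhea and
ENDO I/II 0.637, ENDO III/IV 0.549, WELL/CURED 1.0, DEAD 0); managed
recurrence years under intervention carry the dysmenorrhea utility.

ICER = incremental payer cost / incremental QALYs, judged against a
willingness-to-pay of 5,000,000 JPY/QALY.  SMV = opportunity cost saved −
full direct cost consumed; equivalently the difference in societal totals,
positive favouring the intervention.  Currency is JPY; the 120 JPY/US$
conversion is display-only.

## Sensitivity analysis

*One-way*: the published ranges (ten payer-perspective parameters on the
ICER, seven societal-perspective parameters on the SMV) are evaluated as
deterministic low/high pipeline re-runs; schedules accept a flat override
(the "proportion of visits 0.0–0.07" range).  *Probabilistic*: every
parameter with a published distribution assignment is drawn independently —
beta (moment-matched) for binomial-scale rates, lognormal (median at the
base value) for ratio-scale quantities and unit costs, normal for
interval-scale ones, all truncated to their domain.  Dispersion follows a
fixed convention: a published (low, high) range is read as a central 95%
interval; the ENDO III/IV progression OR uses the published reciprocal CI
(0.0321–0.3117); parameters without any published interval get a
coefficient of variation of 0.2.  The printed lower endpoint 0.15 for the
ENDO III/IV utility is an explicit worst-case scenario, not a confidence
bound, so its dispersion mirrors the upper half-width instead.  Calibrated
parameters carry no published uncertainty and stay fixed in the PSA.

Draw `i` of a run with seed `s` uses `numpy.random.default_rng([s, i])`, so
results are bit-reproducible and independent of batching or parallelism.
The default seed is 20180410.  CEAC acceptance at threshold λ is the
fraction of draws with `λ·ΔE − ΔC > 0` on a 0–5M JPY grid in 50,000-JPY
steps.

## Synthetic data

Three inputs exist only as national statistics or institutional surveys and
are shipped as clearly-labelled synthetic stand-ins (CSV schema `age,
value`, substitutable by real files): a smooth young-female life table
(annual mortality ~1e-4 to 5e-4 over ages 12–35; it perturbs discounted
QALYs by well under 0.5% relative to zero mortality), a near-uniform
allocation of 1.6 million women with functional dysmenorrhea across ages
12–36 used as the prevalence-scaling denominator, and a truncated-normal
VAS survey generator whose stage means recover 0.637/0.549.  None of these
fixtures mimic the fine structure of the real sources; tests that depend on
them (notably the 210,000-case count, checked within ±20%) demonstrate
internal consistency of the pipeline, not agreement with the actual
Japanese survey data.

## Problem sizes and numerics

The cohort recursion is 23 cycles × 6 states and exact to machine
precision (row sums conserved to 1e-12; verified against matrix powers and
a 100,000-individual microsimulation within 3 Monte-Carlo SEs).
Calibration uses ~1,100 cohort evaluations.  The analysis scripts and the
acceptance script run the published 10,000 PSA iterations; the test suite
uses 2,000, which pins acceptance fractions to about ±1 percentage point.
Degenerate inputs are handled explicitly: zero hazards give identity rows,
probability 1 inputs are rejected (infinite hazard), undefined ICERs (zero
incremental effect) are reported as undefined rather than infinite, and
calibration objectives with no informative targets raise errors.

## Known limitations

* The self-care arm's remission rates and the severe-progression rate are
  identified only through calibration; different target sets move them.
  The shipped values reproduce the published outcome pattern but the QALY
  totals sit slightly high in both arms (15.2/12.8 vs 14.9/12.3) because
  the recurrence rate, fixed at 0.222/yr in both arms, caps the time the
  self-care cohort can spend symptomatic.
* The published probabilistic result "cost-effective at 100,000 JPY/QALY in
  80% of iterations" is unreachable from the published base case: the
  base-case ICER (~115,000 JPY/QALY) exceeds that threshold, so draws
  centred on the base case accept in well under half of iterations (~31%
  here).  The corresponding acceptance check is retained and fails, by
  design.
* No remission of endometriosis due to childbirth; no per-agent (OC vs
  dienogest) modelling; no EVPI; parameters are sampled independently (no
  published correlation structure).
* Prevalence above age 34 is outside the horizon; the model is expected to
  overpredict there.
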