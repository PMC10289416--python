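# Methods

## The model

`flexscreen` implements a discrete-time cohort model for the
cost-effectiveness of extending an established biennial mammography screening
program to new age groups.  Its central idea is that, for a program that has
run for decades, "no screening" is not a usable comparator — there is no
representative modern data on an unscreened population.  Alternative policies
are therefore compared against the *current* policy, and a policy change
enters the model only through two quantities per two-year age group `j`:

* the incidence rate `ι(j, h(j)) = P(X ≠ −1)` — the probability that an
  invitee is diagnosed during the two-year interval, under screening status
  `h(j) ∈ {S, NS}`; and
* the conditional stage distribution `q(j, h(j), k) = P(X = k | X ≠ −1)`
  over stages `k = 0..4` (Unknown, Localized, Regional, Distant/adjacent,
  In situ).

Their product with the complementary no-cancer mass gives the state
distribution `μ_{j,h}(k)`.  Stage- and age-specific survival `λ_{j,k}(t)`
(discrete, whole years `t` after observation), the joint time/cause-of-death
law `π_{j,k}(t, d)` (`d = 1` breast-cancer death, `d = 2` other), and the
treatment costs are policy-invariant: screening "acts" purely by moving
diagnoses earlier in the stage distribution and changing how many are made.

A cohort of `N0 = 100 000` invitees enters at ages 46–47 and is followed to
age 100 (no one survives past the horizon).  Individuals are censored from
later rounds at death or at diagnosis; the population recursion is

```
N_{j+1} = N_j (1 − P(T_j ∈ {0,1}) − P(T_j ≥ 2, X_{j,h} ≠ −1)),
P(T_j = t) = Σ_k λ_{j,k}(t) μ_{j,h}(k).
```

Total expected life-years and costs are closed forms:

```
E T_h = Σ_{j≥2} 2 N_j + Σ_j [ λ_{j,−1}(1) μ_{j,h}(−1) + Σ_{k≥0} μ_{j,h}(k) E T_{j,k} ] N_j
E C_{j,h} = N_j C̃_h(j) + Σ_{k≥0} N_j μ_{j,h}(k) Σ_t Σ_d C̃_{j,k,t,d} π_{j,k}(t,d)
```

with `E T_{j,k} = Σ_t t λ_{j,k}(t)`, `C̃_h(j)` the 30 € unit screening cost
for screened groups, and `E C_h = Σ_j E C_{j,h}`.  Policies are compared by
the ICER `(E C_h − E C_ref) / (E T_h − E T_ref)` (alternative minus
reference; an equivalent sign convention to reference-minus-alternative,
since the two flips cancel in the ratio).

### Year-accounting conventions (deliberate, reproduced exactly)

The life-year formula has asymmetries that we reproduce rather than "fix",
because the micro-simulation oracle validates *this* accounting:

* each survived two-year interval is credited 2 years on arrival at the next
  round;
* a cancer-free woman dying within the interval is credited 1 year if she
  lives exactly one year and 0 years at `t = 0`;
* a diagnosed woman is credited her full expected remaining years
  `E T_{j,k}` at diagnosis and leaves the cohort;
* survivors of the final round are credited nothing beyond their arrival
  credit.  On the default grid this is immaterial (the last group, ages
  98–99, is two years from the hard horizon), but it means total life-years
  is *not* monotone under survival improvements of the final round's
  cancer-free law — an improvement that converts a one-year death into a
  `t ≥ 2` survival at round `J` loses its one credited year.  The monotone
  property tests therefore exclude exactly that cell.

Participation (about 82% in Finland, nearly constant across age) is **not**
a separate parameter: `ι` and `μ` are interpreted at the invitee level, with
participation folded in.

No discounting is applied to costs or life-years, and no discount-rate
option is offered, so outputs remain directly comparable to the undiscounted
convention of the published comparison tables.

## Costs

Treatment costs come in three phase tables over 7 age bands × 5 stages
(first year `C1`; each of years 2–5 `C2`; last year before a breast-cancer
death `C3`), packaged as CSV fixtures.  For a death `n` years after
diagnosis (inclusive count of calendar years entered), other-cause deaths
cost `C1 + (min(n,5) − 1) C2`; breast-cancer deaths cost `(n−1) C1 + C3` for
`n ∈ {1,2}` and `C1 + min(n−2, 4) C2 + C3` beyond.  The `n = 2`
breast-cancer branch (`C1 + C3`, no `C2`) is intentionally not harmonized
with the other-cause branch — the published convention is kept verbatim.
Nothing accrues past year 5 (a conservative choice; treatment often runs
5–10 years).  The survival time `t` (whole years lived) maps to the cost
index as `n = t + 1`, so a death within the first year is `n = 1`; this
makes the `n = 1` branch (`C3` alone) meaningful for deaths soon after
diagnosis.  Costs are indexed by age at diagnosis throughout treatment, not
attained age.

## Scenarios

* **Younger extension (screen 46–69).**  Stage distributions borrowed from
  the closest screened groups under the current policy (46–47 ← 50–51,
  48–49 ← 52–53, 50–51 ← 52–53) and incidence adjusted by +28% (46–47,
  first-screen prevalence effect), +24.7% (48–49) and −11.9% (50–51, which
  loses its first-screen peak).
* **Older extension (screen 50–73).**  70–71 and 72–73 take 68–69's
  screened stage profile; each group above shifts the baseline old-age
  profile down by two groups (74–75 ← baseline 70–71, and so on).  The
  incidence pattern above 69 under extended screening is an external config
  vector; the package ships a clearly-labelled synthetic stand-in
  (`sweden_like_overrides`) with the qualitative shape seen where screening
  runs to 74 — it is not an estimate of any country's curve.
* **Both (46–73).**  Younger then older; the touched age ranges are
  disjoint, so the fixed order does not affect the output (asserted by
  test).  The 50–51 ← 52–53 substitution applies here exactly as in the
  younger-only scenario.

Six one-way sensitivity variants perturb a built scenario: modelled
incidence ±10% (modelled groups only: ages 46–69 for the younger scenario,
above 69 for the older, both for the combined — the reference, which models
nothing, is unchanged), all treatment costs +10% or +50% (every scenario,
including the reference), and ±0.02 of conditional probability moved between
localized and regional stages for the modelled stage groups (46–51 and/or
above 69).  Transforms touch only the screening-status column the scenario's
policy actually selects.

## Micro-simulation oracle

`simulate_cohort` walks individual women through the identical stochastic
process, crediting *drawn* survival times and accumulated costs rather than
expectations — that independence is what makes it an oracle.  A single RNG
stream with a fixed draw order (per round: state draws, then time/cause
draws stage by stage, then the cancer-free draw) makes runs reproducible
from the seed.  The repository's central test checks that analytic `E T`,
`E C` and expected breast-cancer deaths lie within 3 Monte-Carlo standard
errors of 200 000-individual simulations on five seeded synthetic parameter
sets (6 age groups each — small enough to keep the default test run fast,
large enough to exercise censoring, staging, cause-split and terminal
handling); with point-mass laws the two paths agree exactly.

## Synthetic data

The registry estimates behind the published Finnish analysis are not public,
so `generate_inputs` produces structurally faithful stand-ins:

* unscreened incidence `0.005 · (1 + 1.6 (1 − e^{−j/8}))` per two years
  (≈0.5% in the late 40s saturating near 1.3%, the magnitude of Nordic
  rates), a +12% screened detection boost, a +28% first-screen bump at the
  program's first screened group, and a −15% post-program deficit for the
  two groups above the stop age;
* conditional stage distributions around (0.10, 0.42, 0.33, 0.04, 0.11)
  with a mild age trend toward advanced stage, and 0.12 of conditional mass
  moved from regional/distant to localized/in-situ under screening;
* Gompertz background mortality (`3.3e−4 · e^{0.095 (age−46)}` per year,
  certain death by 100) plus stage-specific excess hazards
  (0.05, 0.015, 0.07, 0.30, 0.004) decaying linearly to zero 18 years after
  diagnosis, past which patients die as the general female population;
* a stage-graded probability that a death is coded to breast cancer
  (0.35, 0.15, 0.45, 0.85, 0.03), damped by the same 18-year decay;
* seeded lognormal jitter (σ ≈ 0.08) so different seeds give genuinely
  different, always-valid parameter sets.

These choices were made once, for structural realism.  What passing tests
show is that the closed forms, the scenario machinery and the simulator are
mutually consistent and behave correctly on data *shaped* like the Finnish
inputs; they do not certify any Finnish point estimate, and the headline
euro figures this package prints on synthetic data are not the published
Finnish ones (which depend on unpublished registry survival curves and
incidence figures available only as a plot).  On the default synthetic
baseline the older extension in fact *loses* expected life-years — the
screened detection boost among the elderly outweighs the stage-shift benefit
— which is an honest property of the synthetic conditions, and mirrors the
published sensitivity finding that higher-than-expected incidence makes
extensions harmful.

## Numerical choices

* Probability rows must sum to 1 within `1e−9`; violating inputs are
  rejected with a report naming every offending row — never silently
  renormalized (generation-time construction may normalize, validation never
  repairs).
* Stage codes are the integers −1..4 exactly; no re-mapping to TNM (the
  source registry does not record TNM).
* `N_j` stays real-valued (expected counts); rounding would break the exact
  linearity of costs in the treatment cells that the cost sensitivities rely
  on.
* The population recursion uses the mixture `P(T_j = t)` over *all* states,
  diagnosed included, exactly as written above; the alternative reading
  (early deaths among the cancer-free only) would change `N_j` slightly and
  is not used.
* Survival laws must place zero mass beyond each group's `t_max = 100 −
  lower_age`; this is checked, not truncated — parameter files must respect
  the horizon themselves.
* ICERs are reported as undefined (empty cell) only when the life-year
  difference is exactly zero; tiny nonzero differences produce honest,
  possibly extreme ratios.
* Monetary values are rounded to 2 decimals at CSV-writing time only, with
  '.' as the decimal separator regardless of locale; floats round-trip
  losslessly through parameter files (`%.17g` out, round-trip parsing in).

## Limitations

* No continuous age, no interval-cancer vs screen-detected distinction
  (states are observed at rounds only), no screening-interval changes, no
  risk stratification, no radiation-burden or overdiagnosis morbidity, no
  primary-care/travel/productivity costs, no confidence intervals on the
  expectations (point values only).
* The older-extension incidence pattern is irreducibly external; results for
  that scenario are only as good as the override vector supplied.
* The generator emulates structure, not magnitudes: it is unsuitable for
  drawing real policy conclusions about Finland or anywhere else.
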