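# Methods

`mnhsim` is a stochastic individual-based model of maternal and perinatal
health and maternity-service delivery for a Malawi-like population.  This
note records the model, its parameters, the synthetic-data choices and the
numerical conventions, in enough detail to reproduce or modify any of them.

## Population and clock

A closed population of persons (sex, date of birth, urban/rural residence,
wealth quintile 1–5, education level, parity, HIV/malaria/depression risk
flags) advances on a **monthly master clock**.  Each month: background
age-specific mortality, then conception among alive, non-pregnant,
non-postnatal women aged 15–49 with an age-band constant monthly probability
(the stand-in for a mechanistic contraception/fecundity model; the bands are
calibrated to a crude birth rate of roughly 33–35 per 1,000).  Intrapartum
events and the 6-week postnatal / 28-day neonatal window run as a nested
weekly loop executed within the month of delivery; this compresses the
calendar spread of postnatal events into the delivery month, which matters
only for sub-annual reporting (all outputs are annual).

The model-to-real population ratio is carried with every run and rescales
counts at the reporting layer only; rates are scale-invariant.  Desk-scale
defaults are 7,000 agents at a 1:2,000 ratio over 2021–2028.

## Natural history

Each condition has a per-timestep baseline onset risk in one or more phases
(antenatal-monthly with a gestational-month window, intrapartum, weekly
postnatal, weekly neonatal; window (0,0) means "at birth only").  Modifiers
are (predicate, relative-risk) pairs composed **multiplicatively on the
probability scale and clipped at 1**; predicates reference co-occurring
conditions (e.g. untreated obstructed labour → uterine rupture ×4, caesarean
section → postnatal sepsis ×2.2), risk flags (malaria → preterm labour
×1.9), delivered preventative interventions (iron/folic acid → anaemia
×0.45), or timing (week 0, preterm, post-term).  Severity ladders (mild →
severe gestational hypertension; mild → severe pre-eclampsia → eclampsia)
progress with per-month probabilities, one step per cycle, reduced by
delivered treatments; severity never decreases without treatment.

Gestation is tracked in days with 30-day gestational months.  Labour occurs
at 270 days (term), earlier if monthly preterm-labour risk fires in
gestational months 8–9, or at 300 days after a post-term draw (default
probability 0.06).  Cut-points: preterm < 37 completed weeks, post-term
≥ 42 (standard obstetric definitions).  Pregnancy can also end by ectopic
pregnancy, abortion complications or antenatal stillbirth.

## Health system

Care is delivered in discrete **health system interaction (HSI) events**
(ANC contacts 1–8, inpatient antenatal care, post-abortion/ectopic care,
BEmONC/CEmONC facility delivery, maternal/neonatal PNC, postnatal CEmONC),
each defined by facility level, base worker minutes by cadre (ANC 12 min,
PNC 15 min of nursing/midwifery time, deliveries 60+ min) and the
interventions it can house.  Routine care-seeking (ANC initiation, facility
delivery, early PNC) is logistic in wealth, education, age < 20, parity ≥ 4
and urban residence; intercepts are solved at parameter-generation time so
population coverage matches 51% ANC4+, 91% facility delivery, 42% maternal
and 60% newborn PNC.  ANC visits follow a chain: first-visit month drawn
from a configured distribution, each subsequent monthly contact attended
with a per-transition probability (default 0.82), at most 8 contacts,
truncated by delivery.  Emergency care-seeking after a symptomatic
complication is a single fixed probability (default 0.7).

**Quality of care**: an indicated intervention is delivered iff every
required consumable's availability draw succeeds, the clinician-competence
draw succeeds, and — for EmONC-classified interventions — the trained-staffing
draw succeeds; draws are independent per item per event.  Screening
interventions set detection flags which gate curative care during routine
ANC (conditions are taken as clinically evident in labour, emergencies and
the postnatal ward).

**Squeeze and the three delays**: each HSI requests worker minutes from a
per-day, per-facility-level, per-cadre budget that depletes in queue order;
squeeze = required/remaining − 1.  Delays one and two are fixed-probability
Bernoulli draws (defaults 0.35/0.30, calibration knobs) applied to
emergencies and facility delivery; delay three occurs iff squeeze strictly
exceeds the threshold (default 3; boundary equality does not trigger).
Budgets are expressed per 1,000 population and were set so that the median
squeeze across executed events is near the threshold, i.e. roughly half of
care episodes experience delay three — the regime the threshold convention
presumes.  Delays have no explicit time-to-care clock; each delay
experienced shrinks every treatment effect toward null by a factor
(1 − attenuation), attenuation 0.25 by default, so the effective relative
risk is 1 − (1−rr)·(1−a)^d.  Referral between facilities, transport and
private care are not modelled: a complication needing CEmONC at a health
centre goes untreated.

**Mortality**: after care is resolved, each new potentially-fatal condition
episode gets one Bernoulli death draw at CFR × Π(effective treatment RRs).
Maternal deaths are those in pregnancy or ≤ 42 days postpartum (direct and
indirect categories); neonatal deaths at < 28 days; antenatal and
intrapartum stillbirths are fetal events (operative delivery reduces
intrapartum stillbirth risk).

**DALYs**: disability weights of concurrent conditions combine additively,
capped at 1.0; YLD accrues monthly (weekly inside the postnatal window) as
weight × step length in years; YLL at death from a packaged synthetic
reference life table approximating GBD standard expectancies (88.9 years at
birth).  No age-weighting or discounting.  Stillbirths accrue no DALYs; the
ledger carries maternal and neonatal categories only.

## Scenarios

Seventeen named configurations (the SQ comparator plus sixteen
counterfactuals spanning antenatal, intrapartum, postnatal and combined
services at coverage / coverage-and-quality / maximum / none levels) switch
on on 2023-01-01.  Coverage targets are met by **re-solving care-seeking
intercepts against the current covariate distribution** (so socioeconomic
gradients persist), once at switch-on; for the ANC4+ target the
per-transition probability is first raised to 0.99 because the visit chain
caps ANC4+ below the initiation probability.  "Max." scenarios pin
probabilities outright.  Quality overrides either pin every factor of a
service to 1 or replace the whole delivery product with a fixed probability
(e.g. BEmONC interventions in labour at 90%); delay three can be disabled
per service.  "Min." scenarios disable routine services and pin the
relevant emergency care-seeking to zero; intrapartum "min." zeroes delivery
probabilities while facility attendance is unchanged.  Post-abortion and
ectopic care is never modified by any scenario.

## Runs, statistics, economics

Each scenario runs multiple times with seeds base + run-index; scenarios
share the seed list, and every stochastic decision draws from a
counter-based uniform stream keyed by (seed, purpose, person, month)
(splitmix64), so paired runs share **common random numbers** and paired
differencing isolates the scenario effect — without this, rare-outcome
comparisons at desk scale are dominated by between-run noise.

Reporting follows the study design: per run, the mean annual outcome over
the intervention years; across runs, the mean and 95% CI (Student's t on
n−1 df by default; a normal-approximation mode exists).  Differences versus
SQ are computed per paired run first.  The percentage difference is
withheld whenever the difference CI contains zero.  MMR is per 100,000 live
births, NMR per 1,000 live births, SBR per 1,000 total births (a live-birth
denominator is available as an option).

Routine-contact time: hours = contacts × minutes/60 (12 ANC, 15 PNC), also
reported per intervention year.  Maximum ability to pay = Σ (significant
DALYs averted) × CET, with a $62.3/DALY threshold; total health spending
projections grow per-capita spending from a 2015 base at 0.9%/year.

## Calibration

The synthetic parameter set ships with defaults chosen from
order-of-magnitude clinical plausibility (complication incidences,
untreated CFRs, GBD-range disability weights) and then calibrated with the
package's own machinery so that: care-seeking coverage matches the four
coverage targets; SQ-period MMR sits in the several-hundred per 100k range,
NMR in the high teens and SBR in the high teens per 1,000 at desk scale;
and the all-services-minimum / maximum scenarios bracket the SQ in the
direction and rough proportion the service model implies.  The defaults are
a synthetic stand-in, not estimates from any single empirical source.
`tune_parameters` automates further calibration: bounded
multiplicative coordinate descent (factors within [0.1, 10], step-doubling
line search, then √-step refinement; intercept knobs scale the odds) over a
declared knob set against a weighted relative-squared loss, with a full
audit trail and monotone accepted-step loss.

## What the synthetic data does and does not emulate

The generator reproduces: DHS-like coverage levels with socioeconomic
gradients, plausible complication incidence and case fatality, a young age
pyramid, quality gaps in consumables/competence/staffing, and an
over-subscribed workforce.  It does not reproduce: the real calibrated
parameter values or their data sources, secular trends 2010–2022 (runs
start near steady state after a burn-in of one to two years), district
heterogeneity, referral networks, bed capacity (bed-days are not
constrained), or mechanistic HIV/TB/malaria/depression disease dynamics
(risk flags with configurable prevalence feed relative risks instead).
Passing tests therefore demonstrate the *mechanics* — quality model, delays,
DALY accounting, scenario machinery, statistics — and directional behaviour
at reduced scale, not point predictions for Malawi.

## Numerical conventions and degenerate inputs

Probabilities are clipped to [0,1] after modifier composition; a zero
remaining worker budget yields infinite squeeze (the event still runs, with
delay three); rates are undefined (error) at zero live births, with a
period-aggregate fallback when single desk-scale years are empty; CIs
require ≥ 2 runs; identical run values give a zero-width CI; ties at the
delay-three boundary do not trigger it.  Problem sizes used by the test
suite and the acceptance script (7,000 agents, 4 paired runs, 2021–2028,
with smaller populations for unit tests) are the package's desk-scale
profile; all are configurable upward.
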