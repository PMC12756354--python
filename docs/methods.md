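# Methods

## Model and assumptions

The model is a one-period (1-year) expected-value cost–benefit analysis of
an AI-read-MRI triage strategy versus a PET-first pathway for suspected
Parkinson's disease in adults 65+. The assessed cohort is the population
for whom PET would normally be clinically considered; it has size
`N = n_PD / r` where `r` is the PD diagnostic rate among these suspected
outpatients (so `n_nonPD = n_PD (1−r)/r`). Patients are classified by five
binary attributes (PD status, economic burden for PET, AI usage, MRI/AI
detection, PET detection), yielding 24 mutually exclusive types; the non-AI
arm (types 13–24) is clinically identical to the AI arm and accrues no
marginal costs or benefits.

Key structural assumptions:

* **Independence.** PD status, economic burden and AI adoption are
  independent Bernoulli attributes; detection outcomes depend only on PD
  status. No correlation structure is modelled (none is specified by the
  underlying study design).
* **One period.** Treatment-cost terms accrue one year of early-vs-delayed
  cost difference; there is no disease progression, mortality or Markov
  dynamics.
* **Linearity.** Every term is a product of a stratum size, probabilities
  and one unit cost, hence linear in adoption `a`, affine in the
  unaffordability rate `u` and linear in each unit cost. The scenario layer
  exploits this: the break-even AI price is solved in closed form as
  `c* = (NB(c₀) + S c₀)/S` with `S = N·(1−u)·a + n_PD·u·a + n_nonPD·u·a`
  (algebraically `N·a`) and verified post-hoc to be a root.

## Parameters

| field | meaning | Korea default | U.S. default |
|---|---|---|---|
| `pd_dx_rate` | PD prevalence among suspected outpatients | 0.5 | 0.5 |
| `n_pd` | annual PD cases 65+ entering the pathway | 48,888 | 90,000 |
| `ai_adoption` | fraction of cohort on the AI arm | 0.3 | 0.3 |
| `pet_unaffordable` | fraction facing economic burden for PET | 0.3 | 0.3 |
| `sens_ai` / `spec_ai` | AI-read MRI accuracy | 0.943 / 0.917 | same |
| `sens_pet` / `spec_pet` | PET accuracy | 0.932 / 0.857 | same |
| `cost_pet` / `cost_ai` | USD per scan / per AI read | 735 / 7 | 2,587 / 100 |
| `cost_early` / `cost_delayed` | annual treatment cost, USD | 4,062 / 4,753 | 24,439 / 30,439 |
| `persons_per_visit`, `hours_pet`, `wage_65plus`, `employment_65plus`, `transport_roundtrip` | non-medical inputs | 2, 4 h, 14.6 USD/h, 0.396, 18.2 USD | n/a (perspective excludes them) |

`spec_pet` and `hours_visit` are housed for completeness but enter no
closed-form term; the microsimulator uses `spec_pet` only for pathway
realism (non-PD PET outcomes never accrue).

Two Korea files ship. `korea` carries the published (rounded) inputs;
`korea_unrounded` restores the precision the published result table is
consistent with: `cost_ai = 10,000 KRW / 1,416.54 KRW-per-USD ≈ 7.0595 USD`
and `spec_ai = 0.9167`. All internal arithmetic is in USD; a file may
declare `currency: local` to convert every money field once at load via
`exchange_rate`. Residual drift of the recomputed Korea headline numbers
against the published ones is ≤ 0.03% (e.g. net benefit 9,288,288 vs
9,290,818 at 30% adoption) and traces to remaining input rounding
(`cost_pet` is published as 735 USD; the published table is most consistent
with ≈ 735.15). We deliberately do not back-solve unit costs beyond the two
shipped files. The U.S. values reproduce exactly.

## Formula/table reconciliation

Two places where the source's printed formulas and printed results
disagree are resolved **in favour of the results**, because the results are
the quantity of record; both routes remain available and the choice is
logged, never silent.

1. **Term variant.** The verbatim formula set (`as_printed`) does not
   regenerate five printed result cells. The default `table_consistent`
   variant applies the minimal substitutions that do: MC1 uses `(1−Se_AI)`
   in place of `Se_AI` (a burdened PD patient generates an *extra* PET cost
   in the published accounting through the complementary branch), and
   MC8–MC11 use `Se_AI · Se_PET` in place of `(1−Se_AI) · Se_PET`. Every
   other term is identical in both variants.
2. **Aggregation.** Summing all 11 cost terms does not reproduce the
   published net benefit; excluding exactly one of the two transportation
   cost terms does (they are numerically identical when `r = 0.5`, so
   which one is excluded is indistinguishable at the published inputs —
   MC10 by our convention). `published` (default) excludes MC10;
   `all_terms` includes everything.

The semantic labels printed next to MC1/MC8–MC11 ("true positives", "false
positives") do not match the factor sets implied by the results; we carry
the implied factors and keep the labels as description text only.

## Perspectives

`societal` includes all 18 terms. `healthcare_system` (the U.S. analysis)
zeroes the seven non-medical terms (MB5–MB7, MC8–MC11); this is provably
identical to a societal run with wage and transport inputs set to zero, and
a property test asserts it.

## Known discrepancy: the Korean break-even price

The closed-form break-even AI price validates exactly against the published
U.S. figure (1,506.6 vs "1,506 USD") but gives ≈ 324 USD for Korea against
a published "226 USD". No variant/aggregation/perspective combination we
tested reproduces 226 from the published inputs, and the underlying
calculation is not shown. We implement the solver that the U.S. number
validates and report the Korea discrepancy rather than tuning to match; the
Korean break-even is therefore not asserted anywhere.

## Microsimulator

The synthetic-data layer samples patient records with exactly the
statistical structure the closed forms assume: independent Bernoulli draws
for PD status, burden and AI usage; an AI call with probability `Se_AI`
(PD) or `1−Sp_AI` (non-PD); a PET outcome with probability `Se_PET` (PD) or
`1−Sp_PET` (non-PD, realism only). Accrual rules are event-level
translations of the `table_consistent` terms; each record maps to one of
the 24 types. One generator is seeded per cohort and field draws are
consumed in a fixed order, so `(params, n, seed)` determines the cohort
bit-identically.

One wrinkle: the time/transport cost terms for burdened non-PD patients
(MC9, MC11) reference `Se_AI · Se_PET`, which are not the event
probabilities of a non-PD patient. The simulator translates the published
arithmetic faithfully using two auxiliary Bernoulli indicators with those
probabilities rather than reinterpreting the economics; this keeps every
Monte-Carlo term estimate an unbiased estimator of its closed-form value
(verified at n = 10⁶ within 3 standard errors).

What a green microsim test establishes: that the closed forms and the
sampler encode the same joint distribution and accounting. What it does
not establish: anything about real patients — there is no correlation
between burden and disease, no test-performance heterogeneity, no
within-patient cost variance (unit costs are constants), and the 1-year
horizon hides all dynamics.

## Projection

The long-term engine re-evaluates the closed forms year by year with an
adoption ramp (default: linear from the base adoption to 80% over 10
years, then flat; a logistic alternative is provided since real diffusion
is often S-shaped), a cohort-growth multiplier (default: constant) and an
optional discount rate (default 0%, since the source model does not
discount; long-horizon CBA conventionally would). The published long-term
cumulative figure depends on an unpublished prevalence-growth series, so
the engine is fully parameterised but no specific long-term value is
asserted; the bundled illustrative scenario uses a constant cohort.

## Numerical choices

* Internal arithmetic is unrounded `float64`; presentation rounds money
  half-up to integer USD and B/C ratios to two decimals, matching the
  published table conventions (e.g. 13,830.4 → 13,830).
* B/C is reported as NaN when the cost total is zero (undefined, not an
  error); negative nets are allowed so sensitivity sweeps can cross zero.
* Break-even roots are accepted when the recomputed net is within 1e-9 of
  zero relative to gross money flow (benefits + costs), the natural scale
  when the net itself cancels toward zero.
* Monte-Carlo standard errors use per-record (Bernoulli) variance for
  terms and the per-record net variance for the net; replicate estimates
  use between-replicate variance.

## Limitations

* A classification economy, not a disease model: no QALYs, no ICER, no
  progression, one year of treatment-cost difference only.
* Deterministic sensitivity analysis only (one-way sweeps); no
  probabilistic sensitivity analysis over input distributions.
* The 24-type table enumerates realised pathways, not a full product
  space; per-type expected counts beyond the verifiable 8-way collapse are
  an explicitly labelled extrapolation.
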