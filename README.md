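# pdcba — cost–benefit analysis of AI-assisted MRI triage for Parkinson's disease

`pdcba` implements a one-period, patient-classification cost–benefit model
(CBA) comparing two diagnostic pathways for suspected idiopathic Parkinson's
disease (PD) in adults 65+:

* **Conventional pathway** — patients with diagnostic uncertainty proceed
  directly to confirmatory PET imaging.
* **AI triage pathway** — an AI model reads susceptibility-weighted MRI for
  loss of the nigrosome-1 "swallow-tail sign" and decides who still needs
  PET: AI-negative patients without economic burden skip PET (triage
  saving), while AI-positive patients facing out-of-pocket burden are routed
  into reimbursed PET they would otherwise have forgone (access gain).

It is intended for health-economics and HTA analysts who want to reproduce,
stress-test or re-parameterise this kind of diagnostic-triage CBA for other
settings, prices or accuracies.

## The model

The assessed cohort has size `N = n_PD / r`, where `n_PD` is the annual PD
case count and `r` the diagnostic rate among suspected outpatients. Each
patient is classified by five binary attributes — true PD status, economic
burden for PET (probability `u`), AI usage (adoption rate `a`), MRI/AI
detection outcome (sensitivity `Se_AI`, specificity `Sp_AI`) and PET
detection outcome (`Se_PET`) — giving 24 mutually exclusive patient types
(types 13–24, the non-AI arm, accrue nothing by construction).

The incremental economy of the AI arm is a sum of 18 closed-form terms,
7 marginal benefits (MB) and 11 marginal costs (MC), each a product of a
stratum size, probabilities and one unit cost, e.g.

```
MB1 = n_PD · (1−u) · a · (1−Se_AI) · c_PET        (avoided PET scans)
MB4 = n_PD · u · a · Se_AI · Se_PET · c_delayed   (delayed-treatment costs avoided)
MC3 = N · (1−u) · a · c_AI                        (AI reads, no-burden stratum)
```

Decision metrics are the **net benefit** `NB = ΣMB − ΣMC` and the
**benefit–cost ratio** `B/C = ΣMB / ΣMC`. Every term is linear in `a`,
affine in `u` and linear in each unit cost, so adoption sweeps, one-way
sensitivity analysis and the break-even AI price
`c* = (NB(c₀) + S·c₀)/S` (with `S` the AI-scan volume) are exact.

Two perspectives are supported: *societal* (Korea: includes patient and
caregiver time valued at the 65+ wage × employment rate, plus transport) and
*healthcare-system* (U.S.: direct medical costs only). A patient-level
Monte-Carlo microsimulator samples individual trajectories under the same
statistical assumptions and cross-validates every closed-form aggregate.

Two reconciliations between the source's printed formulas and its printed
results are built in and documented (`docs/methods.md`): the default
`table_consistent` term variant and the `published` aggregation rule, which
excludes one of the two numerically identical transportation cost terms.
The verbatim `as_printed` formula set is retained for transparency.

## Worked example

Three parameter sets ship with the package: `korea` (published inputs
verbatim), `korea_unrounded` (precision-restored AI cost and specificity)
and `usa`.

```sh
$ pdcba run --params korea_unrounded
            South Korea AI (30%)
MB1                      430,114
MB2                    6,917,292
...
Net benefit            9,288,288
B/C ratio                   1.48
```

At 30% AI adoption the Korean societal model yields a net benefit of
≈9.29 million USD with a benefit–cost ratio of 1.48: the AI arm's savings
(avoided PET scans, earlier treatment, avoided delayed-treatment costs,
time and transport) exceed its costs (AI reads, extra PET scans and
treatment for burdened patients gaining access) by about half again.

```sh
$ pdcba breakeven --params usa
break-even AI unit cost: 1,506.62 USD
```

The U.S. model stays beneficial up to an AI price of ≈1,507 USD per read —
15× the assumed 100 USD price.

```sh
$ pdcba subgroups --params korea
  subgroup  expected_count  count  pct_of_total
2       B1      31381.2072  31381          32.1
4       C1      13830.4152  13830          14.1
...
```

Of 97,776 assessed patients, 31,381 (32.1%, group B1) are non-PD patients
triaged out of PET, and 13,830 (14.1%, group C1) are burdened PD patients
who gain PET access. Other subcommands: `sweep` (one-way sensitivity),
`project` (multi-year net-benefit projection), `simulate` (Monte-Carlo
cross-check), `reproduce` (full analysis bundle). Everything is also
available as library functions (`import pdcba`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline published quantities from scratch with the bundled
parameter sets — the Korea and U.S. net benefits at 30% and 100% adoption,
the U.S. MB1 term, the U.S. break-even AI price, and the Korea net benefit
at 0% and 100% PET unaffordability — and writes them as JSON. A seeded
microsimulation cross-check of the Korea net benefit is reported on stderr.

See `docs/methods.md` for model assumptions, parameter semantics, the
formula/table reconciliation and known limitations.
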