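# South Korea, societal perspective — precision-restored inputs.
# cost_ai = 10,000 KRW / 1,416.54 KRW-per-USD (the published 7 USD is this
# value rounded); spec_ai = 0.9167 (published 0.917 is this rounded).
# This set reproduces the published result table most closely.
label: South Korea
perspective: societal
currency: USD
pd_dx_rate: 0.5
n_pd: 48888
ai_adoption: 0.3
pet_unaffordable: 0.3
sens_ai: 0.943
spec_ai: 0.9167
sens_pet: 0.932
spec_pet: 0.857
cost_pet: 735
cost_ai: 7.059454727716831  # 10000 / 1416.54
cost_early: 4062
cost_delayed: 4753
persons_per_visit: 2
hours_pet: 4
hours_visit: 4
wage_65plus: 14.6
employment_65plus: 0.396
transport_roundtrip: 18.2
exchange_rate: 1416.54
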