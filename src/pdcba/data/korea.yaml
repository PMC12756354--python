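# South Korea, societal perspective — published input table verbatim.
# Rounded inputs (cost_ai 7 USD, spec_ai 0.917); headline results match the
# published tables to <= 0.03%.  See korea_unrounded.yaml for the
# precision-restored variant.
label: South Korea
perspective: societal
currency: USD
pd_dx_rate: 0.5
n_pd: 48888
ai_adoption: 0.3
pet_unaffordable: 0.3
sens_ai: 0.943
spec_ai: 0.917
sens_pet: 0.932
spec_pet: 0.857
cost_pet: 735
cost_ai: 7
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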