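# United States, healthcare-system perspective: direct medical costs only.
# Non-medical inputs (wage, time, transport) are not applicable and set to 0;
# the perspective flag zeroes the corresponding terms regardless.
# spec_ai carries the unrounded 0.9167 consistent with the published results
# (the input table prints 0.917).
label: United States
perspective: healthcare_system
currency: USD
pd_dx_rate: 0.5
n_pd: 90000
ai_adoption: 0.3
pet_unaffordable: 0.3
sens_ai: 0.943
spec_ai: 0.9167
sens_pet: 0.932
spec_pet: 0.857
cost_pet: 2587
cost_ai: 100
cost_early: 24439
cost_delayed: 30439
persons_per_visit: 0
hours_pet: 0
hours_visit: 0
wage_65plus: 0
employment_65plus: 0
transport_roundtrip: 0
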