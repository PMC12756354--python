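"""Hypothesis strategies shared across the property tests."""

from hypothesis import strategies as st

from pdcba import ParameterSet

_prob = st.floats(0.0, 1.0, allow_nan=False)
_open_prob = st.floats(0.01, 1.0, allow_nan=False)
_money = st.floats(0.0, 50_000.0, allow_nan=False)


def parameter_sets(perspective=st.sampled_from(["societal", "healthcare_system"])):
    """Random in-range parameter sets (valid by construction)."""
    return st.builds(
        ParameterSet,
        pd_dx_rate=_open_prob,
        n_pd=st.floats(1.0, 1e6, allow_nan=False),
        ai_adoption=_prob,
        pet_unaffordable=_prob,
        sens_ai=_prob,
        spec_ai=_prob,
        sens_pet=_prob,
        spec_pet=_prob,
        cost_pet=_money,
        cost_ai=_money,
        cost_early=_money,
        cost_delayed=_money,
        persons_per_visit=st.floats(0.0, 4.0, allow_nan=False),
        hours_pet=st.floats(0.0, 12.0, allow_nan=False),
        hours_visit=st.floats(0.0, 12.0, allow_nan=False),
        wage_65plus=st.floats(0.0, 100.0, allow_nan=False),
        employment_65plus=_prob,
        transport_roundtrip=st.floats(0.0, 200.0, allow_nan=False),
        perspective=perspective,
    )
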