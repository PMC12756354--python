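"""Patient-level Monte-Carlo simulator.

The closed-form engine computes expectations over the joint distribution of
five binary patient attributes.  This module samples that distribution one
patient at a time and accrues the same marginal costs and benefits at the
event level, giving an independent stochastic estimate of every aggregate:
for each term, the mean accrual converges to the closed-form value by the
law of large numbers.

Sampling structure (one draw column per field, consumed in fixed order so a
seed fully determines the cohort):

* ``pd_status``       ~ Bernoulli(pd_dx_rate)
* ``economic_burden`` ~ Bernoulli(pet_unaffordable)
* ``ai_used``         ~ Bernoulli(ai_adoption)
* ``ai_positive``     ~ Bernoulli(sens_ai) for PD, Bernoulli(1 - spec_ai) otherwise
* ``pet_detect``      ~ Bernoulli(sens_pet) for PD, Bernoulli(1 - spec_pet)
  otherwise (the non-PD draw is pathway realism only and never accrues)
* two auxiliary Bernoulli(sens_ai), Bernoulli(sens_pet) indicators used by
  the time/transport cost rules for burdened non-PD patients, whose
  closed-form factors reference the AI and PET sensitivities even though
  those are not the event probabilities of a non-PD patient; the simulator
  translates the published arithmetic faithfully rather than reinterpreting
  it.

Disease status, burden and adoption are independent (the model states no
correlations).  Patients on the conventional arm (``ai_used`` false, types
13-24) accrue nothing: both strategies treat them identically.  Treatment
accruals are one year of cost difference, matching the model's 1-year
horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import NON_MEDICAL_TERMS, Aggregation, evaluate_terms
from .parameters import ParameterSet

__all__ = ["MicrosimCohort", "simulate_cohort", "estimate_net_benefit_mc"]

_TERM_SIGN = {"benefit": 1.0, "cost": -1.0}


@dataclass(frozen=True)
class MicrosimCohort:
    """Aggregates of one simulated cohort, scaled to the full cohort size.

    ``term_values`` holds the Monte-Carlo estimate of each term's magnitude
    (USD, scaled by ``n_total / n``); ``term_se`` the matching standard
    errors.  ``net_benefit`` uses the requested aggregation rule (the
    published rule excludes the duplicate transportation term MC10).
    """

    seed: int | None
    n: int
    scale: float
    aggregation: Aggregation
    term_values: dict[str, float]
    term_se: dict[str, float]
    category_totals: dict[str, float]  # signed, scaled
    net_benefit: float
    net_se: float
    type_counts: dict[int, int]
    records: pd.DataFrame | None = field(default=None, repr=False, compare=False)


def _unit_costs(params: ParameterSet) -> dict[str, float]:
    """Per-event accrual magnitude of each term (USD)."""
    kweh = (
        params.persons_per_visit
        * params.wage_65plus
        * params.employment_65plus
        * params.hours_pet
    )
    kt = params.persons_per_visit * params.transport_roundtrip
    return {
        "MB1": params.cost_pet, "MB2": params.cost_pet,
        "MC1": params.cost_pet, "MC2": params.cost_pet,
        "MC3": params.cost_ai, "MC4": params.cost_ai, "MC5": params.cost_ai,
        "MB3": params.cost_early, "MC6": params.cost_early,
        "MB4": params.cost_delayed, "MC7": params.cost_delayed,
        "MB5": kweh, "MB6": kweh, "MC8": kweh, "MC9": kweh,
        "MB7": kt, "MC10": kt, "MC11": kt,
    }


_TERM_META = {t: ("benefit" if t.startswith("MB") else "cost") for t in (
    "MB1", "MB2", "MB3", "MB4", "MB5", "MB6", "MB7",
    "MC1", "MC2", "MC3", "MC4", "MC5", "MC6", "MC7", "MC8", "MC9", "MC10", "MC11",
)}

_TERM_CATEGORY = {
    "MB1": "pet_cost", "MB2": "pet_cost", "MC1": "pet_cost", "MC2": "pet_cost",
    "MC3": "ai_cost", "MC4": "ai_cost", "MC5": "ai_cost",
    "MB3": "treatment_cost", "MC6": "treatment_cost",
    "MB4": "treatment_cost", "MC7": "treatment_cost",
    "MB5": "time_cost", "MB6": "time_cost", "MC8": "time_cost", "MC9": "time_cost",
    "MB7": "transport_cost", "MC10": "transport_cost", "MC11": "transport_cost",
}


def _assign_types(pd_s, burden, mri_pos, pet_det, ai_used):
    """Map each record to its patient type (1-24)."""
    t = np.zeros(pd_s.shape, dtype=np.int64)
    nb = ~burden
    t[pd_s & nb & mri_pos & pet_det] = 1
    t[pd_s & nb & mri_pos & ~pet_det] = 2
    t[pd_s & nb & ~mri_pos & pet_det] = 3
    t[pd_s & nb & ~mri_pos & ~pet_det] = 4
    t[pd_s & burden & mri_pos] = 5
    t[pd_s & burden & ~mri_pos] = 6
    t[~pd_s & nb & mri_pos & pet_det] = 7
    t[~pd_s & nb & mri_pos & ~pet_det] = 8
    t[~pd_s & nb & ~mri_pos & pet_det] = 9
    t[~pd_s & nb & ~mri_pos & ~pet_det] = 10
    t[~pd_s & burden & mri_pos] = 11
    t[~pd_s & burden & ~mri_pos] = 12
    t[~ai_used] += 12
    return t


def simulate_cohort(
    params: ParameterSet,
    n: int,
    seed: int | np.random.SeedSequence,
    aggregation: Aggregation = "published",
    keep_records: bool = False,
) -> MicrosimCohort:
    """Sample ``n`` patients and accrue per-patient marginal terms.

    All aggregates are scaled to the full assessed cohort (``n_total``)
    so they are directly comparable with the closed-form term values.
    Reproducible: identical ``(params, n, seed)`` give identical cohorts.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)

    # fixed field order — the reproducibility contract
    pd_s = rng.random(n) < params.pd_dx_rate
    burden = rng.random(n) < params.pet_unaffordable
    ai_used = rng.random(n) < params.ai_adoption
    p_ai_pos = np.where(pd_s, params.sens_ai, 1.0 - params.spec_ai)
    ai_pos = rng.random(n) < p_ai_pos
    p_pet = np.where(pd_s, params.sens_pet, 1.0 - params.spec_pet)
    pet_det = rng.random(n) < p_pet
    aux_ai = rng.random(n) < params.sens_ai
    aux_pet = rng.random(n) < params.sens_pet

    nb = ~burden
    costs = _unit_costs(params)

    # event mask per term (table-consistent accrual rules, AI arm only)
    masks = {
        "MB1": pd_s & nb & ai_used & ~ai_pos,
        "MB2": ~pd_s & nb & ai_used & ~ai_pos,
        "MC1": pd_s & burden & ai_used & ~ai_pos,
        "MC2": ~pd_s & burden & ai_used & ai_pos,
        "MC3": nb & ai_used,
        "MC4": pd_s & burden & ai_used,
        "MC5": ~pd_s & burden & ai_used,
        "MB3": pd_s & nb & ai_used & ~ai_pos & pet_det,
        "MC6": pd_s & burden & ai_used & ai_pos & pet_det,
        "MB4": pd_s & burden & ai_used & ai_pos & pet_det,
        "MC7": pd_s & nb & ai_used & ~ai_pos & pet_det,
        "MB5": pd_s & nb & ai_used & ~ai_pos,
        "MB6": ~pd_s & nb & ai_used & ~ai_pos,
        "MC8": pd_s & burden & ai_used & ai_pos & pet_det,
        "MC9": ~pd_s & burden & ai_used & aux_ai & aux_pet,
        "MB7": ~pd_s & nb & ai_used & ~ai_pos,
        "MC10": pd_s & burden & ai_used & ai_pos & pet_det,
        "MC11": ~pd_s & burden & ai_used & aux_ai & aux_pet,
    }

    hs = params.perspective == "healthcare_system"
    scale = params.n_total / n
    excluded = {"MC10"} if aggregation == "published" else set()

    term_values: dict[str, float] = {}
    term_se: dict[str, float] = {}
    category_totals = {c: 0.0 for c in set(_TERM_CATEGORY.values())}
    net_per_patient = np.zeros(n)
    for term, mask in masks.items():
        v = 0.0 if (hs and term in NON_MEDICAL_TERMS) else costs[term]
        c = int(mask.sum())
        # indicator-valued accrual: variance from the per-record Bernoulli
        p_hat = c / n
        term_values[term] = v * c * scale
        term_se[term] = v * math.sqrt(max(p_hat * (1 - p_hat), 0.0) / max(n - 1, 1)) * n * scale
        sign = _TERM_SIGN[_TERM_META[term]]
        category_totals[_TERM_CATEGORY[term]] += sign * v * c * scale
        if term not in excluded and v != 0.0:
            net_per_patient[mask] += sign * v

    net = float(net_per_patient.sum()) * scale
    net_se = float(net_per_patient.std(ddof=1)) / math.sqrt(n) * n * scale if n > 1 else math.nan

    types = _assign_types(pd_s, burden, ai_pos, pet_det, ai_used)
    uniq, cnt = np.unique(types, return_counts=True)
    type_counts = {int(k): int(v) for k, v in zip(uniq, cnt)}

    records = None
    if keep_records:
        records = pd.DataFrame(
            {
                "pd_status": pd_s,
                "economic_burden": burden,
                "ai_used": ai_used,
                "ai_positive": ai_pos,
                "pet_detect": pet_det,
                "patient_type": types,
                "net_accrual": net_per_patient,
            }
        )

    seed_repr = seed if isinstance(seed, int) else None
    return MicrosimCohort(
        seed=seed_repr,
        n=n,
        scale=scale,
        aggregation=aggregation,
        term_values=term_values,
        term_se=term_se,
        category_totals=category_totals,
        net_benefit=net,
        net_se=net_se,
        type_counts=type_counts,
        records=records,
    )


def estimate_net_benefit_mc(
    params: ParameterSet,
    n: int,
    replicates: int,
    seed: int,
    aggregation: Aggregation = "published",
) -> tuple[float, float]:
    """Replicate-based Monte-Carlo estimate of the cohort net benefit.

    Returns the mean over ``replicates`` independent cohorts of size ``n``
    (each scaled to the full cohort) and the standard error of that mean
    across replicates (0.0 for a single replicate in a degenerate
    zero-variance economy, NaN otherwise).
    """
    if n <= 0 or replicates <= 0:
        raise ValueError("n and replicates must be positive")
    children = np.random.SeedSequence(seed).spawn(replicates)
    nets = np.array(
        [simulate_cohort(params, n, s, aggregation).net_benefit for s in children]
    )
    mean = float(nets.mean())
    if replicates > 1:
        se = float(nets.std(ddof=1)) / math.sqrt(replicates)
    else:
        se = 0.0 if nets[0] == 0.0 else math.nan
    return mean, se
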