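"""The 18 marginal-benefit / marginal-cost terms and their aggregation.

The model prices the AI-triage strategy against the PET-first pathway as a
sum of 18 additive terms — seven marginal benefits (MB1-MB7) and eleven
marginal costs (MC1-MC11) — each a product of a cohort stratum size, the
adoption rate, diagnostic-accuracy factors and one unit cost.  Terms fall
into five cost categories: PET scan costs, AI processing costs, treatment
costs, time (productivity) costs and transportation costs.  The last two
categories exist only under the societal perspective; a healthcare-system
analysis zeroes them.

Two term-set variants are provided.  ``as_printed`` transcribes the
published formula table verbatim.  ``table_consistent`` (the default)
applies the minimal corrections under which every published result-table
value is regenerated: MC1 uses ``(1 - sens_ai)`` in place of ``sens_ai``,
and MC8-MC11 use ``sens_ai * sens_pet`` in place of
``(1 - sens_ai) * sens_pet``.  The published net benefit is likewise only
reproduced when exactly one of the two transportation cost terms — which
coincide numerically when PD and non-PD strata are equal — enters the cost
total; the ``published`` aggregation therefore excludes MC10, while
``all_terms`` sums every term.  Both reconciliations are deliberate and
logged, never silent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .parameters import ParameterSet

__all__ = [
    "Variant",
    "Aggregation",
    "TermDefinition",
    "TermValue",
    "ScenarioResult",
    "term_definitions",
    "evaluate_terms",
    "aggregate",
    "evaluate_scenario",
    "TABLE_ROW_ORDER",
    "NON_MEDICAL_TERMS",
    "RECONCILED_TERMS",
]

logger = logging.getLogger(__name__)

VARIANTS = ("as_printed", "table_consistent")
AGGREGATIONS = ("published", "all_terms")
Variant = str
Aggregation = str

#: presentation row order of the published result table
TABLE_ROW_ORDER = (
    "MB1", "MB2", "MC1", "MC2", "MC3", "MC4", "MC5",
    "MB3", "MC6", "MB4", "MC7",
    "MB5", "MB6", "MC8", "MC9", "MB7", "MC10", "MC11",
)

#: societal-only terms, zeroed under the healthcare-system perspective
NON_MEDICAL_TERMS = frozenset({"MB5", "MB6", "MB7", "MC8", "MC9", "MC10", "MC11"})

#: terms whose table_consistent factors differ from the printed formulas
RECONCILED_TERMS = frozenset({"MC1", "MC8", "MC9", "MC10", "MC11"})

# Symbolic factor vocabulary.  Each factor maps a ParameterSet to one number;
# a term's value is the product of its factors.
_FACTOR_EVALUATORS = {
    "n_pd": lambda p: p.n_pd,
    "n_nonpd": lambda p: p.n_nonpd,
    "n_total": lambda p: p.n_total,
    "u": lambda p: p.pet_unaffordable,
    "1-u": lambda p: 1.0 - p.pet_unaffordable,
    "a": lambda p: p.ai_adoption,
    "sens_ai": lambda p: p.sens_ai,
    "1-sens_ai": lambda p: 1.0 - p.sens_ai,
    "spec_ai": lambda p: p.spec_ai,
    "1-spec_ai": lambda p: 1.0 - p.spec_ai,
    "sens_pet": lambda p: p.sens_pet,
    "cost_pet": lambda p: p.cost_pet,
    "cost_ai": lambda p: p.cost_ai,
    "cost_early": lambda p: p.cost_early,
    "cost_delayed": lambda p: p.cost_delayed,
    "time_value": lambda p: (
        p.persons_per_visit * p.wage_65plus * p.employment_65plus * p.hours_pet
    ),
    "transport": lambda p: p.persons_per_visit * p.transport_roundtrip,
}


@dataclass(frozen=True)
class TermDefinition:
    """One marginal term: a symbolic product over model inputs."""

    term_id: str
    role: str  # "benefit" | "cost"
    category: str  # pet_cost | ai_cost | treatment_cost | time_cost | transport_cost
    factors: tuple[str, ...]
    patient_types: tuple[int, ...]
    description: str
    variant: Variant

    def evaluate(self, params: ParameterSet) -> float:
        value = 1.0
        for f in self.factors:
            value *= _FACTOR_EVALUATORS[f](params)
        return value


@dataclass(frozen=True)
class TermValue:
    term_id: str
    role: str
    category: str
    value: float  # USD, nonnegative magnitude
    variant: Variant


@dataclass(frozen=True)
class ScenarioResult:
    """Fully aggregated outcome of one parameter set."""

    params: ParameterSet
    terms: tuple[TermValue, ...]
    total_benefit: float
    total_cost: float
    net_benefit: float
    bc_ratio: float  # NaN when total_cost == 0
    perspective: str
    variant: Variant
    aggregation: Aggregation

    def term(self, term_id: str) -> TermValue:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)


# (term_id, role, category, printed factors, patient types, description)
# The factor lists below are the printed formula table; the table-consistent
# substitutions are applied on top in term_definitions().
_BASE_TERMS: list[tuple[str, str, str, tuple[str, ...], tuple[int, ...], str]] = [
    ("MB1", "benefit", "pet_cost",
     ("n_pd", "1-u", "a", "1-sens_ai", "cost_pet"), (3, 4),
     "Avoided PET costs due to false negatives identified by AI (without economic burden)"),
    ("MB2", "benefit", "pet_cost",
     ("n_nonpd", "1-u", "a", "spec_ai", "cost_pet"), (7, 8),
     "Avoided PET costs for true negatives correctly excluded by AI"),
    ("MC1", "cost", "pet_cost",
     ("n_pd", "u", "a", "sens_ai", "cost_pet"), (5,),
     "Additional PET costs due to true positives identified by AI (with economic burden)"),
    ("MC2", "cost", "pet_cost",
     ("n_nonpd", "u", "a", "1-spec_ai", "cost_pet"), (12,),
     "Additional PET costs due to false positives generated by AI"),
    ("MC3", "cost", "ai_cost",
     ("n_total", "1-u", "a", "cost_ai"), (1, 2, 3, 4, 7, 8, 9, 10),
     "AI usage cost, no-burden stratum"),
    ("MC4", "cost", "ai_cost",
     ("n_pd", "u", "a", "cost_ai"), (5, 6),
     "AI usage cost, PD patients with economic burden"),
    ("MC5", "cost", "ai_cost",
     ("n_nonpd", "u", "a", "cost_ai"), (11, 12),
     "AI usage cost, non-PD patients with economic burden"),
    ("MB3", "benefit", "treatment_cost",
     ("n_pd", "1-u", "a", "1-sens_ai", "sens_pet", "cost_early"), (3,),
     "Reduced treatment costs due to earlier diagnosis of true positives by AI"),
    ("MC6", "cost", "treatment_cost",
     ("n_pd", "u", "a", "sens_ai", "sens_pet", "cost_early"), (5,),
     "Additional early-treatment cost for burdened PD patients gaining PET access"),
    ("MB4", "benefit", "treatment_cost",
     ("n_pd", "u", "a", "sens_ai", "sens_pet", "cost_delayed"), (5,),
     "Delayed-treatment costs avoided for burdened PD patients diagnosed early"),
    ("MC7", "cost", "treatment_cost",
     ("n_pd", "1-u", "a", "1-sens_ai", "sens_pet", "cost_delayed"), (3,),
     "Delayed-diagnosis treatment cost for PD patients missed by AI"),
    ("MB5", "benefit", "time_cost",
     ("n_pd", "1-u", "a", "1-sens_ai", "time_value"), (3, 4),
     "Avoided visit time costs for PD patients whose PET was skipped"),
    ("MB6", "benefit", "time_cost",
     ("n_nonpd", "1-u", "a", "spec_ai", "time_value"), (7, 8),
     "Avoided visit time costs for non-PD patients triaged out of PET"),
    ("MC8", "cost", "time_cost",
     ("n_pd", "u", "a", "1-sens_ai", "sens_pet", "time_value"), (5,),
     "Visit time costs for burdened PD patients newly undergoing PET"),
    ("MC9", "cost", "time_cost",
     ("n_nonpd", "u", "a", "1-sens_ai", "sens_pet", "time_value"), (12,),
     "Visit time costs for burdened non-PD patients sent to PET"),
    ("MB7", "benefit", "transport_cost",
     ("n_nonpd", "1-u", "a", "spec_ai", "transport"), (7, 8),
     "Avoided transportation costs for patients triaged out of PET"),
    ("MC10", "cost", "transport_cost",
     ("n_pd", "u", "a", "1-sens_ai", "sens_pet", "transport"), (5,),
     "Transportation costs for burdened PD patients newly undergoing PET"),
    ("MC11", "cost", "transport_cost",
     ("n_nonpd", "u", "a", "1-sens_ai", "sens_pet", "transport"), (12,),
     "Transportation costs for burdened non-PD patients sent to PET"),
]

# table_consistent factor substitutions, per term
_TC_SUBSTITUTIONS: dict[str, dict[str, str]] = {
    "MC1": {"sens_ai": "1-sens_ai"},
    "MC8": {"1-sens_ai": "sens_ai"},
    "MC9": {"1-sens_ai": "sens_ai"},
    "MC10": {"1-sens_ai": "sens_ai"},
    "MC11": {"1-sens_ai": "sens_ai"},
}


def term_definitions(variant: Variant = "table_consistent") -> list[TermDefinition]:
    """Return the 18 term definitions for the requested variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    out = []
    for term_id, role, category, factors, types, desc in _BASE_TERMS:
        if variant == "table_consistent" and term_id in _TC_SUBSTITUTIONS:
            sub = _TC_SUBSTITUTIONS[term_id]
            factors = tuple(sub.get(f, f) for f in factors)
        out.append(TermDefinition(term_id, role, category, factors, types, desc, variant))
    return out


def evaluate_terms(
    params: ParameterSet, variant: Variant = "table_consistent"
) -> list[TermValue]:
    """Evaluate all 18 terms in USD for one parameter set.

    Under the healthcare-system perspective the societal-only terms
    (time and transport) are forced to zero.
    """
    if variant == "table_consistent":
        logger.debug(
            "table_consistent variant active; reconciled terms: %s",
            ", ".join(sorted(RECONCILED_TERMS)),
        )
    hs = params.perspective == "healthcare_system"
    values = []
    for d in term_definitions(variant):
        v = 0.0 if (hs and d.term_id in NON_MEDICAL_TERMS) else d.evaluate(params)
        values.append(TermValue(d.term_id, d.role, d.category, v, variant))
    return values


def aggregate(
    params: ParameterSet,
    terms: list[TermValue],
    aggregation: Aggregation = "published",
) -> ScenarioResult:
    """Sum the term values into net benefit and benefit-cost ratio.

    ``published`` excludes the duplicate transportation cost term MC10 from
    the cost total; ``all_terms`` includes every cost term.  The B/C ratio
    is NaN (undefined) when the cost total is zero.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}; expected one of {AGGREGATIONS}")
    if len(terms) != 18:
        raise ValueError(f"expected 18 term values, got {len(terms)}")
    total_benefit = sum(t.value for t in terms if t.role == "benefit")
    excluded = {"MC10"} if aggregation == "published" else set()
    total_cost = sum(t.value for t in terms if t.role == "cost" and t.term_id not in excluded)
    net = total_benefit - total_cost
    bc = total_benefit / total_cost if total_cost > 0 else math.nan
    variant = terms[0].variant
    return ScenarioResult(
        params=params,
        terms=tuple(terms),
        total_benefit=total_benefit,
        total_cost=total_cost,
        net_benefit=net,
        bc_ratio=bc,
        perspective=params.perspective,
        variant=variant,
        aggregation=aggregation,
    )


def evaluate_scenario(
    params: ParameterSet,
    variant: Variant = "table_consistent",
    aggregation: Aggregation = "published",
) -> ScenarioResult:
    """Evaluate terms and aggregate in one call."""
    return aggregate(params, evaluate_terms(params, variant), aggregation)
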