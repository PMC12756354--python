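"""Scenario machinery: adoption sweeps, one-way sensitivity, break-even
pricing and multi-year projection.

Every term of the economic model is linear in the adoption rate, affine in
the PET unaffordability rate and linear in each unit cost, which makes the
scenario layer cheap: sweeps re-evaluate the closed forms, and the
break-even AI price has an exact one-step solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

from .economics import Aggregation, ScenarioResult, Variant, evaluate_scenario
from .parameters import ParameterSet

__all__ = [
    "SensitivityCurve",
    "ProjectionSeries",
    "adoption_sweep",
    "one_way_sensitivity",
    "break_even_ai_cost",
    "ai_scan_volume",
    "project_long_term",
    "linear_ramp",
    "logistic_ramp",
]


@dataclass(frozen=True)
class SensitivityCurve:
    """Net benefit as a function of one swept input, plus ratios to base."""

    param_name: str
    grid: tuple[float, ...]
    net_benefit: tuple[float, ...]
    base_net_benefit: float
    ratio_pct: tuple[float, ...]  # 100 * net / base


@dataclass(frozen=True)
class ProjectionSeries:
    """Annual and cumulative net benefit over a multi-year horizon."""

    years: tuple[int, ...]
    adoption: tuple[float, ...]
    n_pd: tuple[float, ...]
    annual_net: tuple[float, ...]  # discounted to the start year if applicable
    cumulative_net: tuple[float, ...]
    discount_rate: float


def adoption_sweep(
    params: ParameterSet,
    rates: Sequence[float],
    variant: Variant = "table_consistent",
    aggregation: Aggregation = "published",
) -> list[ScenarioResult]:
    """Evaluate the full scenario at each adoption rate, all else fixed."""
    if len(rates) == 0:
        raise ValueError("rates must be non-empty")
    return [
        evaluate_scenario(params.replace(ai_adoption=float(r)), variant, aggregation)
        for r in rates
    ]


def one_way_sensitivity(
    params: ParameterSet,
    param_name: str,
    grid: Sequence[float],
    variant: Variant = "table_consistent",
    aggregation: Aggregation = "published",
) -> SensitivityCurve:
    """Recompute net benefit along a grid of one input, all else fixed.

    The ratio column expresses each point as a percentage of the base-case
    net benefit (the unswept parameter set).
    """
    if not hasattr(params, param_name):
        raise ValueError(f"unknown parameter {param_name!r}")
    if not isinstance(getattr(params, param_name), (int, float)):
        raise ValueError(f"parameter {param_name!r} is not numeric")
    grid_t = tuple(float(g) for g in grid)
    if any(b <= a for a, b in zip(grid_t, grid_t[1:])):
        raise ValueError("grid must be strictly increasing")
    base = evaluate_scenario(params, variant, aggregation).net_benefit
    nets = tuple(
        evaluate_scenario(params.replace(**{param_name: g}), variant, aggregation).net_benefit
        for g in grid_t
    )
    ratios = tuple(100.0 * n / base if base != 0 else math.nan for n in nets)
    return SensitivityCurve(param_name, grid_t, nets, base, ratios)


def ai_scan_volume(params: ParameterSet) -> float:
    """Number of AI-read MRIs in the adopted arm.

    Sum of the three AI-cost strata: the no-burden total cohort, burdened PD
    patients and burdened non-PD patients, each times the adoption rate
    (algebraically ``n_total * adoption``).
    """
    a, u = params.ai_adoption, params.pet_unaffordable
    return (params.n_total * (1 - u) + params.n_pd * u + params.n_nonpd * u) * a


def break_even_ai_cost(
    params: ParameterSet,
    variant: Variant = "table_consistent",
    aggregation: Aggregation = "published",
) -> float:
    """AI unit price at which net benefit crosses zero.

    Net benefit is affine in ``cost_ai`` with slope ``-S`` where S is the
    AI-scan volume, so the root is ``c* = (net(c0) + S * c0) / S`` for any
    current price c0.  Returns NaN when S == 0 (no AI usage: the price is
    indeterminate).
    """
    s = ai_scan_volume(params)
    if s <= 0.0:
        return math.nan
    net0 = evaluate_scenario(params, variant, aggregation).net_benefit
    return (net0 + s * params.cost_ai) / s


def linear_ramp(start: float, ceiling: float = 0.8, years_to_ceiling: int = 10) -> Callable[[int], float]:
    """Adoption ramp rising linearly from ``start`` to ``ceiling`` over
    ``years_to_ceiling`` years, then flat."""
    if not 0.0 <= ceiling <= 1.0:
        raise ValueError("ceiling must lie in [0, 1]")

    def ramp(k: int) -> float:
        if years_to_ceiling <= 0 or k >= years_to_ceiling:
            return ceiling
        return start + (ceiling - start) * k / years_to_ceiling

    return ramp


def logistic_ramp(
    start: float, ceiling: float = 0.8, midpoint_year: float = 5.0, steepness: float = 1.0
) -> Callable[[int], float]:
    """S-curve alternative to the linear ramp (technology diffusion is often
    sigmoidal); anchored so that year 0 evaluates to ``start``."""
    if not 0.0 <= ceiling <= 1.0:
        raise ValueError("ceiling must lie in [0, 1]")
    f0 = 1.0 / (1.0 + math.exp(steepness * midpoint_year))

    def ramp(k: int) -> float:
        f = 1.0 / (1.0 + math.exp(-steepness * (k - midpoint_year)))
        return start + (ceiling - start) * (f - f0) / (1.0 - f0)

    return ramp


def project_long_term(
    params: ParameterSet,
    start_year: int,
    end_year: int,
    adoption_ramp: Callable[[int], float] | None = None,
    cohort_growth: Callable[[int], float] | None = None,
    discount_rate: float = 0.0,
    variant: Variant = "table_consistent",
    aggregation: Aggregation = "published",
) -> ProjectionSeries:
    """Project annual and cumulative net benefit over a year range.

    ``adoption_ramp`` maps the year index (0 for ``start_year``) to that
    year's adoption rate; the default rises linearly from the parameter
    set's adoption to 80% over 10 years and stays flat.  ``cohort_growth``
    maps the year index to a multiplier on ``n_pd`` (default: constant
    cohort).  Annual nets are discounted to ``start_year`` when
    ``discount_rate`` > 0; the cumulative series is the running sum of the
    (discounted) annual values.
    """
    if start_year > end_year:
        raise ValueError("start_year must not exceed end_year")
    if discount_rate < 0.0:
        raise ValueError("discount_rate must be >= 0")
    ramp = adoption_ramp or linear_ramp(params.ai_adoption)
    growth = cohort_growth or (lambda k: 1.0)

    years, adoptions, cohorts, annual = [], [], [], []
    for k, year in enumerate(range(start_year, end_year + 1)):
        a_k = ramp(k)
        if not 0.0 <= a_k <= 1.0:
            raise ValueError(f"adoption ramp produced {a_k} outside [0, 1] at year {year}")
        m_k = growth(k)
        if m_k <= 0.0:
            raise ValueError(f"cohort growth produced non-positive multiplier at year {year}")
        p_k = params.replace(ai_adoption=a_k, n_pd=params.n_pd * m_k)
        net_k = evaluate_scenario(p_k, variant, aggregation).net_benefit
        net_k /= (1.0 + discount_rate) ** k
        years.append(year)
        adoptions.append(a_k)
        cohorts.append(p_k.n_pd)
        annual.append(net_k)

    cumulative = []
    running = 0.0
    for v in annual:
        running += v
        cumulative.append(running)
    return ProjectionSeries(
        years=tuple(years),
        adoption=tuple(adoptions),
        n_pd=tuple(cohorts),
        annual_net=tuple(annual),
        cumulative_net=tuple(cumulative),
        discount_rate=discount_rate,
    )
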