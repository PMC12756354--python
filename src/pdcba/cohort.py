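"""The 24-type patient classification and the 8-way cohort partition.

Every individual in the assessed cohort belongs to exactly one of 24
mutually exclusive patient types defined by five binary attributes: true PD
status, economic burden to access PET, MRI detection outcome, PET detection
outcome (detected / not detected / not performed), and whether AI was used
to read the MRI.  Types 1-12 belong to the AI-assisted arm; types 13-24 are
the clinically identical conventional-pathway mirrors (type k+12 shares the
clinical pattern of type k) and accrue no marginal costs or benefits.

The verifiable cohort-level quantity is the coarser 8-way partition by
(PD status, economic burden, AI detection outcome) that drives the PET
utilisation claims: the letters A-D index PD/no-burden, non-PD/no-burden,
PD/burden, non-PD/burden, and the suffix is 1 when the AI call matches the
truth and 2 when it does not.  B1 counts the PET scans avoided by triage,
C1 the burdened PD patients whom a positive AI read routes into reimbursed
PET, A2 the missed PD cases, D2 the unnecessary scans on false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ParameterSet

__all__ = [
    "PatientType",
    "SubgroupCounts",
    "enumerate_patient_types",
    "subgroup_counts",
    "expected_type_counts",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round a nonnegative value to the nearest integer, ties away from zero."""
    import math

    return math.floor(x + 0.5)


@dataclass(frozen=True)
class PatientType:
    type_id: int
    pd_status: bool
    economic_burden: bool
    mri_detection: str  # "detected" | "not_detected"
    pet_detection: str  # "detected" | "not_detected" | "not_performed"
    ai_usage: bool
    note: str

    @property
    def pattern(self) -> tuple[bool, bool, str, str]:
        """Clinical pattern shared between the AI arm and its mirror type."""
        return (self.pd_status, self.economic_burden, self.mri_detection, self.pet_detection)


_D, _ND, _NP = "detected", "not_detected", "not_performed"

# (pd, burden, mri, pet) for types 1-12; 13-24 mirror these on the
# conventional arm.
_AI_ARM_PATTERNS: list[tuple[bool, bool, str, str, str]] = [
    (True, False, _D, _D, "Additional AI cost"),
    (True, False, _D, _ND, "Additional AI cost"),
    (True, False, _ND, _D, "Additional AI cost; missed diagnosis causing delayed diagnosis costs"),
    (True, False, _ND, _ND, "Additional AI cost; missed diagnosis causing delayed diagnosis costs"),
    (True, True, _D, _D, "Additional AI cost; additional PET cost; early treatment cost saving"),
    (True, True, _ND, _NP, "Additional AI cost"),
    (False, False, _D, _D, "Additional AI cost; PET cost saving by triage"),
    (False, False, _D, _ND, "Additional AI cost; PET cost saving by triage"),
    (False, False, _ND, _D, "Additional AI cost"),
    (False, False, _ND, _ND, "Additional AI cost"),
    (False, True, _D, _NP, "Additional AI cost"),
    (False, True, _ND, _D, "Additional AI cost"),
]


def enumerate_patient_types() -> list[PatientType]:
    """Return the 24 patient types in canonical order (AI arm first)."""
    out: list[PatientType] = []
    for i, (pd, burden, mri, pet, note) in enumerate(_AI_ARM_PATTERNS, start=1):
        out.append(PatientType(i, pd, burden, mri, pet, True, note))
    for i, (pd, burden, mri, pet, _) in enumerate(_AI_ARM_PATTERNS, start=13):
        out.append(
            PatientType(i, pd, burden, mri, pet, False, "Same as comparator (conventional PET strategy)")
        )
    return out


@dataclass(frozen=True)
class SubgroupCounts:
    """Expected counts of the eight (PD, burden, AI-outcome) subgroups.

    Counts are real-valued expectations over the full assessed cohort and
    sum to ``total``; round only for presentation.
    """

    a1: float  # PD, no burden, AI detected
    a2: float  # PD, no burden, AI missed
    b1: float  # non-PD, no burden, AI correctly excluded (avoided PET)
    b2: float  # non-PD, no burden, AI false positive
    c1: float  # PD, burden, AI detected (PET access enabled)
    c2: float  # PD, burden, AI missed
    d1: float  # non-PD, burden, AI correctly excluded
    d2: float  # non-PD, burden, AI false positive (unnecessary PET)
    total: float

    def as_dict(self) -> dict[str, float]:
        return {
            "A1": self.a1, "A2": self.a2, "B1": self.b1, "B2": self.b2,
            "C1": self.c1, "C2": self.c2, "D1": self.d1, "D2": self.d2,
        }

    def rounded(self) -> dict[str, int]:
        """Presentation form: half-up integer counts."""
        return {k: round_half_up(v) for k, v in self.as_dict().items()}

    def percentages(self) -> dict[str, float]:
        return {k: 100.0 * v / self.total for k, v in self.as_dict().items()}


def subgroup_counts(params: ParameterSet) -> SubgroupCounts:
    """Partition the full assessed cohort by PD status, burden and AI outcome.

    The partition describes the AI-assisted pathway applied to the whole
    cohort (no adoption factor): it answers "where would every patient land
    under AI triage", which is how the PET-utilisation subgroups are
    reported.
    """
    u = params.pet_unaffordable
    n_pd, n_non = params.n_pd, params.n_nonpd
    sens, spec = params.sens_ai, params.spec_ai
    return SubgroupCounts(
        a1=n_pd * (1 - u) * sens,
        a2=n_pd * (1 - u) * (1 - sens),
        b1=n_non * (1 - u) * spec,
        b2=n_non * (1 - u) * (1 - spec),
        c1=n_pd * u * sens,
        c2=n_pd * u * (1 - sens),
        d1=n_non * u * spec,
        d2=n_non * u * (1 - spec),
        total=params.n_total,
    )


def expected_type_counts(params: ParameterSet) -> dict[int, float]:
    """Expected count for each of the 24 types — an extrapolation.

    Only the 8-way collapse of :func:`subgroup_counts` is pinned down by the
    model's published outputs; per-type splits additionally require PET
    outcome probabilities.  This helper factorises PET detection
    independently of the MRI read, using ``sens_pet`` for PD patients and
    ``1 - spec_pet`` for non-PD patients, and assigns probability 1 to a
    "not performed" PET outcome.  Because the type list enumerates realised
    pathways rather than a full product space, the per-type masses within a
    stratum need not sum to that stratum's count; treat these numbers as
    illustrative, not as a partition.
    """
    u, a = params.pet_unaffordable, params.ai_adoption
    arm_w = {True: a, False: 1.0 - a}
    counts: dict[int, float] = {}
    for t in enumerate_patient_types():
        n_status = params.n_pd if t.pd_status else params.n_nonpd
        p_burden = u if t.economic_burden else 1.0 - u
        if t.pd_status:
            p_mri = params.sens_ai if t.mri_detection == _D else 1.0 - params.sens_ai
            p_pet = {_D: params.sens_pet, _ND: 1.0 - params.sens_pet, _NP: 1.0}[t.pet_detection]
        else:
            p_mri = (1.0 - params.spec_ai) if t.mri_detection == _D else params.spec_ai
            p_pet = {_D: 1.0 - params.spec_pet, _ND: params.spec_pet, _NP: 1.0}[t.pet_detection]
        counts[t.type_id] = n_status * p_burden * p_mri * p_pet * arm_w[t.ai_usage]
    return counts
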