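"""Model input parameters for the AI-triage cost-benefit model.

A :class:`ParameterSet` bundles every input of the one-year decision model:
the size and composition of the assessed cohort, diagnostic accuracies of
the AI-read MRI and of PET, unit costs, and the wage/time/transport inputs
that monetise non-medical burden under a societal perspective.

Three parameter files ship with the package (``korea``, ``korea_unrounded``,
``usa``).  The two Korea sets differ only in precision: the *verbatim* set
carries the rounded published inputs (AI cost 7 USD, AI specificity 0.917),
while the *unrounded* set carries the values the published result tables are
actually consistent with (AI cost 10,000 KRW / 1,416.54 KRW-per-USD ≈
7.0595 USD, specificity 0.9167).  Either reproduces the headline results to
within 0.03%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ParameterSet",
    "ParameterError",
    "load_parameters",
    "load_bundled",
    "bundled_names",
    "write_parameters",
    "derived_counts",
]

PERSPECTIVES = ("societal", "healthcare_system")

#: fields holding money amounts, convertible from local currency at load time
MONEY_FIELDS = (
    "cost_pet",
    "cost_ai",
    "cost_early",
    "cost_delayed",
    "wage_65plus",
    "transport_roundtrip",
)

_PROB_FIELDS = (
    "pd_dx_rate",
    "ai_adoption",
    "pet_unaffordable",
    "sens_ai",
    "spec_ai",
    "sens_pet",
    "spec_pet",
    "employment_65plus",
)

_NONNEG_FIELDS = MONEY_FIELDS + ("persons_per_visit", "hours_pet", "hours_visit")


class ParameterError(ValueError):
    """Raised when a parameter file or value fails validation."""


@dataclass(frozen=True)
class ParameterSet:
    """All inputs of the short-term cost-benefit model, in USD.

    Parameters
    ----------
    pd_dx_rate
        PD diagnostic rate among suspected outpatients entering the pathway,
        i.e. the prevalence of true PD in the assessed cohort; in (0, 1].
    n_pd
        Number of PD patients aged 65+ entering the pathway per year.
    ai_adoption
        Fraction of the cohort whose MRI is read with AI assistance.
    pet_unaffordable
        Fraction of patients facing an economic barrier to PET
        (out-of-pocket burden that would make them forgo the scan).
    sens_ai, spec_ai
        Sensitivity and specificity of the AI-read MRI.
    sens_pet, spec_pet
        Sensitivity and specificity of PET.  ``spec_pet`` is carried for
        completeness but enters no closed-form term; the microsimulator may
        use it for pathway realism only.
    cost_pet, cost_ai
        Unit cost per PET scan and per AI-assisted MRI read, USD.
    cost_early, cost_delayed
        Annual medical cost after early vs. delayed PD diagnosis, USD.
    persons_per_visit
        People travelling per imaging visit (patient plus caregiver).
    hours_pet, hours_visit
        Hours consumed by a PET visit / an outpatient visit.  ``hours_visit``
        is carried but unused by the closed-form terms.
    wage_65plus, employment_65plus
        Average hourly wage and employment rate of the 65+ population, used
        to monetise time under the societal perspective.
    transport_roundtrip
        Round-trip transportation cost per visit, USD.
    perspective
        ``societal`` includes time and transport terms; ``healthcare_system``
        restricts the model to direct medical costs.
    exchange_rate
        Local-currency units per USD; only used when a file declares
        ``currency: local``.
    label
        Free-text name of the scenario (e.g. the country).
    """

    pd_dx_rate: float
    n_pd: float
    ai_adoption: float
    pet_unaffordable: float
    sens_ai: float
    spec_ai: float
    sens_pet: float
    spec_pet: float
    cost_pet: float
    cost_ai: float
    cost_early: float
    cost_delayed: float
    persons_per_visit: float
    hours_pet: float
    hours_visit: float
    wage_65plus: float
    employment_65plus: float
    transport_roundtrip: float
    perspective: str = "societal"
    exchange_rate: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or math.isnan(v) or not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be a probability in [0, 1], got {v!r}")
        if self.pd_dx_rate <= 0.0:
            raise ParameterError(f"pd_dx_rate must be > 0, got {self.pd_dx_rate!r}")
        if not self.n_pd > 0:
            raise ParameterError(f"n_pd must be > 0, got {self.n_pd!r}")
        for name in _NONNEG_FIELDS:
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or math.isnan(v) or v < 0.0:
                raise ParameterError(f"{name} must be >= 0, got {v!r}")
        if self.perspective not in PERSPECTIVES:
            raise ParameterError(
                f"perspective must be one of {PERSPECTIVES}, got {self.perspective!r}"
            )
        if self.exchange_rate is not None and self.exchange_rate <= 0:
            raise ParameterError(f"exchange_rate must be > 0, got {self.exchange_rate!r}")

    # -- derived quantities -------------------------------------------------

    @property
    def n_nonpd(self) -> float:
        """Expected non-PD count in the assessed cohort."""
        return self.n_pd * (1.0 - self.pd_dx_rate) / self.pd_dx_rate

    @property
    def n_total(self) -> float:
        """Total assessed cohort size (PD plus non-PD)."""
        return self.n_pd / self.pd_dx_rate

    def replace(self, **changes: Any) -> "ParameterSet":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None:
                out[f.name] = v
        return out


def derived_counts(params: ParameterSet) -> tuple[float, float]:
    """Return ``(n_nonpd, n_total)`` for the assessed cohort.

    The model takes the yearly PD case count ``n_pd`` and the diagnostic
    rate ``pd_dx_rate`` among suspected outpatients as primitives; the
    non-PD count and the total cohort scale follow as
    ``n_pd * (1 - rate) / rate`` and ``n_pd / rate``.  Values are real
    (no rounding).
    """
    return params.n_nonpd, params.n_total


# -- file I/O ---------------------------------------------------------------

_REQUIRED_KEYS = {
    f.name
    for f in fields(ParameterSet)
    if f.name not in ("perspective", "exchange_rate", "label")
}


def _from_mapping(raw: dict[str, Any], source: str) -> ParameterSet:
    if not isinstance(raw, dict):
        raise ParameterError(f"{source}: expected a mapping of parameter names to values")
    raw = dict(raw)
    currency = str(raw.pop("currency", "USD"))
    unknown = set(raw) - {f.name for f in fields(ParameterSet)}
    if unknown:
        raise ParameterError(f"{source}: unknown keys {sorted(unknown)}")
    missing = _REQUIRED_KEYS - set(raw)
    if missing:
        raise ParameterError(f"{source}: missing required keys {sorted(missing)}")
    if currency.lower() == "local":
        rate = raw.get("exchange_rate")
        if not rate or rate <= 0:
            raise ParameterError(
                f"{source}: currency 'local' requires a positive exchange_rate"
            )
        for name in MONEY_FIELDS:
            raw[name] = raw[name] / rate
    elif currency.upper() != "USD":
        raise ParameterError(f"{source}: currency must be 'USD' or 'local', got {currency!r}")
    try:
        return ParameterSet(**raw)
    except TypeError as exc:  # non-numeric values and similar
        raise ParameterError(f"{source}: {exc}") from exc


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a parameter file (YAML or JSON).

    Keys are the :class:`ParameterSet` field names.  An optional
    ``currency: local`` key converts all money fields to USD by dividing
    by ``exchange_rate`` once at load time.
    """
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"parameter file not found: {path}")
    text = path.read_text()
    try:
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ParameterError(f"{path}: unparseable file: {exc}") from exc
    return _from_mapping(raw, str(path))


def bundled_names() -> list[str]:
    """Names accepted by :func:`load_bundled`."""
    pkg = resources.files(__package__) / "data"
    return sorted(p.name[: -len(".yaml")] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_bundled(name: str) -> ParameterSet:
    """Load one of the bundled parameter sets by name.

    Available: ``korea`` (published inputs verbatim), ``korea_unrounded``
    (precision-restored AI cost and specificity), ``usa``.
    """
    res = resources.files(__package__) / "data" / f"{name}.yaml"
    if not res.is_file():
        raise ParameterError(f"no bundled parameter set {name!r}; have {bundled_names()}")
    raw = yaml.safe_load(res.read_text())
    return _from_mapping(raw, f"bundled:{name}")


def write_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a ParameterSet to YAML (or JSON if the suffix is ``.json``).

    Round-trips bit-identically through :func:`load_parameters`: values are
    always written in USD with no ``currency`` marker.
    """
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
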