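"""Report rendering: the published-style result table and run bundles."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from .cohort import SubgroupCounts, round_half_up
from .economics import NON_MEDICAL_TERMS, TABLE_ROW_ORDER, ScenarioResult
from .scenarios import ProjectionSeries, SensitivityCurve

__all__ = ["render_table4", "render_subgroups", "ReportBundle"]


def _column_label(result: ScenarioResult) -> str:
    label = result.params.label or result.perspective
    return f"{label} AI ({100 * result.params.ai_adoption:g}%)"


def render_table4(results: list[ScenarioResult]) -> pd.DataFrame:
    """Render scenario results as the published-style cost-benefit table.

    One column per scenario, rows in publication order (MB/MC terms, then
    net benefit and B/C ratio).  Money is shown half-up to integer USD and
    the B/C ratio to two decimals; term cells zeroed by a
    healthcare-system perspective are left blank, as in the source table.
    Results must share one variant and one aggregation rule.
    """
    if results and len({(r.variant, r.aggregation) for r in results}) != 1:
        raise ValueError("results mix variants or aggregation rules; refusing to render")
    index = list(TABLE_ROW_ORDER) + ["Net benefit", "B/C ratio"]
    table = pd.DataFrame(index=index)
    for r in results:
        col: list[str] = []
        hs = r.perspective == "healthcare_system"
        for term_id in TABLE_ROW_ORDER:
            if hs and term_id in NON_MEDICAL_TERMS:
                col.append("")
            else:
                col.append(f"{round_half_up(r.term(term_id).value):,d}")
        col.append(f"{round_half_up(r.net_benefit):,d}")
        col.append(f"{r.bc_ratio:.2f}")
        table[_column_label(r)] = col
    return table


def render_subgroups(sub: SubgroupCounts) -> pd.DataFrame:
    """Subgroup counts with percentages of the total cohort."""
    rows = []
    for name, value in sub.as_dict().items():
        rows.append(
            {
                "subgroup": name,
                "expected_count": value,
                "count": round_half_up(value),
                "pct_of_total": round(100.0 * value / sub.total, 1),
            }
        )
    return pd.DataFrame(rows)


def _file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class ReportBundle:
    """A collection of rendered results plus the metadata to re-run them.

    The metadata records variant, aggregation, parameter provenance (file
    hashes) and any simulation seed, which is sufficient to regenerate
    every number bit-identically.
    """

    metadata: dict[str, Any] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    values: dict[str, Any] = field(default_factory=dict)

    def add_parameter_file(self, name: str, path: str | Path) -> None:
        self.metadata.setdefault("parameter_files", {})[name] = {
            "path": str(path),
            "sha256": _file_sha256(path),
        }

    def add_sensitivity(self, name: str, curve: SensitivityCurve) -> None:
        self.values[name] = {
            "parameter": curve.param_name,
            "grid": list(curve.grid),
            "net_benefit": list(curve.net_benefit),
            "ratio_pct": list(curve.ratio_pct),
            "base_net_benefit": curve.base_net_benefit,
        }

    def add_projection(self, name: str, series: ProjectionSeries) -> None:
        self.values[name] = {
            "years": list(series.years),
            "adoption": list(series.adoption),
            "n_pd": list(series.n_pd),
            "annual_net": list(series.annual_net),
            "cumulative_net": list(series.cumulative_net),
            "discount_rate": series.discount_rate,
        }

    def write(self, out_dir: str | Path) -> None:
        """Write all tables as CSV and the metadata/values as JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.csv")
        (out / "bundle.json").write_text(
            json.dumps({"metadata": self.metadata, "values": self.values}, indent=2)
        )
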