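"""Roll-ups of cell-level CHE risks and public-financing scenarios.

Aggregates average the modeled risks over all contributing
(country x service) cells — unweighted pooling by default, with an optional
country-first two-stage mean — and can be rendered in the conventional
"10% threshold (25% threshold in parentheses)" percent layout.  Financing
scenarios re-simulate selected services with a reduced OOP share under the
baseline seed, so per-cell risk reductions are free of Monte-Carlo noise.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import QUINTILES, InputBundle
from .errors import CheriskError, LinkageError, RangeError
from .simulate import RESULT_COLUMNS, SimulationConfig, run_simulation

GROUP_KEYS = {"disease": "disease_id", "service": "service_code",
              "disease_group": "disease_group"}

_STRATA = list(QUINTILES) + ["total"]


class RenderingError(CheriskError):
    """A table cannot be rendered (e.g. a threshold is missing)."""


@dataclass
class AggregateTable:
    """Mean risks per (group key, threshold, stratum) with cell counts."""

    group_by: str               # "disease" | "service" | "disease_group"
    mode: str                   # "pooled" | "country_first"
    table: pd.DataFrame         # columns: key, threshold, quintile, risk, n_cells


def aggregate(results: pd.DataFrame, group_by: str = "disease",
              mode: str = "pooled") -> AggregateTable:
    """Average cell risks within groups.

    ``mode="pooled"`` takes the unweighted mean over every contributing
    (country x service) cell; ``mode="country_first"`` averages within each
    country before averaging across countries.  ``n_cells`` always counts
    the contributing (country x service) cells.
    """
    if group_by not in GROUP_KEYS:
        raise ValueError(f"group_by must be one of {sorted(GROUP_KEYS)}")
    if mode not in ("pooled", "country_first"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if results.empty:
        raise ValueError("results must be non-empty")
    key = GROUP_KEYS[group_by]
    cells = results.groupby([key, "threshold", "quintile"], sort=False)
    n_cells = cells["risk"].size().rename("n_cells")
    if mode == "pooled":
        risk = cells["risk"].mean()
    else:
        risk = (results
                .groupby([key, "threshold", "quintile", "country_id"],
                         sort=False)["risk"].mean()
                .groupby([key, "threshold", "quintile"], sort=False).mean())
    table = (pd.concat([risk, n_cells], axis=1).reset_index()
             .rename(columns={key: "key"}))
    empty = table[table["n_cells"] == 0]
    if not empty.empty:  # pragma: no cover - groupby drops empty groups
        table = table[table["n_cells"] > 0]
    return AggregateTable(group_by=group_by, mode=mode, table=table)


def grand_mean(results: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean risk over all cells, per (threshold, quintile)."""
    return (results.groupby(["threshold", "quintile"], sort=False)["risk"]
            .mean().reset_index())


@dataclass
class ScenarioResult:
    """Baseline vs. public-financing scenario comparison."""

    label: str
    financed_services: tuple[str, ...]
    new_share: float
    baseline: pd.DataFrame
    scenario: pd.DataFrame
    comparison: pd.DataFrame    # adds scenario_risk and risk_reduction


def run_scenario(bundle: InputBundle, financed_services: Iterable[str],
                 new_share: float, config: SimulationConfig,
                 baseline: pd.DataFrame | None = None,
                 label: str = "public financing") -> ScenarioResult:
    """Re-simulate with the OOP share of financed services overridden.

    The scenario shares the baseline seed (and therefore income and
    utilization draws), so every cell's scenario risk is <= its baseline
    risk whenever ``new_share`` does not exceed the current share, exactly.
    Cells of unfinanced services are carried over from the baseline.
    """
    financed = tuple(financed_services)
    unknown = [s for s in financed if s not in bundle.services]
    if unknown:
        raise LinkageError(f"unknown service codes: {unknown}")
    if not 0 <= new_share <= 1:
        raise RangeError(f"new_share must lie in [0, 1], got {new_share}")
    if baseline is None:
        baseline = run_simulation(bundle, config)
    refreshed = run_simulation(bundle, config, services=financed,
                               oop_override={s: new_share for s in financed})
    keep = baseline[~baseline["service_code"].isin(financed)]
    scenario = pd.concat([keep, refreshed], ignore_index=True)

    idx = ["country_id", "service_code", "threshold", "quintile"]
    comparison = baseline.merge(
        scenario[idx + ["risk"]].rename(columns={"risk": "scenario_risk"}),
        on=idx, validate="one_to_one")
    comparison["risk_reduction"] = (comparison["risk"]
                                    - comparison["scenario_risk"])
    return ScenarioResult(label=label, financed_services=financed,
                          new_share=new_share, baseline=baseline,
                          scenario=scenario, comparison=comparison)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _percent(value: float) -> str:
    """Half-up rounding of a fraction to one decimal on the percent scale."""
    return str(Decimal(str(round(value * 100.0, 6)))
               .quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def render_cell(risk_10: float, risk_25: float) -> str:
    """Format a pair of risks as e.g. ``11.9 (2.6)``."""
    return f"{_percent(risk_10)} ({_percent(risk_25)})"


_CELL_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*\(\s*(\d+(?:\.\d+)?)\s*\)\s*$")


def parse_rendered_cell(text: str) -> tuple[float, float]:
    """Inverse of :func:`render_cell`; returns the rounded fractions."""
    m = _CELL_RE.match(text)
    if m is None:
        raise RenderingError(f"cannot parse rendered cell {text!r}")
    return float(m.group(1)) / 100.0, float(m.group(2)) / 100.0


def render_percent_tables(aggregates: AggregateTable,
                        row_order: Sequence[str] | None = None,
                        thresholds: tuple[float, float] = (0.10, 0.25)
                        ) -> pd.DataFrame:
    """Risk table in percent, primary threshold with the secondary in
    parentheses, one row per group key and columns Q1..Q5 plus Total.

    Rows follow ``row_order`` when given (unknown keys are skipped), else
    first appearance order.  An ``Average`` row holds the unweighted mean
    over the group means.
    """
    t10, t25 = thresholds
    table = aggregates.table
    have = set(np.round(table["threshold"].unique(), 12))
    for t in thresholds:
        if round(t, 12) not in have:
            raise RenderingError(f"aggregates lack threshold {t}")
    keys = list(dict.fromkeys(table["key"]))
    if row_order is not None:
        keys = [k for k in row_order if k in set(keys)]
    wide = table.pivot_table(index="key", columns=["threshold", "quintile"],
                             values="risk", sort=False)
    rows = []
    for k in keys:
        row = {"group": k}
        for stratum, header in zip(_STRATA, list(QUINTILES) + ["Total"]):
            row[header] = render_cell(wide.loc[k, (t10, stratum)],
                                      wide.loc[k, (t25, stratum)])
        rows.append(row)
    avg = {"group": "Average"}
    for stratum, header in zip(_STRATA, list(QUINTILES) + ["Total"]):
        avg[header] = render_cell(
            float(np.mean([wide.loc[k, (t10, stratum)] for k in keys])),
            float(np.mean([wide.loc[k, (t25, stratum)] for k in keys])))
    rows.append(avg)
    return pd.DataFrame(rows).set_index("group")
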