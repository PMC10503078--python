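"""Monte-Carlo engine for catastrophic health expenditure (CHE) risk.

For one (country, service) cell the model proceeds, per replicate:

1. draw ``n_individuals`` annual incomes from the country's calibrated gamma
   distribution — everyone simulated has the condition the service treats,
   so risks are conditional on disease;
2. assign wealth quintiles by sorted rank;
3. realize health-service use as an independent Bernoulli draw per
   individual with the quintile-specific utilization probability;
4. charge utilizers an out-of-pocket payment equal to the service's unit
   cost times the disease's OOP share (identical across quintiles);
5. flag CHE wherever the payment strictly exceeds threshold x income, for
   each threshold on the same draws.

The reported risk per (threshold, quintile) is the mean over replicates of
the per-replicate CHE proportion, with non-utilizers kept in the
denominator.  ``analytic_che_risk`` provides the closed-form infinite-
population limit (gamma CDF restricted to quintile probability bands) used
as an independent oracle in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .data_model import N_QUINTILES, QUINTILES, InputBundle
from .errors import LinkageError, RangeError
from .income import (IncomeModel, calibrate_income_model, quintile_sizes,
                     stream_rng)

RESULT_COLUMNS = ["country_id", "service_code", "disease_id", "disease_group",
                  "threshold", "quintile", "risk", "mc_stderr"]

DEFAULT_THRESHOLDS = (0.10, 0.25, 0.40)

_INCOME_STREAM = "__income_panel__"


@dataclass(frozen=True)
class SimulationConfig:
    """Population size, replicate count, CHE thresholds and root seed."""

    n_individuals: int = 1000
    n_samples: int = 1000
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    seed: int = 0
    reuse_income_panel: bool = True

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_samples < 1:
            raise ValueError("n_individuals and n_samples must be >= 1")
        if not self.thresholds:
            raise ValueError("at least one threshold is required")
        if any(not 0 < t <= 1 for t in self.thresholds):
            raise ValueError(f"thresholds must lie in (0, 1], "
                             f"got {self.thresholds}")


@dataclass(frozen=True)
class CHEResultCell:
    """Modeled CHE risk for one (country, service, threshold, stratum)."""

    country_id: str
    service_code: str
    disease_id: str
    threshold: float
    quintile: str          # "Q1".."Q5" or "total"
    risk: float
    mc_stderr: float

    def __post_init__(self):
        if not 0 <= self.risk <= 1:
            raise RangeError(f"risk must lie in [0, 1], got {self.risk}")


def oop_payment(unit_cost: float, oop_share: float) -> float:
    """Out-of-pocket payment: unit cost x disease OOP share (all quintiles
    pay the same share)."""
    if unit_cost < 0:
        raise RangeError(f"unit_cost must be >= 0, got {unit_cost}")
    if not 0 <= oop_share <= 1:
        raise RangeError(f"oop_share must lie in [0, 1], got {oop_share}")
    return unit_cost * oop_share


def is_che(payment: float, income, threshold: float):
    """True iff the payment strictly exceeds threshold x income.

    Boundary equality is not catastrophic.  ``income`` may be a scalar or an
    array; all incomes must be strictly positive.
    """
    if not 0 < threshold <= 1:
        raise RangeError(f"threshold must lie in (0, 1], got {threshold}")
    y = np.asarray(income, dtype=float)
    if (y <= 0).any():
        raise RangeError("income must be > 0")
    out = payment > threshold * y
    return bool(out) if np.isscalar(income) else out


def _quintile_slices(n: int) -> list[tuple[int, int]]:
    stops = np.cumsum(quintile_sizes(n))
    starts = np.concatenate([[0], stops[:-1]])
    return [(int(a), int(b)) for a, b in zip(starts, stops)]


def _draw_sorted_panel(model: IncomeModel, config: SimulationConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """(n_samples, n_individuals) incomes, sorted within each replicate.

    Sorting is the quintile assignment: after the row sort, the columns of
    each quintile's slice are exactly that replicate's quintile members.
    """
    panel = rng.gamma(shape=model.shape, scale=model.scale,
                      size=(config.n_samples, config.n_individuals))
    np.maximum(panel, np.finfo(float).tiny, out=panel)
    panel.sort(axis=1)
    return panel


def _panel_risks(sorted_panel: np.ndarray, payment: float,
                 utilization: np.ndarray, thresholds: Sequence[float],
                 rng: np.random.Generator):
    """Risks and MC standard errors from a sorted income panel.

    Returns {threshold: (risk_q, se_q, risk_total, se_total)}.  One set of
    utilization draws is shared across thresholds, which makes threshold
    monotonicity exact in every replicate.
    """
    n_rep, n = sorted_panel.shape
    slices = _quintile_slices(n)
    u_cols = np.empty(n)
    for q, (a, b) in enumerate(slices):
        u_cols[a:b] = utilization[q]
    used = rng.random((n_rep, n)) < u_cols
    # cumulative utilizer counts along the sorted income axis
    cum = np.zeros((n_rep, n + 1), dtype=np.int64)
    np.cumsum(used, axis=1, out=cum[:, 1:])
    rows = np.arange(n_rep)
    out = {}
    for t in thresholds:
        # CHE iff used and income < payment / t (strict); panel rows are
        # sorted, so the CHE region is the first `below` columns.
        below = (sorted_panel < payment / t).sum(axis=1)
        q_risk = np.empty(N_QUINTILES)
        q_se = np.empty(N_QUINTILES)
        total_counts = cum[rows, below]
        for q, (a, b) in enumerate(slices):
            counts = (cum[rows, np.minimum(b, below)]
                      - cum[rows, np.minimum(a, below)])
            props = counts / (b - a)
            q_risk[q] = props.mean()
            q_se[q] = (props.std(ddof=1) / np.sqrt(n_rep)
                       if n_rep > 1 else 0.0)
        total_props = total_counts / n
        total_se = (total_props.std(ddof=1) / np.sqrt(n_rep)
                    if n_rep > 1 else 0.0)
        out[t] = (q_risk, q_se, float(total_props.mean()), float(total_se))
    return out


def _cell_frame(country_id: str, service_code: str, disease_id: str,
                disease_group: str, risks: Mapping) -> pd.DataFrame:
    records = []
    for t, (q_risk, q_se, total, total_se) in risks.items():
        for q, label in enumerate(QUINTILES):
            records.append((country_id, service_code, disease_id,
                            disease_group, t, label,
                            float(q_risk[q]), float(q_se[q])))
        records.append((country_id, service_code, disease_id, disease_group,
                        t, "total", total, total_se))
    return pd.DataFrame.from_records(records, columns=RESULT_COLUMNS)


def simulate_cell(country_id: str, service_code: str, bundle: InputBundle,
                  config: SimulationConfig,
                  rng: np.random.Generator | None = None,
                  oop_override: Mapping[str, float] | None = None
                  ) -> pd.DataFrame:
    """Simulate one (country, service) cell.

    Returns a tidy frame with one row per threshold x (Q1..Q5, total).  When
    ``rng`` is omitted, income and utilization streams are derived
    deterministically from the config seed and the cell identifiers, so a
    cell's result does not depend on what else is simulated alongside it.
    """
    if country_id not in bundle.countries:
        raise LinkageError(f"unknown country {country_id!r}")
    if service_code not in bundle.services:
        raise LinkageError(f"unknown service {service_code!r}")
    country = bundle.countries[country_id]
    service = bundle.services[service_code]
    resolved = bundle.resolve(country_id, service_code)
    share = resolved.oop_share
    if oop_override and service_code in oop_override:
        share = oop_override[service_code]
    payment = oop_payment(resolved.unit_cost, share)
    model = calibrate_income_model(country.gni_per_capita, country.gini)

    if rng is not None:
        income_rng = util_rng = rng
    else:
        income_key = ((_INCOME_STREAM,) if config.reuse_income_panel
                      else (service_code, _INCOME_STREAM))
        income_rng = stream_rng(config.seed, country_id, *income_key)
        util_rng = stream_rng(config.seed, country_id, service_code)
    panel = _draw_sorted_panel(model, config, income_rng)
    risks = _panel_risks(panel, payment, resolved.utilization,
                         config.thresholds, util_rng)
    return _cell_frame(country_id, service_code, service.disease_id,
                       service.disease_group.value, risks)


def run_simulation(bundle: InputBundle, config: SimulationConfig,
                   countries: Iterable[str] | None = None,
                   services: Iterable[str] | None = None,
                   oop_override: Mapping[str, float] | None = None
                   ) -> pd.DataFrame:
    """Simulate every requested (country, service) cell.

    With ``reuse_income_panel`` (default) the income panel is drawn once per
    country and shared by all that country's services within a replicate;
    utilization is redrawn per service from its own stream.  ``oop_override``
    maps service codes to replacement OOP shares (used by financing
    scenarios).
    """
    country_ids = list(countries) if countries is not None \
        else list(bundle.countries)
    service_codes = list(services) if services is not None \
        else list(bundle.services)
    unknown = [c for c in country_ids if c not in bundle.countries]
    unknown += [s for s in service_codes if s not in bundle.services]
    if unknown:
        raise LinkageError(f"unknown identifiers: {unknown}")

    frames = []
    for cid in country_ids:
        country = bundle.countries[cid]
        model = calibrate_income_model(country.gni_per_capita, country.gini)
        shared_panel = None
        if config.reuse_income_panel:
            shared_panel = _draw_sorted_panel(
                model, config, stream_rng(config.seed, cid, _INCOME_STREAM))
        for code in service_codes:
            service = bundle.services[code]
            resolved = bundle.resolve(cid, code)
            share = resolved.oop_share
            if oop_override and code in oop_override:
                share = oop_override[code]
            payment = oop_payment(resolved.unit_cost, share)
            if shared_panel is not None:
                panel = shared_panel
            else:
                panel = _draw_sorted_panel(
                    model, config,
                    stream_rng(config.seed, cid, code, _INCOME_STREAM))
            risks = _panel_risks(panel, payment, resolved.utilization,
                                 config.thresholds,
                                 stream_rng(config.seed, cid, code))
            frames.append(_cell_frame(cid, code, service.disease_id,
                                      service.disease_group.value, risks))
    return pd.concat(frames, ignore_index=True)


def analytic_che_risk(income_model: IncomeModel, payment: float,
                      threshold: float,
                      utilization_by_quintile: Sequence[float],
                      n_individuals: int | None = None
                      ) -> tuple[np.ndarray, float]:
    """Closed-form CHE risk, per quintile and total.

    CHE requires use of the service and income below c = payment/threshold.
    In the infinite-population limit (default) quintile q occupies the
    probability band [(q-1)/5, q/5] of the income CDF F, so its risk is
    u_q x (min(F(c), q/5) - min(F(c), (q-1)/5)) x 5 and the total is the
    mean of the five quintile risks.

    With ``n_individuals`` given, the function instead returns the exact
    expectation of the finite-population estimator the simulation computes:
    in a sorted sample of n incomes the number below c is
    B ~ Binomial(n, F(c)), and the expected count falling in positions
    [a, b) is E[min(B, b)] - E[min(B, a)].  Near a quintile boundary this
    differs measurably from the band formula (the binomial spread smears
    counts across the edge), so it is the right oracle for comparing
    against simulated quintile risks at finite n.

    Returns (per-quintile risks, total risk).
    """
    if payment < 0:
        raise RangeError(f"payment must be >= 0, got {payment}")
    if not 0 < threshold <= 1:
        raise RangeError(f"threshold must lie in (0, 1], got {threshold}")
    u = np.asarray(utilization_by_quintile, dtype=float)
    if u.shape != (N_QUINTILES,):
        raise RangeError(f"expected {N_QUINTILES} utilization values")
    f_c = float(gamma_dist.cdf(payment / threshold, a=income_model.shape,
                               scale=income_model.scale))
    if n_individuals is None:
        edges = np.arange(N_QUINTILES + 1) / N_QUINTILES
        band_mass = np.minimum(f_c, edges[1:]) - np.minimum(f_c, edges[:-1])
        q_risk = u * band_mass * N_QUINTILES
        return q_risk, float(q_risk.mean())

    from scipy.stats import binom

    n = int(n_individuals)
    # E[min(B, k)] = k - sum_{j<k} CDF_B(j), prefix-summed once for all k.
    cdf = binom.cdf(np.arange(n), n, f_c)
    e_min = np.concatenate([[0.0], np.arange(1, n + 1) - np.cumsum(cdf)])
    slices = _quintile_slices(n)
    q_risk = np.array([u[q] * (e_min[b] - e_min[a]) / (b - a)
                       for q, (a, b) in enumerate(slices)])
    sizes = np.array([b - a for a, b in slices], dtype=float)
    total = float(np.dot(q_risk, sizes) / n)
    return q_risk, total
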