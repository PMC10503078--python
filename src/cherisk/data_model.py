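"""Domain types, CSV input handling, imputation and currency conversion.

The model takes four tabular inputs:

* ``countries.csv`` — one row per study country with its World Bank income
  group (LI or LMI), region, national-health-accounts (NHA) year, GNI per
  capita in 2016 USD and Gini index.
* ``services.csv`` — the catalog of costed primary-care services, each mapped
  to one of 13 disease areas (and through it to one of four broad disease
  groups), with unit costs for LI and LMI countries in 2016 USD.
* ``oop_shares.csv`` — the fraction of disease-specific health spending paid
  out of pocket (OOP) by households, per (country, disease area).
* ``utilization.csv`` — per (country, service), the probability that a person
  with the condition uses the service, by wealth quintile Q1..Q5.

Missing OOP-share or utilization cells are filled with unweighted regional
averages; utilization rows known only as a single flat rate are expanded with
the country's average wealth-quintile gradient.  Both fills are flagged so
downstream reports can distinguish empirical from imputed inputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGradientError,
    ImputationError,
    LinkageError,
    RangeError,
    SchemaError,
    SeriesLookupError,
)

N_QUINTILES = 5
QUINTILES = ("Q1", "Q2", "Q3", "Q4", "Q5")

COUNTRY_COLUMNS = ["country_id", "name", "income_group", "region", "nha_year",
                   "gni_per_capita", "gini", "gini_source_year"]
SERVICE_COLUMNS = ["code", "description", "disease_id", "disease_group",
                   "unit_cost_li", "unit_cost_lmi"]
OOP_COLUMNS = ["country_id", "disease_id", "share"]
UTIL_COLUMNS = ["country_id", "service_code",
                "u_q1", "u_q2", "u_q3", "u_q4", "u_q5"]


class IncomeGroup(str, Enum):
    LI = "LI"
    LMI = "LMI"


class DiseaseGroup(str, Enum):
    childhood = "childhood"
    infectious_parasitic = "infectious_parasitic"
    ncd = "ncd"
    reproductive = "reproductive"


class GradientSource(str, Enum):
    empirical = "empirical"
    country_average_gradient = "country_average_gradient"


@dataclass(frozen=True)
class CountryProfile:
    """Economic and classification inputs for one country."""

    country_id: str
    name: str
    income_group: IncomeGroup
    region: str
    nha_year: int
    gni_per_capita: float   # 2016 USD per person-year
    gini: float             # fraction in (0, 1)
    gini_source_year: int | None = None
    gini_imputed: bool = False

    def __post_init__(self):
        if self.gni_per_capita <= 0:
            raise RangeError(f"gni_per_capita must be > 0, got "
                             f"{self.gni_per_capita} for {self.country_id}")
        if not 0 < self.gini < 1:
            raise RangeError(f"gini must lie strictly in (0, 1), got "
                             f"{self.gini} for {self.country_id}")


@dataclass(frozen=True)
class HealthService:
    """A costed primary-care service mapped to a single disease area."""

    code: str
    description: str
    disease_id: str
    disease_group: DiseaseGroup
    unit_cost_li: float     # 2016 USD
    unit_cost_lmi: float    # 2016 USD

    def __post_init__(self):
        if self.unit_cost_li < 0 or self.unit_cost_lmi < 0:
            raise RangeError(f"unit costs must be >= 0 for {self.code}")


@dataclass(frozen=True)
class OopShare:
    share: float | None             # None = missing, to be imputed
    imputed: bool = False
    region_used: str | None = None

    def __post_init__(self):
        if self.share is not None and not 0 <= self.share <= 1:
            raise RangeError(f"OOP share must lie in [0, 1], got {self.share}")


@dataclass(frozen=True)
class UtilizationEntry:
    u: tuple[float, ...] | None     # five quintile probabilities, or None
    flat_value: float | None = None  # known only as a single rate
    imputed: bool = False
    region_used: str | None = None
    gradient_source: GradientSource = GradientSource.empirical

    def __post_init__(self):
        if self.u is not None:
            if len(self.u) != N_QUINTILES:
                raise SchemaError(f"expected {N_QUINTILES} quintile values, "
                                  f"got {len(self.u)}")
            if any(not 0 <= v <= 1 for v in self.u):
                raise RangeError(f"utilization probabilities must lie in "
                                 f"[0, 1], got {self.u}")
        if self.flat_value is not None and not 0 <= self.flat_value <= 1:
            raise RangeError(f"flat utilization must lie in [0, 1], "
                             f"got {self.flat_value}")


class OopShareTable:
    """Entries keyed by (country_id, disease_id) -> OOP share in [0, 1]."""

    def __init__(self, entries: Mapping[tuple[str, str], OopShare]):
        self.entries: dict[tuple[str, str], OopShare] = dict(entries)

    def share_for(self, country_id: str, disease_id: str) -> float:
        try:
            entry = self.entries[(country_id, disease_id)]
        except KeyError:
            raise LinkageError(f"no OOP share for country={country_id}, "
                               f"disease={disease_id}") from None
        if entry.share is None:
            raise LinkageError(f"OOP share for country={country_id}, "
                               f"disease={disease_id} is missing (not imputed)")
        return entry.share

    def missing_keys(self) -> list[tuple[str, str]]:
        return [k for k, e in self.entries.items() if e.share is None]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"country_id": c, "disease_id": d,
             "share": "" if e.share is None else repr(e.share),
             "imputed": int(e.imputed),
             "region_used": e.region_used or ""}
            for (c, d), e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=OOP_COLUMNS + ["imputed",
                                                         "region_used"])

    def __eq__(self, other):
        return isinstance(other, OopShareTable) and self.entries == other.entries


class UtilizationTable:
    """Entries keyed by (country_id, service_code) -> five quintile rates."""

    def __init__(self, entries: Mapping[tuple[str, str], UtilizationEntry]):
        self.entries: dict[tuple[str, str], UtilizationEntry] = dict(entries)

    def utilization_for(self, country_id: str, service_code: str) -> np.ndarray:
        try:
            entry = self.entries[(country_id, service_code)]
        except KeyError:
            raise LinkageError(f"no utilization for country={country_id}, "
                               f"service={service_code}") from None
        if entry.u is None:
            raise LinkageError(f"utilization for country={country_id}, "
                               f"service={service_code} is unresolved")
        return np.asarray(entry.u, dtype=float)

    def missing_keys(self) -> list[tuple[str, str]]:
        return [k for k, e in self.entries.items()
                if e.u is None and e.flat_value is None]

    def flat_keys(self) -> list[tuple[str, str]]:
        return [k for k, e in self.entries.items()
                if e.u is None and e.flat_value is not None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (c, s), e in sorted(self.entries.items()):
            row = {"country_id": c, "service_code": s}
            for i, q in enumerate(("u_q1", "u_q2", "u_q3", "u_q4", "u_q5")):
                row[q] = "" if e.u is None else repr(e.u[i])
            row["flat_value"] = "" if e.flat_value is None else repr(e.flat_value)
            row["imputed"] = int(e.imputed)
            row["region_used"] = e.region_used or ""
            row["gradient_source"] = e.gradient_source.value
            rows.append(row)
        return pd.DataFrame(rows, columns=UTIL_COLUMNS + [
            "flat_value", "imputed", "region_used", "gradient_source"])

    def __eq__(self, other):
        return (isinstance(other, UtilizationTable)
                and self.entries == other.entries)


@dataclass(frozen=True)
class CurrencySeries:
    """US CPI index by year and local-currency-per-USD FX rates."""

    cpi: Mapping[int, float]
    fx: Mapping[tuple[str, int], float]

    def __post_init__(self):
        if any(v <= 0 for v in self.cpi.values()):
            raise RangeError("CPI values must be > 0")
        if any(v <= 0 for v in self.fx.values()):
            raise RangeError("FX rates must be > 0")
        if 2016 not in self.cpi:
            raise SchemaError("CPI series must contain the base year 2016")


@dataclass(frozen=True)
class ResolvedInputs:
    """Everything needed to simulate one (country, service) cell."""

    unit_cost: float
    oop_share: float
    utilization: np.ndarray  # shape (5,), Q1..Q5


# ---------------------------------------------------------------------------
# CSV loading
# ---------------------------------------------------------------------------

def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise SchemaError(f"cannot read CSV: {exc}", file=str(path)) from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns {missing}",
                          file=str(path))
    if len(df) == 0:
        raise SchemaError("table has a header but no rows", file=str(path))
    return df


def _parse_float(raw: str, *, file: str, row: int, column: str) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise SchemaError(f"not a number: {raw!r}", file=file, row=row,
                          column=column) from None


def _parse_int(raw: str, *, file: str, row: int, column: str) -> int | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return int(raw)
    except ValueError:
        raise SchemaError(f"not an integer: {raw!r}", file=file, row=row,
                          column=column) from None


def load_countries(path: str | Path) -> dict[str, CountryProfile]:
    """Load and validate the country table.

    A Gini printed on the percent scale (value > 1) is divided by 100 on
    load; a missing Gini is filled with the unweighted regional average of
    the non-missing countries (flagged ``gini_imputed``).
    """
    df = _read_csv(path, COUNTRY_COLUMNS)
    fname = str(path)
    raw_rows: list[dict] = []
    for i, rec in enumerate(df.to_dict("records")):
        row_no = i + 2  # 1-based, after the header
        gni = _parse_float(rec["gni_per_capita"], file=fname, row=row_no,
                           column="gni_per_capita")
        if gni is None or gni <= 0:
            raise RangeError(f"gni_per_capita must be > 0, got {gni}",
                             file=fname, row=row_no, column="gni_per_capita")
        gini = _parse_float(rec["gini"], file=fname, row=row_no, column="gini")
        if gini is not None:
            # Accept the printed percent scale (e.g. 47.3) as well as the
            # fraction scale; values in (1, 2) are neither and are rejected.
            if gini >= 2:
                gini = gini / 100.0
            if not 0 < gini < 1:
                raise RangeError(f"gini must lie strictly in (0, 1) "
                                 f"(or 2-100 on the percent scale), got "
                                 f"{gini}", file=fname, row=row_no,
                                 column="gini")
        group_raw = rec["income_group"].strip()
        if group_raw not in (g.value for g in IncomeGroup):
            raise SchemaError(f"income_group must be LI or LMI, got "
                              f"{group_raw!r}", file=fname, row=row_no,
                              column="income_group")
        nha_year = _parse_int(rec["nha_year"], file=fname, row=row_no,
                              column="nha_year")
        if nha_year is None:
            raise SchemaError("nha_year is required", file=fname, row=row_no,
                              column="nha_year")
        raw_rows.append({
            "country_id": rec["country_id"].strip(),
            "name": rec["name"].strip(),
            "income_group": IncomeGroup(group_raw),
            "region": rec["region"].strip(),
            "nha_year": nha_year,
            "gni_per_capita": gni,
            "gini": gini,
            "gini_source_year": _parse_int(rec["gini_source_year"], file=fname,
                                           row=row_no,
                                           column="gini_source_year"),
            "gini_imputed": rec.get("gini_imputed", "0").strip()
                            in ("1", "True", "true"),
        })

    # Regional-average fallback for missing Gini.
    by_region: dict[str, list[float]] = {}
    for r in raw_rows:
        if r["gini"] is not None:
            by_region.setdefault(r["region"], []).append(r["gini"])
    countries: dict[str, CountryProfile] = {}
    for r in raw_rows:
        if r["gini"] is None:
            pool = by_region.get(r["region"], [])
            if not pool:
                raise ImputationError(
                    f"no Gini available anywhere in region "
                    f"{r['region']!r} to impute {r['country_id']}",
                    file=fname)
            r["gini"] = float(np.mean(pool))
            r["gini_imputed"] = True
        cid = r["country_id"]
        if cid in countries:
            raise SchemaError(f"duplicate country_id {cid!r}", file=fname)
        countries[cid] = CountryProfile(**r)
    return countries


def load_services(path: str | Path) -> dict[str, HealthService]:
    df = _read_csv(path, SERVICE_COLUMNS)
    fname = str(path)
    services: dict[str, HealthService] = {}
    disease_to_group: dict[str, DiseaseGroup] = {}
    for i, rec in enumerate(df.to_dict("records")):
        row_no = i + 2
        group_raw = rec["disease_group"].strip()
        if group_raw not in (g.value for g in DiseaseGroup):
            raise SchemaError(f"unknown disease_group {group_raw!r}",
                              file=fname, row=row_no, column="disease_group")
        costs = {}
        for col in ("unit_cost_li", "unit_cost_lmi"):
            v = _parse_float(rec[col], file=fname, row=row_no, column=col)
            if v is None or v < 0:
                raise RangeError(f"{col} must be >= 0, got {v}", file=fname,
                                 row=row_no, column=col)
            costs[col] = v
        svc = HealthService(
            code=rec["code"].strip(),
            description=rec["description"].strip(),
            disease_id=rec["disease_id"].strip(),
            disease_group=DiseaseGroup(group_raw),
            **costs,
        )
        if svc.code in services:
            raise SchemaError(f"duplicate service code {svc.code!r}",
                              file=fname, row=row_no, column="code")
        prior = disease_to_group.setdefault(svc.disease_id, svc.disease_group)
        if prior != svc.disease_group:
            raise SchemaError(
                f"disease {svc.disease_id!r} mapped to two groups "
                f"({prior.value}, {svc.disease_group.value})",
                file=fname, row=row_no, column="disease_group")
        services[svc.code] = svc
    return services


def load_oop_shares(path: str | Path) -> OopShareTable:
    df = _read_csv(path, OOP_COLUMNS)
    fname = str(path)
    entries: dict[tuple[str, str], OopShare] = {}
    for i, rec in enumerate(df.to_dict("records")):
        row_no = i + 2
        share = _parse_float(rec["share"], file=fname, row=row_no,
                             column="share")
        if share is not None and not 0 <= share <= 1:
            raise RangeError(f"share must lie in [0, 1], got {share}",
                             file=fname, row=row_no, column="share")
        imputed = rec.get("imputed", "0").strip() in ("1", "True", "true")
        region_used = rec.get("region_used", "").strip() or None
        entries[(rec["country_id"].strip(), rec["disease_id"].strip())] = \
            OopShare(share=share, imputed=imputed, region_used=region_used)
    return OopShareTable(entries)


def load_utilization(path: str | Path) -> UtilizationTable:
    """Load utilization rates.

    A row with only ``u_q1`` filled (or a ``flat_value`` column) is treated as
    a flat, quintile-less rate awaiting gradient expansion; a fully empty row
    is a missing entry awaiting regional imputation.
    """
    df = _read_csv(path, UTIL_COLUMNS)
    fname = str(path)
    qcols = ["u_q1", "u_q2", "u_q3", "u_q4", "u_q5"]
    entries: dict[tuple[str, str], UtilizationEntry] = {}
    for i, rec in enumerate(df.to_dict("records")):
        row_no = i + 2
        vals = [_parse_float(rec[c], file=fname, row=row_no, column=c)
                for c in qcols]
        for c, v in zip(qcols, vals):
            if v is not None and not 0 <= v <= 1:
                raise RangeError(f"{c} must lie in [0, 1], got {v}",
                                 file=fname, row=row_no, column=c)
        flat = _parse_float(rec.get("flat_value", ""), file=fname, row=row_no,
                            column="flat_value")
        n_present = sum(v is not None for v in vals)
        if n_present == N_QUINTILES:
            u: tuple[float, ...] | None = tuple(vals)  # type: ignore[arg-type]
        elif n_present == 1 and vals[0] is not None and flat is None:
            u, flat = None, vals[0]
        elif n_present == 0:
            u = None
        else:
            raise SchemaError(
                "utilization row must have all five quintile values, a "
                "single u_q1 (flat rate), or none", file=fname, row=row_no)
        imputed = rec.get("imputed", "0").strip() in ("1", "True", "true")
        region_used = rec.get("region_used", "").strip() or None
        gsrc = rec.get("gradient_source", "").strip() or "empirical"
        entries[(rec["country_id"].strip(), rec["service_code"].strip())] = \
            UtilizationEntry(u=u, flat_value=flat, imputed=imputed,
                             region_used=region_used,
                             gradient_source=GradientSource(gsrc))
    return UtilizationTable(entries)


# ---------------------------------------------------------------------------
# Imputation and gradient expansion
# ---------------------------------------------------------------------------

def impute_regional_average(table, region_map: Mapping[str, str]):
    """Fill missing entries with the unweighted same-region, same-key mean.

    ``table`` is an :class:`OopShareTable` (key = disease area) or a
    :class:`UtilizationTable` (key = service code, averaged per quintile).
    Returns a new table; entries filled here carry ``imputed=True`` and the
    region used.  Raises :class:`ImputationError` when an entire region has
    no donor value for a key.
    """
    if isinstance(table, OopShareTable):
        donors: dict[tuple[str, str], list[float]] = {}
        for (cid, key), e in table.entries.items():
            if e.share is not None:
                donors.setdefault((region_map[cid], key), []).append(e.share)
        out: dict[tuple[str, str], OopShare] = {}
        for (cid, key), e in table.entries.items():
            if e.share is None:
                region = region_map[cid]
                pool = donors.get((region, key))
                if not pool:
                    raise ImputationError(
                        f"no donor values in region {region!r} for "
                        f"disease {key!r}")
                out[(cid, key)] = OopShare(share=float(np.mean(pool)),
                                           imputed=True, region_used=region)
            else:
                out[(cid, key)] = e
        return OopShareTable(out)

    if isinstance(table, UtilizationTable):
        udonors: dict[tuple[str, str], list[tuple[float, ...]]] = {}
        for (cid, key), e in table.entries.items():
            if e.u is not None:
                udonors.setdefault((region_map[cid], key), []).append(e.u)
        uout: dict[tuple[str, str], UtilizationEntry] = {}
        for (cid, key), e in table.entries.items():
            if e.u is None and e.flat_value is None:
                region = region_map[cid]
                pool = udonors.get((region, key))
                if not pool:
                    raise ImputationError(
                        f"no donor values in region {region!r} for "
                        f"service {key!r}")
                mean_u = tuple(np.mean(pool, axis=0).tolist())
                uout[(cid, key)] = replace(e, u=mean_u, imputed=True,
                                           region_used=region)
            else:
                uout[(cid, key)] = e
        return UtilizationTable(uout)

    raise TypeError(f"unsupported table type {type(table).__name__}")


def apply_average_gradient(flat_value: float,
                           country_gradient_by_quintile: Sequence[float]
                           ) -> np.ndarray:
    """Spread a flat utilization rate across quintiles.

    The gradient is rescaled to mean one, multiplied by ``flat_value`` and
    clipped to [0, 1]; absent clipping the mean of the result equals the
    flat rate.
    """
    if not 0 <= flat_value <= 1:
        raise RangeError(f"flat_value must lie in [0, 1], got {flat_value}")
    g = np.asarray(country_gradient_by_quintile, dtype=float)
    if g.shape != (N_QUINTILES,):
        raise SchemaError(f"gradient must have {N_QUINTILES} values, "
                          f"got shape {g.shape}")
    if (g < 0).any():
        raise RangeError("gradient values must be non-negative")
    mean = g.mean()
    if mean == 0:
        raise DegenerateGradientError("gradient mean is zero")
    return np.clip(flat_value * g / mean, 0.0, 1.0)


def country_average_gradient(table: UtilizationTable,
                             country_id: str,
                             region_map: Mapping[str, str] | None = None
                             ) -> np.ndarray:
    """Average wealth-quintile gradient (mean-one) for a country.

    Averages the mean-normalized gradients of the country's empirical
    five-value rows; falls back to the region, then to all countries, and
    finally to a uniform gradient when no empirical row exists anywhere.
    """
    def pool(keys: Iterable[tuple[str, str]]) -> np.ndarray | None:
        grads = []
        for k in keys:
            e = table.entries[k]
            if e.u is not None and e.gradient_source is GradientSource.empirical:
                u = np.asarray(e.u, dtype=float)
                if u.mean() > 0:
                    grads.append(u / u.mean())
        return np.mean(grads, axis=0) if grads else None

    own = pool(k for k in table.entries if k[0] == country_id)
    if own is not None:
        return own
    if region_map is not None:
        region = region_map.get(country_id)
        regional = pool(k for k in table.entries
                        if region_map.get(k[0]) == region)
        if regional is not None:
            return regional
    everyone = pool(table.entries.keys())
    if everyone is not None:
        return everyone
    return np.ones(N_QUINTILES)


def expand_flat_utilization(table: UtilizationTable,
                            region_map: Mapping[str, str] | None = None
                            ) -> UtilizationTable:
    """Turn flat-rate rows into five quintile values via average gradients."""
    out = dict(table.entries)
    for key in table.flat_keys():
        cid, _ = key
        grad = country_average_gradient(table, cid, region_map)
        e = table.entries[key]
        u = tuple(apply_average_gradient(e.flat_value, grad).tolist())
        out[key] = replace(e, u=u, flat_value=e.flat_value,
                           gradient_source=GradientSource.country_average_gradient)
    return UtilizationTable(out)


# ---------------------------------------------------------------------------
# Currency conversion
# ---------------------------------------------------------------------------

def convert_to_2016_usd(amount: float, currency: str, year: int,
                        series: CurrencySeries) -> float:
    """Convert a nominal local-currency amount to 2016 USD.

    FX conversion (local currency per USD, skipped for USD amounts) comes
    first, then deflation by the US CPI ratio cpi(2016)/cpi(year).
    """
    if amount < 0:
        raise RangeError(f"amount must be >= 0, got {amount}")
    if year not in series.cpi:
        raise SeriesLookupError(f"CPI series has no year {year}")
    if currency != "USD":
        rate = series.fx.get((currency, year))
        if rate is None:
            raise SeriesLookupError(f"FX series has no rate for "
                                    f"({currency}, {year})")
        amount = amount / rate
    return amount * (series.cpi[2016] / series.cpi[year])


def unit_cost_for(service: HealthService, country: CountryProfile) -> float:
    """Unit cost in 2016 USD for the country's income group."""
    if country.income_group is IncomeGroup.LI:
        return service.unit_cost_li
    return service.unit_cost_lmi


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class InputBundle:
    """All validated inputs needed to run the simulation."""

    countries: dict[str, CountryProfile]
    services: dict[str, HealthService]
    oop_shares: OopShareTable
    utilization: UtilizationTable

    @property
    def diseases(self) -> list[str]:
        seen: dict[str, None] = {}
        for svc in self.services.values():
            seen.setdefault(svc.disease_id, None)
        return list(seen)

    def region_map(self) -> dict[str, str]:
        return {cid: c.region for cid, c in self.countries.items()}

    def resolve(self, country_id: str, service_code: str) -> ResolvedInputs:
        try:
            country = self.countries[country_id]
            service = self.services[service_code]
        except KeyError as exc:
            raise LinkageError(f"unknown identifier {exc.args[0]!r}") from None
        return ResolvedInputs(
            unit_cost=unit_cost_for(service, country),
            oop_share=self.oop_shares.share_for(country_id,
                                                service.disease_id),
            utilization=self.utilization.utilization_for(country_id,
                                                         service_code),
        )

    def validate(self) -> "InputBundle":
        for cid in self.countries:
            for code in self.services:
                self.resolve(cid, code)  # raises LinkageError if unresolvable
        return self

    def write_csvs(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "countries": directory / "countries.csv",
            "services": directory / "services.csv",
            "oop_shares": directory / "oop_shares.csv",
            "utilization": directory / "utilization.csv",
        }
        crows = []
        for c in self.countries.values():
            crows.append({
                "country_id": c.country_id, "name": c.name,
                "income_group": c.income_group.value, "region": c.region,
                "nha_year": c.nha_year, "gni_per_capita": repr(c.gni_per_capita),
                "gini": repr(c.gini),
                "gini_source_year": "" if c.gini_source_year is None
                                    else c.gini_source_year,
                "gini_imputed": int(c.gini_imputed),
            })
        pd.DataFrame(crows).to_csv(paths["countries"], index=False)
        srows = [{
            "code": s.code, "description": s.description,
            "disease_id": s.disease_id, "disease_group": s.disease_group.value,
            "unit_cost_li": repr(s.unit_cost_li),
            "unit_cost_lmi": repr(s.unit_cost_lmi),
        } for s in self.services.values()]
        pd.DataFrame(srows).to_csv(paths["services"], index=False)
        self.oop_shares.to_frame().to_csv(paths["oop_shares"], index=False)
        self.utilization.to_frame().to_csv(paths["utilization"], index=False)
        return paths


def packaged_fixture_path(name: str) -> Path:
    """Path to a CSV shipped with the package (table1_countries,
    table3_services)."""
    return Path(resources.files("cherisk").joinpath("data", f"{name}.csv"))


def load_inputs(countries_path: str | Path, services_path: str | Path,
                oop_path: str | Path, util_path: str | Path) -> InputBundle:
    """Load, validate, impute and link all four input tables.

    After loading, any (country, disease-area) pair required by the service
    catalog but absent from the OOP table — and any (country, service) pair
    absent from the utilization table — is added as missing and filled by
    regional-average imputation; flat utilization rows are expanded with the
    country's average wealth-quintile gradient.
    """
    countries = load_countries(countries_path)
    services = load_services(services_path)
    oop = load_oop_shares(oop_path)
    util = load_utilization(util_path)
    region_map = {cid: c.region for cid, c in countries.items()}

    diseases = {svc.disease_id for svc in services.values()}
    oop_entries = dict(oop.entries)
    for cid in countries:
        for d in diseases:
            oop_entries.setdefault((cid, d), OopShare(share=None))
    util_entries = dict(util.entries)
    for cid in countries:
        for code in services:
            util_entries.setdefault((cid, code), UtilizationEntry(u=None))

    util_table = expand_flat_utilization(UtilizationTable(util_entries),
                                         region_map)
    bundle = InputBundle(
        countries=countries,
        services=services,
        oop_shares=impute_regional_average(OopShareTable(oop_entries),
                                           region_map),
        utilization=impute_regional_average(util_table, region_map),
    )
    return bundle.validate()
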