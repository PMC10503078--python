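"""Synthetic stand-ins for the inputs without a published table.

Two of the four model inputs — disease-specific OOP shares and
quintile-specific utilization rates — come from country NHA reports and
survey proxies that are not published alongside the country and service
tables.  This module generates statistically structured replacements so
every pipeline stage runs and is testable end to end:

* OOP shares are Beta-distributed around disease-level means ordered the way
  the real data behave qualitatively (NCD care paid largely out of pocket;
  childhood and reproductive services heavily subsidized).  The means are
  illustrative, not fitted to any country's accounts.
* Utilization follows a logit-linear wealth gradient,
  ``u_q = expit(base + slope x (q - 3))`` with slope >= 0, giving monotone
  non-decreasing rates from the poorest to the richest quintile.  Real
  survey gradients need not be monotone; ``nonmonotone_noise_sd`` injects
  logit-scale noise to emulate that.
* Optional synthetic country profiles stay inside the GNI and Gini ranges
  observed across the 34 study countries.

Missing cells can be injected at a configurable rate to exercise the
regional-average imputation path.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .data_model import (CountryProfile, GradientSource, HealthService,
                         IncomeGroup, InputBundle, N_QUINTILES, OopShare,
                         OopShareTable, UtilizationEntry, UtilizationTable,
                         impute_regional_average, load_countries,
                         load_services, packaged_fixture_path)
from .errors import RangeError

# Disease-level mean OOP shares (fractions). Ordered qualitatively: NCDs
# highest, infectious in between, childhood and most reproductive care
# lowest; illustrative defaults, not estimates.
DEFAULT_OOP_MEANS: dict[str, float] = {
    "childhood_health": 0.10,
    "diarrheal_diseases": 0.15,
    "hiv_aids_sti": 0.15,
    "malaria": 0.10,
    "other_infectious_parasitic": 0.25,
    "tuberculosis": 0.45,
    "cardiovascular": 0.55,
    "endocrine_metabolic": 0.45,
    "mental_neurological": 0.60,
    "other_ncd": 0.40,
    "family_planning": 0.10,
    "maternal_conditions": 0.20,
    "perinatal_conditions": 0.15,
}
FALLBACK_OOP_MEAN = 0.30

DEFAULT_REGIONS = ("Sub-Saharan Africa", "South Asia", "East Asia & Pacific")


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs for the synthetic input generator.

    GNI ranges default to the min/max observed per income group across the
    study countries (LI 230-903, LMI 1081-3508 USD 2016), Gini to the
    observed 0.296-0.54.
    """

    n_countries: int = 12
    regions: tuple[str, ...] = DEFAULT_REGIONS
    li_fraction: float = 0.5
    gni_range_li: tuple[float, float] = (230.0, 903.0)
    gni_range_lmi: tuple[float, float] = (1081.0, 3508.0)
    gini_range: tuple[float, float] = (0.296, 0.54)
    oop_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OOP_MEANS))
    oop_concentration: float = 12.0     # Beta a+b; larger = tighter
    util_base_logit: float = -1.0       # expit(-1) ~ 0.27 mean usage
    util_base_sd: float = 0.75          # country x service spread (logit)
    util_slope_range: tuple[float, float] = (0.0, 0.6)  # per-service slope
    nonmonotone_noise_sd: float = 0.0   # logit-scale noise breaking monotony
    missingness: float = 0.0

    def __post_init__(self):
        if self.n_countries < 1:
            raise RangeError("n_countries must be >= 1")
        if not 0 <= self.missingness < 1:
            raise RangeError("missingness must lie in [0, 1)")
        if not 0 <= self.li_fraction <= 1:
            raise RangeError("li_fraction must lie in [0, 1]")
        lo, hi = self.gini_range
        if not 0 < lo <= hi < 1:
            raise RangeError("gini_range must lie inside (0, 1)")
        if self.util_slope_range[0] < 0:
            raise RangeError("utilization gradient slopes must be >= 0")


def generate_country_profiles(spec: SyntheticSpec, rng: np.random.Generator
                              ) -> dict[str, CountryProfile]:
    """Synthetic country set with GNI/Gini inside the study ranges."""
    n_li = int(round(spec.n_countries * spec.li_fraction))
    countries: dict[str, CountryProfile] = {}
    for i in range(spec.n_countries):
        group = IncomeGroup.LI if i < n_li else IncomeGroup.LMI
        lo, hi = (spec.gni_range_li if group is IncomeGroup.LI
                  else spec.gni_range_lmi)
        cid = f"SYN{i + 1:02d}"
        countries[cid] = CountryProfile(
            country_id=cid,
            name=f"Synthetic country {i + 1}",
            income_group=group,
            region=spec.regions[i % len(spec.regions)],
            nha_year=int(rng.integers(2010, 2019)),
            gni_per_capita=float(rng.uniform(lo, hi)),
            gini=float(rng.uniform(*spec.gini_range)),
        )
    return countries


def generate_oop_shares(spec: SyntheticSpec,
                        countries: Mapping[str, CountryProfile],
                        diseases: Sequence[str],
                        rng: np.random.Generator) -> OopShareTable:
    """Beta-distributed OOP shares with disease-specific means; cells are
    knocked out at the spec missingness rate (for imputation testing)."""
    if not diseases:
        raise RangeError("disease list must be non-empty")
    entries: dict[tuple[str, str], OopShare] = {}
    for d in diseases:
        mean = spec.oop_means.get(d, FALLBACK_OOP_MEAN)
        a = mean * spec.oop_concentration
        b = (1.0 - mean) * spec.oop_concentration
        for cid in countries:
            if rng.random() < spec.missingness:
                entries[(cid, d)] = OopShare(share=None)
            else:
                entries[(cid, d)] = OopShare(share=float(rng.beta(a, b)))
    return OopShareTable(entries)


def generate_utilization(spec: SyntheticSpec,
                         countries: Mapping[str, CountryProfile],
                         services: Sequence[str],
                         rng: np.random.Generator) -> UtilizationTable:
    """Logit-linear wealth gradients, monotone non-decreasing Q1 -> Q5
    unless ``nonmonotone_noise_sd`` > 0."""
    if not len(services):
        raise RangeError("service list must be non-empty")
    q_centered = np.arange(1, N_QUINTILES + 1) - 3  # -2..2
    slopes = {s: float(rng.uniform(*spec.util_slope_range)) for s in services}
    entries: dict[tuple[str, str], UtilizationEntry] = {}
    for code in services:
        for cid in countries:
            if rng.random() < spec.missingness:
                entries[(cid, code)] = UtilizationEntry(u=None)
                continue
            base = rng.normal(spec.util_base_logit, spec.util_base_sd)
            logits = base + slopes[code] * q_centered
            if spec.nonmonotone_noise_sd > 0:
                logits = logits + rng.normal(0.0, spec.nonmonotone_noise_sd,
                                             size=N_QUINTILES)
            entries[(cid, code)] = UtilizationEntry(
                u=tuple(expit(logits).tolist()))
    return UtilizationTable(entries)


def logit_gradient(base: float, slope: float) -> np.ndarray:
    """The five quintile rates expit(base + slope x (q - 3)), q = 1..5."""
    return expit(base + slope * (np.arange(1, N_QUINTILES + 1) - 3))


def generate_bundle(spec: SyntheticSpec, seed: int = 0,
                    countries: Mapping[str, CountryProfile] | None = None,
                    services: Mapping[str, HealthService] | None = None
                    ) -> InputBundle:
    """Fully synthetic, validated input bundle.

    Injected missing cells are filled by the same regional-average
    imputation the CSV loaders apply, so the result always validates.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    if countries is None:
        countries = generate_country_profiles(spec, rng)
    if services is None:
        services = load_services(packaged_fixture_path("table3_services"))
    diseases = sorted({s.disease_id for s in services.values()})
    oop = generate_oop_shares(spec, countries, diseases, rng)
    util = generate_utilization(spec, countries, list(services), rng)
    region_map = {cid: c.region for cid, c in countries.items()}
    bundle = InputBundle(
        countries=dict(countries),
        services=dict(services),
        oop_shares=impute_regional_average(oop, region_map),
        utilization=impute_regional_average(util, region_map),
    )
    return bundle.validate()


def make_fixture_bundle(seed: int = 0,
                        spec: SyntheticSpec | None = None) -> InputBundle:
    """The packaged 34-country / 29-service tables joined with a complete
    seeded synthetic OOP-share and utilization fill, ready for end-to-end
    runs."""
    countries = load_countries(packaged_fixture_path("table1_countries"))
    services = load_services(packaged_fixture_path("table3_services"))
    if spec is None:
        spec = SyntheticSpec(n_countries=len(countries), missingness=0.0)
    return generate_bundle(spec, seed=seed, countries=countries,
                           services=services)
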