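"""Case ascertainment: inclusion/exclusion filters, incidence estimation,
direct age standardization, region pooling, under-reporting and F/M ratios.

The estimators here follow standard registry fracture epidemiology: fragility
fractures in residents aged 50+, with pathological and high-energy fractures
excluded, repeat admissions for the same fracture deduplicated, rates per
100,000 person-years in 5-year age bands, and direct standardization to a
reference population. Under-ascertainment is quantified by comparing mean
annual counts under a partial (hospital-only) capture regime against a year
with full (hospital + primary care) capture.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = [
    "FractureRecord",
    "FilterCriteria",
    "UnderreportingEstimate",
    "Ratio",
    "UndefinedRatioError",
    "BandMismatchError",
    "round_half_up",
    "filter_cases",
    "compute_incidence",
    "age_standardize",
    "pool_regions",
    "missed_fraction",
    "fm_ratio",
    "national_projection",
]

VALID_SEXES = ("female", "male")

ICD_BY_SITE = {
    "hip": ("S72.0", "S72.1", "S72.2"),
    "forearm": ("S52.5", "S52.6"),
    "humerus": ("S42.2",),
}


class UndefinedRatioError(ZeroDivisionError):
    """A ratio with a zero denominator was requested."""


class BandMismatchError(ValueError):
    """Two tables do not share the same age-band scheme."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round-half-up to ``ndigits`` decimals (reporting convention; ties away
    from zero on the positive side, unlike banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FractureRecord:
    """One candidate fragility-fracture event.

    ``truth`` is a hidden provenance label used only by the synthetic
    generator ('case', 'high_energy', 'duplicate', ...); it is never written
    to the public registry schema unless explicitly requested.
    """

    person_id: str
    event_date: _dt.date
    age: int
    sex: str
    site: str
    icd10: str
    trauma_energy: str
    pathological: int
    resident: int
    care_source: str
    region: str
    truth: str | None = None

    def icd_consistent(self) -> bool:
        return self.icd10 in ICD_BY_SITE.get(self.site, ())


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusion/exclusion configuration.

    The deduplication window separates a readmission for the same fracture
    from a genuine repeat fracture at the same site: a later same-person,
    same-site event within ``dedup_window_days`` of a retained event is a
    readmission; outside the window it is registered as a new event.
    """

    min_age: int = 50
    exclude_high_energy: bool = True
    exclude_pathological: bool = True
    require_resident: bool = True
    dedup_window_days: int = 90


@dataclass(frozen=True)
class UnderreportingEstimate:
    site: str
    annual_counts_partial: tuple[int, ...]
    count_full: int
    missed_fraction: float
    percent: float  # round-half-up to integer per cent
    negative: bool  # partial counts exceeded the full-capture count


@dataclass(frozen=True)
class Ratio:
    """A reported ratio: full-precision value plus its rounded display form."""

    value: float
    rounded: float


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_cases(
    records: list[FractureRecord], criteria: FilterCriteria | None = None
) -> tuple[list[FractureRecord], dict]:
    """Apply the study filters and return (retained, audit).

    Record-level rules (ICD/site consistency, age, trauma energy, pathology,
    residency) are order-independent; a record violating several rules is
    counted under each but excluded once. Deduplication runs last and is
    deterministic: events are ordered by date (ties by person_id) and the
    earliest same-person same-site event is retained; later ones within the
    window of the last retained event are dropped as readmissions.

    The audit dict has per-rule exclusion counts, the number retained, and a
    quarantine list of (person_id, event_date, reason) for records failing
    ICD/site validation.
    """
    criteria = criteria or FilterCriteria()
    audit = {
        "input": len(records),
        "icd_site_mismatch": 0,
        "under_age": 0,
        "high_energy": 0,
        "pathological": 0,
        "non_resident": 0,
        "duplicate_admission": 0,
        "quarantined": [],
    }

    eligible: list[FractureRecord] = []
    for r in records:
        if not r.icd_consistent():
            audit["icd_site_mismatch"] += 1
            audit["quarantined"].append(
                (r.person_id, r.event_date.isoformat(), f"icd {r.icd10} != site {r.site}")
            )
            continue
        bad = False
        if r.age < criteria.min_age:
            audit["under_age"] += 1
            bad = True
        if criteria.exclude_high_energy and r.trauma_energy == "high":
            audit["high_energy"] += 1
            bad = True
        if criteria.exclude_pathological and r.pathological:
            audit["pathological"] += 1
            bad = True
        if criteria.require_resident and not r.resident:
            audit["non_resident"] += 1
            bad = True
        if not bad:
            eligible.append(r)

    eligible.sort(key=lambda r: (r.event_date, r.person_id, r.site))
    last_kept: dict[tuple[str, str], _dt.date] = {}
    retained: list[FractureRecord] = []
    window = _dt.timedelta(days=criteria.dedup_window_days)
    for r in eligible:
        key = (r.person_id, r.site)
        prev = last_kept.get(key)
        if prev is not None and r.event_date - prev <= window:
            audit["duplicate_admission"] += 1
            continue
        retained.append(r)
        last_kept[key] = r.event_date

    audit["retained"] = len(retained)
    return retained, audit


# ---------------------------------------------------------------------------
# Incidence
# ---------------------------------------------------------------------------

def _band_edges(population: pd.DataFrame) -> list[tuple[int, float]]:
    """Sorted unique (age_lo, age_hi) pairs; age_hi is inf for the open band."""
    pairs = {
        (int(lo), float("inf") if pd.isna(hi) else float(hi))
        for lo, hi in zip(population["age_lo"], population["age_hi"])
    }
    return sorted(pairs)


def _assign_band(age: int, bands: list[tuple[int, float]]) -> tuple[int, float]:
    for lo, hi in bands:
        if lo <= age < hi:
            return (lo, hi)
    raise ValueError(f"age {age} falls outside every age band")


def compute_incidence(
    cases: list[FractureRecord],
    population: pd.DataFrame,
    years: float = 1.0,
    sites: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Age/sex/site-specific incidence per 100,000 person-years.

    ``population`` has columns (sex, age_lo, age_hi, person_years) — rows for
    the same (sex, band) cell (e.g. several regions) are summed. ``years``
    multiplies person-years (number of observation years at a mid-period
    population). Returns rows (sex, age_lo, age_hi, site, count,
    person_years, rate_per_100k), zero-filled for empty cells.
    """
    if population.empty:
        raise ValueError("population table is empty")
    pop = (
        population.groupby(["sex", "age_lo", "age_hi"], dropna=False)["person_years"]
        .sum()
        .reset_index()
    )
    pop["person_years"] = pop["person_years"] * years
    bands = _band_edges(pop)
    if sites is None:
        sites = tuple(sorted({r.site for r in cases})) or ("hip", "forearm", "humerus")

    counts: dict[tuple[str, int, float, str], int] = {}
    for r in cases:
        band = _assign_band(r.age, bands)
        counts[(r.sex, band[0], band[1], r.site)] = (
            counts.get((r.sex, band[0], band[1], r.site), 0) + 1
        )

    py_lookup = {
        (row.sex, int(row.age_lo), float("inf") if pd.isna(row.age_hi) else float(row.age_hi)):
        float(row.person_years)
        for row in pop.itertuples()
    }
    rows = []
    for sex in sorted({s for s, *_ in py_lookup}):
        for lo, hi in bands:
            py = py_lookup.get((sex, lo, hi))
            if py is None:
                continue
            for site in sites:
                n = counts.pop((sex, lo, hi, site), 0)
                if py <= 0:
                    if n > 0:
                        raise ValueError(
                            f"cases in band [{lo},{hi}) for {sex} but person-years is 0"
                        )
                    continue
                rows.append(
                    {
                        "sex": sex,
                        "age_lo": lo,
                        "age_hi": np.nan if np.isinf(hi) else hi,
                        "site": site,
                        "count": n,
                        "person_years": py,
                        "rate_per_100k": 1e5 * n / py,
                    }
                )
    if counts:
        key = next(iter(counts))
        raise ValueError(f"cases fall in a cell absent from the population table: {key}")
    return pd.DataFrame(rows)


def _band_key(df: pd.DataFrame) -> set[tuple[str, int, float]]:
    return {
        (s, int(lo), float("inf") if pd.isna(hi) else float(hi))
        for s, lo, hi in zip(df["sex"], df["age_lo"], df["age_hi"])
    }


def age_standardize(inc: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Direct standardization: per (sex, site), the weighted mean of band
    rates with weights proportional to the reference population's
    person-years in each band. Returns rows (sex, site, rate_per_100k).
    """
    ref = (
        reference.groupby(["sex", "age_lo", "age_hi"], dropna=False)["person_years"]
        .sum()
        .reset_index()
    )
    inc_bands = _band_key(inc)
    ref_bands = _band_key(ref)
    if not inc_bands <= ref_bands:
        missing = sorted(inc_bands - ref_bands)
        raise BandMismatchError(f"reference population lacks bands: {missing}")

    merged = inc.merge(
        ref.rename(columns={"person_years": "ref_py"}),
        on=["sex", "age_lo", "age_hi"],
        how="left",
    )
    out = []
    for (sex, site), grp in merged.groupby(["sex", "site"]):
        w = grp["ref_py"].to_numpy(dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"reference weights sum to 0 for ({sex}, {site})")
        out.append(
            {
                "sex": sex,
                "site": site,
                "rate_per_100k": float(w @ grp["rate_per_100k"].to_numpy() / w.sum()),
            }
        )
    return pd.DataFrame(out)


def pool_regions(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool incidence tables from several regions: counts and person-years
    sum cell-wise and rates are recomputed, which is exactly the
    population-size-weighted mean of the regional rates."""
    if not tables:
        raise ValueError("no tables to pool")
    schemes = [_band_key(t) for t in tables]
    if any(s != schemes[0] for s in schemes[1:]):
        raise BandMismatchError("incidence tables use different band schemes")
    cat = pd.concat(tables, ignore_index=True)
    pooled = (
        cat.groupby(["sex", "age_lo", "age_hi", "site"], dropna=False)[
            ["count", "person_years"]
        ]
        .sum()
        .reset_index()
    )
    pooled["rate_per_100k"] = 1e5 * pooled["count"] / pooled["person_years"]
    return pooled


# ---------------------------------------------------------------------------
# Under-reporting, ratios, projection
# ---------------------------------------------------------------------------

def missed_fraction(
    partial_annual_counts, full_count: int, site: str = "all"
) -> UnderreportingEstimate:
    """Fraction of cases invisible to the partial capture regime:
    1 - mean(partial annual counts) / full-capture annual count.

    A negative estimate (partial exceeding full) is flagged, not clamped.
    """
    counts = tuple(int(c) for c in partial_annual_counts)
    if full_count <= 0:
        raise ValueError(f"full-capture count must be > 0, got {full_count}")
    if not counts:
        raise ValueError("at least one partial-regime annual count is required")
    frac = 1.0 - (sum(counts) / len(counts)) / full_count
    return UnderreportingEstimate(
        site=site,
        annual_counts_partial=counts,
        count_full=int(full_count),
        missed_fraction=frac,
        percent=round_half_up(100.0 * frac, 0),
        negative=frac < 0,
    )


def fm_ratio(count_female: int, count_male: int) -> Ratio:
    """Crude female/male case ratio, reported to one decimal."""
    if count_male <= 0:
        raise UndefinedRatioError("female/male ratio undefined: male count is 0")
    value = count_female / count_male
    return Ratio(value=value, rounded=round_half_up(value, 1))


def national_projection(rates: pd.DataFrame, national_population: pd.DataFrame) -> float:
    """Projected annual fracture count: sum over bands of
    rate x person-years / 100,000.

    ``rates`` has per-band rows (sex, age_lo, age_hi, rate_per_100k);
    ``national_population`` the matching (sex, age_lo, age_hi, person_years).
    Every rate band must be present in the population table.
    """
    pop = (
        national_population.groupby(["sex", "age_lo", "age_hi"], dropna=False)[
            "person_years"
        ]
        .sum()
        .reset_index()
    )
    merged = rates.merge(pop, on=["sex", "age_lo", "age_hi"], how="left")
    if merged["person_years"].isna().any():
        missing = merged.loc[merged["person_years"].isna(), ["sex", "age_lo", "age_hi"]]
        raise BandMismatchError(
            f"national population lacks bands: {missing.to_dict('records')}"
        )
    return float(
        (merged["rate_per_100k"] * merged["person_years"]).sum() / 1e5
    )
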