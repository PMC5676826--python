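"""Synthetic fracture-registry generator.

Emulates a two-region, two-regime fracture surveillance study: a retrospective
hospital-only capture period followed by a prospective year that adds primary
care sources. Fragility-fracture events arise from Gompertz (exponentially
age-increasing) site- and sex-specific incidence; a configurable share of true
cases never reaches hospital care, so the hospital-only years under-ascertain
by a known amount. Contaminant records (high-energy trauma, pathological
fractures, non-residents, under-age cases, duplicate admissions) are injected
at configurable rates and carry a hidden truth label so that downstream
filters can be tested against ground truth.

All randomness flows from a single integer seed through a documented
stream-splitting order (see :func:`_split_streams`).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .case_ascertainment import FractureRecord

__all__ = [
    "SITES",
    "ICD_BY_SITE",
    "HOSPITAL_SOURCES",
    "COMMUNITY_SOURCES",
    "GompertzHazard",
    "PopulationBand",
    "RegionSpec",
    "SimulationConfig",
    "ConfigurationError",
    "default_config",
    "solve_rate_at_50",
    "generate_population",
    "generate_registry",
    "generate_life_table",
    "registry_to_frame",
]

SITES = ("hip", "forearm", "humerus")

ICD_BY_SITE = {
    "hip": ("S72.0", "S72.1", "S72.2"),
    "forearm": ("S52.5", "S52.6"),
    "humerus": ("S42.2",),
}

HOSPITAL_SOURCES = ("inpatient", "outpatient", "emergency")
COMMUNITY_SOURCES = ("primary_care", "home_visit")

#: Conditional distribution of care source within each reachability group.
_HOSPITAL_SOURCE_P = (0.60, 0.25, 0.15)
_COMMUNITY_SOURCE_P = (0.80, 0.20)

#: Oldest age represented; the open terminal band is truncated here.
MAX_AGE = 100


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class GompertzHazard:
    """Exponentially age-increasing hazard h(a) = level * exp(slope * (a - 50)).

    ``level`` is the hazard at age 50. For fracture incidence it is expressed
    per 100,000 person-years; for mortality it is an absolute annual hazard.
    """

    level: float
    slope: float

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ConfigurationError(f"Gompertz level must be >= 0, got {self.level}")

    def at(self, age):
        """Hazard at ``age`` (scalar or array), on the scale of ``level``."""
        return self.level * np.exp(self.slope * (np.asarray(age, dtype=float) - 50.0))


@dataclass(frozen=True)
class PopulationBand:
    sex: str
    age_lo: int
    age_hi: int | None  # None marks the open terminal band
    persons: int


@dataclass(frozen=True)
class RegionSpec:
    name: str
    bands: tuple[PopulationBand, ...]


@dataclass
class SimulationConfig:
    """Full description of a synthetic surveillance study.

    incidence maps (site, sex) to a Gompertz incidence (per 100,000 py at 50);
    capture maps (year, care_source) to the probability that a true case seen
    by that source enters the registry; hospital_share maps site to the
    probability that a case is hospital-reachable at all (the complement only
    ever appears in primary-care/home-visit records).
    """

    regions: list[RegionSpec]
    incidence: dict[tuple[str, str], GompertzHazard]
    capture: dict[tuple[int, str], float]
    mortality: dict[str, GompertzHazard]
    years: list[int]
    hospital_share: dict[str, float] = field(
        default_factory=lambda: {s: 0.54 for s in SITES}
    )
    fraction_high_energy: float = 0.0
    fraction_pathological: float = 0.0
    fraction_nonresident: float = 0.0
    fraction_under_age: float = 0.0
    fraction_duplicate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.regions:
            raise ConfigurationError("at least one region is required")
        if not self.years:
            raise ConfigurationError("at least one simulated year is required")
        for (year, source) in (
            (y, s) for y in self.years for s in HOSPITAL_SOURCES + COMMUNITY_SOURCES
        ):
            p = self.capture.get((year, source))
            if p is None:
                raise ConfigurationError(
                    f"capture probability missing for year {year}, source {source!r}"
                )
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"capture[{year},{source}]={p} outside [0,1]")
        for site, p in self.hospital_share.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"hospital_share[{site}]={p} outside [0,1]")
        for frac in (
            self.fraction_high_energy,
            self.fraction_pathological,
            self.fraction_nonresident,
            self.fraction_under_age,
            self.fraction_duplicate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"contamination fraction {frac} outside [0,1]")
        for region in self.regions:
            for sex in ("female", "male"):
                bands = sorted(
                    (b for b in region.bands if b.sex == sex), key=lambda b: b.age_lo
                )
                if not bands:
                    continue
                if bands[0].age_lo != 50:
                    raise ConfigurationError(
                        f"{region.name}/{sex}: bands must start at age 50"
                    )
                for prev, nxt in zip(bands, bands[1:]):
                    if prev.age_hi != nxt.age_lo:
                        raise ConfigurationError(
                            f"{region.name}/{sex}: bands not contiguous at {prev.age_hi}"
                        )
                if bands[-1].age_hi is not None:
                    raise ConfigurationError(
                        f"{region.name}/{sex}: terminal band must be open-ended"
                    )
        for site in SITES:
            for sex in ("female", "male"):
                if (site, sex) not in self.incidence:
                    raise ConfigurationError(f"incidence missing for ({site}, {sex})")
        for sex in ("female", "male"):
            if sex not in self.mortality:
                raise ConfigurationError(f"mortality missing for {sex}")
            if self.mortality[sex].level < 0:
                raise ConfigurationError("mortality level must be >= 0")


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: 5-year band edges from 50 with an open 85+ terminal band.
DEFAULT_BAND_EDGES = (50, 55, 60, 65, 70, 75, 80, 85, None)

#: Share of the 50+ population in each band (both sexes); a typical
#: middle-income post-50 age pyramid, heavier at the younger bands.
DEFAULT_AGE_WEIGHTS = (0.21, 0.19, 0.15, 0.12, 0.11, 0.10, 0.07, 0.05)

#: Region total populations and the 50+ totals by sex (both regions combined).
DEFAULT_REGION_TOTALS = {"Ararat": 284_574, "Vayots Dzor": 52_252}
DEFAULT_POP_50PLUS = {"male": 45_871, "female": 55_838}

#: Target expected crude 50+ incidence per 100,000 py, by (site, sex), and
#: the age slopes (per year) used with them. Hip rises steeply with age;
#: forearm is much flatter.
DEFAULT_TARGET_RATES = {
    ("hip", "female"): 201.0,
    ("hip", "male"): 136.0,
    ("forearm", "female"): 176.4,
    ("forearm", "male"): 56.1,
    ("humerus", "female"): 86.0,
    ("humerus", "male"): 39.2,
}
DEFAULT_SLOPES = {
    ("hip", "female"): 0.105,
    ("hip", "male"): 0.090,
    ("forearm", "female"): 0.050,
    ("forearm", "male"): 0.020,
    ("humerus", "female"): 0.060,
    ("humerus", "male"): 0.040,
}

DEFAULT_MORTALITY = {
    "female": GompertzHazard(level=0.003, slope=0.100),
    "male": GompertzHazard(level=0.006, slope=0.090),
}


def _apportion(total: int, weights) -> list[int]:
    """Split ``total`` into integer parts proportional to ``weights``
    (largest-remainder rounding; parts sum exactly to ``total``)."""
    w = np.asarray(weights, dtype=float)
    raw = total * w / w.sum()
    parts = np.floor(raw).astype(int)
    remainder = total - parts.sum()
    order = np.argsort(-(raw - parts))
    parts[order[:remainder]] += 1
    return parts.tolist()


def band_midpoint(age_lo: int, age_hi: int | None) -> float:
    """Midpoint used to evaluate band-level hazards; the open terminal band
    is treated as [age_lo, MAX_AGE]."""
    hi = MAX_AGE if age_hi is None else age_hi
    return 0.5 * (age_lo + hi)


def solve_rate_at_50(
    target_rate: float, slope: float, band_persons: dict[tuple[int, int | None], int]
) -> float:
    """Gompertz level (rate per 100k at age 50) whose population-weighted mean
    over band midpoints equals ``target_rate``."""
    persons = np.array(list(band_persons.values()), dtype=float)
    mids = np.array([band_midpoint(lo, hi) for lo, hi in band_persons], dtype=float)
    mult = float(persons @ np.exp(slope * (mids - 50.0)) / persons.sum())
    return target_rate / mult


def default_config(seed: int = 0, scale: float = 1.0) -> SimulationConfig:
    """Study conditions matching the two-region surveillance design: region
    totals 284,574 and 52,252; 50+ populations 45,871 men and 55,838 women;
    hospital-only capture in the first two years vs full capture in the third
    with a 0.54 hospital-reachable share (46% of cases invisible to
    hospital-only ascertainment); Gompertz incidence calibrated so the
    expected crude 50+ rates equal the per-site targets.

    ``scale`` shrinks every population count (for fast test fixtures) without
    touching rates or probabilities.
    """
    region_weight = {
        name: t / sum(DEFAULT_REGION_TOTALS.values())
        for name, t in DEFAULT_REGION_TOTALS.items()
    }
    edges = list(zip(DEFAULT_BAND_EDGES[:-1], DEFAULT_BAND_EDGES[1:]))
    regions = []
    combined: dict[tuple[int, int | None], int] = {e: 0 for e in edges}
    for name, wt in region_weight.items():
        bands = []
        for sex, total50 in DEFAULT_POP_50PLUS.items():
            region_total = int(round(total50 * wt * scale))
            counts = _apportion(region_total, DEFAULT_AGE_WEIGHTS)
            for (lo, hi), n in zip(edges, counts):
                bands.append(PopulationBand(sex=sex, age_lo=lo, age_hi=hi, persons=n))
                combined[(lo, hi)] += n
        regions.append(RegionSpec(name=name, bands=tuple(bands)))

    incidence = {}
    for (site, sex), target in DEFAULT_TARGET_RATES.items():
        slope = DEFAULT_SLOPES[(site, sex)]
        # calibrate against the sex-specific combined band counts
        band_persons = {
            e: sum(
                b.persons
                for r in regions
                for b in r.bands
                if b.sex == sex and (b.age_lo, b.age_hi) == e
            )
            for e in edges
        }
        incidence[(site, sex)] = GompertzHazard(
            level=solve_rate_at_50(target, slope, band_persons), slope=slope
        )

    years = [2011, 2012, 2013]
    capture = {}
    for year in years:
        for src in HOSPITAL_SOURCES:
            capture[(year, src)] = 1.0
        for src in COMMUNITY_SOURCES:
            capture[(year, src)] = 1.0 if year == 2013 else 0.0

    return SimulationConfig(
        regions=regions,
        incidence=incidence,
        capture=capture,
        mortality=dict(DEFAULT_MORTALITY),
        years=years,
        hospital_share={s: 0.54 for s in SITES},
        fraction_high_energy=0.05,
        fraction_pathological=0.02,
        fraction_nonresident=0.03,
        fraction_under_age=0.02,
        fraction_duplicate=0.02,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

_STREAM_NAMES = ("events", "attributes", "capture", "contamination")


def _split_streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent generators derived from the single seed, in a fixed order:
    events (Poisson counts), attributes (ages, sources, dates), capture
    (retention draws), contamination (injected records)."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAM_NAMES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAM_NAMES, children)}


def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Population table with one row per (region, sex, band).

    Columns: region, sex, age_lo, age_hi (NaN for the open terminal band),
    person_years.
    """
    config.validate()
    rows = [
        {
            "region": r.name,
            "sex": b.sex,
            "age_lo": b.age_lo,
            "age_hi": np.nan if b.age_hi is None else b.age_hi,
            "person_years": float(b.persons),
        }
        for r in config.regions
        for b in r.bands
    ]
    return pd.DataFrame(rows)


def _draw_sources(rng: np.random.Generator, reachable: np.ndarray) -> np.ndarray:
    """Care source per event given hospital-reachability."""
    out = np.empty(reachable.shape, dtype=object)
    n_h = int(reachable.sum())
    n_c = reachable.size - n_h
    out[reachable] = rng.choice(HOSPITAL_SOURCES, size=n_h, p=_HOSPITAL_SOURCE_P)
    out[~reachable] = rng.choice(COMMUNITY_SOURCES, size=n_c, p=_COMMUNITY_SOURCE_P)
    return out


def _random_dates(rng: np.random.Generator, year: np.ndarray) -> list[_dt.date]:
    days_in_year = np.where((year % 4 == 0) & ((year % 100 != 0) | (year % 400 == 0)), 366, 365)
    offsets = rng.integers(0, days_in_year)
    return [
        _dt.date(int(y), 1, 1) + _dt.timedelta(days=int(d)) for y, d in zip(year, offsets)
    ]


def generate_registry(
    config: SimulationConfig, population: pd.DataFrame | None = None
) -> list[FractureRecord]:
    """Draw a full registry under the configured capture regimes.

    Per (region, sex, band, year, site) the number of true fracture events is
    Poisson with mean persons x Gompertz-rate(band midpoint)/100,000 — repeat
    fractures are allowed, since a later same-site fracture counts as a new
    event. Each event is assigned an age (uniform within band), a care source
    (hospital-reachable with probability hospital_share[site]), and enters the
    registry with the year/source-specific capture probability. Contaminant
    records are then injected at the configured rates, flagged in the hidden
    ``truth`` field ('case' for genuine events).
    """
    config.validate()
    if population is None:
        population = generate_population(config)
    rngs = _split_streams(config.seed)
    ev, at, cp, ct = (rngs[n] for n in _STREAM_NAMES)

    records: list[FractureRecord] = []
    serial = 0

    cells = []  # (region, sex, lo, hi, year, site, n_true)
    for region in config.regions:
        for band in region.bands:
            mid = band_midpoint(band.age_lo, band.age_hi)
            for year in config.years:
                for site in SITES:
                    rate = float(config.incidence[(site, band.sex)].at(mid))
                    mean = band.persons * rate / 1e5
                    n = int(ev.poisson(mean)) if mean > 0 else 0
                    if n:
                        cells.append(
                            (region.name, band.sex, band.age_lo, band.age_hi, year, site, n)
                        )

    for region_name, sex, lo, hi, year, site, n in cells:
        hi_eff = MAX_AGE if hi is None else hi
        ages = at.integers(lo, hi_eff + (1 if hi is None else 0), size=n)
        reachable = at.random(n) < config.hospital_share[site]
        sources = _draw_sources(at, reachable)
        dates = _random_dates(at, np.full(n, year))
        icd = at.choice(ICD_BY_SITE[site], size=n)
        keep = cp.random(n) < np.array(
            [config.capture[(year, s)] for s in sources], dtype=float
        )
        for i in range(n):
            if not keep[i]:
                continue
            serial += 1
            records.append(
                FractureRecord(
                    person_id=f"P{serial:07d}",
                    event_date=dates[i],
                    age=int(ages[i]),
                    sex=sex,
                    site=site,
                    icd10=str(icd[i]),
                    trauma_energy="low",
                    pathological=0,
                    resident=1,
                    care_source=str(sources[i]),
                    region=region_name,
                    truth="case",
                )
            )

    records.extend(_contaminants(config, records, ct))
    return records


def _contaminants(
    config: SimulationConfig, cases: list[FractureRecord], rng: np.random.Generator
) -> list[FractureRecord]:
    n_true = len(cases)
    out: list[FractureRecord] = []
    serial = 0

    def _base(truth: str) -> FractureRecord:
        nonlocal serial
        serial += 1
        site = str(rng.choice(SITES))
        year = int(rng.choice(config.years))
        region = str(rng.choice([r.name for r in config.regions]))
        sex = "female" if rng.random() < 0.55 else "male"
        age = int(rng.integers(50, 95))
        date = _random_dates(rng, np.array([year]))[0]
        return FractureRecord(
            person_id=f"X{serial:06d}",
            event_date=date,
            age=age,
            sex=sex,
            site=site,
            icd10=str(rng.choice(ICD_BY_SITE[site])),
            trauma_energy="low",
            pathological=0,
            resident=1,
            care_source=str(rng.choice(HOSPITAL_SOURCES)),
            region=region,
            truth=truth,
        )

    for _ in range(int(rng.poisson(config.fraction_high_energy * n_true))):
        out.append(dataclasses.replace(_base("high_energy"), trauma_energy="high"))
    for _ in range(int(rng.poisson(config.fraction_pathological * n_true))):
        out.append(dataclasses.replace(_base("pathological"), pathological=1))
    for _ in range(int(rng.poisson(config.fraction_nonresident * n_true))):
        out.append(dataclasses.replace(_base("nonresident"), resident=0))
    for _ in range(int(rng.poisson(config.fraction_under_age * n_true))):
        out.append(dataclasses.replace(_base("under_age"), age=int(rng.integers(25, 50))))
    if n_true and config.fraction_duplicate > 0:
        n_dup = int(rng.poisson(config.fraction_duplicate * n_true))
        for idx in rng.integers(0, n_true, size=n_dup):
            src = cases[int(idx)]
            out.append(
                dataclasses.replace(
                    src,
                    event_date=src.event_date + _dt.timedelta(days=int(rng.integers(1, 30))),
                    truth="duplicate",
                )
            )
    return out


def generate_life_table(config: SimulationConfig) -> pd.DataFrame:
    """Annual death hazards h_d(a) = level * exp(slope*(a-50)) tabulated for
    ages 50..100 per sex. Columns: sex, age, hazard."""
    config.validate()
    ages = np.arange(50, MAX_AGE + 1)
    frames = []
    for sex, gomp in sorted(config.mortality.items()):
        frames.append(
            pd.DataFrame({"sex": sex, "age": ages, "hazard": gomp.at(ages)})
        )
    return pd.concat(frames, ignore_index=True)


def registry_to_frame(records: list[FractureRecord], include_truth: bool = False) -> pd.DataFrame:
    """Tabular view of a registry (public CSV columns, optionally + truth)."""
    cols = [
        "person_id", "event_date", "age", "sex", "site", "icd10",
        "trauma_energy", "pathological", "resident", "care_source", "region",
    ]
    if include_truth:
        cols.append("truth")
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
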