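"""Competing-risk 10-year fracture-probability engine.

The probability of sustaining a (first) fracture within ten years is computed
from an annual fracture hazard h_f and the competing annual death hazard h_d:
within each interval of length dt the chance of exiting by either cause is
1 - exp(-(h_f + h_d) dt), a fraction h_f/(h_f + h_d) of exits are fractures,
and survival to the start of the interval discounts everything after it.
Clinical risk factors and BMD enter as positive multipliers on the fracture
hazard, supplied by the user (there is no claim to any proprietary
coefficient set — the baseline multiplier is 1).

Hazards come from incidence tables: rate per 100,000 person-years / 1e5
anchored at band midpoints, linearly interpolated, constant beyond the outer
midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MOF_SITES",
    "CRF_NAMES",
    "HazardFunction",
    "LifeTable",
    "RiskProfile",
    "MultiplierSpec",
    "RiskModel",
    "hazard_from_incidence",
    "life_table_from_frame",
    "ten_year_probability",
    "hip_probability",
    "mof_probability",
]

#: Sites contributing to a major osteoporotic fracture (MOF).
MOF_SITES = ("hip", "spine", "forearm", "humerus")

#: The six binary clinical risk factors, in canonical order.
CRF_NAMES = (
    "prior_fracture",
    "parent_hip_fracture",
    "smoking",
    "glucocorticoids",
    "rheumatoid_arthritis",
    "alcohol",
)

AGE_MIN, AGE_MAX = 50.0, 100.0


@dataclass(frozen=True)
class HazardFunction:
    """Annual hazard tabulated at anchor ages, evaluated by linear
    interpolation with constant extrapolation beyond the outer anchors."""

    sex: str
    ages: tuple[float, ...]
    hazards: tuple[float, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.hazards) or not self.ages:
            raise ValueError("ages and hazards must be equal-length and non-empty")
        if any(h < 0 for h in self.hazards):
            raise ValueError("hazards must be >= 0")
        if list(self.ages) != sorted(self.ages):
            raise ValueError("anchor ages must be increasing")

    def __call__(self, age):
        return np.interp(np.asarray(age, dtype=float), self.ages, self.hazards)

    def scaled(self, factor) -> "HazardFunction":
        """Pointwise multiple; ``factor`` may be scalar or per-anchor."""
        f = np.broadcast_to(np.asarray(factor, dtype=float), (len(self.ages),))
        return HazardFunction(
            sex=self.sex,
            ages=self.ages,
            hazards=tuple(h * x for h, x in zip(self.hazards, f)),
            source=self.source,
        )

    @staticmethod
    def sum_of(parts: list["HazardFunction"]) -> "HazardFunction":
        """Sum of several hazards on a merged anchor grid (exact for
        piecewise-linear components sharing grids; for mixed grids the sum is
        re-linearized on the union of anchors)."""
        if not parts:
            raise ValueError("no hazards to sum")
        grid = np.unique(np.concatenate([np.asarray(p.ages) for p in parts]))
        total = np.zeros_like(grid)
        for p in parts:
            total = total + p(grid)
        return HazardFunction(
            sex=parts[0].sex, ages=tuple(grid), hazards=tuple(total), source="sum"
        )


class LifeTable:
    """Per-sex annual death hazard by age, from a (sex, age, hazard) frame.
    Evaluated like HazardFunction (linear interpolation, constant tails)."""

    def __init__(self, frame: pd.DataFrame):
        if (frame["hazard"] < 0).any():
            raise ValueError("death hazards must be >= 0")
        self._fns: dict[str, HazardFunction] = {}
        for sex, grp in frame.groupby("sex"):
            grp = grp.sort_values("age")
            self._fns[str(sex)] = HazardFunction(
                sex=str(sex),
                ages=tuple(float(a) for a in grp["age"]),
                hazards=tuple(float(h) for h in grp["hazard"]),
                source="life-table",
            )

    def hazard(self, sex: str) -> HazardFunction:
        if sex not in self._fns:
            raise KeyError(f"life table has no entries for sex {sex!r}")
        return self._fns[sex]


def life_table_from_frame(frame: pd.DataFrame) -> LifeTable:
    return LifeTable(frame)


def hazard_from_incidence(
    inc: pd.DataFrame, sex: str, site: str | None = None
) -> HazardFunction:
    """Fracture hazard from an incidence table: annual hazard =
    rate_per_100k / 1e5 anchored at band midpoints (the open terminal band's
    midpoint uses an upper limit of 100)."""
    sel = inc[inc["sex"] == sex]
    if site is not None:
        sel = sel[sel["site"] == site]
    if sel.empty:
        raise ValueError(f"no incidence rows for sex={sex!r}, site={site!r}")
    if (sel["rate_per_100k"] < 0).any():
        raise ValueError("negative incidence rate")
    sel = sel.sort_values("age_lo")
    mids = [
        0.5 * (float(lo) + (AGE_MAX if pd.isna(hi) else float(hi)))
        for lo, hi in zip(sel["age_lo"], sel["age_hi"])
    ]
    return HazardFunction(
        sex=sex,
        ages=tuple(mids),
        hazards=tuple(float(r) / 1e5 for r in sel["rate_per_100k"]),
        source=site or "all",
    )


# ---------------------------------------------------------------------------
# Core integral
# ---------------------------------------------------------------------------

def ten_year_probability(
    h_f,
    h_d,
    rr: float = 1.0,
    age: float = 50.0,
    horizon: float = 10.0,
    step: float = 1.0,
) -> float:
    """Probability of fracture within ``horizon`` years from ``age`` under
    the competing death hazard.

    P = sum over intervals of S(t) * [h~_f/(h~_f+h_d)] * (1 - exp(-(h~_f+h_d) dt))
    with h~_f = rr * h_f, both hazards evaluated at the interval midpoint,
    and S(t) = exp(-cumulative total hazard up to t). Intervals in which both
    hazards are zero contribute nothing.
    """
    if rr <= 0:
        raise ValueError(f"relative-risk multiplier must be > 0, got {rr}")
    if age < AGE_MIN or age + horizon > AGE_MAX:
        raise ValueError(
            f"[{age}, {age + horizon}] outside the hazard domain [{AGE_MIN}, {AGE_MAX}]"
        )
    n = int(round(horizon / step))
    if abs(n * step - horizon) > 1e-9 or n < 1:
        raise ValueError("horizon must be a whole number of steps")
    mids = age + (np.arange(n) + 0.5) * step
    hf = rr * np.asarray(h_f(mids), dtype=float)
    hd = np.asarray(h_d(mids), dtype=float)
    tot = hf + hd
    cum = np.concatenate([[0.0], np.cumsum(tot * step)[:-1]])
    surv = np.exp(-cum)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(tot > 0, hf / np.where(tot > 0, tot, 1.0), 0.0)
    p = float(np.sum(surv * share * (1.0 - np.exp(-tot * step))))
    return min(max(p, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Risk profiles and models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskProfile:
    """One clinical scenario: six binary risk factors, femoral-neck BMD
    T-score (None = BMD not entered), BMI, age and sex."""

    age: float
    sex: str
    prior_fracture: bool = False
    parent_hip_fracture: bool = False
    smoking: bool = False
    glucocorticoids: bool = False
    rheumatoid_arthritis: bool = False
    alcohol: bool = False
    tscore: float | None = None
    bmi: float = 25.0

    @property
    def crf_bits(self) -> tuple[bool, ...]:
        return tuple(getattr(self, name) for name in CRF_NAMES)


@dataclass(frozen=True)
class MultiplierSpec:
    """Log-linear relative-hazard table mapping a profile to multipliers.

    ``crf_rr[outcome][crf]`` is the per-factor relative hazard; ``bmd_rr_per_sd``
    the relative hazard per SD of T-score below 0. Defaults are all 1.0, so a
    baseline profile (no factors, no BMD) maps to 1.0 by construction.
    Coefficients are deliberately user-supplied configuration, not shipped
    constants.
    """

    crf_rr: dict = field(default_factory=dict)  # outcome -> {crf: rr}
    bmd_rr_per_sd: dict = field(default_factory=dict)  # outcome -> rr per SD below 0
    death_rr: dict = field(default_factory=dict)  # outcome "death" modifiers (rare)

    def __post_init__(self) -> None:
        for outcome, table in self.crf_rr.items():
            for crf, rr in table.items():
                if crf not in CRF_NAMES:
                    raise ValueError(f"unknown clinical risk factor {crf!r}")
                if rr <= 0:
                    raise ValueError(f"multiplier for {crf!r}/{outcome} must be > 0")
        for outcome, rr in self.bmd_rr_per_sd.items():
            if rr <= 0:
                raise ValueError(f"BMD gradient for {outcome} must be > 0")

    def fracture_rr(self, profile: RiskProfile, outcome: str) -> float:
        rr = 1.0
        table = self.crf_rr.get(outcome, {})
        for name, on in zip(CRF_NAMES, profile.crf_bits):
            if on:
                rr *= table.get(name, 1.0)
        if profile.tscore is not None:
            grad = self.bmd_rr_per_sd.get(outcome, 1.0)
            rr *= grad ** max(0.0, -profile.tscore)
        return rr

    def death_multiplier(self, profile: RiskProfile) -> float:
        rr = 1.0
        for name, on in zip(CRF_NAMES, profile.crf_bits):
            if on:
                rr *= self.death_rr.get(name, 1.0)
        return rr


def illustrative_multipliers() -> MultiplierSpec:
    """Plausible, clearly-illustrative relative hazards so the comparison
    machinery can run end to end: per-factor relative risks in the 1.2-2.0
    range and a BMD gradient of risk per SD, in line with the magnitudes the
    osteoporosis literature reports for these factors. They are NOT a fitted
    coefficient set; real analyses must supply their own."""
    return MultiplierSpec(
        crf_rr={
            "mof": {
                "prior_fracture": 1.8,
                "parent_hip_fracture": 1.5,
                "smoking": 1.2,
                "glucocorticoids": 1.6,
                "rheumatoid_arthritis": 1.3,
                "alcohol": 1.4,
            },
            "hip": {
                "prior_fracture": 1.8,
                "parent_hip_fracture": 2.0,
                "smoking": 1.5,
                "glucocorticoids": 1.9,
                "rheumatoid_arthritis": 1.4,
                "alcohol": 1.7,
            },
        },
        bmd_rr_per_sd={"mof": 1.5, "hip": 2.0},
    )


@dataclass
class RiskModel:
    """A country model: per-site fracture hazards (hip mandatory; missing
    sites resolved through site/hip imputation ratios), a life table, and a
    multiplier specification."""

    name: str
    hazards: dict[tuple[str, str], HazardFunction]  # (site, sex) -> hazard
    life_table: LifeTable
    imputation_ratios: pd.DataFrame | None = None
    multipliers: MultiplierSpec = field(default_factory=MultiplierSpec)
    step: float = 1.0

    def site_hazard(self, site: str, sex: str) -> HazardFunction:
        fn = self.hazards.get((site, sex))
        if fn is not None:
            return fn
        hip = self.hazards.get(("hip", sex))
        if hip is None:
            raise ValueError(f"model {self.name!r} lacks a hip hazard for {sex}")
        if self.imputation_ratios is None:
            raise ValueError(
                f"model {self.name!r}: no hazard for ({site}, {sex}) and no "
                "imputation ratios supplied"
            )
        rat = self.imputation_ratios
        rat = rat[(rat["site"] == site) & (rat["sex"] == sex)]
        if rat.empty:
            raise ValueError(f"no {site}/hip ratio available for {sex}")
        rat = rat.sort_values("age_lo")
        mids = [
            0.5 * (float(lo) + (AGE_MAX if pd.isna(hi) else float(hi)))
            for lo, hi in zip(rat["age_lo"], rat["age_hi"])
        ]
        ratio_at = np.interp(np.asarray(hip.ages), mids, rat["ratio"].to_numpy(float))
        return hip.scaled(ratio_at)

    def mof_hazard(self, sex: str) -> HazardFunction:
        return HazardFunction.sum_of([self.site_hazard(s, sex) for s in MOF_SITES])


def hip_probability(model: RiskModel, profile: RiskProfile) -> float:
    """10-year hip fracture probability for one profile under one model."""
    rr = model.multipliers.fracture_rr(profile, "hip")
    h_d = model.life_table.hazard(profile.sex)
    if model.multipliers.death_multiplier(profile) != 1.0:
        h_d = h_d.scaled(model.multipliers.death_multiplier(profile))
    return ten_year_probability(
        model.site_hazard("hip", profile.sex), h_d, rr=rr, age=profile.age,
        step=model.step,
    )


def mof_probability(model: RiskModel, profile: RiskProfile) -> float:
    """10-year probability of a first major osteoporotic fracture.

    The MOF hazard is the sum of the four site hazards (first-event
    approximation: the small double-count of simultaneous multi-site events
    is ignored), scaled by the profile's MOF relative hazard.
    """
    rr = model.multipliers.fracture_rr(profile, "mof")
    h_d = model.life_table.hazard(profile.sex)
    if model.multipliers.death_multiplier(profile) != 1.0:
        h_d = h_d.scaled(model.multipliers.death_multiplier(profile))
    return ten_year_probability(
        model.mof_hazard(profile.sex), h_d, rr=rr, age=profile.age, step=model.step
    )
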