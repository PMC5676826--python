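"""Surrogate-vs-authentic model comparison over an enumerated profile array.

Two country models are evaluated on every combination of the six binary
clinical risk factors and a grid of BMD T-scores (an array of scenarios, not
a population simulation), at each requested age and sex. Agreement is
summarized by Pearson and Spearman correlation, a continuous piecewise-linear
regression of authentic on surrogate probabilities with fixed knots, and a
percentile table giving, at chosen percentiles of the surrogate distribution,
the authentic fitted value with a normal-theory tolerance interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .probability_engine import (
    CRF_NAMES,
    RiskModel,
    RiskProfile,
    hip_probability,
    mof_probability,
)

__all__ = [
    "ProfileGrid",
    "ComparisonConfig",
    "PiecewiseFit",
    "CellResult",
    "ComparisonResult",
    "enumerate_profiles",
    "piecewise_fit",
    "tolerance_interval",
    "compare_models",
    "plot_comparison",
]

DEFAULT_TSCORES = tuple(-0.5 * i for i in range(8))  # 0 .. -3.5 in 0.5 steps


@dataclass(frozen=True)
class ProfileGrid:
    """Enumeration grid: all 2^crf_count CRF combinations crossed with every
    T-score, at fixed BMI, per age and sex (default 2^6 x 8 = 512 per cell)."""

    crfs: tuple[str, ...] = CRF_NAMES
    tscores: tuple[float, ...] = DEFAULT_TSCORES
    bmi: float = 25.0
    ages: tuple[float, ...] = (50.0, 60.0, 70.0, 80.0)
    sexes: tuple[str, ...] = ("female", "male")

    @property
    def size_per_cell(self) -> int:
        return (2 ** len(self.crfs)) * len(self.tscores)


@dataclass(frozen=True)
class ComparisonConfig:
    """Knots are on the surrogate axis in probability per cent; different
    knots for the two outcomes reflect their different probability ranges."""

    knots_mof: tuple[float, float] = (10.0, 30.0)
    knots_hip: tuple[float, float] = (5.0, 20.0)
    percentiles: tuple[float, ...] = (10.0, 50.0, 90.0)
    tolerance_level: float = 0.95

    def knots(self, outcome: str) -> tuple[float, float]:
        return self.knots_mof if outcome == "mof" else self.knots_hip


def enumerate_profiles(grid: ProfileGrid, age: float, sex: str) -> list[RiskProfile]:
    """All profiles for one age-sex cell, in deterministic order: CRF
    bit-pattern major (factor i = bit i of the pattern), T-score minor."""
    if not grid.tscores:
        raise ValueError("T-score grid is empty")
    profiles = []
    for pattern in range(2 ** len(grid.crfs)):
        flags = {
            crf: bool((pattern >> i) & 1) for i, crf in enumerate(grid.crfs)
        }
        for t in grid.tscores:
            profiles.append(
                RiskProfile(age=age, sex=sex, tscore=t, bmi=grid.bmi, **flags)
            )
    return profiles


# ---------------------------------------------------------------------------
# Piecewise-linear regression on the truncated-power basis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PiecewiseFit:
    """Continuous 3-segment linear fit y ~ 1 + x + (x-k1)+ + (x-k2)+.

    ``slopes`` are the per-segment slopes (cumulative sums of the basis
    coefficients); continuity at the knots holds by construction.
    """

    knots: tuple[float, ...]
    coef: tuple[float, ...]  # intercept, slope, then one jump per knot
    resid_sd: float
    df_resid: int
    n: int

    @property
    def intercept(self) -> float:
        return self.coef[0]

    @property
    def slopes(self) -> tuple[float, ...]:
        return tuple(np.cumsum(self.coef[1:]))

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        y = self.coef[0] + self.coef[1] * x
        for k, c in zip(self.knots, self.coef[2:]):
            y = y + c * np.clip(x - k, 0.0, None)
        return y


def _design(x: np.ndarray, knots: tuple[float, ...]) -> np.ndarray:
    cols = [np.ones_like(x), x] + [np.clip(x - k, 0.0, None) for k in knots]
    return np.column_stack(cols)


def piecewise_fit(x, y, knots) -> PiecewiseFit:
    """Least-squares continuous piecewise-linear fit with fixed interior
    knots. Knots outside the observed x-range (or leaving a segment with
    fewer than 2 points) are dropped with a warning, collapsing to fewer
    segments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must be equal-length with at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; piecewise fit is degenerate")
    kept = []
    for k in sorted(set(knots)):
        if x.min() < k < x.max():
            kept.append(float(k))
        else:
            warnings.warn(
                f"knot {k} outside the data range; collapsing to fewer segments",
                stacklevel=2,
            )
    while kept:
        seg = np.searchsorted(np.array(kept), x, side="right")
        counts = [(seg == i).sum() for i in range(len(kept) + 1)]
        if min(counts) >= 2:
            break
        i = int(np.argmin(counts))
        dropped = kept.pop(min(i, len(kept) - 1))
        warnings.warn(
            f"knot {dropped} leaves a segment with fewer than 2 points; "
            "collapsing to fewer segments",
            stacklevel=2,
        )
    X = _design(x, tuple(kept))
    res = sm.OLS(y, X).fit()
    df = int(res.df_resid)
    resid_sd = float(np.sqrt(res.ssr / df)) if df > 0 else 0.0
    return PiecewiseFit(
        knots=tuple(kept),
        coef=tuple(float(c) for c in res.params),
        resid_sd=resid_sd,
        df_resid=df,
        n=int(x.size),
    )


def tolerance_interval(
    fit: PiecewiseFit,
    at_x: float,
    level: float = 0.95,
    method: str = "wald",
) -> tuple[float, float]:
    """Two-sided normal-theory tolerance interval around the fitted value at
    ``at_x``, intended to cover ``level`` of the predictive distribution.

    'wald' uses fitted +/- z_{(1+level)/2} * s; 'exact' inflates s by
    sqrt(df / chi2_{1-level, df}) so the stated content is covered with
    confidence ``level`` even at modest df. Zero residual SD gives a
    zero-width interval.
    """
    if fit.df_resid <= 0:
        raise ValueError("tolerance interval requires positive residual df")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    center = float(fit.predict(at_x))
    z = stats.norm.ppf(0.5 * (1 + level))
    k = z
    if method == "exact":
        k = z * float(np.sqrt(fit.df_resid / stats.chi2.ppf(1 - level, fit.df_resid)))
    elif method != "wald":
        raise ValueError(f"unknown tolerance-interval method {method!r}")
    half = k * fit.resid_sd
    return (center - half, center + half)


# ---------------------------------------------------------------------------
# Full comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellResult:
    """Agreement summary for one (sex, age, outcome) cell. Probabilities are
    in per cent; x is the surrogate (model A) axis, y the authentic (B)."""

    sex: str
    age: float
    outcome: str
    pearson_r: float
    spearman_rho: float
    fit: PiecewiseFit
    percentile_rows: tuple[dict, ...]  # percentile, surrogate, fitted, ti_lo, ti_hi
    median_relative_diff: float  # (fitted(median) - median)/median
    x: np.ndarray = field(repr=False, compare=False, default=None)
    y: np.ndarray = field(repr=False, compare=False, default=None)


@dataclass(frozen=True)
class ComparisonResult:
    model_a: str
    model_b: str
    cells: dict  # (sex, age, outcome) -> CellResult

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sex, age, outcome), cell in sorted(self.cells.items()):
            for pr in cell.percentile_rows:
                rows.append(
                    {
                        "sex": sex,
                        "age": age,
                        "outcome": outcome,
                        "percentile": pr["percentile"],
                        "surrogate_pct": pr["surrogate"],
                        "authentic_fitted_pct": pr["fitted"],
                        "ti_lo": pr["ti_lo"],
                        "ti_hi": pr["ti_hi"],
                        "pearson_r": cell.pearson_r,
                        "spearman_rho": cell.spearman_rho,
                    }
                )
        return pd.DataFrame(rows)


def _probability(model: RiskModel, profile: RiskProfile, outcome: str) -> float:
    return (
        hip_probability(model, profile)
        if outcome == "hip"
        else mof_probability(model, profile)
    )


def compare_models(
    model_a: RiskModel,
    model_b: RiskModel,
    grid: ProfileGrid | None = None,
    config: ComparisonConfig | None = None,
    outcomes: tuple[str, ...] = ("mof", "hip"),
) -> ComparisonResult:
    """Evaluate both models on the full profile array and summarize
    agreement per (sex, age, outcome) cell.

    Model A plays the surrogate role (its distribution defines the
    percentiles and the regression x-axis); model B the authentic role. The
    result is invariant to profile ordering: correlations, least-squares
    fits and quantiles are symmetric in permutation of the paired vectors.
    """
    grid = grid or ProfileGrid()
    config = config or ComparisonConfig()
    cells = {}
    for sex in grid.sexes:
        for age in grid.ages:
            profiles = enumerate_profiles(grid, age, sex)
            for outcome in outcomes:
                try:
                    pa = np.array(
                        [_probability(model_a, p, outcome) for p in profiles]
                    )
                    pb = np.array(
                        [_probability(model_b, p, outcome) for p in profiles]
                    )
                except Exception as exc:  # noqa: BLE001 - annotate the profile
                    raise RuntimeError(
                        f"profile evaluation failed in cell ({sex}, {age}, "
                        f"{outcome}): {exc}"
                    ) from exc
                x, y = 100.0 * pa, 100.0 * pb
                pearson = float(stats.pearsonr(x, y).statistic)
                spearman = float(stats.spearmanr(x, y).statistic)
                fit = piecewise_fit(x, y, config.knots(outcome))
                rows = []
                for pct in config.percentiles:
                    xq = float(np.percentile(x, pct))
                    lo, hi = tolerance_interval(fit, xq, level=config.tolerance_level)
                    rows.append(
                        {
                            "percentile": pct,
                            "surrogate": xq,
                            "fitted": float(fit.predict(xq)),
                            "ti_lo": lo,
                            "ti_hi": hi,
                        }
                    )
                med = float(np.percentile(x, 50.0))
                med_fit = float(fit.predict(med))
                cells[(sex, age, outcome)] = CellResult(
                    sex=sex,
                    age=age,
                    outcome=outcome,
                    pearson_r=pearson,
                    spearman_rho=spearman,
                    fit=fit,
                    percentile_rows=tuple(rows),
                    median_relative_diff=(med_fit - med) / med if med else float("nan"),
                    x=x,
                    y=y,
                )
    return ComparisonResult(model_a=model_a.name, model_b=model_b.name, cells=cells)


def plot_comparison(result: ComparisonResult, outcome: str, sex: str, path=None):
    """Scatter of authentic vs surrogate probabilities with the identity
    line, one panel per age."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = [
        c for (s, _a, o), c in sorted(result.cells.items()) if s == sex and o == outcome
    ]
    fig, axes = plt.subplots(1, len(cells), figsize=(4 * len(cells), 4), squeeze=False)
    for ax, cell in zip(axes[0], cells):
        ax.scatter(cell.x, cell.y, s=6, alpha=0.5)
        lim = max(cell.x.max(), cell.y.max()) * 1.05
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel(f"{result.model_a} probability (%)")
        ax.set_ylabel(f"{result.model_b} probability (%)")
        ax.set_title(f"{sex}, age {cell.age:.0f} (r={cell.pearson_r:.3f})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
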