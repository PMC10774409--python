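"""Effect-size machinery: Cohen's d per year, OLS and standardized-major-axis
trend fits, ln response ratios, and early/late stage contrasts."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from warmsoil.datamodel import MeasurementTable, StudyDesign, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_STAGE_SPLIT_YEAR = 2015  # years <= split are "early", > split are "late"


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r2: float
    r2_adjusted: float
    p_two_sided: float
    stderr: float
    n: int

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope."""
        half = stats.t.ppf(0.5 + level / 2.0, self.n - 2) * self.stderr
        return (self.slope - half, self.slope + half)


def cohens_d(
    treated: Sequence[float], control: Sequence[float], hedges: bool = False
) -> float:
    """Pooled-SD standardized mean difference, treated minus control.

    d = (mean_t − mean_c) / s_pooled with
    s_pooled = sqrt(((n_t−1)s_t² + (n_c−1)s_c²) / (n_t+n_c−2)).
    ``hedges=True`` applies the small-sample correction (off by default).
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if len(t) < 2 or len(c) < 2:
        raise ValidationError("each group needs >= 2 observations")
    nt, nc = len(t), len(c)
    s2 = ((nt - 1) * t.var(ddof=1) + (nc - 1) * c.var(ddof=1)) / (nt + nc - 2)
    if s2 <= 0:
        raise ValidationError("zero pooled variance: Cohen's d undefined")
    d = (t.mean() - c.mean()) / math.sqrt(s2)
    if hedges:
        dof = nt + nc - 2
        d *= 1.0 - 3.0 / (4.0 * dof - 1.0)
    return d


def trend_ols(x: Sequence[float], y: Sequence[float]) -> TrendFit:
    """Simple OLS with slope t-test p-value and adjusted R².

    adjusted R² = 1 − (1 − R²)(n−1)/(n−2). Exact fits give p = 0 for a
    nonzero slope and p = 1 for a constant response.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError("trend_ols needs n >= 3")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant: slope undefined")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - ym) ** 2))
    if sst == 0:
        r2 = 0.0
    else:
        r2 = 1.0 - sse / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    se = math.sqrt(sse / (n - 2) / sxx)
    if se == 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        tval = slope / se
        p = 2.0 * stats.t.sf(abs(tval), n - 2)
    return TrendFit(
        slope=slope,
        intercept=intercept,
        r2=r2,
        r2_adjusted=r2_adj,
        p_two_sided=float(p),
        stderr=se,
        n=n,
    )


def trend_sma(x: Sequence[float], y: Sequence[float]) -> float:
    """Standardized major axis slope: sign(corr) x sd(y)/sd(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValidationError("trend_sma needs n >= 3")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValidationError("zero variance: SMA slope undefined")
    corr = float(np.corrcoef(x, y)[0, 1])
    sign = -1.0 if corr < 0 else 1.0
    return sign * sy / sx


def response_ratio(mean_treated: float, mean_control: float) -> float:
    """ln(mean_treated / mean_control); both means must be > 0."""
    if mean_treated <= 0 or mean_control <= 0:
        raise ValidationError("response ratio requires strictly positive means")
    return math.log(mean_treated) - math.log(mean_control)


@dataclass
class EffectSizeSeries:
    """Per-year warmed-vs-ambient Cohen's d for one variable and management,
    with OLS and SMA trend fits of d on calendar year."""

    variable: str
    management: str
    d_by_year: dict[int, float]
    group_sizes: dict[int, tuple[int, int]]  # year -> (n_treated, n_control)
    trend_slope: float = math.nan
    trend_slope_sma: float = math.nan
    trend_r2_adjusted: float = math.nan
    trend_p: float = math.nan
    trend_fit: TrendFit | None = None

    @property
    def years(self) -> list[int]:
        return sorted(self.d_by_year)


def effect_size_series(
    measurements: MeasurementTable,
    design: StudyDesign,
    variable: str,
    management: str,
    hedges: bool = False,
) -> EffectSizeSeries:
    """Cohen's d of warming per year (blocks as replicates) plus its trend.

    Years with missing values or undefined d are skipped with a log entry;
    fewer than 3 usable years yields NA trends.
    """
    d_by_year: dict[int, float] = {}
    sizes: dict[int, tuple[int, int]] = {}
    for year in design.years:
        groups = {}
        for warming in ("warmed", "ambient"):
            vals = []
            for s in design.subset(management=management, warming=warming, year=year):
                if s.sample_id not in measurements.data.index:
                    continue
                v = measurements.value(s.sample_id, variable)
                if not math.isnan(v):
                    vals.append(v)
            groups[warming] = vals
        if len(groups["warmed"]) < 2 or len(groups["ambient"]) < 2:
            logger.info(
                "%s/%s %d: skipped (insufficient observations)",
                variable, management, year,
            )
            continue
        try:
            d = cohens_d(groups["warmed"], groups["ambient"], hedges=hedges)
        except ValidationError as exc:
            logger.info("%s/%s %d: skipped (%s)", variable, management, year, exc)
            continue
        d_by_year[year] = d
        sizes[year] = (len(groups["warmed"]), len(groups["ambient"]))
    series = EffectSizeSeries(
        variable=variable,
        management=management,
        d_by_year=d_by_year,
        group_sizes=sizes,
    )
    years = series.years
    if len(years) < 3:
        logger.info(
            "%s/%s: %d usable years; trend not fit", variable, management, len(years)
        )
        return series
    d_vals = [d_by_year[y] for y in years]
    fit = trend_ols(years, d_vals)
    series.trend_fit = fit
    series.trend_slope = fit.slope
    series.trend_r2_adjusted = fit.r2_adjusted
    series.trend_p = fit.p_two_sided
    try:
        series.trend_slope_sma = trend_sma(years, d_vals)
    except ValidationError:
        series.trend_slope_sma = math.nan
    return series


@dataclass(frozen=True)
class StageContrast:
    variable: str
    early_years: tuple[int, ...]
    late_years: tuple[int, ...]
    early_mean_d: float
    late_mean_d: float
    difference: float


def stage_contrast(
    series: EffectSizeSeries, split_year: int = DEFAULT_STAGE_SPLIT_YEAR
) -> StageContrast:
    """Mean d in the early (year <= split) vs late (year > split) stage."""
    early = [y for y in series.years if y <= split_year]
    late = [y for y in series.years if y > split_year]
    if not early or not late:
        raise ValidationError(
            f"both stages need >= 1 year with defined d (split {split_year})"
        )
    early_mean = float(np.mean([series.d_by_year[y] for y in early]))
    late_mean = float(np.mean([series.d_by_year[y] for y in late]))
    return StageContrast(
        variable=series.variable,
        early_years=tuple(early),
        late_years=tuple(late),
        early_mean_d=early_mean,
        late_mean_d=late_mean,
        difference=late_mean - early_mean,
    )
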