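"""Community temporal dynamics: rarefaction, Bray-Curtis similarity,
moving-window time-decay relationships (TDR), plot-level permutation slope
comparison, lineage TDRs, and warming-vs-control divergence series.

The TDR is the log-log regression of pairwise community similarity on
temporal distance; pairs are formed only within plot across time points
(moving-window pairing), so a plot sampled at T time points contributes
T(T-1)/2 pairs. The turnover rate v is the negated regression slope.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy import stats

from warmsoil.datamodel import (
    FeatureTable,
    StudyDesign,
    TaxonomyMap,
    ValidationError,
)
from warmsoil.effects import TrendFit, trend_ols

logger = logging.getLogger(__name__)

DEFAULT_RAREFACTION_DEPTH = {"bacteria": 24579, "fungi": 21550}


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped (logged); an error is
    raised if nothing survives.
    """
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    sums = table.column_sums()
    keep_idx = [i for i, s in enumerate(sums) if s >= depth]
    dropped = [table.sample_ids[i] for i, s in enumerate(sums) if s < depth]
    if dropped:
        logger.warning(
            "rarefy: dropped %d samples below depth %d: %s",
            len(dropped), depth, dropped,
        )
    if not keep_idx:
        raise ValidationError(f"all samples below rarefaction depth {depth}")
    cols = []
    for i in keep_idx:
        col = np.asarray(table.counts[:, i], dtype=np.int64)
        if sums[i] == depth:
            cols.append(col)
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
    return FeatureTable(
        table.taxon_ids,
        [table.sample_ids[i] for i in keep_idx],
        np.column_stack(cols),
    )


@dataclass
class SimilarityMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, unit diagonal, in [0, 1]
    metric: str = "bray-curtis"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValidationError("similarity matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValidationError("similarity matrix must be symmetric")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValidationError("similarity values must lie in [0, 1]")
        v = np.clip(v, 0.0, 1.0)
        np.fill_diagonal(v, 1.0)
        self.values = v

    def between(self, a: str, b: str) -> float:
        return float(
            self.values[self.sample_ids.index(a), self.sample_ids.index(b)]
        )


def bray_curtis_similarity(table: FeatureTable) -> SimilarityMatrix:
    """S(x, y) = 1 − Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) between all sample pairs."""
    sums = table.column_sums()
    for i, s in enumerate(sums):
        if s <= 0:
            raise ValidationError(f"zero-sum sample {table.sample_ids[i]!r}")
    dist = squareform(pdist(np.asarray(table.counts, dtype=float).T, "braycurtis"))
    return SimilarityMatrix(list(table.sample_ids), 1.0 - dist)


@dataclass(frozen=True)
class TdrPair:
    plot_id: str
    lag_years: int
    similarity: float


@dataclass
class TDRResult:
    """Log-log time-decay fit; retains the underlying point set so slopes can
    be compared by plot-level permutation."""

    treatment: str
    slope_w: float
    intercept: float
    r2: float
    r2_adjusted: float
    p_value: float
    n_pairs: int
    pairs_per_interval: dict[int, int]
    pairs: list[TdrPair]
    n_zero_dropped: int = 0

    @property
    def turnover_v(self) -> float:
        return -self.slope_w


def make_tdr_pairs(
    sim: SimilarityMatrix,
    design: StudyDesign,
    management: str | None = None,
    warming: str | None = None,
) -> list[TdrPair]:
    """Moving-window pairing: all within-plot pairs across time points,
    restricted to samples present in the similarity matrix and matching the
    treatment filter."""
    present = set(sim.sample_ids)
    by_plot: dict[str, list] = {}
    for s in design.subset(management=management, warming=warming):
        if s.sample_id in present:
            by_plot.setdefault(s.plot_id, []).append(s)
    pairs: list[TdrPair] = []
    for plot_id, samples in sorted(by_plot.items()):
        samples = sorted(samples, key=lambda s: s.year)
        for a, b in itertools.combinations(samples, 2):
            pairs.append(
                TdrPair(
                    plot_id=plot_id,
                    lag_years=abs(b.year - a.year),
                    similarity=sim.between(a.sample_id, b.sample_id),
                )
            )
    return pairs


def tdr_fit_from_pairs(pairs: Sequence[TdrPair], treatment: str = "") -> TDRResult:
    """OLS of log10(similarity) on log10(lag years) over a TDR point set.

    Zero-similarity pairs are dropped (log of 0 undefined) and counted; the
    interval census covers all formed pairs. The slope is invariant to the
    logarithm base because both axes are logged in the same base.
    """
    if not pairs:
        raise ValidationError("no TDR pairs formed")
    census = Counter(p.lag_years for p in pairs)
    usable = [p for p in pairs if p.similarity > 0]
    n_zero = len(pairs) - len(usable)
    if n_zero:
        logger.warning("tdr_fit: dropped %d zero-similarity pairs", n_zero)
    if not usable:
        raise ValidationError("all pairs have zero similarity")
    lags = sorted({p.lag_years for p in usable})
    if len(lags) < 2:
        raise ValidationError(
            f"need >= 2 distinct time lags for a TDR fit (got {lags})"
        )
    if all(p.similarity == 1.0 for p in usable):
        # e.g. a single-taxon lineage after renormalization: identical
        # communities carry no turnover information
        raise ValidationError(
            "degenerate TDR input: similarity is exactly 1 for every pair"
        )
    x = np.log10([p.lag_years for p in usable])
    y = np.log10([p.similarity for p in usable])
    fit = trend_ols(x, y)
    return TDRResult(
        treatment=treatment,
        slope_w=fit.slope,
        intercept=fit.intercept,
        r2=fit.r2,
        r2_adjusted=fit.r2_adjusted,
        p_value=fit.p_two_sided,
        n_pairs=len(pairs),
        pairs_per_interval=dict(sorted(census.items())),
        pairs=list(pairs),
        n_zero_dropped=n_zero,
    )


def tdr_fit(
    sim: SimilarityMatrix,
    design: StudyDesign,
    management: str | None = None,
    warming: str | None = None,
) -> TDRResult:
    """Moving-window TDR for one treatment (within-plot pairs only)."""
    label = "+".join(v for v in (management, warming) if v) or "all"
    pairs = make_tdr_pairs(sim, design, management=management, warming=warming)
    return tdr_fit_from_pairs(pairs, treatment=label)


def _plot_stats(pairs: Sequence[TdrPair]) -> dict[str, np.ndarray]:
    """Per-plot OLS sufficient statistics (n, Σx, Σy, Σxx, Σxy) on log10 axes,
    zero-similarity pairs excluded."""
    out: dict[str, np.ndarray] = {}
    for p in pairs:
        if p.similarity <= 0:
            continue
        x = math.log10(p.lag_years)
        y = math.log10(p.similarity)
        s = out.setdefault(p.plot_id, np.zeros(5))
        s += (1.0, x, y, x * x, x * y)
    return out


def _slope_from_stats(stats_sum: np.ndarray) -> float:
    n, sx, sy, sxx, sxy = stats_sum
    denom = n * sxx - sx * sx
    if denom == 0:
        return math.nan
    return (n * sxy - sx * sy) / denom


def tdr_slope_compare(
    result_a: TDRResult,
    result_b: TDRResult,
    n_perm: int,
    seed: int,
) -> float:
    """Two-sided plot-level permutation test for a TDR slope difference.

    Plots (the experimental units) are exchanged between groups wholesale —
    all of a plot's pairs move together. p = (1 + #{|Δslope_perm| >=
    |Δslope_obs|}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    stats_a = _plot_stats(result_a.pairs)
    stats_b = _plot_stats(result_b.pairs)
    plots = [(k, v) for k, v in stats_a.items()] + [
        (k, v) for k, v in stats_b.items()
    ]
    n_a = len(stats_a)
    if n_a == 0 or len(stats_b) == 0:
        raise ValidationError("both results need at least one plot with pairs")
    arr = np.stack([v for _, v in plots])

    def slope_diff(idx_a: np.ndarray) -> float:
        mask = np.zeros(len(plots), dtype=bool)
        mask[idx_a] = True
        return _slope_from_stats(arr[mask].sum(axis=0)) - _slope_from_stats(
            arr[~mask].sum(axis=0)
        )

    obs = abs(slope_diff(np.arange(n_a)))
    rng = np.random.default_rng(seed)
    n_ge = 0
    indices = np.arange(len(plots))
    for _ in range(n_perm):
        perm = rng.permutation(indices)
        if abs(slope_diff(perm[:n_a])) >= obs:
            n_ge += 1
    return (1 + n_ge) / (1 + n_perm)


def lineage_tdr(
    table: FeatureTable,
    taxonomy: TaxonomyMap,
    rank: str,
    lineage: str,
    design: StudyDesign,
    management: str | None = None,
    warming: str | None = None,
    similarity: Callable[[FeatureTable], SimilarityMatrix] = bray_curtis_similarity,
    min_share: float = 0.0,
    min_prevalence: float = 0.8,
) -> TDRResult:
    """TDR of one taxonomic lineage: subset, renormalize, delegate to tdr_fit.

    Lineages whose count share falls below ``min_share`` in more than
    ``1 - min_prevalence`` of samples are flagged in the log but still fit.
    """
    taxa = taxonomy.taxa_at(rank, lineage)
    taxa = [t for t in taxa if t in set(table.taxon_ids)]
    if not taxa:
        raise ValidationError(f"no taxa in table for {rank}={lineage!r}")
    sub = table.subset_taxa(taxa)
    if min_share > 0:
        shares = sub.column_sums() / np.maximum(table.column_sums(), 1)
        frac_ok = float(np.mean(shares >= min_share))
        if frac_ok < min_prevalence:
            logger.warning(
                "lineage %s=%s below share %.3g in %.0f%% of samples",
                rank, lineage, min_share, 100 * (1 - frac_ok),
            )
    zero = sub.column_sums() == 0
    if np.any(zero):
        keep = [s for s, z in zip(sub.sample_ids, zero) if not z]
        logger.warning(
            "lineage %s=%s absent from %d samples; excluded",
            rank, lineage, int(zero.sum()),
        )
        sub = sub.subset_samples(keep)
    sim = similarity(sub.relative_abundance())
    result = tdr_fit(sim, design, management=management, warming=warming)
    result.treatment = f"{result.treatment}:{rank}={lineage}"
    return result


def lineage_tdr_relative_change(v_warm: float, v_control: float) -> float:
    """(v_warm − v_control) / v_control."""
    if v_control <= 0:
        raise ValidationError("v_control must be > 0")
    return (v_warm - v_control) / v_control


@dataclass
class DivergenceSeries:
    """Paired warmed-vs-ambient dissimilarity per (block, year) within one
    management, with an OLS trend of dissimilarity on calendar year."""

    management: str
    values: dict[int, dict[int, float]]  # year -> block -> dissimilarity
    trend_slope: float = math.nan
    trend_r2: float = math.nan
    trend_p: float = math.nan
    trend_fit: TrendFit | None = None

    @property
    def years(self) -> list[int]:
        return sorted(self.values)


def divergence_series(
    sim: SimilarityMatrix,
    design: StudyDesign,
    management: str,
) -> DivergenceSeries:
    """Warming-induced community divergence trajectory for one management.

    For each (block, year) with both a warmed and an ambient sample present,
    records their Bray-Curtis dissimilarity (1 − similarity); pairs with a
    missing member are skipped with a log entry. The trend is fit only when
    >= 3 years carry data.
    """
    present = set(sim.sample_ids)
    values: dict[int, dict[int, float]] = {}
    for year in design.years:
        for block in design.blocks:
            warmed = [
                s
                for s in design.subset(
                    management=management, warming="warmed", block=block, year=year
                )
                if s.sample_id in present
            ]
            ambient = [
                s
                for s in design.subset(
                    management=management, warming="ambient", block=block, year=year
                )
                if s.sample_id in present
            ]
            if len(warmed) != 1 or len(ambient) != 1:
                logger.info(
                    "divergence %s block %d year %d: missing pair member; skipped",
                    management, block, year,
                )
                continue
            d = 1.0 - sim.between(warmed[0].sample_id, ambient[0].sample_id)
            values.setdefault(year, {})[block] = d
    series = DivergenceSeries(management=management, values=values)
    xs = [y for y in sorted(values) for _ in values[y]]
    ys = [values[y][b] for y in sorted(values) for b in sorted(values[y])]
    if len(set(xs)) < 3:
        logger.info("divergence %s: < 3 years with data; trend not fit", management)
        return series
    fit = trend_ols(xs, ys)
    series.trend_fit = fit
    series.trend_slope = fit.slope
    series.trend_r2 = fit.r2_adjusted
    series.trend_p = fit.p_two_sided
    return series
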