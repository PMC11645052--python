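"""Group-level statistics for entropy grids.

For each (channel, scale) cell of an entropy grid the two groups are
compared with a pooled-variance two-sample t-test (two-sided, alpha 0.05 by
default, df = N_HS + N_AD - 2) together with Cohen's D. Two summary
quantities aggregate a whole grid:

* PSC, the percentage of significant comparisons:
  ``100 * #(p_i < alpha) / (N_scales * N_channels)`` (strict inequality);
* the mean Cohen's D magnitude across cells (the signed mean is also kept),
  with a population-form (divisor N) spread.

Assumption checks — Lilliefors normality per group and mean-centered Levene
homogeneity — are recorded per cell but never gate the t-test (with groups
of 30 the test leans on the central limit theorem). No multiple-testing
correction is applied: PSC deliberately counts raw ``p < alpha``.

Statistical power for the balanced design uses the central-t shift
approximation: with ``t_crit`` the upper ``1 - alpha/2`` quantile of the
central t distribution on ``df`` degrees of freedom,

    beta = T_df( t_crit - d_mean * sqrt(n1 * n2 / (n1 + n2)) ),
    power = 100 * (1 - beta).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

__all__ = [
    "pooled_t_test",
    "lilliefors_statistic",
    "lilliefors_test",
    "levene_test",
    "ComparisonGrid",
    "compare_groups",
    "psc",
    "cohens_d",
    "EffectSummary",
    "summarize_effects",
    "PowerResult",
    "t_test_power",
]


def pooled_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Student's two-sample t-test with pooled variance; returns (t, p, df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    df = na + nb - 2
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, 1.0, df
        raise ValueError("zero pooled variance with unequal means")
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p), df


def lilliefors_statistic(x: np.ndarray) -> float:
    """KS distance between the sample and a normal with estimated mean/SD."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample")
    z = np.sort((x - x.mean()) / sd)
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


@lru_cache(maxsize=64)
def _lilliefors_null(n: int, n_mc: int, seed: int) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of the statistic for sample size n.

    The statistic is location/scale free, so standard-normal draws suffice.
    Cached per (n, n_mc, seed) — a grid of several hundred cells with the
    same group size pays the simulation cost once.
    """
    rng = np.random.default_rng(seed)
    stats = np.empty(n_mc)
    block = max(1, int(5_000_000 / n))
    i = np.arange(1, n + 1)
    done = 0
    while done < n_mc:
        k = min(block, n_mc - done)
        x = rng.standard_normal((k, n))
        mean = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        z = np.sort((x - mean) / sd, axis=1)
        cdf = sps.norm.cdf(z)
        d_plus = (i / n - cdf).max(axis=1)
        d_minus = (cdf - (i - 1) / n).max(axis=1)
        stats[done:done + k] = np.maximum(d_plus, d_minus)
        done += k
    return np.sort(stats)


def lilliefors_test(x: np.ndarray, n_mc: int = 10_000, seed: int = 0) -> float:
    """Lilliefors normality test; p-value from a seeded Monte-Carlo null."""
    stat = lilliefors_statistic(x)
    null = _lilliefors_null(len(np.asarray(x)), n_mc, seed)
    n_ge = len(null) - np.searchsorted(null, stat, side="left")
    return float((n_ge + 1) / (len(null) + 1))


def levene_test(a: np.ndarray, b: np.ndarray) -> float:
    """Classic mean-centered Levene test of equal variances (two groups)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std() == 0 and b.std() == 0:
        raise ValueError("both groups constant")
    if np.array_equal(a, b):
        return 1.0
    _, p = sps.levene(a, b, center="mean")
    return float(p)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference (group a minus group b, pooled SD)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


@dataclass
class ComparisonGrid:
    """Per-(channel, scale) group-comparison results for one combination."""

    t: np.ndarray            # channels x scales
    p: np.ndarray
    d: np.ndarray
    alpha: float
    n_hs: int
    n_ad: int
    combination_id: int | None = None
    amplitude_state: str | None = None
    normality_p: np.ndarray | None = None  # min over the two groups
    levene_p: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("t", "p", "d"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"{name} must be channels x scales")
            setattr(self, name, arr)
        if self.t.shape != self.p.shape or self.t.shape != self.d.shape:
            raise ValueError("t, p, d shapes differ")

    @property
    def df(self) -> int:
        return self.n_hs + self.n_ad - 2

    @property
    def n_cells(self) -> int:
        return self.t.size


def compare_groups(hs_values: np.ndarray, ad_values: np.ndarray,
                   alpha: float = 0.05, check_assumptions: bool = True,
                   lilliefors_mc: int = 10_000, lilliefors_seed: int = 0,
                   combination_id: int | None = None,
                   amplitude_state: str | None = None) -> ComparisonGrid:
    """Cell-wise HS-vs-AD comparison of two (subjects x channels x scales) blocks."""
    hs = np.asarray(hs_values, dtype=float)
    ad = np.asarray(ad_values, dtype=float)
    if hs.ndim != 3 or ad.ndim != 3 or hs.shape[1:] != ad.shape[1:]:
        raise ValueError("expected subjects x channels x scales blocks with "
                         "matching channel/scale dimensions")
    n_hs, n_ch, n_sc = hs.shape
    n_ad = ad.shape[0]
    df = n_hs + n_ad - 2

    sp2 = ((n_hs - 1) * hs.var(axis=0, ddof=1)
           + (n_ad - 1) * ad.var(axis=0, ddof=1)) / df
    diff = hs.mean(axis=0) - ad.mean(axis=0)
    sp = np.sqrt(sp2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / (sp * np.sqrt(1.0 / n_hs + 1.0 / n_ad))
        d = diff / sp
    if np.any((sp2 == 0) & (diff != 0)):
        raise ValueError("zero pooled variance with unequal means in some cell")
    t = np.where(sp2 == 0, 0.0, t)
    p = np.where(t == 0, 1.0, 2.0 * sps.t.sf(np.abs(t), df))

    norm_p = lev_p = None
    if check_assumptions:
        norm_p = np.empty((n_ch, n_sc))
        lev_p = np.empty((n_ch, n_sc))
        for c in range(n_ch):
            for s in range(n_sc):
                a, b = hs[:, c, s], ad[:, c, s]
                norm_p[c, s] = min(
                    lilliefors_test(a, lilliefors_mc, lilliefors_seed),
                    lilliefors_test(b, lilliefors_mc, lilliefors_seed))
                lev_p[c, s] = levene_test(a, b)
    return ComparisonGrid(t=t, p=p, d=d, alpha=alpha, n_hs=n_hs, n_ad=n_ad,
                          combination_id=combination_id,
                          amplitude_state=amplitude_state,
                          normality_p=norm_p, levene_p=lev_p)


def psc(grid: ComparisonGrid) -> float:
    """Percentage of cells with p strictly below alpha."""
    if grid.n_cells == 0:
        raise ValueError("empty comparison grid")
    return float(100.0 * np.count_nonzero(grid.p < grid.alpha) / grid.n_cells)


@dataclass
class EffectSummary:
    """Grid-level aggregates mirroring the published per-combination rows."""

    d_mean: float            # mean |d| across cells
    d_sd: float              # population-form spread of |d|
    d_mean_signed: float
    t_range: tuple[float, float]  # (min |t|, max |t|)
    p_range: tuple[float, float]
    psc: float
    combination_id: int | None = None
    amplitude_state: str | None = None


def summarize_effects(grid: ComparisonGrid) -> EffectSummary:
    abs_d = np.abs(grid.d)
    abs_t = np.abs(grid.t)
    return EffectSummary(
        d_mean=float(abs_d.mean()),
        d_sd=float(abs_d.std()),  # divisor N
        d_mean_signed=float(grid.d.mean()),
        t_range=(float(abs_t.min()), float(abs_t.max())),
        p_range=(float(grid.p.min()), float(grid.p.max())),
        psc=psc(grid),
        combination_id=grid.combination_id,
        amplitude_state=grid.amplitude_state,
    )


@dataclass
class PowerResult:
    cd_mean: float
    n_hs: int
    n_ad: int
    alpha: float
    df: int
    t_critical: float
    beta: float
    power: float  # percent


def t_test_power(cd_mean: float, n_hs: int, n_ad: int,
                 alpha: float = 0.05) -> PowerResult:
    """Two-sample t-test power under the central-t shift approximation."""
    if cd_mean < 0:
        raise ValueError("cd_mean must be non-negative")
    if n_hs < 2 or n_ad < 2:
        raise ValueError("group sizes must be at least 2")
    df = n_hs + n_ad - 2
    t_crit = float(sps.t.ppf(1.0 - alpha / 2.0, df))
    shift = cd_mean * np.sqrt(n_hs * n_ad / (n_hs + n_ad))
    beta = float(sps.t.cdf(t_crit - shift, df))
    return PowerResult(cd_mean=cd_mean, n_hs=n_hs, n_ad=n_ad, alpha=alpha,
                       df=df, t_critical=t_crit, beta=beta,
                       power=100.0 * (1.0 - beta))
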