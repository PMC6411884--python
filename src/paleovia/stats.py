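"""Nonparametric statistics for DNA-damage-index cohorts and development outcomes.

The central procedure is the Steel many-one test: several treatment groups
are each compared with a single shared control by Wilcoxon rank-sum
statistics, and the family-wise adjustment comes from the joint permutation
distribution of the maximum standardized statistic.  Small problems are
enumerated exactly; larger ones use Monte-Carlo resampling.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "GroupedSamples",
    "SteelResult",
    "steel_test",
    "check_normality",
    "check_homoscedasticity",
    "fisher_exact_outcome",
]


@dataclass
class GroupedSamples:
    """A control sample plus named treatment samples (unitless values)."""

    control: np.ndarray
    treatments: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, dtype=float)
        self.treatments = {k: np.asarray(v, dtype=float) for k, v in self.treatments.items()}
        if self.control.size == 0:
            raise ValueError("control group is empty")
        for name, vals in self.treatments.items():
            if vals.size == 0:
                raise ValueError(f"treatment group {name!r} is empty")


@dataclass
class SteelResult:
    statistics: dict[str, float]  # standardized rank-sum z per treatment
    p_values: dict[str, float]  # family-wise adjusted
    alternative: str
    n_permutations: int
    exact: bool  # True when all label assignments were enumerated
    seed: int | None = None
    rank_sums: dict[str, float] = field(default_factory=dict)


def _pairwise_greater(values: np.ndarray) -> np.ndarray:
    """M[i, j] = 1 if v_i > v_j, 0.5 on ties: building block of Mann-Whitney U."""
    v = values[:, None]
    return (v > values[None, :]).astype(float) + 0.5 * (v == values[None, :])


def _tie_correction(values: np.ndarray) -> float:
    n = values.size
    if n < 2:
        return 1.0
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - (counts**3 - counts).sum() / (n**3 - n)


def _enumerate_assignments(n_total: int, sizes: list[int]):
    """Yield tuples of index arrays, one per group, over all distinct label assignments."""

    def rec(remaining: tuple[int, ...], sizes_left: list[int], acc: list[np.ndarray]):
        if len(sizes_left) == 1:
            yield acc + [np.array(remaining, dtype=int)]
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            yield from rec(rest, sizes_left[1:], acc + [np.array(combo, dtype=int)])

    yield from rec(tuple(range(n_total)), sizes, [])


def _n_assignments(n_total: int, sizes: list[int]) -> int:
    out = math.factorial(n_total)
    for s in sizes:
        out //= math.factorial(s)
    return out


def steel_test(
    data: GroupedSamples,
    alternative: str = "two-sided",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> SteelResult:
    """Steel many-one comparison of each treatment against the control.

    For each treatment the Mann-Whitney U of treatment vs control (mid-ranks
    for ties) is standardized; family-wise adjusted p-values are taken from
    the permutation distribution of the maximum standardized statistic under
    joint relabelling of all observations.  When the number of distinct label
    assignments does not exceed ``n_permutations`` the null is enumerated
    exactly; otherwise ``n_permutations`` random relabellings are drawn
    (requires ``seed``).
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    if n_permutations < 100:
        raise ValueError("n_permutations < 100 gives an unstable null; use at least 100")
    if data.control.size < 2:
        raise ValueError("need at least 2 control observations")
    for name, vals in data.treatments.items():
        if vals.size < 2:
            raise ValueError(f"need at least 2 observations in treatment {name!r}")

    names = list(data.treatments)
    pooled = np.concatenate([data.control] + [data.treatments[k] for k in names])
    n_c = data.control.size
    sizes = [n_c] + [data.treatments[k].size for k in names]
    n_total = pooled.size
    offsets = np.cumsum([0] + sizes)

    M = _pairwise_greater(pooled)
    tie_corr = _tie_correction(pooled)

    mus, sds = [], []
    for t, name in enumerate(names):
        n_t = sizes[t + 1]
        mus.append(n_c * n_t / 2.0)
        var = n_c * n_t * (n_c + n_t + 1) / 12.0 * tie_corr
        sds.append(math.sqrt(var) if var > 0 else 0.0)
    mus_a, sds_a = np.array(mus), np.array(sds)

    cidx = np.arange(n_c)
    obs_u = np.array(
        [M[np.ix_(np.arange(offsets[t + 1], offsets[t + 2]), cidx)].sum() for t in range(len(names))]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_z = np.where(sds_a > 0, (obs_u - mus_a) / sds_a, 0.0)
    obs_stat = obs_z if alternative == "greater" else np.abs(obs_z)

    total = _n_assignments(n_total, sizes)
    exact = total <= n_permutations
    if exact:
        max_stats = np.empty(total)
        for b, groups in enumerate(_enumerate_assignments(n_total, sizes)):
            c = groups[0]
            zb = np.empty(len(names))
            for t in range(len(names)):
                u = M[np.ix_(groups[t + 1], c)].sum()
                zb[t] = (u - mus_a[t]) / sds_a[t] if sds_a[t] > 0 else 0.0
            stat = zb if alternative == "greater" else np.abs(zb)
            max_stats[b] = stat.max()
        # exact p: proportion of assignments with max statistic >= observed
        p = np.array([(max_stats >= s - 1e-12).mean() for s in obs_stat])
        n_used = total
    else:
        if seed is None:
            raise ValueError("seed is required for Monte-Carlo permutation")
        rng = np.random.default_rng(seed)
        B = n_permutations
        perms = np.argsort(rng.random((B, n_total)), axis=1)
        rows = np.arange(B)[:, None]
        cmask = np.zeros((B, n_total))
        cmask[rows, perms[:, :n_c]] = 1.0
        max_stats = np.full(B, -np.inf)
        for t in range(len(names)):
            tmask = np.zeros((B, n_total))
            tmask[rows, perms[:, offsets[t + 1] : offsets[t + 2]]] = 1.0
            u = ((tmask @ M) * cmask).sum(axis=1)
            z = (u - mus_a[t]) / sds_a[t] if sds_a[t] > 0 else np.zeros(B)
            stat = z if alternative == "greater" else np.abs(z)
            np.maximum(max_stats, stat, out=max_stats)
        p = np.array([(1 + (max_stats >= s - 1e-12).sum()) / (B + 1) for s in obs_stat])
        n_used = B

    return SteelResult(
        statistics={k: float(z) for k, z in zip(names, obs_z)},
        p_values={k: float(min(1.0, pv)) for k, pv in zip(names, p)},
        alternative=alternative,
        n_permutations=n_used,
        exact=exact,
        seed=seed,
        rank_sums={k: float(u + sizes[t + 1] * (sizes[t + 1] + 1) / 2) for t, (k, u) in enumerate(zip(names, obs_u))},
    )


def check_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk test of normality; (W, p)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    res = _sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def check_homoscedasticity(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Bartlett's test of equal variances across named groups; (chi2, p)."""
    if len(groups) < 2:
        raise ValueError("Bartlett test needs at least 2 groups")
    arrays = []
    for name, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        if x.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        if np.ptp(x) == 0:
            raise ValueError(f"group {name!r} is constant: variance test undefined")
        arrays.append(x)
    res = _sps.bartlett(*arrays)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_outcome(table, alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 development-outcome table; (odds ratio, p).

    A zero margin makes the table degenerate: p = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if t.sum() == 0:
        raise ValueError("empty table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p set to 1", stacklevel=2)
        odds = _sps.contingency.odds_ratio(t, kind="sample")
        return float(odds.statistic) if np.isfinite(odds.statistic) else float("nan"), 1.0
    orat, p = _sps.fisher_exact(t, alternative=alternative)
    return float(orat), float(p)
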