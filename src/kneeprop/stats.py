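"""Small-sample rank inference, power analysis and questionnaire scoring.

With 7 participants per arm, the group comparison of improvement scores
uses the exact Mann-Whitney U test: the null distribution of U is obtained
by the standard counting recurrence over all C(n1+n2, n1) rank assignments,
so p-values are exact rather than normal approximations.  The module also
provides the descriptives (median, IQR), a noncentral-F a-priori sample-
size search matching the repeated-measures between-factors ANOVA power
model, a programmatic normal Q-Q correlation screen, and scoring for the
Intrinsic Motivation Inventory (7-point items, four subscales) and the
User Experience Questionnaire (−3..+3 items, six dimensions grouped into
pragmatic and hedonic quality).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

MAX_EXACT_N = 25

UEQ_PRAGMATIC = ("perspicuity", "efficiency", "dependability")
UEQ_HEDONIC = ("stimulation", "novelty")


@dataclass
class RankTestResult:
    U: float
    p: float
    alternative: str               # "one_sided_greater" | "two_sided"
    method: str                    # "exact" | "normal_approx"
    n1: int
    n2: int


@dataclass
class PowerSpec:
    effect_f: float = 0.78
    alpha: float = 0.05
    target_power: float = 0.80
    n_groups: int = 2
    n_measurements: int = 2
    rho: float = 0.5

    def __post_init__(self):
        if not (0 < self.alpha < 1 and 0 < self.target_power < 1):
            raise ValueError("alpha and target_power must lie in (0, 1)")
        if self.effect_f <= 0 or self.n_groups < 2 or self.n_measurements < 1:
            raise ValueError("invalid power specification")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")


@lru_cache(maxsize=256)
def exact_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Counts of rank assignments per U value for two groups of sizes
    ``n1``, ``n2`` under the null.

    Uses the recurrence ``c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u)``;
    the returned array has length ``n1*n2 + 1``, sums to C(n1+n2, n1) and is
    symmetric about ``n1*n2/2``.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if n1 + n2 > MAX_EXACT_N:
        raise ValueError(f"exact U distribution limited to n1+n2 <= {MAX_EXACT_N}")
    # dp[j, u] = number of assignments with j of the first group among the
    # smallest ranks processed so far achieving statistic u
    dp = np.zeros((n1 + 1, n1 * n2 + 1), dtype=np.int64)
    dp[0, 0] = 1
    # process the pooled sample one observation at a time: adding an
    # x-observation above all current ones adds (number of y's so far) to U
    counts = dp
    for total in range(1, n1 + n2 + 1):
        new = np.zeros_like(counts)
        for j in range(0, min(n1, total) + 1):
            n_y = total - j
            if n_y > n2:
                continue
            # current observation is from x: U gains n_y - ... simpler:
            # recurrence on (j, n_y): largest element is x -> U += n_y
            if j >= 1:
                shift = n_y
                new[j, shift:] += counts[j - 1, : counts.shape[1] - shift] if shift else counts[j - 1]
            # largest element is y: U unchanged
            if n_y >= 1:
                new[j] += counts[j]
        counts = new
    return counts[n1]


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: x.size].sum()
    u1 = r1 - x.size * (x.size + 1) / 2.0
    return float(u1), ranks


def mann_whitney(x, y, alternative: str = "one_sided_greater") -> RankTestResult:
    """Mann-Whitney U test of ``x`` vs ``y``.

    The statistic counts pairs (x_i, y_j) with x_i > y_j, ties counting a
    half.  When the samples are tie-free and small enough, the p-value is
    exact (enumerated null distribution); otherwise a tie-corrected normal
    approximation with continuity correction is used.  "Greater" means the
    first sample is stochastically greater.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("one_sided_greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    u1, ranks = _u_statistic(x, y)
    has_ties = np.unique(np.concatenate([x, y])).size < n1 + n2

    if not has_ties and n1 + n2 <= MAX_EXACT_N:
        counts = exact_u_distribution(n1, n2)
        total = counts.sum()
        u_int = int(round(u1))
        p_ge = counts[u_int:].sum() / total
        p_le = counts[: u_int + 1].sum() / total
        p = p_ge if alternative == "one_sided_greater" else min(1.0, 2.0 * min(p_ge, p_le))
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        tie_sizes = np.unique(ranks, return_counts=True)[1]
        tie_term = ((tie_sizes**3 - tie_sizes).sum()) / ((n1 + n2) * (n1 + n2 - 1))
        sigma2 = n1 * n2 / 12.0 * ((n1 + n2 + 1) - tie_term)
        sigma = np.sqrt(sigma2)
        if sigma == 0:
            p = 1.0
        elif alternative == "one_sided_greater":
            p = float(sps.norm.sf((u1 - mu - 0.5) / sigma))
        else:
            z = (np.abs(u1 - mu) - 0.5) / sigma
            p = float(min(1.0, 2.0 * sps.norm.sf(z)))
        method = "normal_approx"
    return RankTestResult(U=u1, p=float(p), alternative=alternative,
                          method=method, n1=n1, n2=n2)


def exact_p_from_u(u: float, n1: int, n2: int, alternative: str = "two_sided") -> float:
    """Exact p-value for an already-computed (tie-free) U statistic."""
    counts = exact_u_distribution(n1, n2)
    total = counts.sum()
    u_int = int(round(u))
    p_ge = counts[u_int:].sum() / total
    p_le = counts[: u_int + 1].sum() / total
    if alternative == "one_sided_greater":
        return float(p_ge)
    if alternative == "two_sided":
        return float(min(1.0, 2.0 * min(p_ge, p_le)))
    raise ValueError(f"unknown alternative {alternative!r}")


def describe(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) by inclusive linear interpolation."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot describe an empty sample")
    q1, med, q3 = np.percentile(vals, [25.0, 50.0, 75.0], method="linear")
    return float(med), float(q1), float(q3)


def qq_normality_corr(values) -> float:
    """Correlation of the sample's order statistics with normal quantiles —
    a programmatic stand-in for visual Q-Q inspection (1 = perfectly
    normal-looking)."""
    vals = np.sort(np.asarray(list(values), dtype=float))
    n = vals.size
    if n < 3 or np.ptp(vals) == 0:
        return float("nan")
    probs = (np.arange(1, n + 1) - 0.375) / (n + 0.25)    # Blom plotting positions
    theo = sps.norm.ppf(probs)
    return float(np.corrcoef(vals, theo)[0, 1])


def anova_power(n_total: int, spec: PowerSpec) -> float:
    """Power of the between-factors repeated-measures ANOVA F test at a
    balanced total sample size, using the noncentral F distribution with
    λ = f²·N·m / (1 + (m−1)·ρ)."""
    df1 = spec.n_groups - 1
    df2 = n_total - spec.n_groups
    if df2 < 1:
        return 0.0
    lam = spec.effect_f**2 * n_total * spec.n_measurements / (
        1.0 + (spec.n_measurements - 1) * spec.rho
    )
    f_crit = sps.f.ppf(1.0 - spec.alpha, df1, df2)
    return float(sps.ncf.sf(f_crit, df1, df2, lam))


def required_sample_size(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest balanced total N (multiple of the group count) whose
    between-factors power reaches the target."""
    step = spec.n_groups
    for n in range(2 * spec.n_groups, n_max + 1, step):
        if anova_power(n, spec) >= spec.target_power:
            return n
    raise RuntimeError(f"target power not reachable within N <= {n_max}")


# ---------------------------------------------------------------------------
# Questionnaire scoring


def score_imi(
    items: dict[str, list],
    reverse_map: dict[str, list[int]] | None = None,
    mode: str = "sum",
) -> dict[str, float]:
    """Score IMI subscales from 7-point items.

    ``items`` maps subscale → item values (1..7); ``reverse_map`` lists
    1-based indices of reverse-worded items (mapped x → 8 − x before
    aggregation).  Modes: ``sum`` (raw item sum), ``mean`` (item mean) or
    ``centered_sum`` (sum of x − 4, symmetric about the scale midpoint).
    """
    if mode not in ("sum", "mean", "centered_sum"):
        raise ValueError(f"unknown IMI mode {mode!r}")
    reverse_map = reverse_map or {}
    out = {}
    for subscale, vals in items.items():
        arr = np.asarray(list(vals), dtype=float)
        if np.any((arr < 1) | (arr > 7)):
            raise ValueError(f"IMI subscale {subscale!r}: items must lie in [1, 7]")
        for idx in reverse_map.get(subscale, []):
            arr[idx - 1] = 8.0 - arr[idx - 1]
        if mode == "sum":
            out[subscale] = float(arr.sum())
        elif mode == "mean":
            out[subscale] = float(arr.mean())
        else:
            out[subscale] = float((arr - 4.0).sum())
    return out


def score_ueq(
    items: dict[str, list],
    reverse_map: dict[str, list[int]] | None = None,
) -> dict[str, float]:
    """Score UEQ dimensions (mean of −3..+3 items, reverse-polarity items
    negated) and the pragmatic/hedonic quality aggregates."""
    reverse_map = reverse_map or {}
    dims = {}
    for dim, vals in items.items():
        arr = np.asarray(list(vals), dtype=float)
        if np.any((arr < -3) | (arr > 3)):
            raise ValueError(f"UEQ dimension {dim!r}: items must lie in [-3, 3]")
        for idx in reverse_map.get(dim, []):
            arr[idx - 1] = -arr[idx - 1]
        dims[dim] = float(arr.mean())
    return {**dims, **ueq_quality_aggregates(dims)}


def ueq_quality_aggregates(dimension_means: dict[str, float]) -> dict[str, float]:
    """Pragmatic quality = mean of perspicuity, efficiency and
    dependability; hedonic quality = mean of stimulation and novelty."""
    out = {}
    if all(d in dimension_means for d in UEQ_PRAGMATIC):
        out["pragmatic"] = float(np.mean([dimension_means[d] for d in UEQ_PRAGMATIC]))
    if all(d in dimension_means for d in UEQ_HEDONIC):
        out["hedonic"] = float(np.mean([dimension_means[d] for d in UEQ_HEDONIC]))
    return out
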