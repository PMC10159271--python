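"""Statistical kernels for control-vs-dose comparisons.

Implements the two-sided Dunnett many-to-one test (pooled within-group
variance over all groups, p-values from the equicorrelated multivariate-t
distribution), the Dunnett critical distance, a Welch unequal-variance
t-test with confidence interval, Cohen's d, and the extreme-contrast
analysis used to gauge relevance limits of a historical-control pool.

The multivariate-t tail probability is evaluated by deterministic
quadrature (Gauss-Legendre over the pooled-SD mixing variable,
Gauss-Hermite over the shared-control factor), accurate to ~1e-6 and
bit-reproducible across runs, which the resampling engine relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import special
from scipy import stats as _sps
from scipy.optimize import brentq

__all__ = [
    "DunnettResult",
    "GroupComparison",
    "WelchResult",
    "ExtremeContrast",
    "dunnett_test",
    "dunnett_critical_distance",
    "dunnett_quantile",
    "welch_test",
    "cohens_d",
    "extreme_contrast",
]

_N_LEGENDRE = 96
_N_HERMITE = 64


@lru_cache(maxsize=128)
def _chi_nodes(df: int) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes/weights for S = sqrt(chi2_df / df)."""
    lo = math.sqrt(_sps.chi2.ppf(1e-13, df) / df)
    hi = math.sqrt(_sps.chi2.isf(1e-13, df) / df)
    x, w = np.polynomial.legendre.leggauss(_N_LEGENDRE)
    s = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    log_pdf = (
        math.log(2.0)
        + 0.5 * df * math.log(df / 2.0)
        - special.gammaln(df / 2.0)
        + (df - 1) * np.log(s)
        - df * s**2 / 2.0
    )
    return s, w * 0.5 * (hi - lo) * np.exp(log_pdf)


@lru_cache(maxsize=1)
def _hermite_nodes() -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(_N_HERMITE)
    return x * math.sqrt(2.0), w / math.sqrt(math.pi)


def _maxabs_t_cdf_many(t, lambdas: tuple[float, ...], df: int) -> np.ndarray:
    """P(max_i |T_i| <= t) for equicorrelated multivariate t, vectorized in t.

    T_i = Z_i / S with corr(Z_i, Z_j) = lambda_i * lambda_j and
    S = sqrt(chi2_df / df); lambda_i = sqrt(n_i / (n_i + n_0)) for the
    many-to-one design.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    s, ws = _chi_nodes(df)
    z, wz = _hermite_nodes()
    lam = np.asarray(lambdas)
    gam = np.sqrt(1.0 - lam**2)
    u = t[:, None] * s  # (nt, ns)
    a = (u[..., None, None] - lam * z[None, None, :, None]) / gam
    b = (-u[..., None, None] - lam * z[None, None, :, None]) / gam
    prod = np.prod(special.ndtr(a) - special.ndtr(b), axis=3)  # (nt, ns, nz)
    out = np.clip((prod @ wz) @ ws, 0.0, 1.0)
    out[t <= 0.0] = 0.0
    return out


def _maxabs_t_cdf(t: float, lambdas: tuple[float, ...], df: int) -> float:
    return float(_maxabs_t_cdf_many(t, lambdas, df)[0])


@lru_cache(maxsize=1024)
def dunnett_quantile(alpha: float, lambdas: tuple[float, ...], df: int) -> float:
    """Two-sided Dunnett quantile q with P(max_i |T_i| <= q) = 1 - alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return brentq(
        lambda q: _maxabs_t_cdf(q, lambdas, df) - (1.0 - alpha), 1e-9, 50.0,
        xtol=1e-10,
    )


@dataclass(frozen=True)
class GroupComparison:
    """One dose-group-vs-control contrast inside a Dunnett test."""

    label: str
    n: int
    mean_difference: float
    t_statistic: float
    p_value: float
    significant: bool
    direction: str  # "increase", "decrease" or "none"
    critical_distance: float


@dataclass(frozen=True)
class DunnettResult:
    comparisons: tuple[GroupComparison, ...]
    pooled_sd: float
    degrees_of_freedom: int
    alpha: float
    critical_distance: float | None  # common value when group sizes are equal

    @property
    def significant_flags(self) -> tuple[bool, ...]:
        return tuple(c.significant for c in self.comparisons)

    @property
    def directions(self) -> tuple[str, ...]:
        return tuple(c.direction for c in self.comparisons)


def dunnett_test(
    control,
    dose_groups,
    alpha: float = 0.05,
    labels: tuple[str, ...] | None = None,
) -> DunnettResult:
    """Two-sided Dunnett many-to-one test of each dose group vs control.

    The pooled within-group variance uses all groups (control and doses)
    with N_total - k_groups degrees of freedom; adjusted p-values come
    from the maximum-|t| distribution of the equicorrelated multivariate
    t, so p_i = 1 - P(max_j |T_j| <= |t_i|).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    groups = [np.asarray(control, dtype=float)] + [
        np.asarray(g, dtype=float) for g in dose_groups
    ]
    if len(groups) < 2:
        raise ValueError("at least one dose group is required")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    k = len(groups) - 1
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    n_total = int(ns.sum())
    df = n_total - len(groups)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    pooled_var = ss_within / df
    pooled_sd = math.sqrt(pooled_var)

    diffs = means[1:] - means[0]
    if labels is None:
        labels = tuple(f"DG{i + 1}" for i in range(k))

    lambdas = tuple(math.sqrt(n_i / (n_i + ns[0])) for n_i in ns[1:])
    se = pooled_sd * np.sqrt(1.0 / ns[1:] + 1.0 / ns[0])

    if pooled_sd == 0.0:
        if np.any(diffs != 0.0):
            raise ValueError("zero pooled variance with unequal group means")
        t_stats = np.zeros(k)
        p_values = np.ones(k)
        crit_dists = np.zeros(k)
    else:
        t_stats = diffs / se
        p_values = 1.0 - _maxabs_t_cdf_many(np.abs(t_stats), lambdas, df)
        q = dunnett_quantile(alpha, lambdas, df)
        crit_dists = q * se

    comparisons = tuple(
        GroupComparison(
            label=labels[i],
            n=int(ns[i + 1]),
            mean_difference=float(diffs[i]),
            t_statistic=float(t_stats[i]),
            p_value=float(p_values[i]),
            significant=bool(p_values[i] <= alpha),
            direction=(
                "none"
                if diffs[i] == 0.0
                else ("increase" if diffs[i] > 0 else "decrease")
            ),
            critical_distance=float(crit_dists[i]),
        )
        for i in range(k)
    )
    common = float(crit_dists[0]) if np.unique(ns).size == 1 else None
    return DunnettResult(
        comparisons=comparisons,
        pooled_sd=pooled_sd,
        degrees_of_freedom=df,
        alpha=alpha,
        critical_distance=common,
    )


def dunnett_critical_distance(
    alpha: float, k: int, df: int, pooled_sd: float, n_per_group: int
) -> float:
    """Smallest mean difference from control reaching significance.

    q(alpha, k, df) * pooled_sd * sqrt(2/n) for a balanced design with k
    dose groups of n animals each.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if df < 1:
        raise ValueError("df must be >= 1")
    lam = math.sqrt(0.5)
    q = dunnett_quantile(alpha, (lam,) * k, df)
    return q * pooled_sd * math.sqrt(2.0 / n_per_group)


@dataclass(frozen=True)
class WelchResult:
    mean_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    degrees_of_freedom: float
    confidence: float


def welch_test(a, b, confidence: float = 0.95) -> WelchResult:
    """Welch unequal-variance t-test; CI is for mean(b) - mean(a)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("zero variance in both samples")
    res = _sps.ttest_ind(b, a, equal_var=False)
    ci = res.confidence_interval(confidence)
    return WelchResult(
        mean_difference=float(b.mean() - a.mean()),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(res.pvalue),
        degrees_of_freedom=float(res.df),
        confidence=confidence,
    )


def cohens_d(a, b) -> float:
    """Absolute standardized mean difference with (n_i - 1)-weighted pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0.0:
        raise ValueError("zero pooled SD: Cohen's d undefined")
    return abs(float(a.mean() - b.mean())) / math.sqrt(pooled_var)


@dataclass(frozen=True)
class ExtremeContrast:
    """Top-k-vs-bottom-k contrast of a value pool (relevance-limit gauge)."""

    welch: WelchResult
    cohens_d: float
    k: int


def extreme_contrast(values, k: int, confidence: float = 0.95) -> ExtremeContrast:
    """Contrast the k largest against the k smallest values.

    Order statistics are selected deterministically (ties broken by
    original index); the CI and Cohen's d describe top minus bottom.
    """
    values = np.asarray(values, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if 2 * k > values.size:
        raise ValueError(f"2k = {2 * k} exceeds the {values.size} available values")
    order = np.argsort(values, kind="stable")
    bottom = values[order[:k]]
    top = values[order[-k:]]
    d = cohens_d(top, bottom)
    return ExtremeContrast(
        welch=welch_test(bottom, top, confidence=confidence), cohens_d=d, k=k
    )
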