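"""Rank-based and parametric tests used on the pipeline's outputs.

Implemented directly from their textbook definitions so that small-sample
behaviour is fully specified (exact permutation p for Spearman at n <= 10,
pooled-variance t with integer degrees of freedom, tie-corrected
Kruskal-Wallis H, one-sample Kolmogorov-Smirnov against a fitted normal).
The test suite cross-checks every statistic against an independent
reference implementation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special
from scipy import stats as sps

from .types import ValidationError

__all__ = [
    "TestResult",
    "spearman",
    "kruskal_wallis",
    "t_test_independent",
    "ks_normality",
]


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    name: str
    statistic_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    df: float | None = None
    method: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValidationError("p-value outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": list(self.n),
            "df": self.df,
            "method": self.method,
            **({"extra": self.extra} if self.extra else {}),
        }


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = 10,
    name: str = "spearman",
) -> TestResult:
    """Spearman rank correlation with midrank ties.

    The p-value is exact (full permutation enumeration of one rank vector)
    for n <= ``exact_max_n``, otherwise the usual t approximation on
    n - 2 degrees of freedom.  Constant input is an error (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValidationError("spearman requires paired vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("spearman is undefined for a constant vector")
    rx, ry = _midranks(x), _midranks(y)
    rho = _pearson(rx, ry)
    if n <= exact_max_n:
        p = _exact_spearman_p(rx, ry, rho)
        method = f"exact permutation ({math.factorial(n)} permutations)"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(sps.t.sf(abs(t), n - 2))
        method = "t approximation, df = n - 2"
    return TestResult(
        name=name, statistic_name="rho", statistic=rho, p_value=p, n=(n,),
        df=None if n <= exact_max_n else n - 2, method=method,
    )


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p: the fraction of permutations of one
    rank vector whose |rho| is at least |rho_obs| (within 1e-12)."""
    n = len(rx)
    xc = rx - rx.mean()
    sx = math.sqrt(float(xc @ xc))
    yc = ry - ry.mean()
    sy = math.sqrt(float(yc @ yc))
    count = 0
    total = 0
    threshold = abs(rho_obs) - 1e-12
    chunk: list[tuple[int, ...]] = []
    perms = itertools.permutations(range(n))
    ys = yc / sy
    xs = xc / sx
    while True:
        chunk = list(itertools.islice(perms, 200_000))
        if not chunk:
            break
        perm_matrix = ys[np.asarray(chunk)]
        rhos = perm_matrix @ xs
        count += int(np.count_nonzero(np.abs(rhos) >= threshold))
        total += len(chunk)
    return count / total


def kruskal_wallis(groups: Sequence[Sequence[float]], name: str = "kruskal_wallis") -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p on g - 1 df."""
    if len(groups) < 2:
        raise ValidationError("kruskal_wallis requires at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValidationError("kruskal_wallis groups must be non-empty")
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = _midranks(pooled)
    h = 0.0
    offset = 0
    for g in arrays:
        r = ranks[offset:offset + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
        offset += len(g)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n**3 - n)
    if correction <= 0:
        raise ValidationError("all pooled observations are tied; H undefined")
    h /= correction
    df = len(arrays) - 1
    p = float(sps.chi2.sf(h, df))
    return TestResult(
        name=name, statistic_name="H", statistic=h, p_value=p,
        n=tuple(len(g) for g in arrays), df=df,
        method="chi-square approximation with tie correction",
    )


def t_test_independent(
    a: Sequence[float], b: Sequence[float], name: str = "t_test"
) -> TestResult:
    """Two-sample pooled-variance Student t, df = n_a + n_b - 2, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("t test requires n >= 2 in each sample")
    na, nb = len(a), len(b)
    df = na + nb - 2
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if pooled_var <= 0:
        raise ValidationError("zero pooled variance; t undefined")
    t = (a.mean() - b.mean()) / math.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(
        name=name, statistic_name="t", statistic=float(t), p_value=p,
        n=(na, nb), df=df, method="pooled-variance Student t, two-sided",
    )


def ks_normality(x: Sequence[float], name: str = "ks_normality") -> TestResult:
    """One-sample Kolmogorov-Smirnov test against a normal distribution
    with the sample's mean and SD; asymptotic two-sided p."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError("KS normality test requires n >= 3")
    sd = x.std(ddof=1)
    if sd <= 0:
        raise ValidationError("zero variance; KS test undefined")
    xs = np.sort(x)
    cdf = sps.norm.cdf(xs, loc=x.mean(), scale=sd)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    d = float(max(np.max(ecdf_hi - cdf), np.max(cdf - ecdf_lo)))
    p = float(special.kolmogorov(d * math.sqrt(n)))
    return TestResult(
        name=name, statistic_name="D", statistic=d, p_value=p, n=(n,),
        method="asymptotic Kolmogorov distribution; normal fitted by moments",
    )
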