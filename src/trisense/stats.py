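"""Nonparametric and Bayesian inferential toolkit for the planned comparisons.

Implements the statistics the study design calls for: Wilcoxon
signed-rank with the matched-pairs rank-biserial correlation ``r_C``,
the paired t test with Cohen's ``d_z``, the default JZS Bayes factor
with Cauchy prior scale ``sqrt(2)/2``, Spearman rank correlation, a
Shapiro-Wilk normality gate, and post hoc power for the point-biserial
correlation model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import integrate, stats as sps

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "rank_biserial",
    "paired_t",
    "jzs_bf10",
    "spearman",
    "shapiro_wilk",
    "power_point_biserial",
]

DEFAULT_RSCALE = math.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class TestResult:
    """A single inferential result (statistic, p, effect size, optional BF)."""

    statistic_name: str
    statistic: float
    p: float
    tails: int
    effect_size_name: Optional[str] = None
    effect_size: Optional[float] = None
    bf10: Optional[float] = None
    n_used: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.bf10 is not None and not self.bf10 > 0:
            raise ValueError(f"bf10 must be positive, got {self.bf10}")

    def to_dict(self) -> dict:
        return asdict(self)


def _paired_diffs(x: Sequence[float], y: Sequence[float]) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-d samples with n >= 2")
    return x - y


def _signed_rank_statistic(d: np.ndarray):
    """Drop zeros, mid-rank |d|, return (V, ranks, signs, has_ties)."""
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero: no information")
    ranks = sps.rankdata(np.abs(d))
    has_ties = np.unique(np.abs(d)).size != d.size
    v = float(ranks[d > 0].sum())
    return v, ranks, d, has_ties


def _exact_counts(n: int) -> np.ndarray:
    """Null counts of the signed-rank statistic over 0..n(n+1)/2.

    Dynamic program on the generating polynomial prod_k (1 + z^k);
    equivalent to enumerating all 2^n sign patterns.
    """
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for k in range(1, n + 1):
        counts[k:] += counts[: total + 1 - k].copy()
    return counts


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float], tails: int = 2) -> TestResult:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; ties in |d| receive mid-ranks.  The p
    value is exact (full null distribution of the rank sum) when the
    retained n is at most 25 and no ties are present, and otherwise uses
    the normal approximation with tie correction and continuity
    correction.  One-sided alternative: x tends larger than y.
    """
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    d = _paired_diffs(x, y)
    v, ranks, dnz, has_ties = _signed_rank_statistic(d)
    n = dnz.size
    total = n * (n + 1) / 2.0
    if n <= 25 and not has_ties:
        counts = _exact_counts(n)
        denom = 2.0**n
        iv = int(round(v))
        p_greater = counts[iv:].sum() / denom
        p_less = counts[: iv + 1].sum() / denom
        p = p_greater if tails == 1 else min(1.0, 2.0 * min(p_greater, p_less))
    else:
        mn = total / 2.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        se = math.sqrt(var)
        if tails == 1:
            z = (v - mn - 0.5) / se
            p = float(sps.norm.sf(z))
        else:
            z = (abs(v - mn) - 0.5) / se
            p = float(min(1.0, 2.0 * sps.norm.sf(z)))
    r_c = 2.0 * v / total - 1.0
    return TestResult(
        statistic_name="V", statistic=v, p=float(p), tails=tails,
        effect_size_name="r_C", effect_size=float(r_c), n_used=n,
    )


def rank_biserial(x: Sequence[float], y: Sequence[float]) -> float:
    """Matched-pairs rank-biserial correlation ``r_C = 2V/T - 1``.

    Positive when the first sample tends larger.
    """
    d = _paired_diffs(x, y)
    v, _, dnz, _ = _signed_rank_statistic(d)
    total = dnz.size * (dnz.size + 1) / 2.0
    return float(2.0 * v / total - 1.0)


def paired_t(x: Sequence[float], y: Sequence[float], tails: int = 2) -> TestResult:
    """Paired t test with Cohen's ``d_z = mean(d)/sd(d)`` effect size.

    One-sided alternative: x tends larger than y.  The JZS Bayes factor
    for the same contrast is attached.
    """
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    d = _paired_diffs(x, y)
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("differences have zero variance")
    t = float(d.mean() / (sd / math.sqrt(n)))
    if tails == 1:
        p = float(sps.t.sf(t, df=n - 1))
    else:
        p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    d_z = float(d.mean() / sd)
    return TestResult(
        statistic_name="t", statistic=t, p=p, tails=tails,
        effect_size_name="d_z", effect_size=d_z, bf10=jzs_bf10(t, n), n_used=n,
    )


def jzs_bf10(t: float, n: int, rscale: float = DEFAULT_RSCALE) -> float:
    """Default JZS Bayes factor for a one-sample / paired t statistic.

    The alternative places a Cauchy(0, rscale) prior on the standardized
    effect size; the marginal likelihood is computed through the
    inverse-gamma scale-mixture representation, integrating over the
    mixing variance g:

        BF10 = int (1 + n g)^{-1/2} (1 + t^2 / ((1 + n g) nu))^{-(nu+1)/2}
               InvGamma(g; 1/2, rscale^2/2) dg
               / (1 + t^2 / nu)^{-(nu+1)/2},    nu = n - 1.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if rscale <= 0:
        raise ValueError("rscale must be positive")
    nu = n - 1.0
    log_null = -(nu + 1.0) / 2.0 * math.log1p(t * t / nu)

    def integrand(g: float) -> float:
        if g <= 0:
            return 0.0
        log_lik = (
            -0.5 * math.log1p(n * g)
            - (nu + 1.0) / 2.0 * math.log1p(t * t / ((1.0 + n * g) * nu))
        )
        log_prior = (
            0.5 * math.log(rscale**2 / 2.0)
            - math.lgamma(0.5)
            - 1.5 * math.log(g)
            - rscale**2 / (2.0 * g)
        )
        return math.exp(log_lik + log_prior - log_null)

    bf, err = integrate.quad(integrand, 0.0, np.inf, epsrel=1e-8, limit=200)
    if not np.isfinite(bf) or bf <= 0 or (bf > 0 and err / bf > 1e-4):
        raise ArithmeticError(f"JZS BF integration failed: value={bf}, abs err={err}")
    return float(bf)


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with the t-approximation p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input: correlation undefined")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return TestResult(
        statistic_name="rho", statistic=rho, p=p, tails=2,
        effect_size_name="rho", effect_size=rho, n_used=n,
    )


def shapiro_wilk(x: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (standard approximation, 3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    w, p = sps.shapiro(x)
    return TestResult(statistic_name="W", statistic=float(w), p=float(p), tails=2, n_used=x.size)


def power_point_biserial(r: float, n: int, alpha: float = 0.05, tails: int = 1) -> float:
    """Power of the point-biserial correlation test at effect size ``r``.

    Uses the noncentral-t formulation with noncentrality
    ``delta = r sqrt(n) / sqrt(1 - r^2)`` and ``df = n - 2``.
    """
    if not (0.0 <= r < 1.0):
        raise ValueError("r must satisfy 0 <= r < 1")
    if n < 4:
        raise ValueError("n must be >= 4")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = n - 2
    delta = r * math.sqrt(n) / math.sqrt(1.0 - r * r)
    if tails == 1:
        tcrit = sps.t.ppf(1.0 - alpha, df)
        power = sps.nct.sf(tcrit, df, delta)
    else:
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
        power = sps.nct.sf(tcrit, df, delta) + sps.nct.cdf(-tcrit, df, delta)
    return float(power)
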