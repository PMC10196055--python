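"""Group-level inference on per-subject connectivity strengths.

Implements the study's statistical chain — Shapiro-Wilk normality
screening, the pooled-variance (Student) independent-samples t-test with a
directional alternative, Cohen's d on the pooled SD — plus the analytic
power of the pooled t-test from the noncentral-t distribution, used to
calibrate the simulation-based tests.

With equal per-group sizes n and pooled-SD definitions, the statistic and
effect size are linked by ``d = t * sqrt(1/n1 + 1/n2)`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .errors import DegenerateInputError

TAILS = ("two_sided", "one_sided_less", "one_sided_greater")

_SCIPY_ALTERNATIVE = {
    "two_sided": "two-sided",
    "one_sided_less": "less",
    "one_sided_greater": "greater",
}


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group strength comparison (group a vs group b)."""

    t: float
    df: int
    p: float
    d: float
    tail: str
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    group_ns: tuple[int, int]
    shapiro: tuple[tuple[float, float] | None, tuple[float, float] | None]

    def __str__(self) -> str:
        return (
            f"t({self.df}) = {self.t:.3f}, p = {self.p:.4f} ({self.tail}), "
            f"d = {self.d:.3f}"
        )


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test.

    Restricted to 3 <= n <= 50, the range over which the classical
    coefficients are reliable, and rejects constant input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or not 3 <= x.size <= 50:
        raise DegenerateInputError(
            f"Shapiro-Wilk needs a 1-D sample with 3 <= n <= 50, got n={x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateInputError("Shapiro-Wilk undefined for constant input")
    w, p = spstats.shapiro(x)
    return float(w), float(p)


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float(np.sqrt(pooled_var))


def cohens_d(a, b) -> float:
    """Cohen's d with the pooled SD (denominator df = n1 + n2 - 2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs at least 2 values")
    sd = _pooled_sd(a, b)
    if sd == 0:
        raise DegenerateInputError("zero pooled SD: effect size undefined")
    return float((a.mean() - b.mean()) / sd)


def independent_t_test(a, b, tail: str = "two_sided") -> GroupComparison:
    """Pooled-variance independent-samples t-test of group a against group b.

    ``tail="one_sided_less"`` tests the alternative mean(a) < mean(b) — the
    direction of the reduced-connectivity hypothesis when ``a`` is the
    clinical group.  Shapiro-Wilk screens are attached per group when the
    sample size permits (3 <= n <= 50, non-constant), else recorded as None.
    """
    if tail not in TAILS:
        raise DegenerateInputError(f"tail must be one of {TAILS}, got {tail!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs at least 2 values")
    if _pooled_sd(a, b) == 0:
        raise DegenerateInputError("zero pooled variance: t-test undefined")
    res = spstats.ttest_ind(
        a, b, equal_var=True, alternative=_SCIPY_ALTERNATIVE[tail]
    )

    def _screen(x: np.ndarray):
        if 3 <= x.size <= 50 and np.ptp(x) > 0:
            return shapiro_wilk(x)
        return None

    return GroupComparison(
        t=float(res.statistic),
        df=a.size + b.size - 2,
        p=float(res.pvalue),
        d=cohens_d(a, b),
        tail=tail,
        group_means=(float(a.mean()), float(b.mean())),
        group_sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        group_ns=(int(a.size), int(b.size)),
        shapiro=(_screen(a), _screen(b)),
    )


def analytic_power(
    d: float, n_per_group: int, alpha: float = 0.05, tail: str = "one_sided_greater"
) -> float:
    """Power of the pooled two-sample t-test for true effect size ``d``.

    Under effect size d and equal groups of n, the t statistic follows a
    noncentral t with df = 2n - 2 and noncentrality ``d * sqrt(n / 2)``.
    For one-sided tails the sign of ``d`` matters: power is the probability
    of rejecting in the tested direction.
    """
    if tail not in TAILS:
        raise DegenerateInputError(f"tail must be one of {TAILS}, got {tail!r}")
    if n_per_group < 2:
        raise DegenerateInputError("n_per_group must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise DegenerateInputError("alpha must be in (0, 1)")
    df = 2 * n_per_group - 2
    nc = d * np.sqrt(n_per_group / 2.0)
    if tail == "one_sided_greater":
        crit = spstats.t.ppf(1.0 - alpha, df)
        return float(spstats.nct.sf(crit, df, nc))
    if tail == "one_sided_less":
        crit = spstats.t.ppf(alpha, df)
        return float(spstats.nct.cdf(crit, df, nc))
    crit = spstats.t.ppf(1.0 - alpha / 2.0, df)
    return float(spstats.nct.sf(crit, df, nc) + spstats.nct.cdf(-crit, df, nc))
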