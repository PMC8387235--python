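"""Population-level inference on unit counts and learning outcomes.

Covers the exact Fisher test (by hypergeometric enumeration with the
point-probability two-sided rule), the one-sided "any units activated"
fraction test, relative risk of activation between unit populations with
Koopman asymptotic-score 95% confidence intervals, two-group log-rank
comparison of retrieval-onset days with right censoring, and small dose
arithmetic utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import optimize, stats

# relative tolerance for the two-sided Fisher tie rule (include tables whose
# probability is at most (1 + eps) times the observed table's probability)
_FISHER_EPS = 1e-7


def fisher_exact(table, alternative: str = "two-sided") -> float:
    """Exact Fisher p for a 2x2 table by hypergeometric enumeration.

    Margins are held fixed; the two-sided p sums the probabilities of all
    tables no more probable than the observed one (point-probability rule,
    with a 1e-7 relative tie tolerance).  Any empty margin gives p = 1.
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative integers")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    if alternative == "two-sided":
        p = pmf[pmf <= p_obs * (1.0 + _FISHER_EPS)].sum()
    elif alternative == "greater":
        p = pmf[support >= a].sum()
    elif alternative == "less":
        p = pmf[support <= a].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(p, 1.0))


@dataclass
class FractionTest:
    k: int
    n: int
    p_one_sided: float


def fraction_activated_test(k: int, n: int) -> FractionTest:
    """One-sided Fisher test of k activated units out of n against the null
    of zero activated units, built on the table [[k, n-k], [0, n]]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    p = fisher_exact([[k, n - k], [0, n]], alternative="greater")
    return FractionTest(k, n, p)


def _koopman_pt1(theta: float, k1: int, n1: int, k2: int, n2: int) -> float:
    """Constrained MLE of p1 under p1 = theta * p2 (closed form)."""
    N = n1 + n2
    A = theta * (n1 + k2) + k1 + n2
    disc = A * A - 4.0 * theta * N * (k1 + k2)
    return (A - np.sqrt(max(disc, 0.0))) / (2.0 * N)


def koopman_statistic(theta: float, k1: int, n1: int, k2: int, n2: int) -> float:
    """Koopman score chi-square for H0: (p1/p2) = theta."""
    p1 = _koopman_pt1(theta, k1, n1, k2, n2)
    p1 = min(max(p1, 1e-12), 1.0 - 1e-12)
    num = (k1 - n1 * p1) ** 2
    return num / (n1 * p1 * (1.0 - p1)) * (
        1.0 + n1 * (theta - p1) / (n2 * (1.0 - p1))
    )


def koopman_ci(
    k1: int, n1: int, k2: int, n2: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Koopman asymptotic-score confidence interval for the relative risk
    (p1/p2).

    Endpoints are the two roots in rho of the score statistic equalling the
    chi-square(1) critical value, found by bracketed root solving on a log
    scale.  k1 = 0 gives a lower limit of 0; k2 = 0 an infinite upper limit;
    both zero leaves the interval undefined.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if k1 == 0 and k2 == 0:
        return (float("nan"), float("nan"))
    crit = float(stats.chi2.ppf(1.0 - alpha, df=1))

    def f(log_rho: float) -> float:
        return koopman_statistic(np.exp(log_rho), k1, n1, k2, n2) - crit

    rr = (max(k1, 0.5) / n1) / (max(k2, 0.5) / n2)
    lc = np.log(rr)

    lo: float
    hi: float
    if k1 == 0:
        lo = 0.0
    else:
        a = lc
        step = 1.0
        while f(a) < 0 and step < 80:
            a -= step
            step *= 2.0
        lo = float(np.exp(optimize.brentq(f, a, lc, xtol=1e-13, rtol=8.9e-16))) if f(a) > 0 else 0.0
    if k2 == 0:
        hi = float("inf")
    else:
        b = lc
        step = 1.0
        while f(b) < 0 and step < 80:
            b += step
            step *= 2.0
        hi = float(np.exp(optimize.brentq(f, lc, b, xtol=1e-13, rtol=8.9e-16))) if f(b) > 0 else float("inf")
    return (lo, hi)


@dataclass
class GroupComparison:
    k1: int
    n1: int
    k2: int
    n2: int
    p_two_sided: float
    relative_risk: float
    ci95: tuple[float, float]


def compare_activation(k1: int, n1: int, k2: int, n2: int) -> GroupComparison:
    """Compare activated fractions of two unit populations: two-sided Fisher
    p, relative risk (p1-hat / p2-hat), and Koopman 95% CI."""
    p = fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")
    rr = (k1 / n1) / (k2 / n2) if k2 > 0 else float("inf")
    ci = koopman_ci(k1, n1, k2, n2)
    return GroupComparison(k1, n1, k2, n2, p, rr, ci)


@dataclass
class OnsetSurvival:
    """Per-subject retrieval-onset day (or last observed day if censored)."""

    group: str
    day: int
    observed: bool

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError("days are positive integers")


def logrank_onset(
    group_a: list[OnsetSurvival], group_b: list[OnsetSurvival]
) -> tuple[float, float]:
    """Two-group log-rank (Mantel-Cox) test on discrete onset days with
    right censoring.  Returns (chi2, p)."""
    if not any(s.observed for s in group_a + group_b):
        raise ValueError("no observed onsets in either group")
    res = _ll_logrank(
        [s.day for s in group_a],
        [s.day for s in group_b],
        event_observed_A=[s.observed for s in group_a],
        event_observed_B=[s.observed for s in group_b],
    )
    return float(res.test_statistic), float(res.p_value)


def chronic_dose_rate(
    concentration_mg_per_l: float, intake_l_per_day: float, mass_kg: float
) -> float:
    """Chronic drug dose (mg/kg/day) from drinking-water concentration,
    daily intake, and body mass; e.g. 25 mg/l CNO at 6 ml/day for a 30-g
    mouse is 5 mg/kg/day."""
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    if concentration_mg_per_l < 0 or intake_l_per_day < 0:
        raise ValueError("concentration and intake must be non-negative")
    return concentration_mg_per_l * intake_l_per_day / mass_kg


def paired_t(x, y) -> tuple[float, float]:
    """Paired t test (t, two-sided p); thin convenience wrapper."""
    t, p = stats.ttest_rel(np.asarray(x, float), np.asarray(y, float))
    return float(t), float(p)


def one_sample_t(x, popmean: float = 0.0) -> tuple[float, float]:
    """One-sample t test (t, two-sided p); thin convenience wrapper."""
    t, p = stats.ttest_1samp(np.asarray(x, float), popmean)
    return float(t), float(p)
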