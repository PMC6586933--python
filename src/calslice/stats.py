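"""Small-sample-correct statistical tests for responder data.

Pearson chi-squared on 2x2 responder tables is computed *without* the
Yates continuity correction — the convention that matches published
responder-frequency comparisons in this preparation.  Group comparisons
are routed to nonparametric tests (Wilcoxon-Mann-Whitney U, one-sample
sign test) when a normality gate (Shapiro-Wilk or Jarque-Bera) rejects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "chisq_2x2",
    "mann_whitney_u",
    "sign_test",
    "normality_gate",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = condition, columns = responsive / non-responsive."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.total < 1:
            raise ValueError("grand total must be >= 1")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def expected(self) -> np.ndarray:
        n = self.total
        r1, r2 = self.a + self.b, self.c + self.d
        c1, c2 = self.a + self.c, self.b + self.d
        return np.array([[r1 * c1, r1 * c2], [r2 * c1, r2 * c2]], float) / n


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple
    exact: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if not np.isfinite(self.statistic):
            raise ValueError("statistic must be finite")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": list(self.n),
            "exact": self.exact,
        }


def chisq_2x2(table: ContingencyTable2x2) -> TestResult:
    """Pearson chi-squared, df = 1, no continuity correction.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); p from the upper tail
    of chi2_1.
    """
    if (table.expected() == 0).any():
        raise ValueError("degenerate table: an expected cell count is 0")
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    stat = n * (a * d - b * c) ** 2 / denom
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(statistic=float(stat), p_value=p,
                      method="pearson-chi2 (no continuity correction)",
                      n=(n,), exact=False)


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon-Mann-Whitney U with midrank tie handling.

    Exact permutation p when min(n1, n2) <= 8 and there are no ties;
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u: empty sample")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (min(x.size, y.size) <= 8) and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=not exact,
    )
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="mann-whitney-u", n=(int(x.size), int(y.size)),
                      exact=exact)


def sign_test(x, null_median: float, alternative: str = "two-sided") -> TestResult:
    """One-sample sign test: exact binomial on the count above the null
    median (ties dropped), p0 = 0.5; two-sided p = min(1, 2 * min tail)."""
    x = np.asarray(x, float)
    above = int((x > null_median).sum())
    below = int((x < null_median).sum())
    n = above + below
    if n == 0:
        raise ValueError("sign test undefined: all observations tie the null median")
    upper = float(sps.binom.sf(above - 1, n, 0.5))  # P(X >= above)
    lower = float(sps.binom.cdf(above, n, 0.5))  # P(X <= above)
    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(upper, lower))
    elif alternative == "greater":
        p = upper
    elif alternative == "less":
        p = lower
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(statistic=float(above), p_value=p, method="sign-test",
                      n=(n,), exact=True)


def normality_gate(x, alpha: float = 0.05):
    """True (= not normal) if Shapiro-Wilk *or* Jarque-Bera rejects at
    ``alpha``; comparisons are then routed to nonparametric tests.

    Returns (non_normal, diagnostics dict).
    """
    x = np.asarray(x, float)
    if x.size < 3:
        raise ValueError("normality_gate: need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("normality_gate: degenerate constant sample")
    sw_stat, sw_p = sps.shapiro(x)
    jb = sps.jarque_bera(x)
    non_normal = (sw_p < alpha) or (jb.pvalue < alpha)
    return bool(non_normal), {
        "shapiro_stat": float(sw_stat),
        "shapiro_p": float(sw_p),
        "jarque_bera_stat": float(jb.statistic),
        "jarque_bera_p": float(jb.pvalue),
        "alpha": alpha,
        "n": int(x.size),
    }
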