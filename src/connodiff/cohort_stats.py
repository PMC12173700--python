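"""Group-comparison toolkit for cohort description tables.

Demographic/clinical baseline tables pair each test with a matching effect
size: Welch's t-test with pooled-SD Cohen's d for roughly normal continuous
variables, Mann-Whitney U with Rosenthal's r for ordinal/skewed ones, and
chi-squared or Fisher's exact test with the phi coefficient for 2x2 counts.
The d and phi computations take printed summary statistics (mean, SD, n /
cell counts) directly, so published table rows can be reproduced without
raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contrast import mann_whitney_edge, rosenthal_r


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table; rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class SummaryPair:
    """Two groups' printed summaries: mean (SD) and n each."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def __post_init__(self) -> None:
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("SDs must be >= 0")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")


def cohens_d_pooled(s: SummaryPair) -> float:
    """Cohen's d with the pooled standard deviation:

    d = |m1 - m2| / sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2))
    """
    pooled_var = ((s.n1 - 1) * s.sd1**2 + (s.n2 - 1) * s.sd2**2) / (s.n1 + s.n2 - 2)
    if pooled_var == 0:
        raise ValueError("pooled SD is zero")
    return abs(s.mean1 - s.mean2) / np.sqrt(pooled_var)


def phi_2x2(t: TwoByTwo) -> float:
    """Phi coefficient |ad - bc| / sqrt of the margin product, equivalently
    sqrt(chi-squared / N)."""
    r1, r2, c1, c2 = t.margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("phi is undefined with a zero margin")
    return abs(t.a * t.d - t.b * t.c) / np.sqrt(float(r1) * r2 * c1 * c2)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def mwu_rosenthal(a, b) -> tuple[float, float, float]:
    """Mann-Whitney U with Rosenthal's r = |z|/sqrt(N): returns (U, p, r)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u, z, p, _ = mann_whitney_edge(a, b)
    return u, p, rosenthal_r(z, a.size + b.size)


def fisher_exact_p(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p by the point-probability criterion (sum of
    hypergeometric probabilities of tables as or less probable)."""
    r1, r2, c1, c2 = t.margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("Fisher's exact test is undefined with a zero margin")
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def chi2_p(t: TwoByTwo, correction: bool = True) -> float:
    """Pearson chi-squared p for a 2x2 table (Yates correction optional)."""
    res = stats.chi2_contingency(t.as_array(), correction=correction)
    return float(res.pvalue)
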