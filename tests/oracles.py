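"""Independent exact-arithmetic oracles used only by the test suite.

Everything here is computed with ``fractions.Fraction`` (arbitrary
precision rationals) or closed-form linear algebra, independently of
the log-space implementation under test.
"""

from fractions import Fraction
from math import comb

import numpy as np


def exact_pmf(x: int, y: int, r: Fraction) -> Fraction:
    """p(y|x) = r^y * C(x+y, y) / (1+r)^(x+y+1), exactly."""
    return Fraction(r) ** y * comb(x + y, y) / (1 + Fraction(r)) ** (x + y + 1)


def exact_pmf_series(x: int, y_max: int, r: Fraction) -> list[Fraction]:
    """All p(y|x) for y = 0..y_max via the exact recurrence
    p(y+1) = p(y) * r * (x+y+1) / ((y+1) * (1+r))."""
    r = Fraction(r)
    out = [Fraction(1) / (1 + r) ** (x + 1)]
    for y in range(y_max):
        out.append(out[-1] * r * (x + y + 1) / ((y + 1) * (1 + r)))
    return out


def exact_cumulative(x: int, y: int, r: Fraction) -> Fraction:
    return sum(exact_pmf_series(x, y, r))


def exact_two_sided(x: int, y: int, r: Fraction) -> Fraction:
    s = exact_cumulative(x, y, r)
    return 2 * min(s, 1 - s)


def ols_line(x, y) -> tuple[float, float]:
    """Closed-form normal-equations slope/intercept."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xbar, ybar = x.mean(), y.mean()
    slope = ((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum()
    return float(slope), float(ybar - slope * xbar)


def bh_stepup(p):
    """Textbook BH step-up, written independently of statsmodels."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        k = m - rank_from_top
        prev = min(prev, p[idx] * m / k)
        adj[idx] = prev
    return adj
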