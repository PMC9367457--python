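"""Independent brute-force oracles used to check the exact 2×2 machinery.

Everything here is deliberately written from definitions, independent of the
implementation paths it checks: the Fisher p-value by exact rational
enumeration of the hypergeometric distribution, the conditional-MLE odds
ratio and its exact confidence limits by direct noncentral-hypergeometric
tail computations with root bisection, and Benjamini–Hochberg by its O(m²)
definitional formula.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, inf

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher p by exact rational enumeration (point-prob rule)."""
    m1, n1, N = a + b, a + c, a + b + c + d
    lo, hi = max(0, n1 - (c + d)), min(m1, n1)
    denom = comb(N, n1)
    probs = {
        x: Fraction(comb(m1, x) * comb(N - m1, n1 - x), denom) for x in range(lo, hi + 1)
    }
    obs = probs[a]
    return float(sum(p for p in probs.values() if p <= obs))


def _support_logw(a: int, b: int, c: int, d: int):
    m1, n1, N = a + b, a + c, a + b + c + d
    lo, hi = max(0, n1 - (c + d)), min(m1, n1)
    xs = np.arange(lo, hi + 1)
    logw = (
        gammaln(m1 + 1)
        - gammaln(xs + 1)
        - gammaln(m1 - xs + 1)
        + gammaln(N - m1 + 1)
        - gammaln(n1 - xs + 1)
        - gammaln(N - m1 - (n1 - xs) + 1)
    )
    return xs, logw


def _nchg_probs(a, b, c, d, log_psi):
    xs, logw = _support_logw(a, b, c, d)
    logp = logw + xs * log_psi
    logp -= logp.max()
    p = np.exp(logp)
    return xs, p / p.sum()


def conditional_mle_or(a: int, b: int, c: int, d: int) -> float:
    """Conditional MLE: root of E_psi[X] = a over the noncentral family."""
    xs, _ = _support_logw(a, b, c, d)
    if len(xs) == 1:
        return float("nan")  # margins fix the table: no information about psi
    if a == xs[0]:
        return 0.0
    if a == xs[-1]:
        return inf
    def mean_minus_a(t):
        xs2, p = _nchg_probs(a, b, c, d, t)
        return float((xs2 * p).sum()) - a
    root = brentq(mean_minus_a, -60, 60, xtol=1e-13)
    return float(np.exp(root))


def exact_ci(a: int, b: int, c: int, d: int, level: float = 0.95):
    """Exact conditional CI by tail-probability inversion (alpha/2 per tail)."""
    alpha = (1.0 - level) / 2.0
    xs, _ = _support_logw(a, b, c, d)
    def upper_tail(t):  # P(X >= a | psi = e^t)
        xs2, p = _nchg_probs(a, b, c, d, t)
        return float(p[xs2 >= a].sum())
    def lower_tail(t):  # P(X <= a | psi = e^t)
        xs2, p = _nchg_probs(a, b, c, d, t)
        return float(p[xs2 <= a].sum())
    low = 0.0 if a == xs[0] else float(
        np.exp(brentq(lambda t: upper_tail(t) - alpha, -60, 60, xtol=1e-13))
    )
    high = inf if a == xs[-1] else float(
        np.exp(brentq(lambda t: lower_tail(t) - alpha, -60, 60, xtol=1e-13))
    )
    return low, high


def bh_definitional(p_values) -> list[float]:
    """adj_(i) = min_{j >= i} m * p_(j) / j, computed quadratically."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    for rank, idx in enumerate(order, start=1):
        candidates = []
        for rank_j, idx_j in enumerate(order, start=1):
            if rank_j >= rank:
                candidates.append(m * p_values[idx_j] / rank_j)
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted


def random_nondegenerate_table(rng: np.random.Generator, cell_max: int = 7):
    """A random 2×2 table with all margins positive and total <= 28."""
    while True:
        a, b, c, d = (int(x) for x in rng.integers(0, cell_max + 1, size=4))
        if (a + b) and (c + d) and (a + c) and (b + d):
            return a, b, c, d
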