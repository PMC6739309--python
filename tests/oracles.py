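"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: the Fisher oracle
enumerates the hypergeometric support in exact integer arithmetic (point
probabilities share the denominator C(n, c), so only integer numerators are
compared and summed).
"""

from fractions import Fraction
from math import comb


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided minimum-likelihood Fisher p as an exact rational."""
    n = a + b + c + d
    r = a + b  # exposed row margin
    k = a + c  # event column margin
    if n == 0:
        raise ValueError("empty table")
    if r == 0 or k == 0 or r == n or k == n:
        return Fraction(1)
    lo, hi = max(0, r + k - n), min(r, k)
    nums = [comb(r, x) * comb(n - r, k - x) for x in range(lo, hi + 1)]
    obs = nums[a - lo]
    total = sum(num for num in nums if num <= obs)
    return Fraction(total, comb(n, k))


def km_hand_ledger(times, events):
    """Product-limit curve by direct accumulation (no vectorization)."""
    pairs = sorted(zip(times, events))
    distinct = sorted({t for t, e in pairs if e == 1})
    surv = []
    s = 1.0
    for t in distinct:
        at_risk = sum(1 for ti, _ in pairs if ti >= t)
        deaths = sum(1 for ti, ei in pairs if ti == t and ei == 1)
        s *= 1 - deaths / at_risk
        surv.append((t, s))
    return surv
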