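"""Independent oracles used by the test suite.

Everything here recomputes expectations by brute force (enumeration,
exact integer arithmetic, direct textbook formulas) and deliberately
shares no code with the implementation under test.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy.stats import hypergeom


def enum_pmf(probs: np.ndarray) -> np.ndarray:
    """Poisson-binomial pmf by full enumeration of all 2^n outcomes."""
    p = np.asarray(probs, dtype=float)
    n = p.size
    masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    w = np.prod(np.where(masks == 1, p, 1.0 - p), axis=1)
    k = masks.sum(axis=1)
    return np.bincount(k, weights=w, minlength=n + 1)


def quantize_probs(probs: np.ndarray) -> np.ndarray:
    """Round probabilities to exact multiples of 2^-53 (representable
    exactly in doubles for p < 1), so float and integer DP see identical
    inputs."""
    D = 1 << 53
    a = np.rint(np.asarray(probs, dtype=float) * D).astype(object)
    return np.array([int(ai) / D for ai in a], dtype=float)


def exact_tail(probs, k_obs: int) -> Fraction:
    """Exact upper tail P(N >= k_obs) in integer arithmetic.

    Requires every probability to be an integer multiple of 2^-53
    (use :func:`quantize_probs`); the DP then runs entirely on Python
    integers with denominator 2^(53 n).
    """
    D = 1 << 53
    a = [int(round(p * D)) for p in probs]
    for ai, p in zip(a, probs):
        assert ai / D == p, "probabilities must be multiples of 2^-53"
    n = len(a)
    f = [0] * (n + 1)
    f[0] = 1
    for j, aj in enumerate(a, start=1):
        c = D - aj
        for k in range(j, 0, -1):
            f[k] = f[k] * c + f[k - 1] * aj
        f[0] *= c
    return Fraction(sum(f[k_obs:]), D**n)


def fisher_oracle(a: int, b: int, c: int, d: int, sided: str) -> float:
    """Fisher p-value by explicit hypergeometric enumeration over every
    table with the observed margins."""
    r1, c1 = a + b, a + c
    n = a + b + c + d
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = hypergeom.pmf(a, n, c1, r1)
    if sided == "greater":
        return float(pmf[support >= a].sum())
    if sided == "less":
        return float(pmf[support <= a].sum())
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def logrank_oracle(times_a, events_a, times_b, events_b) -> float:
    """Two-group log-rank chi-square by the direct O-E / V sums."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    O_minus_E = 0.0
    V = 0.0
    for t in event_times:
        n1 = np.sum(ta >= t)
        n2 = np.sum(tb >= t)
        d1 = np.sum(ea & (ta == t))
        d2 = np.sum(eb & (tb == t))
        nj, dj = n1 + n2, d1 + d2
        O_minus_E += d1 - dj * n1 / nj
        if nj > 1:
            V += dj * (n1 / nj) * (n2 / nj) * (nj - dj) / (nj - 1)
    return O_minus_E**2 / V


def km_oracle(times, events):
    """Product-limit estimate at each distinct event time."""
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    out = []
    s = 1.0
    for ti in np.unique(t[e]):
        n_at_risk = np.sum(t >= ti)
        d = np.sum(e & (t == ti))
        s *= 1.0 - d / n_at_risk
        out.append((float(ti), s))
    return out
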