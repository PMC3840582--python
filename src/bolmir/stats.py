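"""Shared exact-test kernel.

Both the phasing scan and the GO term-for-term test reduce to the upper tail
of a hypergeometric distribution; they share this one implementation so a
single enumeration oracle validates both.
"""

from __future__ import annotations

from scipy.stats import hypergeom

__all__ = ["hypergeom_tail"]


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(population N, successes K, draws n).

    Computed via the log-space survival function of the scipy hypergeometric
    distribution (exact up to floating point; no normal approximation).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric arguments N={N}, K={K}, n={n}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))
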