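"""Shared set-enrichment statistic: 2x2 / hypergeometric overlap tests.

One ``EnrichmentResult`` container is used by module-signature, key-driver,
GO-term, literature and cross-species overlap tests. The p-value is the
hypergeometric upper tail P(X >= k), equivalent to a one-sided (greater)
Fisher's exact test on the corresponding 2x2 table; only enrichment (not
depletion) is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import hypergeom

__all__ = ["EnrichmentResult", "overlap_test"]


@dataclass
class EnrichmentResult:
    """Overlap of a query set (size n) with a reference set (size K) in a
    universe of N genes; k genes are in both.

    fold = (k/n) / (K/N), the query's reference-gene proportion relative to
    the universe's.
    """

    k: int
    n: int
    K: int
    N: int
    p: float
    p_corrected: float | None = None
    name: str | None = None
    overlap_genes: list[str] = field(default_factory=list)

    @property
    def fold(self) -> float:
        if self.n == 0 or self.K == 0:
            return 0.0
        return (self.k / self.n) / (self.K / self.N)


def overlap_test(k: int, n: int, K: int, N: int) -> float:
    """Hypergeometric upper-tail p-value P(X >= k).

    X ~ Hypergeom(N, K, n): draws of size n from a universe of N containing
    K reference genes.
    """
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"impossible overlap: k={k}, n={n}, K={K}, N={N}")
    if n > N or K > N:
        raise ValueError(f"set larger than universe: n={n}, K={K}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))
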