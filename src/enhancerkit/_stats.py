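"""Shared statistical primitives: hypergeometric tails and BH correction.

Every enrichment test in the package (flat GWAS, tree nodes, module
metadata, gene-set over-representation) routes through
:func:`hypergeom_tail` so that the exactness of the upper-tail
hypergeometric probability is established once.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    ``X`` counts successes in ``n`` draws without replacement from a
    population of ``N`` items of which ``K`` are successes.

    Parameters follow the 2x2-contingency convention used throughout:
    ``k`` observed overlap, ``K`` successes in the background, ``n``
    draws, ``N`` background size.
    """
    if not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"invalid hypergeometric table: k={k} N={N} K={K} n={n}")
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_tail_vec(k, N, K, n) -> np.ndarray:
    """Vectorised :func:`hypergeom_tail`; ``k <= 0`` entries return 1."""
    k = np.asarray(k, dtype=np.int64)
    out = stats.hypergeom.sf(k - 1, N, K, n)
    return np.where(k <= 0, 1.0, out)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for one hypothesis family."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
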