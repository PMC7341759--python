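"""Hypergeometric over-representation analysis against GMT collections.

The tail probability P(X >= k) is computed by exact rational summation of
binomial coefficients, so small-universe results agree bit-for-bit with
brute-force enumeration.  The background universe is supplied by the
caller (the pipeline uses all detection-filtered mRNAs present in the
collection, the standard conservative choice when the original database
background is unknowable).
"""

from __future__ import annotations

import logging
from fractions import Fraction
from math import comb

import pandas as pd

from .errors import ConfigError

logger = logging.getLogger(__name__)


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: annotated set size, n: query size, k: overlap.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= k <= min(n, K)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ConfigError(
            f"hypergeom_p: inconsistent counts k={k}, K={K}, n={n}, N={N}"
        )
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return float(Fraction(num, comb(N, n)))


def run_ora(query, sets: dict, universe, alpha: float = 0.01) -> pd.DataFrame:
    """Over-representation of a gene list against every set in a collection.

    Query genes outside the universe are dropped with a warning; sets are
    intersected with the universe and sets with empty intersection are
    skipped.  One record per set, sorted by ascending p then set name;
    ``significant`` compares the raw p to ``alpha`` (a BH-adjusted column
    is also emitted for optional use).
    """
    universe = sorted(set(universe))
    if not universe:
        raise ConfigError("run_ora: empty universe")
    uni = set(universe)
    query = sorted(set(query))
    dropped = [g for g in query if g not in uni]
    if dropped:
        logger.warning("run_ora: %d query gene(s) outside the universe dropped", len(dropped))
    q = set(query) & uni
    N, n = len(uni), len(q)
    rows = []
    for name in sorted(sets):
        members = set(sets[name]) & uni
        K = len(members)
        if K == 0:
            continue
        k = len(q & members)
        p = hypergeom_p(k, K, n, N)
        rows.append(
            {
                "set_name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
                "significant": p < alpha,
            }
        )
    out = pd.DataFrame(
        rows, columns=["set_name", "k", "K", "n", "N", "p", "significant"]
    )
    if not out.empty:
        from .de import benjamini_hochberg

        out["q_bh"] = benjamini_hochberg(out["p"].to_numpy())
        out = out.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
    else:
        out["q_bh"] = pd.Series(dtype=float)
    return out
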