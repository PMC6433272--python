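"""Hypergeometric gene-set over-representation analysis.

For a foreground list of n genes drawn from a universe of N genes, and a
term containing K universe genes of which k overlap the foreground, the
over-representation p-value is the hypergeometric upper tail

    p = P[X >= k],  X ~ Hypergeometric(N, K, n)

with fold enrichment (k/n) / (K/N). P-values are Benjamini-Hochberg adjusted
across terms and results are sorted by ascending p.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .dm import bh_adjust


def enrich(
    foreground: Iterable[str],
    universe: Iterable[str],
    sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Test every gene set for over-representation in the foreground.

    ``foreground`` must be a subset of ``universe``; set members outside the
    universe are ignored (standard background restriction). Returns a
    DataFrame with one row per term: k, K, n, N, p_value, fold, adj_p.
    """
    fg = set(foreground)
    uni = set(universe)
    stray = sorted(fg - uni)
    if stray:
        raise ValueError(f"foreground genes outside the universe: {stray[:10]}")
    n, N = len(fg), len(uni)
    if n == 0 or N == 0:
        raise ValueError("foreground and universe must be non-empty")

    rows = []
    for term, members in sets.items():
        mem = set(members) & uni
        K = len(mem)
        k = len(mem & fg)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if K > 0 else float("nan")
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "p_value": min(p, 1.0), "fold": fold})
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
    return out
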