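"""Hypergeometric over-representation testing with BH-FDR control.

For a query gene set against a gene-set collection over a fixed background
of N genes, each term of size K overlapping the n-gene query in k genes is
scored with the upper-tail hypergeometric probability P(X >= k).  Raw
p-values are corrected with the Benjamini-Hochberg step-up procedure and a
term is significant when both the raw p and the adjusted value pass their
gates (defaults p < 0.01, FDR < 0.05).

The DAVID-style EASE variant (overlap deflated to k-1 before taking the
upper tail, a conservative penalty on single-gene overlaps) is available
behind the ``ease`` switch for comparability.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from cardiomir.exceptions import InputError

DEFAULT_P_GATE = 0.01
DEFAULT_FDR_GATE = 0.05


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: background size, K: term size in background, n: query size in
    background, k: overlap.  Delegates to the survival function of
    scipy's hypergeometric distribution, which works in log space.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise InputError("need 0 <= K <= N and 0 <= n <= N")
    if not 0 <= k <= min(K, n):
        raise InputError("need 0 <= k <= min(K, n)")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = list(p_values)
    if not p:
        return []
    if any(not 0 < x <= 1 for x in p):
        raise InputError("p-values must lie in (0, 1]")
    if len(p) == 1:
        return [float(p[0])]
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adjusted]


def enrich(
    query: Iterable,
    collections: Mapping[str, Iterable],
    background: Iterable,
    p_gate: float = DEFAULT_P_GATE,
    fdr_gate: float = DEFAULT_FDR_GATE,
    ease: bool = False,
) -> pd.DataFrame:
    """One enrichment record per term of the collection.

    Terms are intersected with the background before counting; the query
    must be a subset of the background (the background is the universe the
    null draws from).
    """
    background = set(background)
    if not background:
        raise InputError("background gene set is empty")
    query = set(query)
    if not query <= background:
        raise InputError("query must be a subset of the background")
    N, n = len(background), len(query)
    rows = []
    for term in sorted(collections):
        term_genes = set(collections[term]) & background
        K = len(term_genes)
        k = len(term_genes & query)
        k_eff = max(k - 1, 0) if ease else k
        p_raw = hypergeom_upper_tail(k_eff, K, n, N)
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p_raw": p_raw})
    records = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_raw"])
    records["p_adjusted"] = bh_adjust(records["p_raw"]) if len(records) else []
    records["significant"] = (records["p_raw"] < p_gate) & (records["p_adjusted"] < fdr_gate)
    return records
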