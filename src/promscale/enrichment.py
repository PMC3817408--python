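"""Hypergeometric enrichment of promoter sets with FDR correction.

Condition-specific promoter sets and clusters are tested for
over-representation of annotation terms (GO-style process/function/
component sets, transcription-factor targets, promoter architectures —
any flat term -> promoter table) against a background universe, using the
upper tail of the hypergeometric distribution with Benjamini-Hochberg
correction across terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def hypergeom_enrichment(query: set, term: set, background: set) -> float:
    """Upper-tail hypergeometric p-value for the query/term overlap.

    With N = |background|, K = |term ∩ background|, n = |query| and
    k = |query ∩ term|, returns P(X >= k) for X ~ Hypergeom(N, K, n).
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    term = set(term) & background
    n_total, n_term, n_query = len(background), len(term), len(query)
    k = len(query & term)
    return float(stats.hypergeom.sf(k - 1, n_total, n_term, n_query))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order preserved)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_annotation_table(path, sep: str = "\t") -> dict[str, set]:
    """Read a two-column (term, promoter) table into term -> promoter sets."""
    df = pd.read_csv(path, sep=sep)
    cols = list(df.columns[:2])
    return {term: set(grp[cols[1]]) for term, grp in df.groupby(cols[0])}


def enrich_table(query: set, annotations: dict[str, set], background: set) -> pd.DataFrame:
    """Enrichment of every annotation term in the query set.

    Returns a table (term, k, K, n, N, p, q) sorted by p-value, where k
    is the query/term overlap, K the term size within the background, n
    the query size and N the background size.
    """
    query = set(query) & set(background)
    rows = []
    for term, members in sorted(annotations.items()):
        members = set(members) & set(background)
        rows.append({
            "term": term,
            "k": len(query & members),
            "K": len(members),
            "n": len(query),
            "N": len(background),
            "p": hypergeom_enrichment(query, members, background),
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
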