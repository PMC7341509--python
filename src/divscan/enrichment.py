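"""Hypergeometric over-representation test with Benjamini–Hochberg FDR.

Given a query gene list and a term-to-gene map, each term is tested for
over-representation of query genes with the upper-tail hypergeometric
probability P(X >= k) for k observed overlaps, a term of size K, a query
of size n and a background universe of size N. P-values are adjusted
across all tested terms with the Benjamini–Hochberg step-up procedure.
Only enrichment (one-sided) is tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class TermMap:
    """Term id -> gene set, with an explicit background universe.

    The background defaults to the union of all term gene sets. Every
    term's genes must lie in the background and no term may be empty.
    """

    terms: dict[str, set[str]]
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.background:
            self.background = set().union(*self.terms.values()) if self.terms else set()
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
            extra = genes - self.background
            if extra:
                raise ValueError(f"term {term!r} has genes outside the background: {sorted(extra)[:5]}")


def hypergeometric_enrichment(
    query: set[str] | list[str],
    term_map: TermMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term over-representation test over a query gene set.

    Query genes outside the background are dropped (logged). Returns a
    DataFrame sorted by raw p with columns term, term_size, overlap,
    p_value, p_adjusted and boolean significance flags at ``alpha`` for
    both the raw and BH-adjusted p. Row order of the input map does not
    affect the result.
    """
    query_set = set(query)
    dropped = query_set - term_map.background
    if dropped:
        logger.info("hypergeometric_enrichment: dropped %d query genes outside background", len(dropped))
    query_set &= term_map.background
    if not query_set:
        raise ValueError("no query genes remain after background intersection")

    big_n = len(term_map.background)
    n = len(query_set)
    rows = []
    for term in sorted(term_map.terms):
        genes = term_map.terms[term]
        k = len(genes & query_set)
        big_k = len(genes)
        # upper tail: P(X >= k)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"term": term, "term_size": big_k, "overlap": k, "p_value": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["p_value"] < alpha
    out["significant_fdr"] = out["p_adjusted"] < alpha
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
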