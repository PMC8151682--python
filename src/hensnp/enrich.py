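"""Over-representation analysis of gene lists against GMT gene sets.

For a query of n genes drawn from a universe of N, a term with K members
and k query hits gets the hypergeometric upper tail

    p = P(X >= k),   X ~ Hypergeometric(N, K, n)

adjusted across terms by Benjamini-Hochberg (default) or Bonferroni.  The
universe defaults to the union of all term genes; pass an explicit universe
to mimic "all known genes" semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "read_gmt", "enrich"]


@dataclass
class GeneSetCollection:
    terms: dict  # term_id -> (name, frozenset of gene ids)
    universe: frozenset

    def __post_init__(self):
        self.terms = {
            t: (name, frozenset(genes)) for t, (name, genes) in self.terms.items() if genes
        }
        self.universe = frozenset(self.universe)
        for t, (_, genes) in self.terms.items():
            if not genes <= self.universe:
                raise ValueError(f"term {t!r} contains genes outside the universe")

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Parse a GMT file (term, description, genes...); raises with line numbers.

    Duplicate genes within a term are deduplicated.  ``universe`` overrides
    the default union-of-terms universe.
    """
    terms = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term_id, desc, *genes = fields
            terms[term_id] = (desc, frozenset(g for g in genes if g))
    if universe is None:
        universe = frozenset().union(*(g for _, g in terms.values())) if terms else frozenset()
    return GeneSetCollection(terms, frozenset(universe))


def enrich(
    query, sets: GeneSetCollection, method: str = "BH", alpha: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in every term.

    Returns a DataFrame sorted by adjusted p with columns
    ``term_id name k K n N p_raw p_adj significant``.
    """
    if method not in ("BH", "bonferroni"):
        raise ValueError("method must be 'BH' or 'bonferroni'")
    query = set(query)
    dropped = query - sets.universe
    if dropped:
        logger.warning("%d query genes outside the universe dropped", len(dropped))
    q = query & sets.universe
    if not q:
        raise ValueError("no query genes inside the universe")

    N, n = len(sets.universe), len(q)
    rows = []
    for term_id, (name, genes) in sets.terms.items():
        K = len(genes)
        k = len(q & genes)
        # upper tail including k: P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(term_id=term_id, name=name, k=k, K=K, n=n, N=N, p_raw=min(p, 1.0)))
    out = pd.DataFrame(rows)
    sm_method = "fdr_bh" if method == "BH" else "bonferroni"
    out["p_adj"] = multipletests(out["p_raw"], method=sm_method)[1]
    out["significant"] = out["p_adj"] < alpha
    return out.sort_values(["p_adj", "p_raw", "term_id"]).reset_index(drop=True)
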