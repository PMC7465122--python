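"""Hypergeometric gene-set enrichment and intersection-based hub calling.

For a query gene set and a GMT library, each term gets the upper-tail
hypergeometric p-value P(X >= overlap) with the library union (or an explicit
override) as the population, followed by Benjamini–Hochberg adjustment within
each library. Hub genes are the genes common to the query overlaps of every
significantly enriched term across all libraries.

The background universe defaults to the union of all term genes in the
library; enrichment p-values depend strongly on this choice, so pass
``universe`` explicitly when a better background is known.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .meta_deg import bh_adjust

log = logging.getLogger("coexffl.enrichment")


@dataclass
class EnrichmentResult:
    library: str
    table: pd.DataFrame  # term, overlap, term_size, query_size, universe_size, p, p_bh, genes

    def significant(self, alpha: float = 0.001) -> pd.DataFrame:
        return self.table[self.table["p_bh"] < alpha]


def enrich(
    query_genes: set[str] | list[str],
    library: dict[str, set[str]],
    library_name: str = "library",
    universe: set[str] | None = None,
) -> EnrichmentResult:
    """Hypergeometric enrichment of a query against one GMT library."""
    query = set(query_genes)
    if not query:
        raise ValueError("query gene set is empty")
    if universe is None:
        universe = set().union(*library.values())
    universe = set(universe)
    q = query & universe
    if not q:
        raise ValueError("query does not intersect the universe")
    M = len(universe)
    rows = []
    for term, genes in library.items():
        K = len(genes & universe)
        overlap = sorted(q & genes)
        x = len(overlap)
        # P(X >= x) for X ~ Hypergeom(M, K, |q|)
        p = float(stats.hypergeom.sf(x - 1, M, K, len(q)))
        rows.append((term, x, K, len(q), M, min(p, 1.0), ";".join(overlap)))
    table = pd.DataFrame(
        rows,
        columns=["term", "overlap", "term_size", "query_size", "universe_size", "p", "overlap_genes"],
    ).set_index("term")
    table["p_bh"] = bh_adjust(table["p"])
    table = table.sort_values(["p_bh", "p", "overlap"], kind="stable")
    return EnrichmentResult(library=library_name, table=table)


def hub_genes(
    results: list[EnrichmentResult],
    query_genes: set[str] | list[str],
    alpha: float = 0.001,
) -> set[str]:
    """Genes common to the query overlap of every significant term.

    Returns the intersection over all significantly enriched terms (across
    all libraries) of term genes ∩ query genes; an empty intersection is a
    valid (reported) outcome, and no significant term at all yields an empty
    set with a warning.
    """
    query = set(query_genes)
    hub: set[str] | None = None
    n_sig = 0
    for res in results:
        sig = res.significant(alpha)
        for _, row in sig.iterrows():
            overlap = set(row["overlap_genes"].split(";")) & query if row["overlap_genes"] else set()
            hub = overlap if hub is None else hub & overlap
            n_sig += 1
    if hub is None:
        warnings.warn("no significantly enriched term; hub set empty", UserWarning, stacklevel=2)
        return set()
    log.info("hub intersection over %d significant terms: %d gene(s)", n_sig, len(hub))
    return hub


def global_bh(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Optional switch: re-adjust p-values across all libraries jointly."""
    stacked = pd.concat([r.table["p"] for r in results])
    adjusted = bh_adjust(stacked)
    out = []
    start = 0
    for r in results:
        n = len(r.table)
        t = r.table.copy()
        t["p_bh"] = adjusted.iloc[start : start + n].to_numpy()
        start += n
        out.append(EnrichmentResult(library=r.library, table=t))
    return out
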