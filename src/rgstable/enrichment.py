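"""Over-representation analysis of a candidate gene list against gene sets.

For each set the overlap with the candidate list is tested with the
upper-tail hypergeometric distribution (probability of at least the
observed overlap when drawing ``len(list)`` genes from the universe);
p-values are corrected across sets by Benjamini-Hochberg FDR.  The
enrichment percentage is the share of a set's (in-universe) members found
in the list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """One row per tested set: overlap, sizes, p, BH q, enrichment %."""

    table: pd.DataFrame
    universe_size: int
    list_size: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["fdr"] < alpha]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def ora(
    gene_list: list[str] | set[str],
    universe: list[str] | set[str],
    sets: GeneSetCollection,
) -> EnrichmentResult:
    """Hypergeometric over-representation test of ``gene_list`` per gene set.

    ``gene_list`` must be a subset of ``universe`` (typically all genes that
    survived the detectable-expression filter).  Sets are intersected with
    the universe before testing; sets with no members in the universe are
    skipped with a warning.
    """
    universe_set = set(universe)
    list_set = set(gene_list)
    if not list_set or not universe_set:
        raise ValueError("gene list and universe must be non-empty")
    stray = list_set - universe_set
    if stray:
        raise ValueError(f"gene list not contained in universe, e.g. {sorted(stray)[:5]}")

    m = len(universe_set)
    n = len(list_set)
    rows = []
    for name, members in sets:
        in_universe = [g for g in members if g in universe_set]
        if not in_universe:
            logger.warning("gene set %r has no members in the universe; skipped", name)
            continue
        k = len(in_universe)
        overlap = sum(1 for g in in_universe if g in list_set)
        # P(X >= overlap), X ~ Hypergeom(M=m, n=k, N=n)
        p = float(hypergeom.sf(overlap - 1, m, k, n))
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": k,
                "universe_size": m,
                "list_size": n,
                "p": min(p, 1.0),
                "enrichment_pct": 100.0 * overlap / k,
            }
        )
    if not rows:
        raise ValueError("no testable gene sets")
    table = pd.DataFrame(rows)
    table["fdr"] = multipletests(table["p"].values, method="fdr_bh")[1]
    table = table.sort_values("p", kind="stable").reset_index(drop=True)
    return EnrichmentResult(table=table, universe_size=m, list_size=n)
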