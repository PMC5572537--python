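"""From-scratch geNorm: expression-stability ranking of candidate reference genes.

The algorithm works on relative quantities derived from Ct values
(``q = E**(minCt - Ct)`` per gene, so the sample with the lowest Ct has
q = 1).  For a pair of genes the pairwise variation ``V_jk`` is the
standard deviation across samples of ``log2(q_j / q_k)``; a gene's
M value is the average of its pairwise variations against every other
candidate.  Genes are ranked by iteratively removing the least stable
(highest M) gene until two remain; those two share rank 1.  The
pairwise-variation series ``V_{n/n+1}`` — the standard deviation of the
log-ratio of normalization factors built from the top n versus top n+1
genes — decides how many reference genes are needed (V < 0.15 means n
suffice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CtTable

logger = logging.getLogger(__name__)

#: below this pairwise variation, adding the (n+1)-th reference gene is unnecessary
V_CUTOFF = 0.15

#: M values at or below this are associated with homogeneous sample sets
M_HOMOGENEOUS = 0.5


@dataclass
class RelativeQuantityMatrix:
    """Gene x sample relative quantities in (0, 1], max 1 per gene."""

    q: pd.DataFrame
    efficiency: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.q.values
        if (vals <= 0).any():
            raise ValueError("relative quantities must be positive")
        if not np.allclose(vals.max(axis=1), 1.0):
            raise ValueError("each gene's maximum relative quantity must be 1")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.q.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.q.columns)


@dataclass
class GeNormResult:
    """Ranking output: final M per gene, removal order, ranks, V series."""

    m_values: pd.Series          # M at the stage each gene was removed (final pair: 2-gene M)
    removal_order: list[str]     # least stable first
    ranking: dict[str, int]      # reverse removal order; last two share rank 1
    v_series: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    n_recommended: int | None = None

    def ranked_genes(self) -> list[str]:
        return sorted(self.ranking, key=lambda g: (self.ranking[g], g))

    def annotate_homogeneous(self) -> pd.Series:
        """Flag genes whose final M meets the homogeneous-sample guideline."""
        return self.m_values <= M_HOMOGENEOUS


def aggregate_ct(ct: CtTable) -> pd.DataFrame:
    """Mean Ct per (gene, sample) over replicates, genes x samples."""
    piv = ct.records.pivot_table(
        index="gene", columns="sample", values="ct", aggfunc="mean", sort=False
    )
    return piv


def relative_quantities(ct: CtTable | pd.DataFrame, efficiency: float = 2.0) -> RelativeQuantityMatrix:
    """Transform Ct values into relative quantities ``E**(minCt - Ct)``.

    Replicates are first averaged (arithmetic mean of Ct).  Missing
    (gene, sample) cells are an error because geNorm requires a complete
    matrix.  ``efficiency`` is the amplification efficiency per cycle,
    2.0 for perfect doubling; values at or below 1 mean no amplification.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError(f"amplification efficiency must be in (1, 2], got {efficiency}")
    mat = aggregate_ct(ct) if isinstance(ct, CtTable) else ct
    if mat.isna().any().any():
        holes = [
            (g, s)
            for g in mat.index
            for s in mat.columns
            if pd.isna(mat.loc[g, s])
        ]
        raise ValueError(f"missing Ct cells: {holes[:10]}")
    mn = mat.min(axis=1)
    q = efficiency ** (mn.values[:, None] - mat.values)
    return RelativeQuantityMatrix(pd.DataFrame(q, index=mat.index, columns=mat.columns))


def genorm_m(q: RelativeQuantityMatrix, subset: list[str] | None = None) -> pd.Series:
    """M value for each gene of ``subset``: mean pairwise log-ratio SD.

    ``V_jk = sd_samples(log2(q_j / q_k))`` with the n-1 denominator;
    ``M_j = mean_k!=j V_jk``.
    """
    genes = list(q.gene_ids if subset is None else subset)
    if len(genes) < 2:
        raise ValueError("geNorm M requires at least 2 genes")
    mat = np.log2(q.q.loc[genes].values)
    if mat.shape[1] < 2:
        raise ValueError("geNorm M requires at least 2 samples")
    # pairwise sd of differences via broadcasting: (k, k, n)
    diffs = mat[:, None, :] - mat[None, :, :]
    v = diffs.std(axis=2, ddof=1)
    k = len(genes)
    m = v.sum(axis=1) / (k - 1)  # diagonal contributes 0
    return pd.Series(m, index=genes, name="M")


def genorm_rank(q: RelativeQuantityMatrix) -> GeNormResult:
    """Iterative-exclusion geNorm ranking plus the V_{n/n+1} series.

    At each stage M is recomputed on the remaining genes and the gene with
    the highest M is removed (ties broken lexicographically by gene id,
    logged) until two genes remain; those share rank 1.  The recorded
    M value of each gene is its M at the stage it was removed; the final
    pair keeps its two-gene M.
    """
    genes = list(q.gene_ids)
    if len(genes) < 3:
        raise ValueError("geNorm ranking requires at least 3 genes")
    remaining = list(genes)
    removal_order: list[str] = []
    m_final = pd.Series(index=pd.Index(genes), dtype=float)
    while len(remaining) > 2:
        m = genorm_m(q, remaining)
        worst_m = m.max()
        ties = sorted(m.index[m == worst_m])
        if len(ties) > 1:
            logger.info("geNorm tie at M=%.6g between %s; removing %r", worst_m, ties, ties[0])
        worst = ties[0]
        m_final[worst] = m[worst]
        removal_order.append(worst)
        remaining.remove(worst)
    m_last = genorm_m(q, remaining)
    for g in remaining:
        m_final[g] = m_last[g]

    ranking: dict[str, int] = {}
    for g in remaining:
        ranking[g] = 1
    for pos, g in enumerate(reversed(removal_order), start=3):
        ranking[g] = pos

    result = GeNormResult(m_values=m_final, removal_order=removal_order, ranking=ranking)
    result.v_series = pairwise_variation(q, result)
    result.n_recommended = recommended_n(result.v_series)
    return result


def recommended_n(v_series: pd.Series, cutoff: float = V_CUTOFF) -> int | None:
    """Smallest n with V_{n/n+1} below the cutoff, or None if none qualifies."""
    below = v_series[v_series < cutoff]
    return int(below.index[0]) if len(below) else None


def pairwise_variation(q: RelativeQuantityMatrix, result: GeNormResult) -> pd.Series:
    """V_{n/n+1} series for n = 2..k-1 given a geNorm ranking.

    ``NF_n`` per sample is the geometric mean of the top-n genes' relative
    quantities (ranking order, ties at rank 1 resolved by gene id);
    ``V_{n/n+1}`` is the across-sample standard deviation (n-1 denominator)
    of ``log2(NF_n / NF_{n+1})``.
    """
    order = result.ranked_genes()
    k = len(order)
    if k < 3:
        raise ValueError("pairwise variation requires at least 3 ranked genes")
    logq = np.log2(q.q.loc[order].values)
    v = {}
    for n in range(2, k):
        nf_n = logq[:n].mean(axis=0)        # log2 geometric mean of top n
        nf_n1 = logq[: n + 1].mean(axis=0)
        v[n] = float(np.std(nf_n - nf_n1, ddof=1))
    return pd.Series(v, name="V")
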