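"""From-scratch NormFinder: model-based reference-gene stability estimation.

NormFinder decomposes log-scale expression into gene, sample and group
effects and scores each gene by combining two sources of instability:

* the intergroup difference ``d_ig`` — how much the gene's group effect
  deviates from the average gene's in group g, shrunken toward zero by an
  empirical-Bayes factor so that genes are not rewarded for noisy estimates
  of a near-zero difference; and
* the intragroup variance ``s2_ig`` — residual variance within group g
  after gene and sample effects are removed.

The stability value is the average over groups of
``|d~_ig| + sqrt(v_ig * gamma2_g / (gamma2_g + v_ig))``, lower = more
stable.  A candidate pair of reference genes is scored by averaging the two
genes' log signals into a virtual gene and re-estimating its stability in
the full model; the minimizing pair is the recommended combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .data_io import CtTable
from .genorm import RelativeQuantityMatrix, relative_quantities


@dataclass
class NormFinderResult:
    """Per-gene stability values and the variance components behind them."""

    stability: pd.Series                 # rho per gene, lower = more stable
    intergroup: pd.DataFrame             # shrunken d~ per gene (rows) x group (cols)
    intragroup_var: pd.DataFrame         # s2 per gene x group
    best_single: str
    groups: list[str]

    def ranked(self) -> pd.Series:
        return self.stability.sort_values(kind="stable")


def _log_matrix(
    data: CtTable | RelativeQuantityMatrix | pd.DataFrame, efficiency: float
) -> pd.DataFrame:
    """Gene x sample log2 relative quantities."""
    if isinstance(data, CtTable):
        data = relative_quantities(data, efficiency)
    if isinstance(data, RelativeQuantityMatrix):
        return pd.DataFrame(
            np.log2(data.q.values), index=data.q.index, columns=data.q.columns
        )
    return data


def _components(y: np.ndarray, group_idx: list[np.ndarray]):
    """Variance components of the NormFinder model on sample-centred data.

    ``y`` is genes x samples on the log2 scale.  Returns (d_shrunk, v, s2,
    gamma2) with genes in rows and groups in columns.
    """
    k = y.shape[0]
    # remove the sample effect: centre each sample across genes
    z = y - y.mean(axis=0, keepdims=True)

    n_groups = len(group_idx)
    zbar = np.empty((k, n_groups))
    s2 = np.empty((k, n_groups))
    n_g = np.empty(n_groups)
    for g, idx in enumerate(group_idx):
        sub = z[:, idx]
        zbar[:, g] = sub.mean(axis=1)
        s2[:, g] = sub.var(axis=1, ddof=1)
        n_g[g] = len(idx)

    # group effect of gene i relative to the average gene, then centred over
    # groups with group-size weights so intergroup differences sum to ~0
    a = zbar - zbar.mean(axis=0, keepdims=True)
    d_hat = a - (a * n_g[None, :]).sum(axis=1, keepdims=True) / n_g.sum()

    # sampling variance of d_hat (the gene's own noise plus the 1/k share of
    # the other genes' noise from the per-sample centring)
    other = s2.sum(axis=0, keepdims=True) - s2
    v = ((k - 1) / k) ** 2 * s2 / n_g[None, :] + other / (k**2 * n_g[None, :])

    # empirical-Bayes shrinkage of the intergroup differences
    gamma2 = np.maximum(0.0, d_hat.var(axis=0, ddof=1) - v.mean(axis=0))
    denom = gamma2[None, :] + v
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(denom > 0, gamma2[None, :] / denom, 0.0)
    d_shrunk = d_hat * shrink
    return d_shrunk, v, s2, gamma2


def _stability(d_shrunk, v, s2, gamma2, single_group: bool) -> np.ndarray:
    if single_group:
        return np.sqrt(s2[:, 0])
    denom = gamma2[None, :] + v
    with np.errstate(invalid="ignore", divide="ignore"):
        post_var = np.where(denom > 0, v * gamma2[None, :] / denom, 0.0)
    # per-group penalty: shrunken bias plus the spread a single sample
    # normalized with this gene would inherit (intragroup variance) plus the
    # posterior uncertainty of the bias itself; gamma2 = 0 leaves the pure
    # intragroup term, matching the single-group reduction
    return (np.abs(d_shrunk) + np.sqrt(s2 + post_var)).mean(axis=1)


def normfinder_stability(
    data: CtTable | RelativeQuantityMatrix | pd.DataFrame,
    groups: dict[str, str] | None = None,
    efficiency: float = 2.0,
) -> NormFinderResult:
    """NormFinder stability value for every gene.

    ``data`` may be a CtTable (replicates averaged, Ct converted to relative
    quantities at the given efficiency), a RelativeQuantityMatrix, or a
    ready-made gene x sample log2 matrix.  ``groups`` maps sample to group
    label; for a CtTable it defaults to the table's own group column.  Every
    group needs at least 2 samples and the model at least 2 genes.

    With a single group the stability value reduces to the within-group
    standard deviation of the sample-centred signal.
    """
    if groups is None:
        if isinstance(data, CtTable):
            groups = data.sample_groups()
        else:
            raise ValueError("groups are required unless data is a CtTable")
    ymat = _log_matrix(data, efficiency)
    if ymat.shape[0] < 2:
        raise ValueError("NormFinder requires at least 2 genes")
    missing = [s for s in ymat.columns if s not in groups]
    if missing:
        raise ValueError(f"samples without group label: {missing}")

    labels = [groups[s] for s in ymat.columns]
    group_names = list(dict.fromkeys(labels))
    group_idx = [
        np.array([j for j, lab in enumerate(labels) if lab == g]) for g in group_names
    ]
    for g, idx in zip(group_names, group_idx):
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    y = ymat.values.astype(float)
    d_shrunk, v, s2, gamma2 = _components(y, group_idx)
    rho = _stability(d_shrunk, v, s2, gamma2, single_group=len(group_names) == 1)

    stability = pd.Series(rho, index=ymat.index, name="stability")
    order = stability.sort_values(kind="stable")
    return NormFinderResult(
        stability=stability,
        intergroup=pd.DataFrame(d_shrunk, index=ymat.index, columns=group_names),
        intragroup_var=pd.DataFrame(s2, index=ymat.index, columns=group_names),
        best_single=str(order.index[0]),
        groups=group_names,
    )


def best_pair(
    data: CtTable | RelativeQuantityMatrix | pd.DataFrame,
    groups: dict[str, str] | None = None,
    efficiency: float = 2.0,
) -> tuple[tuple[str, str], float]:
    """Exhaustive search for the most stable two-gene combination.

    Every pair's log signals are averaged into a virtual gene which is
    appended to the gene set; the pair whose virtual gene attains the lowest
    stability value in the re-fitted full model wins.  Returns the pair
    (sorted by gene id) and its stability value.
    """
    if groups is None:
        if isinstance(data, CtTable):
            groups = data.sample_groups()
        else:
            raise ValueError("groups are required unless data is a CtTable")
    ymat = _log_matrix(data, efficiency)
    if ymat.shape[0] < 3:
        raise ValueError("best-pair search requires at least 3 genes")

    best: tuple[str, str] | None = None
    best_rho = np.inf
    for gi, gj in combinations(sorted(map(str, ymat.index)), 2):
        virtual = (ymat.loc[gi] + ymat.loc[gj]) / 2.0
        aug = pd.concat([ymat, virtual.to_frame("__pair__").T])
        res = normfinder_stability(aug, groups=groups, efficiency=efficiency)
        rho = float(res.stability["__pair__"])
        if rho < best_rho:
            best_rho = rho
            best = (gi, gj)
    assert best is not None
    return best, best_rho
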