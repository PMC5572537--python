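"""Reference-gene screening statistics on RNA-seq expression.

The screen keeps only genes detectable in every sample, then scores each
gene by how stable its TPM is across the cohort:

* CoV — sample standard deviation (n-1) divided by the mean;
* MFC — maximum fold change, the largest TPM over the smallest;
* MFC-CoV — the product score ``CoV * MFC``; lower means more stable;
* candidates — genes whose score falls at or below a lower quantile
  (default the first quartile, type-7 linear interpolation) of the score
  distribution;
* BCV — biological coefficient of variation, the square root of the
  per-gene negative-binomial dispersion (variance = mu + phi * mu**2),
  estimated by a common-dispersion maximum likelihood followed by per-gene
  weighted-likelihood shrinkage toward the common value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data_io import CountMatrix
from .normalization import ExpressionMatrix, NormFactors

logger = logging.getLogger(__name__)


@dataclass
class StabilityTable:
    """Per-gene stability metrics.

    Columns of ``table``: ``mean_tpm``, ``cov``, ``mfc``, ``score``
    (= cov * mfc), optional ``bcv``, boolean ``candidate``.
    """

    table: pd.DataFrame
    threshold: float | None = None

    def __post_init__(self) -> None:
        t = self.table
        if (t["mfc"] < 1 - 1e-12).any():
            raise ValueError("MFC must be >= 1")
        if (t["cov"] < 0).any():
            raise ValueError("CoV must be >= 0")
        if not np.allclose(t["score"], t["cov"] * t["mfc"], rtol=1e-12, atol=1e-12):
            raise ValueError("score must equal cov * mfc")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def candidates(self) -> list[str]:
        if "candidate" not in self.table.columns:
            raise ValueError("run select_candidates first")
        sub = self.table[self.table["candidate"]]
        return list(sub.sort_values("score").index)

    def write(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def filter_expressed(counts: CountMatrix) -> CountMatrix:
    """Keep only genes with a nonzero count in every sample.

    A reference gene must be detectable in all samples, so any gene with a
    zero count anywhere is discarded.
    """
    keep = (counts.counts.values > 0).all(axis=1)
    n_drop = int((~keep).sum())
    logger.info("filter_expressed: %d genes discarded, %d retained", n_drop, int(keep.sum()))
    if keep.sum() == 0:
        logger.warning("filter_expressed: no genes retained")
    return CountMatrix(
        counts.counts.loc[keep], groups=counts.groups, patient_ids=counts.patient_ids
    )


def stability_metrics(tpm: ExpressionMatrix) -> StabilityTable:
    """Compute mean TPM, CoV, MFC and the MFC-CoV score per gene.

    All values must be strictly positive (apply :func:`filter_expressed`
    before the TPM transform); otherwise MFC is undefined.
    """
    vals = tpm.values.values.astype(float)
    if (vals <= 0).any():
        g = tpm.values.index[(vals <= 0).any(axis=1)][0]
        raise ValueError(f"non-positive expression for gene {g!r}; MFC undefined")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    cov = sd / mean
    mfc = vals.max(axis=1) / vals.min(axis=1)
    table = pd.DataFrame(
        {"mean_tpm": mean, "cov": cov, "mfc": mfc, "score": cov * mfc},
        index=tpm.values.index,
    )
    return StabilityTable(table)


def select_candidates(
    table: StabilityTable, quantile: float = 0.25
) -> tuple[float, list[str]]:
    """Flag genes whose MFC-CoV score is at or below a score quantile.

    The threshold is the type-7 (linear-interpolation) quantile of the score
    distribution; candidates are returned sorted by ascending score.  The
    table is annotated in place with the ``candidate`` column.
    """
    if not 0 < quantile < 1:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    if len(table.table) == 0:
        raise ValueError("empty stability table")
    scores = table.table["score"].values
    threshold = float(np.quantile(scores, quantile))  # type-7
    flag = table.table["score"] <= threshold
    table.table["candidate"] = flag
    table.threshold = threshold
    return threshold, table.candidates()


# ---------------------------------------------------------------------------
# BCV: negative-binomial dispersion estimation
# ---------------------------------------------------------------------------

_PHI_GRID = np.logspace(-6, 1, 43)


def _fit_means(y: np.ndarray, s: np.ndarray, phi: float, n_iter: int = 25) -> np.ndarray:
    """Per-gene MLE of the mean scale m (mu_gj = m_g * s_j) at fixed dispersion.

    Newton-Raphson on beta = log m with Fisher scoring; vectorized over genes.
    """
    tot = y.sum(axis=1)
    beta = np.log(np.maximum(tot, 0.5) / s.sum())
    for _ in range(n_iter):
        mu = np.exp(beta)[:, None] * s[None, :]
        w = 1.0 + phi * mu
        score = ((y - mu) / w).sum(axis=1)
        info = (mu / w).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        beta = beta + np.clip(step, -5, 5)
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.exp(beta)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-gene NB log-likelihood (variance = mu + phi mu^2), summed over samples."""
    if phi < 1e-12:
        ll = y * np.log(np.maximum(mu, 1e-300)) - mu - gammaln(y + 1)
        return ll.sum(axis=1)
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-300)
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return ll.sum(axis=1)


def _quadratic_refine(grid_log: np.ndarray, values: np.ndarray, idx: int) -> float:
    """Interpolate the maximizer of a 1-d function from three grid points."""
    if idx == 0 or idx == len(grid_log) - 1:
        return grid_log[idx]
    x0, x1, x2 = grid_log[idx - 1], grid_log[idx], grid_log[idx + 1]
    y0, y1, y2 = values[idx - 1], values[idx], values[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= -1e-12:  # not concave at this resolution
        return float(x1)
    h = x1 - x0  # grid is equally spaced in log-dispersion
    x = x1 + 0.5 * h * (y0 - y2) / denom
    return float(np.clip(x, x0, x2))


def estimate_bcv(
    counts: CountMatrix,
    factors: NormFactors,
    prior_df: float = 10.0,
) -> pd.Series:
    """Per-gene biological coefficient of variation, sqrt of NB dispersion.

    Dispersion is profiled on a log-spaced grid: per-gene means are re-fit
    by Newton's method at every grid value with per-sample offsets
    ``library_size * factor``.  The common dispersion maximizes the summed
    likelihood; each gene then maximizes its own likelihood plus
    ``prior_df / (n_samples - 1)`` times the average per-gene likelihood,
    which shrinks noisy per-gene estimates toward the common value (the
    common estimate is recovered exactly as ``prior_df -> inf``).
    """
    if counts.n_samples < 3:
        raise ValueError("BCV estimation requires at least 3 samples")
    y = counts.counts.values.astype(float)
    s = factors.effective_sizes().reindex(counts.counts.columns).values.astype(float)
    s = s / np.exp(np.mean(np.log(s)))  # offsets centred for numerical stability

    grid = _PHI_GRID
    grid_log = np.log(grid)
    ll = np.empty((y.shape[0], grid.size))
    for j, phi in enumerate(grid):
        m = _fit_means(y, s, phi)
        mu = m[:, None] * s[None, :]
        ll[:, j] = _nb_loglik(y, mu, phi)

    total = ll.sum(axis=0)
    common_log = _quadratic_refine(grid_log, total, int(np.argmax(total)))

    df = counts.n_samples - 1
    weight = prior_df / df if df > 0 else prior_df
    if np.isinf(weight):
        phi_tag = np.full(y.shape[0], np.exp(common_log))
    else:
        penalized = ll + weight * ll.mean(axis=0)[None, :]
        idx = np.argmax(penalized, axis=1)
        phi_tag = np.array(
            [
                np.exp(_quadratic_refine(grid_log, penalized[g], int(idx[g])))
                for g in range(y.shape[0])
            ]
        )
    return pd.Series(np.sqrt(phi_tag), index=counts.counts.index, name="bcv")
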