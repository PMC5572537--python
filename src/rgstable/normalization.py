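"""Between-sample scaling (TMM) and within-sample abundance transforms (CPM, TPM).

TMM (trimmed mean of M-values) estimates one scaling factor per sample by
comparing it against a reference sample: per-gene log-ratios (M) and average
log-abundances (A) are computed over genes expressed in both samples, the
most extreme 30% of M and 5% of A are trimmed from both tails, and the factor
is 2 raised to the precision-weighted mean of the surviving M values.
Factors are rescaled so their geometric mean is exactly 1.

TPM divides each gene's (optionally TMM-adjusted) count by its union-exon
length and rescales each sample so the column sums to one million.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import CountMatrix, GeneLengths


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors and library sizes.

    Invariant: factors are positive and have geometric mean 1.
    """

    factors: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        gm = np.exp(np.log(self.factors.values).mean())
        if abs(gm - 1.0) > 1e-8:
            raise ValueError(f"factors must have geometric mean 1 (got {gm})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.factors.index)

    def effective_sizes(self) -> pd.Series:
        """library size x factor, the denominator of normalized CPM."""
        return self.library_sizes * self.factors


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a unit tag (``CPM`` or ``TPM``)."""

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ("CPM", "TPM"):
            raise ValueError(f"unit must be CPM or TPM, got {self.unit!r}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.unit == "TPM":
            colsums = self.values.sum(axis=0).values
            if not np.allclose(colsums, 1e6, rtol=1e-3):
                raise ValueError("TPM columns must sum to 1e6")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _unit_factors(counts: CountMatrix) -> NormFactors:
    lib = counts.library_sizes().astype(float)
    return NormFactors(pd.Series(1.0, index=lib.index), lib)


def tmm_factors(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormFactors:
    """Estimate TMM scaling factors.

    The reference sample is the one whose 75th-percentile CPM (type-7
    quantile) is closest to the mean 75th percentile across samples.  For
    every other sample, M and A are computed over genes with nonzero counts
    in both it and the reference; two-sided trimming removes the ``trim_m``
    fraction by M and ``trim_a`` fraction by A from each ranking; the factor
    is ``2**weighted_mean(M)`` with inverse delta-method (binomial) variance
    weights.  All factors are rescaled to geometric mean 1.
    """
    y = counts.counts.values.astype(float)
    lib = y.sum(axis=0)
    if counts.n_samples < 2:
        raise ValueError("TMM requires at least 2 samples")
    if (lib == 0).any():
        bad = counts.counts.columns[lib == 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")

    cpm_ = y / lib * 1e6
    f75 = np.quantile(cpm_, 0.75, axis=0)  # type-7 linear interpolation
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    logf = np.zeros(counts.n_samples)
    for k in range(counts.n_samples):
        if k == ref:
            continue
        logf[k] = _tmm_pair_log2(y[:, k], y[:, ref], lib[k], lib[ref], trim_m, trim_a)
    factors = 2.0 ** logf
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(
        pd.Series(factors, index=counts.counts.columns),
        counts.library_sizes().astype(float),
    )


def _tmm_pair_log2(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos], ref[pos]
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method variance of M under binomial sampling
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    w = 1.0 / v[keep]
    f = float(np.sum(w * m[keep]) / np.sum(w))
    return 0.0 if not np.isfinite(f) else f


def cpm(counts: CountMatrix, factors: NormFactors | None = None) -> ExpressionMatrix:
    """Counts per million, optionally on TMM-adjusted effective library sizes."""
    if factors is None:
        factors = _unit_factors(counts)
    if set(factors.sample_ids) != set(counts.sample_ids):
        raise ValueError("normalization factors do not match the sample set")
    eff = factors.effective_sizes().reindex(counts.counts.columns)
    vals = counts.counts / eff * 1e6
    return ExpressionMatrix(vals, "CPM")


def tpm(
    counts: CountMatrix,
    lengths: GeneLengths,
    factors: NormFactors | None = None,
) -> ExpressionMatrix:
    """Transcripts per kilobase million.

    Per sample: ``rate_g = effective_count_g / length_g`` and
    ``TPM_g = rate_g / sum(rates) * 1e6``.  With ``factors`` given, the
    effective count is ``count / factor`` (the library size cancels in the
    ratio); otherwise the raw count is used.  Every gene must have a length.
    """
    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        head = ", ".join(map(str, missing[:5]))
        raise ValueError(
            f"{len(missing)} genes missing from the length table (e.g. {head})"
        )
    L = np.array([lengths[g] for g in counts.gene_ids], dtype=float)
    eff = counts.counts.values.astype(float)
    if factors is not None:
        if set(factors.sample_ids) != set(counts.sample_ids):
            raise ValueError("normalization factors do not match the sample set")
        f = factors.factors.reindex(counts.counts.columns).values
        eff = eff / f
    rate = eff / L[:, None]
    colsum = rate.sum(axis=0)
    if (colsum == 0).any():
        bad = counts.counts.columns[colsum == 0][0]
        raise ValueError(f"sample {bad!r} has no expressed genes; TPM undefined")
    vals = pd.DataFrame(
        rate / colsum * 1e6, index=counts.counts.index, columns=counts.counts.columns
    )
    return ExpressionMatrix(vals, "TPM")


def write_factors(factors: NormFactors, path) -> None:
    out = pd.DataFrame(
        {
            "sample": factors.sample_ids,
            "lib_size": factors.library_sizes.reindex(factors.sample_ids).values,
            "factor": factors.factors.values,
        }
    )
    out.to_csv(path, sep="\t", index=False)
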