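"""Synthetic RNA-seq counts and qPCR Ct tables with known ground truth.

The count generator draws negative-binomial counts (edgeR parameterization,
``variance = mu + phi * mu**2`` so BCV = sqrt(phi) by construction) over a
small cohort of lesion groups.  A designated fraction of genes is "stable":
zero group log-fold-change and dispersion at the low end of the range —
exactly the behaviour a reference gene should show.  The remaining genes
receive per-group log2 fold-changes drawn from a normal distribution.
Library-size factors are log-normal; baseline means log-uniform.

The Ct generator inverts the comparative-Ct model: for a chosen subset of
genes, ``Ct = intercept - log(expression) / log(E)`` plus Gaussian cycle
noise, per technical replicate.

Defaults mirror the cohort the screen was designed for: 29 samples in four
groups (13 actinic keratosis, 7 intraepidermal carcinoma, 5 squamous cell
carcinoma, 4 non-photodamaged skin).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import CountMatrix, CtTable, GeneLengths

#: lesion groups and sample counts of the emulated 29-sample skin cohort
DEFAULT_GROUPS = ("AK", "IEC", "SCC", "NORM")
DEFAULT_SAMPLES_PER_GROUP = (13, 7, 5, 4)


@dataclass
class SimTruth:
    """Ground truth behind a simulated dataset.

    ``genes``: per-gene baseline mean, dispersion phi, stable flag and one
    ``lfc_<group>`` column per group (log2 fold-changes; all zero for
    stable genes).  ``samples``: per-sample group label and library-size
    factor.  ``seed`` reproduces the draw.
    """

    genes: pd.DataFrame
    samples: pd.DataFrame
    seed: int

    def __post_init__(self) -> None:
        lfc_cols = [c for c in self.genes.columns if c.startswith("lfc_")]
        stable = self.genes["stable"].values
        if stable.any() and not (self.genes.loc[stable, lfc_cols].values == 0).all():
            raise ValueError("stable genes must have zero log-fold-changes")
        if (self.genes["dispersion"].values < 0).any():
            raise ValueError("dispersions must be >= 0")
        if (self.samples["libsize_factor"].values <= 0).any():
            raise ValueError("library-size factors must be positive")

    @property
    def stable_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["stable"]])

    def expression(self) -> pd.DataFrame:
        """True per-sample expected abundance (baseline x 2**group LFC)."""
        lfc = np.array(
            [
                self.genes[f"lfc_{grp}"].values
                for grp in self.samples["group"].values
            ]
        ).T  # genes x samples
        vals = self.genes["baseline"].values[:, None] * 2.0**lfc
        return pd.DataFrame(vals, index=self.genes.index, columns=self.samples.index)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB draw with variance = mu + phi mu^2 (Poisson where phi == 0)."""
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = phi == 0
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    if (~poisson).any():
        r = 1.0 / phi[~poisson]
        p = r / (r + mu[~poisson])
        out[~poisson] = rng.negative_binomial(r, p)
    return out


def simulate_counts(
    n_genes: int = 2000,
    n_samples_per_group: int | Sequence[int] = DEFAULT_SAMPLES_PER_GROUP,
    groups: Sequence[str] = DEFAULT_GROUPS,
    frac_stable: float = 0.1,
    lfc_sd: float = 1.0,
    dispersion_range: tuple[float, float] = (0.01, 0.36),
    libsize_cv: float = 0.25,
    baseline_range: tuple[float, float] = (0.5, 5000.0),
    seed: int = 0,
) -> tuple[CountMatrix, SimTruth]:
    """Draw a gene x sample NB count matrix with designated stable genes.

    Counts for gene g, sample j are NB with mean
    ``baseline_g * 2**lfc_g,group(j) * libsize_factor_j`` and dispersion
    ``phi_g``.  Stable genes get ``phi`` at the low end of
    ``dispersion_range`` and zero fold-change in every group; other genes
    draw ``phi`` log-uniformly over the range and per-group LFCs from
    ``Normal(0, lfc_sd)``.  Library-size factors are log-normal with
    coefficient of variation ``libsize_cv``; baselines log-uniform over
    ``baseline_range``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= frac_stable <= 1:
        raise ValueError("frac_stable must be in [0, 1]")
    if lfc_sd < 0 or libsize_cv < 0:
        raise ValueError("lfc_sd and libsize_cv must be >= 0")
    lo, hi = dispersion_range
    if lo < 0 or hi < lo:
        raise ValueError("dispersion_range must satisfy 0 <= lo <= hi")
    if isinstance(n_samples_per_group, int):
        n_per = [n_samples_per_group] * len(groups)
    else:
        n_per = list(n_samples_per_group)
        if len(n_per) != len(groups):
            raise ValueError("n_samples_per_group length must match groups")
    if any(n < 1 for n in n_per):
        raise ValueError("every group needs at least 1 sample")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i+1:05d}" for i in range(n_genes)]
    sample_ids, sample_groups = [], []
    for grp, n in zip(groups, n_per):
        for j in range(n):
            sample_ids.append(f"{grp}_{j+1}")
            sample_groups.append(grp)

    n_stable = int(round(frac_stable * n_genes))
    stable = np.zeros(n_genes, dtype=bool)
    stable[rng.choice(n_genes, size=n_stable, replace=False)] = True

    baseline = np.exp(
        rng.uniform(np.log(baseline_range[0]), np.log(baseline_range[1]), n_genes)
    )
    if hi > 0:
        phi = np.exp(rng.uniform(np.log(max(lo, 1e-8)), np.log(hi), n_genes)) if lo > 0 else (
            rng.uniform(lo, hi, n_genes)
        )
    else:
        phi = np.zeros(n_genes)
    phi[stable] = lo

    lfc = rng.normal(0.0, lfc_sd, size=(n_genes, len(groups)))
    lfc[stable, :] = 0.0

    if libsize_cv > 0:
        sigma2 = np.log1p(libsize_cv**2)
        libfac = rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), len(sample_ids))
    else:
        libfac = np.ones(len(sample_ids))

    group_of = {g: i for i, g in enumerate(groups)}
    gcol = np.array([group_of[g] for g in sample_groups])
    mu = baseline[:, None] * 2.0 ** lfc[:, gcol] * libfac[None, :]
    counts = _nb_draw(rng, mu, np.repeat(phi[:, None], len(sample_ids), axis=1))

    genes = pd.DataFrame(
        {"baseline": baseline, "dispersion": phi, "stable": stable},
        index=pd.Index(gene_ids, name="gene"),
    )
    for gi, grp in enumerate(groups):
        genes[f"lfc_{grp}"] = lfc[:, gi]
    samples = pd.DataFrame(
        {"group": sample_groups, "libsize_factor": libfac},
        index=pd.Index(sample_ids, name="sample"),
    )
    truth = SimTruth(genes=genes, samples=samples, seed=seed)
    cm = CountMatrix(
        pd.DataFrame(counts, index=genes.index, columns=samples.index),
        groups=dict(zip(sample_ids, sample_groups)),
    )
    return cm, truth


def simulate_ct(
    truth: SimTruth,
    genes: Sequence[str] | None = None,
    efficiency: float = 2.0,
    noise_sd: float = 0.2,
    replicates: int = 3,
    intercept: float = 34.0,
    biological_variation: bool = True,
    seed: int = 0,
) -> CtTable:
    """Generate triplicate qPCR Ct values from true expression.

    ``Ct = intercept - log(expression) / log(E) + Normal(0, noise_sd)`` per
    replicate.  Expression is the sample's true abundance: the expected
    value ``baseline x 2**group-LFC`` times, when ``biological_variation``
    is on, a per-(gene, sample) gamma variate with the gene's dispersion
    (mean 1, variance phi — the mixing distribution behind the NB counts),
    so that biologically variable genes fluctuate between samples in the
    qPCR assay exactly as they do in the sequencing counts.  The
    library-size factor is a sequencing artefact and does not enter.
    Technical replicates share the sample's abundance and differ only by
    the Gaussian cycle noise.  Zero expression has no finite Ct and is
    rejected.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError(f"efficiency must be in (1, 2], got {efficiency}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    expr = truth.expression()
    if genes is not None:
        missing = [g for g in genes if g not in expr.index]
        if missing:
            raise ValueError(f"genes not in truth: {missing}")
        expr = expr.loc[list(genes)]
    bad = (expr.values <= 0) | ~np.isfinite(expr.values)
    if bad.any():
        g = expr.index[bad.any(axis=1)][0]
        raise ValueError(f"zero expression for gene {g!r}: Ct undefined")

    rng = np.random.default_rng(seed)
    values = expr.values
    if biological_variation:
        phi = truth.genes.loc[expr.index, "dispersion"].values
        mult = np.ones_like(values)
        pos = phi > 0
        if pos.any():
            shape = 1.0 / phi[pos]
            mult[pos, :] = rng.gamma(
                shape[:, None], (1.0 / shape)[:, None], size=(pos.sum(), values.shape[1])
            )
        values = values * mult
    base_ct = intercept - np.log(values) / np.log(efficiency)
    rows = []
    for r in range(1, replicates + 1):
        noise = rng.normal(0.0, noise_sd, size=base_ct.shape) if noise_sd > 0 else 0.0
        ct = base_ct + noise
        for gi, gene in enumerate(expr.index):
            for sj, sample in enumerate(expr.columns):
                rows.append(
                    {
                        "sample": sample,
                        "group": truth.samples.loc[sample, "group"],
                        "gene": gene,
                        "replicate": r,
                        "ct": float(ct[gi, sj]),
                    }
                )
    return CtTable(pd.DataFrame(rows))


def simulate_lengths(
    gene_ids: Sequence[str], seed: int = 0, low: int = 500, high: int = 10_000
) -> GeneLengths:
    """Uniform union-exon lengths in [low, high] bases for the given genes."""
    rng = np.random.default_rng(seed)
    return GeneLengths(
        {g: int(L) for g, L in zip(gene_ids, rng.integers(low, high + 1, len(gene_ids)))}
    )


def write_truth(truth: SimTruth, path: str | Path) -> None:
    out = truth.genes.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
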