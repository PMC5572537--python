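"""Comparative Ct (delta-delta-Ct) relative quantitation and group comparison.

The classic Livak method at amplification efficiency 2: per sample,
``dCt = Ct_target - mean(Ct_refs)`` (the arithmetic mean of reference Cts
equals the geometric mean of reference quantities), ``ddCt = dCt -
mean(dCt over calibrator samples)`` and ``fold = 2**-ddCt``.  Group means
are compared by one-way ANOVA with Tukey HSD post-tests, reported as
mean +/- SEM per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CtTable
from .genorm import aggregate_ct

#: replicate Ct standard deviations above this are flagged as technically noisy
DEFAULT_MAX_REPLICATE_SD = 0.5


@dataclass
class FoldChangeResult:
    """Per-sample ddCt fold changes plus per-group summary statistics."""

    per_sample: pd.DataFrame     # sample, group, dct, ddct, fold
    target: str
    references: list[str]
    calibrator: str
    per_group: pd.DataFrame | None = None   # group, n, mean_fold, sem_fold
    anova_p: float | None = None
    tukey: pd.DataFrame | None = None       # group_a, group_b, p_adj
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.per_sample["fold"] <= 0).any():
            raise ValueError("fold changes must be positive")


def aggregate_replicates(
    ct: CtTable, max_sd: float = DEFAULT_MAX_REPLICATE_SD
) -> pd.DataFrame:
    """Mean Ct per (sample, gene) with the replicate SD recorded.

    Cells whose replicate SD exceeds ``max_sd`` cycles are flagged, not
    dropped — the flag marks technically questionable wells for review.
    Returns a long DataFrame with columns sample, group, gene, ct_mean,
    ct_sd (NaN for single replicates), n_replicates, flagged.
    """
    grouped = ct.records.groupby(["sample", "gene"], sort=False)
    out = grouped.agg(
        group=("group", "first"),
        ct_mean=("ct", "mean"),
        ct_sd=("ct", lambda s: s.std(ddof=1) if len(s) > 1 else np.nan),
        n_replicates=("ct", "size"),
    ).reset_index()
    out["flagged"] = out["ct_sd"] > max_sd
    return out


def ddct_fold_change(
    ct: CtTable,
    target: str,
    references: list[str],
    calibrator: str,
) -> FoldChangeResult:
    """Fold change of ``target`` relative to the calibrator group.

    References are combined by the arithmetic mean of their Cts.  The
    calibrator group's mean ddCt is 0 by construction, so its fold changes
    have geometric mean 1.
    """
    mat = aggregate_ct(ct)  # genes x samples, replicate-averaged
    needed = [target] + list(references)
    missing_genes = [g for g in needed if g not in mat.index]
    if missing_genes:
        raise ValueError(f"genes absent from the Ct table: {missing_genes}")
    holes = mat.loc[needed].isna()
    if holes.any().any():
        cells = [(g, s) for g in needed for s in mat.columns if holes.loc[g, s]]
        raise ValueError(f"missing Ct cells: {cells[:10]}")

    groups = ct.sample_groups()
    samples = list(mat.columns)
    cal_samples = [s for s in samples if groups[s] == calibrator]
    if not cal_samples:
        raise ValueError(f"calibrator group {calibrator!r} has no samples")

    ref_ct = mat.loc[list(references)].mean(axis=0)
    dct = mat.loc[target] - ref_ct
    ddct = dct - dct[cal_samples].mean()
    per_sample = pd.DataFrame(
        {
            "sample": samples,
            "group": [groups[s] for s in samples],
            "dct": dct.values,
            "ddct": ddct.values,
            "fold": 2.0 ** (-ddct.values),
        }
    )
    return FoldChangeResult(
        per_sample=per_sample,
        target=target,
        references=list(references),
        calibrator=calibrator,
    )


def group_compare(result: FoldChangeResult, on: str = "fold") -> FoldChangeResult:
    """Annotate a fold-change result with group summaries, ANOVA and Tukey HSD.

    ``on`` selects the tested quantity: ``"fold"`` (the plotted scale,
    default) or ``"ddct"`` (log2 scale, sometimes preferred because fold
    changes are right-skewed; the choice is recorded in ``notes``).
    Requires at least 2 groups with at least 2 samples each.
    """
    if on not in ("fold", "ddct"):
        raise ValueError("on must be 'fold' or 'ddct'")
    ps = result.per_sample
    by_group = {g: sub[on].values for g, sub in ps.groupby("group", sort=False)}
    if len(by_group) < 2:
        raise ValueError("group comparison requires at least 2 groups")
    small = [g for g, v in by_group.items() if len(v) < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    names = list(by_group)
    arrays = [by_group[g] for g in names]
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        # identical values everywhere: no variance on either side, F = 0, p = 1
        anova_p = 1.0
        tukey_rows = [
            {"group_a": a, "group_b": b, "p_adj": 1.0}
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        ]
    else:
        _, anova_p = stats.f_oneway(*arrays)
        hsd = stats.tukey_hsd(*arrays)
        tukey_rows = [
            {"group_a": names[i], "group_b": names[j], "p_adj": float(hsd.pvalue[i, j])}
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]

    summary = (
        ps.groupby("group", sort=False)["fold"]
        .agg(n="size", mean_fold="mean", sem_fold=lambda s: s.std(ddof=1) / np.sqrt(len(s)))
        .reset_index()
    )
    result.per_group = summary
    result.anova_p = float(anova_p)
    result.tukey = pd.DataFrame(tukey_rows)
    result.notes.append(f"group comparison on the {on} scale")
    return result
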