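"""Readers and writers for the external formats the pipeline touches.

Count matrices are tab-separated with gene identifiers in the first column
and one column per sample.  Gene lengths come either from a two-column TSV
or from a GENCODE-style GTF (union of exonic bases per gene).  qPCR
measurements arrive as a long-format CSV of Ct values; gene sets for
over-representation analysis use the standard GMT format.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Raw gene x sample read counts with optional sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, indexed by gene id with one
        column per sample id.  Gene and sample ids must be unique.
    groups
        Optional map ``sample_id -> group label`` (lesion type).  Group
        labels are required by NormFinder-style analyses but not by the
        screen itself.
    patient_ids
        Optional map ``sample_id -> patient label``.
    """

    counts: pd.DataFrame
    groups: dict[str, str] | None = None
    patient_ids: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if (self.counts.values < 0).any():
            g, s = np.argwhere(self.counts.values < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if self.groups is not None:
            missing = set(self.counts.columns) - set(self.groups)
            if missing:
                raise ValueError(f"samples without group label: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        """Column sums (total mapped reads per sample)."""
        return self.counts.sum(axis=0)

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[list(gene_ids)], groups=self.groups, patient_ids=self.patient_ids
        )


class GeneLengths(dict):
    """Map ``gene_id -> union-exon length`` in bases (all lengths > 0)."""

    def __init__(self, data: Mapping[str, int]):
        bad = [g for g, L in data.items() if L <= 0]
        if bad:
            raise ValueError(f"non-positive gene lengths for: {bad[:5]}")
        super().__init__({g: int(L) for g, L in data.items()})


@dataclass
class CtTable:
    """Long-format qPCR measurements: one row per (sample, gene, replicate).

    Columns: ``sample``, ``group``, ``gene``, ``replicate`` (1-based),
    ``ct`` (cycles).  Ct values must be finite and the
    (sample, gene, replicate) triple unique.
    """

    records: pd.DataFrame

    REQUIRED = ("sample", "group", "gene", "replicate", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        rec = self.records
        ct = pd.to_numeric(rec["ct"], errors="coerce")
        if ct.isna().any() or not np.isfinite(ct).all():
            bad = rec.loc[~np.isfinite(ct.astype(float))].iloc[0]
            raise ValueError(
                f"non-finite Ct for sample={bad['sample']!r} gene={bad['gene']!r} "
                f"replicate={bad['replicate']!r}: {bad['ct']!r}"
            )
        if (rec["replicate"].astype(int) < 1).any():
            raise ValueError("replicate indices must be >= 1")
        dups = rec.duplicated(subset=["sample", "gene", "replicate"])
        if dups.any():
            bad = rec.loc[dups].iloc[0]
            raise ValueError(
                "duplicate (sample, gene, replicate): "
                f"({bad['sample']!r}, {bad['gene']!r}, {bad['replicate']!r})"
            )
        rec = rec.copy()
        rec["ct"] = ct.astype(float)
        rec["replicate"] = rec["replicate"].astype(int)
        self.records = rec.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.records["gene"]))

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.records["sample"]))

    def sample_groups(self) -> dict[str, str]:
        """Map sample -> group label (first occurrence wins; must be consistent)."""
        g = self.records.groupby("sample", sort=False)["group"].agg(lambda s: s.iloc[0])
        ngroups = self.records.groupby("sample", sort=False)["group"].nunique()
        if (ngroups > 1).any():
            bad = ngroups[ngroups > 1].index[0]
            raise ValueError(f"sample {bad!r} carries more than one group label")
        return dict(g)


@dataclass
class GeneSetCollection:
    """Named gene sets for over-representation analysis (GMT content).

    ``sets`` maps set name -> tuple of member gene ids (unique, non-empty);
    ``descriptions`` carries the GMT description field.
    """

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene x sample raw count TSV.

    First column holds gene ids, header row holds sample ids, body must be
    non-negative integers.  File order of genes and samples is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty count matrix")
    body = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            gene = df.index[vals.isna()][0]
            raise ValueError(f"{path}: non-numeric count at gene {gene!r}, sample {col!r}")
        body[col] = vals
    arr = body.values
    if not np.allclose(arr, np.round(arr)):
        g, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ValueError(
            f"{path}: non-integer count at gene {body.index[g]!r}, sample {body.columns[s]!r}"
        )
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"{path}: negative count at gene {body.index[g]!r}, sample {body.columns[s]!r}"
        )
    counts = body.astype(np.int64)
    counts.index = counts.index.astype(str)
    counts.index.name = df.index.name or "gene"
    return CountMatrix(counts)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    out = cm.counts.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep="\t")


_GTF_ATTR_RE = re.compile(r'gene_id\s+"([^"]+)"')


def gene_lengths_from_gtf(path: str | Path) -> GeneLengths:
    """Compute per-gene union-exon lengths from a GENCODE-style GTF.

    For each gene the length is the number of bases covered by the union of
    its exon intervals across all isoforms.  GTF coordinates are 1-based
    inclusive; intervals are converted to half-open 0-based at this boundary
    and merged.  Strand is ignored.  Genes with no exon features are omitted
    with a warning.  Attribute syntax must be the quoted GENCODE dialect
    (``gene_id "ENSG..."``); anything else is rejected.
    """
    path = Path(path)
    exons: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line ({len(fields)} fields)")
            chrom, _source, feature, start, end, _score, _strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if s < 1 or e < s:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            m = _GTF_ATTR_RE.search(attrs)
            if m is None:
                raise ValueError(
                    f"{path}:{lineno}: no GENCODE-style gene_id attribute "
                    f'(expected gene_id "..."): {attrs[:80]!r}'
                )
            # 1-based inclusive -> half-open 0-based
            exons.setdefault(m.group(1), []).append((chrom, s - 1, e))
    if not exons:
        logger.warning("%s: no exon features found; empty gene length table", path)
    lengths: dict[str, int] = {}
    for gene, ivs in exons.items():
        total = 0
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in ivs:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom_ivs in by_chrom.values():
            chrom_ivs.sort()
            cur_s, cur_e = chrom_ivs[0]
            for s, e in chrom_ivs[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    total += cur_e - cur_s
                    cur_s, cur_e = s, e
            total += cur_e - cur_s
        lengths[gene] = total
    return GeneLengths(lengths)


def read_gene_lengths(path: str | Path) -> GeneLengths:
    """Read a two-column TSV of gene_id and length (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene_id, length)")
    # tolerate a header row
    first = df.iloc[0, 1]
    try:
        int(first)
    except (TypeError, ValueError):
        df = df.iloc[1:]
    return GeneLengths({str(g): int(L) for g, L in zip(df.iloc[:, 0], df.iloc[:, 1])})


def write_gene_lengths(lengths: GeneLengths, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlength\n")
        for g, L in lengths.items():
            fh.write(f"{g}\t{L}\n")


def read_ct_table(path: str | Path) -> CtTable:
    """Read a long-format qPCR CSV with columns sample, group, gene, replicate, ct."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CtTable.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return CtTable(df)


def write_ct_table(ct: CtTable, path: str | Path) -> None:
    ct.records.to_csv(path, index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format: name TAB description TAB member genes."""
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: gene set {parts[0]!r} has no members"
                )
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                logger.warning(
                    "%s:%d: gene set %r has duplicate members; deduplicated",
                    path, lineno, name,
                )
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = tuple(unique)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def read_sample_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sample id to group label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns sample, group")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
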