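"""Haplotype collapsing, Nei's haplotype diversity and nucleotide diversity.

Nucleotide diversity pi is the average per-site pairwise difference
(Nei 1987) under *complete deletion*: only columns free of gaps and N in
every accession contribute, matching the accounting convention of DnaSP.
Haplotypes are distinct allele vectors over SNP columns (indels excluded by
default, switchable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _seq
from .alignment import AlignedGenomeSet
from .context import ContextIndex, column_regions
from .errors import UndefinedStatisticError
from .structure import RegionPartition, REGIONS


@dataclass
class Haplotype:
    hap_id: str
    representative: str  # accession id whose row defines the haplotype
    members: tuple[str, ...]

    @property
    def frequency(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeTable:
    haplotypes: list[Haplotype]
    n: int

    @property
    def spectrum(self) -> tuple[int, ...]:
        return tuple(h.frequency for h in self.haplotypes)

    @property
    def count(self) -> int:
        return len(self.haplotypes)

    def members_of(self, hap_id: str) -> tuple[str, ...]:
        for h in self.haplotypes:
            if h.hap_id == hap_id:
                return h.members
        raise KeyError(hap_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype": [h.hap_id for h in self.haplotypes],
                "frequency": [h.frequency for h in self.haplotypes],
                "representative": [h.representative for h in self.haplotypes],
                "members": [",".join(h.members) for h in self.haplotypes],
            }
        )


def _complete_columns(matrix: np.ndarray, columns: np.ndarray | None = None) -> np.ndarray:
    """Columns free of gaps and N in all rows (complete deletion)."""
    codes = _seq.CODE[matrix]
    ok = (codes < 4).all(axis=0)
    idx = np.flatnonzero(ok)
    if columns is not None:
        idx = np.intersect1d(idx, columns)
    return idx


def _snp_columns(matrix: np.ndarray, columns: np.ndarray | None = None) -> np.ndarray:
    """Polymorphic complete-deletion columns."""
    idx = _complete_columns(matrix, columns)
    sub = matrix[:, idx]
    poly = (sub != sub[0]).any(axis=0)
    return idx[poly]


def collapse_haplotypes(
    aln: AlignedGenomeSet,
    key: str = "snp-only",
    columns: np.ndarray | None = None,
) -> HaplotypeTable:
    """Group accessions into haplotypes by identity of their allele vectors.

    ``key='snp-only'`` (default) uses polymorphic gap/N-free columns only;
    ``key='snp+indel'`` additionally distinguishes accessions by their gap
    patterns.  Haplotype ids are numbered by first appearance.
    """
    if key not in ("snp-only", "snp+indel"):
        raise ValueError(f"unknown haplotype key {key!r}")
    if key == "snp-only":
        cols = _snp_columns(aln.matrix, columns)
        keys = [aln.matrix[i, cols].tobytes() for i in range(aln.n)]
    else:
        sub = aln.matrix if columns is None else aln.matrix[:, columns]
        varying = (sub != sub[0]).any(axis=0)
        keys = [sub[i, varying].tobytes() for i in range(aln.n)]
    groups: dict[bytes, list[str]] = {}
    order: list[bytes] = []
    for acc, k in zip(aln.accessions, keys):
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(acc)
    haplotypes = [
        Haplotype(f"Hap{i + 1}", groups[k][0], tuple(groups[k]))
        for i, k in enumerate(order)
    ]
    return HaplotypeTable(haplotypes, aln.n)


def haplotype_diversity(tab: HaplotypeTable) -> float:
    """Nei's haplotype diversity Hd = n/(n-1) * (1 - sum p_i^2)."""
    n = tab.n
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity needs n >= 2")
    p2 = sum((f / n) ** 2 for f in tab.spectrum)
    return n / (n - 1) * (1.0 - p2)


def _pairwise_diff_per_column(matrix: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Number of differing pairs per column, via allele counts:
    C(n,2) - sum_a C(c_a, 2)."""
    n = matrix.shape[0]
    codes = _seq.CODE[matrix[:, cols]]
    counts = np.zeros((len(cols), 4), dtype=np.int64)
    for b in range(4):
        counts[:, b] = (codes == b).sum(axis=0)
    same = (counts * (counts - 1) // 2).sum(axis=1)
    return n * (n - 1) // 2 - same


def nucleotide_diversity(
    aln: AlignedGenomeSet, columns: np.ndarray | None = None
) -> float:
    """Nucleotide diversity pi over the given columns (default: all).

    pi = sum_{i<j} d_ij / (C(n,2) * m) with d_ij the count of differing
    sites between accessions i and j over the m complete-deletion columns.
    """
    if aln.n < 2:
        raise UndefinedStatisticError("nucleotide diversity needs n >= 2")
    cols = _complete_columns(aln.matrix, columns)
    m = len(cols)
    if m == 0:
        raise UndefinedStatisticError("no gap/N-free columns (m = 0)")
    diffs = _pairwise_diff_per_column(aln.matrix, cols)
    npairs = aln.n * (aln.n - 1) // 2
    return float(diffs.sum()) / (npairs * m)


@dataclass
class WindowProfile:
    windows: pd.DataFrame  # start, end, m, pi, hotspot
    window: int
    step: int

    @property
    def peak(self) -> pd.Series:
        return self.windows.loc[self.windows["pi"].idxmax()]


def sliding_window_pi(
    aln: AlignedGenomeSet,
    window: int = 600,
    step: int = 100,
    hotspot_quantile: float = 0.95,
) -> WindowProfile:
    """Sliding-window pi over alignment columns.

    Windows are [k*step, k*step + window) for k = 0..floor((L-window)/step);
    the trailing partial window is dropped.  Windows whose pi exceeds the
    given quantile of nonzero window values are flagged as hotspots.  When
    the alignment is shorter than one window, a single whole-alignment
    window is returned with a warning.
    """
    L = aln.length
    if L < window:
        warnings.warn(
            f"alignment length {L} < window {window}: single window", stacklevel=2
        )
        starts = [0]
        ends = [L]
    else:
        ks = range((L - window) // step + 1)
        starts = [k * step for k in ks]
        ends = [s + window for s in starts]
    codes = _seq.CODE[aln.matrix]
    complete = (codes < 4).all(axis=0)
    per_col = np.zeros(L, dtype=np.int64)
    cols = np.flatnonzero(complete)
    per_col[cols] = _pairwise_diff_per_column(aln.matrix, cols)
    cum_d = np.concatenate([[0], np.cumsum(per_col)])
    cum_m = np.concatenate([[0], np.cumsum(complete)])
    npairs = aln.n * (aln.n - 1) // 2
    rows = []
    for s, e in zip(starts, ends):
        m = int(cum_m[e] - cum_m[s])
        d = int(cum_d[e] - cum_d[s])
        pi = d / (npairs * m) if m > 0 else float("nan")
        rows.append({"start": s, "end": e, "m": m, "pi": pi})
    df = pd.DataFrame(rows)
    finite = df["pi"].dropna()
    cutoff = finite.quantile(hotspot_quantile) if len(finite) else float("nan")
    df["hotspot"] = (df["pi"] > 0) & (df["pi"] >= cutoff)
    return WindowProfile(df, window, step)


def diversity_by_region(
    aln: AlignedGenomeSet,
    part: RegionPartition,
    index: ContextIndex,
) -> pd.DataFrame:
    """Per-region diversity table (LSC / IR / SSC / Total rows).

    The IR row uses the IRb copy only (single-copy convention); regional
    haplotype counts collapse accessions over the region's columns.
    """
    from .variants import call_snp_sites

    region_codes = column_regions(aln, index)
    blocks = {
        "LSC": np.flatnonzero(region_codes == REGIONS.index("LSC")),
        "IR": np.flatnonzero(region_codes == REGIONS.index("IRb")),
        "SSC": np.flatnonzero(region_codes == REGIONS.index("SSC")),
        "Total": np.arange(aln.length),
    }
    snps = call_snp_sites(aln, part, index, dedupe_ir=True)
    rows = []
    for name, cols in blocks.items():
        colset = set(cols.tolist())
        region_snps = [s for s in snps if s.column in colset]
        tab = collapse_haplotypes(aln, columns=cols)
        rows.append(
            {
                "region": name,
                "aligned_length": len(cols),
                "polymorphic_sites": len(region_snps),
                "singletons": sum(s.site_class == "singleton" for s in region_snps),
                "parsimony_informative": sum(
                    s.site_class == "parsimony-informative" for s in region_snps
                ),
                "pi": nucleotide_diversity(aln, cols),
                "haplotypes": tab.count,
                "hd": haplotype_diversity(tab),
            }
        )
    return pd.DataFrame(rows)
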