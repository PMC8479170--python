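"""Classify alignment columns into region and feature context.

Every column gets exactly one :class:`FeatureContext`: a region (LSC, IRb,
SSC, IRa), a site class (exon, intron or spacer) and, for genic sites, the
gene name.  Precedence follows coding depth: a CDS part nested inside
another gene's intron (the classic case of *matK* inside the *trnK-UUU*
intron) classifies as exon of the coding gene.  Columns where the reference
is gapped inherit the context of the nearest preceding reference base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import AlignedGenomeSet
from .annotation import AnnotationSet
from .structure import RegionPartition, REGIONS

SITE_CLASSES = ("exon", "intron", "spacer")


@dataclass(frozen=True)
class FeatureContext:
    region: str
    site_class: str
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.site_class in ("exon", "intron") and self.gene is None:
            raise ValueError("genic site class requires a gene name")


class ContextIndex:
    """Precomputed per-position context for the ungapped reference.

    Construction order encodes precedence: gene spans (larger spans first,
    so nested genes overwrite their host) mark positions as intron; exon
    parts of noncoding genes then CDS parts mark exon, CDS last so coding
    context always wins.
    """

    def __init__(self, ann: AnnotationSet, part: RegionPartition):
        g = part.genome_length
        if ann.genome_length != g:
            raise ValueError(
                f"annotation length {ann.genome_length} != partition {g}"
            )
        self.part = part
        self.ann = ann
        self.genes: list[str] = ann.gene_names()
        gene_code = {name: i for i, name in enumerate(self.genes)}
        # site class: 0 spacer, 1 intron, 2 exon
        self.class_code = np.zeros(g, dtype=np.int8)
        self.gene_idx = np.full(g, -1, dtype=np.int32)
        spans = sorted(
            ann.gene_spans(), key=lambda f: -(f.span[1] - f.span[0])
        )
        for f in spans:
            for s, e in f.parts:
                self.class_code[s:e] = 1
                self.gene_idx[s:e] = gene_code[f.gene]
        for f in ann.features:
            if f.kind == "exon":
                for s, e in f.parts:
                    self.class_code[s:e] = 2
                    self.gene_idx[s:e] = gene_code[f.gene]
        for f in ann.cds_features():
            for s, e in f.parts:
                self.class_code[s:e] = 2
                self.gene_idx[s:e] = gene_code[f.gene]
        self.region_code = np.empty(g, dtype=np.int8)
        for code, name in enumerate(REGIONS):
            s, e = part.interval(name)
            self.region_code[s:e] = code

    def context_at(self, pos: int) -> FeatureContext:
        gi = self.gene_idx[pos]
        return FeatureContext(
            region=REGIONS[self.region_code[pos]],
            site_class=("spacer", "intron", "exon")[self.class_code[pos]],
            gene=self.genes[gi] if gi >= 0 else None,
        )

    def gene_at(self, pos: int) -> str | None:
        gi = self.gene_idx[pos]
        return self.genes[gi] if gi >= 0 else None


def classify_column(
    col: int,
    aln: AlignedGenomeSet,
    index: ContextIndex,
) -> FeatureContext:
    """Context of one alignment column (gap-in-reference columns inherit the
    nearest preceding reference base's context)."""
    pos = aln.reference_map.previous_position(col)
    if pos is None:
        # leading gap-in-reference columns: inherit the first reference base
        pos = 0
    return index.context_at(pos)


def column_positions(aln: AlignedGenomeSet) -> np.ndarray:
    """Reference ungapped position per column, backward-filled over gaps
    (leading gaps map to position 0)."""
    prev = aln.reference_map.prev_pos
    return np.maximum(prev, 0)


def column_regions(aln: AlignedGenomeSet, index: ContextIndex) -> np.ndarray:
    """Region code (index into REGIONS) per alignment column."""
    return index.region_code[column_positions(aln)]


def column_classes(aln: AlignedGenomeSet, index: ContextIndex) -> np.ndarray:
    """Site class code (0 spacer, 1 intron, 2 exon) per alignment column."""
    return index.class_code[column_positions(aln)]


def region_column_counts(aln: AlignedGenomeSet, index: ContextIndex) -> dict[str, int]:
    """Aligned length (column count) of each region, plus the total."""
    codes = column_regions(aln, index)
    counts = {name: int((codes == i).sum()) for i, name in enumerate(REGIONS)}
    counts["total"] = aln.length
    return counts
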