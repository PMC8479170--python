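"""SNP site and indel event calling from a gapped plastome alignment.

SNP sites are polymorphic alignment columns (gaps and N ignored for the
polymorphism test: a column varying only by gaps is an indel, not a SNP).
Indel events are maximal runs of consecutive columns sharing an identical
accession gap pattern.  Because IRa duplicates IRb, sites falling in IRa
are counted once: with ``dedupe_ir`` (the default) they are dropped from
the returned catalogs, mirroring the "IR region only counted one time"
accounting convention of plastome comparative studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seq
from .alignment import AlignedGenomeSet
from .context import ContextIndex, FeatureContext, column_positions
from .errors import PlastdivError
from .structure import RegionPartition, REGIONS

SINGLETON = "singleton"
PARSIMONY_INFORMATIVE = "parsimony-informative"

# six non-strand-specific directed substitution classes
_CLASS_REPS = [
    (("G", "A"), ("C", "T"), "G>A/C>T"),
    (("A", "G"), ("T", "C"), "A>G/T>C"),
    (("G", "T"), ("C", "A"), "G>T/C>A"),
    (("T", "G"), ("A", "C"), "T>G/A>C"),
    (("G", "C"), ("C", "G"), "G>C/C>G"),
    (("A", "T"), ("T", "A"), "A>T/T>A"),
]
SPECTRUM_CLASSES = [label for _, _, label in _CLASS_REPS]
SPECTRUM_CLASS_OF = {}
for _p1, _p2, _label in _CLASS_REPS:
    SPECTRUM_CLASS_OF[_p1] = _label
    SPECTRUM_CLASS_OF[_p2] = _label


@dataclass
class SnpSite:
    """One polymorphic alignment column."""

    column: int
    ref_position: int
    alleles: dict[str, int]
    carriers: dict[str, tuple[str, ...]]
    site_class: str
    reference_allele: str | None
    ancestral: str | None = None  # major allele (polarized)
    derived: str | None = None
    substitution: str | None = None  # transition / transversion (biallelic)
    spectrum_class: str | None = None
    context: FeatureContext | None = None
    in_ir_duplicate: bool = False

    @property
    def biallelic(self) -> bool:
        return len(self.alleles) == 2


@dataclass
class IndelEvent:
    """One maximal gap-run mutation event relative to the reference."""

    start_column: int
    length: int
    kind: str  # insertion / deletion
    accessions: tuple[str, ...]
    ref_position: int
    context: FeatureContext | None = None
    in_ir_duplicate: bool = False


@dataclass
class SpectrumTable:
    counts: dict[str, int]
    ts: int
    tv: int
    ratio: float  # nan when tv == 0
    skipped_multiallelic: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"class": list(self.counts), "count": list(self.counts.values())}
        )


def _position_regions(part: RegionPartition) -> np.ndarray:
    codes = np.empty(part.genome_length, dtype=np.int8)
    for code, name in enumerate(REGIONS):
        s, e = part.interval(name)
        codes[s:e] = code
    return codes


def call_snp_sites(
    aln: AlignedGenomeSet,
    part: RegionPartition | None = None,
    index: ContextIndex | None = None,
    dedupe_ir: bool = True,
) -> list[SnpSite]:
    """Call one :class:`SnpSite` per polymorphic column.

    With ``dedupe_ir`` and a partition, sites whose reference position falls
    in IRa are excluded (they mirror IRb sites); without it they are
    returned flagged via ``in_ir_duplicate``.
    """
    codes = _seq.CODE[aln.matrix]
    base = codes < 4
    ncol = aln.length
    counts = np.zeros((ncol, 4), dtype=np.int32)
    cols_idx = np.nonzero(base.T)[0]
    np.add.at(counts, (cols_idx, codes.T[base.T]), 1)
    poly_cols = np.flatnonzero((counts > 0).sum(axis=1) >= 2)

    pos_of_col = column_positions(aln)
    region_codes = _position_regions(part) if part is not None else None
    acc = np.array(aln.accessions)
    ref_row = aln.matrix[aln.reference_index]
    ira_code = REGIONS.index("IRa")

    sites: list[SnpSite] = []
    for col in poly_cols:
        col = int(col)
        c = counts[col]
        alleles = {b: int(c[i]) for i, b in enumerate(_seq.BASES) if c[i] > 0}
        col_codes = codes[:, col]
        carriers = {
            b: tuple(acc[col_codes == i]) for i, b in enumerate(_seq.BASES) if c[i] > 0
        }
        n_major = sum(1 for v in alleles.values() if v >= 2)
        site_class = (
            PARSIMONY_INFORMATIVE if n_major >= 2 else SINGLETON
        )
        ref_base = chr(ref_row[col])
        ref_allele = ref_base if ref_base in alleles else None
        ancestral = derived = substitution = spectrum = None
        if len(alleles) == 2:
            (b1, n1), (b2, n2) = sorted(alleles.items())
            if n1 > n2:
                ancestral, derived = b1, b2
            elif n2 > n1:
                ancestral, derived = b2, b1
            else:  # tie: reference allele is ancestral
                if ref_allele == b2:
                    ancestral, derived = b2, b1
                else:
                    ancestral, derived = b1, b2
            substitution = (
                "transition" if _seq.is_transition(ancestral, derived) else "transversion"
            )
            spectrum = SPECTRUM_CLASS_OF[(ancestral, derived)]
        ref_pos = int(pos_of_col[col])
        in_ira = bool(
            region_codes is not None and region_codes[ref_pos] == ira_code
        )
        if in_ira and dedupe_ir:
            continue
        sites.append(
            SnpSite(
                column=col,
                ref_position=ref_pos,
                alleles=alleles,
                carriers=carriers,
                site_class=site_class,
                reference_allele=ref_allele,
                ancestral=ancestral,
                derived=derived,
                substitution=substitution,
                spectrum_class=spectrum,
                context=index.context_at(ref_pos) if index is not None else None,
                in_ir_duplicate=in_ira,
            )
        )
    return sites


def substitution_spectrum(
    snps: list[SnpSite], polarize: str = "major-allele"
) -> SpectrumTable:
    """Lump biallelic SNPs into the six non-strand-specific directed classes.

    ``polarize`` chooses the ancestral allele: the major allele (default,
    ties broken by the reference allele) or the reference allele.
    Multiallelic sites are skipped and counted.
    """
    if polarize not in ("major-allele", "reference"):
        raise ValueError(f"unknown polarization {polarize!r}")
    counts = {label: 0 for label in SPECTRUM_CLASSES}
    ts = tv = skipped = 0
    for s in snps:
        if s.in_ir_duplicate:
            continue
        if not s.biallelic:
            skipped += 1
            continue
        anc, der = s.ancestral, s.derived
        if polarize == "reference":
            if s.reference_allele is None:
                skipped += 1
                continue
            anc = s.reference_allele
            der = next(b for b in s.alleles if b != anc)
        counts[SPECTRUM_CLASS_OF[(anc, der)]] += 1
        if _seq.is_transition(anc, der):
            ts += 1
        else:
            tv += 1
    if tv == 0:
        warnings.warn("no transversions: Ts/Tv ratio undefined", stacklevel=2)
        ratio = float("nan")
    else:
        ratio = ts / tv
    return SpectrumTable(counts, ts, tv, ratio, skipped)


def call_indel_events(
    aln: AlignedGenomeSet,
    part: RegionPartition | None = None,
    index: ContextIndex | None = None,
    dedupe_ir: bool = True,
) -> list[IndelEvent]:
    """Call maximal gap-run indel events.

    Consecutive columns sharing an identical accession gap pattern form one
    event; a gap in the reference means an insertion (carried by the
    non-gapped accessions), a gap in non-reference accessions a deletion.
    """
    gaps = aln.matrix == _seq.GAP
    any_gap = gaps.any(axis=0)
    if not any_gap.any():
        return []
    pos_of_col = column_positions(aln)
    region_codes = _position_regions(part) if part is not None else None
    ira_code = REGIONS.index("IRa")
    acc = np.array(aln.accessions)
    ref_i = aln.reference_index

    # boundaries where the gap pattern changes
    change = np.ones(aln.length, dtype=bool)
    change[1:] = (gaps[:, 1:] != gaps[:, :-1]).any(axis=0)
    run_starts = np.flatnonzero(change & any_gap)
    events: list[IndelEvent] = []
    for start in run_starts:
        start = int(start)
        end = start + 1
        while end < aln.length and not change[end]:
            end += 1
        pattern = gaps[:, start]
        if pattern[ref_i]:
            kind = "insertion"
            carriers = tuple(acc[~pattern])
        else:
            kind = "deletion"
            carriers = tuple(acc[pattern])
        ref_pos = int(pos_of_col[start])
        in_ira = bool(region_codes is not None and region_codes[ref_pos] == ira_code)
        if in_ira and dedupe_ir:
            continue
        events.append(
            IndelEvent(
                start_column=start,
                length=end - start,
                kind=kind,
                accessions=carriers,
                ref_position=ref_pos,
                context=index.context_at(ref_pos) if index is not None else None,
                in_ir_duplicate=in_ira,
            )
        )
    return events


def density(count: int, span_bp: int, ndigits: int | None = 2) -> float:
    """Per-kb rate 1000 * count / span_bp, rounded for reporting."""
    if span_bp <= 0:
        raise PlastdivError(f"span_bp must be positive, got {span_bp}")
    if count < 0:
        raise PlastdivError(f"count must be non-negative, got {count}")
    value = 1000.0 * count / span_bp
    return round(value, ndigits) if ndigits is not None else value


def variant_summary(
    snps: list[SnpSite],
    indels: list[IndelEvent],
    aln: AlignedGenomeSet,
    index: ContextIndex,
    effects: dict[int, object] | None = None,
) -> pd.DataFrame:
    """Variant summary table: rows SNPs / Snon / Ssyn / Indels, columns the
    exon/spacer/intron split plus per-region densities per kb.

    Density denominators are aligned region lengths (column counts; the IR
    denominator is the single IRb copy).  ``effects`` maps SNP columns to
    effect calls; when omitted it is computed from the coding SNPs.
    """
    from .context import region_column_counts
    from .effects import classify_snps, NONSYNONYMOUS_EFFECTS

    snps = [s for s in snps if not s.in_ir_duplicate]
    indels = [e for e in indels if not e.in_ir_duplicate]
    if effects is None:
        effects = classify_snps(snps, index, aln)

    lengths = region_column_counts(aln, index)
    span = {
        "LSC": lengths["LSC"],
        "SSC": lengths["SSC"],
        "IR": lengths["IRb"],
        "total": lengths["total"],
    }

    def row(items, region_of, context_of) -> dict:
        by_class = {c: 0 for c in ("exon", "spacer", "intron")}
        by_region = {r: 0 for r in ("LSC", "SSC", "IR")}
        for it in items:
            ctx = context_of(it)
            by_class[ctx.site_class] += 1
            region = region_of(it)
            by_region["IR" if region in ("IRb", "IRa") else region] += 1
        total = len(items)
        out = dict(by_class)
        out["total"] = total
        for r in ("LSC", "SSC", "IR"):
            out[f"{r}_per_kb"] = density(by_region[r], span[r])
        out["total_per_kb"] = density(total, span["total"])
        return out

    ctx_of = lambda it: it.context  # noqa: E731
    reg_of = lambda it: it.context.region  # noqa: E731
    snp_row = row(snps, reg_of, ctx_of)
    indel_row = row(indels, reg_of, ctx_of)

    nonsyn = syn = 0
    for s in snps:
        eff = effects.get(s.column)
        if eff is None:
            continue
        if eff.effect in NONSYNONYMOUS_EFFECTS:
            nonsyn += 1
        elif eff.effect == "synonymous":
            syn += 1
    snon_row = dict.fromkeys(snp_row, None)
    snon_row["exon"] = nonsyn
    ssyn_row = dict.fromkeys(snp_row, None)
    ssyn_row["exon"] = syn

    return pd.DataFrame(
        [snp_row, snon_row, ssyn_row, indel_row],
        index=["SNPs", "Snon", "Ssyn", "Indels"],
    )
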