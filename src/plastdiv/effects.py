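"""Codon-aware synonymous / nonsynonymous classification of coding SNPs.

Codons are assembled from the reference accession's CDS in transcription
order (minus-strand genes reverse-complemented, multi-exon and trans-spliced
CDS concatenated) and translated with the plastid/bacterial genetic code
(NCBI translation table 11).  For each SNP the codon carrying the
alternative allele is compared against the reference codon, one SNP at a
time with all other positions held at the reference state.

Stop-gain (nonsense) and start-codon loss are reported as subtypes but
count as nonsynonymous in all tallies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from . import _seq
from .alignment import AlignedGenomeSet
from .annotation import AnnotationSet, Feature
from .context import ContextIndex
from .errors import NotProteinCodingError
from .variants import SnpSite

NONSYNONYMOUS_EFFECTS = ("nonsynonymous", "nonsense", "start-loss")


def _codon_maps(table: int) -> tuple[dict[str, str], set[str]]:
    t = CodonTable.unambiguous_dna_by_id[table]
    aa = dict(t.forward_table)
    for stop in t.stop_codons:
        aa[stop] = "*"
    return aa, set(t.start_codons)


@dataclass
class EffectCall:
    gene: str
    codon_index: int
    codon_position: int  # 1-based within the codon
    ref_codon: str
    derived_codon: str
    effect: str  # synonymous / nonsynonymous / nonsense / start-loss / unclassifiable


class CdsLocator:
    """Maps reference genomic positions into per-gene CDS coordinates."""

    def __init__(self, ann: AnnotationSet, reference_seq: str, table: int = 11):
        self.ann = ann
        self.ref = reference_seq
        self.aa_of, self.starts = _codon_maps(table)
        self._cache: dict[str, tuple[str, dict[int, int], np.ndarray]] = {}

    def cds_of(self, gene: str) -> tuple[str, dict[int, int], np.ndarray]:
        """(cds string, genomic position -> cds index, cds index -> position)."""
        if gene not in self._cache:
            feat: Feature = self.ann.feature(gene, "CDS")
            chunks: list[str] = []
            pos_list: list[int] = []
            for s, e in feat.transcription_parts():
                part = self.ref[s:e]
                if feat.strand == "-":
                    chunks.append(_seq.revcomp(part))
                    pos_list.extend(range(e - 1, s - 1, -1))
                else:
                    chunks.append(part)
                    pos_list.extend(range(s, e))
            cds = "".join(chunks)
            positions = np.array(pos_list)
            self._cache[gene] = (cds, {p: i for i, p in enumerate(pos_list)}, positions)
        return self._cache[gene]


def classify_coding_snp(
    site: SnpSite,
    ann: AnnotationSet,
    aln: AlignedGenomeSet,
    table: int = 11,
    locator: CdsLocator | None = None,
) -> EffectCall:
    """Classify one coding SNP as synonymous / nonsynonymous (or subtypes).

    The site's context must be the exon of a protein-coding gene; a site in
    a tRNA/rRNA exon raises :class:`NotProteinCodingError`.  A codon
    containing N yields effect ``unclassifiable``.
    """
    if site.context is None or site.context.site_class != "exon":
        raise NotProteinCodingError(
            f"site at column {site.column} is not in an exon context"
        )
    gene = site.context.gene
    if not ann.has_feature(gene, "CDS"):
        raise NotProteinCodingError(f"gene {gene!r} has no CDS (not protein coding)")
    if locator is None:
        locator = CdsLocator(ann, aln.ungapped(aln.reference_id), table)
    cds, pos_to_idx, _ = locator.cds_of(gene)
    feat = ann.feature(gene, "CDS")
    idx = pos_to_idx[site.ref_position]
    ci, cp = divmod(idx, 3)
    ref_codon = cds[3 * ci : 3 * ci + 3]

    # the alternative allele in CDS strand orientation
    ref_allele = site.reference_allele
    alts = [b for b in site.alleles if b != ref_allele]
    alt = alts[0] if len(alts) == 1 else (site.derived if site.derived != ref_allele else site.ancestral)
    if alt is None:
        alt = alts[0]
    alt_cds = _seq.complement(alt) if feat.strand == "-" else alt
    derived_codon = ref_codon[:cp] + alt_cds + ref_codon[cp + 1 :]

    if "N" in ref_codon or "N" in derived_codon:
        effect = "unclassifiable"
    else:
        aa_ref = locator.aa_of[ref_codon]
        aa_alt = locator.aa_of[derived_codon]
        if aa_ref == aa_alt:
            effect = "synonymous"
        elif aa_alt == "*":
            effect = "nonsense"
        elif ci == 0 and ref_codon in locator.starts and derived_codon not in locator.starts:
            effect = "start-loss"
        else:
            effect = "nonsynonymous"
    return EffectCall(gene, ci, cp + 1, ref_codon, derived_codon, effect)


def classify_snps(
    snps: list[SnpSite],
    index: ContextIndex,
    aln: AlignedGenomeSet,
    table: int = 11,
) -> dict[int, EffectCall]:
    """Classify every protein-coding SNP; returns column -> EffectCall.

    SNPs in noncoding exons (tRNA/rRNA) are skipped.  At a multiallelic
    coding site each alternative allele is evaluated against the reference
    codon and the site is represented by a nonsynonymous call if any
    alternative is nonsynonymous.
    """
    ann = index.ann
    locator = CdsLocator(ann, aln.ungapped(aln.reference_id), table)
    out: dict[int, EffectCall] = {}
    for s in snps:
        if s.in_ir_duplicate or s.context is None or s.context.site_class != "exon":
            continue
        if s.context.gene is None or not ann.has_feature(s.context.gene, "CDS"):
            continue
        if s.biallelic:
            out[s.column] = classify_coding_snp(s, ann, aln, table, locator)
            continue
        calls = []
        ref_allele = s.reference_allele
        for alt in [b for b in s.alleles if b != ref_allele]:
            sub = SnpSite(
                column=s.column,
                ref_position=s.ref_position,
                alleles={ref_allele: 1, alt: 1} if ref_allele else {alt: 1},
                carriers={},
                site_class=s.site_class,
                reference_allele=ref_allele,
                ancestral=ref_allele,
                derived=alt,
                context=s.context,
            )
            calls.append(classify_coding_snp(sub, ann, aln, table, locator))
        rep = next(
            (c for c in calls if c.effect in NONSYNONYMOUS_EFFECTS), calls[0]
        )
        out[s.column] = rep
    return out


def gene_snp_table(
    snps: list[SnpSite],
    effects: dict[int, EffectCall],
    ann: AnnotationSet,
) -> pd.DataFrame:
    """Per-gene SNP hotspot table for protein-coding genes with >= 1 SNP.

    Columns: gene, snps, nonsyn, syn, length_bp, snps_per_kb, product;
    sorted by SNP count descending, ties by density descending.
    """
    rows: dict[str, dict] = {}
    for s in snps:
        eff = effects.get(s.column)
        if eff is None:
            continue
        gene = eff.gene
        if gene not in rows:
            feat = ann.feature(gene, "CDS")
            rows[gene] = {
                "gene": gene,
                "snps": 0,
                "nonsyn": 0,
                "syn": 0,
                "length_bp": feat.length,
                "product": feat.product or "",
            }
        rows[gene]["snps"] += 1
        if eff.effect in NONSYNONYMOUS_EFFECTS:
            rows[gene]["nonsyn"] += 1
        elif eff.effect == "synonymous":
            rows[gene]["syn"] += 1
    df = pd.DataFrame(list(rows.values()))
    if df.empty:
        return pd.DataFrame(
            columns=["gene", "snps", "nonsyn", "syn", "length_bp", "snps_per_kb", "product"]
        )
    df["snps_per_kb"] = (1000.0 * df["snps"] / df["length_bp"]).round(2)
    df = df.sort_values(
        ["snps", "snps_per_kb"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)
    return df[["gene", "snps", "nonsyn", "syn", "length_bp", "snps_per_kb", "product"]]
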