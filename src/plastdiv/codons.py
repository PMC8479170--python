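"""Codon counting over concatenated protein-coding genes and RSCU.

RSCU (relative synonymous codon usage) is the observed count of a codon
divided by the mean count over its synonymous family; 1 means no bias.
Stop codons are treated as one three-member family, and each protein-coding
gene is counted once (the gene list, not a genome scan, so IR-duplicated
genes do not count twice).  Codons are reported in the RNA alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Data import CodonTable

from . import _seq
from .alignment import AlignedGenomeSet
from .annotation import AnnotationSet
from .errors import FrameError

_BASES = "UCAG"
ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]


def _families(table: int) -> dict[str, list[str]]:
    """Synonymous families keyed by amino acid ('*' = stop) in RNA codons."""
    t = CodonTable.unambiguous_dna_by_id[table]
    fam: dict[str, list[str]] = {}
    for codon, aa in t.forward_table.items():
        fam.setdefault(aa, []).append(codon.replace("T", "U"))
    fam["*"] = [c.replace("T", "U") for c in t.stop_codons]
    return fam


def extract_cds(
    accession: str, aln: AlignedGenomeSet, ann: AnnotationSet
) -> str:
    """Concatenated coding sequence of one accession.

    Per gene, exons are concatenated in transcription order (minus-strand
    genes reverse-complemented) with alignment gaps removed; genes follow
    annotation order.  Raises :class:`FrameError` (naming the gene) if any
    gene's ungapped CDS length is not divisible by three.
    """
    cmap = aln.coordinate_map(aln.reference_id)
    row = aln.row(accession)
    pieces: list[str] = []
    for feat in ann.cds_features():
        gene_parts: list[str] = []
        for s, e in feat.transcription_parts():
            cols = cmap.columns(s, e)
            sub = row[cols]
            chunk = _seq.to_str(sub[sub != _seq.GAP])
            if feat.strand == "-":
                chunk = _seq.revcomp(chunk)
            gene_parts.append(chunk)
        gene_cds = "".join(gene_parts)
        if len(gene_cds) % 3 != 0:
            raise FrameError(
                f"CDS of {feat.gene} has ungapped length {len(gene_cds)} "
                "in accession "
                f"{accession}, not divisible by 3"
            )
        pieces.append(gene_cds)
    return "".join(pieces)


@dataclass
class CodonCounts:
    counts: dict[str, int]  # RNA codons, all 64 keys present
    total: int
    skipped_n: int = 0

    def amino_acid_totals(self, table: int = 11) -> dict[str, int]:
        return {
            aa: sum(self.counts[c] for c in codons)
            for aa, codons in _families(table).items()
        }


def codon_counts(cds: str) -> CodonCounts:
    """Count non-overlapping codons of an in-frame coding sequence.

    T is transliterated to U for reporting; codons containing N are skipped
    and counted separately.  Raises :class:`FrameError` when the length is
    not divisible by three.
    """
    if len(cds) % 3 != 0:
        raise FrameError(f"sequence length {len(cds)} not divisible by 3")
    counts = dict.fromkeys(ALL_CODONS, 0)
    skipped = 0
    rna = cds.upper().replace("T", "U")
    for i in range(0, len(rna), 3):
        codon = rna[i : i + 3]
        if codon in counts:
            counts[codon] += 1
        else:
            skipped += 1
    return CodonCounts(counts, sum(counts.values()), skipped)


def rscu(tab: CodonCounts, table: int = 11) -> pd.DataFrame:
    """RSCU per codon: count / mean count over its synonymous family.

    Families with zero total get empty (NaN) RSCU.  Single-member families
    (AUG, UGG in table 11) have RSCU 1 whenever present.
    """
    rows = []
    for aa, codons in sorted(_families(table).items()):
        k = len(codons)
        fam_total = sum(tab.counts[c] for c in codons)
        for c in sorted(codons):
            if fam_total == 0:
                value = float("nan")
            else:
                value = tab.counts[c] / (fam_total / k)
            rows.append(
                {
                    "codon": c,
                    "amino_acid": aa,
                    "count": tab.counts[c],
                    "family_size": k,
                    "rscu": value,
                }
            )
    return pd.DataFrame(rows)


def rscu_matrix(
    aln: AlignedGenomeSet,
    ann: AnnotationSet,
    representatives: dict[str, str],
    table: int = 11,
) -> pd.DataFrame:
    """Codon x haplotype RSCU matrix (rows = 64 codons).

    ``representatives`` maps haplotype label -> accession id.
    """
    out = {}
    for label, acc in representatives.items():
        cds = extract_cds(acc, aln, ann)
        out[label] = rscu(codon_counts(cds), table).set_index("codon")["rscu"]
    return pd.DataFrame(out)
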