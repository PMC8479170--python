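"""Synthetic plastome generator with a machine-readable truth catalog.

The generator builds a quadripartite ancestor genome (LSC | IRb | SSC | IRa,
with IRa the exact reverse complement of IRb), annotates it with a
plastid-style gene complement (junction-spanning genes included, a
*matK*-like CDS nested inside a *trnK*-like intron, two-exon CDS genes with
introns, seeded SSR runs, planted dispersed/tandem repeats), then evolves a
set of accessions along a star genealogy by planting SNPs, indels and SSR
slippage events with fixed per-region, per-context, per-branch and
Ts/Tv / synonymous-nonsynonymous budgets.

Because every mutation is planted, the emitted alignment is the *true*
alignment (gap columns are constructed, not inferred) and the
:class:`TruthCatalog` is exact: downstream callers can verify full-pipeline
parameter recovery without any aligner in the loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from . import _seq
from .alignment import AlignedGenomeSet
from .annotation import AnnotationSet, Feature
from .context import ContextIndex
from .errors import SimulationError
from .repeats import find_ssrs
from .structure import RegionPartition

_STOPS = ("TAA", "TAG", "TGA")
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_AA_OF = dict(_TABLE11.forward_table)
for _s in _STOPS:
    _AA_OF[_s] = "*"
_NONSTOP_CODONS = [c for c in _AA_OF if _AA_OF[c] != "*"]
_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


# -- configuration ----------------------------------------------------------

# per-gene coding SNP budgets (nonsynonymous, synonymous); the hotspot genes
# of the analysis this simulator emulates, lengths in bp (CDS, incl. stop)
DEFAULT_GENE_SNPS = {
    "ycf1": (17, 4),
    "rpoC2": (5, 4),
    "ndhF": (2, 6),
    "ndhH": (3, 3),
    "matK": (4, 1),
    "ndhD": (1, 3),
    "psaA": (0, 4),
    "ndhA": (2, 1),
    "psaB": (0, 3),
    "ycf2": (3, 0),
}

DEFAULT_GENE_LENGTHS = {
    "ycf1": 5571,  # spans JSA by 1,084 bp
    "rpoC2": 4191,
    "ndhF": 2223,  # spans JSB by 20 bp
    "ndhH": 1182,
    "matK": 1536,  # nested in the trnK intron
    "ndhD": 1410,
    "ndhA": 1095,  # two-exon
    "psaA": 2253,
    "psaB": 2205,
    "ycf2": 6867,
    "rps19": 279,  # spans JLB by 34 bp
}

DEFAULT_PRODUCTS = {
    "ycf1": "ATP-binding cassette glutathione S-conjugate transporter",
    "rpoC2": "DNA-directed RNA polymerase subunit beta''",
    "ndhF": "NAD(P)H-quinone oxidoreductase subunit 5",
    "ndhH": "NAD(P)H-quinone oxidoreductase subunit 7",
    "matK": "maturase K",
    "ndhD": "NAD(P)H-quinone oxidoreductase subunit 4",
    "psaA": "photosystem I P700 apoprotein A1",
    "ndhA": "NAD(P)H-quinone oxidoreductase subunit 1",
    "psaB": "photosystem I P700 apoprotein A2",
    "ycf2": "hypothetical chloroplast reading frame",
}

_LSC_CDS_NAMES = [
    "psbA", "psbB", "psbC", "psbD", "rbcL", "atpA", "atpB", "atpE",
    "atpH", "atpI", "rpoA", "rpoB", "petA", "psaI", "psaJ", "petG",
    "petL", "petN", "psbE", "psbF", "psbH", "psbI", "psbJ", "psbK",
    "psbL", "psbM", "psbN", "psbT", "psbZ", "rps2",
]
_LSC_INTRON_CDS = ["atpF", "rpoC1", "clpP", "ycf3", "rps16", "petB", "petD", "rpl16"]
_LSC_TRNAS = [
    "trnQ-UUG", "trnS-GCU", "trnG-UCC", "trnC-GCA", "trnD-GUC", "trnY-GUA",
    "trnE-UUC", "trnT-GGU", "trnS-UGA", "trnfM-CAU", "trnG-GCC", "trnT-UGU",
    "trnL-UAA", "trnF-GAA", "trnV-UAC", "trnM-CAU", "trnW-CCA",
]
_SSC_EXTRA_CDS = ["rpl32", "ccsA"]


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic plastome set.

    The defaults mirror the comparative design this package emulates:
    22 accessions collapsing to 8 haplotypes with a skewed frequency
    spectrum, 225 deduplicated SNPs split 151/10/64 over LSC/IR/SSC and
    99/114/12 over exon/spacer/intron, Ts:Tv 93:132, 55 nonsynonymous vs 44
    synonymous coding changes, 49 indels (1 bp mode, 546 bp maximum, one
    52 bp insertion), and 22 polymorphic SSR loci (14 spacer / 7 intron /
    1 exon).
    """

    lsc_len: int = 82_600
    ir_len: int = 25_650
    ssc_len: int = 17_650
    n_accessions: int = 22
    haplotype_spectrum: tuple[int, ...] = (11, 4, 2, 1, 1, 1, 1, 1)
    # SNP branch budgets per haplotype (reference haplotype first); chosen
    # so that 83 sites are singletons, 142 parsimony-informative, and the
    # expected whole-alignment pi (IR mirrors included) is ~0.00042
    snp_branch_budgets: tuple[int, ...] = (60, 50, 32, 17, 17, 17, 16, 16)
    # joint (region, site class) SNP quotas
    snp_quotas: dict = field(
        default_factory=lambda: {
            ("LSC", "exon"): 57,
            ("LSC", "intron"): 9,
            ("LSC", "spacer"): 85,
            ("SSC", "exon"): 42,
            ("SSC", "intron"): 3,
            ("SSC", "spacer"): 19,
            ("IR", "spacer"): 10,
        }
    )
    gene_snps: dict = field(default_factory=lambda: dict(DEFAULT_GENE_SNPS))
    nonsyn_count: int = 55
    syn_count: int = 44
    ts_count: int = 93
    tv_count: int = 132
    hotspot_snps: int = 12  # of the LSC spacer quota, packed into one window
    hotspot_window: int = 600
    # indels: (region, class, n_slippage, n_other)
    indel_plan: dict = field(
        default_factory=lambda: {
            ("LSC", "spacer"): (11, 20),  # incl. the 546 bp del + 52 bp ins
            ("LSC", "intron"): (6, 0),
            ("LSC", "exon"): (1, 2),  # noncoding (tRNA) exons only
            ("IR", "spacer"): (0, 4),
            ("SSC", "spacer"): (3, 1),
            ("SSC", "intron"): (1, 0),
        }
    )
    large_deletion: int = 546
    large_insertion: int = 52
    gc: float = 0.38
    reference_id: str = "LC01"

    @property
    def genome_length(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len

    @property
    def snp_total(self) -> int:
        return sum(self.snp_quotas.values())

    @property
    def indel_total(self) -> int:
        return sum(a + b for a, b in self.indel_plan.values())

    def validate(self) -> None:
        if sum(self.haplotype_spectrum) != self.n_accessions:
            raise SimulationError("haplotype spectrum must sum to n_accessions")
        if len(self.snp_branch_budgets) != len(self.haplotype_spectrum):
            raise SimulationError("one SNP budget per haplotype required")
        if sum(self.snp_branch_budgets) != self.snp_total:
            raise SimulationError("branch budgets must sum to the SNP total")
        if self.ts_count + self.tv_count != self.snp_total:
            raise SimulationError("Ts + Tv must equal the SNP total")
        exon_total = sum(
            v for (_, cls), v in self.snp_quotas.items() if cls == "exon"
        )
        if self.nonsyn_count + self.syn_count != exon_total:
            raise SimulationError(
                "nonsyn + syn budgets must equal the exon SNP quota"
            )
        named = sum(a + b for a, b in self.gene_snps.values())
        if named > exon_total:
            raise SimulationError("per-gene SNP budgets exceed the exon quota")


# -- truth catalog ----------------------------------------------------------


@dataclass
class PlantedSnp:
    position: int  # ancestor/reference coordinate
    column: int  # alignment column
    region: str
    site_class: str
    gene: str | None
    ancestral: str
    derived: str
    haplotype: str
    transition: bool
    effect: str | None = None  # synonymous / nonsynonymous for coding SNPs
    mirrored_position: int | None = None  # IRa copy for IR SNPs


@dataclass
class PlantedIndel:
    position: int
    column: int
    length: int
    kind: str  # insertion / deletion
    region: str
    site_class: str
    gene: str | None
    haplotype: str
    slippage: bool = False
    motif: str | None = None
    mirrored_position: int | None = None


@dataclass
class TruthCatalog:
    snps: list[PlantedSnp]
    indels: list[PlantedIndel]
    haplotypes: dict[str, tuple[str, ...]]
    partition: RegionPartition

    @property
    def spectrum(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.haplotypes.values())

    def snp_count(self) -> int:
        return len(self.snps)

    def indel_count(self) -> int:
        return len(self.indels)

    def region_snp_counts(self) -> dict[str, int]:
        out = {"LSC": 0, "IR": 0, "SSC": 0}
        for s in self.snps:
            out[s.region] += 1
        return out

    def class_snp_counts(self) -> dict[str, int]:
        out = {"exon": 0, "intron": 0, "spacer": 0}
        for s in self.snps:
            out[s.site_class] += 1
        return out

    def effect_counts(self) -> dict[str, int]:
        out = {"nonsynonymous": 0, "synonymous": 0}
        for s in self.snps:
            if s.effect:
                out[s.effect] += 1
        return out

    def slippage_loci(self) -> list[PlantedIndel]:
        return [e for e in self.indels if e.slippage]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "snps": [vars(s) for s in self.snps],
            "indels": [vars(e) for e in self.indels],
            "haplotypes": {k: list(v) for k, v in self.haplotypes.items()},
            "partition": json.loads(self.partition.to_json()),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


# -- ancestor generation ----------------------------------------------------


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """Random in-frame CDS: start codon, non-stop body, one stop."""
    ncod = length // 3
    body = rng.choice(_NONSTOP_CODONS, size=ncod - 2)
    return "ATG" + "".join(body) + str(rng.choice(_STOPS))


def _write(master: np.ndarray, start: int, content: str) -> None:
    end = min(start + len(content), len(master))
    if end > start:
        master[start:end] = _seq.to_array(content[: end - start])


@dataclass
class _GeneDraft:
    name: str
    kind: str  # CDS / tRNA
    strand: str
    parts: list[tuple[int, int]]  # genomic order
    span: tuple[int, int]
    product: str | None = None


def _pack_genes(
    rng: np.random.Generator,
    interval: tuple[int, int],
    spans: list[int],
    min_gap: int = 60,
    boosts: dict[int, int] | None = None,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Place gene spans left-to-right inside ``interval`` with random gaps.

    ``boosts`` maps gap index -> extra width for designated wide gaps
    (mutation hotspot, large-deletion site).  Returns (placements, gaps).
    """
    lo, hi = interval
    total = sum(spans)
    boosts = boosts or {}
    n_gaps = len(spans) + 1
    leftover = (hi - lo) - total - min_gap * n_gaps - sum(boosts.values())
    if leftover < 0:
        raise SimulationError(
            f"gene packing infeasible: need {total + min_gap * n_gaps} "
            f"in {hi - lo}"
        )
    extra = rng.multinomial(leftover, np.full(n_gaps, 1.0 / n_gaps))
    gaps = [min_gap + int(e) + boosts.get(i, 0) for i, e in enumerate(extra)]
    placements = []
    gap_intervals = []
    cursor = lo
    for i, span in enumerate(spans):
        gap_intervals.append((cursor, cursor + gaps[i]))
        cursor += gaps[i]
        placements.append((cursor, cursor + span))
        cursor += span
    gap_intervals.append((cursor, cursor + gaps[-1]))
    return placements, gap_intervals


def generate_ancestor(
    cfg: SimConfig, seed: int
) -> tuple[str, AnnotationSet, RegionPartition]:
    """Build the ancestor genome, its annotation and its region partition.

    IRa is the exact reverse complement of IRb; one gene spans each of the
    four junctions; SSR runs are seeded above threshold in spacers, introns
    and exons; a handful of dispersed and tandem repeats are planted in
    spacers.  Gene content scales with the configured region lengths, so
    small test genomes carry proportionally fewer and shorter genes (genes
    with coding-SNP budgets and the junction genes are always kept).
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    G = cfg.genome_length
    jlb = cfg.lsc_len
    jsb = cfg.lsc_len + cfg.ir_len
    jsa = jsb + cfg.ssc_len
    master = _seq.random_dna(rng, jsa, cfg.gc)  # LSC + IRb + SSC
    f = min(1.0, cfg.lsc_len / 82_600)

    def fit3(x: int, lo: int = 300) -> int:
        return x if f == 1.0 else max(lo, 3 * int(x * f / 3))

    genes: list[_GeneDraft] = []
    glen = DEFAULT_GENE_LENGTHS

    # --- fixed junction genes -----------------------------------------
    genes.append(
        _GeneDraft("trnH-GUG", "tRNA", "+", [(G - 1, G), (0, 74)], (G - 1, 74))
    )
    rps19_iv = (jlb - (glen["rps19"] - 34), jlb + 34)
    genes.append(_GeneDraft("rps19", "CDS", "+", [rps19_iv], rps19_iv,
                            product="ribosomal protein S19"))
    ndhf_len = fit3(glen["ndhF"])
    ndhf_iv = (jsb - 20, jsb - 20 + ndhf_len)
    genes.append(_GeneDraft("ndhF", "CDS", "-", [ndhf_iv], ndhf_iv,
                            product=DEFAULT_PRODUCTS["ndhF"]))
    jsa_over = 1084 if f == 1.0 else max(33, int(1084 * f))
    ycf1_ssc = fit3(4487)
    ycf1_ssc += (3 - (ycf1_ssc + jsa_over) % 3) % 3
    ycf1_iv = (jsa - ycf1_ssc, jsa + jsa_over)
    genes.append(_GeneDraft("ycf1", "CDS", "+", [ycf1_iv], ycf1_iv,
                            product=DEFAULT_PRODUCTS["ycf1"]))

    # --- LSC interior -------------------------------------------------
    n_other = 30 if f == 1.0 else max(2, int(30 * f))
    n_intron = 8 if f == 1.0 else max(1, int(8 * f))
    n_trna = 17 if f == 1.0 else max(1, int(17 * f))
    other_names = _LSC_CDS_NAMES[:n_other]
    intron_names = _LSC_INTRON_CDS[:n_intron]
    trna_names = _LSC_TRNAS[:n_trna]
    other_lens = {n: int(rng.integers(100, 500)) * 3 for n in other_names}
    intron_exons = {
        n: (int(rng.integers(80, 200)) * 3, int(rng.integers(80, 200)) * 3)
        for n in intron_names
    }
    intron_lens = {n: int(rng.integers(420, 700)) for n in intron_names}
    trna_lens = {n: int(rng.integers(72, 90)) for n in trna_names}
    matk_len = fit3(glen["matK"])
    trnk_block = max(matk_len + 220, 2135 if f == 1.0 else 0)

    order: list[tuple[str, int]] = [("trnK-UUU", trnk_block)]
    order += [(n, fit3(glen[n])) for n in ("rpoC2", "psaA", "psaB", "ycf2")]
    order += [(n, other_lens[n]) for n in other_names]
    order += [
        (n, intron_exons[n][0] + intron_lens[n] + intron_exons[n][1])
        for n in intron_names
    ]
    order += [(n, trna_lens[n]) for n in trna_names]
    perm = rng.permutation(len(order))
    order = [order[i] for i in perm]

    # designated wide gaps: mutation hotspot and the large-deletion site
    hot_boost = cfg.hotspot_window + 240
    del_boost = cfg.large_deletion + 60
    keep = {"trnK-UUU", trna_names[0], *cfg.gene_snps}
    interior = rps19_iv[0] - 74

    def feasible(o):
        return (
            sum(s for _, s in o) + 60 * (len(o) + 1) + hot_boost + del_boost
            <= interior
        )

    while not feasible(order):
        droppable = [i for i, (n, _) in enumerate(order) if n not in keep]
        if not droppable:
            raise SimulationError("LSC too short for the configured genes")
        order.pop(droppable[-1])
    boosts = {len(order) // 3: hot_boost, (2 * len(order)) // 3: del_boost}
    spans = [s for _, s in order]
    placements, lsc_gaps = _pack_genes(rng, (74, rps19_iv[0]), spans, boosts=boosts)

    ssr_hosts_cds: list[str] = []
    for (name, _), (s, e) in zip(order, placements):
        if name == "trnK-UUU":
            parts = [(s, s + 37), (e - 37, e)]
            genes.append(_GeneDraft(name, "tRNA", "+", parts, (s, e)))
            off = (e - s - matk_len) // 2
            matk_iv = (s + off, s + off + matk_len)
            genes.append(_GeneDraft("matK", "CDS", "+", [matk_iv], matk_iv,
                                    product=DEFAULT_PRODUCTS["matK"]))
        elif name in intron_names:
            ex1, ex2 = intron_exons[name]
            parts = [(s, s + ex1), (e - ex2, e)]
            strand = str(rng.choice(["+", "-"]))
            genes.append(_GeneDraft(name, "CDS", strand, parts, (s, e)))
        elif name in trna_lens:
            genes.append(_GeneDraft(name, "tRNA", str(rng.choice(["+", "-"])),
                                    [(s, e)], (s, e)))
        else:
            named = name in DEFAULT_PRODUCTS
            if len(ssr_hosts_cds) < 5 and not named and (e - s) >= 600:
                strand = "+"  # exon SSR hosts kept on + for codon-aligned runs
                ssr_hosts_cds.append(name)
            else:
                strand = str(rng.choice(["+", "-"]))
            genes.append(_GeneDraft(name, "CDS", strand, [(s, e)], (s, e),
                                    product=DEFAULT_PRODUCTS.get(name)))

    # --- SSC interior -------------------------------------------------
    ndha_exons = (fit3(540, 150), fit3(555, 150))
    ndha_intron = max(200, int(540 * f))
    ssc_lens = {
        "ndhH": fit3(glen["ndhH"]),
        "ndhD": fit3(glen["ndhD"]),
        "ndhA": ndha_exons[0] + ndha_intron + ndha_exons[1],
        "rpl32": 171,
        "ccsA": fit3(963),
        "trnL-UAG": 80,
    }
    ssc_names = ["ndhH", "ndhD", "ndhA"] + _SSC_EXTRA_CDS + ["trnL-UAG"]
    perm = rng.permutation(len(ssc_names))
    ssc_names = [ssc_names[i] for i in perm]
    ssc_iv = (ndhf_iv[1] + 10, ycf1_iv[0] - 10)
    ssc_keep = set(cfg.gene_snps)
    while ssc_names and (
        sum(ssc_lens[n] for n in ssc_names) + 60 * (len(ssc_names) + 1)
        > ssc_iv[1] - ssc_iv[0]
    ):
        droppable = [n for n in ssc_names if n not in ssc_keep]
        if not droppable:
            raise SimulationError("SSC too short for the configured genes")
        ssc_names.remove(droppable[-1])
    ssc_place, ssc_gaps = _pack_genes(
        rng, ssc_iv, [ssc_lens[n] for n in ssc_names]
    )
    for name, (s, e) in zip(ssc_names, ssc_place):
        if name == "ndhA":
            parts = [(s, s + ndha_exons[0]), (e - ndha_exons[1], e)]
            genes.append(_GeneDraft(name, "CDS", str(rng.choice(["+", "-"])),
                                    parts, (s, e), product=DEFAULT_PRODUCTS[name]))
        elif name == "trnL-UAG":
            genes.append(_GeneDraft(name, "tRNA", "+", [(s, e)], (s, e)))
        else:
            genes.append(_GeneDraft(name, "CDS", str(rng.choice(["+", "-"])),
                                    [(s, e)], (s, e),
                                    product=DEFAULT_PRODUCTS.get(name)))

    # --- write CDS/tRNA content into the master sequence --------------
    for g in genes:
        if g.kind != "CDS":
            continue
        cds_len = sum(e - s for s, e in g.parts)
        cds = _random_cds(rng, cds_len)
        chunks: list[tuple[int, str]] = []
        offset = 0
        tparts = list(reversed(g.parts)) if g.strand == "-" else list(g.parts)
        for s, e in tparts:
            chunk = cds[offset : offset + (e - s)]
            offset += e - s
            chunks.append((s, _seq.revcomp(chunk) if g.strand == "-" else chunk))
        for s, chunk in chunks:
            _write(master, s, chunk)

    # --- SSR seeds -----------------------------------------------------
    # (region, context) -> list of (unit motif, repeat count)
    seed_plan = {
        ("LSC", "spacer"): [("A", 12)] * 6 + [("T", 12)] * 5
        + [("AT", 6), ("AAT", 5), ("AATC", 4), ("TTGTA", 3)],
        ("SSC", "spacer"): [("A", 12), ("T", 13), ("A", 12), ("AT", 6),
                            ("AAG", 5), ("AATG", 4)],
        ("LSC", "intron"): [("A", 12), ("T", 12), ("A", 13), ("T", 12),
                            ("A", 12), ("T", 14)],
        ("SSC", "intron"): [("A", 12)],
    }
    if f < 1.0:
        seed_plan = {
            k: v[: max(1, int(len(v) * f) + 1)] for k, v in seed_plan.items()
        }
    used_lsc: set[int] = set()
    used_ssc: set[int] = set()

    def _free_gap(gap_list, width, used: set):
        for gi, (gs, ge) in enumerate(gap_list):
            if gi in used:
                continue
            if ge - gs >= width + 8:
                used.add(gi)
                return gs, ge
        raise SimulationError("no free spacer gap wide enough")

    hotspot_gi = int(np.argmax([e - s for s, e in lsc_gaps]))
    bigdel_gi = int(np.argsort([e - s for s, e in lsc_gaps])[-2])

    def _seed_run(start: int, motif: str, count: int) -> None:
        run = motif * count
        # hard flanks so the run cannot extend
        flank = "C" if motif[0] != "C" else "G"
        _write(master, start - 1, flank)
        _write(master, start, run)
        end_flank = "C" if motif[(len(run) - 1) % len(motif)] != "C" else "G"
        _write(master, start + len(run), end_flank)

    used_lsc.update({hotspot_gi, bigdel_gi})
    for (region, ctx), seeds in seed_plan.items():
        if ctx == "spacer":
            gap_list = lsc_gaps if region == "LSC" else ssc_gaps
            used = used_lsc if region == "LSC" else used_ssc
            for motif, count in seeds:
                try:
                    gs, _ = _free_gap(gap_list, len(motif) * count, used)
                except SimulationError:
                    break
                _seed_run(gs + 4, motif, count)
        else:  # introns of two-exon genes
            hosts = [
                g for g in genes
                if g.kind == "CDS" and len(g.parts) == 2
                and (g.span[0] < jlb) == (region == "LSC")
            ]
            for (motif, count), host in zip(seeds, hosts):
                intron_start = host.parts[0][1]
                _seed_run(intron_start + 25, motif, count)

    # codon-aligned exon SSR runs: CDS hosts + 1 tRNA host
    for gi, name in enumerate(ssr_hosts_cds):
        g = next(x for x in genes if x.name == name)
        s, e = g.parts[0]
        ci = (e - s) // 6 // 3 * 3  # a codon boundary ~1/6 into the gene
        start = s + 30 + ci
        start -= (start - s) % 3
        base = "A" if gi % 2 == 0 else "T"
        _write(master, start - 3, "GGC")
        _write(master, start, base * 12)
        _write(master, start + 12, "GGC")
    trna_host = next(g for g in genes if g.name == trna_names[0])
    _seed_run(trna_host.parts[0][0] + 30, "A", 12)

    # --- dispersed + tandem repeat plants ------------------------------
    plants = [("forward", 35), ("forward", 40), ("palindromic", 32), ("reverse", 31)]
    for kind, ln in plants:
        try:
            src_s, _ = _free_gap(lsc_gaps, ln, used_lsc)
            dst_s, _ = _free_gap(lsc_gaps, ln, used_lsc)
        except SimulationError:
            break
        seg = _seq.to_str(master[src_s + 4 : src_s + 4 + ln])
        if kind == "palindromic":
            seg = _seq.revcomp(seg)
        elif kind == "reverse":
            seg = seg[::-1]
        _write(master, dst_s + 4, seg)
    for unit_len, copies in ((12, 3), (20, 2)):
        try:
            gs, _ = _free_gap(lsc_gaps, unit_len * copies, used_lsc)
        except SimulationError:
            break
        unit = _seq.to_str(master[gs + 4 : gs + 4 + unit_len])
        _write(master, gs + 4, unit * copies)

    # forbid chance maximal extension of the IR pair across the SSC
    # boundaries: the base after JSB must not complement the base before JSA
    master[jsa - 1] = master[jsb]

    # --- assemble genome ------------------------------------------------
    irb = master[jlb:jsb]
    genome_arr = np.concatenate([master, _seq.comp_array(irb)[::-1]])
    genome = _seq.to_str(genome_arr)

    part = RegionPartition(
        (0, jlb), (jlb, jsb), (jsb, jsa), (jsa, G), G
    )
    features: list[Feature] = []
    for g in genes:
        if g.kind == "CDS":
            span_parts = [(g.span[0], g.span[1])]
            features.append(Feature(g.name, "gene", g.strand, span_parts,
                                    product=g.product))
            acc = 0
            tparts = list(reversed(g.parts)) if g.strand == "-" else list(g.parts)
            ph = {}
            for s, e in tparts:
                ph[(s, e)] = (3 - acc % 3) % 3
                acc += e - s
            features.append(
                Feature(g.name, "CDS", g.strand, list(g.parts),
                        phases=[ph[p] for p in g.parts], product=g.product)
            )
        else:
            # tRNA span feature: single full-span part so the intron of a
            # two-exon tRNA (trnK) classifies as intron -- except trnH,
            # whose two parts straddle the origin (no intron between them)
            if g.name == "trnH-GUG" or len(g.parts) == 1:
                span_parts = list(g.parts)
            else:
                span_parts = [(g.span[0], g.span[1])]
            features.append(Feature(g.name, g.kind, g.strand, span_parts))
            features.append(Feature(g.name, "exon", g.strand, list(g.parts)))
    ann = AnnotationSet(features, G)
    return genome, ann, part


# -- haplotype evolution ----------------------------------------------------


def _transition_of(base: str) -> str:
    return _TS_PARTNER[base]


class _Painter:
    """Tracks positions consumed by planted mutations (with a 1-bp halo).

    Two levels of blocking: ``soft`` additionally avoids near-threshold SSR
    runs (so substitutions can never push a run over an SSR threshold);
    ``hard`` only avoids actual SSR loci and already-planted mutations
    (enough for large deletions, which get an explicit junction check).
    """

    def __init__(self, soft_reserved: np.ndarray, hard_reserved: np.ndarray):
        self.blocked = soft_reserved | hard_reserved
        self.hard = hard_reserved.copy()

    def free(self, pos: int, length: int = 1, soft: bool = True) -> bool:
        lo = max(0, pos - 1)
        mask = self.blocked if soft else self.hard
        return not mask[lo : pos + length + 1].any()

    def take(self, pos: int, length: int = 1) -> None:
        lo = max(0, pos - 1)
        self.blocked[lo : pos + length + 1] = True
        self.hard[lo : pos + length + 1] = True


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    return list(zip(np.flatnonzero(diff == 1).tolist(),
                    np.flatnonzero(diff == -1).tolist()))


def evolve_haplotypes(
    genome: str,
    ann: AnnotationSet,
    part: RegionPartition,
    cfg: SimConfig,
    seed: int,
) -> tuple[AlignedGenomeSet, TruthCatalog]:
    """Plant SNP/indel/slippage mutations on a star genealogy and emit the
    true alignment plus the truth catalog.

    All per-region, per-context, per-branch, Ts/Tv and effect budgets of the
    configuration are met exactly; mutation positions avoid SSR loci (and
    near-threshold runs) except for the deliberate slippage events, so the
    planted polymorphic-SSR set is exactly the slippage set.
    """
    from .effects import CdsLocator

    cfg.validate()
    rng = np.random.default_rng((seed * 2 + 1) % (2**31))
    G = len(genome)
    arr = _seq.to_array(genome)
    index = ContextIndex(ann, part)
    rcode, ccode = index.region_code, index.class_code
    region_name = {0: "LSC", 1: "IR", 2: "SSC", 3: "IRa"}

    # reserve every SSR locus (hard) and near-threshold run (soft, + halo)
    relaxed = {k: max(2, v - 1) for k, v in
               {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}.items()}
    soft = np.zeros(G, dtype=bool)
    for loc in find_ssrs(genome, relaxed):
        pad = loc.unit + 1
        soft[max(0, loc.start - pad) : loc.end + pad] = True
    loci = find_ssrs(genome)
    hard = np.zeros(G, dtype=bool)
    for loc in loci:
        pad = loc.unit + 1
        hard[max(0, loc.start - pad) : loc.end + pad] = True
    painter = _Painter(soft, hard)

    def ssr_inert(pos: int) -> bool:
        """A substitution here can never create or destroy an SSR locus,
        whatever the derived base (guards against run *joining*, which the
        near-threshold reservation alone does not catch)."""
        lo = max(0, pos - 30)
        w = genome[lo : pos + 31]
        base = find_ssrs(w)
        key = [(x.start, x.unit, x.count) for x in base]
        i = pos - lo
        for alt in "ACGT":
            if alt == w[i]:
                continue
            mut = w[:i] + alt + w[i + 1 :]
            if [(x.start, x.unit, x.count) for x in find_ssrs(mut)] != key:
                return False
        return True

    def junction_safe(p: int, length: int, kind: str, content: str = "") -> bool:
        """No SSR locus may newly arise across an indel junction in a
        carrier sequence."""
        left = genome[max(0, p - 30) : p]
        if kind == "deletion":
            s = left + genome[p + length : p + length + 30]
            cuts = [len(left)]
        else:
            s = left + content + genome[p : p + 30]
            cuts = [len(left), len(left) + len(content)]
        for loc in find_ssrs(s):
            if any(loc.start < c < loc.end for c in cuts):
                return False
        return True

    hap_names = [f"Hap{i + 1}" for i in range(len(cfg.haplotype_spectrum))]
    ids = [f"LC{i + 1:02d}" for i in range(cfg.n_accessions)]
    members: dict[str, tuple[str, ...]] = {}
    cursor = 0
    for name, freq in zip(hap_names, cfg.haplotype_spectrum):
        members[name] = tuple(ids[cursor : cursor + freq])
        cursor += freq
    row_of = {a: i for i, a in enumerate(ids)}
    rows_of_hap = {h: [row_of[a] for a in m] for h, m in members.items()}

    # ---------------- coding SNPs --------------------------------------
    locator = CdsLocator(ann, genome)
    snps: list[PlantedSnp] = []

    def gene_region(gene: str) -> int:
        _, _, positions = locator.cds_of(gene)
        vals, counts = np.unique(rcode[positions], return_counts=True)
        return int(vals[np.argmax(counts)])

    def plant_coding(gene: str, n_non: int, n_syn: int) -> None:
        cds, _, positions = locator.cds_of(gene)
        strand = ann.feature(gene, "CDS").strand
        req_region = gene_region(gene)
        ncod = len(cds) // 3
        wanted = ["nonsynonymous"] * n_non + ["synonymous"] * n_syn
        for effect in wanted:
            for _attempt in range(2000):
                ci = int(rng.integers(1, ncod - 1))
                codon = cds[3 * ci : 3 * ci + 3]
                gpos = positions[3 * ci : 3 * ci + 3]
                if (rcode[gpos] != req_region).any():
                    continue
                if not all(painter.free(int(p)) for p in gpos):
                    continue
                if not all(ssr_inert(int(p)) for p in gpos):
                    continue
                if effect == "synonymous":
                    cp = 2
                    alt = _transition_of(codon[2])
                    newc = codon[:2] + alt
                    if _AA_OF[newc] != _AA_OF[codon]:
                        continue
                else:
                    choices = [(cp, a) for cp in (0, 1, 2)
                               for a in _TV_PARTNERS[codon[cp]]]
                    rng.shuffle(choices)
                    ok = None
                    for cp, a in choices:
                        newc = codon[:cp] + a + codon[cp + 1 :]
                        if _AA_OF[newc] not in ("*", _AA_OF[codon]):
                            ok = (cp, a, newc)
                            break
                    if ok is None:
                        continue
                    cp, alt, newc = ok
                pos = int(gpos[cp])
                derived = _seq.complement(alt) if strand == "-" else alt
                for p in gpos:
                    painter.take(int(p))
                snps.append(
                    PlantedSnp(
                        position=pos,
                        column=-1,
                        region=region_name[int(rcode[pos])],
                        site_class="exon",
                        gene=gene,
                        ancestral=genome[pos],
                        derived=derived,
                        haplotype="",
                        transition=_seq.is_transition(codon[cp], alt),
                        effect=effect,
                    )
                )
                break
            else:
                raise SimulationError(
                    f"could not plant a {effect} SNP in {gene}"
                )

    for gene, (n_non, n_syn) in cfg.gene_snps.items():
        plant_coding(gene, n_non, n_syn)

    # spread the remaining exon quota over unnamed CDS genes (<= 2 each)
    planted_exon = {"LSC": 0, "SSC": 0}
    for s in snps:
        planted_exon[s.region] += 1
    eff_remaining = {
        "nonsynonymous": cfg.nonsyn_count,
        "synonymous": cfg.syn_count,
    }
    for s in snps:
        eff_remaining[s.effect] -= 1
    for reg in ("LSC", "SSC"):
        need = cfg.snp_quotas.get((reg, "exon"), 0) - planted_exon[reg]
        if need <= 0:
            continue
        hosts = [
            f.gene for f in ann.cds_features()
            if f.gene not in cfg.gene_snps and f.gene != "rps19"
            and region_name[gene_region(f.gene)] == reg
            and f.length >= 300
        ]
        rng.shuffle(hosts)
        per_gene = {}
        hi = 0
        for _ in range(need):
            g = hosts[hi % len(hosts)]
            while per_gene.get(g, 0) >= 2:
                hi += 1
                g = hosts[hi % len(hosts)]
            per_gene[g] = per_gene.get(g, 0) + 1
        labels = (["nonsynonymous"] * eff_remaining["nonsynonymous"]
                  + ["synonymous"] * eff_remaining["synonymous"])
        rng.shuffle(labels)
        li = 0
        for g, k in per_gene.items():
            n_non = sum(1 for x in labels[li : li + k] if x == "nonsynonymous")
            plant_coding(g, n_non, k - n_non)
            li += k

    coding_ts = sum(1 for s in snps if s.transition)
    coding_tv = len(snps) - coding_ts

    # shared masks for noncoding placement
    region_code_of = {"LSC": 0, "IR": 1, "SSC": 2}
    class_code_of = {"spacer": 0, "intron": 1, "exon": 2}
    boundary_guard = np.ones(G, dtype=bool)
    for j in (part.irb[0], part.irb[1], part.ira[0]):
        boundary_guard[j - 50 : j + 50] = False
    lsc_spacer = (rcode == 0) & (ccode == 0)
    runs = _runs_of(lsc_spacer)

    # ---------------- indels -------------------------------------------
    indels: list[PlantedIndel] = []
    other_haps = hap_names[1:]  # the reference haplotype stays indel-free

    def hap_pick() -> str:
        return str(rng.choice(other_haps))

    # slippage events at seeded SSR loci
    for (region, site_class), (n_slip, _n_other) in cfg.indel_plan.items():
        if n_slip == 0:
            continue
        cands = []
        for loc in loci:
            if loc.unit != 1 or loc.count < 12:
                continue
            r, c = int(rcode[loc.start]), int(ccode[loc.start])
            if region_name[r] != region or ("spacer", "intron", "exon")[c] != site_class:
                continue
            if site_class == "exon":
                gene = index.gene_at(loc.start)
                if gene is None or ann.has_feature(gene, "CDS"):
                    continue  # coding frames stay intact
            cands.append(loc)
        if len(cands) < n_slip:
            raise SimulationError(
                f"not enough SSR loci for slippage in {region}/{site_class}"
            )
        perm = rng.permutation(len(cands))[:n_slip]
        for pi in perm:
            loc = cands[int(pi)]
            kind = str(rng.choice(["insertion", "deletion"]))
            painter.take(loc.start, loc.span)
            indels.append(
                PlantedIndel(
                    position=loc.start,
                    column=-1,
                    length=1,
                    kind=kind,
                    region=region,
                    site_class=site_class,
                    gene=index.gene_at(loc.start),
                    haplotype=hap_pick(),
                    slippage=True,
                    motif=loc.motif,
                )
            )

    # other (non-slippage) indels
    size_menu = [1, 1, 1, 1, 2, 2, 3, 4, 5, 6, 8, 10]

    def plant_indel(region: str, site_class: str, length: int, kind: str,
                    mask: np.ndarray, hap: str | None = None,
                    soft: bool = True) -> None:
        pool = np.flatnonzero(mask)
        rng.shuffle(pool)
        content = ""
        if kind == "insertion":
            content = _seq.to_str(_seq.random_dna(rng, length, cfg.gc))
        for p in pool:
            p = int(p)
            span = length if kind == "deletion" else 1
            if not painter.free(p, span, soft=soft):
                continue
            if kind == "deletion" and not (
                (rcode[p : p + length] == rcode[p]).all()
                and (ccode[p : p + length] == ccode[p]).all()
            ):
                continue
            if not junction_safe(p, length, kind, content):
                continue
            painter.take(p, span)
            mirrored = None
            if region == "IR":
                mirrored = part.mirror_in_ira(p + length - 1)
                painter.take(mirrored, length)
            indels.append(
                PlantedIndel(
                    position=p,
                    column=-1,
                    length=length,
                    kind=kind,
                    region=region,
                    site_class=site_class,
                    gene=index.gene_at(p) if site_class != "spacer" else None,
                    haplotype=hap or hap_pick(),
                    motif=content or None,
                    mirrored_position=mirrored,
                )
            )
            return
        raise SimulationError(f"no room for {length} bp {kind} in {region}")

    for (region, site_class), (_n_slip, n_other) in cfg.indel_plan.items():
        if n_other == 0:
            continue
        mask = (
            (rcode == region_code_of[region])
            & (ccode == class_code_of[site_class])
            & boundary_guard
        )
        if site_class == "exon":
            # noncoding-gene exons only
            okg = np.zeros(G, dtype=bool)
            for f in ann.features:
                if f.kind == "exon" and not ann.has_feature(f.gene, "CDS"):
                    for s_, e_ in f.parts:
                        okg[s_:e_] = True
            mask &= okg
        todo = n_other
        if region == "LSC" and site_class == "spacer":
            # the flagship large deletion and large insertion
            widest2 = sorted(runs, key=lambda r: r[1] - r[0])[-2]
            big_mask = np.zeros(G, dtype=bool)
            big_mask[widest2[0] + 10 : widest2[1] - 10] = True
            plant_indel(region, site_class, cfg.large_deletion, "deletion",
                        mask & big_mask, hap=hap_names[1], soft=False)
            plant_indel(region, site_class, cfg.large_insertion, "insertion",
                        mask, hap=hap_names[2])
            todo -= 2
        for _ in range(todo):
            kind = "deletion" if region == "IR" else str(
                rng.choice(["insertion", "deletion"])
            )
            length = int(rng.choice(size_menu))
            plant_indel(region, site_class, length, kind, mask)

    # ---------------- noncoding SNPs -----------------------------------
    def draw_positions(mask: np.ndarray, k: int) -> list[int]:
        pool = np.flatnonzero(mask)
        rng.shuffle(pool)
        out = []
        for p in pool:
            if len(out) == k:
                break
            p = int(p)
            if painter.free(p) and ssr_inert(p):
                painter.take(p)
                out.append(p)
        if len(out) < k:
            raise SimulationError("position pool exhausted")
        return out

    # hotspot: central window of the widest LSC spacer run
    widest = max(runs, key=lambda r: r[1] - r[0])
    mid = (widest[0] + widest[1]) // 2
    hot_iv = (mid - cfg.hotspot_window // 2, mid + cfg.hotspot_window // 2)
    hot_mask = np.zeros(G, dtype=bool)
    hot_mask[hot_iv[0] : hot_iv[1]] = True

    noncoding: list[PlantedSnp] = []

    def plant_noncoding(region: str, site_class: str, mask: np.ndarray, k: int):
        for pos in draw_positions(mask, k):
            gene = index.gene_at(pos) if site_class != "spacer" else None
            noncoding.append(
                PlantedSnp(
                    position=pos,
                    column=-1,
                    region=region,
                    site_class=site_class,
                    gene=gene,
                    ancestral=genome[pos],
                    derived="",
                    haplotype="",
                    transition=False,
                    mirrored_position=(
                        part.mirror_in_ira(pos) if region == "IR" else None
                    ),
                )
            )

    for (region, site_class), quota in cfg.snp_quotas.items():
        if site_class == "exon":
            continue
        mask = (
            (rcode == region_code_of[region])
            & (ccode == class_code_of[site_class])
            & boundary_guard
        )
        if region == "LSC" and site_class == "spacer":
            plant_noncoding(region, site_class, mask & hot_mask, cfg.hotspot_snps)
            plant_noncoding(region, site_class, mask & ~hot_mask,
                            quota - cfg.hotspot_snps)
        else:
            plant_noncoding(region, site_class, mask, quota)

    # exact Ts/Tv bookkeeping: noncoding sites fill the remaining budgets
    n_ts_nc = cfg.ts_count - coding_ts
    n_tv_nc = cfg.tv_count - coding_tv
    if n_ts_nc < 0 or n_tv_nc < 0 or n_ts_nc + n_tv_nc != len(noncoding):
        raise SimulationError("Ts/Tv budgets infeasible with coding plan")
    labels = np.array(["ts"] * n_ts_nc + ["tv"] * n_tv_nc)
    rng.shuffle(labels)
    for s, lab in zip(noncoding, labels):
        anc = s.ancestral
        if lab == "ts":
            s.derived = _transition_of(anc)
            s.transition = True
        else:
            s.derived = str(rng.choice(list(_TV_PARTNERS[anc])))
            s.transition = False
    snps.extend(noncoding)

    # branch assignment
    branch_labels = []
    for name, budget in zip(hap_names, cfg.snp_branch_budgets):
        branch_labels += [name] * budget
    branch_labels = np.array(branch_labels)
    rng.shuffle(branch_labels)
    if len(branch_labels) != len(snps):
        raise SimulationError("branch budgets do not match planted SNPs")
    for s, b in zip(snps, branch_labels):
        s.haplotype = str(b)

    # ---------------- assembly -----------------------------------------
    n = cfg.n_accessions
    matrix = np.tile(arr, (n, 1))
    comp_byte = {b: ord(_seq.complement(b)) for b in "ACGT"}

    for s in snps:
        rows = rows_of_hap[s.haplotype]
        matrix[rows, s.position] = ord(s.derived)
        if s.mirrored_position is not None:
            matrix[rows, s.mirrored_position] = comp_byte[s.derived]

    insertions = []  # (anchor, content, rows)
    for e in indels:
        rows = rows_of_hap[e.haplotype]
        if e.kind == "deletion":
            matrix[np.ix_(rows, range(e.position, e.position + e.length))] = _seq.GAP
            if e.mirrored_position is not None:
                m0 = e.mirrored_position
                matrix[np.ix_(rows, range(m0, m0 + e.length))] = _seq.GAP
        else:
            content = e.motif * e.length if e.slippage else e.motif
            insertions.append((e.position, content, rows, e))

    insertions.sort(key=lambda x: x[0])
    anchors = [i[0] for i in insertions]

    def col_of(pos: int) -> int:
        shift = sum(len(c) for a, c, _, _ in insertions if a <= pos)
        return pos + shift

    pieces = np.split(matrix, anchors, axis=1)
    out_blocks = [pieces[0]]
    for (anchor, content, rows, e), piece in zip(insertions, pieces[1:]):
        block = np.full((n, len(content)), _seq.GAP, dtype=np.uint8)
        block[rows, :] = np.tile(_seq.to_array(content), (len(rows), 1))
        out_blocks.append(block)
        out_blocks.append(piece)
    full = np.concatenate(out_blocks, axis=1)

    for s in snps:
        s.column = col_of(s.position)
    for e in indels:
        if e.kind == "deletion":
            e.column = col_of(e.position)
        else:
            prior = sum(len(c) for a, c, _, _ in insertions if a < e.position)
            e.column = e.position + prior

    aln = AlignedGenomeSet(ids, full, cfg.reference_id)
    truth = TruthCatalog(snps, indels, members, part)
    return aln, truth


@dataclass
class SimResult:
    aln: AlignedGenomeSet
    ann: AnnotationSet
    part: RegionPartition
    truth: TruthCatalog
    ancestor: str


def simulate(cfg: SimConfig | None = None, seed: int = 0) -> SimResult:
    """Generate an ancestor and evolve the full accession set (one call)."""
    cfg = cfg or SimConfig()
    genome, ann, part = generate_ancestor(cfg, seed)
    aln, truth = evolve_haplotypes(genome, ann, part, cfg, seed)
    return SimResult(aln, ann, part, truth, genome)
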