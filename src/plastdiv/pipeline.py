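"""Full-analysis orchestration: structure -> variants -> effects ->
diversity -> codons -> repeats -> network, written as a report bundle.

:func:`run_analysis` drives the whole pipeline on in-memory objects and is
what the CLI, the examples and the acceptance script share;
:func:`run_all` is the file-based wrapper that reads an aligned FASTA +
GFF3, runs everything and writes one TSV/JSON per table plus a manifest.
All rounding happens at serialization time only (densities 2 dp, Hd and
Ts/Tv 3 dp, pi 5 dp).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .alignment import AlignedGenomeSet, read_alignment
from .annotation import AnnotationSet, read_annotation
from .codons import codon_counts, extract_cds, rscu_matrix
from .context import ContextIndex
from .diversity import (
    HaplotypeTable,
    WindowProfile,
    collapse_haplotypes,
    diversity_by_region,
    haplotype_diversity,
    nucleotide_diversity,
    sliding_window_pi,
)
from .effects import classify_snps, gene_snp_table
from .network import StepMatrix, build_msn, build_nj_tree, pairwise_steps
from .repeats import (
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    polymorphic_ssrs,
)
from .structure import RegionPartition, detect_inverted_repeat, junction_report
from .variants import call_indel_events, call_snp_sites, substitution_spectrum, variant_summary

log = logging.getLogger("plastdiv")


@dataclass
class RunConfig:
    alignment: str
    annotation: str
    reference_id: str
    out_dir: str = "plastdiv_out"
    partition: str | None = None  # JSON override; otherwise detected
    dedupe_ir: bool = True
    window: int = 600
    step: int = 100
    min_ir_len: int = 1000
    ssr_thresholds: dict | None = None
    repeat_min_len: int = 30
    repeat_max_mismatch: int = 3
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class ReportBundle:
    part: RegionPartition
    junctions: pd.DataFrame
    snps: list
    indels: list
    spectrum: object
    summary: pd.DataFrame
    gene_table: pd.DataFrame
    diversity: pd.DataFrame
    windows: WindowProfile
    haplotypes: HaplotypeTable
    hd: float
    pi: float
    rscu: pd.DataFrame
    codon_totals: dict[str, int]
    ssrs_by_hap: dict[str, list]
    dispersed_by_hap: dict[str, list]
    tandem_by_hap: dict[str, list]
    poly_ssrs: list
    steps: StepMatrix | None
    msn: nx.Graph | None
    nj_newick: str | None
    effects: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    def snp_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.snps:
            rows.append(
                {
                    "column": s.column,
                    "ref_position": s.ref_position,
                    "alleles": "/".join(f"{b}:{c}" for b, c in sorted(s.alleles.items())),
                    "class": s.site_class,
                    "substitution": s.substitution or "",
                    "spectrum_class": s.spectrum_class or "",
                    "region": s.context.region if s.context else "",
                    "site_class": s.context.site_class if s.context else "",
                    "gene": (s.context.gene or "") if s.context else "",
                }
            )
        return pd.DataFrame(rows)

    def indel_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.indels:
            rows.append(
                {
                    "start_column": e.start_column,
                    "ref_position": e.ref_position,
                    "length": e.length,
                    "kind": e.kind,
                    "n_accessions": len(e.accessions),
                    "region": e.context.region if e.context else "",
                    "site_class": e.context.site_class if e.context else "",
                    "gene": (e.context.gene or "") if e.context else "",
                }
            )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path, manifest_extra: dict | None = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.part.to_json(out / "partition.json")
        self.junctions.to_csv(out / "junctions.tsv", sep="\t", index=False)
        self.snp_frame().to_csv(out / "snp_sites.tsv", sep="\t", index=False)
        self.indel_frame().to_csv(out / "indel_events.tsv", sep="\t", index=False)
        spec = self.spectrum.to_frame()
        spec.loc[len(spec)] = ["Ts", self.spectrum.ts]
        spec.loc[len(spec)] = ["Tv", self.spectrum.tv]
        spec.loc[len(spec)] = ["Ts/Tv", round(self.spectrum.ratio, 3)]
        spec.to_csv(out / "spectrum.tsv", sep="\t", index=False)
        self.summary.to_csv(out / "summary.tsv", sep="\t")
        self.gene_table.to_csv(out / "gene_snp_table.tsv", sep="\t", index=False)
        div = self.diversity.copy()
        div["pi"] = div["pi"].round(5)
        div["hd"] = div["hd"].round(3)
        div.to_csv(out / "diversity_by_region.tsv", sep="\t", index=False)
        win = self.windows.windows.copy()
        win["midpoint"] = (win["start"] + win["end"]) // 2
        win["pi"] = win["pi"].round(5)
        win.to_csv(out / "windows.tsv", sep="\t", index=False)
        self.haplotypes.to_frame().to_csv(out / "haplotypes.tsv", sep="\t", index=False)
        self.rscu.round(4).to_csv(out / "rscu_matrix.tsv", sep="\t")
        rows = []
        for hap, loci in self.ssrs_by_hap.items():
            for l in loci:
                rows.append(
                    {
                        "haplotype": hap,
                        "start": l.start,
                        "motif": l.motif,
                        "unit": l.unit,
                        "count": l.count,
                        "region": l.context.region if l.context else "",
                        "site_class": l.context.site_class if l.context else "",
                    }
                )
        pd.DataFrame(rows).to_csv(out / "ssrs.tsv", sep="\t", index=False)
        rows = []
        for hap, reps in self.dispersed_by_hap.items():
            for r in reps:
                rows.append(
                    {
                        "haplotype": hap,
                        "kind": r.kind,
                        "start1": r.interval1[0],
                        "end1": r.interval1[1],
                        "start2": r.interval2[0],
                        "end2": r.interval2[1],
                        "length": r.length,
                        "mismatches": r.mismatches,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "dispersed_repeats.tsv", sep="\t", index=False)
        rows = []
        for hap, reps in self.tandem_by_hap.items():
            for t in reps:
                rows.append(
                    {
                        "haplotype": hap,
                        "start": t.start,
                        "period": t.period,
                        "copies": t.copies,
                        "unit": t.unit,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "tandem_repeats.tsv", sep="\t", index=False)
        rows = []
        for p in self.poly_ssrs:
            rows.append(
                {
                    "col_start": p.columns[0],
                    "col_end": p.columns[1],
                    "motif": p.motif,
                    "region": p.context.region if p.context else "",
                    "site_class": p.context.site_class if p.context else "",
                    **{f"count_{h}": c for h, c in sorted(p.counts.items())},
                }
            )
        pd.DataFrame(rows).to_csv(out / "polymorphic_ssrs.tsv", sep="\t", index=False)
        if self.msn is not None:
            edges = [
                {
                    "hap_i": u,
                    "hap_j": v,
                    "steps": d["steps"],
                    "in_all_msts": d["in_all_msts"],
                    "freq_i": self.msn.nodes[u]["frequency"],
                    "freq_j": self.msn.nodes[v]["frequency"],
                }
                for u, v, d in self.msn.edges(data=True)
            ]
            pd.DataFrame(edges).to_csv(out / "network_edges.tsv", sep="\t", index=False)
            nx.write_graphml(self.msn, out / "network.graphml")
        if self.nj_newick is not None:
            (out / "nj_tree.nwk").write_text(self.nj_newick + "\n")
        manifest = {"tables": sorted(p.name for p in out.iterdir())}
        if manifest_extra:
            manifest.update(manifest_extra)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_analysis(
    aln: AlignedGenomeSet,
    ann: AnnotationSet,
    part: RegionPartition | None = None,
    dedupe_ir: bool = True,
    window: int = 600,
    step: int = 100,
    min_ir_len: int = 1000,
    ssr_thresholds: dict | None = None,
    repeat_min_len: int = 30,
    repeat_max_mismatch: int = 3,
    scan_repeats: bool = True,
) -> ReportBundle:
    """Run the complete comparative analysis on in-memory inputs."""
    ref_seq = aln.ungapped(aln.reference_id)
    if part is None:
        log.info("detecting inverted repeat on the reference")
        part = detect_inverted_repeat(ref_seq, min_ir_len)
    index = ContextIndex(ann, part)

    jr = junction_report(part, ann)
    junctions = pd.DataFrame(
        [
            {
                "junction": e.junction,
                "gene": e.gene or "",
                "bp_side_a": e.bp_side_a,
                "bp_side_b": e.bp_side_b,
            }
            for e in jr.entries
        ]
    )

    log.info("calling SNP sites and indel events")
    snps = call_snp_sites(aln, part, index, dedupe_ir=dedupe_ir)
    indels = call_indel_events(aln, part, index, dedupe_ir=dedupe_ir)
    spectrum = substitution_spectrum(snps)
    effects = classify_snps(snps, index, aln)
    summary = variant_summary(snps, indels, aln, index, effects)
    gene_table = gene_snp_table(snps, effects, index.ann)

    log.info("diversity statistics")
    haplotypes = collapse_haplotypes(aln)
    hd = haplotype_diversity(haplotypes)
    pi = nucleotide_diversity(aln)
    div = diversity_by_region(aln, part, index)
    windows = sliding_window_pi(aln, window, step)

    log.info("codon usage")
    reps = {h.hap_id: h.representative for h in haplotypes.haplotypes}
    rscu_df = rscu_matrix(aln, ann, reps)
    codon_totals = {
        h: codon_counts(extract_cds(acc, aln, ann)).total
        for h, acc in reps.items()
    }

    ssrs_by_hap: dict[str, list] = {}
    dispersed_by_hap: dict[str, list] = {}
    tandem_by_hap: dict[str, list] = {}
    poly = []
    if scan_repeats:
        log.info("repeat scans")
        maps = {}
        for h in haplotypes.haplotypes:
            acc = h.representative
            seq = aln.ungapped(acc)
            cmap = aln.coordinate_map(acc)
            maps[h.hap_id] = cmap
            ref_map = aln.reference_map
            loci = []
            for loc in find_ssrs(seq, ssr_thresholds):
                col = cmap.column(loc.start)
                rpos = ref_map.previous_position(col) or 0
                ctx = index.context_at(rpos)
                if dedupe_ir and ctx.region == "IRa":
                    continue
                loc.context = ctx
                loci.append(loc)
            ssrs_by_hap[h.hap_id] = loci
            dispersed_by_hap[h.hap_id] = find_dispersed_repeats(
                seq, repeat_min_len, repeat_max_mismatch
            )
            tandem_by_hap[h.hap_id] = find_tandem_repeats(seq)
        poly = polymorphic_ssrs(ssrs_by_hap, maps)

    steps = msn = nj = None
    if haplotypes.count >= 2:
        log.info("haplotype network")
        steps = pairwise_steps(haplotypes, aln)
        freqs = {h.hap_id: h.frequency for h in haplotypes.haplotypes}
        membs = {h.hap_id: h.members for h in haplotypes.haplotypes}
        msn = build_msn(steps, freqs, membs)
        if haplotypes.count >= 3:
            nj = build_nj_tree(steps)

    return ReportBundle(
        part=part,
        junctions=junctions,
        snps=snps,
        indels=indels,
        spectrum=spectrum,
        summary=summary,
        gene_table=gene_table,
        diversity=div,
        windows=windows,
        haplotypes=haplotypes,
        hd=hd,
        pi=pi,
        rscu=rscu_df,
        codon_totals=codon_totals,
        ssrs_by_hap=ssrs_by_hap,
        dispersed_by_hap=dispersed_by_hap,
        tandem_by_hap=tandem_by_hap,
        poly_ssrs=poly,
        steps=steps,
        msn=msn,
        nj_newick=nj,
        effects=effects,
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(cfg: RunConfig) -> ReportBundle:
    """File-based pipeline: read inputs, run everything, write the bundle."""
    logging.basicConfig(level=cfg.log_level)
    aln = read_alignment(cfg.alignment, cfg.reference_id)
    ref_len = len(aln.ungapped(cfg.reference_id))
    ann = read_annotation(cfg.annotation, ref_len)
    part = RegionPartition.from_json(cfg.partition) if cfg.partition else None
    bundle = run_analysis(
        aln,
        ann,
        part,
        dedupe_ir=cfg.dedupe_ir,
        window=cfg.window,
        step=cfg.step,
        min_ir_len=cfg.min_ir_len,
        ssr_thresholds=cfg.ssr_thresholds,
        repeat_min_len=cfg.repeat_min_len,
        repeat_max_mismatch=cfg.repeat_max_mismatch,
    )
    manifest = {
        "config": vars(cfg),
        "inputs": {
            "alignment": _sha256(cfg.alignment),
            "annotation": _sha256(cfg.annotation),
        },
    }
    bundle.write(cfg.out_dir, manifest)
    return bundle
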