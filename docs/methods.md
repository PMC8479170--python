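# Methods

This note documents the statistical and algorithmic choices behind
`plastdiv`: what each estimator computes, the conventions where several
were defensible, what the synthetic data do and do not emulate, and the
known limitations.

## Coordinates and contexts

Internally every interval is 0-based half-open; GFF3 I/O converts from/to
1-based inclusive. The alignment is treated as a linear sequence starting
at the LSC start (the usual plastome convention); circular rotation is the
simulator's concern, and `detect_inverted_repeat` reports an
`origin_offset` rather than rotating input that does not start at the LSC.

Each alignment column receives exactly one `(region, site class, gene)`
context. Site class follows coding depth: CDS parts win over host-gene
introns, so a *matK*-type CDS nested in a *trnK* intron classifies as exon
of the coding gene — effect classification needs the coding context.
Columns where the reference is gapped inherit the context of the nearest
preceding reference base. N bases are allowed in input but excluded from
every variant and diversity count (treated as missing); the simulator never
emits them.

## Structure

IR detection finds the maximal pair of non-overlapping segments where one
equals the reverse complement of the other, by exact k-mer seeding
(k = min(64, min_ir_len)) with maximal extension; the longer single-copy
region is named LSC. `min_ir_len` defaults to 1,000 bp — plastome IRs are
typically >10 kb, and the threshold just suppresses short palindromes. The
detector is checked against an O(n²) brute-force search on ≤5 kb toys.
Junction reports give, for each of JLB/JSB/JSA/JLA, the containing (or
nearest abutting) gene and its extent on both sides of the boundary; the
origin-wrapping junction JLA handles genes annotated across the origin.

## Variant catalogs

A column is a SNP site when it carries ≥2 distinct A/C/G/T alleles —
columns varying only by gaps are indels, not SNPs (the accounting DnaSP
uses, which is what yields separate SNP and indel tallies). Sites are
parsimony-informative when ≥2 alleles occur in ≥2 accessions each,
singleton otherwise; multiallelic sites count once as sites and are
excluded (with a counter) from the transition/transversion spectrum.
Polarization for the directed six-class spectrum uses the major allele,
ties broken by the reference allele — no outgroup is assumed.

Because IRa mirrors IRb, sites and events whose reference position falls
in IRa are dropped from all catalogs and densities when `dedupe_ir` is on
(masking IRa and keeping IRb is arbitrary but fixed). Densities are
1000·count/span with *aligned* region lengths (column counts) as
denominators, the IR denominator being the single IRb copy while the total
uses the full alignment length — this is the convention that makes the
published per-region densities reproducible from their own printed counts
and lengths.

Indel events are maximal runs of consecutive columns sharing one accession
gap pattern; a reference gap is an insertion (carried by the non-gapped
accessions), otherwise a deletion (carried by the gapped ones). Adjacent
runs with different patterns are distinct events.

## Effects

Coding SNPs are classified by assembling the reference codon from the CDS
in transcription order (minus-strand parts reverse-complemented;
trans-spliced parts follow an explicit `part_order` attribute rather than
genomic order) and substituting the single alternative allele, all other
positions held at the reference state; translation uses NCBI table 11.
Stop-gain and start-loss are reported as subtypes but counted as
nonsynonymous. Codons carrying two SNPs are evaluated one SNP at a time
against the reference codon. Classification is verified against a
whole-protein translation oracle, and synonymy is invariant under swapping
the two alleles. No dN/dS or selection inference is attempted.

## Diversity

π is the mean per-site pairwise difference over columns free of gaps and N
in *all* accessions (complete deletion, the DnaSP default), computed per
column from allele counts as C(n,2) − Σ C(c_a,2). Haplotypes are distinct
allele vectors over gap-free SNP columns (indels excluded from the key by
default, switchable to `snp+indel`); Hd uses the n/(n−1) small-sample
factor. Sliding windows are alignment columns, [k·s, k·s+w) with the
trailing partial window dropped; per-window m may be below w, and windows
with m = 0 report NaN. Reported precision: π 5 dp, Hd 3 dp, densities
2 dp, Ts/Tv 3 dp — rounding happens at serialization only.

## Codon usage

Codon counts run over the concatenated CDS of the annotated gene list —
one copy per gene, so IR-duplicated genes are not double-counted. RSCU is
count over synonymous-family mean; the three stop codons form one family;
single-member families (AUG, UGG in table 11) are identically 1; families
with zero total are undefined (NaN). Codons containing N are skipped and
counted.

## Repeats

SSRs are maximal perfect tandem runs of a primitive 1–6 bp motif with
minimum counts 10/5/4/3/3/3 (the published search thresholds read as
"at least"; a strict-inequality mode is available since the original
tool's wording is ambiguous). A run is reported only at its smallest
period; motifs are canonicalised to their lexicographically minimal
rotation on the observed strand (no reverse-complement folding, so A and T
runs stay distinct); runs break at N.

Dispersed repeats are maximal pairs ≥30 bp with ≤3 mismatches (hence ≥90%
identity) in four orientations. The scanner seeds with exact k-mers of
k = ⌊min_len/(max_mismatch+1)⌋, which every qualifying pair must contain,
then extends each seed to all maximal windows; it is therefore equivalent
to the exhaustive quadratic scan (and is tested for set equality against
one on ~1 kb inputs) while scanning a full plastome in seconds. Pairs
whose two intervals overlap — including self-matches — are excluded, and
results are deduplicated by symmetric pair identity.

The tandem-repeat finder is a simplified exact-array model (period 7–100,
≥2 full copies, primitive unit), not an alignment-scoring reimplementation
of Tandem Repeats Finder; its acceptance is oracle-based, not
tool-replicating, and imperfect/compound arrays are out of scope.

Polymorphic SSR typing projects each haplotype representative's loci to
alignment columns through its coordinate map, merges projected intervals
that overlap by ≥1 column into homologous loci, and flags a locus when
repeat counts differ (absence counts as 0). Flanking-sequence export for
primer design is the caller's job; primer design itself is out of scope.

## Network

Step distances are differing-SNP-column counts between haplotype
representatives (complete deletion); note that IR-mirrored mutations
contribute two columns each, as they would in any whole-genome distance.
The network is the ε = 0 minimum-spanning network — the union of all
minimum spanning trees, built by Kruskal over equal-weight groups, with
edges present in *every* MST flagged — rather than a TCS
statistical-parsimony network: the 95% connection-limit machinery adds
little for step-annotated intraspecific topologies, and the MSN is checked
against exhaustive spanning-tree enumeration. Median vectors (inferred
nodes) are not implemented. The NJ tree is scikit-bio's neighbor joining
over the same matrix, negative branch lengths clamped to zero; rooting and
likelihood phylogenetics are out of scope.

## Synthetic plastomes

The generator's defaults are the study conditions the package is built
around: a 151,550 bp genome (LSC 82,600, IR 25,650 ×2, SSC 17,650), 22
accessions in 8 haplotypes with spectrum (11,4,2,1,1,1,1,1), 225
deduplicated SNPs placed 151/10/64 across LSC/IR/SSC and 99/114/12 across
exon/spacer/intron, per-gene coding budgets reproducing the published
hotspot table (ycf1 21 = 17+4, …, with the ycf1 analog at 5,571 bp since
the published 5,570 is not divisible by three), 55 nonsynonymous vs 44
synonymous coding changes, exactly 93 transitions and 132 transversions,
49 indels (22 of them 1-bp SSR slippage events at seeded loci — 14
spacer / 7 intron / 1 exon — plus a 546 bp deletion and a 52 bp
insertion), and junction genes overlapping JLB/JSB/JSA/JLA by
34/20/1,084/1 bp. Branch budgets (60, 50, 32, 17, 17, 17, 16, 16) were
chosen so 83 sites are singletons, 142 parsimony-informative, and the
expected whole-alignment π (IR mirror columns included) is ≈0.00042. A
12-SNP cluster in one 600 bp spacer window provides a divergence hotspot.

Mutations are planted on a star genealogy; every quantity above is exact
by construction, which is what makes full-pipeline parameter recovery a
sharp test. To keep it sharp, substitutions are only placed at positions
where no alternative base could create or destroy an SSR locus, indels get
an explicit junction-safety check (no locus may newly arise across an
indel junction in a carrier), and exon indels go to noncoding-gene exons
so reading frames stay intact — the published data place some exon indels
in CDS genes, but frame-breaking indels would contradict the equal-CDS
-length design of the codon-usage comparison, so the simulator trades that
detail for exactness. The reference haplotype carries SNPs but no indels,
keeping the emitted GFF3 in ancestor coordinates. Gene content scales with
configured region lengths so small test genomes remain feasible.

What the simulator does *not* emulate: realistic substitution models
(HKY/GTR rate structure beyond the Ts/Tv quota), recurrent or back
mutation, recombination, alignment error (the emitted alignment is true by
construction — real MAFFT output near indels is messier), base-composition
heterogeneity along the genome, and sequencing artefacts. Passing the
recovery tests therefore demonstrates the correctness of the accounting
and the estimators, not robustness to alignment or assembly noise.

## Problem sizes

The test suite runs the full-scale default simulation once (session
fixture) plus scaled-down (~15 kb, 6 accession) genomes for the file-based
pipeline tests; oracle-equality suites use ≤2 kb random sequences, n ≤ 6
alignments, ≤8-taxon trees and ≤7-haplotype networks, sizes at which the
brute-force oracles are exact and fast. The acceptance script runs the
full-scale set end to end in about a minute.
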