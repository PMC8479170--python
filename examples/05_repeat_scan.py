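"""SSR, dispersed-repeat and tandem-repeat scans on one genome, plus
cross-haplotype polymorphic SSR typing."""

from collections import Counter

from _smallconfig import small_config

from plastdiv.diversity import collapse_haplotypes
from plastdiv.repeats import (
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    polymorphic_ssrs,
)
from plastdiv.simulate import simulate

res = simulate(small_config(), seed=11)
genome = res.aln.ungapped(res.aln.reference_id)

ssrs = find_ssrs(genome)
print(f"SSRs: {len(ssrs)}  by unit length {dict(Counter(l.unit for l in ssrs))}")

dispersed = find_dispersed_repeats(genome)
print(f"dispersed repeats (>=30 bp, <=3 mismatches): "
      f"{dict(Counter(r.kind for r in dispersed))}")
longest = max(dispersed, key=lambda r: r.length)
print(f"  longest: {longest.kind}, {longest.length} bp (the IR pair itself)")

tandem = find_tandem_repeats(genome)
print(f"tandem arrays (period 7-100): {len(tandem)}")

tab = collapse_haplotypes(res.aln)
by_hap = {
    h.hap_id: find_ssrs(res.aln.ungapped(h.representative))
    for h in tab.haplotypes
}
maps = {h.hap_id: res.aln.coordinate_map(h.representative) for h in tab.haplotypes}
poly = polymorphic_ssrs(by_hap, maps)
print(f"polymorphic SSR loci across haplotypes: {len(poly)}")
for p in poly:
    print(f"  motif {p.motif}: repeat counts {p.counts}")
# Polymorphic loci are homologous SSRs whose repeat counts differ between
# haplotypes -- in the simulation, exactly the planted slippage events.
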