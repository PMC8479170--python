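"""Simulate a small plastome set, then call SNPs and indels from it.

The simulator plants every mutation, so the counts printed by the variant
caller can be compared against the truth catalog line by line.
"""

from _smallconfig import small_config

from plastdiv.context import ContextIndex
from plastdiv.simulate import simulate
from plastdiv.variants import call_indel_events, call_snp_sites, substitution_spectrum

res = simulate(small_config(), seed=11)
index = ContextIndex(res.ann, res.part)

snps = call_snp_sites(res.aln, res.part, index)
indels = call_indel_events(res.aln, res.part, index)
spectrum = substitution_spectrum(snps)

print(f"planted SNPs:    {res.truth.snp_count():3d}   called: {len(snps):3d}")
print(f"planted indels:  {res.truth.indel_count():3d}   called: {len(indels):3d}")
print(f"Ts:Tv = {spectrum.ts}:{spectrum.tv} (ratio {spectrum.ratio:.3f})")
for s in snps[:3]:
    print(
        f"  column {s.column:6d}  {s.ancestral}->{s.derived}  "
        f"{s.site_class:22s} {s.context.region}/{s.context.site_class}"
    )
# Each called site is one polymorphic alignment column; the IRa copies of
# the planted IR mutations are deduplicated, so called == planted exactly.
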