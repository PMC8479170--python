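"""Minimum-spanning haplotype network and a neighbor-joining tree."""

from _smallconfig import small_config

from plastdiv.diversity import collapse_haplotypes
from plastdiv.network import build_msn, build_nj_tree, pairwise_steps
from plastdiv.simulate import simulate

res = simulate(small_config(), seed=11)
tab = collapse_haplotypes(res.aln)
steps = pairwise_steps(tab, res.aln)

print("step matrix (pairwise differing SNP columns):")
print("      " + "  ".join(f"{h:>5s}" for h in steps.ids))
for i, h in enumerate(steps.ids):
    print(f"{h:>5s} " + "  ".join(f"{int(v):5d}" for v in steps.matrix[i]))

freqs = {h.hap_id: h.frequency for h in tab.haplotypes}
msn = build_msn(steps, freqs)
print("minimum-spanning network edges (union of all MSTs):")
for u, v, d in msn.edges(data=True):
    tag = "forced" if d["in_all_msts"] else "one of several"
    print(f"  {u} -- {v}: {d['steps']} steps ({tag})")

print("NJ tree:", build_nj_tree(steps))
# Edge weights are mutation steps between haplotypes; node frequencies give
# the circle sizes in the usual TCS-style figure.
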