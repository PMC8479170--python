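"""Codon counting over all protein-coding genes and RSCU values."""

from _smallconfig import small_config

from plastdiv.codons import codon_counts, extract_cds, rscu
from plastdiv.simulate import simulate

res = simulate(small_config(), seed=11)

cds = extract_cds(res.aln.reference_id, res.aln, res.ann)
tab = codon_counts(cds)
print(f"concatenated CDS: {len(cds)} bp -> {tab.total} codons")

df = rscu(tab).set_index("codon")
print(f"RSCU(AUG) = {df.loc['AUG', 'rscu']:.2f}  (single-member family, no bias)")
lys = df.loc[["AAA", "AAG"]]
print("Lys family:")
print(lys[["count", "rscu"]].to_string())
# RSCU > 1 means a codon is used more often than its synonymous-family
# average; the family-sum always equals the family size.
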