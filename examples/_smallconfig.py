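"""A scaled-down simulator configuration shared by the example scripts.

A 15 kb genome (LSC 8 kb, IR 2.5 kb, SSC 2 kb) with 6 accessions in 4
haplotypes; every pipeline stage still has something to find, but each
example runs in a couple of seconds.  Swap in ``SimConfig()`` for the
full-scale study-design set (22 accessions, ~151.5 kb).
"""

from plastdiv.simulate import SimConfig


def small_config() -> SimConfig:
    return SimConfig(
        lsc_len=8000,
        ir_len=2500,
        ssc_len=2000,
        n_accessions=6,
        haplotype_spectrum=(3, 1, 1, 1),
        snp_branch_budgets=(7, 4, 3, 3),
        snp_quotas={
            ("LSC", "exon"): 2,
            ("SSC", "exon"): 4,
            ("LSC", "spacer"): 6,
            ("SSC", "spacer"): 3,
            ("IR", "spacer"): 2,
        },
        gene_snps={"ycf1": (1, 1), "ndhF": (1, 1)},
        nonsyn_count=3,
        syn_count=3,
        ts_count=8,
        tv_count=9,
        hotspot_snps=3,
        indel_plan={("LSC", "spacer"): (1, 2)},
        large_deletion=60,
        large_insertion=20,
    )
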