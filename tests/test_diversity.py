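"""Haplotype collapsing, Hd, pi and sliding windows, checked against
pairwise / draw-probability oracles."""

import itertools
import math

import numpy as np
import pytest

from plastdiv.alignment import AlignedGenomeSet
from plastdiv.diversity import (
    HaplotypeTable,
    Haplotype,
    collapse_haplotypes,
    haplotype_diversity,
    nucleotide_diversity,
    sliding_window_pi,
)
from plastdiv.errors import UndefinedStatisticError


def aln_from(rows):
    names = [f"s{i}" for i in range(len(rows))]
    return AlignedGenomeSet.from_sequences(dict(zip(names, rows)), "s0")


def table_from_spectrum(spectrum):
    haps = []
    n = 0
    for i, f in enumerate(spectrum):
        members = tuple(f"a{n + j}" for j in range(f))
        haps.append(Haplotype(f"Hap{i + 1}", members[0], members))
        n += f
    return HaplotypeTable(haps, n)


class TestCollapseHaplotypes:
    def test_two_identical_vectors(self):
        aln = aln_from(["ACGT", "ACGA", "ACGA", "ACTT"])
        tab = collapse_haplotypes(aln)
        assert tab.count == 3 and sorted(tab.spectrum, reverse=True) == [2, 1, 1]

    def test_monomorphic_single_haplotype(self):
        aln = aln_from(["ACGT"] * 4)
        assert collapse_haplotypes(aln).count == 1

    def test_gap_columns_excluded_from_key(self):
        # the only variation is a gap: snp-only key collapses to 1 haplotype
        aln = aln_from(["ACGT", "AC-T"])
        assert collapse_haplotypes(aln, key="snp-only").count == 1
        assert collapse_haplotypes(aln, key="snp+indel").count == 2

    def test_planted_partition_recovered(self, sim, bundle):
        got = {h.hap_id: set(h.members) for h in bundle.haplotypes.haplotypes}
        want = {k: set(v) for k, v in sim.truth.haplotypes.items()}
        # ids are by first appearance; compare as partitions
        assert sorted(map(frozenset, got.values())) == sorted(
            map(frozenset, want.values())
        )


class TestHaplotypeDiversity:
    def test_published_style_spectrum(self):
        tab = table_from_spectrum((11, 4, 2, 1, 1, 1, 1, 1))
        assert round(haplotype_diversity(tab), 3) == 0.732

    def test_monomorphic_zero(self):
        assert haplotype_diversity(table_from_spectrum((7,))) == 0.0

    def test_small_case_closed_form(self):
        # {2,1}: 1.5 * (1 - 5/9) = 0.667
        assert round(haplotype_diversity(table_from_spectrum((2, 1))), 3) == 0.667

    def test_needs_two_accessions(self):
        with pytest.raises(UndefinedStatisticError):
            haplotype_diversity(table_from_spectrum((1,)))

    @pytest.mark.parametrize("spectrum", [(3, 2), (5, 1, 1), (2, 2, 2, 1), (4,)])
    def test_equals_draw_probability_oracle(self, spectrum):
        """Hd equals the probability that two draws without replacement are
        different haplotypes (exhaustive enumeration)."""
        labels = [i for i, f in enumerate(spectrum) for _ in range(f)]
        pairs = list(itertools.combinations(range(len(labels)), 2))
        p_diff = sum(labels[i] != labels[j] for i, j in pairs) / len(pairs)
        tab = table_from_spectrum(spectrum)
        assert math.isclose(haplotype_diversity(tab), p_diff, rel_tol=1e-12)


def pairwise_pi_oracle(rows):
    """Average per-site pairwise difference over complete-deletion columns."""
    keep = [
        i for i in range(len(rows[0]))
        if all(r[i] in "ACGT" for r in rows)
    ]
    m = len(keep)
    pairs = list(itertools.combinations(range(len(rows)), 2))
    total = sum(
        sum(rows[i][c] != rows[j][c] for c in keep) for i, j in pairs
    )
    return total / (len(pairs) * m)


class TestNucleotideDiversity:
    def test_three_sequence_hand_count(self):
        aln = aln_from(["ACGT", "ACGA", "ACGA"])
        assert math.isclose(nucleotide_diversity(aln), 2 / 12)

    def test_identical_sequences(self):
        aln = aln_from(["ACGT"] * 5)
        assert nucleotide_diversity(aln) == 0.0

    def test_single_pair_single_difference(self):
        rows = ["A" * 100, "A" * 50 + "C" + "A" * 49]
        assert math.isclose(nucleotide_diversity(aln_from(rows)), 0.01)

    def test_all_columns_gapped_undefined(self):
        aln = aln_from(["A-G", "ANG"])
        with pytest.raises(UndefinedStatisticError):
            nucleotide_diversity(aln, columns=np.array([1]))

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        L = 60
        rows = []
        base = rng.choice(list("ACGT"), size=L)
        for _ in range(n):
            r = base.copy()
            nmut = rng.integers(0, 8)
            for p in rng.integers(0, L, size=nmut):
                r[p] = rng.choice(list("ACGT-N"))
            rows.append("".join(r))
        if any(all(r[i] == "-" for r in rows) for i in range(L)):
            pytest.skip("all-gap column drawn")
        aln = aln_from(rows)
        assert math.isclose(
            nucleotide_diversity(aln), pairwise_pi_oracle(rows), rel_tol=1e-12
        )

    def test_invariant_under_reordering(self):
        rows = ["ACGTAC", "ACGAAC", "TCGTAC", "ACGTTC"]
        a1 = aln_from(rows)
        a2 = aln_from(rows[::-1])
        assert nucleotide_diversity(a1) == nucleotide_diversity(a2)


class TestSlidingWindow:
    def test_window_count(self):
        rows = ["A" * 1000, "A" * 1000]
        wp = sliding_window_pi(aln_from(rows), window=600, step=100)
        assert len(wp.windows) == 5
        assert list(wp.windows["start"]) == [0, 100, 200, 300, 400]

    def test_monomorphic_all_zero(self):
        rows = ["ACGT" * 300] * 3
        wp = sliding_window_pi(aln_from(rows))
        assert (wp.windows["pi"] == 0).all()

    def test_short_alignment_single_window_with_warning(self):
        rows = ["ACGT" * 10, "ACGT" * 10]
        with pytest.warns(UserWarning):
            wp = sliding_window_pi(aln_from(rows), window=600)
        assert len(wp.windows) == 1

    def test_whole_pi_within_window_range(self, sim, bundle):
        wp = bundle.windows
        finite = wp.windows["pi"].dropna()
        assert finite.min() <= bundle.pi <= finite.max()

    def test_peak_window_overlaps_planted_hotspot(self, sim, bundle):
        peak = bundle.windows.peak
        hot_cols = [
            t.column for t in sim.truth.snps
            if t.region == "LSC" and t.site_class == "spacer"
        ]
        # the 12 densest planted spacer SNPs sit inside one 600-bp window;
        # the argmax window must overlap that cluster
        hot_cols.sort()
        best_cluster = max(
            range(len(hot_cols)),
            key=lambda i: sum(1 for c in hot_cols if hot_cols[i] <= c < hot_cols[i] + 600),
        )
        lo = hot_cols[best_cluster]
        assert peak["start"] < lo + 600 and peak["end"] > lo

    def test_regional_table_consistency(self, bundle):
        df = bundle.diversity.set_index("region")
        assert df.loc["Total", "polymorphic_sites"] == 225
        assert (
            df.loc["Total", "singletons"] + df.loc["Total", "parsimony_informative"]
            == 225
        )
        assert df.loc["Total", "haplotypes"] == 8
        assert round(df.loc["Total", "hd"], 3) == 0.732
        assert round(df.loc["Total", "pi"], 5) == pytest.approx(0.00042, abs=2e-5)
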