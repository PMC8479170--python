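"""Repeat scanners against brute-force oracles, and polymorphic SSR typing."""

import numpy as np
import pytest

from plastdiv._seq import complement, revcomp
from plastdiv.alignment import AlignedGenomeSet
from plastdiv.repeats import (
    DEFAULT_SSR_THRESHOLDS,
    REPEAT_KINDS,
    canonical_rotation,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    is_primitive,
    polymorphic_ssrs,
    _transform,
    _second_interval,
)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------- SSRs


def ssr_oracle(seq, thresholds):
    """Brute force: for every start and period, expand the maximal perfect
    run; keep primitive-motif runs meeting the threshold, deduplicated."""
    out = set()
    n = len(seq)
    for k, thr in thresholds.items():
        for i in range(n - k):
            unit = seq[i : i + k]
            if "N" in unit or not is_primitive(unit):
                continue
            # maximality on the left (a full unit or a partial tail of it)
            if i >= 1 and seq[i - 1] == seq[i + k - 1]:
                continue
            count = 1
            j = i + k
            while seq[j : j + k] == unit:
                count += 1
                j += k
            if count >= thr:
                out.add((i, k, count))
    return out


class TestFindSsrs:
    def test_mono_run_at_threshold(self):
        loci = find_ssrs("C" + "A" * 10 + "G")
        assert [(l.start, l.motif, l.count) for l in loci] == [(1, "A", 10)]

    def test_below_threshold_ignored(self):
        assert find_ssrs("C" + "A" * 9 + "G") == []

    def test_dinucleotide_not_reported_as_mono(self):
        loci = find_ssrs("G" + "AT" * 5 + "G")
        assert [(l.motif, l.unit, l.count) for l in loci] == [("AT", 2, 5)]

    def test_run_broken_at_n(self):
        assert find_ssrs("A" * 6 + "N" + "A" * 6) == []

    def test_strict_threshold_semantics(self):
        seq = "C" + "A" * 10 + "G"
        assert len(find_ssrs(seq, strict=False)) == 1
        assert find_ssrs(seq, strict=True) == []

    def test_span_and_end(self):
        (l,) = find_ssrs("G" + "AATC" * 3 + "G", {4: 3})
        assert l.span == 12 and l.end == l.start + 12

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # AT-rich alphabet so runs actually occur at small n
        seq = "".join(rng.choice(list("AATTC"), size=400))
        thresholds = {1: 6, 2: 4, 3: 3, 4: 3, 5: 3, 6: 3}
        got = {(l.start, l.unit, l.count) for l in find_ssrs(seq, thresholds)}
        assert got == ssr_oracle(seq, thresholds)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(99)
        seq = "".join(rng.choice(list("AATTC"), size=600))
        low = {1: 5, 2: 3, 3: 3, 4: 2, 5: 2, 6: 2}
        high = {k: v + 1 for k, v in low.items()}
        assert len(find_ssrs(seq, high)) <= len(find_ssrs(seq, low))

    def test_canonical_rotation(self):
        assert canonical_rotation("TTA") == "ATT"
        assert canonical_rotation("A") == "A"


# -------------------------------------------------- dispersed repeats


def dispersed_oracle(seq, min_len, max_mm, kinds=REPEAT_KINDS):
    """Quadratic scan: every diagonal of (seq, transform(seq)), all maximal
    <=max_mm windows, same exclusion/dedup rules as the implementation."""
    n = len(seq)
    out = set()
    for kind in kinds:
        b = _transform(seq, kind)
        for d in range(-(n - 1), n):
            # diagonal: a[i] vs b[i - d]
            i_lo = max(0, d)
            i_hi = min(n, n + d)
            if i_hi - i_lo < min_len:
                continue
            mism = [-10**9] + [
                i for i in range(i_lo, i_hi) if seq[i] != b[i - d]
            ] + [10**9]
            for t in range(len(mism) - max_mm - 1):
                s = max(i_lo, mism[t] + 1)
                e = min(i_hi, mism[t + max_mm + 1])
                if e - s < min_len:
                    continue
                # maximality: window must touch a mismatch or the boundary
                inner = sum(1 for m in mism[1:-1] if s <= m < e)
                length = e - s
                iv1 = (s, e)
                iv2 = _second_interval(kind, s - d, length, n)
                if iv1 > iv2:
                    iv1, iv2 = iv2, iv1
                if iv1 == iv2 or iv1[1] > iv2[0]:
                    continue
                out.add((kind, iv1, iv2, inner))
    # drop non-maximal windows nested in a same-kind, same-diagonal window
    final = set()
    for item in out:
        kind, iv1, iv2, mm = item
        nested = any(
            k2 == kind and o1[0] <= iv1[0] and iv1[1] <= o1[1]
            and o2[0] <= iv2[0] and iv2[1] <= o2[1]
            and (o1, o2) != (iv1, iv2)
            for k2, o1, o2, _ in out
        )
        if not nested:
            final.add(item)
    return final


class TestDispersedRepeats:
    def test_planted_forward_duplicate(self):
        rng = np.random.default_rng(0)
        base = random_seq(rng, 2000)
        seg = base[100:135]
        seq = base[:1000] + seg + base[1000:]
        hits = find_dispersed_repeats(seq, kinds=("forward",))
        # a maximal window containing the exact 35-bp copy pair must exist
        assert any(
            r.interval1[0] <= 100 and r.interval1[1] >= 135
            and r.interval2[0] <= 1000 and r.interval2[1] >= 1035
            for r in hits
        )

    def test_planted_palindrome(self):
        rng = np.random.default_rng(1)
        base = random_seq(rng, 1500)
        seg = base[200:230]
        seq = base[:900] + revcomp(seg) + base[900:]
        hits = find_dispersed_repeats(seq, kinds=("palindromic",))
        assert any(r.length >= 30 for r in hits)

    def test_pair_members_do_not_overlap(self):
        rng = np.random.default_rng(2)
        seq = random_seq(rng, 800) * 2  # strong self-similarity
        for r in find_dispersed_repeats(seq):
            assert r.interval1[1] <= r.interval2[0]

    def test_similarity_invariant(self):
        rng = np.random.default_rng(3)
        base = random_seq(rng, 1200)
        seg = list(base[50:90])
        seg[10] = complement(seg[10])
        seq = base + "".join(seg)
        for r in find_dispersed_repeats(seq):
            assert r.similarity >= 0.9 and r.mismatches <= 3

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_quadratic_oracle_random(self, seed):
        rng = np.random.default_rng(seed + 100)
        seq = random_seq(rng, 700)
        # plant one duplicate (2 mismatches) and one palindrome to make hits
        seg = list(seq[30:70])
        seg[5] = complement(seg[5])
        seg[20] = complement(seg[20])
        seq = seq[:350] + "".join(seg) + seq[350:590] + revcomp(seq[100:133]) + seq[590:]
        got = {
            (r.kind, r.interval1, r.interval2, r.mismatches)
            for r in find_dispersed_repeats(seq)
        }
        assert got == dispersed_oracle(seq, 30, 3)

    def test_revalidates_against_sequence(self, sim, bundle):
        seq = sim.aln.ungapped(sim.aln.reference_id)
        for r in bundle.dispersed_by_hap["Hap1"]:
            s1 = seq[slice(*r.interval1)]
            s2 = seq[slice(*r.interval2)]
            if r.kind == "forward":
                t = s2
            elif r.kind == "palindromic":
                t = revcomp(s2)
            elif r.kind == "reverse":
                t = s2[::-1]
            else:
                t = complement(s2)
            mm = sum(a != b for a, b in zip(s1, t))
            assert mm == r.mismatches <= 3 and len(s1) >= 30

    def test_ir_pair_is_longest_palindromic_repeat(self, sim, bundle):
        pals = [r for r in bundle.dispersed_by_hap["Hap1"] if r.kind == "palindromic"]
        longest = max(pals, key=lambda r: r.length)
        ir_len = sim.part.length("IRb")
        assert longest.length >= ir_len


# ---------------------------------------------------- tandem repeats


def tandem_oracle(seq, min_period, max_period, min_copies):
    out = set()
    n = len(seq)
    for k in range(min_period, min(max_period, n // 2) + 1):
        i = 0
        # maximal self-shift runs
        eq = [seq[i] == seq[i + k] for i in range(n - k)]
        i = 0
        while i < len(eq):
            if not eq[i]:
                i += 1
                continue
            j = i
            while j < len(eq) and eq[j]:
                j += 1
            span = (j - i) + k
            unit = seq[i : i + k]
            if span >= min_copies * k and is_primitive(unit):
                out.add((i, k, span // k))
            i = j
    return out


class TestTandemRepeats:
    def test_planted_array(self):
        rng = np.random.default_rng(4)
        unit = random_seq(rng, 12)
        assert is_primitive(unit)
        seq = random_seq(rng, 300) + unit * 3 + random_seq(rng, 300)
        hits = find_tandem_repeats(seq)
        assert any(t.period == 12 and t.copies == 3 for t in hits)

    def test_no_repeats_in_short_random(self):
        rng = np.random.default_rng(5)
        assert find_tandem_repeats(random_seq(rng, 200)) == []

    def test_ssr_periods_excluded(self):
        seq = "C" + "AT" * 30 + "G"
        assert find_tandem_repeats(seq) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed + 50)
        unit = random_seq(rng, 20)
        seq = random_seq(rng, 400) + unit * 2 + random_seq(rng, 200)
        got = {(t.start, t.period, t.copies) for t in find_tandem_repeats(seq)}
        assert got == tandem_oracle(seq, 7, 100, 2.0)


# ------------------------------------------------- polymorphic SSRs


class TestPolymorphicSsrs:
    def test_differing_counts_flagged(self):
        h1 = "GG" + "A" * 10 + "CC"
        h2 = "GG" + "A" * 12 + "CC"
        aln = AlignedGenomeSet.from_sequences(
            {"h1": h1 + "--", "h2": h2}, "h2"
        )
        by_hap = {"h1": find_ssrs(h1), "h2": find_ssrs(h2)}
        maps = {k: aln.coordinate_map(k) for k in by_hap}
        (p,) = polymorphic_ssrs(by_hap, maps)
        assert p.counts == {"h1": 10, "h2": 12} and p.polymorphic

    def test_identical_content_no_loci(self):
        h = "GG" + "A" * 10 + "CC"
        aln = AlignedGenomeSet.from_sequences({"h1": h, "h2": h}, "h1")
        by_hap = {k: find_ssrs(h) for k in ("h1", "h2")}
        maps = {k: aln.coordinate_map(k) for k in by_hap}
        assert polymorphic_ssrs(by_hap, maps) == []

    def test_planted_slippage_loci_recovered(self, sim, bundle):
        truth = sim.truth.slippage_loci()
        assert len(bundle.poly_ssrs) == len(truth) == 22
        from collections import Counter

        got_ctx = Counter(p.context.site_class for p in bundle.poly_ssrs)
        want_ctx = Counter(t.site_class for t in truth)
        assert got_ctx == want_ctx
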