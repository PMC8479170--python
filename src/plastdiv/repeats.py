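"""Repeat scanning: SSRs, dispersed repeats, tandem arrays, polymorphic SSRs.

SSRs (microsatellites) are maximal perfect tandem runs of a primitive
1-6 bp motif meeting per-unit-length minimum repeat counts
(default >=10/5/4/3/3/3 for mono..hexa).  Dispersed repeats are maximal
pairs of segments, >= 30 bp with at most 3 mismatches (>= 90% similarity),
in four orientations: forward (direct), palindromic (reverse-complement),
reverse, and complement.  The dispersed scan is seed-and-extend with exact
k-mer seeds short enough to guarantee that every qualifying pair contains a
seed, so it is equivalent to an exhaustive scan while staying fast on full
plastomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _seq
from .alignment import AlignedGenomeSet, CoordinateMap
from .context import FeatureContext

DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}
REPEAT_KINDS = ("forward", "palindromic", "reverse", "complement")


def canonical_rotation(motif: str) -> str:
    """Lexicographically minimal rotation of the motif (observed strand)."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def is_primitive(unit: str) -> bool:
    """True when the unit is not a whole-number power of a shorter string."""
    k = len(unit)
    for d in range(1, k):
        if k % d == 0 and unit == unit[:d] * (k // d):
            return False
    return True


@dataclass
class SsrLocus:
    start: int  # ungapped position on the scanned sequence
    motif: str  # canonical rotation, observed strand
    unit: int
    count: int
    context: FeatureContext | None = None

    @property
    def span(self) -> int:
        return self.unit * self.count

    @property
    def end(self) -> int:
        return self.start + self.span


@dataclass
class DispersedRepeat:
    kind: str
    interval1: tuple[int, int]
    interval2: tuple[int, int]
    mismatches: int

    @property
    def length(self) -> int:
        return self.interval1[1] - self.interval1[0]

    @property
    def similarity(self) -> float:
        return 1.0 - self.mismatches / self.length


@dataclass
class TandemRepeat:
    start: int
    period: int
    copies: int
    unit: str

    @property
    def span(self) -> int:
        return self.period * self.copies


@dataclass
class PolymorphicSsr:
    columns: tuple[int, int]  # merged alignment-column interval
    motif: str
    counts: dict[str, int]  # haplotype label -> repeat count (0 = absent)
    context: FeatureContext | None = None

    @property
    def polymorphic(self) -> bool:
        return len(set(self.counts.values())) >= 2


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) runs of True in a boolean array."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def find_ssrs(
    seq: str,
    thresholds: dict[int, int] | None = None,
    strict: bool = False,
) -> list[SsrLocus]:
    """Scan for maximal perfect SSRs of unit length 1-6.

    A run reportable at several unit lengths is reported only at its
    smallest period (the motif must be primitive); runs are broken at N.
    ``strict=True`` interprets the thresholds as strict '>' minima instead
    of the default '>='.
    """
    thresholds = dict(DEFAULT_SSR_THRESHOLDS if thresholds is None else thresholds)
    arr = _seq.to_array(seq.upper())
    valid = _seq.CODE[arr] < 4
    out: list[SsrLocus] = []
    n = len(arr)
    for k, thr in sorted(thresholds.items()):
        if n <= k:
            continue
        eq = (arr[:-k] == arr[k:]) & valid[:-k] & valid[k:]
        for i, j in _true_runs(eq):
            span = (j - i) + k
            count = span // k
            if count < thr or (strict and count == thr):
                continue
            unit = seq[i : i + k]
            if not is_primitive(unit):
                continue
            out.append(SsrLocus(start=i, motif=canonical_rotation(unit), unit=k, count=count))
    out.sort(key=lambda s: (s.start, s.unit))
    return out


# -- dispersed repeats ------------------------------------------------------


def _transform(seq: str, kind: str) -> str:
    if kind == "forward":
        return seq
    if kind == "palindromic":
        return _seq.revcomp(seq)
    if kind == "reverse":
        return seq[::-1]
    if kind == "complement":
        return _seq.complement(seq)
    raise ValueError(f"unknown repeat kind {kind!r}")


def _second_interval(kind: str, j: int, length: int, n: int) -> tuple[int, int]:
    """Genome interval of b[j:j+length] for transform b of kind."""
    if kind in ("forward", "complement"):
        return (j, j + length)
    return (n - j - length, n - j)


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, integer codes) of all valid (N-free) k-mers."""
    n = len(codes)
    if n < k:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    m = n - k + 1
    c = np.zeros(m, dtype=np.int64)
    v = np.ones(m, dtype=bool)
    valid = codes < 4
    for t in range(k):
        c = c * 4 + codes[t : t + m]
        v &= valid[t : t + m]
    pos = np.flatnonzero(v)
    return pos, c[pos]


def _seed_runs(a_codes: np.ndarray, b_codes: np.ndarray, k: int, same: bool):
    """Merged exact seed runs between a and b: arrays (i0, j0, run_len)."""
    apos, ac = _kmer_codes(a_codes, k)
    bpos, bc = _kmer_codes(b_codes, k)
    if len(ac) == 0 or len(bc) == 0:
        return np.empty((0, 3), dtype=np.int64)
    order = np.argsort(bc, kind="stable")
    bs = bc[order]
    lo = np.searchsorted(bs, ac, side="left")
    hi = np.searchsorted(bs, ac, side="right")
    cnt = hi - lo
    total = int(cnt.sum())
    if total == 0:
        return np.empty((0, 3), dtype=np.int64)
    ai = np.repeat(apos, cnt)
    base = np.repeat(np.cumsum(cnt) - cnt, cnt)
    flat = np.arange(total) - base + np.repeat(lo, cnt)
    bj = bpos[order[flat]]
    if same:
        keep = ai != bj
        ai, bj = ai[keep], bj[keep]
        if len(ai) == 0:
            return np.empty((0, 3), dtype=np.int64)
    diag = ai - bj
    order2 = np.lexsort((ai, diag))
    ai, bj, diag = ai[order2], bj[order2], diag[order2]
    new = np.ones(len(ai), dtype=bool)
    new[1:] = (diag[1:] != diag[:-1]) | (ai[1:] != ai[:-1] + 1)
    starts = np.flatnonzero(new)
    ends = np.append(starts[1:], len(ai))
    i0 = ai[starts]
    j0 = bj[starts]
    run_len = (ai[ends - 1] - i0) + k
    return np.stack([i0, j0, run_len], axis=1)


def _prefilter(a: np.ndarray, b: np.ndarray, runs: np.ndarray, k: int,
               min_len: int, max_mm: int) -> np.ndarray:
    """Drop seed runs that no <=max_mm window of length min_len can cover.

    Any qualifying window containing a run also contains the run's first
    k-mer, so checking windows around the first k-mer is a sound
    (necessary-condition) filter for runs shorter than min_len; longer
    exact runs qualify outright.
    """
    if len(runs) == 0:
        return runs
    short = runs[:, 2] < min_len
    long_runs = runs[~short]
    cand = runs[short]
    if len(cand) == 0:
        return long_runs
    pad = min_len
    A = np.full(len(a) + 2 * pad, 254, dtype=np.uint8)
    A[pad : pad + len(a)] = a
    B = np.full(len(b) + 2 * pad, 255, dtype=np.uint8)
    B[pad : pad + len(b)] = b
    offsets = range(-(min_len - k), min_len)
    i0 = (cand[:, 0] + pad).astype(np.intp)
    j0 = (cand[:, 1] + pad).astype(np.intp)
    # mismatch profile per offset, built by cheap 1-D gathers
    cs = np.zeros((len(offsets) + 1, len(cand)), dtype=np.int16)
    for t, o in enumerate(offsets):
        cs[t + 1] = cs[t] + (A[i0 + o] != B[j0 + o])
    n_off = min_len - k + 1
    ok = np.zeros(len(cand), dtype=bool)
    for s in range(n_off):
        ok |= (cs[s + min_len] - cs[s]) <= max_mm
    return np.concatenate([long_runs, cand[ok]], axis=0)


def _maximal_windows(a: np.ndarray, b: np.ndarray, i0: int, j0: int,
                     run_len: int, max_mm: int):
    """All maximal <=max_mm-mismatch windows containing the exact seed run.

    Yields (start_a, start_b, length, mismatches)."""
    na, nb = len(a), len(b)
    # walk left collecting mismatch positions (a coordinates)
    mpos_l: list[int] = []
    p, q = i0 - 1, j0 - 1
    while p >= 0 and q >= 0 and len(mpos_l) <= max_mm:
        if a[p] != b[q]:
            mpos_l.append(p)
        p -= 1
        q -= 1
    left_boundary = p + 1  # leftmost reachable start (beyond last mismatch seen)
    mpos_r: list[int] = []
    p, q = i0 + run_len, j0 + run_len
    while p < na and q < nb and len(mpos_r) <= max_mm:
        if a[p] != b[q]:
            mpos_r.append(p)
        p += 1
        q += 1
    right_boundary = p  # exclusive

    def left_start(t: int) -> tuple[int, int]:
        """(window start, mismatches used) with t mismatches allowed left."""
        if t < len(mpos_l):
            return mpos_l[t] + 1, t
        return left_boundary, len(mpos_l)

    def right_end(t: int) -> tuple[int, int]:
        if t < len(mpos_r):
            return mpos_r[t], t
        return right_boundary, len(mpos_r)

    candidates: dict[tuple[int, int], int] = {}
    for t in range(max_mm + 1):
        s, used_l = left_start(max_mm - t)
        e, used_r = right_end(t)
        candidates[(s, e)] = used_l + used_r
    # at sequence edges a smaller-budget window can be nested in a larger
    # one from another split; only truly maximal (non-contained) windows stay
    for (s, e), mm in candidates.items():
        if any(
            (s2 <= s and e <= e2) and (s2, e2) != (s, e)
            for (s2, e2) in candidates
        ):
            continue
        yield s, j0 - (i0 - s), e - s, mm


def find_dispersed_repeats(
    seq: str,
    min_len: int = 30,
    max_mismatch: int = 3,
    kinds: tuple[str, ...] = REPEAT_KINDS,
) -> list[DispersedRepeat]:
    """Find maximal dispersed repeat pairs of the requested kinds.

    A pair is maximal when it cannot be extended on either side without
    exceeding ``max_mismatch`` (or running off the sequence).  Pairs whose
    two intervals overlap (including self-matches) are excluded and results
    are deduplicated by symmetric pair identity.
    """
    n = len(seq)
    a_str = seq.upper()
    a = _seq.to_array(a_str)
    a_codes = _seq.CODE[a]
    # seed length: every >=min_len window with <=max_mismatch mismatches
    # contains an exact stretch of ceil((min_len - max_mismatch) / (max_mismatch + 1))
    k = max(4, (min_len - max_mismatch + max_mismatch) // (max_mismatch + 1))
    k = min(k, 15)
    out: dict[tuple, DispersedRepeat] = {}
    for kind in kinds:
        b_str = _transform(a_str, kind)
        b = _seq.to_array(b_str)
        b_codes = _seq.CODE[b]
        runs = _seed_runs(a_codes, b_codes, k, same=(kind == "forward"))
        runs = _prefilter(a, b, runs, k, min_len, max_mismatch)
        seen_windows: set[tuple[int, int, int]] = set()
        for i0, j0, run_len in runs:
            for s_a, s_b, length, mm in _maximal_windows(
                a, b, int(i0), int(j0), int(run_len), max_mismatch
            ):
                if length < min_len:
                    continue
                key_w = (s_a, s_b, length)
                if key_w in seen_windows:
                    continue
                seen_windows.add(key_w)
                iv1 = (s_a, s_a + length)
                iv2 = _second_interval(kind, s_b, length, n)
                if iv1 > iv2:
                    iv1, iv2 = iv2, iv1
                if iv1 == iv2 or iv1[1] > iv2[0]:
                    continue  # identical or overlapping member intervals
                key = (kind, iv1, iv2)
                if key not in out:
                    out[key] = DispersedRepeat(kind, iv1, iv2, mm)
    result = list(out.values())
    result.sort(key=lambda r: (r.interval1, r.interval2, r.kind))
    return result


def find_tandem_repeats(
    seq: str,
    min_period: int = 7,
    max_period: int = 100,
    min_copies: float = 2.0,
) -> list[TandemRepeat]:
    """Maximal exact tandem arrays with period in [min_period, max_period].

    This is a simplified exact-match model of tandem-repeat finding (no
    alignment scoring of imperfect copies); periods of 6 or less are SSR
    territory and excluded by the default range.
    """
    arr = _seq.to_array(seq.upper())
    valid = _seq.CODE[arr] < 4
    n = len(arr)
    out: list[TandemRepeat] = []
    for k in range(min_period, min(max_period, n // 2) + 1):
        eq = (arr[:-k] == arr[k:]) & valid[:-k] & valid[k:]
        for i, j in _true_runs(eq):
            span = (j - i) + k
            if span < min_copies * k:
                continue
            unit = seq[i : i + k]
            if not is_primitive(unit):
                continue
            out.append(TandemRepeat(start=i, period=k, copies=span // k, unit=unit))
    out.sort(key=lambda t: (t.start, t.period))
    return out


def polymorphic_ssrs(
    ssrs_by_hap: dict[str, list[SsrLocus]],
    maps: dict[str, CoordinateMap],
) -> list[PolymorphicSsr]:
    """Merge per-haplotype SSR loci into homologous loci and flag polymorphism.

    Loci are projected to alignment columns through each haplotype
    representative's coordinate map; projected intervals that overlap by at
    least one column merge into one homologous locus.  A locus is
    polymorphic when repeat counts differ between haplotypes (a haplotype
    lacking the locus counts 0).
    """
    entries = []  # (col_start, col_end, hap, locus)
    for hap, loci in ssrs_by_hap.items():
        cmap = maps[hap]
        for loc in loci:
            c0 = cmap.column(loc.start)
            c1 = cmap.column(loc.end - 1) + 1
            entries.append((c0, c1, hap, loc))
    entries.sort(key=lambda e: (e[0], e[1]))
    merged: list[list] = []
    for e in entries:
        if merged and e[0] < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e[1])
            merged[-1][2].append(e)
        else:
            merged.append([e[0], e[1], [e]])
    out: list[PolymorphicSsr] = []
    for c0, c1, group in merged:
        counts = dict.fromkeys(ssrs_by_hap, 0)
        for _, _, hap, loc in group:
            counts[hap] += loc.count
        first = group[0][3]
        locus = PolymorphicSsr(
            columns=(c0, c1),
            motif=first.motif,
            counts=counts,
            context=first.context,
        )
        if locus.polymorphic:
            out.append(locus)
    return out
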