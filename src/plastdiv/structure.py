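"""Quadripartite plastome structure: IR detection and junction reports.

A plastome is LSC | IRb | SSC | IRa where IRa is the exact reverse
complement of IRb.  :func:`detect_inverted_repeat` recovers that partition
from an ungapped genome by finding the maximal pair of non-overlapping
segments where one equals the reverse complement of the other.
:func:`junction_report` describes, IRscope-style, which gene sits on each
of the four junctions (JLB, JSB, JSA, JLA) and by how many bp it extends
into each neighbouring region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _seq
from .annotation import AnnotationSet, Feature
from .errors import NoInvertedRepeatError, PlastdivError

REGIONS = ("LSC", "IRb", "SSC", "IRa")
JUNCTIONS = ("JLB", "JSB", "JSA", "JLA")


@dataclass(frozen=True)
class RegionPartition:
    """LSC/IRb/SSC/IRa intervals (0-based half-open) on the ungapped reference.

    ``origin_offset`` records, for inputs that do not already start at the
    LSC start, the position in the *input* sequence of the coordinate origin
    used here; the input sequence itself is never rotated.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int
    origin_offset: int = 0

    def __post_init__(self) -> None:
        ivs = [self.lsc, self.irb, self.ssc, self.ira]
        if [self.lsc[0]] != [0] or any(
            ivs[i][1] != ivs[i + 1][0] for i in range(3)
        ) or self.ira[1] != self.genome_length:
            raise PlastdivError(
                f"partition {ivs} does not tile [0,{self.genome_length}) "
                "in LSC,IRb,SSC,IRa order"
            )
        if self._len(self.ira) != self._len(self.irb):
            raise PlastdivError("IRa and IRb lengths differ")
        if self._len(self.lsc) <= self._len(self.ssc):
            raise PlastdivError("LSC must be longer than SSC")

    @staticmethod
    def _len(iv: tuple[int, int]) -> int:
        return iv[1] - iv[0]

    def interval(self, region: str) -> tuple[int, int]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}[
            region
        ]

    def length(self, region: str) -> int:
        return self._len(self.interval(region))

    def region_of(self, pos: int) -> str:
        for name in REGIONS:
            s, e = self.interval(name)
            if s <= pos < e:
                return name
        raise IndexError(f"position {pos} outside [0,{self.genome_length})")

    def mirror_in_ira(self, pos: int) -> int:
        """Map an IRb position onto its IRa mirror position."""
        s, e = self.irb
        if not s <= pos < e:
            raise IndexError(f"{pos} not in IRb {self.irb}")
        return self.ira[0] + (e - 1 - pos)

    # -- junction positions (boundary between two regions) --------------
    @property
    def junctions(self) -> dict[str, int]:
        return {
            "JLB": self.irb[0],
            "JSB": self.ssc[0],
            "JSA": self.ira[0],
            "JLA": self.genome_length,  # wraps to LSC start on the circle
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "lsc": list(self.lsc),
            "irb": list(self.irb),
            "ssc": list(self.ssc),
            "ira": list(self.ira),
            "genome_length": self.genome_length,
            "origin_offset": self.origin_offset,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "RegionPartition":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            tuple(d["lsc"]),
            tuple(d["irb"]),
            tuple(d["ssc"]),
            tuple(d["ira"]),
            d["genome_length"],
            d.get("origin_offset", 0),
        )


def _seed_pairs(seq: str, rc: str, k: int) -> list[tuple[int, int, int]]:
    """Merged exact seed runs (i, j, length) between seq and rc."""
    index: dict[str, list[int]] = {}
    for j in range(len(rc) - k + 1):
        index.setdefault(rc[j : j + k], []).append(j)
    hits: list[tuple[int, int]] = []  # (diag, i)
    for i in range(len(seq) - k + 1):
        for j in index.get(seq[i : i + k], ()):  # noqa: B905
            hits.append((i - j, i))
    hits.sort()
    runs: list[tuple[int, int, int]] = []
    prev_d = prev_i = None
    start_i = None
    for d, i in hits:
        if d == prev_d and i == prev_i + 1:
            prev_i = i
            continue
        if prev_d is not None:
            runs.append((start_i, start_i - prev_d, prev_i - start_i + k))
        prev_d, prev_i, start_i = d, i, i
    if prev_d is not None:
        runs.append((start_i, start_i - prev_d, prev_i - start_i + k))
    return runs


def _extend_exact(seq: str, rc: str, i: int, j: int, length: int) -> tuple[int, int, int]:
    """Maximally extend an exact match seq[i:i+len] == rc[j:j+len]."""
    while i > 0 and j > 0 and seq[i - 1] == rc[j - 1]:
        i -= 1
        j -= 1
        length += 1
    while i + length < len(seq) and j + length < len(rc) and seq[i + length] == rc[j + length]:
        length += 1
    return i, j, length


def detect_inverted_repeat(seq: str, min_ir_len: int = 1000) -> RegionPartition:
    """Detect the quadripartite partition of an ungapped plastome.

    Finds the maximal-length pair of non-overlapping segments where one is
    the exact reverse complement of the other (each extended maximally),
    then names the longer single-copy region LSC.  The default
    ``min_ir_len`` of 1 kb skips small palindromic repeats: plastome IRs are
    typically >10 kb.

    Raises :class:`NoInvertedRepeatError` when no such pair of length
    >= ``min_ir_len`` exists.
    """
    n = len(seq)
    if n <= 4 * min_ir_len:
        raise PlastdivError(
            f"sequence length {n} must exceed 4 x min_ir_len ({4 * min_ir_len})"
        )
    rc = _seq.revcomp(seq)
    k = min(64, min_ir_len)
    best: tuple[int, tuple[int, int], tuple[int, int]] | None = None
    seen: set[tuple[int, int, int]] = set()
    for i0, j0, ln0 in _seed_pairs(seq, rc, k):
        i, j, ln = _extend_exact(seq, rc, i0, j0, ln0)
        if (i, j, ln) in seen or ln < min_ir_len:
            continue
        seen.add((i, j, ln))
        # second copy in genome coordinates: rc[j:j+ln] == revcomp(seq[n-j-ln:n-j])
        a = (i, i + ln)
        b = (n - j - ln, n - j)
        if a > b:
            a, b = b, a
        if a[1] > b[0]:  # overlapping (e.g. a self-palindrome) -> not an IR pair
            continue
        if best is None or ln > best[0] or (ln == best[0] and (a, b) < best[1:]):
            best = (ln, a, b)
    if best is None:
        raise NoInvertedRepeatError(
            f"no inverted repeat pair of length >= {min_ir_len} found"
        )
    ln, a, b = best
    # single-copy segments on the circle: between = [a1,b0), outer = [b1,n)+[0,a0)
    between = b[0] - a[1]
    outer = (n - b[1]) + a[0]
    if outer >= between:
        # canonical layout: outer segment is the LSC (wraps the origin);
        # partition is expressed from the LSC start (= b[1] on the input).
        offset = b[1] % n
        lsc_len, ssc_len = outer, between
        part = RegionPartition(
            (0, lsc_len),
            (lsc_len, lsc_len + ln),
            (lsc_len + ln, lsc_len + ln + ssc_len),
            (lsc_len + ln + ssc_len, n),
            n,
            origin_offset=offset % n,
        )
        return part
    # between segment is the LSC: rotated origin at a[1]
    offset = a[1]
    lsc_len, ssc_len = between, outer
    return RegionPartition(
        (0, lsc_len),
        (lsc_len, lsc_len + ln),
        (lsc_len + ln, lsc_len + ln + ssc_len),
        (lsc_len + ln + ssc_len, n),
        n,
        origin_offset=offset,
    )


@dataclass
class JunctionGene:
    junction: str
    gene: str | None
    bp_side_a: int  # extent into the region before the junction
    bp_side_b: int  # extent into the region after the junction


@dataclass
class JunctionReport:
    entries: list[JunctionGene]

    def entry(self, junction: str) -> JunctionGene:
        for e in self.entries:
            if e.junction == junction:
                return e
        raise KeyError(junction)


def _gene_extent_near(f: Feature, j: int, n: int) -> tuple[int, int]:
    """Gene extent (start, end) in coordinates local to junction ``j``.

    Positions further than half a genome from ``j`` are wrapped so genes
    spanning the origin (JLA) are handled correctly.
    """
    coords: list[int] = []
    for s, e in f.parts:
        for x in (s, e):
            if x - j > n // 2:
                x -= n
            elif j - x > n // 2:
                x += n
            coords.append(x)
    return min(coords), max(coords)


def junction_report(part: RegionPartition, ann: AnnotationSet) -> JunctionReport:
    """Report, for each junction, the overlapping (or nearest abutting) gene
    and the bp it extends into the regions on either side.

    A gene containing JLB at position j with extent [s, e) contributes
    ``j - s`` bp on the LSC side and ``e - j`` bp on the IRb side.  A gene
    ending exactly on the junction reports 0 bp on the far side.
    """
    n = part.genome_length
    entries = []
    for name, j in part.junctions.items():
        best: tuple[int, Feature, int, int] | None = None
        for f in ann.gene_spans():
            s, e = _gene_extent_near(f, j, n)
            if s <= j <= e:
                dist = 0
            else:
                dist = min(abs(s - j), abs(e - j))
            if best is None or dist < best[0]:
                best = (dist, f, s, e)
        if best is None:
            entries.append(JunctionGene(name, None, 0, 0))
            continue
        _, f, s, e = best
        side_a = max(0, min(j, e) - s)  # bp of the gene before the junction
        side_b = max(0, e - max(j, s))  # bp of the gene after the junction
        entries.append(JunctionGene(name, f.gene, side_a, side_b))
    return JunctionReport(entries)
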