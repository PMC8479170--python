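"""Haplotype step distances, minimum-spanning network, and an NJ tree.

The minimum spanning network (MSN, epsilon = 0) is the union of all
minimum spanning trees over pairwise haplotype step counts — a
TCS/median-joining-style surrogate that annotates every edge with its
mutation-step count and every node with its haplotype frequency.  An
optional neighbor-joining tree over the same distances is provided as
plumbing (negative branch lengths clamped to zero).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .alignment import AlignedGenomeSet
from .diversity import HaplotypeTable, _snp_columns
from .errors import DegenerateTreeError, PlastdivError


@dataclass
class StepMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal

    def step(self, a: str, b: str) -> int:
        return int(self.matrix[self.ids.index(a), self.ids.index(b)])


def pairwise_steps(tab: HaplotypeTable, aln: AlignedGenomeSet) -> StepMatrix:
    """Pairwise differing-SNP-column counts between haplotype representatives.

    Columns containing any gap or N are excluded (complete deletion), so
    steps count SNP differences only.
    """
    if tab.count < 2:
        raise PlastdivError("need at least two haplotypes for a step matrix")
    cols = _snp_columns(aln.matrix)
    reps = [aln.accessions.index(h.representative) for h in tab.haplotypes]
    sub = aln.matrix[np.ix_(reps, cols)]
    k = len(reps)
    mat = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(i + 1, k):
            d = int((sub[i] != sub[j]).sum())
            mat[i, j] = mat[j, i] = d
            if d == 0:
                warnings.warn(
                    f"haplotypes {tab.haplotypes[i].hap_id} and "
                    f"{tab.haplotypes[j].hap_id} are identical (steps 0); "
                    "they should have been collapsed",
                    stacklevel=2,
                )
    return StepMatrix([h.hap_id for h in tab.haplotypes], mat)


class _DisjointSet:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_msn(
    steps: StepMatrix, freqs: dict[str, int] | None = None,
    members: dict[str, tuple[str, ...]] | None = None,
) -> nx.Graph:
    """Union of all minimum spanning trees over the step matrix.

    Kruskal processed by equal-weight groups: an edge belongs to some MST
    iff its endpoints are unconnected by strictly lighter edges; it belongs
    to *all* MSTs (edge attribute ``in_all_msts``) iff additionally no
    alternative equal-weight path connects them.  Deterministic under
    id-sorted tie-breaking.
    """
    ids = steps.ids
    edges = sorted(
        (int(steps.matrix[i, j]), ids[i], ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    )
    G = nx.Graph()
    for h in ids:
        G.add_node(
            h,
            frequency=(freqs or {}).get(h, 1),
            members=",".join((members or {}).get(h, ())),
        )
    ds = _DisjointSet(ids)
    pos = 0
    while pos < len(edges):
        w = edges[pos][0]
        group = []
        while pos < len(edges) and edges[pos][0] == w:
            group.append(edges[pos])
            pos += 1
        # edges of this weight joining distinct lighter-weight components
        useful = [
            (w, u, v)
            for w, u, v in group
            if ds.find(u) != ds.find(v)
        ]
        # multigraph over lighter-weight components to find forced edges
        H = nx.MultiGraph()
        for w_, u, v in useful:
            H.add_edge(ds.find(u), ds.find(v), key=(u, v))
        for w_, u, v in useful:
            ru, rv = ds.find(u), ds.find(v)
            H2 = H.copy()
            H2.remove_edge(ru, rv, key=(u, v))
            forced = not (H2.has_node(ru) and H2.has_node(rv) and nx.has_path(H2, ru, rv))
            G.add_edge(u, v, steps=w, in_all_msts=forced)
        for _, u, v in useful:
            ds.union(u, v)
    return G


def build_nj_tree(steps: StepMatrix) -> str:
    """Neighbor-joining tree over haplotype steps, as a newick string.

    Negative branch lengths produced by the NJ agglomeration are clamped to
    zero with a warning.  Raises :class:`DegenerateTreeError` for fewer
    than three haplotypes.
    """
    if len(steps.ids) < 3:
        raise DegenerateTreeError("neighbor joining needs at least 3 haplotypes")
    dm = DistanceMatrix(steps.matrix.astype(float), steps.ids)
    tree = nj(dm)
    clamped = False
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0", stacklevel=2)
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()
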