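"""Step matrices, minimum-spanning networks (vs exhaustive spanning-tree
enumeration) and neighbor joining (vs additive-tree recovery)."""

import itertools

import networkx as nx
import numpy as np
import pytest

from plastdiv.alignment import AlignedGenomeSet
from plastdiv.diversity import collapse_haplotypes
from plastdiv.errors import DegenerateTreeError
from plastdiv.network import StepMatrix, build_msn, build_nj_tree, pairwise_steps


def steps_from(ids, entries):
    k = len(ids)
    m = np.zeros((k, k), dtype=np.int64)
    for (a, b), w in entries.items():
        i, j = ids.index(a), ids.index(b)
        m[i, j] = m[j, i] = w
    return StepMatrix(list(ids), m)


def all_mst_edges(steps):
    """Oracle: enumerate every spanning tree, keep the minimum-weight ones,
    return the union of their edge sets."""
    ids = steps.ids
    edges = [
        (ids[i], ids[j], int(steps.matrix[i, j]))
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    ]
    best_w = None
    union = set()
    for combo in itertools.combinations(edges, len(ids) - 1):
        G = nx.Graph()
        G.add_nodes_from(ids)
        G.add_weighted_edges_from(combo)
        if not nx.is_connected(G):
            continue
        w = sum(e[2] for e in combo)
        if best_w is None or w < best_w:
            best_w = w
            union = {frozenset((e[0], e[1])) for e in combo}
        elif w == best_w:
            union |= {frozenset((e[0], e[1])) for e in combo}
    return union


class TestPairwiseSteps:
    def test_hand_counted_matrix(self):
        rows = {
            "a": "AAAA", "b": "AAAT", "c": "AATT", "d": "TTTT",
        }
        aln = AlignedGenomeSet.from_sequences(rows, "a")
        tab = collapse_haplotypes(aln)
        steps = pairwise_steps(tab, aln)
        assert steps.step("Hap1", "Hap2") == 1
        assert steps.step("Hap1", "Hap4") == 4
        assert steps.step("Hap2", "Hap3") == 1
        assert np.array_equal(steps.matrix, steps.matrix.T)
        assert (np.diag(steps.matrix) == 0).all()

    def test_star_genealogy_steps_are_branch_budget_sums(self, sim, bundle):
        """On a star genealogy, the step distance between two haplotypes is
        the sum of their planted branch budgets (disjoint mutation sets)."""
        from collections import Counter

        # IR SNPs are mirrored into both copies, so they contribute two
        # differing columns each
        budgets = Counter(t.haplotype for t in sim.truth.snps)
        budgets.update(t.haplotype for t in sim.truth.snps if t.region == "IR")
        steps = bundle.steps
        for i, a in enumerate(steps.ids):
            for b in steps.ids[i + 1 :]:
                assert steps.step(a, b) == budgets[a] + budgets[b]

    def test_gap_columns_excluded(self):
        rows = {"a": "AA-A", "b": "AATA", "c": "TA-A"}
        aln = AlignedGenomeSet.from_sequences(rows, "a")
        tab = collapse_haplotypes(aln)
        steps = pairwise_steps(tab, aln)
        # column 2 has a gap; only column 0 is a usable SNP column
        assert steps.matrix.max() == 1


class TestBuildMsn:
    def test_chain_topology(self):
        steps = steps_from(
            ["H1", "H2", "H3"], {("H1", "H2"): 1, ("H2", "H3"): 1, ("H1", "H3"): 2}
        )
        G = build_msn(steps)
        assert set(map(frozenset, G.edges())) == {
            frozenset(("H1", "H2")), frozenset(("H2", "H3")),
        }

    def test_two_haplotypes_single_edge(self):
        steps = steps_from(["H1", "H2"], {("H1", "H2"): 3})
        G = build_msn(steps)
        assert list(G.edges(data="steps")) == [("H1", "H2", 3)]

    def test_equilateral_tie_keeps_all_edges(self):
        steps = steps_from(
            ["H1", "H2", "H3"], {("H1", "H2"): 1, ("H2", "H3"): 1, ("H1", "H3"): 1}
        )
        G = build_msn(steps)
        assert G.number_of_edges() == 3
        assert not any(d["in_all_msts"] for _, _, d in G.edges(data=True))

    @pytest.mark.parametrize("seed", range(8))
    def test_union_of_all_msts_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(4, 8))
        ids = [f"H{i}" for i in range(k)]
        m = rng.integers(1, 5, size=(k, k))
        m = np.triu(m, 1)
        m = m + m.T
        steps = StepMatrix(ids, m)
        G = build_msn(steps)
        got = {frozenset(e) for e in G.edges()}
        assert got == all_mst_edges(steps)

    def test_contains_a_spanning_tree(self, bundle):
        G = bundle.msn
        assert nx.is_connected(G)
        assert G.number_of_edges() >= G.number_of_nodes() - 1
        assert all(d["steps"] >= 1 for _, _, d in G.edges(data=True))

    def test_node_frequencies(self, bundle):
        freqs = sorted(
            (d["frequency"] for _, d in bundle.msn.nodes(data=True)), reverse=True
        )
        assert freqs == [11, 4, 2, 1, 1, 1, 1, 1]


def tree_path_lengths(newick, ids):
    import io

    from skbio import TreeNode

    t = TreeNode.read(io.StringIO(newick))
    out = {}
    for a, b in itertools.combinations(ids, 2):
        out[(a, b)] = t.find(a).distance(t.find(b))
    return out


class TestBuildNjTree:
    def test_three_taxon_closed_form(self):
        steps = steps_from(
            ["A", "B", "C"], {("A", "B"): 2, ("A", "C"): 4, ("B", "C"): 4}
        )
        newick = build_nj_tree(steps)
        d = tree_path_lengths(newick, ["A", "B", "C"])
        assert d[("A", "B")] == pytest.approx(2)
        assert d[("A", "C")] == pytest.approx(4)
        assert d[("B", "C")] == pytest.approx(4)

    def test_degenerate_inputs_rejected(self):
        steps = steps_from(["A", "B"], {("A", "B"): 1})
        with pytest.raises(DegenerateTreeError):
            build_nj_tree(steps)

    def test_zero_distances_give_zero_branches(self):
        steps = steps_from(["A", "B", "C"], {})
        newick = build_nj_tree(steps)
        d = tree_path_lengths(newick, ["A", "B", "C"])
        assert all(v == 0 for v in d.values())

    @pytest.mark.parametrize("seed", range(6))
    def test_recovers_random_additive_trees(self, seed):
        """NJ reproduces the exact pairwise distances of random additive
        trees with up to 8 taxa."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(4, 9))
        ids = [f"T{i}" for i in range(k)]
        # random binary tree by sequential attachment, integer branch lengths
        G = nx.Graph()
        G.add_edge(ids[0], ids[1], length=int(rng.integers(1, 6)))
        internal = 0
        for leaf in ids[2:]:
            u, v = list(G.edges())[rng.integers(0, G.number_of_edges())]
            w = G.edges[u, v]["length"]
            internal += 1
            mid = f"I{internal}"
            split = int(rng.integers(0, w + 1))
            G.remove_edge(u, v)
            G.add_edge(u, mid, length=split)
            G.add_edge(mid, v, length=w - split)
            G.add_edge(mid, leaf, length=int(rng.integers(1, 6)))
        dist = {}
        m = np.zeros((k, k))
        for i, a in enumerate(ids):
            for j in range(i + 1, k):
                d = nx.shortest_path_length(G, a, ids[j], weight="length")
                m[i, j] = m[j, i] = d
        steps = StepMatrix(ids, m.astype(np.int64))
        newick = build_nj_tree(steps)
        got = tree_path_lengths(newick, ids)
        for (a, b), v in got.items():
            assert v == pytest.approx(m[ids.index(a), ids.index(b)], abs=1e-6)
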