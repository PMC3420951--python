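"""Neighbour joining against hand solutions, additivity, and scikit-bio."""

import numpy as np
import pytest

from dinobarcode.distance import DistanceMatrix
from dinobarcode.njtree import annotate_groups, neighbor_joining
from dinobarcode.delimitation import SpeciesGroup

from conftest import make_dm


def leaf_lengths(tree):
    return {leaf.name: leaf.length for leaf in tree.root.leaves()}


def canonical_side(side, all_leaves):
    """The smaller (then lexicographically first) side of a bipartition."""
    comp = frozenset(all_leaves - side)
    return min(side, comp, key=lambda s: (len(s), tuple(sorted(s))))


def normalised_splits(bipartitions, all_leaves):
    out = {}
    for side, length in bipartitions.items():
        out[canonical_side(side, all_leaves)] = length
    return out


def random_additive_tree(rng, n):
    """Random unrooted binary tree; returns (edges dict, leaf list, D matrix).

    Built by repeatedly splitting a random edge to attach a new leaf;
    distances are path sums, so the matrix is exactly additive.
    """
    # nodes: 0..n-1 leaves, internal nodes get ids >= n
    next_internal = [n]
    edges = {}  # frozenset({u, v}) -> length

    def add_edge(u, v):
        edges[frozenset((u, v))] = round(float(rng.uniform(0.02, 0.3)), 4)

    center = next_internal[0]
    next_internal[0] += 1
    for leaf in range(3):
        add_edge(center, leaf)
    for leaf in range(3, n):
        edge = list(edges)[int(rng.integers(len(edges)))]
        u, v = tuple(edge)
        length = edges.pop(edge)
        mid = next_internal[0]
        next_internal[0] += 1
        edges[frozenset((u, mid))] = round(length / 2, 6)
        edges[frozenset((mid, v))] = round(length - length / 2, 6)
        add_edge(mid, leaf)

    adj = {}
    for edge, length in edges.items():
        u, v = tuple(edge)
        adj.setdefault(u, []).append((v, length))
        adj.setdefault(v, []).append((u, length))
    D = np.zeros((n, n))
    for src in range(n):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, length in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + length
                    stack.append(v)
        for dst in range(n):
            D[src, dst] = dist[dst]
    if D.max() > 0.95:  # keep path distances on the p-distance scale
        scale = 0.95 / D.max()
        D *= scale
        edges = {e: length * scale for e, length in edges.items()}
    return edges, D


def true_split_lengths(edges, leaves, n):
    """Map each edge of the true tree to its leaf split and length."""
    adj = {}
    for edge, length in edges.items():
        u, v = tuple(edge)
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def side_leaves(start, blocked):
        seen = {blocked, start}
        stack = [start]
        out = set()
        while stack:
            u = stack.pop()
            if u < n:
                out.add(f"t{u}")
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return frozenset(out)

    all_leaves = frozenset(f"t{i}" for i in range(n))
    out = {}
    for edge, length in edges.items():
        u, v = tuple(edge)
        side = side_leaves(u, v)
        out[canonical_side(side, all_leaves)] = length
    return out


class TestNeighborJoining:
    def test_three_taxon_hand_solution(self):
        dm = make_dm(["a", "b", "c"],
                     {("a", "b"): 0.2, ("a", "c"): 0.3, ("b", "c"): 0.4})
        tree = neighbor_joining(dm)
        assert leaf_lengths(tree) == pytest.approx(
            {"a": 0.05, "b": 0.15, "c": 0.25})

    def test_two_taxon_trivial_tree(self):
        dm = make_dm(["a", "b"], {("a", "b"): 0.3})
        tree = neighbor_joining(dm)
        assert leaf_lengths(tree) == pytest.approx({"a": 0.15, "b": 0.15})

    def test_additive_four_taxon_exact(self):
        # tree ((a:0.1, b:0.2):0.05, c:0.3, d:0.4) -> additive matrix
        dm = make_dm(["a", "b", "c", "d"], {
            ("a", "b"): 0.3, ("a", "c"): 0.45, ("a", "d"): 0.55,
            ("b", "c"): 0.55, ("b", "d"): 0.65, ("c", "d"): 0.7,
        })
        tree = neighbor_joining(dm)
        leaves = tree.leaf_names
        splits = normalised_splits(tree.bipartitions(), leaves)
        assert splits[frozenset({"a"})] == pytest.approx(0.1)
        assert splits[frozenset({"b"})] == pytest.approx(0.2)
        # the ab|cd internal edge is recovered with its length
        assert splits[frozenset({"a", "b"})] == pytest.approx(0.05)

    def test_identical_leaves_become_zero_length_siblings(self):
        dm = make_dm(["a", "b", "c", "d"], {
            ("a", "b"): 0.0, ("a", "c"): 0.3, ("a", "d"): 0.3,
            ("b", "c"): 0.3, ("b", "d"): 0.3, ("c", "d"): 0.2,
        })
        tree = neighbor_joining(dm)
        splits = normalised_splits(tree.bipartitions(), tree.leaf_names)
        assert frozenset({"a", "b"}) in splits  # the identical pair is a cherry
        assert splits[frozenset({"a"})] == pytest.approx(0.0)
        assert splits[frozenset({"b"})] == pytest.approx(0.0)

    def test_negative_estimates_clamped_raw_kept(self):
        # a non-additive matrix that drives one estimate negative
        dm = make_dm(["a", "b", "c", "d"], {
            ("a", "b"): 0.1, ("a", "c"): 0.1, ("a", "d"): 0.4,
            ("b", "c"): 0.1, ("b", "d"): 0.4, ("c", "d"): 0.4,
        })
        tree = neighbor_joining(dm)
        for node in tree.root.walk():
            if node.length is not None:
                assert node.length >= 0.0
                if node.raw_length is not None and node.raw_length < 0:
                    assert node.length == 0.0

    def test_deterministic_newick(self):
        rng = np.random.default_rng(0)
        _, D = random_additive_tree(rng, 9)
        ids = tuple(f"t{i}" for i in range(9))
        dm = DistanceMatrix(ids=ids, values=D, policy="complete_deletion", n_sites=100)
        assert neighbor_joining(dm).newick() == neighbor_joining(dm).newick()

    def test_edge_count_is_2n_minus_3(self):
        rng = np.random.default_rng(1)
        for n in (4, 7, 12):
            _, D = random_additive_tree(rng, n)
            ids = tuple(f"t{i}" for i in range(n))
            dm = DistanceMatrix(ids=ids, values=D, policy="complete_deletion",
                                n_sites=100)
            tree = neighbor_joining(dm)
            assert tree.n_edges() == 2 * n - 3
            assert tree.leaf_names == frozenset(ids)

    @pytest.mark.parametrize("seed", range(8))
    def test_additive_matrices_recovered_exactly(self, seed):
        """Topology and branch lengths recovered from additive matrices."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 17))
        edges, D = random_additive_tree(rng, n)
        ids = tuple(f"t{i}" for i in range(n))
        dm = DistanceMatrix(ids=ids, values=D, policy="complete_deletion",
                            n_sites=100)
        tree = neighbor_joining(dm)
        got = normalised_splits(tree.bipartitions(), tree.leaf_names)
        want = true_split_lengths(edges, tree.leaf_names, n)
        assert set(got) == set(want)
        for split in want:
            assert got[split] == pytest.approx(want[split], abs=1e-9)

    def test_matches_scikit_bio_topology(self):
        """Independent cross-check against scikit-bio's NJ on a random matrix."""
        import skbio

        rng = np.random.default_rng(42)
        n = 8
        v = rng.uniform(0.05, 0.5, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        ids = tuple(f"t{i}" for i in range(n))
        dm = DistanceMatrix(ids=ids, values=v, policy="complete_deletion",
                            n_sites=100)
        ours = neighbor_joining(dm)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(v, ids))
        our_splits = {
            s for s in normalised_splits(ours.bipartitions(), ours.leaf_names)
            if 1 < len(s) < n - 1
        }
        their_splits = set()
        all_leaves = frozenset(ids)
        for node in theirs.traverse(include_self=False):
            side = frozenset(t.name for t in node.tips()) or frozenset({node.name})
            key = canonical_side(side, all_leaves)
            if 1 < len(key) < n - 1:
                their_splits.add(key)
        assert our_splits == their_splits


class TestAnnotateGroups:
    @staticmethod
    def tree_and_groups():
        dm = make_dm(["a", "b", "c", "d", "e"], {
            ("a", "b"): 0.02, ("c", "d"): 0.02, ("a", "c"): 0.3, ("a", "d"): 0.3,
            ("a", "e"): 0.4, ("b", "c"): 0.3, ("b", "d"): 0.3, ("b", "e"): 0.4,
            ("c", "e"): 0.4, ("d", "e"): 0.4,
        })
        return neighbor_joining(dm)

    def test_cherry_group_is_monophyletic(self):
        tree = self.tree_and_groups()
        reports = annotate_groups(tree, [SpeciesGroup(1, ("a", "b"), "G1", "confirmed_species")])
        assert reports[0].monophyletic

    def test_split_group_is_not_monophyletic(self):
        tree = self.tree_and_groups()
        reports = annotate_groups(tree, [SpeciesGroup(1, ("a", "c"), "bad", "new_group")])
        assert not reports[0].monophyletic

    def test_member_missing_from_tree_warns(self):
        tree = self.tree_and_groups()
        with pytest.warns(UserWarning, match="not on the tree"):
            reports = annotate_groups(
                tree, [SpeciesGroup(1, ("a", "b", "zz"), "G1", "confirmed_species")])
        assert reports[0].n_on_tree == 2
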