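"""Distances, neighbor joining and bootstrap support."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from codonbias import phylogeny as ph


# --- oracle: random additive matrices from random trees ---------------------

def random_additive(rng, n_taxa):
    """Build a random unrooted binary tree over n_taxa with positive branch
    lengths; return (taxon labels, distance matrix, set of bipartitions)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # start from a 3-star, attach remaining taxa to random edges
    # represent tree as edge list between node ids; leaves carry labels
    nodes = {0: None}
    edges = {}  # (a, b) -> length, a<b
    next_id = 1

    def add_edge(a, b, ln):
        edges[(min(a, b), max(a, b))] = ln

    leaf_ids = {}
    for i in range(3):
        leaf_ids[labels[i]] = next_id
        add_edge(0, next_id, rng.uniform(0.1, 1.0))
        next_id += 1
    internal_next = [next_id]

    for label in labels[3:]:
        (a, b) = list(edges)[rng.integers(len(edges))]
        ln = edges.pop((a, b))
        mid = internal_next[0]
        internal_next[0] += 1
        split = rng.uniform(0.2, 0.8) * ln
        add_edge(a, mid, split)
        add_edge(mid, b, ln - split)
        leaf = internal_next[0]
        internal_next[0] += 1
        leaf_ids[label] = leaf
        add_edge(mid, leaf, rng.uniform(0.1, 1.0))

    # all-pairs shortest paths (tree, so BFS)
    import collections

    adj = collections.defaultdict(list)
    for (a, b), ln in edges.items():
        adj[a].append((b, ln))
        adj[b].append((a, ln))

    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, ln in adj[u]:
                if v not in out:
                    out[v] = out[u] + ln
                    stack.append(v)
        return out

    n = len(labels)
    D = np.zeros((n, n))
    for i, la in enumerate(labels):
        dd = dists_from(leaf_ids[la])
        for j, lb in enumerate(labels):
            D[i, j] = dd[leaf_ids[lb]]
    D = (D + D.T) / 2  # BFS float round-off can break exact symmetry
    np.fill_diagonal(D, 0.0)

    # bipartitions: removing each internal edge splits leaves
    id_to_label = {v: k for k, v in leaf_ids.items()}
    taxa = frozenset(labels)
    first = min(taxa)
    parts = set()
    for (a, b) in edges:
        # side of b when edge (a,b) removed
        seen = {a, b}
        stack = [b]
        side = set()
        while stack:
            u = stack.pop()
            if u in id_to_label:
                side.add(id_to_label[u])
            for v, _ in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        side_f = frozenset(side)
        if 2 <= len(side_f) <= n - 2:
            parts.add(taxa - side_f if first in side_f else side_f)
    return labels, D, parts


class TestDistances:
    def test_identical_sequences_zero(self):
        aln = {"a": "AUGGCU", "b": "AUGGCU"}
        assert ph.p_distance(aln)["a", "b"] == 0.0
        assert ph.k2p_distance(aln)["a", "b"] == 0.0

    def test_p_distance_quarter(self):
        d = ph.p_distance({"a": "AAAA", "b": "AAAU"})
        assert d["a", "b"] == pytest.approx(0.25)

    def test_p_distance_matches_column_scan(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGU"))
        s1 = "".join(rng.choice(bases, 300))
        s2 = "".join(rng.choice(bases, 300))
        expected = sum(a != b for a, b in zip(s1, s2)) / 300
        assert ph.p_distance({"x": s1, "y": s2})["x", "y"] == pytest.approx(expected)

    def test_gapped_ambiguous_columns_ignored(self):
        d = ph.p_distance({"a": "A-ANU", "b": "AUAGU"})
        # only columns 1, 3, 5 comparable; one mismatch (G vs N dropped, - dropped)
        assert d["a", "b"] == pytest.approx(0.0)

    def test_k2p_closed_form(self):
        # 10% transitions, no transversions
        s1 = "A" * 100
        s2 = "G" * 10 + "A" * 90
        d = ph.k2p_distance({"a": s1, "b": s2})
        assert d["a", "b"] == pytest.approx(-0.5 * np.log(0.8), rel=1e-12)

    def test_k2p_saturation_names_pair(self):
        aln = {"a": "AG" * 50, "b": "GA" * 50}
        with pytest.raises(ph.PhylogenyError, match="a / b"):
            ph.k2p_distance(aln)

    def test_k2p_simulation_recovery(self):
        """Pairs simulated under the K2P process recover the true distance
        within Monte-Carlo error (transition matrix via expm oracle)."""
        from scipy.linalg import expm

        alpha, beta, t = 0.6, 0.3, 0.4  # d = (alpha + 2 beta) t
        order = "AGCU"
        Q = np.zeros((4, 4))
        for i, x in enumerate(order):
            for j, y in enumerate(order):
                if i == j:
                    continue
                transition = {x, y} in ({"A", "G"}, {"C", "U"})
                Q[i, j] = alpha if transition else beta
        np.fill_diagonal(Q, -Q.sum(axis=1))
        P = expm(Q * t)
        rng = np.random.default_rng(17)
        n = 60000
        anc = rng.integers(0, 4, size=n)
        der = np.array([rng.choice(4, p=P[a]) for a in anc])
        aln = {
            "anc": "".join(order[i] for i in anc),
            "der": "".join(order[i] for i in der),
        }
        d = ph.k2p_distance(aln)["anc", "der"]
        true_d = (alpha + 2 * beta) * t
        assert d == pytest.approx(true_d, abs=0.01)

    def test_length_mismatch(self):
        with pytest.raises(ph.PhylogenyError):
            ph.p_distance({"a": "AAA", "b": "AAAA"})


class TestNeighborJoining:
    def test_three_taxa_exact(self):
        D = DistanceMatrix([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]],
                           ids=["a", "b", "c"])
        tree = ph.neighbor_joining(D)
        tips = {t.name: t.length for t in tree.tips()}
        # three-point formulas
        assert tips["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert tips["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert tips["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_four_taxon_additive_recovery(self):
        rng = np.random.default_rng(0)
        labels, D, parts = random_additive(rng, 4)
        tree = ph.neighbor_joining(DistanceMatrix(D, ids=labels))
        assert ph.tree_bipartitions(tree) == parts
        # reconstructed path lengths reproduce the additive matrix
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    ta = tree.find(a)
                    assert ta.distance(tree.find(b)) == pytest.approx(D[i, j], abs=1e-9)

    def test_additive_matrices_up_to_8_taxa(self):
        rng = np.random.default_rng(100)
        for trial in range(30):
            n = int(rng.integers(4, 9))
            labels, D, parts = random_additive(rng, n)
            tree = ph.neighbor_joining(DistanceMatrix(D, ids=labels))
            assert ph.tree_bipartitions(tree) == parts, f"trial {trial}"

    def test_too_few_taxa(self):
        with pytest.raises(ph.PhylogenyError):
            ph.neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))

    def test_matches_skbio_nj_topology(self):
        """Cross-check against scikit-bio's independent NJ on a random
        (noisy, non-additive) matrix: same topology."""
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(7)
        labels, D, _ = random_additive(rng, 6)
        D = D + rng.uniform(0, 0.01, D.shape)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        dm = DistanceMatrix(D, ids=labels)
        mine = ph.tree_bipartitions(ph.neighbor_joining(dm))
        theirs = ph.tree_bipartitions(skbio_nj(dm))
        assert mine == theirs

    def test_cohort_groups_are_monophyletic(self, default_cohort):
        aln = {r.isolate_id: r.concatenated for r in default_cohort.regions}
        tree = ph.neighbor_joining(ph.k2p_distance(aln))
        parts = ph.tree_bipartitions(tree)
        taxa = frozenset(aln)
        first = min(taxa)
        for lab in set(default_cohort.group_labels):
            side = frozenset(
                r.isolate_id
                for r, g in zip(default_cohort.regions, default_cohort.group_labels)
                if g == lab
            )
            canon = taxa - side if first in side else side
            assert canon in parts, f"group {lab} not monophyletic"


class TestBootstrap:
    def _clade_alignment(self, n_sites=600, seed=5):
        """Three 3-taxon clades with strong within-clade similarity."""
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGU"))
        aln = {}
        for g in range(3):
            anc = rng.choice(bases, n_sites)
            for i in range(3):
                seq = anc.copy()
                mut = rng.random(n_sites) < 0.02
                seq[mut] = rng.choice(bases, mut.sum())
                aln[f"g{g}x{i}"] = "".join(seq)
        return aln

    def test_identical_sequences_star_tree(self):
        aln = {f"s{i}": "AUGGCUAAAGGG" for i in range(5)}
        tree = ph.bootstrap_support(aln, replicates=10, seed=1, distance="p")
        # zero-length internal edges collapse: star tree, no bipartitions
        assert ph.tree_bipartitions(tree) == set()
        assert all(t.length == 0.0 for t in tree.tips())

    def test_strong_clades_supported(self):
        aln = self._clade_alignment()
        tree = ph.bootstrap_support(aln, replicates=100, seed=3, distance="p")
        parts_support = {}
        taxa = frozenset(aln)
        first = min(taxa)
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if first in side:
                side = taxa - side
            if node.name:
                parts_support[side] = float(node.name)
        for g in range(3):
            clade = frozenset(f"g{g}x{i}" for i in range(3))
            canon = taxa - clade if first in clade else clade
            assert parts_support.get(canon, 0) >= 95

    def test_seed_determinism_and_order_invariance(self):
        aln = self._clade_alignment(n_sites=300)
        t1 = ph.write_newick(ph.bootstrap_support(aln, replicates=25, seed=9, distance="p"))
        t2 = ph.write_newick(ph.bootstrap_support(aln, replicates=25, seed=9, distance="p"))
        shuffled = dict(reversed(list(aln.items())))
        t3 = ph.write_newick(ph.bootstrap_support(shuffled, replicates=25, seed=9, distance="p"))
        assert t1 == t2 == t3


class TestNewick:
    def test_three_taxon_newick(self):
        D = DistanceMatrix([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]],
                           ids=["a", "b", "c"])
        text = ph.write_newick(ph.neighbor_joining(D))
        assert text.endswith(";")
        back = ph.read_newick(text)
        assert sorted(t.name for t in back.tips()) == ["a", "b", "c"]

    def test_round_trip_topology_and_lengths(self):
        rng = np.random.default_rng(12)
        labels, D, parts = random_additive(rng, 6)
        tree = ph.neighbor_joining(DistanceMatrix(D, ids=labels))
        back = ph.read_newick(ph.write_newick(tree))
        assert ph.tree_bipartitions(back) == parts
        for lab in labels:
            assert back.find(lab).length == pytest.approx(tree.find(lab).length)

    def test_independent_parser_accepts_output(self):
        """dendropy (an independent Newick implementation) parses our trees."""
        import dendropy

        rng = np.random.default_rng(13)
        labels, D, _ = random_additive(rng, 7)
        text = ph.write_newick(ph.neighbor_joining(DistanceMatrix(D, ids=labels)))
        t = dendropy.Tree.get(data=text, schema="newick")
        assert len(t.leaf_nodes()) == 7
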