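"""Distance-based neighbor-joining phylogeny with bootstrap support.

The tree stage consumes an already-aligned set of equal-length sequences
(alignment itself is out of scope here). Distances are p-distance or the
Kimura two-parameter correction; trees come from the Saitou-Nei
neighbor-joining agglomeration with deterministic tie-breaking (taxa are
processed in sorted label order), and internal-edge support is the
percentage of column-resampled replicate trees containing each bipartition.
Containers are scikit-bio's DistanceMatrix and TreeNode, so Newick I/O is
the standard library path.
"""

from __future__ import annotations

import io
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .genetic_code import rna

logger = logging.getLogger("codonbias")

_UNAMBIG = frozenset("ACGU")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CU")


class PhylogenyError(ValueError):
    pass


Alignment = Mapping[str, str]


def _canonical(alignment: Alignment) -> tuple[list[str], list[str]]:
    """Sorted labels and RNA-normalized sequences; validates equal lengths."""
    labels = sorted(alignment)
    if len(labels) < 2:
        raise PhylogenyError("alignment needs at least 2 sequences")
    seqs = [rna(alignment[l]) for l in labels]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise PhylogenyError(f"aligned sequences differ in length: {sorted(lengths)}")
    return labels, seqs


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned multi-FASTA into a label -> sequence map."""
    from Bio import SeqIO

    out = {str(r.id): str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    if not out:
        raise PhylogenyError(f"no sequences in {path}")
    return out


# base codes: A=0, G=1 (purines), C=2, U=3 (pyrimidines); -1 = other
_CODE = np.full(128, -1, dtype=np.int8)
for _b, _v in (("A", 0), ("G", 1), ("C", 2), ("U", 3)):
    _CODE[ord(_b)] = _v


def _encode(seqs: Sequence[str]) -> np.ndarray:
    mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return _CODE[mat].reshape(len(seqs), -1)


def _pair_fractions_enc(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """(transition fraction P, transversion fraction Q, #valid columns),
    ignoring gapped or ambiguous columns."""
    ok = (a >= 0) & (b >= 0)
    valid = int(ok.sum())
    if valid == 0:
        raise PhylogenyError("no comparable (ungapped, unambiguous) columns")
    x, y = a[ok], b[ok]
    diff = x != y
    # same purine/pyrimidine class -> transition
    ts = int((diff & ((x >> 1) == (y >> 1))).sum())
    tv = int(diff.sum()) - ts
    return ts / valid, tv / valid, valid


def _pair_fractions(a: str, b: str) -> tuple[float, float, int]:
    enc = _encode([a, b])
    return _pair_fractions_enc(enc[0], enc[1])


def _distance_from_encoded(labels: list[str], enc: np.ndarray, kind: str) -> DistanceMatrix:
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p, q, _ = _pair_fractions_enc(enc[i], enc[j])
            if kind == "p":
                d[i, j] = d[j, i] = p + q
            else:
                w1 = 1.0 - 2.0 * p - q
                w2 = 1.0 - 2.0 * q
                if w1 <= 0 or w2 <= 0:
                    raise PhylogenyError(
                        f"saturated pair {labels[i]} / {labels[j]}: "
                        "K2P log argument non-positive"
                    )
                d[i, j] = d[j, i] = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    return DistanceMatrix(d, ids=labels)


def p_distance(alignment: Alignment) -> DistanceMatrix:
    """Pairwise mismatch proportion over ungapped, unambiguous columns."""
    labels, seqs = _canonical(alignment)
    return _distance_from_encoded(labels, _encode(seqs), "p")


def k2p_distance(alignment: Alignment) -> DistanceMatrix:
    """Kimura two-parameter distance: d = -ln(1-2P-Q)/2 - ln(1-2Q)/4."""
    labels, seqs = _canonical(alignment)
    return _distance_from_encoded(labels, _encode(seqs), "k2p")


def _clamp(length: float, context: str) -> float:
    if length < 0:
        if length < -1e-9:
            logger.warning("negative NJ branch length %.3g at %s clamped to 0", length, context)
        return 0.0
    return length


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcating
    root) with non-negative branch lengths.

    Ties in the Q criterion are broken by (sorted) label order, so the
    result is deterministic for any input order of taxa.
    """
    ids = sorted(dm.ids)
    n = len(ids)
    if n < 3:
        raise PhylogenyError("neighbor joining needs at least 3 taxa")
    # work on a plain dict-of-dicts over active nodes
    nodes: dict[str, TreeNode] = {l: TreeNode(name=l) for l in ids}
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            d[(a, b)] = d[(b, a)] = float(dm[a, b])
    active = list(ids)
    counter = 0

    def dist(a: str, b: str) -> float:
        return 0.0 if a == b else d[(a, b)]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active) for a in active}
        best = None
        best_q = np.inf
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best  # type: ignore[misc]
        la = 0.5 * dist(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        lb = dist(a, b) - la
        new_name = f"_nj{counter}"
        counter += 1
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length = _clamp(la, f"{a}")
        child_b.length = _clamp(lb, f"{b}")
        nodes[new_name] = TreeNode(children=[child_a, child_b])
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
            d[(new_name, c)] = d[(c, new_name)] = duc
        active = [x for x in active if x not in (a, b)] + [new_name]

    a, b, c = active
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    for name, length in ((a, la), (b, lb), (c, lc)):
        nodes[name].length = _clamp(length, name)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    # collapse zero-length internal edges into polytomies, so e.g. identical
    # sequences give a star tree rather than an arbitrary resolution
    for node in [n for n in root.postorder(include_self=False) if not n.is_tip()]:
        if (node.length or 0.0) <= 1e-12:
            parent = node.parent
            parent.remove(node)
            parent.extend(node.children)
    return root


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalized as
    the side not containing the alphabetically first taxon."""
    taxa = frozenset(t.name for t in tree.tips())
    first = min(taxa)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        if first in side:
            side = taxa - side
        parts.add(side)
    return parts


def bootstrap_support(
    alignment: Alignment,
    replicates: int = 1000,
    seed: int = 0,
    distance: str = "k2p",
) -> TreeNode:
    """NJ tree with internal-edge bootstrap percentages.

    Alignment columns are resampled with replacement ``replicates`` times;
    each internal edge of the full-data tree is annotated (``node.name``)
    with the percentage of replicate trees containing its bipartition.
    Results depend only on the seed, not on taxon input order.
    """
    if replicates < 1:
        raise PhylogenyError("need at least 1 bootstrap replicate")
    if distance not in ("k2p", "p"):
        raise PhylogenyError(f"unknown distance {distance!r}")
    labels, seqs = _canonical(alignment)
    enc = _encode(seqs)  # taxa x sites
    n_sites = enc.shape[1]
    main_tree = neighbor_joining(_distance_from_encoded(labels, enc, distance))

    taxa = frozenset(labels)
    first = min(taxa)
    tally: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        idx = rng.integers(0, n_sites, size=n_sites)
        try:
            btree = neighbor_joining(
                _distance_from_encoded(labels, enc[:, idx], distance)
            )
        except PhylogenyError:
            continue  # saturated / degenerate replicate
        for part in tree_bipartitions(btree):
            tally[part] = tally.get(part, 0) + 1

    for node in main_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        if first in side:
            side = taxa - side
        pct = 100.0 * tally.get(side, 0) / replicates
        node.name = f"{pct:.0f}"
    return main_tree


def write_newick(tree: TreeNode) -> str:
    """Serialize to Newick (branch lengths; internal names carry support)."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), format="newick")
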