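"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap.

Neighbor joining (Saitou–Nei) agglomerates taxa by minimizing the
Q-criterion

    Q(i,j) = (m - 2) d(i,j) - r_i - r_j,   r_i = sum_k d(i,k)

over the current m nodes, with the standard branch-length formulas. On an
additive distance matrix NJ recovers the generating tree exactly, with
path lengths between leaves equal to the input distances. Ties in the
Q-minimization break on the lowest (i, j) index pair so results are
platform-independent; negative branch-length estimates are clamped to
zero and the deficit shifted to the sibling edge.

Bootstrap support for each internal bipartition of the full-data tree is
the percentage of column-resampled replicates whose NJ tree contains that
bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Node",
    "p_distance",
    "poisson_distance",
    "nj",
    "bipartitions",
    "bootstrap",
    "to_newick",
    "from_newick",
]


@dataclass
class Node:
    """A node of an (un)rooted tree; leaves carry a name."""

    name: str | None = None
    children: list[tuple["Node", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


def _pairwise_mismatch(a: str, b: str) -> float:
    gaps = set("-.")
    mism = comp = 0
    for ca, cb in zip(a, b):
        if ca in gaps or cb in gaps:
            continue
        comp += 1
        if ca != cb:
            mism += 1
    if comp == 0:
        raise ValueError("no comparable (ungapped) sites between two sequences")
    return mism / comp


def p_distance(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distance matrix; gapped columns excluded pairwise."""
    ids = list(alignment)
    if len(ids) < 2:
        raise ValueError("need at least two taxa")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    m = len(ids)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = _pairwise_mismatch(alignment[ids[i]], alignment[ids[j]])
    return ids, d


def poisson_distance(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Poisson-corrected distance -ln(1 - p) from the p-distance."""
    ids, d = p_distance(alignment)
    if (d >= 1).any():
        raise ValueError("p-distance of 1 cannot be Poisson-corrected")
    return ids, -np.log1p(-d)


def nj(taxa: list[str], dist: np.ndarray) -> Node:
    """Neighbor-joining tree from a symmetric distance matrix.

    Returns an unrooted tree represented by a root node of degree 3 (or a
    2-leaf cherry for the degenerate 2-taxon input). For >= 3 taxa the
    final three nodes are joined in a single multifurcating root.
    """
    n = len(taxa)
    if dist.shape != (n, n):
        raise ValueError("matrix shape does not match taxa")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[Node] = [Node(name=t) for t in taxa]
    d = dist.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among ties, scanning row-major upper triangle
        best = (np.inf, -1, -1)
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] < best[0] - 1e-12:
                    best = (q[a, b], a, b)
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))
        lj = dij - li
        # clamp negative estimates, pushing the deficit onto the sibling
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new = Node(children=[(nodes[i], li), (nodes[j], lj)])
        nodes.append(new)
        k = len(nodes) - 1
        newrow = np.zeros(k + 1)
        grown = np.zeros((k + 1, k + 1))
        grown[:k, :k] = d
        for other in active:
            if other in (i, j):
                continue
            grown[k, other] = grown[other, k] = 0.5 * (d[i, other] + d[j, other] - dij)
        d = grown
        active = [a for a in active if a not in (i, j)] + [k]
    # join the final three nodes at one internal vertex
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return Node(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])


def bipartitions(tree: Node) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge splits the leaf set in two; the split is recorded
    as the smaller side (ties by sorted names) so that it is invariant to
    rooting and taxon order.
    """
    all_leaves = frozenset(tree.leaves())
    splits: set[frozenset] = set()

    def walk(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            side = walk(child)
            if 1 < len(side) < len(all_leaves) - 1:
                other = all_leaves - side
                canon = min(side, other, key=lambda s: (len(s), sorted(s)))
                splits.add(canon)
            below |= side
        return below

    walk(tree)
    return splits


def _pairwise_from_alignment(alignment, model):
    if model == "p":
        return p_distance(alignment)
    if model == "poisson":
        return poisson_distance(alignment)
    raise ValueError(f"unknown distance model {model!r}")


def bootstrap(
    alignment: dict[str, str],
    n_reps: int = 1000,
    seed: int | None = None,
    model: str = "p",
) -> Node:
    """NJ tree of the full alignment with bootstrap supports (percent).

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of each internal bipartition of the full-data tree is the
    percentage of replicate trees containing it. ``n_reps=0`` returns the
    tree without supports.
    """
    ids, d = _pairwise_from_alignment(alignment, model)
    tree = nj(ids, d)
    if n_reps == 0:
        return tree
    rng = np.random.default_rng(seed)
    length = len(next(iter(alignment.values())))
    mats = {tid: np.frombuffer(seq.encode(), dtype="S1") for tid, seq in alignment.items()}
    counts: dict[frozenset, int] = {split: 0 for split in bipartitions(tree)}
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = {
            tid: mats[tid][cols].tobytes().decode() for tid in alignment
        }
        rep_ids, rep_d = _pairwise_from_alignment(resampled, model)
        rep_splits = bipartitions(nj(rep_ids, rep_d))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    supports = {split: 100.0 * c / n_reps for split, c in counts.items()}
    all_leaves = frozenset(tree.leaves())

    def annotate(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            below |= annotate(child)
        if 1 < len(below) < len(all_leaves) - 1:
            other = all_leaves - below
            canon = min(below, other, key=lambda s: (len(s), sorted(s)))
            node.support = supports.get(canon)
        return below

    annotate(tree)
    return tree


def to_newick(tree: Node) -> str:
    """Newick string with branch lengths and supports as internal labels."""

    def render(node: Node, length: float | None) -> str:
        if node.is_leaf:
            body = node.name
        else:
            inner = ",".join(render(c, bl) for c, bl in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            body = f"({inner}){label}"
        return body if length is None else f"{body}:{length:.6g}"

    return render(tree, None) + ";"


def from_newick(text: str) -> Node:
    """Parse a newick string with branch lengths (and internal labels)."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse() -> tuple[Node, float | None]:
        nonlocal pos
        node = Node()
        if s[pos] == "(":
            pos += 1
            while True:
                child, bl = parse()
                node.children.append((child, 0.0 if bl is None else bl))
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        # label (leaf name or internal support)
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        if label:
            if node.is_leaf:
                node.name = label
            else:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        length: float | None = None
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            length = float(s[start:pos])
        return node, length

    root, _ = parse()
    if pos != len(s):
        raise ValueError(f"trailing characters in newick string at {pos}")
    return root
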