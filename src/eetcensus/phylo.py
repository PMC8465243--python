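"""16S rRNA identity, distance matrices and neighbor-joining phylogeny.

Distances are p-distance (proportion of mismatched sites under pairwise
deletion of gap/N sites; a common default for 16S trees) or its
Jukes-Cantor correction -(3/4)ln(1 - 4p/3).  Tree building is the
Saitou-Nei neighbor-joining algorithm with the standard Q criterion,
deterministic tie-breaking (lexicographically smallest cluster pair) and
negative branch lengths clamped to zero.  Branch support comes from
nonparametric bootstrap over alignment columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner

GAP_CHARS = set("-.")


def pairwise_identity(a: str, b: str, match: float = 1.0,
                      mismatch: float = -1.0, gap_open: float = 2.0,
                      gap_extend: float = 0.5) -> float:
    """Percent identity of two nucleotide sequences after global alignment.

    Identity is identical columns over columns with a residue in BOTH
    sequences: end and internal gap columns are excluded from the
    denominator.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    # canonical argument order: co-optimal alignments depend on order,
    # so fix it to make identity exactly symmetric
    a, b = sorted((a.upper(), b.upper()))
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    compared = counts.identities + counts.mismatches
    if compared == 0:
        raise ValueError("no comparable columns between sequences")
    return 100.0 * counts.identities / compared


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("nonzero diagonal")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")


def distance_matrix(seqs: Sequence[tuple[str, str]],
                    model: str = "p") -> DistanceMatrix:
    """Pairwise distances from an aligned set (pairwise deletion).

    Sites where either sequence has a gap or N are excluded per pair.
    ``model`` is ``"p"`` or ``"jukes_cantor"``.
    """
    if model not in ("p", "jukes_cantor"):
        raise ValueError(f"unknown model {model!r}")
    if len(seqs) < 3:
        raise ValueError("need at least 3 taxa")
    lengths = {len(s) for _, s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    taxa = [t for t, _ in seqs]
    arr = np.array([list(s.upper()) for _, s in seqs])
    bad = np.isin(arr, list(GAP_CHARS | {"N"}))
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(bad[i] | bad[j])
            compared = int(ok.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable sites between {taxa[i]} and {taxa[j]}")
            p = float((arr[i, ok] != arr[j, ok]).sum()) / compared
            if model == "jukes_cantor":
                if p >= 0.75:
                    raise ValueError(
                        f"Jukes-Cantor saturation (p={p:.3f} >= 0.75) "
                        f"between {taxa[i]} and {taxa[j]}")
                p = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(taxa, d)


@dataclass
class TreeNode:
    name: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree rendered with a basal multifurcation."""

    root: TreeNode
    clamped_branches: int = 0

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def newick(self, supports: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name or ""
            inner = ",".join(f"{fmt(c)}:{bl:g}" for c, bl in node.children)
            label = ""
            if supports and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}"
        return fmt(self.root) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Nontrivial splits as frozenset{side, complement} of leaf names."""
        all_leaves = frozenset(self.leaf_names())
        splits: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if 2 <= len(below) <= len(all_leaves) - 2:
                splits.add(frozenset([below, all_leaves - below]))
            return below

        for c, _ in self.root.children:
            walk(c)
        return splits

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (sums of branch lengths)."""
        names = sorted(self.leaf_names())
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: dict[str, float] = {}
            per_child = []
            for c, bl in node.children:
                sub = {k: v + bl for k, v in walk(c).items()}
                per_child.append(sub)
                below.update(sub)
            for i in range(len(per_child)):
                for j in range(i + 1, len(per_child)):
                    for na, da in per_child[i].items():
                        for nb, db in per_child[j].items():
                            d[idx[na], idx[nb]] = d[idx[nb], idx[na]] = da + db
            return below

        walk(self.root)
        return DistanceMatrix(names, d)

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        from Bio import Phylo

        clade_tree = Phylo.read(io.StringIO(text), "newick")

        def convert(clade) -> tuple[TreeNode, float]:
            node = TreeNode(name=clade.name)
            if clade.clades:
                if clade.confidence is not None:
                    node.support = float(clade.confidence)
                elif clade.name is not None:
                    # newick internal labels hold supports
                    try:
                        node.support = float(clade.name)
                        node.name = None
                    except ValueError:
                        pass
                node.children = [convert(c) for c in clade.clades]
            return node, float(clade.branch_length or 0.0)

        root, _ = convert(clade_tree.root)
        return cls(root)


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Joins are chosen by minimal Q = (n-2)d_ij - r_i - r_j; ties are broken
    by the lexicographically smallest pair of cluster representatives
    (the smallest leaf label in each cluster).  Negative branch lengths
    are clamped to 0 and counted in ``clamped_branches``.
    """
    n = len(D.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = {(i, j): float(D.d[i, j]) for i in range(n) for j in range(n)}
    nodes: dict[int, TreeNode] = {i: TreeNode(name=t) for i, t in enumerate(D.taxa)}
    reps: dict[int, str] = {i: t for i, t in enumerate(D.taxa)}
    pending: dict[int, float] = {}  # node id -> branch length to its parent
    active = list(range(n))
    next_id = n
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 2:
        m = len(active)
        r = {i: sum(d[(i, k)] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[(i, j)] - r[i] - r[j]
                pair_key = tuple(sorted((reps[i], reps[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = d[(i, j)] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[(i, j)] - li
        u = next_id
        next_id += 1
        nodes[u] = TreeNode(children=[(nodes[i], clamp(li)),
                                      (nodes[j], clamp(lj))])
        reps[u] = min(reps[i], reps[j])
        for k in active:
            if k in (i, j):
                continue
            duk = (d[(i, k)] + d[(j, k)] - d[(i, j)]) / 2
            d[(u, k)] = d[(k, u)] = duk
        d[(u, u)] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]

    i, j = active
    edge = clamp(d[(i, j)])
    # render unrooted: graft the second cluster onto the first internal node
    if not nodes[i].is_leaf:
        root = nodes[i]
        root.children.append((nodes[j], edge))
    else:
        root = nodes[j]
        root.children.append((nodes[i], edge))
    return Tree(root, clamped)


def nj_tree(seqs: Sequence[tuple[str, str]], model: str = "p") -> Tree:
    return neighbor_joining(distance_matrix(seqs, model))


def bootstrap_support(alignment: Sequence[tuple[str, str]],
                      n_replicates: int, seed: int,
                      model: str = "p") -> Tree:
    """NJ tree on the full alignment with bootstrap supports.

    Columns are resampled with replacement per replicate; the support of
    each internal bipartition of the full-data tree is the percentage of
    replicate trees containing it.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    full = nj_tree(alignment, model)
    splits = full.bipartitions()
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    names = [t for t, _ in alignment]
    cols = np.array([list(s) for _, s in alignment])  # taxa x sites
    n_sites = cols.shape[1]
    for _ in range(n_replicates):
        pick = rng.integers(0, n_sites, size=n_sites)
        rep = [(names[i], "".join(cols[i, pick])) for i in range(len(names))]
        try:
            rep_splits = nj_tree(rep, model).bipartitions()
        except ValueError:
            continue  # saturated / incomparable replicate
        for s in splits:
            if s in rep_splits:
                counts[s] += 1

    all_leaves = frozenset(full.leaf_names())

    def annotate(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c) for c, _ in node.children))
        split = frozenset([below, all_leaves - below])
        if split in counts:
            node.support = 100.0 * counts[split] / n_replicates
        return below

    for c, _ in full.root.children:
        annotate(c)
    return full
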