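"""Independent oracles used by the test suite.

Each oracle is a deliberately naive, separately written implementation
(brute-force enumeration or textbook dynamic programming) used only to
check the package; none shares code with the implementation under test.
"""

from __future__ import annotations

import re

import numpy as np
from Bio.Align import substitution_matrices

# ---------------------------------------------------------------------------
# heme-motif oracle: enumerate every C(X)nCH occurrence with regex
# lookaheads, then resolve overlaps left-to-right, shortest spacer first.

_MOTIF_RES = {n: re.compile(rf"(?=(C.{{{n}}}CH))") for n in (2, 3, 4)}


def brute_force_motif_scan(protein: str, n_min: int = 2, n_max: int = 4
                           ) -> list[tuple[int, int]]:
    seq = protein.rstrip("*").upper()
    if "*" in seq:
        return []
    occurrences: list[tuple[int, int]] = []
    for n in range(n_min, n_max + 1):
        for m in _MOTIF_RES[n].finditer(seq):
            occurrences.append((m.start(), n))
    occurrences.sort()  # by start, then shortest spacer
    chosen: list[tuple[int, int]] = []
    cursor = 0
    for start, n in occurrences:
        if start >= cursor:
            chosen.append((start, n))
            cursor = start + n + 3  # past the matched histidine
    return chosen


# ---------------------------------------------------------------------------
# textbook Gotoh local alignment (affine gaps), quadratic space.
# Gap of length k costs open + k * extend (BLAST convention).

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(a: str, b: str, gap_open: int = 11,
                      gap_extend: int = 1) -> float:
    first = gap_open + gap_extend
    la, lb = len(a), len(b)
    NEG = -1e9
    M = np.full((la + 1, lb + 1), 0.0)
    X = np.full((la + 1, lb + 1), NEG)  # gap in b (consume a)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in a (consume b)
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            X[i, j] = max(M[i - 1, j] - first, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - first, Y[i, j - 1] - gap_extend)
            M[i, j] = max(0.0,
                          max(M[i - 1, j - 1], X[i - 1, j - 1],
                              Y[i - 1, j - 1]) + s)
            best = max(best, M[i, j])
    return best


# ---------------------------------------------------------------------------
# random binary trees with an independent path-sum distance oracle.


def random_additive_tree(n_taxa: int, rng: np.random.Generator,
                         min_bl: float = 0.1, max_bl: float = 2.0):
    """Random binary tree; returns (newick, distance dict, split set).

    Distances are accumulated by explicit path sums at each join, kept
    independent of any tree class in the package.
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    # each cluster: (newick, {leaf: depth}, leafset)
    clusters = [(lab, {lab: 0.0}, frozenset([lab])) for lab in labels]
    dist: dict[frozenset, float] = {}
    splits: set[frozenset] = set()
    all_leaves = frozenset(labels)
    while len(clusters) > 2:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        ci = clusters.pop(j)
        cj = clusters.pop(i)
        bi, bj = rng.uniform(min_bl, max_bl, size=2)
        for x, dx in ci[1].items():
            for y, dy in cj[1].items():
                dist[frozenset([x, y])] = dx + bi + dy + bj
        depths = {x: d + bi for x, d in ci[1].items()}
        depths.update({y: d + bj for y, d in cj[1].items()})
        leafset = ci[2] | cj[2]
        if 2 <= len(leafset) <= n_taxa - 2:
            splits.add(frozenset([leafset, all_leaves - leafset]))
        nwk = f"({ci[0]}:{bi:.6f},{cj[0]}:{bj:.6f})"
        clusters.append((nwk, depths, leafset))
    (na, da, sa), (nb, db, sb) = clusters
    bl = float(rng.uniform(min_bl, max_bl))
    for x, dx in da.items():
        for y, dy in db.items():
            dist[frozenset([x, y])] = dx + dy + bl
    for side in (sa, sb):
        if 2 <= len(side) <= n_taxa - 2:
            splits.add(frozenset([side, all_leaves - side]))
    newick = f"({na}:{bl:.6f},{nb}:0.0);"
    return newick, labels, dist, splits


def mutate_preserving_motifs(seq: str, truth: list[tuple[int, int]],
                             fraction: float, seed: int,
                             alphabet: str = "ADEFGIKLMNPQRSTVWY") -> str:
    """Point-mutate a motif-planted protein without touching its motifs."""
    rng = np.random.default_rng(seed)
    protected = set()
    for start, n in truth:
        protected.update(range(start, start + n + 3))
    free = [i for i in range(len(seq)) if i not in protected]
    rng.shuffle(free)
    chars = list(seq)
    for p in free[: int(fraction * len(seq))]:
        options = [c for c in alphabet if c != chars[p]]
        chars[p] = options[rng.integers(0, len(options))]
    return "".join(chars)
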