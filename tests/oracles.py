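"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming / greedy code
paths: alignment scores come from exhaustive enumeration of alignment
paths, clustering from a separately written greedy loop over an all-pairs
identity matrix, additive distances from explicit trees, and SASA from a
naive all-pairs point-in-sphere count.
"""

from __future__ import annotations

import math
import random
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from skbio import TreeNode

from gpxprx.alignment import _INDEX, load_matrix

NEG = float("-inf")


def brute_force_best_score(
    a: str, b: str, matrix: str = "blosum62",
    gap_open: float = 10.0, gap_extend: float = 1.0,
) -> float:
    """Optimal global affine-gap score by exhaustive path enumeration.

    Every alignment is a lattice path of diagonal / up / left moves with no
    dual-gap columns; a gap run of length k costs open + (k-1)*extend.
    Exponential — use only for short sequences.
    """
    S = load_matrix(matrix)
    n, m = len(a), len(b)
    best = NEG

    # stack of (i, j, state, score); state: 0 none/match, 1 gap-in-b, 2 gap-in-a
    stack = [(0, 0, 0, 0.0)]
    while stack:
        i, j, state, score = stack.pop()
        if i == n and j == m:
            if score > best:
                best = score
            continue
        if i < n and j < m:
            stack.append(
                (i + 1, j + 1, 0, score + S[_INDEX[a[i]], _INDEX[b[j]]])
            )
        if i < n:
            stack.append(
                (i + 1, j, 1, score - (gap_extend if state == 1 else gap_open))
            )
        if j < m:
            stack.append(
                (i, j + 1, 2, score - (gap_extend if state == 2 else gap_open))
            )
    return best


def brute_force_optimal_identities(
    a: str, b: str, matrix: str = "blosum62",
    gap_open: float = 10.0, gap_extend: float = 1.0,
) -> Set[float]:
    """Fractional identities of *all* score-optimal global alignments."""
    S = load_matrix(matrix)
    n, m = len(a), len(b)
    best = brute_force_best_score(a, b, matrix, gap_open, gap_extend)
    out: Set[float] = set()
    # (i, j, state, score, matches, columns)
    stack = [(0, 0, 0, 0.0, 0, 0)]
    while stack:
        i, j, state, score, matches, cols = stack.pop()
        if i == n and j == m:
            if abs(score - best) < 1e-9:
                out.add(matches / cols if cols else 0.0)
            continue
        if i < n and j < m:
            stack.append(
                (i + 1, j + 1, 0, score + S[_INDEX[a[i]], _INDEX[b[j]]],
                 matches + (a[i] == b[j]), cols + 1)
            )
        if i < n:
            stack.append(
                (i + 1, j, 1, score - (gap_extend if state == 1 else gap_open),
                 matches, cols + 1)
            )
        if j < m:
            stack.append(
                (i, j + 1, 2, score - (gap_extend if state == 2 else gap_open),
                 matches, cols + 1)
            )
    return out


def reference_greedy_cluster(
    ids: Sequence[str],
    lengths: Dict[str, int],
    identity: Dict[Tuple[str, str], float],
    threshold: float,
) -> List[Tuple[str, List[str]]]:
    """Independent implementation of the longest-first greedy rule.

    ``identity`` maps unordered id pairs to fractional identity.
    """

    def ident(x: str, y: str) -> float:
        return identity[(x, y)] if (x, y) in identity else identity[(y, x)]

    order = sorted(ids, key=lambda i: (-lengths[i], i))
    clusters: List[Tuple[str, List[str]]] = []
    for rid in order:
        placed = False
        for k, (rep, members) in enumerate(clusters):
            if ident(rid, rep) > threshold:
                clusters[k] = (rep, members + [rid])
                placed = True
                break
        if not placed:
            clusters.append((rid, [rid]))
    return clusters


def random_additive_tree(n: int, rng: random.Random) -> TreeNode:
    """Random unrooted binary tree over taxa t0..t{n-1} with branch lengths
    in [0.1, 1.0], represented with a trifurcating root."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    for nd in nodes:
        nd.length = rng.uniform(0.1, 1.0)
    while len(nodes) > 3:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        parent = TreeNode()
        parent.length = rng.uniform(0.1, 1.0)
        parent.append(nodes.pop(i))
        parent.append(nodes.pop(j))
        nodes.append(parent)
    root = TreeNode()
    for nd in nodes:
        root.append(nd)
    return root


def tree_distance_matrix(tree: TreeNode) -> Tuple[List[str], np.ndarray]:
    """Path-length (additive) distances between all leaf pairs."""
    ids = sorted(t.name for t in tree.tips())
    dm = tree.tip_tip_distances(endpoints=ids)
    return ids, np.asarray(dm.data, dtype=float)


def naive_sasa_point_count(
    coords: np.ndarray, radii: np.ndarray, probe: float, points: np.ndarray
) -> np.ndarray:
    """Per-atom SASA by checking every sample point against every other atom."""
    n = len(coords)
    ext = radii + probe
    areas = np.zeros(n)
    for i in range(n):
        free = 0
        for p in coords[i] + ext[i] * points:
            buried = False
            for j in range(n):
                if j == i:
                    continue
                if np.dot(p - coords[j], p - coords[j]) <= ext[j] ** 2:
                    buried = True
                    break
            if not buried:
                free += 1
        areas[i] = 4.0 * math.pi * ext[i] ** 2 * free / len(points)
    return areas
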