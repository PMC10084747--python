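"""Distance-based phylogeny: p-distance / Poisson-corrected distances,
Saitou–Nei neighbor joining, column-resampling bootstrap, and the two
summary statistics used to describe a radiation — star-likeness (fraction of
poorly supported internal edges) and phylum mixing (how scattered each
phylum is across the tree).

Trees are :class:`skbio.TreeNode` objects (unrooted, trifurcating root);
bootstrap supports live on internal nodes as ``node.support`` (0–100) and
are serialized as internal node labels in Newick.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import numpy as np
from skbio import DistanceMatrix, TreeNode

if TYPE_CHECKING:  # pragma: no cover
    from .alignment import Alignment

from .records import GAP

log = logging.getLogger(__name__)


class PhylogenyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# distances


def distance_matrix(aln: "Alignment", model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances from an alignment.

    ``p_distance``: mismatches / shared non-gap columns.
    ``poisson``: −ln(1 − p), the Poisson correction for multiple hits.

    A pair with no shared non-gap columns, or with p ≥ 1 under the Poisson
    model, is an error naming the pair.
    """
    if model not in ("p_distance", "poisson"):
        raise PhylogenyError(f"unknown distance model {model!r}")
    ids = list(aln.ids)
    if len(ids) < 3:
        raise PhylogenyError("need at least 3 rows for a distance matrix")
    M = aln.matrix()
    nongap = M != GAP
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            ns = int(shared.sum())
            if ns == 0:
                raise PhylogenyError(
                    f"no shared non-gap columns between {ids[i]!r} and {ids[j]!r}"
                )
            p = float((M[i, shared] != M[j, shared]).sum()) / ns
            if model == "poisson":
                if p >= 1.0:
                    raise PhylogenyError(
                        f"Poisson distance undefined (p={p}) for pair "
                        f"{ids[i]!r}, {ids[j]!r}"
                    )
                d = -np.log(1.0 - p)
            else:
                d = p
            D[i, j] = D[j, i] = d
    return DistanceMatrix(D, ids)


def mask_gap_columns(aln: "Alignment", max_gap_fraction: float = 0.5) -> "Alignment":
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``.

    Used before tree building to remove large-gap regions (such as an
    oligomerization-loop insertion carried by a minority of rows).
    """
    M = aln.matrix()
    gap_frac = (M == GAP).mean(axis=0)
    keep = [c + 1 for c in range(aln.n_columns) if gap_frac[c] <= max_gap_fraction]
    return aln.subset_columns(keep)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    The pair with minimal Q is joined; ties take the lowest (row, column)
    index pair.  Negative branch-length estimates are clamped to 0 and
    flagged (``node.length_clamped``).  Returns an unrooted tree represented
    with a trifurcating root.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise PhylogenyError("neighbor joining needs at least 3 taxa")
    D = np.array(dm.data, dtype=float)
    nodes: List[TreeNode] = [TreeNode(name=name) for name in ids]

    def clamp(x: float, node: TreeNode) -> float:
        if x < 0:
            node.length_clamped = True
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest flat index among minima -> lowest (i, j) pair
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length = clamp(li, a)
        b.length = clamp(lj, b)
        parent.append(a)
        parent.append(b)
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]

    # final three nodes: three-point formulas
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    root = TreeNode()
    a.length = clamp(0.5 * (dab + dac - dbc), a)
    b.length = clamp(0.5 * (dab + dbc - dac), b)
    c.length = clamp(0.5 * (dac + dbc - dab), c)
    for nd in (a, b, c):
        root.append(nd)
    return root


# ---------------------------------------------------------------------------
# bipartitions / Robinson–Foulds


def bipartitions(tree: TreeNode) -> Set[FrozenSet[str]]:
    """Non-trivial splits of an unrooted tree, canonicalized.

    Each internal edge induces a split of the leaf set; the split is
    represented by the side *not* containing the lexicographically smallest
    leaf, so representation is rooting-independent.
    """
    leaves = sorted(t.name for t in tree.tips())
    full = set(leaves)
    anchor = leaves[0]
    out: Set[FrozenSet[str]] = set()
    for node in tree.non_tips(include_self=False):
        below = {t.name for t in node.tips()}
        side = below if anchor not in below else full - below
        if 2 <= len(side) <= len(full) - 2:
            out.add(frozenset(side))
    return out


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Symmetric-difference (Robinson–Foulds) distance between two unrooted trees."""
    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    if l1 != l2:
        raise PhylogenyError("trees have different leaf sets")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    aln: "Alignment",
    model: str = "poisson",
    n_reps: int = 100,
    seed: int = 0,
) -> TreeNode:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    is re-aligned into a tree and internal-edge support is the percentage of
    successful replicates containing the same bipartition.  Replicates whose
    resampled rows are all identical are skipped (counted in
    ``tree.n_skipped_replicates``); the support denominator is the number of
    successful replicates.
    """
    from .alignment import Alignment  # local import avoids a cycle

    if n_reps < 1:
        raise PhylogenyError("n_reps must be >= 1")
    tree = neighbor_joining(distance_matrix(aln, model))
    rng = np.random.default_rng(seed)
    counts: Dict[FrozenSet[str], int] = {}
    n_ok = 0
    n_skip = 0
    ncol = aln.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rows = {
            rid: "".join(aln.rows[rid][c] for c in cols) for rid in aln.ids
        }
        if len(set(rows.values())) == 1:
            n_skip += 1
            log.warning("bootstrap replicate skipped: all resampled rows identical")
            continue
        rep_aln = Alignment(list(aln.ids), rows)
        try:
            rep_tree = neighbor_joining(distance_matrix(rep_aln, model))
        except PhylogenyError:
            n_skip += 1
            log.warning("bootstrap replicate skipped: undefined distances")
            continue
        n_ok += 1
        for split in bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1

    leaves = sorted(t.name for t in tree.tips())
    full = set(leaves)
    anchor = leaves[0]
    for node in tree.non_tips(include_self=False):
        below = {t.name for t in node.tips()}
        side = frozenset(below if anchor not in below else full - below)
        if not 2 <= len(side) <= len(full) - 2:
            continue
        node.support = (
            100.0 * counts.get(side, 0) / n_ok if n_ok else 0.0
        )
    tree.n_skipped_replicates = n_skip
    tree.n_bootstrap_replicates = n_ok
    return tree


def star_likeness(tree: TreeNode, support_threshold: float = 70.0) -> float:
    """Fraction of internal edges with bootstrap support below threshold.

    A value near 1 indicates a star-like radiation: essentially no internal
    edge is confidently resolved.  Trees without internal edges return 0
    with a warning.
    """
    supports = [
        node.support
        for node in tree.non_tips(include_self=False)
        if getattr(node, "support", None) is not None
    ]
    if not supports:
        warnings.warn("tree has no supported internal edges; star_likeness = 0")
        return 0.0
    return sum(s < support_threshold for s in supports) / len(supports)


# ---------------------------------------------------------------------------
# phylum mixing


@dataclass
class PhylumMixing:
    """Scatter of phyla over the tree.

    ``clades_per_phylum`` counts, for each phylum, the maximal monophyletic
    groups consisting only of that phylum (1 = perfectly clustered; equal to
    the leaf count = maximally scattered).  ``mixing_index`` is the mean of
    clades/leaves over phyla, in (0, 1]: small = clustered, near 1 = mixed.
    """

    clades_per_phylum: Dict[str, int]
    leaves_per_phylum: Dict[str, int]

    @property
    def mixing_index(self) -> float:
        ratios = [
            self.clades_per_phylum[p] / self.leaves_per_phylum[p]
            for p in self.clades_per_phylum
        ]
        return float(np.mean(ratios))


def phylum_mixing(tree: TreeNode, labels: Dict[str, str]) -> PhylumMixing:
    """Count maximal monophyletic same-phylum clades per phylum.

    The tree is read as rooted at its (trifurcating) root node; every leaf
    must appear in ``labels``.
    """
    tips = list(tree.tips())
    missing = [t.name for t in tips if t.name not in labels]
    if missing:
        raise PhylogenyError(f"unlabeled leaves: {missing}")
    leaves_per: Dict[str, int] = {}
    for t in tips:
        leaves_per[labels[t.name]] = leaves_per.get(labels[t.name], 0) + 1

    pure: Dict[int, Optional[str]] = {}
    for node in tree.postorder():
        if node.is_tip():
            pure[id(node)] = labels[node.name]
        else:
            kinds = {pure[id(ch)] for ch in node.children}
            pure[id(node)] = kinds.pop() if len(kinds) == 1 and None not in kinds else None

    clades: Dict[str, int] = {p: 0 for p in leaves_per}
    for node in tree.traverse(include_self=True):
        p = pure[id(node)]
        if p is None:
            continue
        parent = node.parent
        if parent is None or pure[id(parent)] != p:
            clades[p] += 1
    return PhylumMixing(clades, leaves_per)


# ---------------------------------------------------------------------------
# Newick I/O


def to_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialize to Newick, writing supports as internal node labels."""
    clone = tree.copy()
    for node in clone.non_tips(include_self=False):
        sup = getattr(node, "support", None)
        if sup is not None:
            node.name = f"{sup:g}"
            node.support = None  # else the writer would emit the value twice
    txt = str(clone)
    if path is not None:
        Path(path).write_text(txt)
    return txt


def read_newick(source: str | Path) -> TreeNode:
    """Read a Newick tree; numeric internal labels become ``node.support``."""
    import io

    text = str(source)
    try:
        is_file = Path(text).exists()
    except OSError:
        is_file = False
    if isinstance(source, Path) or is_file:
        text = Path(text).read_text()
    tree = TreeNode.read(io.StringIO(text), format="newick")
    for node in tree.non_tips(include_self=False):
        if node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
    return tree
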