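"""Distance-based phylogeny: neighbor joining, bootstrap, Newick I/O.

Distances come from percent identity (p-distance ``p = 1 - id/100``,
optionally Jukes-Cantor corrected). Trees are built with the Saitou-Nei
neighbor-joining algorithm, implemented here with fixed deterministic
rules: the pair minimizing the Q-criterion is joined, ties broken by
the smallest (row, column) index pair in the current matrix order, and
negative branch lengths are clamped to zero with a log entry. The
result is the fully resolved unrooted tree, represented as a
:class:`skbio.TreeNode` rooted at the final trifurcation.

Bootstrap supports are computed by resampling alignment columns with
replacement, rebuilding distance + NJ per replicate, and mapping the
percentage of replicates containing each leaf bipartition onto the
internal edges of the full-data tree.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .core_seq import GAP, NucSeq
from .identity import IdentityMatrix

logger = logging.getLogger(__name__)


class NewickParseError(ValueError):
    """Malformed Newick input, with the character offset of the defect."""


def to_distance(m: IdentityMatrix, correction: str = "none") -> DistanceMatrix:
    """Convert a percent-identity matrix to evolutionary distances.

    ``none`` gives the uncorrected p-distance ``p = 1 - identity/100``;
    ``jukes_cantor`` applies ``d = -(3/4) ln(1 - 4p/3)``, which is
    undefined (error) at ``p >= 0.75``.
    """
    p = 1.0 - np.asarray(m.values, dtype=float) / 100.0
    if correction == "none":
        d = p
    elif correction == "jukes_cantor":
        if np.any(p[~np.eye(len(m.labels), dtype=bool)] >= 0.75):
            raise ValueError("Jukes-Cantor correction undefined for p >= 0.75")
        d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(m.labels))


def _clamped(length: float, context: str) -> float:
    if length < 0:
        logger.info("%s: clamping negative branch length %.4g to 0", context, length)
        return 0.0
    return length


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining on a distance matrix (n >= 3).

    Returns an unrooted tree (root node of degree 3) with branch lengths;
    exact on additive matrices.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    # canonical label order: ties in Q are broken by the smallest (i, j)
    # pair in this order, so the tree is invariant to input row order
    order = sorted(range(n), key=lambda k: str(dm.ids[k]))
    D = np.array(dm.data, dtype=float)[np.ix_(order, order)]
    nodes: list[TreeNode] = [TreeNode(name=dm.ids[k]) for k in order]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # first occurrence in row-major order = smallest (i, j) tie-break
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        a, b = nodes[i], nodes[j]
        a.length = _clamped(li, "nj join")
        b.length = _clamped(lj, "nj join")
        parent = TreeNode(children=[a, b])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D2[m - 2, : m - 2] = D2[: m - 2, m - 2] = dnew[keep]
        D2[m - 2, m - 2] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]

    # terminal three-taxon join: closed-form branch lengths
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = _clamped(0.5 * (dab + dac - dbc), "nj final")
    b.length = _clamped(0.5 * (dab + dbc - dac), "nj final")
    c.length = _clamped(0.5 * (dac + dbc - dab), "nj final")
    return TreeNode(children=[a, b, c])


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions of an unrooted tree.

    Each internal edge splits the leaves in two; the side not containing
    the lexicographically smallest leaf is the canonical representative,
    so the set is invariant to (re)rooting.
    """
    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    two trees' non-trivial bipartition sets."""
    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


def _aligned_rows(rows: Sequence[NucSeq]) -> np.ndarray:
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("rows have unequal lengths (input must be aligned)")
    return np.array([list(r.residues) for r in rows])


def p_distance_from_alignment(rows: Sequence[NucSeq]) -> DistanceMatrix:
    """Pairwise p-distances over alignment columns.

    For each pair, only columns where both rows are gap-free are counted;
    a difference is any pair of non-identical symbols.
    """
    if len(rows) < 3:
        raise ValueError("need at least 3 aligned rows")
    chars = _aligned_rows(rows)
    nongap = chars != GAP
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = nongap[i] & nongap[j]
            total = int(valid.sum())
            if total == 0:
                raise ValueError(
                    f"rows {rows[i].id!r} and {rows[j].id!r} share no gap-free columns"
                )
            diff = int((chars[i][valid] != chars[j][valid]).sum())
            d[i, j] = d[j, i] = diff / total
    return DistanceMatrix(d, ids=[r.id for r in rows])


def bootstrap_supports(
    rows: Sequence[NucSeq],
    n_replicates: int = 1000,
    seed: int | None = None,
    correction: str = "none",
) -> TreeNode:
    """NJ tree from an alignment with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement ``n_replicates``
    times; each replicate is rebuilt (distance matrix + NJ) and the
    support of every internal edge of the full-data tree is the
    percentage of replicates whose tree contains the same leaf
    bipartition. Supports are stored as internal node names (integer
    percent). Deterministic for a fixed seed and input order.
    """
    if len(rows) < 3:
        raise ValueError("bootstrap needs at least 3 aligned rows")
    chars = _aligned_rows(rows)
    L = chars.shape[1]
    ids = [r.id for r in rows]

    def tree_from_chars(c: np.ndarray) -> TreeNode:
        sub = [NucSeq(i, "".join(row), allow_gaps=True) for i, row in zip(ids, c)]
        dm = p_distance_from_alignment(sub)
        if correction == "jukes_cantor":
            p = dm.data
            if np.any(p[~np.eye(len(ids), dtype=bool)] >= 0.75):
                raise ValueError("Jukes-Cantor correction undefined for p >= 0.75")
            d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            np.fill_diagonal(d, 0.0)
            dm = DistanceMatrix(d, ids=ids)
        return nj_tree(dm)

    full = tree_from_chars(chars)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(full)}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep_bps = bipartitions(tree_from_chars(chars[:, cols]))
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    leaves = frozenset(ids)
    anchor = min(leaves)
    for node in full.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = leaves - side
        if side in counts:
            node.name = str(round(100.0 * counts[side] / n_replicates))
    return full


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize a tree to Newick; branch lengths rounded to 6 significant
    digits, bootstrap supports written as internal node labels."""
    out = tree.copy()
    for node in out.traverse():
        if node.length is not None:
            node.length = _round_sig(float(node.length))
    out.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    """Parse a Newick file, reporting the character offset of unbalanced
    parentheses before delegating the full grammar to scikit-bio."""
    text = Path(path).read_text()
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at character {pos}")
    if depth != 0:
        raise NewickParseError(f"{depth} unclosed '(' at end of input")
    try:
        return TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise NewickParseError(f"newick parse failed: {exc}") from exc
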