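"""Pairwise identity, neighbor-joining trees and bootstrap-supported clusters.

Distances are 1 - fractional identity (optionally Poisson-corrected).  Trees
are built with the classic Saitou-Nei neighbor-joining agglomeration; branch
support comes from resampling alignment columns with replacement, rebuilding
the tree per replicate, and counting how often each bipartition recurs.
Clusters are the outermost clades whose bipartition support exceeds the
cutoff (the survey convention is > 50%) with at least ``min_size`` leaves;
everything outside such a clade stays unassigned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skbio.tree import TreeNode

from ._util import GAP_CODE, encode_rows

log = logging.getLogger(__name__)


def _as_rows(msa):
    """Accept {id: row} dicts, (ids, rows) pairs or bare row lists."""
    if isinstance(msa, dict):
        return list(msa.keys()), list(msa.values())
    if (isinstance(msa, (tuple, list)) and len(msa) == 2
            and not isinstance(msa[0], str)
            and len(msa[0]) == len(msa[1])
            and not isinstance(msa[1], str)):
        ids, rows = msa
        return [str(i) for i in ids], list(rows)
    rows = list(msa)
    return [str(i) for i in range(len(rows))], rows


def pairwise_identity(msa) -> np.ndarray:
    """Identity matrix over aligned rows.

    identity(i, j) = matches / columns where neither row has a gap.  A pair
    with zero comparable columns is undefined and reported as NaN with a
    warning.
    """
    _, rows = _as_rows(msa)
    return _identity_from_encoded(encode_rows(rows))


def _identity_from_encoded(enc: np.ndarray) -> np.ndarray:
    n = enc.shape[0]
    gap = enc == GAP_CODE
    ident = np.ones((n, n))
    for i in range(n):
        comparable = ~(gap[i] | gap[i + 1 :])
        matches = (enc[i] == enc[i + 1 :]) & comparable
        denom = comparable.sum(axis=1)
        with np.errstate(invalid="ignore"):
            vals = np.where(denom > 0, matches.sum(axis=1) / np.maximum(denom, 1),
                            np.nan)
        ident[i, i + 1 :] = vals
        ident[i + 1 :, i] = vals
    if np.isnan(ident).any():
        log.warning("some sequence pairs share no comparable columns; "
                    "their identity is undefined (NaN)")
    return ident


def distance_matrix(msa, correction: str | None = None) -> tuple[list, np.ndarray]:
    """(ids, distances) from an alignment; distance = 1 - identity.

    ``correction='poisson'`` applies the Poisson multiple-hit correction
    d = -ln(identity).
    """
    ids, rows = _as_rows(msa)
    ident = pairwise_identity((ids, rows))
    if correction is None:
        d = 1.0 - ident
    elif correction == "poisson":
        d = -np.log(np.clip(ident, 1e-12, None))
    else:
        raise ValueError(f"unknown distance correction {correction!r}")
    np.fill_diagonal(d, 0.0)
    return ids, d


def _validate_distances(d: np.ndarray) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ValueError("distance matrix must have a zero diagonal")
    if not np.isfinite(d).all():
        raise ValueError("distance matrix entries must be finite")


def nj_tree(ids, d: np.ndarray) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcating root).

    At each step the pair minimizing Q(i,j) = (r-2) d(i,j) - R_i - R_j is
    joined (ties break toward the lexicographically first index pair);
    branch lengths below zero are clamped to zero with the deficit shifted
    to the sister branch.
    """
    d = np.asarray(d, dtype=float).copy()
    _validate_distances(d)
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if len(ids) != n:
        raise ValueError("ids and distance matrix disagree in size")
    nodes = [TreeNode(name=str(t)) for t in ids]
    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)  # row-major: first min wins
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (rowsum[i] - rowsum[j]) / (2.0 * (r - 2))
        lj = dij - li
        if li < 0.0:
            li, lj = 0.0, dij
        elif lj < 0.0:
            li, lj = dij, 0.0
        a, b = active[i], active[j]
        parent = TreeNode(children=[nodes[a], nodes[b]])
        nodes[a].length = float(li)
        nodes[b].length = float(lj)
        new_d = 0.5 * (d[a, :] + d[b, :] - d[a, b])
        d[a, :] = new_d
        d[:, a] = new_d
        d[a, a] = 0.0
        nodes[a] = parent
        active.pop(j)
    # final three-way join: closed-form three-point branch lengths
    x, y, z = active
    lx = 0.5 * (d[x, y] + d[x, z] - d[y, z])
    ly = 0.5 * (d[x, y] + d[y, z] - d[x, z])
    lz = 0.5 * (d[x, z] + d[y, z] - d[x, y])
    root = TreeNode(children=[nodes[x], nodes[y], nodes[z]])
    for node, length in ((nodes[x], lx), (nodes[y], ly), (nodes[z], lz)):
        node.length = float(max(length, 0.0))
    return root


def bipartitions(tree: TreeNode, taxa: frozenset | None = None) -> dict:
    """Non-trivial bipartitions of an unrooted tree.

    Each is canonicalized as the frozenset of leaf names on the side *not*
    containing the lexicographically smallest taxon.  Returns a mapping
    {bipartition: node} (the node whose subtree is the named side, when the
    side is the node's own leaf set).
    """
    if taxa is None:
        taxa = frozenset(l.name for l in tree.tips())
    ref = min(taxa)
    out = {}
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(l.name for l in node.tips())
        if len(side) <= 1 or len(taxa - side) <= 1:
            continue
        key = taxa - side if ref in side else side
        out[key] = node
    return out


@dataclass
class ClusterAssignment:
    """Sequence -> cluster map from a bootstrap-supported tree."""

    assignments: dict  # sequence id -> cluster id (1..k) or None (unassigned)
    supports: dict  # cluster id -> bootstrap support percentage
    members: dict  # cluster id -> sorted tuple of sequence ids
    tree: TreeNode | None = None
    n_replicates: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def cluster_of(self, seq_id) -> int | None:
        return self.assignments.get(seq_id)


def bootstrap_clusters(
    msa,
    n_reps: int = 500,
    seed: int = 0,
    support_min: float = 50.0,
    min_size: int = 3,
    correction: str | None = None,
) -> ClusterAssignment:
    """Column-resampling bootstrap and extraction of supported clusters.

    Per replicate, alignment columns are resampled with replacement, the
    tree rebuilt, and bipartitions collected; the support of a branch is the
    percentage of replicates containing the same bipartition.  Clusters are
    the outermost clades of the original tree with support > ``support_min``
    and at least ``min_size`` leaves; nested qualifying clades are absorbed
    by the outermost one, and leaves outside every qualifying clade stay
    unassigned.
    """
    if n_reps < 100:
        raise ValueError("bootstrap needs at least 100 replicates")
    ids, rows = _as_rows(msa)
    if len(rows) < max(min_size, 3):
        log.warning("alignment has %d rows < min cluster size %d: no clusters",
                    len(rows), min_size)
        return ClusterAssignment(
            assignments={t: None for t in ids}, supports={}, members={},
        )
    enc = encode_rows(rows)
    n_cols = enc.shape[1]
    rng = np.random.default_rng(seed)

    def distances_from(cols: np.ndarray | None) -> np.ndarray:
        sub = enc if cols is None else enc[:, cols]
        ident = _identity_from_encoded(sub)
        if np.isnan(ident).any():
            raise ValueError("undefined distances (no comparable columns) in replicate")
        if correction is None:
            dist = 1.0 - ident
        elif correction == "poisson":
            dist = -np.log(np.clip(ident, 1e-12, None))
        else:
            raise ValueError(f"unknown distance correction {correction!r}")
        np.fill_diagonal(dist, 0.0)
        return dist

    def tree_from(cols: np.ndarray | None) -> TreeNode:
        return nj_tree(ids, distances_from(cols))

    d_original = distances_from(None)
    original = nj_tree(ids, d_original)
    taxa = frozenset(str(t) for t in ids)
    original_bip = bipartitions(original, taxa)
    counts = {bip: 0 for bip in original_bip}
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_bips = bipartitions(tree_from(cols), taxa)
        for bip in rep_bips:
            if bip in counts:
                counts[bip] += 1

    support_of_node: dict[int, float] = {}
    for bip, node in original_bip.items():
        node.name = None  # will carry integer support labels for newick output
        support_of_node[id(node)] = 100.0 * counts[bip] / n_reps
    for bip, node in original_bip.items():
        node.name = str(int(round(support_of_node[id(node)])))

    # Cluster extraction works on bipartition sides (the tree is unrooted,
    # so a cluster may sit on either side of its supporting edge).  A side
    # qualifies when its support clears the cutoff and it is large enough.
    # Two filters keep "the rest of the tree" from masquerading as a
    # cluster: a side containing two disjoint qualifying sides is a
    # backbone grouping (otherwise one stable deep split -- e.g. tight
    # families versus long-branch singletons -- would absorb every family
    # into a single mega-cluster), and a side must be cohesive -- every
    # member must be, on average over the original distances, at least as
    # close to its own side as to the rest.  Among the survivors, higher
    # support wins, then the outermost (larger) side; overlapping
    # candidates are dropped greedily.
    index_of = {str(t): i for i, t in enumerate(ids)}
    qualifying: list[tuple[frozenset, float]] = []
    seen_sides = set()
    for bip, node in original_bip.items():
        sup = support_of_node[id(node)]
        if sup <= support_min:
            continue
        side = frozenset(l.name for l in node.tips())
        for s in (side, taxa - side):
            if min_size <= len(s) < len(taxa) and s not in seen_sides:
                seen_sides.add(s)
                qualifying.append((s, sup))

    def decomposable(s: frozenset) -> bool:
        inner = [t for t, _ in qualifying if t < s]
        return any(
            a.isdisjoint(b)
            for i, a in enumerate(inner) for b in inner[i + 1 :]
        )

    def cohesive(s: frozenset) -> bool:
        inside = np.array(sorted(index_of[t] for t in s))
        outside = np.array(sorted(set(range(len(ids))) - set(inside)))
        within = d_original[np.ix_(inside, inside)]
        mean_in = within.sum(axis=1) / (len(inside) - 1)
        mean_out = d_original[np.ix_(inside, outside)].mean(axis=1)
        return bool(np.all(mean_in <= mean_out))

    atomic = [
        (s, sup) for s, sup in qualifying
        if not decomposable(s) and cohesive(s)
    ]
    atomic.sort(key=lambda t: (-t[1], -len(t[0]), min(t[0])))
    members: dict[int, tuple] = {}
    supports: dict[int, float] = {}
    for s, sup in atomic:
        if any(not s.isdisjoint(set(m)) for m in members.values()):
            continue  # nested inside or conflicting with a chosen cluster
        cid = len(members) + 1
        members[cid] = tuple(sorted(s))
        supports[cid] = sup
    # stable cluster numbering: by first (smallest) member id
    order = sorted(members, key=lambda c: members[c][0])
    remap = {old: new + 1 for new, old in enumerate(order)}
    members = {remap[c]: members[c] for c in order}
    supports = {remap[c]: supports[c] for c in order}
    assignments = {str(t): None for t in ids}
    for cid, leaves in members.items():
        for leaf in leaves:
            assignments[leaf] = cid
    return ClusterAssignment(
        assignments=assignments, supports=supports, members=members,
        tree=original, n_replicates=n_reps,
    )


def residue_conservation(msa, column: int) -> float:
    """Entropy-based column conservation in [0, 1], gaps as a 21st symbol.

    score = 1 - H(column) / log(21); 1 for a fully conserved column, 0 for a
    uniform distribution over all 21 symbols.  The survey convention treats
    scores above 0.7 as functionally significant.
    """
    _, rows = _as_rows(msa)
    enc = encode_rows(rows)
    if not 0 <= column < enc.shape[1]:
        raise IndexError(f"column {column} outside alignment of width {enc.shape[1]}")
    counts = np.bincount(enc[:, column].astype(int), minlength=21)
    freqs = counts[counts > 0] / counts.sum()
    entropy = float(-(freqs * np.log(freqs)).sum())
    return 1.0 - entropy / math.log(21)
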