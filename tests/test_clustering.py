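"""Identity, neighbor joining, bootstrap clusters, conservation score."""

import math

import numpy as np
import pytest

from popsurvey._util import AMINO_ACIDS
from popsurvey.clustering import (
    bipartitions, bootstrap_clusters, distance_matrix, nj_tree,
    pairwise_identity, residue_conservation,
)


def test_pairwise_identity_examples():
    ident = pairwise_identity((["a", "b"], ["ACDE", "ACEE"]))
    assert ident[0, 1] == pytest.approx(0.75)
    ident = pairwise_identity((["a", "b"], ["ACDE", "ACDE"]))
    assert ident[0, 1] == 1.0


def test_pairwise_identity_ignores_gapped_columns():
    # comparable columns: positions 1,2 -> one match of two
    ident = pairwise_identity((["a", "b"], ["-CDE", "ACD-"]))
    assert ident[0, 1] == pytest.approx(1.0)  # C,D both match
    ident = pairwise_identity((["a", "b"], ["-CDE", "AGD-"]))
    assert ident[0, 1] == pytest.approx(0.5)


def test_pairwise_identity_matches_recount_oracle(rng):
    rows = ["".join(rng.choice(list(AMINO_ACIDS + "-"), size=40)) for _ in range(6)]
    ident = pairwise_identity((list("abcdef"), rows))
    for i in range(6):
        for j in range(6):
            matches = comparable = 0
            for a, b in zip(rows[i], rows[j]):
                if a != "-" and b != "-":
                    comparable += 1
                    matches += a == b
            expected = matches / comparable if comparable else float("nan")
            assert ident[i, j] == pytest.approx(expected)


def test_no_comparable_columns_is_nan():
    with np.errstate(all="ignore"):
        ident = pairwise_identity((["a", "b"], ["A---", "---C"]))
    assert math.isnan(ident[0, 1])


def _tip_lengths(tree):
    return {t.name: t.length for t in tree.tips()}


def test_nj_worked_four_taxon_example():
    """Additive matrix from ((A:1,B:2):1,(C:3,D:4)) is recovered exactly."""
    ids = ["A", "B", "C", "D"]
    d = np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0],
    ], dtype=float)
    tree = nj_tree(ids, d)
    bips = bipartitions(tree)
    assert frozenset({"C", "D"}) in bips or frozenset({"A", "B"}) in bips
    lengths = _tip_lengths(tree)
    assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
    internal = [n for n in tree.postorder(include_self=False)
                if not n.is_tip()]
    assert len(internal) == 1 and internal[0].length == pytest.approx(1.0)
    # additivity: path lengths reproduce the input matrix
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                assert tree.find(a).distance(tree.find(b)) == pytest.approx(d[i, j])


def test_nj_three_taxa_closed_form():
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    tree = nj_tree(["A", "B", "C"], d)
    assert _tip_lengths(tree) == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})


def test_nj_input_validation():
    with pytest.raises(ValueError):
        nj_tree(["A", "B"], np.zeros((2, 2)))
    bad = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], dtype=float)
    with pytest.raises(ValueError):
        nj_tree(["A", "B", "C"], bad)


def _random_additive(rng, n):
    """A random unrooted binary tree on n taxa and its additive distances."""
    # adjacency: node -> {neighbor: branch length}; taxa are 0..n-1
    adj = {0: {}, 1: {}, 2: {}, "i0": {}}
    for leaf in (0, 1, 2):
        w = rng.uniform(0.1, 1.0)
        adj[leaf]["i0"] = w
        adj["i0"][leaf] = w
    edges = [(0, "i0"), (1, "i0"), (2, "i0")]
    for leaf in range(3, n):
        a, b = edges[rng.integers(len(edges))]
        mid = f"i{leaf - 2}"
        w = adj[a].pop(b)
        adj[b].pop(a)
        cut = rng.uniform(0.25, 0.75) * w
        adj[mid] = {a: cut, b: w - cut}
        adj[a][mid] = cut
        adj[b][mid] = w - cut
        wl = rng.uniform(0.1, 1.0)
        adj[leaf] = {mid: wl}
        adj[mid][leaf] = wl
        edges.remove((a, b))
        edges += [(a, mid), (b, mid), (leaf, mid)]
    # BFS path lengths between taxa
    d = np.zeros((n, n))
    for src in range(n):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n):
            d[src, dst] = dist[dst]
    # true bipartitions: remove each internal edge, collect one side
    taxa = frozenset(str(t) for t in range(n))
    bips = set()
    internal_edges = {
        (u, v) for u in adj for v in adj[u]
        if isinstance(u, str) and isinstance(v, str)
    }
    for u, v in internal_edges:
        side = set()
        stack, seen = [u], {u, v}
        while stack:
            x = stack.pop()
            if not isinstance(x, str):
                side.add(str(x))
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 2 <= len(side) <= n - 2:
            key = frozenset(side)
            ref = min(taxa)
            bips.add(taxa - key if ref in key else key)
    return d, bips


@pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
def test_nj_recovers_random_additive_topologies(n, rng):
    for _ in range(10):
        d, true_bips = _random_additive(rng, n)
        tree = nj_tree([str(i) for i in range(n)], d)
        assert set(bipartitions(tree)) == true_bips


def test_nj_invariant_to_taxon_order(rng):
    d, _ = _random_additive(rng, 7)
    ids = [str(i) for i in range(7)]
    base = set(bipartitions(nj_tree(ids, d)))
    perm = rng.permutation(7)
    d2 = d[np.ix_(perm, perm)]
    ids2 = [ids[i] for i in perm]
    assert set(bipartitions(nj_tree(ids2, d2))) == base


def test_nj_agrees_with_independent_implementation(rng):
    """Cross-check against scikit-bio's neighbor joining on a noisy matrix."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    d, _ = _random_additive(rng, 8)
    d += rng.uniform(0, 0.02, size=d.shape)
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    ids = [str(i) for i in range(8)]
    ours = set(bipartitions(nj_tree(ids, d)))
    theirs = set(bipartitions(skbio_nj(DistanceMatrix(d, ids))))
    assert ours == theirs


def _planted_two_family_msa(rng, per_family=6, cols=60, noise=0.1):
    fams = {}
    for fam in ("X", "Y"):
        consensus = rng.choice(list(AMINO_ACIDS), size=cols)
        for i in range(per_family):
            keep = rng.random(cols) >= noise
            row = np.where(keep, consensus, rng.choice(list(AMINO_ACIDS), size=cols))
            fams[f"{fam}{i}"] = "".join(row)
    return fams


def test_bootstrap_recovers_planted_partition(rng):
    msa = _planted_two_family_msa(rng)
    asg = bootstrap_clusters(msa, n_reps=200, seed=4)
    assert asg.n_clusters == 2
    got = {frozenset(m) for m in asg.members.values()}
    want = {
        frozenset(k for k in msa if k.startswith("X")),
        frozenset(k for k in msa if k.startswith("Y")),
    }
    assert got == want
    assert all(s > 50 for s in asg.supports.values())


def test_bootstrap_identical_rows_single_cluster(rng):
    row = "".join(rng.choice(list(AMINO_ACIDS), size=40))
    msa = {f"s{i}": row for i in range(8)}
    asg = bootstrap_clusters(msa, n_reps=100, seed=1)
    assert asg.n_clusters == 1


def test_bootstrap_determinism_and_validation(rng):
    msa = _planted_two_family_msa(rng, per_family=4, cols=30)
    a = bootstrap_clusters(msa, n_reps=100, seed=9)
    b = bootstrap_clusters(msa, n_reps=100, seed=9)
    assert a.supports == b.supports and a.members == b.members
    with pytest.raises(ValueError):
        bootstrap_clusters(msa, n_reps=50, seed=1)
    tiny = bootstrap_clusters({"a": "AC", "b": "AC"}, n_reps=100, seed=1)
    assert tiny.n_clusters == 0


def test_clusters_never_overlap(small_run):
    import pandas as pd

    _, rundir, _, _ = small_run
    clusters = pd.read_csv(rundir / "clusters.tsv", sep="\t")
    assigned = clusters[clusters["cluster_id"] != "UNASSIGNED"]
    assert assigned["sequence_id"].is_unique


def test_residue_conservation_examples():
    msa = ["AAAA"] * 10
    assert residue_conservation(msa, 0) == pytest.approx(1.0)
    # uniform over all 21 symbols
    col = list(AMINO_ACIDS + "-")
    msa = [c + "A" for c in col]
    assert residue_conservation(msa, 0) == pytest.approx(0.0, abs=1e-12)
    msa = ["AX"[0] * 2] * 10 + ["V" + "V"] * 10
    assert residue_conservation(msa, 0) == pytest.approx(
        1 - math.log(2) / math.log(21))
    with pytest.raises(IndexError):
        residue_conservation(msa, 5)


def test_poisson_distance_option():
    ids, d = distance_matrix((["a", "b"], ["AAAA", "AAAC"]), correction="poisson")
    assert d[0, 1] == pytest.approx(-math.log(0.75))
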