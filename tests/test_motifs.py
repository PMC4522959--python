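"""Conserved-motif statistic, class-specificity exclusion, subtype calls."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popsurvey._util import AMINO_ACIDS
from popsurvey.motifs import (
    Motif, assign_subtype, column_conservation, define_subtypes,
    find_conserved_motifs, test_class_specific,
)


def test_column_conservation_examples():
    msa = ["G"] * 19 + ["A"]
    assert column_conservation(msa, 0) == pytest.approx(0.95)
    msa = ["G"] * 18 + ["A", "A"]
    assert column_conservation(msa, 0) == pytest.approx(0.90)
    msa = ["-"] * 20
    assert column_conservation(msa, 0) == 0.0
    with pytest.raises(IndexError):
        column_conservation(["AC"], 5)


def test_find_conserved_motifs_planted():
    rng = np.random.default_rng(0)
    rows = []
    aas = list(AMINO_ACIDS)
    for i in range(8):
        row = [aas[(i + j) % 20] for j in range(12)]  # every column varied
        row[4:7] = list("GDS")
        rows.append("".join(row))
    motifs = find_conserved_motifs(rows, threshold=0.95, min_len=3)
    assert len(motifs) == 1
    assert (motifs[0].start, motifs[0].end, motifs[0].consensus) == (4, 7, "GDS")


def test_find_conserved_motifs_empty_when_nothing_passes():
    rows = ["".join(AMINO_ACIDS[(i + j) % 20] for j in range(20)) for i in range(6)]
    assert find_conserved_motifs(rows) == []
    with pytest.raises(ValueError):
        find_conserved_motifs(rows[:1])


def _brute_force_motifs(rows, threshold, min_len):
    """Independent oracle: exhaustive scan over all windows of all lengths."""
    n, L = len(rows), len(rows[0])

    def column(c):
        counts = Counter(r[c] for r in rows if r[c] not in "-.")
        if not counts:
            return 0.0, None
        best = max(sorted(counts), key=lambda a: counts[a])
        return counts[best] / n, best

    stats = [column(c) for c in range(L)]
    passing = [f >= threshold for f, _ in stats]
    out = []
    c = 0
    while c < L:
        if passing[c]:
            end = c
            while end < L and passing[end]:
                end += 1
            if end - c >= min_len:
                out.append((c, end, "".join(stats[k][1] for k in range(c, end))))
            c = end
        else:
            c += 1
    return out


def _random_alignment(rng, n_rows, n_cols):
    consensus = rng.choice(list(AMINO_ACIDS), size=n_cols)
    conservation = rng.choice([1.0, 0.95, 0.8, 0.5, 0.2], size=n_cols)
    rows = []
    for _ in range(n_rows):
        keep = rng.random(n_cols) < conservation
        row = np.where(keep, consensus, rng.choice(list(AMINO_ACIDS), size=n_cols))
        gaps = rng.random(n_cols) < 0.05
        rows.append("".join("-" if g else ch for g, ch in zip(gaps, row)))
    return rows


def test_find_conserved_motifs_matches_brute_force(rng):
    for _ in range(60):
        rows = _random_alignment(rng, int(rng.integers(3, 16)),
                                 int(rng.integers(10, 61)))
        for threshold, min_len in ((0.95, 3), (0.8, 4)):
            got = [
                (m.start, m.end, m.consensus)
                for m in find_conserved_motifs(rows, threshold, min_len)
            ]
            assert got == _brute_force_motifs(rows, threshold, min_len)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_motif_monotonicity_under_stricter_parameters(seed):
    """Raising threshold or min_len only refines: new motifs lie inside old ones."""
    rng = np.random.default_rng(seed)
    rows = _random_alignment(rng, 8, 50)
    loose = find_conserved_motifs(rows, threshold=0.8, min_len=3)
    for threshold, min_len in ((0.95, 3), (0.8, 5)):
        strict = find_conserved_motifs(rows, threshold, min_len)
        for m in strict:
            assert any(o.start <= m.start and m.end <= o.end for o in loose)


def test_class_specific_accept_and_reject():
    motif = Motif(cluster_id=1, start=0, end=4, consensus="HGGG",
                  conservations=(1.0,) * 4)
    others = {1: ["HGGGAAAA"], 2: ["ACDEACDE"], 3: ["MMMM-MMM"]}
    accepted = test_class_specific(motif, others)
    assert accepted is not None
    assert accepted.other_cluster_matches == {2: 0, 3: 0}
    # one occurrence anywhere else (even across a gap) rejects the motif
    others[3] = ["MMHG-GGM"]
    assert test_class_specific(motif, others) is None


def _toy_clusters(n_clusters=9, share_last=True):
    """Cluster i: rows with shared flanks and motif(s); last cluster shares."""
    motifs = ["WWW", "YYY", "HHH", "QQQ", "MMM", "FFF", "PPP", "RRR", "EEE"]
    clusters = {}
    for i in range(n_clusters):
        core = motifs[0] if (share_last and i == n_clusters - 1) else motifs[i]
        extra = motifs[i] if i == 0 else ""
        # flanks AAA/CCC are conserved but shared across clusters
        row = "AAA" + core + "CCC" + extra
        clusters[i + 1] = [row, row, row]
    return clusters, motifs


def test_define_subtypes_eight_of_nine():
    """Nine clusters, one owning no exclusive motif -> eight subtypes."""
    clusters, motifs = _toy_clusters()
    table = define_subtypes(clusters)
    assert table.n_subtypes == 8
    assert table.non_subtype_clusters == (9,)
    # cluster 1 keeps its extra exclusive motif even though WWW is shared
    assert any(c.motif.consensus == "WWW" + "CCC" + "WWW"
               or "WWW" in c.motif.consensus
               for c in table.motifs[table.subtype_of_cluster[1]])


def test_define_subtypes_none_when_everything_shared():
    clusters = {i: ["AAACCCGGG"] * 3 for i in range(1, 4)}
    table = define_subtypes(clusters)
    assert table.n_subtypes == 0
    assert table.non_subtype_clusters == (1, 2, 3)
    with pytest.raises(ValueError):
        define_subtypes({1: ["AAA"] * 2})


def test_assign_subtype_rules():
    clusters, motifs = _toy_clusters(n_clusters=3, share_last=False)
    table = define_subtypes(clusters)
    assert table.n_subtypes == 3
    consensus = {s: table.motifs[s][0].motif.consensus for s in table.motifs}
    call = assign_subtype("XXXX" + consensus[1] + "XXXX", table, seq_id="q")
    assert call.subtype == 1 and call.reason == ""
    both = "X" + consensus[1] + "X" + consensus[2]
    assert assign_subtype(both, table).reason == "ambiguous"
    none = assign_subtype("ACDEACDEACDE", table)
    assert none.subtype is None and none.reason == "no-match"
    with pytest.raises(ValueError):
        assign_subtype("ACDE", define_subtypes(
            {1: ["AAAWWW"] * 2, 2: ["AAAWWW"] * 2}))


def test_exclusivity_soundness_on_survey(small_run):
    """Re-scan: accepted class-specific motifs occur nowhere outside their cluster."""
    import pandas as pd

    _, rundir, _, _ = small_run
    from popsurvey.pipeline import _cluster_msas

    msas = _cluster_msas(rundir)
    mo = pd.read_csv(rundir / "motifs.tsv", sep="\t")
    for r in mo[mo["class_specific"]].itertuples(index=False):
        for cid, rows in msas.items():
            if cid != r.cluster_id:
                assert not any(r.consensus in row for row in rows)
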