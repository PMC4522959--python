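"""Cluster-specific conserved motifs and the subtype classification they define.

A *conserved motif* is a maximal run of at least ``min_len`` consecutive
alignment columns in one cluster's alignment where at least ``threshold``
(default 95%) of the sequences share the single most frequent residue.  A
*class-specific motif* is a conserved motif whose consensus never occurs,
as an exact ungapped substring, in any sequence of any other cluster.
Clusters owning at least one class-specific motif define subtypes; a
sequence is assigned to a subtype when it contains a class-specific motif
of exactly that one subtype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import encode_rows, ungap

log = logging.getLogger(__name__)

#: survey conventions: >= 95% of sequences conserved over >= 3 consecutive columns
DEFAULT_THRESHOLD = 0.95
DEFAULT_MIN_LEN = 3


@dataclass(frozen=True)
class Motif:
    """A conserved alignment stretch within one cluster."""

    cluster_id: int
    start: int  # alignment columns, 0-based half-open
    end: int
    consensus: str
    conservations: tuple  # per-column majority fraction

    def __post_init__(self):
        if len(self.consensus) != self.end - self.start:
            raise ValueError("consensus length must match the column span")


@dataclass(frozen=True)
class ClassSpecificMotif:
    """A motif proven absent from every other cluster."""

    motif: Motif
    other_cluster_matches: dict  # other cluster id -> sequences containing it

    def __post_init__(self):
        if any(self.other_cluster_matches.values()):
            raise ValueError("class-specific motif with non-zero match counts")


@dataclass(frozen=True)
class SubtypeCall:
    seq_id: str
    subtype: int | None  # None = UNCLASSIFIED
    matched_motifs: tuple
    reason: str = ""  # 'no-match' or 'ambiguous' when unclassified


def column_conservation(msa_rows, column: int) -> float:
    """Fraction of sequences carrying the most frequent residue at a column.

    Gaps never count toward the majority; an all-gap column scores 0.  The
    denominator is the total number of sequences.
    """
    rows = list(msa_rows)
    enc = encode_rows(rows)
    if not 0 <= column < enc.shape[1]:
        raise IndexError(f"column {column} outside alignment")
    counts = np.bincount(enc[:, column].astype(int), minlength=21)[:20]
    return float(counts.max()) / len(rows)


def _column_profile(rows) -> tuple[np.ndarray, np.ndarray]:
    """(majority fraction, majority residue code) per column, gaps excluded."""
    enc = encode_rows(rows)
    n, L = enc.shape
    counts = np.zeros((L, 20), dtype=np.int64)
    for a in range(20):
        counts[:, a] = (enc == a).sum(axis=0)
    best = counts.argmax(axis=1)  # ties: lowest residue code wins
    frac = counts[np.arange(L), best] / n
    return frac, best


def find_conserved_motifs(
    cluster_msa,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    cluster_id: int = 0,
) -> list[Motif]:
    """Maximal runs of conserved columns, reported left to right.

    Each column of a run must individually reach the conservation threshold;
    the consensus is the per-column majority residue (ties break to the
    alphabetically first residue).
    """
    rows = list(cluster_msa.values()) if isinstance(cluster_msa, dict) else list(cluster_msa)
    if len(rows) < 2:
        raise ValueError("motif discovery needs at least 2 sequences")
    frac, best = _column_profile(rows)
    passing = frac >= threshold
    motifs: list[Motif] = []
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    i = 0
    L = len(passing)
    while i < L:
        if not passing[i]:
            i += 1
            continue
        j = i
        while j < L and passing[j]:
            j += 1
        if j - i >= min_len:
            motifs.append(Motif(
                cluster_id=cluster_id, start=i, end=j,
                consensus="".join(alphabet[b] for b in best[i:j]),
                conservations=tuple(float(f) for f in frac[i:j]),
            ))
        i = j
    return motifs


def test_class_specific(motif: Motif, other_clusters: dict) -> ClassSpecificMotif | None:
    """Exclusion scan: accept the motif only if completely absent elsewhere.

    ``other_clusters`` maps cluster id -> iterable of sequences (alignment
    rows or raw sequences; gaps are removed before the substring scan).
    Returns the accepted :class:`ClassSpecificMotif` with per-cluster match
    counts (all zero), or None when any other cluster contains the motif
    consensus.
    """
    evidence = {}
    rejected = False
    for cid, seqs in other_clusters.items():
        if cid == motif.cluster_id:
            continue
        n = sum(1 for s in seqs if motif.consensus in ungap(s))
        evidence[cid] = n
        if n:
            rejected = True
    if rejected:
        return None
    return ClassSpecificMotif(motif=motif, other_cluster_matches=evidence)


# "test" here is the statistical exclusion test, not a pytest case
test_class_specific.__test__ = False


@dataclass
class SubtypeTable:
    """Clusters promoted to subtypes by their class-specific motifs."""

    subtype_of_cluster: dict  # cluster id -> subtype id
    motifs: dict  # subtype id -> tuple of ClassSpecificMotif
    non_subtype_clusters: tuple  # cluster ids with no class-specific motif
    all_motifs: dict = field(default_factory=dict)  # cluster id -> all conserved motifs

    @property
    def n_subtypes(self) -> int:
        return len(self.motifs)


def define_subtypes(
    cluster_msas: dict,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
) -> SubtypeTable:
    """Discover class-specific motifs per cluster and number the subtypes.

    Subtype ids run 1..k in increasing cluster-id order over clusters that
    own at least one class-specific motif; clusters with none are recorded
    separately (a survey may well find fewer subtypes than clusters).
    """
    if len(cluster_msas) < 2:
        raise ValueError("subtype definition needs at least 2 clusters")
    conserved = {
        cid: find_conserved_motifs(rows, threshold, min_len, cluster_id=cid)
        for cid, rows in cluster_msas.items()
    }
    specific: dict[int, list[ClassSpecificMotif]] = {}
    for cid, motifs in conserved.items():
        accepted = []
        for m in motifs:
            csm = test_class_specific(m, cluster_msas)
            if csm is not None:
                accepted.append(csm)
        if accepted:
            specific[cid] = accepted
    subtype_of_cluster = {
        cid: i + 1 for i, cid in enumerate(sorted(specific))
    }
    motifs = {
        subtype_of_cluster[cid]: tuple(ms) for cid, ms in specific.items()
    }
    non_subtype = tuple(sorted(set(cluster_msas) - set(specific)))
    if non_subtype:
        log.info("%d cluster(s) own no class-specific motif and define no subtype: %s",
                 len(non_subtype), non_subtype)
    return SubtypeTable(
        subtype_of_cluster=subtype_of_cluster, motifs=motifs,
        non_subtype_clusters=non_subtype, all_motifs=conserved,
    )


def assign_subtype(sequence: str, table: SubtypeTable, seq_id: str = "") -> SubtypeCall:
    """Classify one sequence by exact substring match of class-specific motifs.

    Exactly one subtype matched -> assigned; zero or several -> unclassified
    with the reason recorded.
    """
    if not table.motifs:
        raise ValueError("subtype table is empty")
    seq = ungap(sequence)
    matched: dict[int, list[str]] = {}
    for subtype, csms in table.motifs.items():
        found = [c.motif.consensus for c in csms if c.motif.consensus in seq]
        if found:
            matched[subtype] = found
    if len(matched) == 1:
        ((subtype, found),) = matched.items()
        return SubtypeCall(seq_id=seq_id, subtype=subtype,
                           matched_motifs=tuple(found))
    reason = "no-match" if not matched else "ambiguous"
    all_found = tuple(m for found in matched.values() for m in found)
    return SubtypeCall(seq_id=seq_id, subtype=None, matched_motifs=all_found,
                       reason=reason)


def motif_count_matrix(cluster_msa, motif: Motif) -> pd.DataFrame:
    """Per-column residue counts over the motif span (sequence-logo input)."""
    rows = list(cluster_msa.values()) if isinstance(cluster_msa, dict) else list(cluster_msa)
    enc = encode_rows(rows)[:, motif.start : motif.end]
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    data = {
        a: (enc == i).sum(axis=0) for i, a in enumerate(alphabet)
    }
    return pd.DataFrame(data, index=range(motif.start, motif.end))


def motif_table(table: SubtypeTable) -> pd.DataFrame:
    """Flat TSV-ready view of all conserved motifs with their specificity."""
    specific = {
        (c.motif.cluster_id, c.motif.start, c.motif.end)
        for csms in table.motifs.values() for c in csms
    }
    rows = []
    for cid in sorted(table.all_motifs):
        for m in table.all_motifs[cid]:
            rows.append({
                "cluster_id": cid,
                "start": m.start,
                "end": m.end,
                "consensus": m.consensus,
                "min_conservation": min(m.conservations),
                "class_specific": (cid, m.start, m.end) in specific,
                "subtype": table.subtype_of_cluster.get(cid)
                if (cid, m.start, m.end) in specific else None,
            })
    return pd.DataFrame(
        rows, columns=["cluster_id", "start", "end", "consensus",
                       "min_conservation", "class_specific", "subtype"],
    )
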