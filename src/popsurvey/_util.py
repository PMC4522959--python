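"""Shared low-level helpers: alphabet encoding, hydropathy, identity, FASTA I/O."""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CHARS = frozenset("-.")
GAP_CODE = 20  # gaps encode as 20, one past the last residue index

# Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_KD_BY_CODE = np.array([KYTE_DOOLITTLE[a] for a in AMINO_ACIDS] + [0.0])


def encode(seq: str) -> np.ndarray:
    """Encode an amino-acid string (gaps allowed) as int8 codes 0..19, gap=20."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        if ch in GAP_CHARS:
            out[i] = GAP_CODE
        else:
            try:
                out[i] = AA_INDEX[ch]
            except KeyError:
                raise ValueError(f"unknown residue {ch!r} at position {i}") from None
    return out


def encode_rows(rows) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) int8 matrix."""
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    return np.vstack([encode(r) for r in rows])


def decode(codes: np.ndarray) -> str:
    alphabet = AMINO_ACIDS + "-"
    return "".join(alphabet[c] for c in codes)


def hydropathy(seq: str) -> np.ndarray:
    return _KD_BY_CODE[encode(seq)]


def ungap(seq: str) -> str:
    return "".join(ch for ch in seq if ch not in GAP_CHARS)


def global_aligner() -> PairwiseAligner:
    """Fixed simple scoring for pairwise identity: match 1, mismatch 0, gap -1."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = global_aligner()


def pairwise_identity_global(a: str, b: str) -> float:
    """Identity of an optimal global alignment of two unaligned sequences.

    Identity = matches / columns where neither row is gapped, computed on a
    single optimal alignment (ties resolved deterministically by the aligner).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    alignment = _ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    comparable = counts.identities + counts.mismatches
    if comparable == 0:
        return float("nan")
    return counts.identities / comparable


def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered {id: sequence} dict."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(path, records: dict) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")
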