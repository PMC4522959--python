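"""Position-specific scoring models with simulation-based E-values.

A :class:`ProfileModel` is a per-column log-odds matrix built from an
ungapped-column view of a seed alignment, scored against every ungapped
window of a target sequence.  Statistical significance is calibrated by
simulation: the maximum window score of random background sequences is
fitted with a Gumbel (extreme-value) distribution, and the E-value of a
score *s* against a database exposing ``D`` windows is ``D * P(max-null
score >= s)``.  This is the classic Karlin-Altschul-style contract made
fully recomputable, standing in for the search statistics of HMMER/BLAST.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from ._util import AMINO_ACIDS, GAP_CODE, encode, encode_rows, pairwise_identity_global

log = logging.getLogger(__name__)

#: Smallest reported tail probability; keeps every E-value strictly positive
#: even when the Gumbel survival function underflows.
MIN_TAIL_P = 1e-300


class CalibrationError(RuntimeError):
    """Raised when the null-score distribution is degenerate."""


@dataclass(frozen=True)
class GumbelCalibration:
    """Null distribution of max-window scores for one profile.

    Within the sampled score range the survival probability is the
    empirical exceedance with the (r+1)/(n+1) plotting position, which is
    calibrated to sampling error by construction; beyond the largest null
    sample the fitted Gumbel right tail extrapolates, scaled to continue
    the empirical curve.
    """

    loc: float
    scale: float
    n_samples: int
    null_length: int
    null_scores: np.ndarray = None  # sorted ascending

    def tail_p(self, score: float) -> float:
        """P(max null score >= score)."""
        if self.null_scores is None:
            p = stats.gumbel_r.sf(score, loc=self.loc, scale=self.scale)
            return float(max(p, MIN_TAIL_P))
        n = len(self.null_scores)
        r = n - np.searchsorted(self.null_scores, score, side="left")
        if r > 0:
            return (r + 1.0) / (n + 1.0)
        top = self.null_scores[-1]
        sf_top = max(stats.gumbel_r.sf(top, self.loc, self.scale), MIN_TAIL_P)
        p = (stats.gumbel_r.sf(score, self.loc, self.scale) / sf_top) / (n + 1.0)
        return float(max(p, MIN_TAIL_P))


@dataclass(frozen=True)
class ProfileModel:
    """Per-column log-odds scoring model for one domain or family."""

    name: str
    log_odds: np.ndarray  # (length, 20), bits
    frequencies: np.ndarray  # (length, 20), pseudocounted, rows sum to 1
    background: np.ndarray  # (20,)
    calibration: GumbelCalibration | None = None

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.log_odds, axis=1))

    def window_scores(self, encoded: np.ndarray) -> np.ndarray:
        """Score every ungapped window of an encoded sequence (bits)."""
        L = self.length
        n = encoded.shape[0] - L + 1
        if n <= 0:
            return np.empty(0)
        scores = np.zeros(n)
        for i in range(L):
            scores += self.log_odds[i, encoded[i : i + n]]
        return scores

    def evalue(self, score: float, n_windows: int) -> float:
        if self.calibration is None:
            raise CalibrationError(
                f"profile {self.name!r} is not calibrated; no E-value available"
            )
        return n_windows * self.calibration.tail_p(score)


@dataclass(frozen=True)
class DomainHit:
    """A located, non-overlapping profile match on one sequence."""

    seq_id: str
    profile: str
    start: int  # 0-based, half-open
    end: int
    bits: float
    evalue: float


def build_profile(
    seed_alignment,
    pseudocount: float = 1.0,
    background=None,
    name: str = "profile",
) -> ProfileModel:
    """Build a log-odds profile from an aligned set of sequences.

    Per column, the pseudocounted frequency of residue ``a`` is
    ``(n_a + pseudocount * bg_a) / (N + pseudocount)`` where ``N`` counts
    the non-gap residues in the column; the score is ``log2(freq / bg_a)``.
    """
    rows = list(seed_alignment.values()) if isinstance(seed_alignment, dict) else list(seed_alignment)
    if len(rows) < 2:
        raise ValueError("seed alignment needs at least 2 sequences")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = _checked_background(background)
    enc = encode_rows(rows)  # raises on ragged input
    length = enc.shape[1]
    counts = np.zeros((length, 20))
    for a in range(20):
        counts[:, a] = (enc == a).sum(axis=0)
    n_col = counts.sum(axis=1, keepdims=True)  # gaps excluded
    freqs = (counts + pseudocount * bg) / (n_col + pseudocount)
    log_odds = np.log2(freqs / bg)
    return ProfileModel(name=name, log_odds=log_odds, frequencies=freqs, background=bg)


def _checked_background(background) -> np.ndarray:
    if background is None:
        return np.full(20, 1.0 / 20)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (20,) or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 20 positive probabilities summing to 1")
    return bg


def sample_null_max_scores(
    profile: ProfileModel,
    null_length: int,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Max window score of ``n_samples`` random background sequences."""
    if null_length < profile.length:
        raise ValueError("null sequence length must cover the profile")
    seqs = rng.choice(20, size=(n_samples, null_length), p=profile.background)
    n_win = null_length - profile.length + 1
    scores = np.zeros((n_samples, n_win))
    for i in range(profile.length):
        scores += profile.log_odds[i, seqs[:, i : i + n_win]]
    return scores.max(axis=1)


def calibrate(
    profile: ProfileModel,
    null_length: int,
    n_samples: int = 2000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> ProfileModel:
    """Return a copy of ``profile`` with a fitted Gumbel null."""
    if n_samples < 200:
        raise ValueError("calibration needs at least 200 null samples")
    if rng is None:
        rng = np.random.default_rng(seed)
    maxima = sample_null_max_scores(profile, null_length, n_samples, rng)
    if np.std(maxima) < 1e-9:
        raise CalibrationError(f"degenerate null variance for profile {profile.name!r}")
    loc, scale = stats.gumbel_r.fit(maxima)
    cal = GumbelCalibration(
        loc=float(loc), scale=float(scale), n_samples=n_samples,
        null_length=null_length, null_scores=np.sort(maxima),
    )
    return replace(profile, calibration=cal)


def scan(
    profile: ProfileModel,
    sequence: str,
    seq_id: str = "",
    max_hits: int | None = None,
    n_windows: int | None = None,
) -> list[DomainHit]:
    """Greedy non-overlapping profile hits on one sequence, best score first.

    ``n_windows`` sets the database size D used in the E-value; it defaults
    to the number of windows in this sequence.  Ties in score break toward
    the smaller start coordinate.
    """
    enc = encode(sequence)
    if enc.shape[0] < profile.length:
        log.warning(
            "sequence %s shorter than profile %s (%d < %d); no windows",
            seq_id, profile.name, enc.shape[0], profile.length,
        )
        return []
    scores = profile.window_scores(enc)
    D = len(scores) if n_windows is None else n_windows
    order = np.lexsort((np.arange(len(scores)), -scores))
    hits: list[DomainHit] = []
    taken = np.zeros(len(sequence), dtype=bool)
    for start in order:
        end = start + profile.length
        if taken[start:end].any():
            continue
        taken[start:end] = True
        hits.append(
            DomainHit(
                seq_id=seq_id,
                profile=profile.name,
                start=int(start),
                end=int(end),
                bits=float(scores[start]),
                evalue=profile.evalue(float(scores[start]), D),
            )
        )
        if max_hits is not None and len(hits) >= max_hits:
            break
    return hits


def best_hit(profile: ProfileModel, sequence: str, seq_id: str = "",
             n_windows: int | None = None) -> DomainHit | None:
    hits = scan(profile, sequence, seq_id=seq_id, max_hits=1, n_windows=n_windows)
    return hits[0] if hits else None


def iterative_search(
    seed_queries: dict,
    database: dict,
    e_threshold: float = 1e-3,
    max_rounds: int = 3,
    pseudocount: float = 1.0,
    background=None,
    calibration_samples: int = 1000,
    null_length: int | None = None,
    seed: int = 0,
) -> dict:
    """Jackhmmer-style iterative profile search.

    Round 1 scores the database against a profile built from the seed
    queries (which must be equal length, ungapped); hits with best E-value
    at or below the threshold join the seed set as their best-hit windows,
    and the search repeats until no new sequence is accepted or
    ``max_rounds`` is reached.  Returns ``{seq_id: best DomainHit}`` for the
    accepted set, which grows monotonically across rounds.
    """
    if not seed_queries:
        raise ValueError("seed query set is empty")
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    seed_rows = dict(seed_queries)
    if len({len(s) for s in seed_rows.values()}) != 1:
        raise ValueError("seed queries must have equal length")
    profile_len = len(next(iter(seed_rows.values())))
    if null_length is None:
        null_length = max(profile_len, max((len(s) for s in database.values()), default=profile_len))
    total_windows = sum(
        max(len(s) - profile_len + 1, 0) for s in database.values()
    )
    accepted: dict[str, DomainHit] = {}
    for round_no in range(1, max_rounds + 1):
        rows = list(seed_rows.values())
        if len(rows) == 1:
            rows = rows * 2  # single seed: duplicate so column counts are defined
        profile = build_profile(
            rows, pseudocount=pseudocount, background=background,
            name=f"iter_round{round_no}",
        )
        profile = calibrate(
            profile, null_length=null_length, n_samples=calibration_samples,
            seed=seed + round_no,
        )
        new = 0
        for sid, seq in database.items():
            hit = best_hit(profile, seq, seq_id=sid, n_windows=max(total_windows, 1))
            if hit is None or hit.evalue > e_threshold:
                continue
            if sid not in accepted:
                new += 1
                seed_rows[f"{sid}|round{round_no}"] = seq[hit.start : hit.end]
            accepted[sid] = hit
        log.info("iterative_search round %d: %d new, %d total", round_no, new, len(accepted))
        if new == 0:
            break
    return accepted


def deduplicate(sequences: dict, identity_threshold: float = 0.9) -> list[str]:
    """Greedy length-sorted redundancy removal (CD-HIT-style contract).

    Sequences are visited by decreasing length (ties by id); each joins the
    first existing representative it matches at or above the identity
    threshold, otherwise it founds a new representative.  Returns
    representative ids in founding order.
    """
    if not 0.5 <= identity_threshold <= 1.0:
        raise ValueError("identity threshold must be in [0.5, 1]")
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    reps: list[str] = []
    for sid in order:
        seq = sequences[sid]
        for rep in reps:
            if pairwise_identity_global(sequences[rep], seq) >= identity_threshold:
                break
        else:
            reps.append(sid)
    return reps
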