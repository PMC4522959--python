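"""Profile construction, scanning, calibration, iterative search, dedup."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popsurvey._util import AMINO_ACIDS, encode, pairwise_identity_global
from popsurvey.profiles import (
    CalibrationError, build_profile, calibrate, deduplicate, iterative_search,
    sample_null_max_scores, scan,
)
from popsurvey.synthetic import emit_from_template, generate_domain_template


def test_single_residue_columns_score_log2_20():
    rows = ["AC" * 10] * 5
    p = build_profile(rows, pseudocount=1e-9)
    assert np.allclose(p.log_odds.max(axis=1), math.log2(20), atol=1e-5)


def test_background_frequency_columns_score_zero():
    rows = [a * 8 for a in AMINO_ACIDS]  # every residue once per column
    p = build_profile(rows, pseudocount=1.0)
    assert np.allclose(p.log_odds, 0.0, atol=1e-12)


def test_profile_formula_oracle(rng):
    """Scores equal a direct evaluation of the stated pseudocount formula."""
    rows = ["".join(rng.choice(list(AMINO_ACIDS), size=30)) for _ in range(10)]
    alpha = 1.0
    p = build_profile(rows, pseudocount=alpha)
    bg = 1.0 / 20
    for col in range(30):
        for a_idx, a in enumerate(AMINO_ACIDS):
            n_a = sum(1 for r in rows if r[col] == a)
            expected = math.log2(((n_a + alpha * bg) / (10 + alpha)) / bg)
            assert p.log_odds[col, a_idx] == pytest.approx(expected)


def test_profile_frequencies_sum_to_one(rng):
    rows = ["".join(rng.choice(list(AMINO_ACIDS + "-"), size=15)) for _ in range(6)]
    p = build_profile(rows)
    assert np.allclose(p.frequencies.sum(axis=1), 1.0)


def test_build_profile_input_validation():
    with pytest.raises(ValueError):
        build_profile(["ACDE"])  # single sequence
    with pytest.raises(ValueError):
        build_profile(["ACDE", "ACD"])  # ragged
    with pytest.raises(ValueError):
        build_profile(["ACDE", "ACDE"], pseudocount=0.0)
    with pytest.raises(ValueError):
        build_profile(["ACDE", "ACDE"], background=np.zeros(20))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_window_score_additivity(seed):
    """A window's score is the sum of its per-column scores."""
    rng = np.random.default_rng(seed)
    rows = ["".join(rng.choice(list(AMINO_ACIDS), size=12)) for _ in range(4)]
    p = build_profile(rows)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=30))
    scores = p.window_scores(encode(seq))
    w = int(rng.integers(len(scores)))
    manual = sum(
        p.log_odds[i, AMINO_ACIDS.index(seq[w + i])] for i in range(p.length)
    )
    assert scores[w] == pytest.approx(manual)


def _calibrated_toy(rng, length=50, conservation=0.9, n_samples=1000, seed=0):
    t = generate_domain_template("T", length, conservation, rng=rng)
    rows = [emit_from_template(t, rng) for _ in range(10)]
    p = build_profile(rows, name="T")
    return t, calibrate(p, null_length=120, n_samples=n_samples, seed=seed)


def test_scan_recovers_planted_offset(rng):
    t, p = _calibrated_toy(rng)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=7)) + t.consensus + \
        "".join(rng.choice(list(AMINO_ACIDS), size=20))
    hits = scan(p, seq, seq_id="s")
    assert hits[0].start == 7
    assert hits[0].end == 7 + p.length
    assert hits[0].evalue < 1e-10


def test_scan_single_window_and_short_sequence(rng):
    t, p = _calibrated_toy(rng)
    hits = scan(p, t.consensus)
    assert len(hits) == 1 and hits[0].start == 0
    assert scan(p, t.consensus[:-1]) == []


def test_scan_hits_do_not_overlap(rng):
    t, p = _calibrated_toy(rng)
    seq = t.consensus + "AC" + t.consensus
    hits = scan(p, seq)
    spans = sorted((h.start, h.end) for h in hits)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2


def test_calibration_determinism_and_validation(rng):
    t = generate_domain_template("T", 40, 0.9, rng=rng)
    rows = [emit_from_template(t, rng) for _ in range(8)]
    p = build_profile(rows)
    c1 = calibrate(p, null_length=100, n_samples=500, seed=3).calibration
    c2 = calibrate(p, null_length=100, n_samples=500, seed=3).calibration
    assert c1.loc == c2.loc and c1.scale == c2.scale
    assert np.array_equal(c1.null_scores, c2.null_scores)
    with pytest.raises(ValueError):
        calibrate(p, null_length=100, n_samples=100, seed=1)
    with pytest.raises(CalibrationError):
        scan(p, t.consensus)  # E-values require calibration


def test_consensus_evalue_below_1e10_for_conserved_profiles(rng):
    """A >= 40-column well-conserved profile finds its consensus at E < 1e-10."""
    for length in (40, 60, 80):
        t, p = _calibrated_toy(rng, length=length, conservation=0.95)
        hit = scan(p, t.consensus)[0]
        assert hit.evalue < 1e-10


def test_null_exceedance_matches_nominal_rates(rng):
    """Held-out null sequences exceed E = q*D at rate q (within 3 SE)."""
    _, p = _calibrated_toy(rng, n_samples=5000, seed=21)
    held = sample_null_max_scores(p, 120, 1000, np.random.default_rng(77))
    for q in (0.2, 0.05, 0.01):
        emp = float(np.mean([p.calibration.tail_p(s) <= q for s in held]))
        assert abs(emp - q) <= 3 * math.sqrt(q * (1 - q) / 1000), q


def test_threshold_monotonicity(rng):
    """The stringent-tier hit set is nested inside the relaxed-tier set."""
    t, p = _calibrated_toy(rng)
    db = {}
    for i in range(30):
        noisy = emit_from_template(t, rng)
        db[f"s{i}"] = noisy if i % 2 else "".join(
            rng.choice(list(AMINO_ACIDS), size=60))
    hits = {sid: scan(p, s, seq_id=sid) for sid, s in db.items()}
    at = lambda thr: {s for s, hs in hits.items() if hs and hs[0].evalue <= thr}
    assert at(1e-10) <= at(1e-3)


def test_iterative_search_contracts(rng):
    t = generate_domain_template("T", 60, 1.0, rng=rng)
    seeds = {"q1": t.consensus, "q2": t.consensus}
    db = {"q1": t.consensus, "q2": t.consensus}
    accepted = iterative_search(seeds, db, e_threshold=1e-3, max_rounds=3, seed=1)
    assert set(accepted) == {"q1", "q2"}
    with pytest.raises(ValueError):
        iterative_search({}, db)
    with pytest.raises(ValueError):
        iterative_search(seeds, db, max_rounds=0)


def test_iterative_search_transitive_chain(rng):
    """A finds B, B finds C, A alone does not find C: needs >= 2 rounds."""
    a = "".join(rng.choice(list(AMINO_ACIDS), size=60))
    c = "".join(rng.choice(list(AMINO_ACIDS), size=60))
    b = a[:30] + c[30:]
    db = {"A": a, "B": b, "C": c}
    one = iterative_search({"A": a}, db, e_threshold=1e-3, max_rounds=1, seed=2)
    multi = iterative_search({"A": a}, db, e_threshold=1e-3, max_rounds=3, seed=2)
    assert set(one) == {"A", "B"}
    assert set(multi) == {"A", "B", "C"}
    assert set(one) <= set(multi)  # accepted set grows monotonically


def test_deduplicate_examples(rng):
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=50))
    assert deduplicate({"a": seq, "b": seq}, 0.9) == ["a"]
    distinct = {
        f"s{i}": "".join(rng.choice(list(AMINO_ACIDS), size=50)) for i in range(6)
    }
    assert len(deduplicate(distinct, 0.9)) == 6
    with pytest.raises(ValueError):
        deduplicate(distinct, 0.4)


def test_deduplicate_matches_greedy_oracle(rng):
    """Representatives equal an independent greedy pass over the identity matrix."""
    t = generate_domain_template("T", 40, 0.7, rng=rng)
    seqs = {f"s{i}": emit_from_template(t, rng) for i in range(10)}
    threshold = 0.8
    got = deduplicate(seqs, threshold)
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    reps = []
    for sid in order:
        if not any(
            pairwise_identity_global(seqs[r], seqs[sid]) >= threshold for r in reps
        ):
            reps.append(sid)
    assert got == reps
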