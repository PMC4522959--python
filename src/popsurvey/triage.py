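"""Homolog-acceptance logic: architecture rule, two-tier enrichment, family calls.

A sequence is a *full POP* only when both the beta-propeller (POP_N) and the
alpha/beta-hydrolase (POP_C) domains are found on it; a hydrolase-only hit is
a *partial POP*; a propeller without its catalytic domain is rejected and
never propagates downstream.  Hits found only at the relaxed E-value tier
(1e-3) are kept only when they in turn match the database of stringent-tier
(1e-10) "true homologs".  Unannotated sequences are promoted to POP when an
annotated POP query finds them at the relaxed threshold and they carry the
full two-domain architecture; otherwise a four-profile scan (POP, DPP, ACC,
other alpha/beta hydrolases) may still resolve them within the superfamily.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .profiles import DomainHit, ProfileModel, best_hit

log = logging.getLogger(__name__)

STRINGENT_EVALUE = 1e-10
RELAXED_EVALUE = 1e-3

FULL_POP = "FULL_POP"
PARTIAL_C = "PARTIAL_C"
REJECTED = "REJECTED"

TIER_STRINGENT = "STRINGENT"
TIER_RELAXED_CONFIRMED = "RELAXED_CONFIRMED"

ANNOTATED = "ANNOTATED"
NEWLY_ANNOTATED_POP = "NEWLY_ANNOTATED_POP"
NEWLY_ANNOTATED_ABH = "NEWLY_ANNOTATED_ABH"
UNANNOTATED = "UNANNOTATED"

#: fixed family precedence for exact ties in the four-profile scan
FAMILY_ORDER = ("POP", "DPP", "ACC", "ABH")
#: no profile below this E-value -> unresolved within the superfamily
UNRESOLVED_EVALUE = 10.0
UNRESOLVED = "ABH-superfamily-unresolved"


@dataclass
class HomologCall:
    """Per-sequence verdict of the survey."""

    seq_id: str
    genome_id: str
    architecture: str  # FULL_POP | PARTIAL_C | REJECTED
    family: str | None = None
    family_margin: float | None = None
    tier: str | None = None
    annotation_status: str = ANNOTATED
    best_evalue: float | None = None
    hits: tuple = ()  # supporting DomainHits


def classify_architecture(domain_hits, e_threshold: float = RELAXED_EVALUE) -> str:
    """FULL_POP needs both domains below threshold; POP_C alone is PARTIAL_C;
    anything else (including a lone propeller) is rejected."""
    seq_ids = {h.seq_id for h in domain_hits}
    if len(seq_ids) > 1:
        raise ValueError(f"hits from multiple sequences: {sorted(seq_ids)}")
    passing = {h.profile for h in domain_hits if h.evalue <= e_threshold}
    if "POP_N" in passing and "POP_C" in passing:
        return FULL_POP
    if "POP_C" in passing:
        return PARTIAL_C
    return REJECTED


def two_tier_enrichment(
    stringent: set,
    relaxed: set,
    cross_evalue,
    architectures: dict,
    cross_threshold: float = RELAXED_EVALUE,
) -> set:
    """Confirm relaxed-tier hits against the stringent "true homolog" database.

    ``cross_evalue`` maps a sequence id to its best E-value against the
    stringent-hit database (here: a profile built from the stringent hits'
    domain windows, a declared stand-in for the all-vs-all BLAST of the
    original procedure).  The result always satisfies
    stringent <= confirmed <= relaxed.
    """
    stringent, relaxed = set(stringent), set(relaxed)
    if not stringent <= relaxed:
        raise ValueError("stringent hit set must be a subset of the relaxed set")
    confirmed = set(stringent)
    for sid in relaxed - stringent:
        if architectures.get(sid) not in (FULL_POP, PARTIAL_C):
            continue
        e = cross_evalue(sid) if callable(cross_evalue) else cross_evalue[sid]
        if e is not None and e <= cross_threshold:
            confirmed.add(sid)
    return confirmed


def assign_family(
    sequence: str,
    family_profiles: dict,
    seq_id: str = "",
    n_windows: int | None = None,
) -> tuple[str, float | None]:
    """Best of the four calibrated family profiles, with a log10 E-value margin.

    Returns ``(family, margin)`` where margin is log10(runner-up E / best E);
    exact E-value ties break by higher bit score, then by the fixed family
    order POP > DPP > ACC > ABH.  When no profile scores below E=10 the
    sequence is reported unresolved within the superfamily.
    """
    import math

    results = []
    for rank, fam in enumerate(FAMILY_ORDER):
        if fam not in family_profiles:
            continue
        if len(sequence) < family_profiles[fam].length:
            continue  # profile cannot fit; scanning would only warn
        hit = best_hit(family_profiles[fam], sequence, seq_id=seq_id,
                       n_windows=n_windows)
        if hit is not None:
            results.append((hit.evalue, -hit.bits, rank, fam))
    results.sort()
    if not results or results[0][0] > UNRESOLVED_EVALUE:
        return UNRESOLVED, None
    best = results[0]
    margin = None
    if len(results) > 1:
        margin = math.log10(results[1][0] / best[0]) if best[0] > 0 else float("inf")
    return best[3], margin


def annotate_hypothetical(
    architecture: str,
    pop_query_evalue: float | None,
    family: str,
    e_threshold: float = RELAXED_EVALUE,
) -> str:
    """Annotation verdict for a sequence without a prior POP annotation.

    Promoted to POP only when an annotated-POP query finds it at the relaxed
    threshold *and* it shows the full two-domain architecture; otherwise a
    resolved family call still places it in the alpha/beta-hydrolase
    superfamily; otherwise it stays unannotated.
    """
    if (pop_query_evalue is not None and pop_query_evalue <= e_threshold
            and architecture == FULL_POP):
        return NEWLY_ANNOTATED_POP
    if family != UNRESOLVED:
        return NEWLY_ANNOTATED_ABH
    return UNANNOTATED
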