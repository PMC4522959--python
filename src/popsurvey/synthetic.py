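"""Synthetic prokaryotic proteomes with planted serine-protease ground truth.

The generator emulates the inputs of a genome-wide prolyl oligopeptidase
(POP) survey: per-genome proteome FASTA files, gene tables with chromosome
ordinals, seed alignments for domain and family profiles, and optional
localization labels.  Every sequence carries a truth record (family,
architecture, subtype, planted features, paralog origin) so each downstream
stage can be scored against a known answer.

Design of the planted POP subtypes
----------------------------------
All POP subtypes share one base consensus for the seven-bladed beta-propeller
(``POP_N``) and the alpha/beta-hydrolase catalytic domain (``POP_C``) and
differ only at fixed motif slots where each subtype carries its own exclusive
signature (conservation 1.0), flanked by low-conservation spacer columns.
Shared background means spurious conserved stretches inside one subtype's
alignment carry base consensus, which re-occurs in other subtypes and is
therefore rejected by the class-specificity exclusion scan; spacers stop
maximal conserved runs from leaking past the signature, so discovered
class-specific motifs coincide with the planted ones column for column.

Mutation model: at each column the consensus residue survives with the
column's conservation ``c``, otherwise it is replaced by a uniform draw over
all 20 residues (self-replacement possible), giving the closed-form match
probability ``c + (1 - c)/20``.  There is no indel process; linkers have
fixed lengths.  Signal peptides and TM helices are planted as unambiguous
hydrophobic runs, and domain consensus generation avoids hydrophobic windows
so the hydropathy detector's verdict always agrees with the planted flags.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import AMINO_ACIDS, hydropathy, pairwise_identity_global, write_fasta
from .genome_stats import (
    SIGNAL_REGION, SIGNAL_WINDOW, TM_WINDOW, feature_flags,
)

log = logging.getLogger(__name__)

ARCHITECTURES = ("FULL", "PARTIAL_C", "PROPELLER_ONLY", "NONE")
FAMILIES = ("POP", "DPP", "OPB", "ACC", "ABH", "NONE")
ORIGINS = ("ANCESTRAL", "DUPLICATED", "TRANSFERRED")

_HYDROPHOBIC = "LIVF"  # strongly hydrophobic per Kyte-Doolittle
#: consensus windows are kept below this mean hydropathy so that emission
#: noise cannot push an unplanted window over the detector thresholds
_CONSENSUS_HYDROPATHY_MARGIN = 1.0


class MotifCollisionError(ValueError):
    """A planted subtype motif occurs in another subtype's template."""


@dataclass(frozen=True)
class DomainTemplate:
    """Consensus plus per-column conservation for one domain."""

    name: str
    consensus: str
    conservation: np.ndarray  # per-column probability in [0, 1]

    def __post_init__(self):
        if len(self.consensus) != len(self.conservation):
            raise ValueError("conservation vector must match consensus length")
        if np.any(self.conservation < 0) or np.any(self.conservation > 1):
            raise ValueError("conservation values must lie in [0, 1]")

    @property
    def length(self) -> int:
        return len(self.consensus)


def _random_consensus(length: int, rng: np.random.Generator,
                      background=None) -> str:
    p = background if background is not None else None
    codes = rng.choice(20, size=length, p=p)
    return "".join(AMINO_ACIDS[c] for c in codes)


def _too_hydrophobic(consensus: str) -> np.ndarray | None:
    """Return indices of the first offending hydrophobic window, if any."""
    kd = hydropathy(consensus)
    for w in (SIGNAL_WINDOW, TM_WINDOW):
        if len(kd) < w:
            continue
        means = np.convolve(kd, np.ones(w) / w, mode="valid")
        bad = np.flatnonzero(means >= _CONSENSUS_HYDROPATHY_MARGIN)
        if bad.size:
            return np.arange(bad[0], bad[0] + w)
    return None


def generate_domain_template(
    name: str,
    length: int,
    conservation: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    background=None,
) -> DomainTemplate:
    """Draw a uniform-random consensus of ``length`` columns.

    Hydrophobic windows are redrawn so that the consensus itself can never
    trip the signal/TM hydropathy detector; planted features remain the
    only unambiguous hydrophobic runs in emitted sequences.
    """
    if length < 10:
        raise ValueError("domain template length must be at least 10")
    if not 0 < conservation <= 1:
        raise ValueError("conservation must lie in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    consensus = list(_random_consensus(length, rng, background))
    for _ in range(1000):
        bad = _too_hydrophobic("".join(consensus))
        if bad is None:
            break
        for i in bad:
            consensus[i] = AMINO_ACIDS[rng.integers(20)]
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not draw a consensus without hydrophobic runs")
    return DomainTemplate(
        name=name,
        consensus="".join(consensus),
        conservation=np.full(length, float(conservation)),
    )


def emit_from_template(template: DomainTemplate, rng: np.random.Generator) -> str:
    """One noisy instance: per column keep consensus w.p. c, else uniform draw."""
    keep = rng.random(template.length) < template.conservation
    draws = rng.integers(0, 20, size=template.length)
    out = [
        template.consensus[i] if keep[i] else AMINO_ACIDS[draws[i]]
        for i in range(template.length)
    ]
    return "".join(out)


@dataclass(frozen=True)
class EmissionInfo:
    architecture: str
    domain_spans: dict  # template name -> (start, end) on the emitted sequence
    signal: bool
    tm: bool


def _signal_peptide(rng: np.random.Generator) -> str:
    # Met + 12-residue strongly hydrophobic core inside the first 30 positions
    core = "".join(rng.choice(list(_HYDROPHOBIC), size=12))
    tail = "".join(rng.choice(list("KRNDQ"), size=2))
    return "M" + core + tail


def _tm_tail(rng: np.random.Generator) -> str:
    helix = "".join(rng.choice(list(_HYDROPHOBIC), size=TM_WINDOW))
    return "".join(rng.choice(list("KRNDQ"), size=4)) + helix + "".join(
        rng.choice(list("KRNDQ"), size=3)
    )


def emit_sequence(
    architecture: str,
    templates: dict,
    motifs=None,
    signal: bool = False,
    tm: bool = False,
    linker_length: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    none_length: int = 140,
    domain_order=("POP_N", "POP_C"),
    max_tries: int = 200,
) -> tuple[str, EmissionInfo]:
    """Emit one sequence of the requested domain architecture plus its truth.

    ``motifs`` is an optional list of ``(template_name, offset, motif)``
    triples; each motif overwrites the stated columns of its domain segment
    in every emission.  The emission is redrawn until the hydropathy
    detector's signal/TM verdict matches the planted flags, which is the
    generator's "unambiguous features" contract.
    """
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_name, c_name = domain_order
    if architecture == "FULL":
        parts = [n_name, "linker", c_name]
    elif architecture == "PARTIAL_C":
        parts = [c_name]
    elif architecture == "PROPELLER_ONLY":
        parts = [n_name]
    else:
        parts = ["random"]
    for (tname, offset, motif) in motifs or ():
        tmpl = templates[tname]
        if offset < 0 or offset + len(motif) > tmpl.length:
            raise ValueError(
                f"motif offset {offset}+{len(motif)} outside template "
                f"{tname!r} of length {tmpl.length}"
            )

    for _ in range(max_tries):
        segments: list[str] = []
        spans: dict = {}
        pos = 0
        prefix = _signal_peptide(rng) if signal else ""
        pos = len(prefix)
        for part in parts:
            if part == "linker":
                seg = _random_consensus(linker_length, rng)
            elif part == "random":
                seg = _random_consensus(none_length, rng)
            else:
                seg = emit_from_template(templates[part], rng)
                for (tname, offset, motif) in motifs or ():
                    if tname == part:
                        seg = seg[:offset] + motif + seg[offset + len(motif):]
                spans[part] = (pos, pos + len(seg))
            segments.append(seg)
            pos += len(seg)
        suffix = _tm_tail(rng) if tm else ""
        seq = prefix + "".join(segments) + suffix
        flags = feature_flags(seq, warn=False)
        if flags.signal == signal and bool(flags.tm_spans) == tm:
            return seq, EmissionInfo(
                architecture=architecture, domain_spans=spans,
                signal=signal, tm=tm,
            )
    raise RuntimeError(
        f"could not emit a {architecture} sequence with unambiguous features "
        f"after {max_tries} tries"
    )


# --------------------------------------------------------------------------
# survey-level generation


@dataclass
class SurveyPlan:
    """Study conditions for one synthetic survey (defaults are the study)."""

    n_subtypes: int = 8
    seqs_per_subtype: int = 12
    n_genomes: int = 12
    n_lineages: int = 3
    pop_n_len: int = 80
    pop_c_len: int = 60
    linker_len: int = 10
    base_conservation: float = 0.9
    motif_len: int = 6
    motifs_per_subtype: int = 4
    spacer_conservation: float = 0.5
    motif_slots: tuple = (("POP_N", 20), ("POP_N", 50), ("POP_C", 15), ("POP_C", 40))
    # related families and decoys
    n_dpp: int = 6
    n_opb: int = 6
    n_acc: int = 6
    n_abh: int = 8
    n_partial: int = 6
    n_propeller_only: int = 4
    # twilight-zone POPs: real full POPs too diverged for the stringent tier
    n_twilight: int = 4
    twilight_conservation: float = 0.5
    # paralog plan: one transfer-expanded genome, one tandem duplication
    n_transferred: int = 16
    transfer_conservation: float = 0.5
    transfer_identity_ceiling: float = 0.35
    transfer_min_separation: int = 10
    duplicate_mutation_rate: float = 0.02
    # planted membrane/secretion features
    n_signal: int = 6
    n_tm: int = 6
    seed_alignment_size: int = 12
    genome_size: int = 40
    filler_length: int = 140
    hypothetical_per_subtype: int = 1

    def validate(self) -> None:
        if self.n_subtypes < 2:
            raise ValueError("at least 2 subtypes are required")
        if self.motifs_per_subtype > len(self.motif_slots):
            raise ValueError("more motifs per subtype than motif slots")
        if self.n_lineages < 1 or self.n_genomes < 3:
            raise ValueError("need >= 3 genomes and >= 1 lineage")
        # motif slots (plus one spacer column each side) must not collide
        slots = sorted(self.motif_slots[: self.motifs_per_subtype])
        for (da, oa), (db, ob) in itertools.combinations(slots, 2):
            if da == db and abs(oa - ob) < self.motif_len + 2:
                raise MotifCollisionError(f"motif slots {oa} and {ob} overlap on {da}")
        for dom, off in slots:
            length = self.pop_n_len if dom == "POP_N" else self.pop_c_len
            if off < 1 or off + self.motif_len + 1 > length:
                raise ValueError(f"motif slot {dom}:{off} outside domain")


@dataclass
class Survey:
    """A generated survey: proteomes, tables, seeds and planted truth."""

    plan: SurveyPlan
    seed: int
    genomes: dict  # genome id -> {gene id: sequence}
    gene_table: pd.DataFrame  # includes truth columns
    seed_alignments: dict  # profile name -> list of aligned sequences
    localization: pd.DataFrame
    subtype_motifs: dict  # subtype id -> tuple of planted exclusive motifs
    templates: dict  # template name -> DomainTemplate (incl. per-subtype)
    lineages: dict  # genome id -> lineage label

    @property
    def sequences(self) -> dict:
        """All sequences across genomes as one {gene_id: sequence} dict."""
        return {g: s for genes in self.genomes.values() for g, s in genes.items()}

    def subtype_templates(self, subtype: int) -> dict:
        return {
            "POP_N": self.templates[f"POP_N_s{subtype}"],
            "POP_C": self.templates[f"POP_C_s{subtype}"],
        }

    def emit_holdout(self, subtype: int, n: int, seed: int) -> list[str]:
        """Fresh emissions from one subtype's templates (not in the survey)."""
        rng = np.random.default_rng(seed)
        tmpls = self.subtype_templates(subtype)
        return [
            emit_sequence("FULL", tmpls, linker_length=self.plan.linker_len,
                          rng=rng)[0]
            for _ in range(n)
        ]


def _draw_motif(rng: np.random.Generator, length: int, forbidden_text: str,
                used: set) -> str:
    """An exclusive signature: absent from all consensi drawn so far and
    hydrophilic enough never to imitate a planted membrane feature."""
    for _ in range(10000):
        motif = _random_consensus(length, rng)
        if motif in used or motif in forbidden_text:
            continue
        if float(np.mean(hydropathy(motif))) > _CONSENSUS_HYDROPATHY_MARGIN:
            continue
        return motif
    raise MotifCollisionError("could not draw a collision-free subtype motif")


def _subtype_template(base: DomainTemplate, subtype: int, slots, motifs,
                      spacer_conservation: float) -> DomainTemplate:
    consensus = list(base.consensus)
    conservation = base.conservation.copy()
    for (off, motif) in zip(slots, motifs):
        consensus[off : off + len(motif)] = motif
        conservation[off : off + len(motif)] = 1.0
        conservation[off - 1] = spacer_conservation
        conservation[off + len(motif)] = spacer_conservation
    return DomainTemplate(
        name=f"{base.name}_s{subtype}",
        consensus="".join(consensus),
        conservation=conservation,
    )


_ANNOTATIONS = {
    "POP": "prolyl oligopeptidase",
    "DPP": "dipeptidyl peptidase IV",
    "OPB": "oligopeptidase B",
    "ACC": "acylaminoacyl peptidase",
    "ABH": "alpha/beta fold hydrolase",
}

TRUTH_COLUMNS = [
    "gene_id", "genome_id", "ordinal", "lineage", "annotation",
    "family", "architecture", "subtype", "signal", "tm", "origin",
    "conservation",
]


def generate_survey(plan: SurveyPlan | None = None, seed: int = 0) -> Survey:
    """Generate a full survey with planted ground truth, deterministic per seed."""
    plan = plan or SurveyPlan()
    plan.validate()
    rng = np.random.default_rng(seed)

    # -- base and family templates ------------------------------------------
    c = plan.base_conservation
    templates = {
        "POP_N": generate_domain_template("POP_N", plan.pop_n_len, c, rng=rng),
        "POP_C": generate_domain_template("POP_C", plan.pop_c_len, c, rng=rng),
        "DPP_N": generate_domain_template("DPP_N", 70, c, rng=rng),
        "DPP_C": generate_domain_template("DPP_C", 55, c, rng=rng),
        "OPB_N": generate_domain_template("OPB_N", 75, c, rng=rng),
        "OPB_C": generate_domain_template("OPB_C", 58, c, rng=rng),
        "ACC_N": generate_domain_template("ACC_N", 72, c, rng=rng),
        "ACC_C": generate_domain_template("ACC_C", 52, c, rng=rng),
        "ABH": generate_domain_template("ABH", 60, c, rng=rng),
    }

    # -- subtype signatures --------------------------------------------------
    slots = list(plan.motif_slots[: plan.motifs_per_subtype])
    subtype_motifs: dict[int, tuple] = {}
    used: set[str] = set()
    for s in range(1, plan.n_subtypes + 1):
        for _ in range(100):
            motifs = []
            forbidden = " ".join(t.consensus for t in templates.values())
            for _slot in slots:
                m = _draw_motif(rng, plan.motif_len, forbidden, used)
                motifs.append(m)
                forbidden += " " + m
            for dom in ("POP_N", "POP_C"):
                dom_slots = [off for (d, off) in slots if d == dom]
                dom_motifs = [m for (d, _), m in zip(slots, motifs) if d == dom]
                templates[f"{dom}_s{s}"] = _subtype_template(
                    templates[dom], s, dom_slots, dom_motifs,
                    plan.spacer_conservation,
                )
            # redraw the whole motif set if planting created a hydrophobic run
            # or put an earlier subtype's motif at a motif/base junction
            new_cons = (templates[f"POP_N_s{s}"].consensus
                        + " " + templates[f"POP_C_s{s}"].consensus)
            if (_too_hydrophobic(templates[f"POP_N_s{s}"].consensus) is None
                    and _too_hydrophobic(templates[f"POP_C_s{s}"].consensus) is None
                    and not any(m in new_cons for m in used)):
                used.update(motifs)
                subtype_motifs[s] = tuple(motifs)
                break
        else:  # pragma: no cover
            raise MotifCollisionError(f"could not plant motifs for subtype {s}")

    # -- genome roster -------------------------------------------------------
    genome_ids = [f"G{i + 1:02d}" for i in range(plan.n_genomes)]
    lineages = {g: f"L{i % plan.n_lineages + 1}" for i, g in enumerate(genome_ids)}
    hgt_genome = genome_ids[0]
    dup_genome = genome_ids[1]
    ordinary = genome_ids[1:]

    @dataclass
    class _GeneSpec:
        genome: str
        family: str
        architecture: str
        subtype: int | None = None
        origin: str = "ANCESTRAL"
        conservation: float = plan.base_conservation
        signal: bool = False
        tm: bool = False
        annotation: str = ""
        sequence: str = ""
        copy_of: int | None = None  # index of the parent spec, for duplicates

    specs: list[_GeneSpec] = []
    # ancestral subtype POPs, round-robin over the non-HGT genomes
    k = 0
    for s in range(1, plan.n_subtypes + 1):
        for i in range(plan.seqs_per_subtype):
            ann = ("hypothetical protein" if i < plan.hypothetical_per_subtype
                   else _ANNOTATIONS["POP"])
            specs.append(_GeneSpec(
                genome=ordinary[k % len(ordinary)], family="POP",
                architecture="FULL", subtype=s, annotation=ann,
            ))
            k += 1
    # one tandem duplication of the first subtype-1 POP in the dup genome
    parent_idx = next(
        i for i, sp in enumerate(specs) if sp.genome == dup_genome and sp.subtype == 1
    )
    specs.append(_GeneSpec(
        genome=dup_genome, family="POP", architecture="FULL", subtype=1,
        origin="DUPLICATED", annotation=_ANNOTATIONS["POP"], copy_of=parent_idx,
    ))
    # transfer-expanded genome
    for _ in range(plan.n_transferred):
        specs.append(_GeneSpec(
            genome=hgt_genome, family="POP", architecture="FULL",
            origin="TRANSFERRED", conservation=plan.transfer_conservation,
            annotation=_ANNOTATIONS["POP"],
        ))
    # related families, partials, decoys, twilight POPs
    rosters = [
        ("DPP", "NONE", plan.n_dpp, c, _ANNOTATIONS["DPP"]),
        ("OPB", "NONE", plan.n_opb, c, _ANNOTATIONS["OPB"]),
        ("ACC", "NONE", plan.n_acc, c, _ANNOTATIONS["ACC"]),
        ("ABH", "NONE", plan.n_abh, c, "hypothetical protein"),
        ("POP", "PARTIAL_C", plan.n_partial, c, _ANNOTATIONS["POP"]),
        ("POP", "PROPELLER_ONLY", plan.n_propeller_only, c, "hypothetical protein"),
        ("POP", "FULL", plan.n_twilight, plan.twilight_conservation,
         "hypothetical protein"),
    ]
    for family, arch, n, cons, ann in rosters:
        for _ in range(n):
            specs.append(_GeneSpec(
                genome=ordinary[k % len(ordinary)], family=family,
                architecture=arch, conservation=cons, annotation=ann,
            ))
            k += 1
    # plant signal/TM flags on partial POPs and ancestral POPs, alternating
    partial_idx = [i for i, sp in enumerate(specs) if sp.architecture == "PARTIAL_C"]
    pop_idx = [i for i, sp in enumerate(specs)
               if sp.architecture == "FULL" and sp.origin == "ANCESTRAL"
               and sp.subtype is not None]
    for i in (partial_idx + pop_idx)[: plan.n_signal]:
        specs[i].signal = True
    for i in (pop_idx[::-1] + partial_idx[::-1])[: plan.n_tm]:
        specs[i].tm = True

    # -- emission ------------------------------------------------------------
    def emit_spec(sp: _GeneSpec) -> str:
        if sp.family == "POP":
            if sp.subtype is not None:
                tmpls = {
                    "POP_N": templates[f"POP_N_s{sp.subtype}"],
                    "POP_C": templates[f"POP_C_s{sp.subtype}"],
                }
            else:
                tmpls = {
                    "POP_N": dataclasses.replace(
                        templates["POP_N"],
                        conservation=np.full(plan.pop_n_len, sp.conservation)),
                    "POP_C": dataclasses.replace(
                        templates["POP_C"],
                        conservation=np.full(plan.pop_c_len, sp.conservation)),
                }
            return emit_sequence(
                sp.architecture, tmpls, signal=sp.signal, tm=sp.tm,
                linker_length=plan.linker_len, rng=rng,
            )[0]
        if sp.family == "NONE":
            return emit_sequence(
                "NONE", {}, signal=sp.signal, tm=sp.tm,
                none_length=plan.filler_length, rng=rng,
            )[0]
        if sp.family == "ABH":
            return emit_sequence(
                "PARTIAL_C", {"POP_C": templates["ABH"]}, signal=sp.signal,
                tm=sp.tm, rng=rng,
            )[0]
        # two-domain related families
        tmpls = {"POP_N": templates[f"{sp.family}_N"],
                 "POP_C": templates[f"{sp.family}_C"]}
        return emit_sequence(
            "FULL", tmpls, signal=sp.signal, tm=sp.tm,
            linker_length=plan.linker_len, rng=rng,
        )[0]

    def mutate(seq: str, rate: float) -> str:
        hit = rng.random(len(seq)) < rate
        draws = rng.integers(0, 20, size=len(seq))
        return "".join(
            AMINO_ACIDS[draws[i]] if hit[i] else ch for i, ch in enumerate(seq)
        )

    for sp in specs:
        if sp.copy_of is not None:
            parent = specs[sp.copy_of]
            for _ in range(200):
                seq = mutate(parent.sequence, plan.duplicate_mutation_rate)
                fl = feature_flags(seq, warn=False)
                if fl.signal == sp.signal and bool(fl.tm_spans) == sp.tm:
                    break
            sp.sequence = seq
        else:
            sp.sequence = emit_spec(sp)

    # transferred paralogs must stay below the identity ceiling pairwise
    trans = [sp for sp in specs if sp.origin == "TRANSFERRED"]
    for _ in range(200):
        bad = None
        for a, b in itertools.combinations(trans, 2):
            if pairwise_identity_global(a.sequence, b.sequence) > plan.transfer_identity_ceiling:
                bad = b
                break
        if bad is None:
            break
        bad.sequence = emit_spec(bad)
    else:  # pragma: no cover
        raise RuntimeError("could not satisfy the transfer identity ceiling")

    # planted-motif exclusivity must hold in the emitted data
    def motif_ok() -> bool:
        for s, motifs in subtype_motifs.items():
            for sp in specs:
                holds = {m for m in motifs if m in sp.sequence}
                if sp.subtype == s:
                    if len(holds) != len(motifs):
                        # only mutation noise on a tandem duplicate can erase
                        # a planted motif; redraw its mutations
                        if sp.copy_of is None:  # pragma: no cover
                            raise AssertionError(
                                "planted motif missing from own subtype")
                        sp.sequence = mutate(specs[sp.copy_of].sequence,
                                             plan.duplicate_mutation_rate)
                        return False
                elif holds:
                    sp.sequence = (mutate(specs[sp.copy_of].sequence,
                                          plan.duplicate_mutation_rate)
                                   if sp.copy_of is not None else emit_spec(sp))
                    return False
        return True

    for _ in range(100):
        if motif_ok():
            break
    else:  # pragma: no cover
        raise MotifCollisionError("could not keep planted motifs exclusive")

    # -- chromosome layout ---------------------------------------------------
    genomes: dict[str, dict[str, str]] = {g: {} for g in genome_ids}
    rows = []
    by_genome: dict[str, list[_GeneSpec]] = {g: [] for g in genome_ids}
    for sp in specs:
        by_genome[sp.genome].append(sp)

    for g in genome_ids:
        members = by_genome[g]
        placements: dict[int, int] = {}  # spec index within members -> ordinal
        if g == hgt_genome:
            sep = plan.transfer_min_separation
            for j, sp in enumerate(members):
                placements[j] = j * sep
            n_genes = max(plan.genome_size, (len(members) - 1) * sep + 1 + 4)
        else:
            n_genes = plan.genome_size
            dup_j = next((j for j, sp in enumerate(members) if sp.copy_of is not None), None)
            taken: set[int] = set()
            if dup_j is not None:
                parent = specs[members[dup_j].copy_of]
                pj = members.index(parent)
                o = int(rng.integers(0, n_genes - 1))
                placements[pj], placements[dup_j] = o, o + 1
                taken = {o, o + 1}
            free = [o for o in range(n_genes) if o not in taken]
            free = list(rng.permutation(free))
            for j, sp in enumerate(members):
                if j not in placements:
                    placements[j] = int(free.pop())
        member_ordinals = set(placements.values())
        filler_ordinals = [o for o in range(n_genes) if o not in member_ordinals]

        entries = []  # (ordinal, spec or None)
        for j, sp in enumerate(members):
            entries.append((placements[j], sp))
        for o in filler_ordinals:
            entries.append((o, None))
        for o, sp in sorted(entries, key=lambda t: t[0]):
            gene_id = f"{g}_{o:04d}"
            if sp is None:
                seq = emit_sequence("NONE", {}, none_length=plan.filler_length,
                                    rng=rng)[0]
                row = dict(family="NONE", architecture="NONE", subtype=None,
                           signal=False, tm=False, origin="ANCESTRAL",
                           conservation=0.0, annotation="hypothetical protein")
            else:
                seq = sp.sequence
                row = dict(family=sp.family, architecture=sp.architecture,
                           subtype=sp.subtype, signal=sp.signal, tm=sp.tm,
                           origin=sp.origin, conservation=sp.conservation,
                           annotation=sp.annotation)
            genomes[g][gene_id] = seq
            rows.append({"gene_id": gene_id, "genome_id": g, "ordinal": o,
                         "lineage": lineages[g], **row})

    gene_table = pd.DataFrame(rows, columns=TRUTH_COLUMNS)

    # -- seed alignments for profile construction ----------------------------
    n_seed = plan.seed_alignment_size
    seed_alignments = {
        "POP_N": [emit_from_template(templates["POP_N"], rng) for _ in range(n_seed)],
        "POP_C": [emit_from_template(templates["POP_C"], rng) for _ in range(n_seed)],
    }
    for fam in ("POP", "DPP", "ACC"):
        n_t = templates["POP_N" if fam == "POP" else f"{fam}_N"]
        c_t = templates["POP_C" if fam == "POP" else f"{fam}_C"]
        linker = _random_consensus(plan.linker_len, rng)
        seed_alignments[f"FAM_{fam}"] = [
            emit_from_template(n_t, rng) + linker + emit_from_template(c_t, rng)
            for _ in range(n_seed)
        ]
    seed_alignments["FAM_ABH"] = [
        emit_from_template(templates["ABH"], rng) for _ in range(n_seed)
    ]

    # -- localization labels (ingested, never predicted) ---------------------
    loc_rows = []
    compartments = ["cytoplasmic", "periplasmic", "membrane", "extracellular"]
    for _, r in gene_table[gene_table["family"] != "NONE"].iterrows():
        loc_rows.append({
            "gene_id": r["gene_id"], "genome_id": r["genome_id"],
            "localization": compartments[int(rng.integers(len(compartments)))],
        })
    localization = pd.DataFrame(loc_rows,
                                columns=["gene_id", "genome_id", "localization"])

    return Survey(
        plan=plan, seed=seed, genomes=genomes, gene_table=gene_table,
        seed_alignments=seed_alignments, localization=localization,
        subtype_motifs=subtype_motifs, templates=templates, lineages=lineages,
    )


def write_survey(survey: Survey, outdir) -> None:
    """Write proteome FASTAs, gene/localization tables, seeds and config."""
    from pathlib import Path

    out = Path(outdir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "seeds").mkdir(parents=True, exist_ok=True)
    ordinal_of = dict(zip(survey.gene_table["gene_id"], survey.gene_table["ordinal"]))
    for g, genes in sorted(survey.genomes.items()):
        records = {
            f"{g}|{gene}|{ordinal_of[gene]}": seq for gene, seq in sorted(genes.items())
        }
        write_fasta(out / "genomes" / f"{g}.fasta", records)
    survey.gene_table.to_csv(out / "gene_table.tsv", sep="\t", index=False)
    survey.localization.to_csv(out / "localization.tsv", sep="\t", index=False)
    for name, rows in sorted(survey.seed_alignments.items()):
        write_fasta(out / "seeds" / f"{name}.afa",
                    {f"{name}_{i + 1}": r for i, r in enumerate(rows)})
    with open(out / "survey.cfg", "w") as fh:
        fh.write(f"seed={survey.seed}\n")
        for f in dataclasses.fields(survey.plan):
            fh.write(f"{f.name}={getattr(survey.plan, f.name)}\n")
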