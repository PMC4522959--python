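"""End-to-end survey orchestration: simulate -> search -> triage -> cluster ->
motifs -> classify -> stats, with a reproducible run manifest.

Each stage reads its inputs from, and writes its outputs to, one run
directory, so stages can be re-run individually from the command line.
All randomness is funnelled through seeds recorded in the manifest; a rerun
with the same configuration and seed reproduces byte-identical outputs
(the manifest deliberately contains no timestamps).
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import read_fasta, write_fasta
from .clustering import bootstrap_clusters
from .genome_stats import lineage_stats, summarize_genomes
from .motifs import (
    ClassSpecificMotif, Motif, SubtypeTable, assign_subtype, define_subtypes,
    motif_table,
)
from .profiles import ProfileModel, best_hit, build_profile, calibrate, scan
from .synthetic import SurveyPlan, generate_survey, write_survey
from .triage import (
    ANNOTATED, FULL_POP, PARTIAL_C, REJECTED, TIER_RELAXED_CONFIRMED,
    TIER_STRINGENT, UNRESOLVED, annotate_hypothetical, assign_family,
    classify_architecture, two_tier_enrichment,
)
from .profiles import DomainHit

log = logging.getLogger(__name__)

STAGES = ("simulate", "search", "triage", "cluster", "motifs", "classify", "stats")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class SurveyConfig:
    """Run-level thresholds and sizes (defaults are the survey conventions)."""

    seed: int = 0
    stringent_evalue: float = 1e-10
    relaxed_evalue: float = 1e-3
    cross_threshold: float = 1e-3
    motif_threshold: float = 0.95
    motif_min_len: int = 3
    bootstrap_reps: int = 500
    support_min: float = 50.0
    min_cluster_size: int = 3
    max_intervening: int = 5
    calibration_samples: int = 2000
    null_length: int = 150
    pseudocount: float = 1.0

    def validate(self) -> None:
        if not (0 < self.stringent_evalue <= self.relaxed_evalue <= 1):
            raise ValueError("need 0 < stringent <= relaxed <= 1")
        if not 0 < self.motif_threshold <= 1:
            raise ValueError("motif threshold must lie in (0, 1]")
        if self.bootstrap_reps < 100:
            raise ValueError("bootstrap replicates must be >= 100")
        if self.motif_min_len < 1 or self.min_cluster_size < 1:
            raise ValueError("minimum lengths/sizes must be positive")


def load_config(path) -> SurveyConfig:
    """Read a flat key=value config file; unknown keys are rejected."""
    fields = {f.name: f.type for f in dataclasses.fields(SurveyConfig)}
    kwargs = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in fields:
            raise ValueError(f"unknown config key {key!r}")
        typ = fields[key]
        kwargs[key] = int(value) if "int" in str(typ) else float(value)
    cfg = SurveyConfig(**kwargs)
    cfg.validate()
    return cfg


# -------------------------------------------------------------------------
# input loading


def load_run_inputs(rundir):
    """Load proteomes, gene table, seed alignments and localization labels."""
    rundir = Path(rundir)
    sequences: dict[str, str] = {}
    genome_of: dict[str, str] = {}
    for fa in sorted((rundir / "genomes").glob("*.fasta")):
        for header, seq in read_fasta(fa).items():
            genome_id, gene_id, _ordinal = header.split("|")
            sequences[gene_id] = seq
            genome_of[gene_id] = genome_id
    gene_table = pd.read_csv(rundir / "gene_table.tsv", sep="\t")
    seeds = {
        p.stem: list(read_fasta(p).values())
        for p in sorted((rundir / "seeds").glob("*.afa"))
    }
    loc_path = rundir / "localization.tsv"
    localization = pd.read_csv(loc_path, sep="\t") if loc_path.exists() else None
    return sequences, genome_of, gene_table, seeds, localization


def validate_inputs(rundir) -> list[tuple[str, str]]:
    """Diagnostics over a run directory's inputs: (severity, message) pairs.

    Severities: 'fatal' (unusable inputs: unreadable files, duplicate or
    malformed records) and 'warning' (recoverable: gene-table rows without a
    sequence and vice versa).
    """
    rundir = Path(rundir)
    diags: list[tuple[str, str]] = []
    sequences: dict[str, str] = {}
    genome_dir = rundir / "genomes"
    if not genome_dir.is_dir():
        return [("fatal", f"missing genomes directory {genome_dir}")]
    for fa in sorted(genome_dir.glob("*.fasta")):
        try:
            records = read_fasta(fa)
        except Exception as exc:  # malformed FASTA or duplicate ids
            diags.append(("fatal", f"{fa.name}: {exc}"))
            continue
        for header, seq in records.items():
            parts = header.split("|")
            if len(parts) != 3:
                diags.append(("fatal", f"{fa.name}: malformed header {header!r}"))
                continue
            gene_id = parts[1]
            if gene_id in sequences:
                diags.append(("fatal", f"duplicate gene id {gene_id!r}"))
            if not seq or any(c not in "ACDEFGHIKLMNPQRSTVWYX" for c in seq):
                diags.append(("fatal", f"{gene_id}: invalid residues"))
            sequences[gene_id] = seq
    table_path = rundir / "gene_table.tsv"
    if not table_path.exists():
        diags.append(("fatal", f"missing gene table {table_path}"))
        return diags
    gene_table = pd.read_csv(table_path, sep="\t")
    for gid in gene_table["gene_id"]:
        if gid not in sequences:
            diags.append(("warning", f"gene table references missing sequence {gid!r}"))
    known = set(gene_table["gene_id"])
    for gid in sequences:
        if gid not in known:
            diags.append(("warning", f"sequence {gid!r} absent from gene table"))
    return diags


# -------------------------------------------------------------------------
# profile construction (deterministic given seeds + config)


def _calibrated_profile(rows, name, config: SurveyConfig, salt: int) -> ProfileModel:
    profile = build_profile(rows, pseudocount=config.pseudocount, name=name)
    null_length = max(config.null_length, profile.length)
    return calibrate(
        profile, null_length=null_length, n_samples=config.calibration_samples,
        seed=config.seed * 1009 + salt,
    )


def domain_profiles(seeds, config: SurveyConfig) -> dict:
    return {
        name: _calibrated_profile(seeds[name], name, config, salt)
        for salt, name in enumerate(("POP_N", "POP_C"), start=1)
    }


def family_profiles(seeds, config: SurveyConfig) -> dict:
    out = {}
    for salt, fam in enumerate(("POP", "DPP", "ACC", "ABH"), start=11):
        key = f"FAM_{fam}"
        if key in seeds:
            out[fam] = _calibrated_profile(seeds[key], key, config, salt)
    return out


# -------------------------------------------------------------------------
# stages


def stage_simulate(config: SurveyConfig, rundir, plan: SurveyPlan | None = None) -> dict:
    survey = generate_survey(plan, seed=config.seed)
    write_survey(survey, rundir)
    return {
        "sequences": len(survey.sequences),
        "genomes": len(survey.genomes),
        "seed_alignments": len(survey.seed_alignments),
    }


def stage_search(config: SurveyConfig, rundir) -> dict:
    sequences, _, _, seeds, _ = load_run_inputs(rundir)
    profiles = domain_profiles(seeds, config)
    rows = []
    for name, profile in profiles.items():
        total_windows = sum(
            max(len(s) - profile.length + 1, 0) for s in sequences.values()
        )
        for gene_id, seq in sequences.items():
            hit = best_hit(profile, seq, seq_id=gene_id, n_windows=total_windows)
            if hit is not None and hit.evalue <= config.relaxed_evalue:
                rows.append({
                    "sequence_id": hit.seq_id, "profile": hit.profile,
                    "start": hit.start, "end": hit.end,
                    "bits": round(hit.bits, 6), "evalue": float(f"{hit.evalue:.6e}"),
                })
    hits = pd.DataFrame(
        rows, columns=["sequence_id", "profile", "start", "end", "bits", "evalue"],
    ).sort_values(["sequence_id", "profile"], kind="mergesort").reset_index(drop=True)
    hits.to_csv(Path(rundir) / "hits.tsv", sep="\t", index=False)
    return {
        "hits_pop_n": int((hits["profile"] == "POP_N").sum()),
        "hits_pop_c": int((hits["profile"] == "POP_C").sum()),
    }


def _load_hits(rundir) -> dict:
    """hits.tsv -> {sequence_id: [DomainHit, ...]}"""
    df = pd.read_csv(Path(rundir) / "hits.tsv", sep="\t")
    out: dict[str, list] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.sequence_id, []).append(
            DomainHit(seq_id=r.sequence_id, profile=r.profile, start=int(r.start),
                      end=int(r.end), bits=float(r.bits), evalue=float(r.evalue))
        )
    return out


def stage_triage(config: SurveyConfig, rundir) -> dict:
    sequences, genome_of, gene_table, seeds, _ = load_run_inputs(rundir)
    hits_by_seq = _load_hits(rundir)
    annotation_of = dict(zip(gene_table["gene_id"], gene_table["annotation"]))

    architecture = {
        sid: classify_architecture(hs, e_threshold=config.relaxed_evalue)
        for sid, hs in hits_by_seq.items()
    }
    arch_stringent = {
        sid: classify_architecture(hs, e_threshold=config.stringent_evalue)
        for sid, hs in hits_by_seq.items()
    }
    stringent = {s for s, a in arch_stringent.items() if a != REJECTED}
    relaxed = {s for s, a in architecture.items() if a != REJECTED}

    # cross-search stand-in: one profile over the stringent hits' POP_C windows
    def window(sid, profile_name):
        for h in hits_by_seq.get(sid, ()):
            if h.profile == profile_name:
                return sequences[sid][h.start : h.end]
        return None

    cross_rows = [window(s, "POP_C") for s in sorted(stringent)]
    cross_rows = [w for w in cross_rows if w is not None]
    if len(cross_rows) >= 2:
        cross = _calibrated_profile(cross_rows, "TRUE_HOMOLOGS", config, salt=7)

        def cross_evalue(sid):
            hit = best_hit(cross, sequences[sid], seq_id=sid)
            return hit.evalue if hit else None
    else:
        def cross_evalue(sid):  # no stringent database: nothing can be confirmed
            return None

    confirmed = two_tier_enrichment(
        stringent, relaxed, cross_evalue, architecture,
        cross_threshold=config.cross_threshold,
    )

    fams = family_profiles(seeds, config)
    pop_annotated = [
        s for s in sorted(confirmed)
        if "prolyl oligopeptidase" in str(annotation_of.get(s, ""))
    ]
    pop_query_rows = [w for s in pop_annotated if (w := window(s, "POP_C"))]
    pop_query = (
        _calibrated_profile(pop_query_rows, "POP_QUERIES", config, salt=8)
        if len(pop_query_rows) >= 2 else None
    )

    call_rows = []
    for sid in sorted(confirmed):
        family, margin = assign_family(sequences[sid], fams, seq_id=sid)
        tier = TIER_STRINGENT if sid in stringent else TIER_RELAXED_CONFIRMED
        best_e = min(h.evalue for h in hits_by_seq[sid])
        status = ANNOTATED
        if "hypothetical" in str(annotation_of.get(sid, "")):
            pq_e = None
            if pop_query is not None:
                h = best_hit(pop_query, sequences[sid], seq_id=sid)
                pq_e = h.evalue if h else None
            status = annotate_hypothetical(
                architecture[sid], pq_e, family, e_threshold=config.relaxed_evalue,
            )
        call_rows.append({
            "sequence_id": sid, "genome_id": genome_of[sid],
            "architecture": architecture[sid], "family": family,
            "family_margin": None if margin is None else round(margin, 4),
            "tier": tier, "annotation_status": status,
            "best_evalue": float(f"{best_e:.6e}"),
        })
    calls = pd.DataFrame(
        call_rows,
        columns=["sequence_id", "genome_id", "architecture", "family",
                 "family_margin", "tier", "annotation_status", "best_evalue"],
    )
    calls.to_csv(Path(rundir) / "homolog_calls.tsv", sep="\t", index=False)

    # superfamily annotation sweep over unconfirmed hypothetical sequences
    # that showed a POP-like signature in the search (i.e. have a domain hit)
    ann_rows = []
    for sid in sorted(hits_by_seq):
        if sid in confirmed or "hypothetical" not in str(annotation_of.get(sid, "")):
            continue
        family, _ = assign_family(sequences[sid], fams, seq_id=sid)
        status = annotate_hypothetical(
            architecture.get(sid, REJECTED), None, family,
            e_threshold=config.relaxed_evalue,
        )
        if status != "UNANNOTATED":
            ann_rows.append({"sequence_id": sid, "genome_id": genome_of[sid],
                             "family": family, "annotation_status": status})
    annotations = pd.DataFrame(
        ann_rows, columns=["sequence_id", "genome_id", "family", "annotation_status"],
    )
    annotations.to_csv(Path(rundir) / "new_annotations.tsv", sep="\t", index=False)

    return {
        "stringent": len(stringent),
        "relaxed": len(relaxed),
        "confirmed": len(confirmed),
        "full_pop": int((calls["architecture"] == FULL_POP).sum()),
        "partial_pop": int((calls["architecture"] == PARTIAL_C).sum()),
        "newly_annotated_pop": int(
            (calls["annotation_status"] == "NEWLY_ANNOTATED_POP").sum()),
        "newly_annotated_abh": len(annotations),
    }


def _cluster_rows(rundir) -> tuple[list, list]:
    """Profile-anchored alignment: POP_N window + POP_C window per full POP."""
    sequences, _, _, _, _ = load_run_inputs(rundir)
    hits_by_seq = _load_hits(rundir)
    calls = pd.read_csv(Path(rundir) / "homolog_calls.tsv", sep="\t")
    ids, rows = [], []
    for sid in calls.loc[calls["architecture"] == FULL_POP, "sequence_id"]:
        segs = {}
        for h in hits_by_seq.get(sid, ()):
            segs[h.profile] = sequences[sid][h.start : h.end]
        if "POP_N" in segs and "POP_C" in segs:
            ids.append(sid)
            rows.append(segs["POP_N"] + segs["POP_C"])
    return ids, rows


def stage_cluster(config: SurveyConfig, rundir) -> dict:
    ids, rows = _cluster_rows(rundir)
    assignment = bootstrap_clusters(
        (ids, rows), n_reps=config.bootstrap_reps, seed=config.seed * 1009 + 9,
        support_min=config.support_min, min_size=config.min_cluster_size,
    )
    out = pd.DataFrame({
        "sequence_id": ids,
        "cluster_id": [
            assignment.assignments[i] if assignment.assignments[i] is not None
            else "UNASSIGNED" for i in ids
        ],
        "support": [
            round(assignment.supports[assignment.assignments[i]], 1)
            if assignment.assignments[i] is not None else ""
            for i in ids
        ],
    })
    out.to_csv(Path(rundir) / "clusters.tsv", sep="\t", index=False)
    if assignment.tree is not None:
        assignment.tree.write(str(Path(rundir) / "tree.nwk"))
    return {
        "clustered_sequences": int((out["cluster_id"] != "UNASSIGNED").sum()),
        "clusters": assignment.n_clusters,
        "unassigned": int((out["cluster_id"] == "UNASSIGNED").sum()),
    }


def _cluster_msas(rundir) -> dict:
    ids, rows = _cluster_rows(rundir)
    row_of = dict(zip(ids, rows))
    clusters = pd.read_csv(Path(rundir) / "clusters.tsv", sep="\t")
    msas: dict[int, list] = {}
    for r in clusters.itertuples(index=False):
        if r.cluster_id != "UNASSIGNED":
            msas.setdefault(int(r.cluster_id), []).append(row_of[r.sequence_id])
    return msas


def stage_motifs(config: SurveyConfig, rundir) -> dict:
    msas = _cluster_msas(rundir)
    if len(msas) < 2:
        raise PipelineError("motifs", f"need >= 2 clusters, found {len(msas)}")
    table = define_subtypes(
        msas, threshold=config.motif_threshold, min_len=config.motif_min_len,
    )
    df = motif_table(table)
    df.to_csv(Path(rundir) / "motifs.tsv", sep="\t", index=False)
    return {
        "conserved_motifs": len(df),
        "class_specific_motifs": int(df["class_specific"].sum()),
        "subtypes": table.n_subtypes,
        "non_subtype_clusters": len(table.non_subtype_clusters),
    }


def load_subtype_table(rundir) -> SubtypeTable:
    df = pd.read_csv(Path(rundir) / "motifs.tsv", sep="\t")
    spec = df[df["class_specific"]]
    motifs: dict[int, list] = {}
    subtype_of_cluster = {}
    for r in spec.itertuples(index=False):
        subtype = int(r.subtype)
        subtype_of_cluster[int(r.cluster_id)] = subtype
        m = Motif(cluster_id=int(r.cluster_id), start=int(r.start), end=int(r.end),
                  consensus=r.consensus,
                  conservations=(float(r.min_conservation),) * (int(r.end) - int(r.start)))
        motifs.setdefault(subtype, []).append(
            ClassSpecificMotif(motif=m, other_cluster_matches={})
        )
    all_clusters = set(df["cluster_id"].astype(int))
    return SubtypeTable(
        subtype_of_cluster=subtype_of_cluster,
        motifs={s: tuple(ms) for s, ms in motifs.items()},
        non_subtype_clusters=tuple(sorted(all_clusters - set(subtype_of_cluster))),
    )


def stage_classify(config: SurveyConfig, rundir) -> dict:
    sequences, _, _, _, _ = load_run_inputs(rundir)
    calls = pd.read_csv(Path(rundir) / "homolog_calls.tsv", sep="\t")
    table = load_subtype_table(rundir)
    rows = []
    for sid in calls.loc[calls["architecture"] == FULL_POP, "sequence_id"]:
        call = assign_subtype(sequences[sid], table, seq_id=sid)
        rows.append({
            "sequence_id": sid,
            "subtype": call.subtype if call.subtype is not None else "UNCLASSIFIED",
            "reason": call.reason,
            "matched_motifs": ",".join(call.matched_motifs),
        })
    out = pd.DataFrame(rows, columns=["sequence_id", "subtype", "reason",
                                      "matched_motifs"])
    out.to_csv(Path(rundir) / "subtype_calls.tsv", sep="\t", index=False)
    return {
        "subtype_calls": len(out),
        "classified": int((out["subtype"] != "UNCLASSIFIED").sum()),
    }


def stage_stats(config: SurveyConfig, rundir) -> dict:
    sequences, _, gene_table, _, localization = load_run_inputs(rundir)
    calls = pd.read_csv(Path(rundir) / "homolog_calls.tsv", sep="\t")
    lstats = lineage_stats(calls, gene_table)
    lstats.to_csv(Path(rundir) / "lineage_stats.tsv", sep="\t", index=False,
                  float_format="%.6g")
    summaries = summarize_genomes(
        calls, gene_table, sequences, localization=localization,
        max_intervening=config.max_intervening,
    )
    rows = []
    for s in summaries:
        ps, cl = s.paralog_stats, s.colocalization
        rows.append({
            "genome_id": s.genome_id,
            "lineage": s.lineage,
            "n_homologs": sum(s.family_counts.values()),
            "n_full_pop": s.architecture_counts.get(FULL_POP, 0),
            "n_partial_pop": s.architecture_counts.get(PARTIAL_C, 0),
            "n_pop_paralogs": len(s.pop_paralogs),
            "multi_copy": bool(ps and ps.multi_copy),
            "paralog_identity_mean": round(ps.mean_identity, 4)
            if ps and ps.mean_identity is not None else "",
            "paralog_identity_min": round(ps.min_identity, 4)
            if ps and ps.min_identity is not None else "",
            "paralog_identity_max": round(ps.max_identity, 4)
            if ps and ps.max_identity is not None else "",
            "n_colocalized_pairs": sum(p.colocalized for p in cl.pairs) if cl else 0,
            "hgt_consistent": bool(cl and cl.hgt_consistent),
            "localization_counts": ";".join(
                f"{k}:{v}" for k, v in sorted(s.localization_counts.items())),
        })
    gsum = pd.DataFrame(rows)
    gsum.to_csv(Path(rundir) / "genome_summary.tsv", sep="\t", index=False)
    return {
        "lineages": len(lstats),
        "genome_summaries": len(gsum),
        "multi_copy_genomes": int(gsum["multi_copy"].sum()) if len(gsum) else 0,
        "hgt_consistent_genomes": int(gsum["hgt_consistent"].sum()) if len(gsum) else 0,
    }


# -------------------------------------------------------------------------
# run-all + manifest

_STAGE_FN = {
    "simulate": stage_simulate,
    "search": stage_search,
    "triage": stage_triage,
    "cluster": stage_cluster,
    "motifs": stage_motifs,
    "classify": stage_classify,
    "stats": stage_stats,
}


def run_pipeline(
    config: SurveyConfig,
    rundir,
    plan: SurveyPlan | None = None,
    stages=STAGES,
) -> dict:
    """Run the survey stages in order, writing TSVs and a run manifest.

    Returns the manifest as a dict.  A stage failure raises
    :class:`PipelineError` naming the stage; outputs of prior stages are
    preserved.
    """
    config.validate()
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    for stage in stages:
        if stage not in _STAGE_FN:
            raise ValueError(f"unknown stage {stage!r}")
        fn = _STAGE_FN[stage]
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                stage_counts = fn(config, rundir, plan=plan)
            else:
                stage_counts = fn(config, rundir)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        for key, value in stage_counts.items():
            counts[f"{stage}.{key}"] = value
        print(f"[popsurvey] stage {stage}: {time.perf_counter() - t0:.2f}s "
              f"{stage_counts}", file=sys.stderr)
    manifest = {"version": __version__}
    for f in dataclasses.fields(config):
        manifest[f"config.{f.name}"] = getattr(config, f.name)
    if plan is not None:
        for f in dataclasses.fields(plan):
            manifest[f"plan.{f.name}"] = getattr(plan, f.name)
    manifest.update({f"counts.{k}": v for k, v in sorted(counts.items())})
    with open(rundir / "manifest.txt", "w") as fh:
        for key in manifest:
            fh.write(f"{key}={manifest[key]}\n")
    return manifest
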