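"""Survey-level statistics: density/occurrence, paralogs, co-localization, features.

These are the quantities behind the gene-family-expansion analysis: how many
homologs a taxonomic lineage carries per genome and per gene product, whether
a genome holds multiple POP paralogs, how similar those paralogs are, and
whether paralog pairs sit next to each other on the chromosome.  Dispersed,
mutually dissimilar paralogs are the pattern read as horizontal-transfer-
driven family expansion; tandem, near-identical pairs as duplication.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import hydropathy, pairwise_identity_global

log = logging.getLogger(__name__)

SIGNAL_WINDOW = 10
SIGNAL_HYDROPATHY_MIN = 2.0
SIGNAL_REGION = 30  # a signal window must start within the first 30 positions
TM_WINDOW = 19
TM_HYDROPATHY_MIN = 1.6


@dataclass(frozen=True)
class FeatureFlags:
    """Heuristic N-terminal signal and transmembrane-helix verdicts."""

    signal: bool
    tm_spans: tuple  # ((start, end), ...) 0-based half-open


def feature_flags(sequence: str, warn: bool = True) -> FeatureFlags:
    """Hydropathy-window stand-in for signal-peptide and TM-helix prediction.

    Signal: some 10-residue window with mean Kyte-Doolittle hydropathy >= 2.0
    starting within the first 30 positions.  TM: a 19-residue window with
    mean hydropathy >= 1.6 starting after position 30; overlapping TM windows
    are merged into maximal spans.
    """
    if len(sequence) < SIGNAL_REGION:
        if warn:
            log.warning("sequence of length %d < %d: feature flags forced false",
                        len(sequence), SIGNAL_REGION)
        return FeatureFlags(signal=False, tm_spans=())
    kd = hydropathy(sequence)
    csum = np.concatenate([[0.0], np.cumsum(kd)])

    signal = False
    n_sig = min(SIGNAL_REGION, len(sequence) - SIGNAL_WINDOW + 1)
    if n_sig > 0:
        means = (csum[SIGNAL_WINDOW:SIGNAL_WINDOW + n_sig] - csum[:n_sig]) / SIGNAL_WINDOW
        signal = bool(np.any(means >= SIGNAL_HYDROPATHY_MIN))

    spans = []
    first_tm_start = SIGNAL_REGION + 1  # start > 30, 0-based start >= 31
    if len(sequence) - TM_WINDOW >= first_tm_start:
        starts = np.arange(first_tm_start, len(sequence) - TM_WINDOW + 1)
        means = (csum[starts + TM_WINDOW] - csum[starts]) / TM_WINDOW
        for s in starts[means >= TM_HYDROPATHY_MIN]:
            if spans and s < spans[-1][1]:
                spans[-1] = (spans[-1][0], int(s) + TM_WINDOW)
            else:
                spans.append((int(s), int(s) + TM_WINDOW))
    return FeatureFlags(signal=signal, tm_spans=tuple(spans))


def relative_density(homolog_count: int, genome_count: int) -> float:
    """Homologs identified in a lineage per genome of that lineage."""
    if genome_count < 1:
        log.warning("relative density undefined for %d genomes", genome_count)
        return float("nan")
    return homolog_count / genome_count


def relative_occurrence(homolog_count: int, gene_product_count: int) -> float:
    """Homologs identified in a lineage per gene product of that lineage."""
    if gene_product_count < 1:
        log.warning("relative occurrence undefined for %d gene products",
                    gene_product_count)
        return float("nan")
    return homolog_count / gene_product_count


@dataclass(frozen=True)
class ParalogStats:
    n_paralogs: int
    multi_copy: bool
    mean_identity: float | None = None
    min_identity: float | None = None
    max_identity: float | None = None


def paralog_summary(sequences: dict) -> ParalogStats:
    """Pairwise-identity summary for one genome's POP paralogs.

    Identities come from optimal global alignments under the fixed simple
    scoring (match 1, mismatch 0, gap -1), matches counted over columns
    where neither sequence is gapped.
    """
    n = len(sequences)
    if n < 2:
        return ParalogStats(n_paralogs=n, multi_copy=False)
    idents = [
        pairwise_identity_global(a, b)
        for a, b in itertools.combinations(sequences.values(), 2)
    ]
    return ParalogStats(
        n_paralogs=n,
        multi_copy=True,
        mean_identity=float(np.mean(idents)),
        min_identity=float(np.min(idents)),
        max_identity=float(np.max(idents)),
    )


@dataclass(frozen=True)
class ColocalizationVerdict:
    gene_a: str
    gene_b: str
    intervening: int
    colocalized: bool


@dataclass(frozen=True)
class ColocalizationReport:
    pairs: tuple  # ColocalizationVerdict, symmetric, each unordered pair once
    hgt_consistent: bool  # >= 2 paralogs and no pair co-localized


def colocalization_test(ordinals: dict, max_intervening: int = 5) -> ColocalizationReport:
    """Count intervening genes between each paralog pair of one genome.

    A pair is co-localized when at most ``max_intervening`` genes separate
    them; with the default cutoff of 5, a pair separated by six other genes
    is *not* co-localized.  A genome with >= 2 paralogs and no co-localized
    pair is flagged consistent with transfer-driven (rather than tandem-
    duplication) expansion.
    """
    if len(set(ordinals.values())) != len(ordinals):
        raise ValueError("duplicate chromosome ordinals among paralogs")
    pairs = []
    for (ga, oa), (gb, ob) in itertools.combinations(sorted(ordinals.items()), 2):
        intervening = abs(oa - ob) - 1
        pairs.append(
            ColocalizationVerdict(
                gene_a=ga, gene_b=gb, intervening=intervening,
                colocalized=intervening <= max_intervening,
            )
        )
    hgt = len(ordinals) >= 2 and not any(p.colocalized for p in pairs)
    return ColocalizationReport(pairs=tuple(pairs), hgt_consistent=hgt)


@dataclass
class GenomeSummary:
    genome_id: str
    lineage: str
    family_counts: dict
    architecture_counts: dict
    pop_paralogs: dict  # gene id -> chromosome ordinal
    paralog_stats: ParalogStats | None
    colocalization: ColocalizationReport | None
    localization_counts: dict = field(default_factory=dict)


def summarize_genomes(
    calls: pd.DataFrame,
    gene_table: pd.DataFrame,
    sequences: dict,
    localization: pd.DataFrame | None = None,
    max_intervening: int = 5,
) -> list[GenomeSummary]:
    """Per-genome copy counts, paralog identities and co-localization verdicts.

    ``calls`` is the confirmed homolog-call table (sequence_id, genome_id,
    architecture, family, ...); ``gene_table`` supplies chromosome ordinals
    and lineages; ``sequences`` maps sequence id to amino-acid string.
    """
    ordinal_of = dict(zip(gene_table["gene_id"], gene_table["ordinal"]))
    lineage_of = dict(zip(gene_table["genome_id"], gene_table.get("lineage", "")))
    loc_of = {}
    if localization is not None and len(localization):
        loc_of = dict(zip(localization["gene_id"], localization["localization"]))

    out = []
    for genome_id, sub in calls.groupby("genome_id", sort=True):
        fam_counts = sub["family"].value_counts().to_dict()
        arch_counts = sub["architecture"].value_counts().to_dict()
        pops = sub[(sub["family"] == "POP") & (sub["architecture"] == "FULL_POP")]
        paralogs = {g: int(ordinal_of[g]) for g in sorted(pops["sequence_id"])}
        stats = coloc = None
        if paralogs:
            stats = paralog_summary({g: sequences[g] for g in paralogs})
            if len(paralogs) >= 2:
                coloc = colocalization_test(paralogs, max_intervening=max_intervening)
        loc_counts: dict = {}
        for g in sub["sequence_id"]:
            if g in loc_of:
                loc_counts[loc_of[g]] = loc_counts.get(loc_of[g], 0) + 1
        out.append(
            GenomeSummary(
                genome_id=genome_id,
                lineage=lineage_of.get(genome_id, ""),
                family_counts=fam_counts,
                architecture_counts=arch_counts,
                pop_paralogs=paralogs,
                paralog_stats=stats,
                colocalization=coloc,
                localization_counts=loc_counts,
            )
        )
    return out


def lineage_stats(calls: pd.DataFrame, gene_table: pd.DataFrame) -> pd.DataFrame:
    """Relative density and occurrence per taxonomic lineage."""
    genomes = gene_table[["genome_id", "lineage"]].drop_duplicates()
    rows = []
    for lineage, sub in genomes.groupby("lineage", sort=True):
        lineage_genomes = set(sub["genome_id"])
        n_genomes = len(lineage_genomes)
        n_products = int((gene_table["genome_id"].isin(lineage_genomes)).sum())
        n_homologs = int((calls["genome_id"].isin(lineage_genomes)).sum())
        rows.append(
            {
                "lineage": lineage,
                "n_genomes": n_genomes,
                "n_gene_products": n_products,
                "n_homologs": n_homologs,
                "relative_density": relative_density(n_homologs, n_genomes),
                "relative_occurrence": relative_occurrence(n_homologs, n_products),
            }
        )
    return pd.DataFrame(rows)
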