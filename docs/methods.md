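# Methods

`popsurvey` implements a desk-scale genome survey of prolyl oligopeptidase
(POP, MEROPS family S9) homologs: profile-based homolog search with
simulation-calibrated E-values, a two-tier acceptance procedure, domain-
architecture triage, neighbor-joining clustering with bootstrap support,
cluster-specific motif discovery that defines POP subtypes, and gene-family
expansion statistics.  Every stage is exercised on synthetic proteomes with
planted ground truth, so the note below covers both the survey method and
the generator that defines the study conditions.

## Profile search and E-value calibration

A domain profile is a position-specific log-odds matrix built from an
aligned seed set.  For column frequency we use the pseudocounted estimator

    f_c(a) = (n_c(a) + alpha * bg(a)) / (N_c + alpha),      score_c(a) = log2(f_c(a) / bg(a))

where `n_c(a)` counts residue `a` among the non-gap entries of column `c`,
`N_c` is the column's non-gap count, `alpha` the pseudocount weight
(default 1.0) and `bg` the background distribution (uniform 1/20 by
default, configurable).  A sequence is scanned by evaluating every ungapped
window; the window score is the sum of its per-column scores.  Hits are
reported greedily by decreasing score (ties break toward the smaller start
coordinate) subject to non-overlap.  There is no gapped alignment, domain-
boundary refinement, or composition adjustment: the synthetic data contain
no indels inside domains, and the windowed model is exactly testable.

Significance is calibrated per profile by simulation: the maximum window
score of `n` random background sequences of a fixed null length (default
150 residues, 2,000 samples in the pipeline) defines the null distribution
of the per-sequence best score.  The E-value of score `s` against a
database exposing `D` windows is `D * P(null max >= s)`.  The survival
probability uses the empirical exceedance with `(r+1)/(n+1)` plotting
positions inside the sampled range — calibrated to sampling error by
construction — and a fitted Gumbel right tail beyond the largest null
sample, scaled to continue the empirical curve.  A pure Gumbel fit is kept
as the extrapolation model only: the maximum over overlapping, correlated
windows is close to but not exactly Gumbel, and the fitted tail is visibly
miscalibrated at the 1% level, whereas the hybrid passes the exceedance
check (`P(E <= q D) = q` for q in {0.2, 0.05, 0.01}) within three binomial
standard errors.  Where the calibration itself is under test we raise the
calibration sample to 20,000 so that calibration-side noise is small
against the held-out tolerance; this follows from the standard-error
arithmetic, not from tuning.

Iterative (Jackhmmer-style) search rebuilds the profile each round from the
seed set plus the best-hit windows of all newly accepted sequences (equal
weights) and stops when a round accepts nothing or after `max_rounds`
(default 3; the convergence criterion is not specified by the survey
convention, so it is configuration).  Redundancy removal follows the
CD-HIT contract: greedy clustering by decreasing length, a sequence joining
the first representative it matches at or above the identity threshold.

## Homolog triage

The acceptance rule is architectural: a hit is a **full POP** only when
both the seven-bladed beta-propeller (POP_N) and the alpha/beta-hydrolase
catalytic domain (POP_C) are found on the same sequence below the E-value
threshold; a hydrolase-only hit is a **partial POP**; a propeller without
its catalytic domain is rejected and never propagates downstream.

Searches run at two tiers, stringent E <= 1e-10 and relaxed E <= 1e-3.
Relaxed-tier candidates are confirmed only if they in turn match the
database of stringent-tier "true homologs" at E <= 1e-3; the cross-search
is a profile scan against a single profile built from the stringent hits'
POP_C windows (a deterministic stand-in for an all-vs-all BLAST against the
stringent database).  The confirmed set therefore always satisfies
stringent ⊆ confirmed ⊆ relaxed.

Family assignment scans four calibrated family profiles (POP, DPP, ACC,
other alpha/beta hydrolases) and reports the profile with the lowest best-
hit E-value, with a log10 E-value margin; exact ties break by bit score and
then the fixed order POP > DPP > ACC > ABH.  A sequence no profile scores
below E = 10 is reported unresolved within the superfamily.  Sequences
annotated as hypothetical that carried a POP-like signature in the search
are promoted to POP when an annotated-POP query profile finds them at the
relaxed threshold *and* they show the full two-domain architecture;
otherwise a resolved family call still places them in the superfamily.

## Clustering

Confirmed full POPs are aligned by profile anchoring: each sequence
contributes its best POP_N window concatenated with its best POP_C window,
giving an ungapped, equal-length alignment in domain coordinates.  This is
the natural alignment for a windowed profile search (the package does not
ship a progressive aligner; externally produced alignments are accepted by
every clustering function).

Distances are 1 − fractional identity, where identity counts matches over
columns in which neither row is gapped (a Poisson multiple-hit correction,
d = −ln identity, is available but off by default since the survey reports
raw identities).  Trees are built with classic Saitou–Nei neighbor joining:
join the pair minimizing Q(i,j) = (r−2)·d(i,j) − R_i − R_j, with ties
broken toward the first index pair; negative branch lengths are clamped to
zero with the deficit shifted to the sister branch.  Bootstrap support
resamples alignment columns with replacement (default 500 replicates; the
survey convention fixes only the >50% support cutoff) and counts how often
each bipartition of the original tree recurs.

Clusters are extracted from bipartition *sides* (the tree is unrooted, so a
cluster may lie on either side of its supporting edge).  A side qualifies
with support above the cutoff and at least `min_size` (default 3) leaves.
Two filters stop "the rest of the tree" from masquerading as a cluster:

* a side containing two disjoint qualifying sides is a backbone grouping
  and is decomposed rather than reported — without this, one stable deep
  split (e.g. tight families versus a group of long-branch transfer
  candidates) absorbs every family into a single mega-cluster;
* a side must be cohesive: every member, averaged over the original
  distances, at least as close to its own side as to the rest.  This
  rejects sides that annex an outlier leaf merely because the outlier's
  true group forms a stable clade next door.

Among the surviving atomic sides, higher support wins, then the outermost
(larger) side; overlapping candidates are dropped greedily, so reported
clusters never overlap.  Sequences outside every chosen side stay
unassigned — in the default survey this is where the heavily diverged
transferred paralogs end up, which is the scientifically correct verdict.

Column conservation for functional-residue scoring is entropy-based:
score = 1 − H/ln 21 with gaps as a 21st symbol; scores above 0.7 are
treated as significant, preserving the cutoff semantics of the original
scoring tool.

## Motifs and subtypes

A **conserved motif** is a maximal run of at least 3 consecutive alignment
columns in one cluster's alignment where at least 95% of sequences carry
the single most frequent residue (gaps never count toward the majority; the
95% criterion applies per column, the stricter of the two possible
readings).  A **class-specific motif** is a conserved motif whose consensus
never occurs as an exact ungapped substring in any sequence of any other
cluster; this substring contract is used because different clusters'
alignments are not column-compatible.  Clusters owning at least one
class-specific motif define subtypes (so a survey can legitimately find
fewer subtypes than clusters); a sequence is assigned to a subtype when it
contains class-specific motifs of exactly one subtype, and is otherwise
unclassified as `no-match` or `ambiguous`.  "Conserved" means identity of
the majority residue, not similarity classes.  Motif positions are reported
in domain-anchored coordinates, so hydrolase-domain versus propeller-domain
localization is direct bookkeeping.

## Genome statistics

Relative density is homologs per genome of a lineage; relative occurrence
is homologs per gene product of a lineage.  Paralog identity statistics use
optimal global pairwise alignments under a fixed simple scoring (match 1,
mismatch 0, linear gap −1), with identity counted over columns where
neither sequence is gapped.  The co-localization test counts intervening
genes between paralog ordinals; a pair is co-localized when at most 5 genes
separate them, which deliberately classifies a pair separated by six genes
as dispersed.  A genome with two or more paralogs and no co-localized pair
is flagged consistent with transfer-driven expansion.  Cellular
localization is never predicted — labels are optionally ingested from a TSV
and tabulated.  Signal peptides and TM helices use fixed hydropathy
heuristics (mean Kyte–Doolittle >= 2.0 over a 10-residue window starting in
the first 30 positions; >= 1.6 over a 19-residue window starting later);
these are declared simplified stand-ins whose accuracy is defined only on
the generator's unambiguous planted features.

## The synthetic survey

Defaults (one "study"): 12 genomes in 3 lineages; 8 POP subtypes with 12
sequences each; domains of 80 (POP_N) and 60 (POP_C) columns joined by a
10-residue linker; background conservation 0.9; per subtype 4 exclusive
6-residue motifs at fixed slots (two per domain) with conservation 1.0 and
single flanking spacer columns at conservation 0.5; related families (DPP,
OPB, ACC), hydrolase-only decoys, partial POPs, propeller-only rejects,
twilight-zone POPs at conservation 0.5; one transfer-expanded genome with
16 POP paralogs emitted at retention 0.5 from the base consensus, placed at
least 10 ordinals apart and kept under a 0.35 pairwise-identity ceiling by
checked resampling; one tandem duplication (adjacent ordinals, 2% point
mutations); and uniform-random filler proteins.

The mutation model keeps the consensus residue with probability `c`,
otherwise replaces it by a uniform draw over all 20 residues, so the match
probability has the closed form `c + (1−c)/20` used by the tests.  The
shared-base design is deliberate: spurious conserved runs inside one
subtype's alignment carry base consensus, which recurs in every other
cluster and is therefore rejected by the exclusion scan, while the spacer
columns stop maximal runs from leaking past the planted signature — so
discovered class-specific motifs coincide with the planted ones column for
column.  Consensus generation redraws hydrophobic windows and emissions are
redrawn until the hydropathy detector agrees with the planted signal/TM
flags, which is what "unambiguous planted features" means operationally.

What the generator does **not** emulate: insertions and deletions (fixed
linkers only), substitution-matrix or phylogenetic sequence evolution,
base-pair coordinates (ordinals only), genome composition signals (GC, codon
usage), and realistic annotation noise.  Passing tests therefore demonstrate
the correctness of the statistics and decision rules under their stated
contracts, not search sensitivity on real diverged proteomes.

## Numerical and reproducibility choices

* Coordinates are 0-based half-open everywhere; FASTA headers
  (`genome|gene|ordinal`) carry ids verbatim.
* E-values are floored at 1e-300 so they remain strictly positive.
* Majority-residue ties in motif consensus resolve to the alphabetically
  first residue; NJ Q-matrix ties to the first index pair; family-call ties
  by bit score then fixed family order.
* Degenerate inputs fail loudly: ragged alignments, non-symmetric distance
  matrices, duplicate paralog ordinals, empty seed sets and degenerate null
  variances all raise; sequences shorter than a profile scan to an empty
  hit list with a warning; pairs with no comparable columns report NaN.
* All randomness flows through seeds recorded in the run manifest, which
  contains no timestamps; a rerun with identical configuration and seed is
  byte-identical, and the test suite asserts this.
* Problem sizes in the test suite are the package's scaled study: the full
  default survey (595 proteins) for end-to-end recovery, a 4-subtype
  6-genome survey for plumbing tests, 200 random alignments for the motif
  oracle, 100 random additive matrices (4–8 taxa) for neighbor joining, and
  2,000 held-out null sequences for calibration validity.

## Known limitations

* The ungapped windowed profile model cannot detect homologs whose domains
  contain indels; on real proteomes an HMM with insert states would be
  required, and reported E-values transfer only qualitatively.
* Cluster extraction assumes clusters are tighter within than between
  (the cohesion filter); overlapping or hierarchically nested real
  subfamilies would need the support cutoff and min-size re-examined.
* The subtype classifier is exact-substring matching of motif consensi; a
  single substitution inside a motif instance defeats it by design, exactly
  as the class-specific-motif definition dictates.
* Family assignment for sequences shorter than a family profile is
  conservative (that profile simply cannot fire), which leaves partial POPs
  resolvable only within the superfamily.
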