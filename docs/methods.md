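# Methods

This note documents the models and procedures implemented in `eremap`,
the choices made where the design was genuinely open, and what the
synthetic studies do and do not demonstrate.

## Expression atlas and tissue specificity

Transcript- or instance-level TPM values are summed into repeat-family
(or gene) rows; the unit is preserved and a partition map conserves
per-sample totals. Per-tissue summaries are medians over the tissue's
samples (even counts: mean of the two central values). Row z-scores
use the sample standard deviation (n−1 denominator); constant rows
cannot be scaled and are returned as zeros with a flag rather than
NaN.

Tissues are clustered on Euclidean distances between their z-score
columns. The linkage method is average linkage by default and
configurable — the distance is part of the method, the linkage is
not, so it is exposed. Cluster support is the plain bootstrap
probability: the fraction of feature-resampled trees containing
exactly that tissue set. The multiscale (approximately unbiased)
correction used by pvclust-style tools is not implemented; plain
bootstrap probabilities are conservative for well-separated clusters
and the support semantics are simpler to state. Columns are sorted by
tissue id before clustering so that equidistant merges are resolved
reproducibly.

The tau index of tissue specificity is

    tau = Σ_i (1 − x_i) / (N − 1),   x_i = v_i / max_j v_j,

0 for uniform expression and 1 for single-tissue expression, and
invariant to positive rescaling. An all-zero profile has no defined
tau and is signalled, never reported as 0. Features are called
tissue-restricted at tau ≥ 0.8; profiles at or below 0.4 behave as
housekeeping. Which tissues overexpress a restricted feature comes
from max-gap binarization: sort tissues by expression descending, find
the largest difference between neighbours, and mark everything
strictly above it. Two equal maximal gaps resolve toward the top of
the ranking (fewer overexpressing tissues — the conservative choice).
Features whose maximal expression falls below a floor (default 1 TPM,
settable to 0) are excluded from restricted calls: tau is scale-free,
so at trace expression it measures noise, not biology.

Quintile ranking cuts each family's tissue ranking into five bins of
floor(N/5) with the remainder added to the middle bin — for the
32-tissue panel this is the 6, 6, 8, 6, 6 layout — and tallies
fifth-quintile (highest) memberships per tissue. Ranking ties break by
stable tissue id and the affected families are reported.

Small-sample two-group comparisons use a Mann-Whitney U whose p-value
is computed by full enumeration of group labelings when n+m ≤ 12
(exact under ties) and by the tie-corrected normal approximation
otherwise. Chi-squared, Kendall tau-b and Pearson statistics follow
their standard definitions (scipy); constant inputs to a correlation
are signalled as undefined rather than returned as NaN.

## Proteogenomic ereMAP identification

**Read QC and partitioning.** Only primary, properly paired FR reads
with clean flags are used (equivalently: FLAG in {99, 147, 163, 83}
over the pairing bits, nothing in the 3852 exclusion mask). A read
joins the ERE dataset when its reference span (from the CIGAR, so
clipping and splicing count correctly) is entirely contained in a
repeat annotation, and the canonical dataset when entirely contained
in an exon; a read qualifying for both is canonical only, which
removes it from the ERE side. Containment in exons — not gene spans —
is deliberate: intronic reads must remain ERE-eligible, since intronic
repeats are the dominant source of ERE-derived peptides. Mates are
partitioned independently.

**Proteomes.** Each ERE read is trimmed at ambiguous bases, translated
in all six frames, and spliced at stop codons; sequences of at least
8 aa become uniquely identified proteome entries, with duplicates from
different reads kept under distinct provenance. The default splicing
keeps only the prefix before the first stop; a split-at-every-stop
mode is available behind a flag because the narrower reading drops
real ORFs downstream of an early stop — both readings are defensible
and the switch preserves the ambiguity explicitly. The canonical
proteome applies single-nucleotide variants with alternate count ≥ 5
to transcript sequences (a mismatched reference base is an error
naming transcript and position), translates only transcripts with
TPM > 0, from the annotated CDS start when gene models provide one and
from the first ATG otherwise, to the first stop.

**Filter cascade.** Candidates run through, in order: target-decoy FDR
at q = 0.05 (threshold = the minimal score t with #decoys≥t /
#targets≥t ≤ q; decoys never appear in output) — the ratio estimator
is the standard construction, chosen because the estimate is exact
when decoys model the incorrect-target score distribution 1:1; the
binder filter (8–11-mers with best available HLA percentile rank
≤ 2%, inclusive; missing alleles are ignored); proteome status — yes
(ERE only), no (canonical only), maybe (both), undetermined (neither;
treated as a search/proteome mismatch and discarded with a reason).

Maybe candidates are arbitrated on 24-nt k-mer databases built from
the ERE and canonical read datasets under reverse-complement
canonicalization (word ↦ lexicographic min of word and its reverse
complement; N-containing windows are skipped). The minimal occurrence
of a coding sequence (MCS) is the minimum over its 24-mer set. A
candidate is discarded when any of its MCSs is seen only in the
canonical reads, and kept when its most abundant MCS satisfies
min_ere ≥ 10 × min_canonical (inclusive). "Most abundant" is ranked
by ERE minimal occurrence, ties broken by canonical occurrence
ascending then lexicographically, so the arbitration is
deterministic. Candidates supported by fewer than two reads are
discarded as sequencing-error risks; this package applies the
read-support rule to *every* ERE candidate, not only the maybe class —
a yes-status peptide seen in a single read carries the same error risk
and there is no principled reason to exempt it.

I/L isobaric variants (mass spectrometry cannot distinguish them) are
enumerated exhaustively (≤ 2^11 for MAPs); a variant present in the
proteome at higher expression displaces the candidate. ERE support is
measured in distinct supporting reads and canonical support in
transcript TPM; the two scales are not commensurable, so each variant
is compared within its own source and a canonical variant that beats
the candidate on the canonical scale dominates.

**Genomic origin.** The top-ranked MCS is located by exact match on
both strands. Only loci contained in a repeat interval can attest an
ERE origin; no such locus, or conflicting (region, orientation)
annotations among them, means no clear genomic region and the
candidate is discarded. Region precedence is CDS > intronic >
intergenic. The count of distinct repeat intervals containing any
matching locus feeds the orientation decision: discard CDS-sense
candidates; keep intergenic candidates regardless of orientation;
discard intronic candidates only when simultaneously sense to the host
gene, antisense to the repeat, and confined to a single repeat locus
(such a sequence reads as plain intron rather than repeat; matches in
other repeat copies rescue it). Surviving candidates are aggregated to
non-redundant peptide records; conflicting per-sample annotations are
all retained as alternatives.

## Peptide analytics

Expression of a peptide's coding sequence in an RNA-seq sample is
rphm = r_overlap / total_reads × 10⁸, with r_overlap the minimal
24-mer count of the MCS in that sample's k-mer table (the best MCS is
used when several encode the peptide). The multiplication happens
before the division so round counts stay exact in floating point. A
tissue is flagged significant when its mean of log10(rphm+1) exceeds
log10(10+1); a linear-scale comparison is available behind a flag
because the threshold is stated on the rphm scale while the averaging
is done on the log scale — the log-scale reading is the default since
that is the scale on which the means are formed. Methylation coupling
is the per-probe Pearson r against rphm, restricted to probes within
5000 nt of either end of the coding locus.

Viral homology uses exact Smith-Waterman local alignment under PAM30
(Biopython's published matrix) with affine gaps costing
open + extend·g (defaults 5 and 2). Exact DP replaces word-seeded
heuristic search: at 8–11-mer scale the heuristic with word size 2 and
a huge e-value ceiling approximates exhaustive search, and exact DP is
strictly more complete. Per subject, %I = matches / L_p × 100 (the
identity fraction times alignment length over peptide length; the
L_a terms cancel), and the reported %I is the maximum over subjects —
identity-maximal by default, score-maximal behind a flag. The
formula's identity term is implemented as a fraction so %I ∈ [0, 100];
a switch reproduces the literal percentage×100 variant. The bootstrap
test draws groups of |query set| canonical peptides without
replacement within each of n_boot = 10,000 sets (with-replacement via
flag) and reports p = #(bootstrap mean > observed mean) / n_boot, so
p = 0 is read as < 1/n_boot.

Amino-acid composition is reported overall (frequencies over all
residues, summing to 1) and per position within each length bin; bins
with fewer than 3 peptides are dropped and flagged, since positional
frequencies from one or two peptides are not interpretable.

## Synthetic data: what it emulates, what it does not

The generators produce every input format the pipeline reads, with
planted ground truth, and are byte-deterministic given their seed.

The tissue panel (defaults: 32 tissues, 200 families, 20 restricted,
5 samples per tissue) gives housekeeping families one shared mean
across tissues (lognormal across families, median 20 TPM) and
restricted families a 20× overexpression in one or two tissues over a
low baseline (1–3 TPM). Noise is multiplicative lognormal with
σ = 0.15, chosen so that planted housekeeping profiles actually sit in
the housekeeping regime (tau ≤ 0.4) that defines them — at
substantially larger σ a "housekeeping" profile is no longer
housekeeping by the tau definition. Columns are renormalized to 10⁶
(TPM closure).

The genome generator (two 300-kb chromosomes by default) lays down
three-exon genes on the plus strand whose exons are stop-free codons
in the transcript frame, and repeat copies — mutated clones of
per-family consensus sequences at a configurable divergence — in
intronic (51% of copies, the genome-wide share of intronic repeat
sequence), intergenic, and exon-straddling contexts.

The read-set generator rewrites selected repeat copies as stop-free
codon cassettes embedding each planted peptide's coding sequence, so
that any read covering the MCS translates through it in frame. Read
pairs covering each MCS are emitted at controlled counts, background
fragments are blocked from overlapping planted MCS loci so that
minimal k-mer counts equal the planted fragment counts exactly, and
the planted cases span: every keep branch of the orientation tree
(intronic-sense, intergenic in both orientations, intronic-antisense
rescued by a second locus), both discard branches (CDS-sense;
intronic-antisense at a single locus), one-read cases, canonical CDS
peptides, ambiguous cases with ERE:canonical coverage ratios
bracketing 10×, and one reversed-sequence decoy PSM per target.
Planted peptides avoid I and L so the isobaric-variant rule stays
inert for them; that rule is exercised by dedicated constructions in
the unit tests. Reads are error-free by default (the ≥2-read rule
exists to guard against sequencing errors; testing the rule must not
depend on simulating them), qualities are constant, and there are no
indels — so the synthetic studies validate the decision logic and the
counting kernels, not robustness to base-calling noise, misalignment,
or repeat-family sequence homology, which real data add on top.

The PSM score generator used for FDR calibration draws correct targets
from N(10, 2), incorrect targets from N(5, 2), and decoys from the
same null distribution with count equal to the incorrect-target count,
which is the regime in which the target-decoy ratio estimates the
false-discovery proportion without bias; the realized-FDP check
measures exactly that property. The methylation generator blends the
standardized rphm vector with Gaussian noise at the target correlation
and maps it linearly into (0, 1), so a target of ρ = 1 with no noise
yields a downstream Pearson r of exactly 1; probes are placed on both
sides of the 5000-nt window.

## Numerical and policy details

- Internal coordinates are 0-based half-open everywhere; RepeatMasker
  `.out` and GTF conversion happens only at the parse/serialize
  boundary and is self-inverse.
- Repeat families without a group mapping become `other` and are
  excluded from LINE/LTR/SINE proportion analyses.
- Matrix writers emit `%.17g`, which round-trips IEEE doubles exactly;
  the reader parses with round-trip precision.
- Expression tables reject negative values except in z-score units.
- All stochastic components take explicit seeds; the bootstrap,
  generators and tests are reproducible run-to-run.

## Problem sizes used in the checks

The packaged verification suite runs on synthetic studies sized for a
single CPU: a 50,000-pair read set for end-to-end ereMAP calling (80
planted cases, 176 PSMs including decoys), 10,000 PSMs × 20 replicates
for FDR calibration, 10,000 random reads for the k-mer oracle, 1,000
reads for the translation oracle, and a 150-peptide canonical pool
against a 20-peptide viral set with n_boot = 500 over 200 replicates
for the bootstrap calibration. These sizes give the recovery and
calibration statements comfortable margins while keeping the whole
suite in the minutes range.

## Known limitations

- Minus-strand genes are supported in the data model but the synthetic
  genome places all genes on the plus strand; orientation logic for
  minus-strand hosts is exercised only through repeat strands.
- The multiscale bootstrap correction for cluster support is not
  implemented (plain bootstrap probabilities only).
- Multi-mapping reads are not modelled: partitioning assumes one
  primary alignment per read, and containment is evaluated on that
  alignment only.
- Indels are out of scope end to end (variants are single-nucleotide
  substitutions; alignments have match-only CIGARs in the generator).
- The I/L cross-scale comparison (read counts vs TPM) has no common
  unit; the within-source rule documented above is a policy, not a
  measurement.
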