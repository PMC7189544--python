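"""The ereMAP filter cascade.

Candidates from peptide-spectrum-match tables run through, in order:
target-decoy FDR (5%), the binder filter (8-11-mers, best HLA
percentile rank <= 2%), proteome status assignment (yes / maybe / no),
read-support and 24-mer arbitration of "maybe" candidates (the 10x
rule), the I/L isobaric-variant check, exact-match genomic locus
classification, and the orientation decision tree (CDS-sense
discarded; intergenic kept; intronic discarded only when sense to the
gene, antisense to the repeat and mapping to a single repeat locus).
Every candidate carries an append-only verdict trail and a discarded
candidate has exactly one terminal reason.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .expression import kendall_tau, mann_whitney_exact
from .io_formats import (
    AlignedRead,
    ERE_GROUPS,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    PeptideCandidate,
    RepeatRecord,
)
from .proteogenomics import (
    CODON_TABLE as _CODON,
    CombinedProteome,
    ReadPartition,
    revcomp,
    translate as _translate,
)

__all__ = [
    "apply_fdr",
    "filter_binders",
    "assign_status",
    "KmerCountTable",
    "canonical_kmer",
    "build_kmer_table",
    "recover_mcs",
    "mcs_min_occurrence",
    "resolve_maybe",
    "il_variants",
    "il_variant_check",
    "LocusCall",
    "classify_origin",
    "orientation_decision",
    "EreMapRecord",
    "aggregate_nonredundant",
    "characterize_cohort",
    "call_eremaps",
]

DEFAULT_FDR_Q = 0.05
DEFAULT_RANK_MAX = 2.0  # percentile rank, inclusive
DEFAULT_KMER_K = 24
DEFAULT_RATIO_MIN = 10.0  # ERE/canonical minimal-occurrence ratio, inclusive
DEFAULT_MIN_READS = 2  # "more than one read"
MIN_PEPTIDE_LEN = 8
MAX_PEPTIDE_LEN = 11


# ---------------------------------------------------------------------------
# FDR and binder filters


def apply_fdr(
    candidates: Sequence[PeptideCandidate],
    q: float = DEFAULT_FDR_Q,
) -> list[PeptideCandidate]:
    """Target-decoy FDR on peptide scores.

    The score threshold is the minimal score t such that
    ``#(decoys >= t) / #(targets >= t) <= q``; all targets at or above
    t pass and decoys are removed from the output.  With no decoys the
    estimator is undefined and this raises.
    """
    if not any(c.is_decoy for c in candidates):
        raise ValueError("no decoy PSMs present: FDR estimate undefined")
    ordered = sorted(candidates, key=lambda c: c.score)
    n = len(ordered)
    decoys_ge = 0
    targets_ge = 0
    threshold = None
    # walk thresholds from the lowest score upward; counts of >= t shrink
    suffix_decoys = np.cumsum([c.is_decoy for c in ordered][::-1])[::-1]
    suffix_targets = np.cumsum([not c.is_decoy for c in ordered][::-1])[::-1]
    for i, c in enumerate(ordered):
        if i > 0 and c.score == ordered[i - 1].score:
            continue
        t_count = suffix_targets[i]
        d_count = suffix_decoys[i]
        if t_count > 0 and d_count / t_count <= q:
            threshold = c.score
            break
    passed = []
    for c in candidates:
        if c.is_decoy:
            continue
        if threshold is not None and c.score >= threshold:
            c.log("fdr", f"pass (score {c.score} >= {threshold}, q={q})")
            passed.append(c)
        else:
            c.log("fdr", "discard: below FDR threshold")
    return passed


def filter_binders(
    candidates: Sequence[PeptideCandidate],
    rank_max: float = DEFAULT_RANK_MAX,
) -> list[PeptideCandidate]:
    """Keep 8-11-mers whose best percentile rank is <= ``rank_max``."""
    kept = []
    for c in candidates:
        if not (MIN_PEPTIDE_LEN <= len(c.peptide) <= MAX_PEPTIDE_LEN):
            c.log("binder", f"discard: length {len(c.peptide)} outside 8-11")
            continue
        best = c.best_rank
        if best is None or best > rank_max:
            c.log("binder", f"discard: best rank {best} > {rank_max}")
            continue
        c.log("binder", f"pass (best rank {best})")
        kept.append(c)
    return kept


def assign_status(candidate: PeptideCandidate, proteome: CombinedProteome) -> str:
    """yes = ERE proteome only; no = canonical only; maybe = both.

    A peptide in neither proteome signals a search/proteome mismatch
    and is marked ``undetermined``.
    """
    in_ere, in_can = proteome.membership(candidate.peptide)
    status = {
        (True, False): "yes",
        (False, True): "no",
        (True, True): "maybe",
        (False, False): "undetermined",
    }[(in_ere, in_can)]
    candidate.status = status
    candidate.log("status", status)
    return status


# ---------------------------------------------------------------------------
# k-mer tables


@dataclass
class KmerCountTable:
    """Reverse-complement-canonical k-mer counts."""

    k: int
    counts: dict[str, int]
    total_words: int

    def get(self, word: str) -> int:
        return self.counts.get(canonical_kmer(word), 0)


def canonical_kmer(word: str) -> str:
    rc = revcomp(word)
    return word if word <= rc else rc


def build_kmer_table(
    reads: Sequence[AlignedRead] | Sequence[str],
    k: int = DEFAULT_KMER_K,
) -> KmerCountTable:
    """Count all k-length windows of the reads under canonicalization.

    A word and its reverse complement accumulate into the same
    (lexicographically smaller) key; windows containing N are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    total = 0
    for read in reads:
        seq = read.sequence if isinstance(read, AlignedRead) else read
        L = len(seq)
        if L < k:
            continue
        rc = revcomp(seq)
        for i in range(L - k + 1):
            fwd = seq[i : i + k]
            if "N" in fwd:
                continue
            rev = rc[L - k - i : L - i]
            counts[fwd if fwd <= rev else rev] += 1
            total += 1
    return KmerCountTable(k, dict(counts), total)


# ---------------------------------------------------------------------------
# MCS recovery and arbitration


class TranslatedReads:
    """Six-frame translations of a read set, computed once.

    MCS recovery scans every read in every frame for every candidate;
    caching the translations makes that scan linear in candidates.
    """

    def __init__(self, reads: Sequence[AlignedRead]):
        self.items: list[tuple[str, str, str]] = []  # (read_id, frame nt, aa)
        for read in reads:
            seq = read.sequence
            rc = revcomp(seq)
            for strand_seq in (seq, rc):
                for frame in range(3):
                    sub = strand_seq[frame:]
                    self.items.append((read.read_id, sub, _translate_cached(sub)))


def recover_mcs(
    peptide: str,
    reads: Sequence[AlignedRead] | None = None,
    cache: TranslatedReads | None = None,
) -> list[tuple[str, int]]:
    """All nucleotide coding sequences of ``peptide`` found in the reads.

    Each read is translated in six frames; wherever the peptide occurs,
    the corresponding nucleotide window (in coding orientation) is an
    MCS.  Returns (MCS, number of distinct supporting reads) sorted by
    support descending then sequence.
    """
    if cache is None:
        if reads is None:
            raise ValueError("need reads or a TranslatedReads cache")
        cache = TranslatedReads(reads)
    support: dict[str, set[str]] = {}
    for read_id, sub, aa in cache.items:
        start = aa.find(peptide)
        while start != -1:
            nt = sub[start * 3 : (start + len(peptide)) * 3]
            support.setdefault(nt, set()).add(read_id)
            start = aa.find(peptide, start + 1)
    return sorted(
        ((m, len(ids)) for m, ids in support.items()),
        key=lambda t: (-t[1], t[0]),
    )


def _translate_cached(nt: str) -> str:
    if "N" in nt:
        # N-containing codons become X (never matches a peptide)
        out = []
        for i in range(0, len(nt) - len(nt) % 3, 3):
            codon = nt[i : i + 3]
            out.append("X" if "N" in codon else _CODON[codon])
        return "".join(out)
    return _translate(nt)


def mcs_min_occurrence(mcs: str, table: KmerCountTable) -> int:
    """Minimal count, over the MCS's k-mer set, in a k-mer table."""
    k = table.k
    if len(mcs) < k:
        raise ValueError(f"MCS shorter than k={k}: {len(mcs)} nt")
    return min(table.get(mcs[i : i + k]) for i in range(len(mcs) - k + 1))


def _rank_mcs(
    mcs_set: Sequence[tuple[str, int]],
    ere_table: KmerCountTable,
    canonical_table: KmerCountTable,
) -> list[tuple[str, int, int]]:
    """(mcs, min_ere, min_canonical) sorted by the abundance tie-break:
    ERE minimal occurrence desc, canonical asc, then lexicographic."""
    scored = [
        (m, mcs_min_occurrence(m, ere_table), mcs_min_occurrence(m, canonical_table))
        for m, _ in mcs_set
    ]
    return sorted(scored, key=lambda t: (-t[1], t[2], t[0]))


def resolve_maybe(
    candidate: PeptideCandidate,
    ere_table: KmerCountTable,
    canonical_table: KmerCountTable,
    ratio_min: float = DEFAULT_RATIO_MIN,
    min_reads: int = DEFAULT_MIN_READS,
) -> bool:
    """Arbitrate a both-proteome candidate with the k-mer databases.

    Discards when any MCS is seen only in the canonical read dataset,
    when total read support is below ``min_reads``, or when the most
    abundant MCS fails ``min_ere >= ratio_min * min_canonical``.
    """
    if not candidate.mcs_set:
        candidate.log("kmer-arbitration", "discard: no MCS recovered from reads")
        return False
    n_reads = sum(n for _, n in candidate.mcs_set)
    if n_reads < min_reads:
        candidate.log(
            "kmer-arbitration",
            f"discard: supported by {n_reads} read(s) < {min_reads}",
        )
        return False
    ranked = _rank_mcs(candidate.mcs_set, ere_table, canonical_table)
    for m, min_ere, min_can in ranked:
        if min_ere == 0 and min_can > 0:
            candidate.log(
                "kmer-arbitration",
                f"discard: MCS {m} seen only in canonical read dataset",
            )
            return False
    top_mcs, min_ere, min_can = ranked[0]
    if min_ere >= ratio_min * min_can:
        candidate.log(
            "kmer-arbitration",
            f"keep: most abundant MCS {top_mcs} min_ere={min_ere} "
            f">= {ratio_min} x min_canonical={min_can}",
        )
        return True
    candidate.log(
        "kmer-arbitration",
        f"discard: min_ere={min_ere} < {ratio_min} x min_canonical={min_can}",
    )
    return False


# ---------------------------------------------------------------------------
# I/L isobaric variants


def il_variants(peptide: str) -> list[str]:
    """All I/L substitution variants of a peptide, excluding itself."""
    positions = [i for i, aa in enumerate(peptide) if aa in "IL"]
    if len(positions) > 20:
        raise ValueError("more than 20 I/L positions")  # unreachable for MAPs
    variants = []
    for mask in range(1, 1 << len(positions)):
        chars = list(peptide)
        for bit, pos in enumerate(positions):
            if mask >> bit & 1:
                chars[pos] = "L" if chars[pos] == "I" else "I"
        variants.append("".join(chars))
    return variants


def il_variant_check(
    candidate: PeptideCandidate,
    proteome: CombinedProteome,
    own_expression: float,
) -> bool:
    """Discard when an I/L-indistinguishable variant out-expresses the
    candidate.

    MS cannot tell I from L, so a higher-expressed isobaric variant in
    the personalized proteome is the likelier identification.  ERE
    support (read counts) and canonical support (TPM) live on different
    scales; each variant is compared within its own source and a
    canonical variant beating the candidate on the canonical scale
    dominates (conflict logged).
    """
    for variant in il_variants(candidate.peptide):
        ere_expr = proteome.peptide_expression(variant, "ere-read")
        can_expr = proteome.peptide_expression(variant, "canonical-transcript")
        if can_expr > 0 and can_expr > proteome.peptide_expression(
            candidate.peptide, "canonical-transcript"
        ):
            candidate.log(
                "il-check",
                f"discard: variant {variant} at higher canonical expression "
                f"({can_expr:.3g})",
            )
            return False
        if ere_expr > own_expression:
            candidate.log(
                "il-check",
                f"discard: variant {variant} at higher ERE read support "
                f"({ere_expr:.0f} > {own_expression:.0f})",
            )
            return False
    candidate.log("il-check", "pass")
    return True


# ---------------------------------------------------------------------------
# genomic locus classification


@dataclass
class LocusCall:
    region_class: str  # CDS / intronic / intergenic
    orientation_vs_ere: str  # sense / antisense
    orientation_vs_gene: str  # sense / antisense / n/a
    n_ere_loci: int
    family: str | None
    group: str | None
    locus: GenomicInterval | None


def _overlap_tree(intervals: list[tuple[int, int, object]]) -> IntervalTree:
    tree = IntervalTree()
    for start, end, data in intervals:
        tree.addi(start, end, data)
    return tree


def classify_origin(
    mcs: str,
    repeats: Sequence[RepeatRecord],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> LocusCall | None:
    """Locate an MCS in the genome by exact match and annotate it.

    Region precedence is CDS > intronic > intergenic.  Only loci
    contained in a repeat interval can explain an ERE origin: when none
    exists, or when the repeat-contained loci disagree on their
    (region, orientation) annotation, no clear genomic region can be
    assigned and the caller discards the candidate (None).
    ``n_ere_loci`` counts the distinct repeat intervals containing any
    exact-match locus — the "maps in other ERE sequences" input of the
    orientation decision.
    """
    loci: list[GenomicInterval] = []
    rc = revcomp(mcs)
    for chrom, seq in genome.items():
        for query, strand in ((mcs, "+"), (rc, "-")):
            start = seq.find(query)
            while start != -1:
                loci.append(GenomicInterval(chrom, start, start + len(mcs), strand))
                start = seq.find(query, start + 1)
    if not loci:
        return None

    repeat_trees: dict[str, IntervalTree] = {}
    for r in repeats:
        repeat_trees.setdefault(r.interval.chrom, IntervalTree()).addi(
            r.interval.start, r.interval.end, r
        )
    cds_trees: dict[str, IntervalTree] = {}
    intron_trees: dict[str, IntervalTree] = {}
    for g in genes:
        for iv in g.cds:
            cds_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, g)
        for iv in g.introns():
            intron_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, g)

    containing_repeats: set[tuple[str, int, int]] = set()
    annotations: list[tuple[GenomicInterval, RepeatRecord | None, str, str]] = []
    for locus in loci:
        host: RepeatRecord | None = None
        tree = repeat_trees.get(locus.chrom)
        if tree is not None:
            for iv in tree.overlap(locus.start, locus.end):
                if iv.begin <= locus.start and locus.end <= iv.end:
                    host = iv.data
                    containing_repeats.add((locus.chrom, iv.begin, iv.end))
                    break
        region = "intergenic"
        gene_strand = None
        ctree = cds_trees.get(locus.chrom)
        if ctree is not None:
            hits = ctree.overlap(locus.start, locus.end)
            if hits:
                region = "CDS"
                gene_strand = next(iter(hits)).data.strand
        if region == "intergenic":
            itree = intron_trees.get(locus.chrom)
            if itree is not None:
                hits = [
                    iv
                    for iv in itree.overlap(locus.start, locus.end)
                    if iv.begin <= locus.start and locus.end <= iv.end
                ]
                if hits:
                    region = "intronic"
                    gene_strand = hits[0].data.strand
        annotations.append((locus, host, region, gene_strand or "n/a"))

    in_repeat = [a for a in annotations if a[1] is not None]
    if not in_repeat:
        return None  # no repeat-attributable locus: no clear ERE origin
    in_repeat.sort(key=lambda a: (a[0].chrom, a[0].start, a[0].strand))
    calls = set()
    for locus, host, region, gene_strand in in_repeat:
        vs_ere = "sense" if locus.strand == host.interval.strand else "antisense"
        vs_gene = (
            "n/a" if gene_strand == "n/a"
            else ("sense" if locus.strand == gene_strand else "antisense")
        )
        calls.add((region, vs_ere, vs_gene))
    if len(calls) > 1:
        return None  # conflicting contexts: no clear genomic region
    region, vs_ere, vs_gene = next(iter(calls))
    locus, host, _, _ = in_repeat[0]
    return LocusCall(
        region_class=region,
        orientation_vs_ere=vs_ere,
        orientation_vs_gene=vs_gene,
        n_ere_loci=len(containing_repeats),
        family=host.family,
        group=host.group,
        locus=locus,
    )


def orientation_decision(
    region_class: str,
    sense_vs_gene: str,
    sense_vs_ere: str,
    n_ere_loci: int,
) -> tuple[bool, str]:
    """Final keep/discard from the genomic context of the MCS.

    CDS-sense candidates are canonical translation products and are
    discarded.  Intergenic candidates are kept regardless of
    orientation.  Intronic candidates are discarded only when sense to
    the host gene, antisense to the repeat, and mapping to a single
    repeat locus (such a sequence reads as plain intron, not repeat).
    """
    if region_class == "CDS" and sense_vs_gene == "sense":
        return False, "MCS in the sense of a gene coding sequence"
    if region_class == "intergenic":
        return True, "intergenic: kept regardless of orientation"
    if region_class == "intronic":
        if sense_vs_gene == "sense" and sense_vs_ere == "antisense" and n_ere_loci <= 1:
            return False, (
                "intronic, sense to gene, antisense to ERE, single ERE locus"
            )
        return True, "intronic, repeat-attributable orientation"
    return True, f"{region_class}, orientation compatible with ERE origin"


# ---------------------------------------------------------------------------
# aggregation and cohort characterization


@dataclass(frozen=True)
class EreMapRecord:
    peptide: str
    samples: tuple[str, ...]
    # one tuple per distinct characteristic set seen across samples:
    # (family, group, region_class, orientation_vs_ere, orientation_vs_gene)
    characteristics: tuple[tuple[str, str, str, str, str], ...]

    @property
    def family(self) -> str:
        return self.characteristics[0][0]

    @property
    def group(self) -> str:
        return self.characteristics[0][1]

    @property
    def region_class(self) -> str:
        return self.characteristics[0][2]

    @property
    def orientation_vs_ere(self) -> str:
        return self.characteristics[0][3]


def aggregate_nonredundant(
    per_sample: Sequence[tuple[str, str, tuple[str, str, str, str, str]]],
) -> list[EreMapRecord]:
    """Merge per-sample calls into unique-peptide records.

    Input items are (peptide, sample, characteristics).  Identical
    characteristics collapse; conflicting ones are all retained as
    alternatives on the single record for that peptide.
    """
    by_peptide: dict[str, dict] = {}
    for peptide, sample, chars in per_sample:
        slot = by_peptide.setdefault(peptide, {"samples": [], "chars": []})
        if sample not in slot["samples"]:
            slot["samples"].append(sample)
        if chars not in slot["chars"]:
            slot["chars"].append(chars)
    return [
        EreMapRecord(p, tuple(v["samples"]), tuple(v["chars"]))
        for p, v in sorted(by_peptide.items())
    ]


def characterize_cohort(
    records: Sequence[EreMapRecord],
    repeats: Sequence[RepeatRecord],
    genes: Sequence[GeneModel],
    family_expression: ExpressionTable | None = None,
) -> dict:
    """Cohort-level summary of a set of ereMAPs.

    Reports LINE/LTR/SINE proportions at the genome (repeat bases),
    transcriptome (per-sample group TPM share, averaged) and
    immunopeptidome (record) levels; intron/intergenic/CDS shares of
    ereMAP loci vs all repeat bases; the Kendall tau-b between
    per-family ereMAP counts and genomic copy numbers; and the
    source vs non-source family expression comparison.
    """
    if not records:
        raise ValueError("no records to characterize")

    # immunopeptidome group proportions (first characteristics set per record)
    immuno = Counter(r.group for r in records if r.group in ERE_GROUPS)
    n_immuno = sum(immuno.values())

    # genomic proportions: repeat bases per group
    genome_bases = Counter()
    for r in repeats:
        if r.group in ERE_GROUPS:
            genome_bases[r.group] += len(r.interval)
    n_genome = sum(genome_bases.values())

    out: dict = {
        "immunopeptidome_proportions": {
            g: immuno.get(g, 0) / n_immuno if n_immuno else float("nan")
            for g in ERE_GROUPS
        },
        "genome_proportions": {
            g: genome_bases.get(g, 0) / n_genome if n_genome else float("nan")
            for g in ERE_GROUPS
        },
    }

    if family_expression is not None:
        fam_group = {r.family: r.group for r in repeats}
        df = family_expression.values
        shares = []
        for col in df.columns:
            per_group = Counter()
            for fam, v in df[col].items():
                g = fam_group.get(fam)
                if g in ERE_GROUPS:
                    per_group[g] += v
            total = sum(per_group.values())
            if total > 0:
                shares.append({g: per_group.get(g, 0.0) / total for g in ERE_GROUPS})
        out["transcriptome_proportions"] = {
            g: float(np.mean([s[g] for s in shares])) for g in ERE_GROUPS
        } if shares else None

        # source vs non-source family mean expression
        source_families = {r.family for r in records}
        mean_expr = df.mean(axis=1)
        src = [v for f, v in mean_expr.items() if f in source_families]
        non = [v for f, v in mean_expr.items() if f not in source_families]
        if src and non:
            u, p = mann_whitney_exact(src, non)
            out["source_vs_nonsource"] = {"U": u, "p_value": p}

    # region-class proportions: ereMAP loci vs all repeat bases
    region_counts = Counter(r.region_class for r in records)
    out["eremap_region_proportions"] = {
        k: region_counts.get(k, 0) / len(records)
        for k in ("intronic", "intergenic", "CDS")
    }
    intron_trees: dict[str, IntervalTree] = {}
    exon_trees: dict[str, IntervalTree] = {}
    for g in genes:
        for iv in g.introns():
            intron_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        for iv in g.exons:
            exon_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    repeat_region = Counter()
    for r in repeats:
        iv = r.interval
        mid = (iv.start + iv.end) // 2
        if exon_trees.get(iv.chrom) and exon_trees[iv.chrom].overlap(mid, mid + 1):
            repeat_region["CDS"] += len(iv)
        elif intron_trees.get(iv.chrom) and intron_trees[iv.chrom].overlap(mid, mid + 1):
            repeat_region["intronic"] += len(iv)
        else:
            repeat_region["intergenic"] += len(iv)
    total_rep = sum(repeat_region.values())
    out["repeat_region_proportions"] = {
        k: repeat_region.get(k, 0) / total_rep if total_rep else float("nan")
        for k in ("intronic", "intergenic", "CDS")
    }

    # copy number vs ereMAP yield
    copies = Counter(r.family for r in repeats)
    fam_counts = Counter(r.family for r in records)
    families = sorted(copies)
    x = [copies[f] for f in families]
    y = [fam_counts.get(f, 0) for f in families]
    try:
        tau, p = kendall_tau(x, y)
        out["copy_number_kendall"] = {"tau_b": tau, "p_value": p}
    except ValueError as exc:
        out["copy_number_kendall"] = {"undefined": str(exc)}
    return out


# ---------------------------------------------------------------------------
# pipeline driver


def call_eremaps(
    candidates: Sequence[PeptideCandidate],
    partition: ReadPartition,
    proteome: CombinedProteome,
    repeats: Sequence[RepeatRecord],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    fdr_q: float = DEFAULT_FDR_Q,
    rank_max: float = DEFAULT_RANK_MAX,
    kmer_k: int = DEFAULT_KMER_K,
    ratio_min: float = DEFAULT_RATIO_MIN,
    min_reads: int = DEFAULT_MIN_READS,
) -> tuple[list[EreMapRecord], list[PeptideCandidate]]:
    """Run the full cascade over one or more samples' candidates.

    Returns (non-redundant ereMAP records, all candidates with their
    verdict trails for auditing).
    """
    all_reads = partition.ere_reads + partition.canonical_reads
    translations = TranslatedReads(all_reads)
    ere_table = build_kmer_table(partition.ere_reads, k=kmer_k)
    canonical_table = build_kmer_table(partition.canonical_reads, k=kmer_k)

    survivors: list[tuple[str, str, tuple[str, str, str, str, str]]] = []
    audited: list[PeptideCandidate] = list(candidates)

    by_sample: dict[str, list[PeptideCandidate]] = {}
    for c in candidates:
        by_sample.setdefault(c.sample, []).append(c)

    for sample in sorted(by_sample):
        stage = apply_fdr(by_sample[sample], q=fdr_q)
        stage = filter_binders(stage, rank_max=rank_max)
        for cand in stage:
            status = assign_status(cand, proteome)
            if status == "no":
                cand.log("terminal", "discard: canonical peptide")
                continue
            if status == "undetermined":
                cand.log("terminal", "discard: absent from both proteomes")
                continue
            cand.mcs_set = recover_mcs(cand.peptide, cache=translations)
            if status == "maybe":
                if not resolve_maybe(
                    cand, ere_table, canonical_table,
                    ratio_min=ratio_min, min_reads=min_reads,
                ):
                    continue
            else:  # yes: still require multi-read support (sequencing-error guard)
                n_support = sum(n for _, n in cand.mcs_set)
                if n_support < min_reads:
                    cand.log(
                        "read-support",
                        f"discard: supported by {n_support} read(s) < {min_reads}",
                    )
                    continue
                cand.log("read-support", f"pass ({n_support} reads)")
            own = proteome.peptide_expression(cand.peptide, "ere-read")
            if not il_variant_check(cand, proteome, own):
                continue
            ranked = _rank_mcs(cand.mcs_set, ere_table, canonical_table)
            top_mcs = ranked[0][0]
            call = classify_origin(top_mcs, repeats, genes, genome)
            if call is None:
                cand.log("locus", "discard: no clear genomic region")
                continue
            cand.log(
                "locus",
                f"{call.region_class}, {call.orientation_vs_ere} vs ERE, "
                f"{call.orientation_vs_gene} vs gene, {call.n_ere_loci} ERE loci",
            )
            keep, reason = orientation_decision(
                call.region_class,
                call.orientation_vs_gene,
                call.orientation_vs_ere,
                call.n_ere_loci,
            )
            if not keep:
                cand.log("orientation", f"discard: {reason}")
                continue
            cand.log("orientation", f"keep: {reason}")
            cand.log("terminal", "ereMAP")
            survivors.append(
                (
                    cand.peptide,
                    sample,
                    (
                        call.family or "n/a",
                        call.group or "n/a",
                        call.region_class,
                        call.orientation_vs_ere,
                        call.orientation_vs_gene,
                    ),
                )
            )
    return aggregate_nonredundant(survivors), audited
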