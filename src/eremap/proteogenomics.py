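"""Per-sample proteome construction from RNA-seq reads.

QC-passing reads are split into an ERE dataset (reads entirely
contained in a repeat annotation) and a canonical dataset (reads
entirely contained in an exon); a read qualifying for both goes to the
canonical dataset only.  ERE reads are N-trimmed, translated in all
six frames, spliced at stop codons and collected into a theoretical
ERE proteome; canonical transcripts carry sample variants and are
translated in their annotated frame into a personalized canonical
proteome.  The two concatenated form the search space against which
peptide identifications are classified.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import AlignedRead, ExpressionTable, GeneModel, RepeatRecord

__all__ = [
    "REVCOMP_TABLE",
    "revcomp",
    "translate",
    "filter_alignments",
    "ReadPartition",
    "partition_reads",
    "segment_ambiguous",
    "six_frame_translate",
    "splice_at_stops",
    "ProteomeEntry",
    "build_ere_proteome",
    "build_personalized_proteome",
    "CombinedProteome",
    "concat_proteomes",
]

REVCOMP_TABLE = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code, codons enumerated T,C,A,G by position.
_BASES = "TCAG"
_CODE = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = {
    b1 + b2 + b3: aa
    for aa, (b1, b2, b3) in zip(
        _CODE, ((a, b, c) for a in _BASES for b in _BASES for c in _BASES)
    )
}
STOP = "*"


def revcomp(seq: str) -> str:
    return seq.translate(REVCOMP_TABLE)[::-1]


def translate(nt: str) -> str:
    """Translate an N-free nucleotide string; trailing partial codon dropped."""
    table = CODON_TABLE
    return "".join(
        table[nt[i : i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3)
    )


# ---------------------------------------------------------------------------
# alignment QC

# FLAG bits that disqualify a read: unmapped, mate unmapped, secondary,
# QC-fail, duplicate, supplementary (the 3852 exclusion mask).
EXCLUDE_MASK = 0x4 | 0x8 | 0x100 | 0x200 | 0x400 | 0x800


def passes_qc(read: AlignedRead) -> bool:
    """True for primary, properly-paired FR reads with clean flags.

    Equivalent to accepting exactly FLAGs 99, 147, 163 and 83 over the
    pairing/orientation bits while rejecting anything intersecting the
    3852 exclusion mask.
    """
    return (
        (read.flag & EXCLUDE_MASK) == 0
        and read.is_paired
        and read.is_proper_pair
        and read.pair_orientation in ("F1R2", "R1F2")
    )


def filter_alignments(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    return [r for r in reads if passes_qc(r)]


# ---------------------------------------------------------------------------
# partitioning


@dataclass
class ReadPartition:
    ere_reads: list[AlignedRead]
    canonical_reads: list[AlignedRead]
    discarded: list[tuple[AlignedRead, str]]

    def __post_init__(self) -> None:
        overlap = {r.read_id for r in self.ere_reads} & {
            r.read_id for r in self.canonical_reads
        }
        if overlap:
            raise ValueError(f"reads in both datasets: {sorted(overlap)[:5]}")


def _containment_trees(
    intervals: Iterable[tuple[str, int, int]],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def _contained(trees: Mapping[str, IntervalTree], chrom: str, start: int, end: int) -> bool:
    tree = trees.get(chrom)
    if tree is None:
        return False
    return any(iv.begin <= start and end <= iv.end for iv in tree.overlap(start, end))


def partition_reads(
    reads: Sequence[AlignedRead],
    repeats: Sequence[RepeatRecord],
    genes: Sequence[GeneModel],
) -> ReadPartition:
    """Split QC-passing reads into ERE and canonical datasets.

    Containment uses the reference span of the alignment.  A read
    contained in both a repeat and an exon is canonical only; a read
    contained in neither (including reads on unannotated contigs) is
    discarded with a reason.  Mates are partitioned independently.
    """
    repeat_trees = _containment_trees(
        (r.interval.chrom, r.interval.start, r.interval.end) for r in repeats
    )
    exon_trees = _containment_trees(
        (e.chrom, e.start, e.end) for g in genes for e in g.exons
    )
    ere, canonical, discarded = [], [], []
    for read in reads:
        if read.interval is None:
            discarded.append((read, "unmapped"))
            continue
        iv = read.interval
        in_exon = _contained(exon_trees, iv.chrom, iv.start, iv.end)
        in_repeat = _contained(repeat_trees, iv.chrom, iv.start, iv.end)
        if in_exon:
            canonical.append(read)
        elif in_repeat:
            ere.append(read)
        else:
            discarded.append((read, "not contained in any annotation"))
    return ReadPartition(ere, canonical, discarded)


# ---------------------------------------------------------------------------
# translation pipeline


def segment_ambiguous(sequence: str) -> list[tuple[str, int]]:
    """Maximal N-free segments of a read with their offsets."""
    out = []
    start = None
    for i, base in enumerate(sequence):
        if base == "N":
            if start is not None:
                out.append((sequence[start:i], start))
                start = None
        elif start is None:
            start = i
    if start is not None:
        out.append((sequence[start:], start))
    return out


def six_frame_translate(nt_sequence: str) -> list[str]:
    """Translations of frames +1..+3 and the reverse complement +1..+3.

    Stop codons appear as ``*``; sequences shorter than one codon give
    an empty list.
    """
    if len(nt_sequence) < 3:
        return []
    rc = revcomp(nt_sequence)
    return [translate(nt_sequence[f:]) for f in range(3)] + [
        translate(rc[f:]) for f in range(3)
    ]


def splice_at_stops(
    aa_with_stops: str,
    min_len: int = 8,
    mode: str = "prefix",
) -> list[str]:
    """Remove sequence following stop codons; keep pieces >= ``min_len``.

    ``prefix`` (default) keeps only the segment preceding the first
    stop.  ``split`` keeps every inter-stop segment — the alternative
    reading of "spliced to remove sequences following stop codons".
    """
    if mode not in ("prefix", "split"):
        raise ValueError(f"unknown splice mode {mode!r}")
    if mode == "prefix":
        pieces = [aa_with_stops.split(STOP, 1)[0]]
    else:
        pieces = aa_with_stops.split(STOP)
    return [p for p in pieces if len(p) >= min_len]


@dataclass(frozen=True)
class ProteomeEntry:
    entry_id: str
    aa_sequence: str
    source: str  # "ere-read" | "canonical-transcript"
    provenance: str  # read id + frame, or transcript id + variant set
    expression: float = 0.0  # read support (ERE) or transcript TPM (canonical)

    def __post_init__(self) -> None:
        if STOP in self.aa_sequence:
            raise ValueError(f"{self.entry_id}: stop symbol in proteome entry")
        if self.source == "ere-read" and len(self.aa_sequence) < 8:
            raise ValueError(f"{self.entry_id}: ERE entry shorter than 8 aa")


def build_ere_proteome(
    ere_reads: Sequence[AlignedRead] | ReadPartition,
    min_len: int = 8,
    splice_mode: str = "prefix",
) -> list[ProteomeEntry]:
    """Theoretical ERE proteome: every ERE read, N-trimmed, six-frame
    translated, stop-spliced, kept at >= ``min_len`` aa.

    Duplicate amino-acid sequences from different reads/frames are kept
    as separate entries with distinct provenance.
    """
    if isinstance(ere_reads, ReadPartition):
        ere_reads = ere_reads.ere_reads
    entries = []
    uid = 0
    for read in ere_reads:
        for segment, offset in segment_ambiguous(read.sequence):
            if len(segment) < 3:
                continue
            for frame, aa in enumerate(six_frame_translate(segment)):
                for piece in splice_at_stops(aa, min_len=min_len, mode=splice_mode):
                    uid += 1
                    entries.append(
                        ProteomeEntry(
                            entry_id=f"ere_{uid:07d}",
                            aa_sequence=piece,
                            source="ere-read",
                            provenance=f"{read.read_id}|seg{offset}|frame{frame}",
                            expression=1.0,
                        )
                    )
    return entries


def cds_start_offsets(genes: Sequence[GeneModel]) -> dict[str, int]:
    """Offset of the CDS start within each spliced transcript.

    Derived from the gene models' CDS intervals; transcripts without
    CDS annotation are omitted (the personalized-proteome builder then
    falls back to the first ATG for them).
    """
    out: dict[str, int] = {}
    for g in genes:
        if not g.cds:
            continue
        if g.strand == "+":
            exons = sorted(g.exons, key=lambda e: e.start)
            cds_5p = min(c.start for c in g.cds)
            off = 0
            for e in exons:
                if e.start <= cds_5p < e.end:
                    off += cds_5p - e.start
                    break
                off += len(e)
        else:
            exons = sorted(g.exons, key=lambda e: -e.start)
            cds_5p = max(c.end for c in g.cds)  # transcript 5' end
            off = 0
            for e in exons:
                if e.start < cds_5p <= e.end:
                    off += e.end - cds_5p
                    break
                off += len(e)
        for tid in g.transcript_ids:
            out[tid] = off
    return out


def build_personalized_proteome(
    transcripts: Mapping[str, str],
    variants: pd.DataFrame | None,
    expression: ExpressionTable | Mapping[str, float],
    sample: str | None = None,
    cds_start: Mapping[str, int] | None = None,
    min_alt_count: int = 5,
) -> list[ProteomeEntry]:
    """Personalized canonical proteome for one sample.

    Single-nucleotide variants with ``alt_count >= min_alt_count`` are
    substituted into the transcript sequence (``position`` is 1-based
    in transcript coordinates and the ``ref`` base must match).  Only
    transcripts with TPM > 0 are translated, from the annotated CDS
    start when provided, otherwise from the first ATG, up to the first
    stop codon.
    """
    if isinstance(expression, ExpressionTable):
        if sample is None:
            raise ValueError("sample id required with an expression table")
        tpm = expression.values[sample].to_dict()
    else:
        tpm = dict(expression)
    applied: dict[str, list[str]] = {}
    seqs = {t: s for t, s in transcripts.items()}
    if variants is not None and len(variants):
        for row in variants.itertuples(index=False):
            if int(row.alt_count) < min_alt_count:
                continue
            tid = str(row.transcript_id)
            if tid not in seqs:
                continue
            pos = int(row.position) - 1
            seq = seqs[tid]
            if not (0 <= pos < len(seq)) or seq[pos] != str(row.ref).upper():
                raise ValueError(
                    f"variant ref mismatch in {tid} at position {row.position}: "
                    f"expected {row.ref}, transcript has "
                    f"{seq[pos] if 0 <= pos < len(seq) else 'out-of-range'}"
                )
            seqs[tid] = seq[:pos] + str(row.alt).upper() + seq[pos + 1 :]
            applied.setdefault(tid, []).append(f"{row.position}{row.ref}>{row.alt}")
    entries = []
    for tid in sorted(seqs):
        expr = float(tpm.get(tid, 0.0))
        if expr <= 0:
            continue
        seq = seqs[tid]
        if cds_start is not None and tid in cds_start:
            start = cds_start[tid]
        else:
            start = seq.find("ATG")
            if start == -1:
                continue
        aa = translate(seq[start:]).split(STOP, 1)[0]
        if not aa:
            continue
        variant_tag = ",".join(applied.get(tid, [])) or "none"
        entries.append(
            ProteomeEntry(
                entry_id=f"can_{tid}",
                aa_sequence=aa,
                source="canonical-transcript",
                provenance=f"{tid}|variants:{variant_tag}",
                expression=expr,
            )
        )
    return entries


# ---------------------------------------------------------------------------
# combined proteome


class CombinedProteome:
    """Concatenated ERE + canonical proteome with substring queries.

    Membership queries for 8-11-mer peptides run against one
    separator-joined string per source; match offsets map back to
    entries so expression lookups for I/L arbitration stay exact.
    """

    def __init__(self, entries: Sequence[ProteomeEntry]):
        ids = [e.entry_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("entry id collision in combined proteome")
        self.entries = list(entries)
        self._by_source: dict[str, tuple[str, list[int], list[ProteomeEntry]]] = {}
        for source in ("ere-read", "canonical-transcript"):
            subset = [e for e in entries if e.source == source]
            offsets: list[int] = []
            pos = 0
            chunks = []
            for e in subset:
                offsets.append(pos)
                chunks.append(e.aa_sequence)
                pos += len(e.aa_sequence) + 1
            self._by_source[source] = ("#".join(chunks), offsets, subset)

    def entries_containing(self, peptide: str, source: str) -> list[ProteomeEntry]:
        haystack, offsets, subset = self._by_source[source]
        found: dict[int, ProteomeEntry] = {}
        start = haystack.find(peptide)
        while start != -1:
            idx = bisect.bisect_right(offsets, start) - 1
            found[idx] = subset[idx]
            start = haystack.find(peptide, start + 1)
        return [found[i] for i in sorted(found)]

    def membership(self, peptide: str) -> tuple[bool, bool]:
        """(present in ERE proteome, present in canonical proteome)."""
        return (
            self._by_source["ere-read"][0].find(peptide) != -1,
            self._by_source["canonical-transcript"][0].find(peptide) != -1,
        )

    def peptide_expression(self, peptide: str, source: str) -> float:
        """Expression attributable to a peptide within one source.

        Canonical: max transcript TPM over entries containing it.
        ERE: number of distinct supporting reads containing it.
        """
        hits = self.entries_containing(peptide, source)
        if not hits:
            return 0.0
        if source == "canonical-transcript":
            return max(e.expression for e in hits)
        return float(len({e.provenance.split("|")[0] for e in hits}))


def concat_proteomes(
    ere: Sequence[ProteomeEntry],
    canonical: Sequence[ProteomeEntry],
) -> CombinedProteome:
    return CombinedProteome(list(ere) + list(canonical))
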