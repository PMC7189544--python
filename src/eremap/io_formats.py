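"""Readers and writers for the formats the pipeline touches.

Every coordinate held in memory is 0-based, half-open, on an explicit
strand.  Conversion from the 1-based closed conventions of RepeatMasker
``.out`` and GTF happens at the parse boundary and nowhere else; writers
convert back symmetrically.

SAM support is deliberately minimal (QNAME, FLAG, RNAME, POS, CIGAR,
SEQ): the pipeline only ever needs the reference span of an alignment
for containment tests, never base-level alignment detail.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ParseError",
    "GenomicInterval",
    "RepeatRecord",
    "GeneModel",
    "AlignedRead",
    "ExpressionTable",
    "PeptideCandidate",
    "read_repeatmasker",
    "read_gtf",
    "read_psm_table",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_sam_min",
    "write_sam_min",
    "read_tsv_matrix",
    "write_tsv_matrix",
    "read_methylation_table",
    "cigar_reference_span",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

ERE_GROUPS = ("LINE", "LTR", "SINE")

# SAM FLAG bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800


class ParseError(ValueError):
    """A malformed input line; the message names the file and line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open stranded interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """Strand-blind containment of *other* within self."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RepeatRecord:
    """One repeat annotation interval (e.g. a single AluY insertion)."""

    interval: GenomicInterval
    family: str
    group: str  # LINE / LTR / SINE / other
    element_name: str

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("repeat family must be non-empty")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    transcript_ids: tuple[str, ...]
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...]
    strand: str
    has_overlapping_exons: bool = False

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.exons[0].chrom,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )

    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between sorted exons, on the gene strand."""
        exons = sorted(self.exons, key=lambda e: e.start)
        out = []
        for a, b in zip(exons, exons[1:]):
            if a.end < b.start:
                out.append(GenomicInterval(a.chrom, a.end, b.start, self.strand))
        return tuple(out)


@dataclass(frozen=True)
class AlignedRead:
    """A read with the subset of SAM state the pipeline consumes."""

    read_id: str
    sequence: str
    interval: GenomicInterval | None
    flag: int = 0

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flag & FLAG_PROPER_PAIR)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def mate_unmapped(self) -> bool:
        return bool(self.flag & FLAG_MATE_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def mate_reverse(self) -> bool:
        return bool(self.flag & FLAG_MATE_REVERSE)

    @property
    def is_read1(self) -> bool:
        return bool(self.flag & FLAG_READ1)

    @property
    def is_read2(self) -> bool:
        return bool(self.flag & FLAG_READ2)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def qc_fail(self) -> bool:
        return bool(self.flag & FLAG_QCFAIL)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUPLICATE)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def pair_orientation(self) -> str | None:
        """``F1R2`` / ``R1F2`` for the two standard FR layouts, else None."""
        if not (self.is_read1 ^ self.is_read2):
            return None
        if self.is_reverse == self.mate_reverse:
            return None
        fwd_first = self.is_read1 and not self.is_reverse
        rev_second = self.is_read2 and self.is_reverse
        if fwd_first or rev_second:
            return "F1R2"
        return "R1F2"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if self.is_unmapped and self.interval is not None:
            raise ValueError(f"read {self.read_id}: unmapped read with interval")


@dataclass
class ExpressionTable:
    """Features x samples matrix with a unit tag; thin pandas wrapper."""

    values: pd.DataFrame  # index = feature ids, columns = sample ids
    unit: str = "TPM"

    _ALLOWED_UNITS = ("TPM", "rphm", "raw", "zscore")

    def __post_init__(self) -> None:
        if self.unit not in self._ALLOWED_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if not self.values.index.is_unique or not self.values.columns.is_unique:
            raise ValueError("row/column ids must be unique")
        if self.unit != "zscore" and (self.values.to_numpy() < 0).any():
            raise ValueError(f"negative values in a {self.unit} table")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PeptideCandidate:
    """A peptide identification with its filter state.

    ``verdict_trail`` is append-only: every cascade stage that touches the
    candidate records (rule, outcome) so the audit of a call is complete.
    """

    peptide: str
    sample: str
    score: float
    is_decoy: bool
    binding_ranks: dict[str, float] = field(default_factory=dict)
    status: str | None = None  # yes / maybe / no / undetermined
    mcs_set: list[tuple[str, int]] = field(default_factory=list)
    verdict_trail: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.peptide) - _AA_SET
        if bad:
            raise ParseError(
                f"peptide {self.peptide!r} contains non-amino-acid "
                f"characters {sorted(bad)}"
            )

    @property
    def best_rank(self) -> float | None:
        """Minimum binding percentile over available alleles (lower = stronger)."""
        if not self.binding_ranks:
            return None
        return min(self.binding_ranks.values())

    def log(self, rule: str, outcome: str) -> None:
        self.verdict_trail.append((rule, outcome))


# ---------------------------------------------------------------------------
# repeats


def _is_bed_line(fields: Sequence[str]) -> bool:
    return (
        len(fields) >= 3
        and fields[1].isdigit()
        and fields[2].isdigit()
        and not fields[0].lstrip("-").isdigit()
    )


def read_repeatmasker(
    path: str | Path,
    family_group_map: Mapping[str, str],
) -> list[RepeatRecord]:
    """Load repeat annotations from RepeatMasker ``.out`` or BED.

    ``.out`` rows use 1-based closed coordinates and are converted;
    BED rows are already 0-based half-open.  Families absent from
    ``family_group_map`` are assigned group ``"other"``.
    """
    records: list[RepeatRecord] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            # RepeatMasker .out header lines start with the column words
            if fields[0] in ("SW", "score") or fields[0].startswith("="):
                continue
            try:
                if _is_bed_line(fields):
                    chrom = fields[0]
                    start, end = int(fields[1]), int(fields[2])
                    family = fields[3] if len(fields) > 3 else "unknown"
                    strand = fields[5] if len(fields) > 5 else "+"
                    name = f"{family}|{chrom}:{start}-{end}"
                else:
                    # .out: score div del ins query begin end (left) strand
                    #       repeat class/family [begin end (left) ID]
                    chrom = fields[4]
                    begin, end1 = int(fields[5]), int(fields[6])
                    strand = "-" if fields[8] in ("C", "-") else "+"
                    family = fields[9]
                    uid = fields[14] if len(fields) > 14 else str(lineno)
                    start, end = begin - 1, end1
                    name = f"{family}#{uid}"
                if fields[8:9] and fields[8] not in ("C", "+", "-") and not _is_bed_line(fields):
                    raise ValueError(f"unknown strand symbol {fields[8]!r}")
                interval = GenomicInterval(chrom, start, end, strand)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            group = family_group_map.get(family, "other")
            records.append(RepeatRecord(interval, family, group, name))
    return records


def write_repeatmasker_out(records: Iterable[RepeatRecord], path: str | Path) -> None:
    """Serialize repeats back to a minimal ``.out`` layout (1-based closed)."""
    with open(path, "w") as fh:
        fh.write(
            "SW perc perc perc query begin end (left) strand repeat "
            "class/family begin end (left) ID\n\n"
        )
        for i, rec in enumerate(records, 1):
            iv = rec.interval
            strand = "C" if iv.strand == "-" else "+"
            fh.write(
                f"1000 0.0 0.0 0.0 {iv.chrom} {iv.start + 1} {iv.end} (0) "
                f"{strand} {rec.family} {rec.group}/{rec.family} 1 {len(iv)} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# genes

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse exon and CDS features of a GTF into gene models.

    GTF coordinates are 1-based closed and are converted on the way in.
    Transcripts are grouped under genes; overlapping exons within one
    gene are retained but flagged.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    strands: dict[str, str] = {}
    cds_only_tx: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            try:
                iv = GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            attr = dict(_GTF_ATTR.findall(attrs))
            try:
                gene_id, tx_id = attr["gene_id"], attr["transcript_id"]
            except KeyError as exc:
                raise ParseError(
                    f"{path}:{lineno}: missing {exc} attribute"
                ) from exc
            tx_gene[tx_id] = gene_id
            strands[gene_id] = strand
            if feature == "exon":
                exons.setdefault(tx_id, []).append(iv)
                cds_only_tx.discard(tx_id)
            else:
                cds.setdefault(tx_id, []).append(iv)
                if tx_id not in exons:
                    cds_only_tx.add(tx_id)
    if cds_only_tx:
        raise ParseError(
            f"{path}: CDS feature(s) without parent transcript exons: "
            f"{sorted(cds_only_tx)}"
        )
    genes: dict[str, dict] = {}
    for tx_id, tx_exons in exons.items():
        gid = tx_gene[tx_id]
        g = genes.setdefault(gid, {"tx": [], "exons": [], "cds": []})
        g["tx"].append(tx_id)
        g["exons"].extend(tx_exons)
        g["cds"].extend(cds.get(tx_id, []))
    out = []
    for gid in sorted(genes):
        g = genes[gid]
        ex = sorted(set(g["exons"]), key=lambda e: (e.start, e.end))
        overlapping = any(a.end > b.start for a, b in zip(ex, ex[1:]))
        out.append(
            GeneModel(
                gene_id=gid,
                transcript_ids=tuple(sorted(g["tx"])),
                exons=tuple(ex),
                cds=tuple(sorted(set(g["cds"]), key=lambda e: (e.start, e.end))),
                strand=strands[gid],
                has_overlapping_exons=overlapping,
            )
        )
    return out


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            tx = g.transcript_ids[0] if g.transcript_ids else g.gene_id + ".t1"
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{tx}";'
            for iv in g.exons:
                fh.write(
                    f"{iv.chrom}\teremap\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
            for iv in g.cds:
                fh.write(
                    f"{iv.chrom}\teremap\tCDS\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{g.strand}\t0\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# PSM tables


def read_psm_table(path: str | Path) -> list[PeptideCandidate]:
    """Load a peptide-spectrum-match table.

    Expected columns: ``peptide``, ``sample``, ``score``, ``is_decoy``,
    plus one column per HLA allele holding binding percentile ranks.
    Duplicate (peptide, sample) rows keep the max-score instance.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "sample": str})
    required = {"peptide", "sample", "score", "is_decoy"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    allele_cols = [c for c in df.columns if c not in required]
    df["peptide"] = df["peptide"].str.upper()
    df = (
        df.sort_values("score", ascending=False)
        .drop_duplicates(["peptide", "sample"], keep="first")
        .sort_index()
    )
    out = []
    for row in df.itertuples(index=False):
        ranks = {
            a: float(getattr(row, a))
            for a in allele_cols
            if pd.notna(getattr(row, a))
        }
        decoy = row.is_decoy
        if isinstance(decoy, str):
            decoy = decoy.strip().lower() in ("true", "1", "yes")
        out.append(
            PeptideCandidate(
                peptide=str(row.peptide).upper(),
                sample=str(row.sample),
                score=float(row.score),
                is_decoy=bool(decoy),
                binding_ranks=ranks,
            )
        )
    return out


def write_psm_table(candidates: Iterable[PeptideCandidate], path: str | Path) -> None:
    alleles = sorted({a for c in candidates for a in c.binding_ranks})
    rows = []
    for c in candidates:
        row = {
            "peptide": c.peptide,
            "sample": c.sample,
            "score": c.score,
            "is_decoy": c.is_decoy,
        }
        row.update({a: c.binding_ranks.get(a) for a in alleles})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# SAM (minimal text support)

_CIGAR_OP = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = frozenset("MDN=X")


def cigar_reference_span(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string."""
    if cigar == "*":
        return 0
    span = 0
    consumed = 0
    for length, op in _CIGAR_OP.findall(cigar):
        consumed += len(length) + 1
        if op in _REF_CONSUMING:
            span += int(length)
    if consumed != len(cigar):
        raise ParseError(f"malformed CIGAR {cigar!r}")
    return span


def read_sam_min(path: str | Path) -> list[AlignedRead]:
    """Parse a text SAM into :class:`AlignedRead` records.

    The alignment interval spans the reference bases implied by the
    CIGAR (not the read length), so clipped and spliced alignments get
    their true footprint.  Strand comes from the FLAG reverse bit.
    """
    path = Path(path)
    reads = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if raw.startswith("@") or not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise ParseError(f"{path}:{lineno}: expected >= 10 SAM columns")
            qname, flag_s, rname, pos_s, _, cigar = fields[:6]
            seq = fields[9]
            try:
                flag = int(flag_s)
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if flag & FLAG_UNMAPPED or rname == "*":
                flag |= FLAG_UNMAPPED
                interval = None
            else:
                span = cigar_reference_span(cigar) or len(seq)
                strand = "-" if flag & FLAG_REVERSE else "+"
                interval = GenomicInterval(rname, pos - 1, pos - 1 + span, strand)
            reads.append(AlignedRead(qname, seq.upper(), interval, flag))
    return reads


def write_sam_min(
    reads: Iterable[AlignedRead],
    path: str | Path,
    chrom_sizes: Mapping[str, int] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, size in (chrom_sizes or {}).items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{size}\n")
        for r in reads:
            if r.interval is None:
                fh.write(f"{r.read_id}\t{r.flag}\t*\t0\t0\t*\t*\t0\t0\t{r.sequence}\t*\n")
            else:
                iv = r.interval
                fh.write(
                    f"{r.read_id}\t{r.flag}\t{iv.chrom}\t{iv.start + 1}\t60\t"
                    f"{len(r.sequence)}M\t*\t0\t0\t{r.sequence}\t*\n"
                )


# ---------------------------------------------------------------------------
# matrices and probe tables


def write_tsv_matrix(table: ExpressionTable, path: str | Path) -> None:
    """Write a matrix with the unit recorded on a leading comment line."""
    with open(path, "w") as fh:
        fh.write(f"#unit={table.unit}\n")
        # %.17g round-trips IEEE doubles exactly
        table.values.to_csv(fh, sep="\t", index_label="feature", float_format="%.17g")


def read_tsv_matrix(path: str | Path, unit: str | None = None) -> ExpressionTable:
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#unit="):
            unit = unit or first.strip().split("=", 1)[1]
        else:
            fh.seek(0)
            unit = unit or "raw"
        df = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
    return ExpressionTable(df, unit=unit)


def read_methylation_table(path: str | Path) -> pd.DataFrame:
    """Probe table: probe_id, chrom, pos, then one beta column per sample."""
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "chrom", "pos"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df
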