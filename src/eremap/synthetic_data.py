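"""Synthetic inputs with planted ground truth.

Every input the pipeline consumes can be generated here with a known
answer attached: a small genome carrying repeat copies in intronic,
intergenic and exon-straddling contexts; a multi-tissue expression
panel with planted housekeeping and tissue-restricted families; a
B-LCL-like read set in which peptide-coding sequences are planted so
that each candidate has a predetermined correct verdict under the
validation cascade; methylation probe tables with a controlled
expression correlation; and calibrated PSM score sets for the
target-decoy FDR estimator.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AlignedRead,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    PeptideCandidate,
    RepeatRecord,
    write_fasta,
    write_fastq,
    write_gtf,
    write_psm_table,
    write_repeatmasker_out,
    write_sam_min,
    write_tsv_matrix,
)
from .proteogenomics import CODON_TABLE, revcomp

__all__ = [
    "GenomeBundle",
    "make_genome",
    "PanelTruth",
    "make_tissue_panel",
    "PlantedPeptide",
    "ReadSetTruth",
    "ReadSetBundle",
    "make_blcl_readset",
    "make_methylation",
    "make_psm_scores",
]

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
# codon choices per amino acid, for encoding planted peptides
_CODONS_OF = {}
for codon, aa in CODON_TABLE.items():
    _CODONS_OF.setdefault(aa, []).append(codon)
for aa in _CODONS_OF:
    _CODONS_OF[aa].sort()

# planted peptides avoid I and L so the isobaric-variant check is inert
# for them (that rule is exercised with dedicated constructions)
_PLANT_ALPHABET = "ADEFGHKNPQRSTVWY"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_sense_codons(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _random_peptide(rng: np.random.Generator, length: int, alphabet: str = _PLANT_ALPHABET) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def _encode_peptide(rng: np.random.Generator, peptide: str) -> str:
    return "".join(
        _CODONS_OF[aa][rng.integers(0, len(_CODONS_OF[aa]))] for aa in peptide
    )


# ---------------------------------------------------------------------------
# genome


@dataclass
class GenomeBundle:
    sequences: dict[str, str]
    repeats: list[RepeatRecord]
    genes: list[GeneModel]
    family_group_map: dict[str, str]

    def transcripts(self) -> tuple[dict[str, str], dict[str, int]]:
        """Spliced transcript sequences and their CDS start offsets."""
        tx: dict[str, str] = {}
        cds_start: dict[str, int] = {}
        for g in self.genes:
            seq = "".join(
                self.sequences[e.chrom][e.start : e.end]
                for e in sorted(g.exons, key=lambda e: e.start)
            )
            tid = g.transcript_ids[0]
            tx[tid] = seq
            cds_start[tid] = 0  # whole transcript is coding by construction
        return tx, cds_start

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


# gene architecture: exon1-intron1-exon2-intron2-exon3, all "+" strand
_EXON_LEN = 900  # multiple of 3: exons stay frame-aligned in the transcript
_INTRON_LEN = 1800
_GENE_PITCH = 12_000
_GENE_MARGIN = 3_000


def make_genome(
    n_chrom: int = 2,
    length: int = 300_000,
    repeat_families: int = 12,
    copies_per_family: int = 8,
    divergence: float = 0.05,
    seed: int = 0,
    repeat_length: int = 400,
    intronic_fraction: float = 0.51,
    intergenic_fraction: float = 0.45,
) -> GenomeBundle:
    """Small genome with genes and repeat copies in three contexts.

    Repeat copies are mutated clones of per-family consensus sequences
    (substitution rate = ``divergence``) placed intronic (default 51%
    of copies, the genome-wide share of intronic repeat sequence),
    intergenic, or straddling an exon boundary.  Gene exons are
    written as stop-free codons in the transcript frame so every gene
    translates full-length; introns and intergenic space are uniform
    random sequence.
    """
    if not (0 <= divergence <= 0.3):
        raise ValueError("divergence must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)
    sequences = {
        f"chr{i + 1}": list(_random_seq(rng, length)) for i in range(n_chrom)
    }

    genes: list[GeneModel] = []
    intronic_slots: list[tuple[str, int]] = []
    intergenic_slots: list[tuple[str, int]] = []
    exonic_slots: list[tuple[str, int, str]] = []  # (chrom, exon2_start, gene)
    for chrom in sequences:
        pos = _GENE_MARGIN
        gi = 0
        prev_end = 0
        while pos + 3 * _EXON_LEN + 2 * _INTRON_LEN + _GENE_MARGIN <= length:
            gi += 1
            gid = f"{chrom}_g{gi:03d}"
            e1 = GenomicInterval(chrom, pos, pos + _EXON_LEN, "+")
            i1s = e1.end
            e2 = GenomicInterval(chrom, i1s + _INTRON_LEN, i1s + _INTRON_LEN + _EXON_LEN, "+")
            i2s = e2.end
            e3 = GenomicInterval(chrom, i2s + _INTRON_LEN, i2s + _INTRON_LEN + _EXON_LEN, "+")
            genes.append(
                GeneModel(gid, (f"{gid}.t1",), (e1, e2, e3), (e1, e2, e3), "+")
            )
            # exon content: stop-free codons in transcript frame
            coding = _random_sense_codons(rng, _EXON_LEN)  # 3 exons worth
            for k, e in enumerate((e1, e2, e3)):
                chunk = coding[k * _EXON_LEN : (k + 1) * _EXON_LEN]
                sequences[chrom][e.start : e.end] = list(chunk)
            for intron_start in (i1s, i2s):
                intronic_slots.append((chrom, intron_start + 700))
            exonic_slots.append((chrom, e2.start, gid))
            # intergenic gap between previous gene and this one
            gap_lo, gap_hi = prev_end, pos
            off = gap_lo + 500
            while off + repeat_length + 300 <= gap_hi:
                intergenic_slots.append((chrom, off))
                off += repeat_length + 1100
            prev_end = e3.end
            pos += _GENE_PITCH

    total = repeat_families * copies_per_family
    n_intronic = round(intronic_fraction * total)
    n_intergenic = round(intergenic_fraction * total)
    n_exonic = total - n_intronic - n_intergenic
    if n_intronic > len(intronic_slots) or n_exonic > len(exonic_slots):
        raise ValueError("requested copies exceed available genic space")
    if n_intergenic > len(intergenic_slots):
        raise ValueError("requested copies exceed available intergenic space")

    groups = ["LINE", "LTR", "SINE"]
    family_group_map = {
        f"FAM{j + 1:03d}": groups[j % 3] for j in range(repeat_families)
    }
    consensi = {
        fam: _random_seq(rng, repeat_length) for fam in sorted(family_group_map)
    }
    assignments = (
        ["intronic"] * n_intronic
        + ["intergenic"] * n_intergenic
        + ["exonic"] * n_exonic
    )
    rng.shuffle(assignments)
    slot_iters = {
        "intronic": iter(intronic_slots),
        "intergenic": iter(intergenic_slots),
        "exonic": iter((c, s - 200) for c, s, _ in exonic_slots),
    }
    repeats: list[RepeatRecord] = []
    fam_cycle = [
        fam for fam in sorted(family_group_map) for _ in range(copies_per_family)
    ]
    for idx, (fam, context) in enumerate(zip(fam_cycle, assignments), 1):
        chrom, start = next(slot_iters[context])
        consensus = consensi[fam]
        copy = list(consensus)
        n_mut = rng.binomial(repeat_length, divergence)
        for p in rng.choice(repeat_length, size=n_mut, replace=False):
            alts = [b for b in "ACGT" if b != copy[p]]
            copy[p] = alts[rng.integers(0, 3)]
        sequences[chrom][start : start + repeat_length] = copy
        strand = "+" if rng.random() < 0.5 else "-"
        repeats.append(
            RepeatRecord(
                GenomicInterval(chrom, start, start + repeat_length, strand),
                fam,
                family_group_map[fam],
                f"{fam}#{idx}",
            )
        )
    return GenomeBundle(
        {c: "".join(s) for c, s in sequences.items()},
        repeats,
        genes,
        family_group_map,
    )


# ---------------------------------------------------------------------------
# tissue panel


@dataclass
class PanelTruth:
    kind: dict[str, str]  # family -> "housekeeping" | "restricted"
    restricted_tissues: dict[str, frozenset[str]]
    means: dict[str, dict[str, float]]  # family -> tissue -> planted mean
    sigma: float
    ratio: float
    sample_to_tissue: dict[str, str]


def make_tissue_panel(
    n_tissues: int = 32,
    n_families: int = 200,
    n_restricted: int = 20,
    samples_per_tissue: int = 5,
    seed: int = 0,
    ratio: float = 20.0,
    sigma: float = 0.15,
) -> tuple[ExpressionTable, PanelTruth]:
    """Family x sample TPM panel with planted specificity structure.

    Housekeeping families share one mean across tissues; restricted
    families overexpress ``ratio``-fold in one or two tissues.  Noise
    is multiplicative lognormal (``sigma``), and each sample column is
    renormalized to sum to 1e6 (TPM closure).
    """
    if n_restricted > n_families:
        raise ValueError("n_restricted exceeds n_families")
    if samples_per_tissue < 1:
        raise ValueError("samples_per_tissue must be >= 1")
    rng = np.random.default_rng(seed)
    tissues = [f"T{i + 1:02d}" for i in range(n_tissues)]
    families = [f"FAM{i + 1:04d}" for i in range(n_families)]
    restricted = list(rng.choice(families, size=n_restricted, replace=False))
    kind = {
        f: ("restricted" if f in restricted else "housekeeping") for f in families
    }
    restricted_tissues: dict[str, frozenset[str]] = {}
    means: dict[str, dict[str, float]] = {}
    for fam in families:
        if kind[fam] == "restricted":
            n_over = 1 if rng.random() < 0.7 else 2
            over = frozenset(rng.choice(tissues, size=n_over, replace=False))
            restricted_tissues[fam] = over
            low = float(rng.uniform(1.0, 3.0))
            means[fam] = {
                t: (low * ratio if t in over else low) for t in tissues
            }
        else:
            base = float(np.exp(rng.normal(np.log(20.0), 0.8)))
            means[fam] = {t: base for t in tissues}
    samples = [f"{t}_s{k + 1}" for t in tissues for k in range(samples_per_tissue)]
    sample_to_tissue = {s: s.split("_")[0] for s in samples}
    data = np.empty((n_families, len(samples)))
    for i, fam in enumerate(families):
        for j, s in enumerate(samples):
            mu = means[fam][sample_to_tissue[s]]
            data[i, j] = mu * np.exp(rng.normal(0.0, sigma))
    data = data / data.sum(axis=0, keepdims=True) * 1e6
    table = ExpressionTable(
        pd.DataFrame(data, index=families, columns=samples), unit="TPM"
    )
    return table, PanelTruth(
        kind, restricted_tissues, means, sigma, ratio, sample_to_tissue
    )


# ---------------------------------------------------------------------------
# B-LCL-like read set


@dataclass
class PlantedPeptide:
    peptide: str
    mcs: str
    intended_verdict: str  # eremap | canonical | ambiguous-keep |
    #                        ambiguous-discard | discard
    reason: str  # branch label (e.g. "intronic-sense", "one-read")
    region_class: str | None
    orientation_vs_ere: str | None
    orientation_vs_gene: str | None
    family: str | None
    group: str | None
    n_ere_reads: int
    n_canonical_reads: int
    mcs_loci: list[GenomicInterval] = field(default_factory=list)


@dataclass
class ReadSetTruth:
    planted: list[PlantedPeptide]
    sample: str

    def by_verdict(self, verdict: str) -> list[PlantedPeptide]:
        return [p for p in self.planted if p.intended_verdict == verdict]


@dataclass
class ReadSetBundle:
    genome: GenomeBundle  # sequences reflect the planted cassettes
    reads: list[AlignedRead]  # SAM-equivalent alignment records
    fastq_r1: list[tuple[str, str]]
    fastq_r2: list[tuple[str, str]]
    candidates: list[PeptideCandidate]
    transcripts: dict[str, str]
    cds_start: dict[str, int]
    transcript_expression: ExpressionTable
    truth: ReadSetTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome.sequences, outdir / "genome.fa")
        write_fasta(self.transcripts, outdir / "transcripts.fa")
        write_repeatmasker_out(self.genome.repeats, outdir / "repeats.out")
        write_gtf(self.genome.genes, outdir / "genes.gtf")
        write_sam_min(self.reads, outdir / "alignments.sam", self.genome.chrom_sizes())
        write_fastq(self.fastq_r1, outdir / "reads_R1.fastq")
        write_fastq(self.fastq_r2, outdir / "reads_R2.fastq")
        write_psm_table(self.candidates, outdir / "psms.tsv")
        write_tsv_matrix(self.transcript_expression, outdir / "transcript_tpm.tsv")


def _repeat_context(
    repeat: RepeatRecord, genes: Sequence[GeneModel]
) -> str:
    iv = repeat.interval
    for g in genes:
        if g.span.chrom != iv.chrom:
            continue
        for e in g.exons:
            if e.overlaps(iv):
                return "exonic" if not e.contains(iv) else "exon-contained"
        for intron in g.introns():
            if intron.contains(iv):
                return "intronic"
    return "intergenic"


class _FragmentSampler:
    """Paired-end fragment generation with blocked intervals."""

    def __init__(
        self,
        sequences: Mapping[str, str],
        rng: np.random.Generator,
        read_len: int,
        frag_len: int,
    ):
        self.seq = sequences
        self.rng = rng
        self.read_len = read_len
        self.frag_len = frag_len
        self.blocked: dict[str, list[tuple[int, int]]] = {}
        self.reads: list[AlignedRead] = []
        self.r1: list[tuple[str, str]] = []
        self.r2: list[tuple[str, str]] = []
        self._n = 0

    def block(self, chrom: str, start: int, end: int) -> None:
        self.blocked.setdefault(chrom, []).append((start, end))

    def _is_blocked(self, chrom: str, start: int, end: int) -> bool:
        return any(
            start < b_end and b_start < end
            for b_start, b_end in self.blocked.get(chrom, [])
        )

    def emit_fragment(self, chrom: str, frag_start: int) -> None:
        """Emit one proper FR pair for the fragment at ``frag_start``."""
        rl, fl = self.read_len, self.frag_len
        self._n += 1
        name = f"frag{self._n:07d}"
        left_seq = self.seq[chrom][frag_start : frag_start + rl]
        right_ref = self.seq[chrom][frag_start + fl - rl : frag_start + fl]
        # R1 is the forward-left mate half the time (FLAGs 99/147),
        # otherwise the reverse-right mate (83/163)
        r1_left = self.rng.random() < 0.5
        left_flag, right_flag = (99, 147) if r1_left else (163, 83)
        left_id = f"{name}/{'1' if r1_left else '2'}"
        right_id = f"{name}/{'2' if r1_left else '1'}"
        self.reads.append(
            AlignedRead(
                left_id,
                left_seq,
                GenomicInterval(chrom, frag_start, frag_start + rl, "+"),
                left_flag,
            )
        )
        self.reads.append(
            AlignedRead(
                right_id,
                right_ref,
                GenomicInterval(chrom, frag_start + fl - rl, frag_start + fl, "-"),
                right_flag,
            )
        )
        left_fq = (left_id, left_seq)
        right_fq = (right_id, revcomp(right_ref))
        if r1_left:
            self.r1.append(left_fq)
            self.r2.append(right_fq)
        else:
            self.r1.append(right_fq)
            self.r2.append(left_fq)

    def emit_background(self, n_pairs: int) -> None:
        chroms = sorted(self.seq)
        lengths = np.array([len(self.seq[c]) for c in chroms], dtype=float)
        probs = lengths / lengths.sum()
        made = 0
        while made < n_pairs:
            chrom = chroms[self.rng.choice(len(chroms), p=probs)]
            start = int(self.rng.integers(0, len(self.seq[chrom]) - self.frag_len))
            if self._is_blocked(chrom, start, start + self.frag_len):
                continue
            self.emit_fragment(chrom, start)
            made += 1

    def emit_junk(self, n: int) -> None:
        """Reads that must fail alignment QC (exercise the flag filter)."""
        chroms = sorted(self.seq)
        junk_flags = [1187, 355, 77, 141, 3221, 99 | 0x200]
        for i in range(n):
            chrom = chroms[i % len(chroms)]
            start = int(self.rng.integers(0, len(self.seq[chrom]) - self.read_len))
            flag = junk_flags[i % len(junk_flags)]
            seq = (
                _random_seq(self.rng, self.read_len)
                if flag & 0x4
                else self.seq[chrom][start : start + self.read_len]
            )
            self.reads.append(
                AlignedRead(
                    f"junk{i:05d}/1",
                    seq,
                    None if flag & 0x4 else GenomicInterval(chrom, start, start + self.read_len, "+"),
                    flag,
                )
            )


def make_blcl_readset(
    genome_bundle: GenomeBundle,
    n_eremap: int = 30,
    n_canonical: int = 30,
    n_ambiguous: int = 12,
    n_one_read: int = 4,
    depth: int = 50_000,
    read_len: int = 100,
    frag_len: int = 180,
    seed: int = 0,
    sample: str = "BLCL01",
) -> ReadSetBundle:
    """Plant peptide-coding sequences with predetermined verdicts.

    The genome of ``genome_bundle`` is rewritten in place of selected
    repeat copies: each planted case gets a stop-free codon cassette
    carrying the peptide's coding sequence (MCS), read pairs covering
    it at a controlled count, and a PSM entry with a passing binding
    rank.  Cases:

    * ``n_eremap`` true ereMAPs spread over the keep branches of the
      orientation tree (intronic-sense, intergenic sense/antisense,
      intronic-antisense rescued by a second repeat locus);
    * orientation-discard plants (CDS-sense; intronic-antisense at a
      single locus);
    * ``n_canonical`` canonical peptides planted in-frame in gene CDS;
    * ``n_ambiguous`` both-proteome peptides whose ERE:canonical
      coverage ratios bracket the 10x arbitration rule;
    * ``n_one_read`` candidates supported by a single read;
    * one reversed-sequence decoy PSM per target (1:1).

    Background fragments fill the read set to ``depth`` pairs, blocked
    from overlapping any planted MCS so coverage ratios stay exact.
    """
    if read_len < 26:
        raise ValueError("read_len must be >= 26 (24-mers with margin)")
    rng = np.random.default_rng(seed)
    sequences = {c: list(s) for c, s in genome_bundle.sequences.items()}
    genes = genome_bundle.genes
    repeats = list(genome_bundle.repeats)

    by_context: dict[str, list[int]] = {"intronic": [], "intergenic": [], "exonic": []}
    for i, r in enumerate(repeats):
        ctx = _repeat_context(r, genes)
        if ctx in by_context:
            by_context[ctx].append(i)
    for ctx in by_context:
        by_context[ctx] = list(rng.permutation(by_context[ctx]))
    # genes untouched by straddling repeats, available for CDS planting
    free_genes = [
        g
        for g in genes
        if not any(
            repeats[i].interval.overlaps(e)
            for i in by_context["exonic"]
            for e in g.exons
        )
    ]
    free_genes = list(rng.permutation(np.array(free_genes, dtype=object)))

    planted: list[PlantedPeptide] = []
    used_peptides: set[str] = set()

    def new_peptide(length: int = 9) -> tuple[str, str]:
        while True:
            pep = _random_peptide(rng, length)
            if pep not in used_peptides:
                used_peptides.add(pep)
                return pep, _encode_peptide(rng, pep)

    def take_repeat(context: str, strand: str) -> RepeatRecord:
        idx = by_context[context].pop()
        rec = repeats[idx]
        if rec.interval.strand != strand:
            rec = replace(rec, interval=replace(rec.interval, strand=strand))
            repeats[idx] = rec
        return rec

    def write_cassette(rec: RepeatRecord, mcs: str, codon_offset: int = 60) -> int:
        """Rewrite a repeat with stop-free codons embedding the MCS.

        Returns the genomic start of the MCS.  The cassette frame is
        aligned to the repeat start so any read covering the MCS
        translates through it without an upstream stop.
        """
        iv = rec.interval
        n_codons = len(iv) // 3
        cassette = _random_sense_codons(rng, n_codons)
        mcs_at = codon_offset * 3
        cassette = cassette[:mcs_at] + mcs + cassette[mcs_at + len(mcs):]
        sequences[iv.chrom][iv.start : iv.start + len(cassette)] = list(cassette)
        return iv.start + mcs_at

    sampler = _FragmentSampler(
        {c: "" for c in sequences}, rng, read_len, frag_len
    )  # sequences injected after all cassettes are written

    pending_fragments: list[tuple[str, int]] = []

    def cover_with_fragments(
        chrom: str, mcs_start: int, mcs_len: int, n: int, max_delta: int | None = None
    ) -> None:
        """Queue n fragments whose forward-left read fully covers the MCS."""
        hi = max_delta if max_delta is not None else read_len - mcs_len - 5
        for _ in range(n):
            delta = int(rng.integers(10, hi + 1))
            pending_fragments.append((chrom, mcs_start - delta))

    candidates: list[PeptideCandidate] = []
    alleles = ("HLA_A0201", "HLA_B0702")

    def add_psm(pep: str, rank: float | None = None) -> None:
        r = float(rng.uniform(0.1, 1.9)) if rank is None else rank
        candidates.append(
            PeptideCandidate(
                peptide=pep,
                sample=sample,
                score=float(rng.uniform(60, 100)),
                is_decoy=False,
                binding_ranks={
                    alleles[0]: r,
                    alleles[1]: float(rng.uniform(2.5, 40.0)),
                },
            )
        )

    # -- true ereMAPs across the keep branches ------------------------------
    branch_plan: list[tuple[str, str, str]] = []
    n_intronic_sense = max(n_eremap - 10, 1)
    branch_plan += [("intronic", "+", "intronic-sense")] * n_intronic_sense
    rest = n_eremap - n_intronic_sense
    third = rest // 3
    branch_plan += [("intergenic", "+", "intergenic-sense")] * (rest - 2 * third)
    branch_plan += [("intergenic", "-", "intergenic-antisense")] * third
    branch_plan += [("intronic-multi", "-", "intronic-antisense-multilocus")] * third

    for context, strand, label in branch_plan:
        pep, mcs = new_peptide()
        if context == "intronic-multi":
            rec = take_repeat("intronic", strand)
            rec2 = take_repeat("intronic", strand)
            mcs_start = write_cassette(rec, mcs)
            mcs_start2 = write_cassette(rec2, mcs)
            loci = [
                GenomicInterval(rec.interval.chrom, mcs_start, mcs_start + len(mcs), "+"),
                GenomicInterval(rec2.interval.chrom, mcs_start2, mcs_start2 + len(mcs), "+"),
            ]
            region = "intronic"
            # annotation is attributed to the genomically first locus
            if (loci[1].chrom, loci[1].start) < (loci[0].chrom, loci[0].start):
                rec = rec2
        else:
            rec = take_repeat(context, strand)
            mcs_start = write_cassette(rec, mcs)
            loci = [
                GenomicInterval(rec.interval.chrom, mcs_start, mcs_start + len(mcs), "+")
            ]
            region = "intronic" if context == "intronic" else "intergenic"
        n_e = int(rng.integers(3, 9))
        cover_with_fragments(loci[0].chrom, loci[0].start, len(mcs), n_e)
        add_psm(pep)
        planted.append(
            PlantedPeptide(
                pep, mcs, "eremap", label, region,
                "sense" if strand == "+" else "antisense",
                "sense" if region == "intronic" else "n/a",
                rec.family, rec.group, n_e, 0, loci,
            )
        )

    # -- orientation-discard plants -----------------------------------------
    for _ in range(2):  # CDS-sense: repeat straddling an exon boundary
        pep, mcs = new_peptide()
        rec = take_repeat("exonic", "+")
        iv = rec.interval
        exon_start = iv.start + 200  # straddle layout from make_genome
        # cassette frame anchored at repeat start; 200 % 3 == 2 so the MCS
        # is out of the transcript frame and stays absent from the
        # canonical proteome
        n_codons = len(iv) // 3
        cassette = _random_sense_codons(rng, n_codons)
        mcs_at = ((exon_start + 21 - iv.start) // 3) * 3  # ~21 nt into the exon
        cassette = cassette[:mcs_at] + mcs + cassette[mcs_at + len(mcs):]
        sequences[iv.chrom][iv.start : iv.start + len(cassette)] = list(cassette)
        mcs_start = iv.start + mcs_at
        # reads must sit inside the repeat but straddle the exon start so
        # they stay out of the canonical (exon-contained) dataset
        n_e = int(rng.integers(3, 6))
        for _ in range(n_e):
            delta = int(rng.integers(mcs_start - exon_start + 2, read_len - len(mcs) - 2))
            pending_fragments.append((iv.chrom, mcs_start - delta))
        add_psm(pep)
        planted.append(
            PlantedPeptide(
                pep, mcs, "discard", "cds-sense", "CDS", "sense", "sense",
                rec.family, rec.group, n_e, 0,
                [GenomicInterval(iv.chrom, mcs_start, mcs_start + len(mcs), "+")],
            )
        )

    for _ in range(2):  # intronic, antisense to the repeat, single locus
        pep, mcs = new_peptide()
        rec = take_repeat("intronic", "-")
        mcs_start = write_cassette(rec, mcs)
        n_e = int(rng.integers(3, 6))
        cover_with_fragments(rec.interval.chrom, mcs_start, len(mcs), n_e)
        add_psm(pep)
        planted.append(
            PlantedPeptide(
                pep, mcs, "discard", "intronic-antisense-single", "intronic",
                "antisense", "sense", rec.family, rec.group, n_e, 0,
                [GenomicInterval(rec.interval.chrom, mcs_start, mcs_start + len(mcs), "+")],
            )
        )

    # -- one-read cases ------------------------------------------------------
    for _ in range(n_one_read):
        pep, mcs = new_peptide()
        rec = take_repeat("intronic", "+")
        mcs_start = write_cassette(rec, mcs)
        cover_with_fragments(rec.interval.chrom, mcs_start, len(mcs), 1)
        add_psm(pep)
        planted.append(
            PlantedPeptide(
                pep, mcs, "discard", "one-read", "intronic", "sense", "sense",
                rec.family, rec.group, 1, 0,
                [GenomicInterval(rec.interval.chrom, mcs_start, mcs_start + len(mcs), "+")],
            )
        )

    # -- canonical peptides in gene CDS --------------------------------------
    gene_iter = iter(free_genes)

    def plant_in_exon(gene: GeneModel, mcs: str, n_reads: int) -> GenomicInterval:
        """In-frame substitution into the middle exon; queue covering reads."""
        e2 = gene.exons[1]
        at = e2.start + 300  # codon-aligned: exons are frame-aligned multiples of 3
        sequences[e2.chrom][at : at + len(mcs)] = list(mcs)
        if n_reads:
            # fragments fully inside the exon -> canonical dataset
            for _ in range(n_reads):
                delta = int(rng.integers(10, min(read_len - len(mcs) - 5, 79 - len(mcs)) + 1))
                pending_fragments.append((e2.chrom, at - delta))
        return GenomicInterval(e2.chrom, at, at + len(mcs), "+")

    for _ in range(n_canonical):
        pep, mcs = new_peptide()
        gene = next(gene_iter)
        n_c = int(rng.integers(2, 6))
        locus = plant_in_exon(gene, mcs, n_c)
        add_psm(pep)
        planted.append(
            PlantedPeptide(
                pep, mcs, "canonical", "canonical-cds", "CDS", None, "sense",
                None, None, 0, n_c, [locus],
            )
        )

    # -- ambiguous cases bracketing the 10x rule ------------------------------
    n_keep = n_ambiguous // 2
    keep_ratios = [(40, 4), (30, 3), (20, 2), (50, 5), (25, 2), (10, 1)]
    discard_ratios = [(9, 1), (19, 2), (5, 1), (9, 1), (29, 3), (9, 1)]
    amb_plan = [("ambiguous-keep", r) for r in keep_ratios[:n_keep]]
    amb_plan += [("ambiguous-discard", r) for r in discard_ratios[: n_ambiguous - n_keep]]
    for verdict, (n_e, n_c) in amb_plan:
        pep, mcs = new_peptide()
        rec = take_repeat("intergenic", "+")
        mcs_start = write_cassette(rec, mcs)
        gene = next(gene_iter)
        exon_locus = plant_in_exon(gene, mcs, n_c)
        # cap delta so the right-hand mate never overlaps the MCS: the
        # ERE-side minimal k-mer count must equal the fragment count
        cover_with_fragments(
            rec.interval.chrom, mcs_start, len(mcs), n_e,
            max_delta=frag_len - read_len - len(mcs),
        )
        add_psm(pep)
        planted.append(
            PlantedPeptide(
                pep, mcs, verdict, f"ratio-{n_e}:{n_c}", "intergenic", "sense",
                "n/a", rec.family, rec.group, n_e, n_c,
                [
                    GenomicInterval(rec.interval.chrom, mcs_start, mcs_start + len(mcs), "+"),
                    exon_locus,
                ],
            )
        )

    # -- decoys (1:1) and filler PSMs ----------------------------------------
    n_targets = len(candidates)
    for i in range(8):  # low-scoring fillers around the decoy score range
        pep = _random_peptide(rng, 9)
        candidates.append(
            PeptideCandidate(
                pep, sample, float(rng.uniform(10, 40)), False,
                {alleles[0]: float(rng.uniform(0.1, 1.9) if i % 2 else rng.uniform(3, 30))},
            )
        )
    for c in list(candidates):
        if not c.is_decoy:
            candidates.append(
                PeptideCandidate(
                    c.peptide[::-1], sample, float(rng.uniform(5, 45)), True,
                    dict(c.binding_ranks),
                )
            )

    # -- materialize reads -----------------------------------------------------
    final_sequences = {c: "".join(s) for c, s in sequences.items()}
    sampler.seq = final_sequences
    for p in planted:
        for locus in p.mcs_loci:
            sampler.block(locus.chrom, locus.start, locus.end)
    for chrom, start in pending_fragments:
        sampler.emit_fragment(chrom, start)
    n_background = max(depth - len(pending_fragments), 0)
    sampler.emit_background(n_background)
    sampler.emit_junk(120)

    genome = GenomeBundle(
        final_sequences, repeats, genes, genome_bundle.family_group_map
    )
    transcripts, cds_start = genome.transcripts()
    tpm = {tid: float(rng.uniform(5, 50)) for tid in transcripts}
    # a couple of silent transcripts exercise the TPM > 0 exclusion
    for tid in sorted(tpm)[-2:]:
        used = {g.transcript_ids[0] for g in free_genes[: len(planted)]}
        if tid not in used:
            tpm[tid] = 0.0
    expr = ExpressionTable(
        pd.DataFrame({sample: pd.Series(tpm)}), unit="TPM"
    )
    return ReadSetBundle(
        genome=genome,
        reads=sampler.reads,
        fastq_r1=sampler.r1,
        fastq_r2=sampler.r2,
        candidates=candidates,
        transcripts=transcripts,
        cds_start=cds_start,
        transcript_expression=expr,
        truth=ReadSetTruth(planted, sample),
    )


# ---------------------------------------------------------------------------
# methylation


def make_methylation(
    eremap_positions: Sequence[tuple[str, int, int]],
    rphm_vector: Mapping[str, float],
    rho: float,
    window: int = 5000,
    seed: int = 0,
    n_probes_in: int = 3,
    n_probes_out: int = 2,
) -> pd.DataFrame:
    """Probe table with betas correlated to rphm at target ``rho``.

    In-window probe betas are a linear blend of the standardized rphm
    vector and Gaussian noise mapped linearly into (0, 1) — linear so
    that ``rho = 1`` with no noise gives an exact downstream Pearson r
    of 1.  Out-of-window probes (distance > ``window``) carry
    independent noise.
    """
    if not (-1 <= rho <= 1):
        raise ValueError("rho must lie in [-1, 1]")
    samples = sorted(rphm_vector)
    if len(samples) < 3:
        raise ValueError("need >= 3 samples for a defined correlation")
    rng = np.random.default_rng(seed)
    x = np.array([rphm_vector[s] for s in samples], dtype=float)
    sd = x.std()
    zx = (x - x.mean()) / (sd if sd > 0 else 1.0)
    rows = []
    pid = 0
    for chrom, start, end in eremap_positions:
        offsets_in = [int(rng.integers(-window, window)) for _ in range(n_probes_in)]
        offsets_out = [
            int(s * (window + 1 + rng.integers(0, 3000)))
            for s, _ in zip([-1, 1] * n_probes_out, range(n_probes_out))
        ]
        for off in offsets_in + offsets_out:
            pid += 1
            pos = (start if off < 0 else end - 1) + off
            if pos < 0:
                # mirror upstream probes that would fall off the contig,
                # preserving their distance class
                pos = end - 1 - off
            inside = abs(off) <= window
            if inside and abs(rho) > 0:
                noise = rng.normal(size=len(samples))
                y = rho * zx + np.sqrt(1 - rho**2) * noise
            else:
                y = rng.normal(size=len(samples))
            lo, hi = y.min(), y.max()
            beta = (y - lo) / (hi - lo) * 0.9 + 0.05 if hi > lo else np.full_like(y, 0.5)
            row = {"probe_id": f"cg{pid:06d}", "chrom": chrom, "pos": max(pos, 0)}
            row.update(dict(zip(samples, beta)))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PSM score calibration sets


def make_psm_scores(
    n_true: int = 4000,
    n_null: int = 3000,
    seed: int = 0,
    mu_true: float = 10.0,
    mu_null: float = 5.0,
    sd: float = 2.0,
    sample: str = "S1",
) -> tuple[list[PeptideCandidate], set[str]]:
    """Scored PSMs with known true/false-target labels.

    ``n_true`` correct targets score around ``mu_true``; ``n_null``
    incorrect targets and an equal number of decoys share the null
    distribution around ``mu_null`` — with matched null/decoy counts
    the target-decoy ratio is an unbiased estimate of the false
    discovery proportion.  Returns (candidates, ids of true targets);
    peptides are tagged through their sequence for truth lookup.
    """
    rng = np.random.default_rng(seed)
    candidates = []
    true_ids = set()
    for i in range(n_true):
        pep = f"T{i:06d}"
        pep_aa = _random_peptide(rng, 9)
        candidates.append(
            PeptideCandidate(pep_aa, sample, float(rng.normal(mu_true, sd)), False)
        )
        true_ids.add(pep_aa)
    for _ in range(n_null):
        candidates.append(
            PeptideCandidate(
                _random_peptide(rng, 9), sample, float(rng.normal(mu_null, sd)), False
            )
        )
    for _ in range(n_null):
        candidates.append(
            PeptideCandidate(
                _random_peptide(rng, 9), sample, float(rng.normal(mu_null, sd)), True
            )
        )
    return candidates, true_ids
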