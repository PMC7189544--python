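"""Read QC, partitioning, six-frame proteome construction."""

import re

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from eremap.io_formats import (
    AlignedRead,
    GeneModel,
    GenomicInterval,
    RepeatRecord,
)
from eremap.proteogenomics import (
    CombinedProteome,
    build_ere_proteome,
    build_personalized_proteome,
    concat_proteomes,
    filter_alignments,
    partition_reads,
    passes_qc,
    revcomp,
    segment_ambiguous,
    six_frame_translate,
    splice_at_stops,
    translate,
)


def _read(flag, chrom="chr1", start=100, seq="ACGT" * 19):
    iv = None if flag & 0x4 else GenomicInterval(chrom, start, start + len(seq))
    return AlignedRead(f"r{flag}_{chrom}_{start}", seq, iv, flag)


class TestFilterAlignments:
    def test_accepts_exactly_the_four_proper_fr_flags(self):
        # oracle: accepted iff flag is one of 163/147/99/83 over the
        # pairing bits and intersects nothing of the 3852 exclusion mask
        for flag in range(4096):
            expected = (flag & 3852) == 0 and (flag & ~3852) in (99, 147, 163, 83)
            assert passes_qc(_read(flag)) == expected, flag

    def test_secondary_and_duplicate_removed(self):
        reads = [_read(99), _read(99 | 0x100), _read(147 | 0x400), _read(83)]
        kept = filter_alignments(reads)
        assert [r.flag for r in kept] == [99, 83]


def _repeat(chrom, start, end, family="FAM1", group="LINE", strand="+"):
    return RepeatRecord(
        GenomicInterval(chrom, start, end, strand), family, group, f"{family}@{start}"
    )


def _gene(chrom, exons, gid="g1"):
    ivs = tuple(GenomicInterval(chrom, s, e, "+") for s, e in exons)
    return GeneModel(gid, (f"{gid}.t1",), ivs, ivs, "+")


class TestPartitionReads:
    def test_containment_rules(self):
        repeats = [_repeat("chr1", 99, 300)]
        genes = [_gene("chr1", [(1000, 1500)])]
        inside_repeat = _read(99, start=100, seq="A" * 76)
        inside_exon = _read(99, start=1100, seq="A" * 76)
        straddling = _read(99, start=250, seq="A" * 76)  # half out of the repeat
        nowhere = _read(99, start=5000, seq="A" * 76)
        part = partition_reads(
            [inside_repeat, inside_exon, straddling, nowhere], repeats, genes
        )
        assert part.ere_reads == [inside_repeat]
        assert part.canonical_reads == [inside_exon]
        reasons = {r.read_id: why for r, why in part.discarded}
        assert straddling.read_id in reasons and nowhere.read_id in reasons

    def test_read_in_both_goes_canonical_only(self):
        repeats = [_repeat("chr1", 1000, 1600)]
        genes = [_gene("chr1", [(900, 1700)])]
        read = _read(99, start=1100, seq="A" * 76)
        part = partition_reads([read], repeats, genes)
        assert part.canonical_reads == [read] and part.ere_reads == []

    def test_unannotated_contig_discarded_not_error(self):
        part = partition_reads(
            [_read(99, chrom="chrUn", start=10, seq="A" * 50)],
            [_repeat("chr1", 0, 100)],
            [],
        )
        assert len(part.discarded) == 1

    def test_sets_disjoint_and_complete(self, pipeline_run):
        part = pipeline_run["partition"]
        ere = {r.read_id for r in part.ere_reads}
        can = {r.read_id for r in part.canonical_reads}
        assert not ere & can
        total = len(part.ere_reads) + len(part.canonical_reads) + len(part.discarded)
        filtered = filter_alignments(pipeline_run["bundle"].reads)
        assert total == len(filtered)


class TestSegmentAmbiguous:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACGTNNACGT", [("ACGT", 0), ("ACGT", 6)]),
            ("ACGT", [("ACGT", 0)]),
            ("NNNN", []),
            ("NACGTN", [("ACGT", 1)]),
        ],
    )
    def test_cases(self, seq, expected):
        assert segment_ambiguous(seq) == expected


class TestSixFrameTranslate:
    def test_forward_frame(self):
        assert six_frame_translate("ATGAAA")[0] == "MK"

    def test_reverse_complement_frame(self):
        assert six_frame_translate("TTTCAT")[3] == "MK"  # revcomp = ATGAAA

    def test_matches_biopython_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(3, 120))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
            frames = six_frame_translate(seq)
            rc = str(Seq(seq).reverse_complement())
            for f in range(3):
                for src, got in ((seq, frames[f]), (rc, frames[3 + f])):
                    sub = src[f:]
                    sub = sub[: len(sub) - len(sub) % 3]
                    assert got == str(Seq(sub).translate())

    def test_short_sequence_empty(self):
        assert six_frame_translate("AC") == []


class TestSpliceAtStops:
    def test_prefix_mode(self):
        assert splice_at_stops("MKLVQWERT*AAA") == ["MKLVQWERT"]
        assert splice_at_stops("MKL*VQWERTAAA") == []  # prefix too short
        assert splice_at_stops("MKLVQWER") == ["MKLVQWER"]  # exactly 8, no stop

    def test_split_mode_keeps_all_long_segments(self):
        got = splice_at_stops("MKLVQWERT*SHORTAAA*KLMNPQRSTV", mode="split")
        assert got == ["MKLVQWERT", "SHORTAAA", "KLMNPQRSTV"]

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError):
            splice_at_stops("MKLVQWERT", mode="bogus")


def _oracle_proteome_pieces(sequence, min_len=8):
    """Independent pipeline re-implementation on Biopython primitives."""
    pieces = []
    for segment in re.split("N+", sequence):
        if len(segment) < 3:
            continue
        rc = str(Seq(segment).reverse_complement())
        for src in (segment, rc):
            for f in range(3):
                sub = src[f:]
                sub = sub[: len(sub) - len(sub) % 3]
                aa = str(Seq(sub).translate())
                prefix = aa.split("*", 1)[0]
                if len(prefix) >= min_len:
                    pieces.append(prefix)
    return pieces


class TestBuildEreProteome:
    def test_frame_bound_and_empty_input(self):
        read = _read(99, seq="ACGT" * 19)
        assert len(build_ere_proteome([read])) <= 6
        assert build_ere_proteome([]) == []

    def test_matches_independent_oracle_on_random_reads(self):
        rng = np.random.default_rng(1)
        reads = []
        for i in range(1000):
            n = int(rng.integers(40, 130))
            chars = list("ACGT"[j] for j in rng.integers(0, 4, size=n))
            for p in rng.integers(0, n, size=max(1, n // 100)):
                if rng.random() < 0.3:
                    chars[p] = "N"
            reads.append(
                AlignedRead(f"r{i}", "".join(chars), GenomicInterval("c", 0, n), 99)
            )
        entries = build_ere_proteome(reads)
        expected = []
        for r in reads:
            expected.extend(_oracle_proteome_pieces(r.sequence))
        assert sorted(e.aa_sequence for e in entries) == sorted(expected)

    def test_invariant_to_read_order(self):
        rng = np.random.default_rng(2)
        reads = [
            AlignedRead(
                f"r{i}",
                "".join("ACGT"[j] for j in rng.integers(0, 4, size=90)),
                GenomicInterval("c", 0, 90),
                99,
            )
            for i in range(50)
        ]
        fwd = build_ere_proteome(reads)
        rev = build_ere_proteome(reads[::-1])
        key = lambda e: (e.provenance, e.aa_sequence)
        assert sorted((e.provenance, e.aa_sequence) for e in fwd) == sorted(
            (e.provenance, e.aa_sequence) for e in rev
        )

    def test_duplicate_sequences_keep_distinct_provenance(self):
        seq = "ATGGCTGCTGCTGCTGCTGCTGCTGCT"  # MAAAAAAAA in frame +1
        reads = [
            AlignedRead("r1", seq, GenomicInterval("c", 0, len(seq)), 99),
            AlignedRead("r2", seq, GenomicInterval("c", 50, 50 + len(seq)), 99),
        ]
        entries = build_ere_proteome(reads)
        dupes = [e for e in entries if e.aa_sequence == "MAAAAAAAA"]
        assert len(dupes) == 2
        assert dupes[0].provenance != dupes[1].provenance


class TestPersonalizedProteome:
    TX = {"t1": "ATG" + "GCT" * 10 + "TAA", "t2": "ATG" + "TGT" * 10 + "TAA"}

    def test_tpm_zero_excluded(self):
        entries = build_personalized_proteome(
            self.TX, None, {"t1": 5.0, "t2": 0.0}
        )
        assert [e.entry_id for e in entries] == ["can_t1"]
        assert entries[0].aa_sequence == "M" + "A" * 10

    def test_variant_threshold_and_application(self):
        variants = pd.DataFrame(
            [
                {"transcript_id": "t1", "position": 5, "ref": "C", "alt": "A",
                 "alt_count": 5},
                {"transcript_id": "t2", "position": 5, "ref": "G", "alt": "A",
                 "alt_count": 4},  # below threshold: ignored
            ]
        )
        entries = build_personalized_proteome(
            self.TX, variants, {"t1": 1.0, "t2": 1.0}
        )
        by_id = {e.entry_id: e for e in entries}
        assert by_id["can_t1"].aa_sequence == "MD" + "A" * 9  # GCT->GAT at codon 2
        assert by_id["can_t2"].aa_sequence == "M" + "C" * 10  # unchanged

    def test_synonymous_variant_leaves_protein(self):
        variants = pd.DataFrame(
            [{"transcript_id": "t1", "position": 6, "ref": "T", "alt": "C",
              "alt_count": 10}]
        )  # GCT -> GCC, still Ala
        entries = build_personalized_proteome(self.TX, variants, {"t1": 1.0})
        assert entries[0].aa_sequence == "M" + "A" * 10

    def test_ref_mismatch_names_position(self):
        variants = pd.DataFrame(
            [{"transcript_id": "t1", "position": 5, "ref": "G", "alt": "A",
              "alt_count": 9}]
        )
        with pytest.raises(ValueError, match="t1.*position 5"):
            build_personalized_proteome(self.TX, variants, {"t1": 1.0})


class TestCombinedProteome:
    def _proteome(self):
        ere = build_ere_proteome(
            [
                AlignedRead(
                    "r1",
                    "ATGGATGATCATAAAGAAAATCGTTGG",  # MDDHKENRW
                    GenomicInterval("c", 0, 27),
                    99,
                )
            ]
        )
        can = build_personalized_proteome(
            {"t1": "ATG" + "CCT" * 12 + "TAA"}, None, {"t1": 3.0}
        )
        return concat_proteomes(ere, can)

    def test_membership_by_source(self):
        prot = self._proteome()
        assert prot.membership("MDDHKENR") == (True, False)
        assert prot.membership("PPPPPPPP") == (False, True)
        assert prot.membership("WWWWWWWW") == (False, False)

    def test_membership_matches_naive_scan(self, pipeline_run):
        prot = pipeline_run["proteome"]
        rng = np.random.default_rng(3)
        entries = prot.entries
        queries = []
        for _ in range(250):
            e = entries[rng.integers(0, len(entries))]
            if len(e.aa_sequence) >= 9:
                s = rng.integers(0, len(e.aa_sequence) - 8)
                queries.append(e.aa_sequence[s : s + 9])
        queries += ["W" * 9, "ADHKW" + "PQR"]
        for q in queries:
            naive_ere = any(
                q in e.aa_sequence for e in entries if e.source == "ere-read"
            )
            naive_can = any(
                q in e.aa_sequence
                for e in entries
                if e.source == "canonical-transcript"
            )
            assert prot.membership(q) == (naive_ere, naive_can)

    def test_id_collision_errors(self):
        ere = build_ere_proteome(
            [AlignedRead("r1", "ATG" + "GCA" * 9, GenomicInterval("c", 0, 30), 99)]
        )
        with pytest.raises(ValueError, match="collision"):
            CombinedProteome(list(ere) + list(ere))


def test_translate_and_revcomp_helpers():
    assert translate("ATGAAATAG") == "MK*"
    assert revcomp("ACGTN") == "NACGT"
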