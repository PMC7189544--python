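"""The ereMAP filter cascade: FDR, binders, k-mer arbitration, orientation."""

from collections import Counter

import numpy as np
import pytest

from eremap.eremap_validation import (
    aggregate_nonredundant,
    apply_fdr,
    assign_status,
    build_kmer_table,
    canonical_kmer,
    characterize_cohort,
    classify_origin,
    filter_binders,
    il_variant_check,
    il_variants,
    mcs_min_occurrence,
    orientation_decision,
    recover_mcs,
    resolve_maybe,
)
from eremap.io_formats import (
    AlignedRead,
    GeneModel,
    GenomicInterval,
    PeptideCandidate,
    RepeatRecord,
)
from eremap.proteogenomics import (
    build_ere_proteome,
    build_personalized_proteome,
    concat_proteomes,
    revcomp,
)


def _cand(peptide="ADHKNPQRT", score=10.0, decoy=False, ranks=None, sample="s1"):
    return PeptideCandidate(
        peptide, sample, score, decoy,
        ranks if ranks is not None else {"A0201": 0.5},
    )


class TestApplyFdr:
    def test_separated_scores_all_targets_pass(self):
        cands = [_cand(score=s) for s in (10, 9, 8, 7)] + [
            _cand(score=s, decoy=True) for s in (6, 5)
        ]
        passed = apply_fdr(cands, q=0.05)
        assert len(passed) == 4
        assert all(not c.is_decoy for c in passed)

    def test_dominant_decoy_empties_the_pass_set(self):
        cands = [_cand(score=float(s)) for s in range(10)]
        cands.append(_cand(score=100.0, decoy=True))
        assert apply_fdr(cands, q=0.05) == []

    def test_q_one_passes_all_targets(self):
        cands = [_cand(score=1.0), _cand(score=0.5, decoy=True)]
        assert len(apply_fdr(cands, q=1.0)) == 1

    def test_threshold_is_minimal_admitting_score(self):
        # enumeration: at t=4 ratio 1/5 > 0.1; at t=5 ratio 0/4 = 0 <= 0.1
        cands = [_cand(score=float(s)) for s in (9, 8, 7, 6, 4)]
        cands.append(_cand(score=4.5, decoy=True))
        passed = apply_fdr(cands, q=0.1)
        assert sorted(c.score for c in passed) == [6, 7, 8, 9]

    def test_no_decoys_errors(self):
        with pytest.raises(ValueError, match="decoy"):
            apply_fdr([_cand()], q=0.05)


class TestFilterBinders:
    def test_length_and_rank_rules(self):
        keep_9mer = _cand("ADHKNPQRT", ranks={"A": 0.5})
        at_bound = _cand("ADHKNPQRT", ranks={"A": 2.0})  # inclusive
        weak = _cand("ADHKNPQRT", ranks={"A": 2.01})
        too_long = _cand("ADHKNPQRTADHK", ranks={"A": 0.1})  # 13-mer
        too_short = _cand("ADHKNPQ", ranks={"A": 0.1})  # 7-mer
        out = filter_binders([keep_9mer, at_bound, weak, too_long, too_short])
        assert out == [keep_9mer, at_bound]

    def test_min_over_available_alleles(self):
        c = _cand(ranks={"A": 9.0, "B": 1.5})
        assert filter_binders([c]) == [c]


class TestKmerTable:
    def test_canonical_merges_reverse_complement(self):
        table = build_kmer_table(["A" * 24, "T" * 24], k=24)
        assert table.counts == {"A" * 24: 2}
        assert table.get("T" * 24) == 2

    def test_window_count_per_read(self):
        table = build_kmer_table(["ACGTACGTACGTACGTACGTACGTACGT"], k=24)  # L=28
        assert table.total_words == 5  # L - k + 1

    def test_n_windows_skipped(self):
        seq = "A" * 23 + "N" + "A" * 23
        assert build_kmer_table([seq], k=24).total_words == 0

    def test_matches_naive_oracle_on_random_reads(self):
        rng = np.random.default_rng(0)
        reads = []
        for _ in range(400):
            chars = ["ACGTN"[min(i, 3)] for i in rng.integers(0, 30, size=60)]
            reads.append("".join("N" if rng.random() < 0.01 else c for c in chars))
        k = 24
        naive = Counter()
        for seq in reads:
            for i in range(len(seq) - k + 1):
                w = seq[i : i + k]
                if "N" in w:
                    continue
                naive[min(w, revcomp(w))] += 1
        table = build_kmer_table(reads, k=k)
        assert table.counts == dict(naive)
        assert table.total_words == sum(naive.values())

    def test_min_occurrence(self):
        mcs = "GATCACAAAGAACGTACCGATCACAAA"  # 27 nt, 4 distinct windows
        table = build_kmer_table([mcs, mcs[:26]], k=24)
        # the last window is covered once, the first three twice
        assert mcs_min_occurrence(mcs, table) == 1
        assert mcs_min_occurrence(mcs[:26], table) == 2
        with pytest.raises(ValueError):
            mcs_min_occurrence("A" * 20, table)

    def test_canonical_kmer_involution(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            w = "".join("ACGT"[i] for i in rng.integers(0, 4, size=24))
            c = canonical_kmer(w)
            assert c == canonical_kmer(revcomp(w)) == canonical_kmer(c)
            assert c <= revcomp(c)


class TestAssignStatus:
    def _proteome(self):
        # ERE proteome holds ADHKNPQRT; canonical holds poly-P and ADHKNPQRT
        ere = build_ere_proteome(
            [
                AlignedRead(
                    "r1", "GCTGATCATAAAAATCCTCAACGTACT",
                    GenomicInterval("c", 0, 27), 99,
                )
            ]
        )
        can = build_personalized_proteome(
            {"t1": "ATG" + "CCT" * 12 + "TAA",
             "t2": "ATGGCTGATCATAAAAATCCTCAACGTACTTAA"},
            None, {"t1": 1.0, "t2": 1.0},
        )
        return ere, can

    def test_yes_maybe_no_undetermined(self):
        ere, can = self._proteome()
        both = concat_proteomes(ere, can)
        cases = {
            "ADHKNPQRT": "maybe",  # in both proteomes
            "PPPPPPPP": "no",  # canonical only
            "WWWWWWWW": "undetermined",  # in neither
        }
        for pep, expected in cases.items():
            cand = _cand(pep)
            assert assign_status(cand, both) == expected
            assert cand.status == expected
        ere_only = concat_proteomes(ere, can[:1])
        cand = _cand("ADHKNPQRT")
        assert assign_status(cand, ere_only) == "yes"


def _mcs_candidate(n_reads, mcs="GATCACAAAGAACGTACCGATCACAAA"):
    c = _cand()
    c.status = "maybe"
    c.mcs_set = [(mcs, n_reads)]
    return c, mcs


class TestResolveMaybe:
    def _tables(self, min_ere, min_can, mcs):
        ere = build_kmer_table([mcs] * min_ere, k=24) if min_ere else build_kmer_table([], k=24)
        can = build_kmer_table([mcs] * min_can, k=24) if min_can else build_kmer_table([], k=24)
        return ere, can

    @pytest.mark.parametrize(
        "min_ere,min_can,kept",
        [(50, 4, True), (40, 4, True), (9, 1, False), (10, 1, True), (39, 4, False)],
    )
    def test_ten_x_rule(self, min_ere, min_can, kept):
        cand, mcs = _mcs_candidate(n_reads=min_ere)
        ere, can = self._tables(min_ere, min_can, mcs)
        assert resolve_maybe(cand, ere, can) is kept

    def test_single_read_support_discarded(self):
        cand, mcs = _mcs_candidate(n_reads=1)
        ere, can = self._tables(50, 0, mcs)
        assert resolve_maybe(cand, ere, can) is False
        assert "read" in cand.verdict_trail[-1][1]

    def test_canonical_only_mcs_discards(self):
        cand, mcs = _mcs_candidate(n_reads=5)
        ere, can = self._tables(0, 3, mcs)
        assert resolve_maybe(cand, ere, can) is False
        assert "canonical" in cand.verdict_trail[-1][1]

    def test_monotone_in_ere_support(self):
        mcs = "GATCACAAAGAACGTACCGATCACAAA"
        kept_at = None
        for min_ere in range(1, 60, 3):
            cand, _ = _mcs_candidate(n_reads=max(min_ere, 2), mcs=mcs)
            ere, can = self._tables(min_ere, 3, mcs)
            kept = resolve_maybe(cand, ere, can)
            if kept_at is not None:
                assert kept  # once kept, more ERE support never flips it
            if kept:
                kept_at = min_ere


class TestIlVariants:
    def test_enumeration(self):
        assert set(il_variants("AIA")) == {"ALA"}
        assert set(il_variants("IL")) == {"II", "LL", "LI"}
        assert il_variants("ADHK") == []

    def test_higher_expressed_variant_discards(self):
        # canonical transcript carries the L-variant at high TPM
        can = build_personalized_proteome(
            {"t1": "ATG" + "AAT CTT GTT CCT ATG GTT GCT ACT GTT".replace(" ", "") + "TAA"},
            None,
            {"t1": 50.0},
        )  # encodes MNLVPMVATV
        prot = concat_proteomes([], can)
        cand = _cand("NIVPMVATV")
        assert il_variant_check(cand, prot, own_expression=3.0) is False

    def test_no_il_trivially_kept(self):
        prot = concat_proteomes([], [])
        cand = _cand("ADHKNPQRT")
        assert il_variant_check(cand, prot, own_expression=1.0) is True

    def test_lower_expressed_variant_keeps(self):
        ere = build_ere_proteome(
            [
                AlignedRead(
                    "r1",
                    "ATGAATCTTGTTCCTATGGTTGCTACTGTT",  # MNLVPMVATV
                    GenomicInterval("c", 0, 30),
                    99,
                )
            ]
        )
        prot = concat_proteomes(ere, [])
        cand = _cand("NIVPMVATV")
        # variant NLVPMVATV present in 1 ERE read; candidate supported by 3
        assert il_variant_check(cand, prot, own_expression=3.0) is True


class TestRecoverMcs:
    def test_finds_coding_windows_on_both_strands(self):
        mcs = "GCTGATCATAAAAATCCTCAACGTACT"  # ADHKNPQRT
        r1 = AlignedRead("a", "ACGTAC" + mcs + "GGTACG", GenomicInterval("c", 0, 39), 99)
        r2 = AlignedRead("b", revcomp("ACG" + mcs + "GG"), GenomicInterval("c", 0, 33), 147)
        out = recover_mcs("ADHKNPQRT", [r1, r2])
        assert out == [(mcs, 2)]

    def test_distinct_codings_counted_separately(self):
        mcs_a = "GCTGATCATAAAAATCCTCAACGTACT"
        mcs_b = "GCAGATCATAAAAATCCTCAACGTACT"  # synonymous first codon
        reads = [
            AlignedRead("a", mcs_a, GenomicInterval("c", 0, 27), 99),
            AlignedRead("b", mcs_b, GenomicInterval("c", 0, 27), 99),
            AlignedRead("c", mcs_b + "AAA", GenomicInterval("c", 0, 30), 99),
        ]
        out = recover_mcs("ADHKNPQRT", reads)
        assert out == [(mcs_b, 2), (mcs_a, 1)]


def _toy_locus():
    """chr 'c': gene at [100, 700) with exons [100,200)+[600,700),
    intron [200,600); repeats as declared per test."""
    exons = (
        GenomicInterval("c", 100, 200, "+"),
        GenomicInterval("c", 600, 700, "+"),
    )
    gene = GeneModel("g1", ("g1.t1",), exons, exons, "+")
    return gene


class TestClassifyOrigin:
    def _genome_with(self, mcs, at, size=1000):
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=size))
        return {"c": seq[:at] + mcs + seq[at + len(mcs):]}

    MCS = "GCTGATCATAAAAATCCTCAACGTACT"

    def test_intronic_sense(self):
        gene = _toy_locus()
        repeat = RepeatRecord(
            GenomicInterval("c", 250, 550, "+"), "FAM1", "LTR", "FAM1#1"
        )
        genome = self._genome_with(self.MCS, 300)
        call = classify_origin(self.MCS, [repeat], [gene], genome)
        assert (call.region_class, call.orientation_vs_ere) == ("intronic", "sense")
        assert call.orientation_vs_gene == "sense"
        assert call.n_ere_loci == 1 and call.family == "FAM1"

    def test_intergenic_antisense(self):
        repeat = RepeatRecord(
            GenomicInterval("c", 800, 990, "-"), "FAM2", "SINE", "FAM2#1"
        )
        genome = self._genome_with(self.MCS, 850)
        call = classify_origin(self.MCS, [repeat], [_toy_locus()], genome)
        assert (call.region_class, call.orientation_vs_ere) == (
            "intergenic", "antisense",
        )
        assert call.orientation_vs_gene == "n/a"

    def test_reverse_strand_match_found(self):
        repeat = RepeatRecord(
            GenomicInterval("c", 800, 990, "+"), "FAM2", "SINE", "FAM2#1"
        )
        genome = self._genome_with(revcomp(self.MCS), 850)
        call = classify_origin(self.MCS, [repeat], [], genome)
        assert call.orientation_vs_ere == "antisense"  # locus '-', repeat '+'

    def test_no_locus_returns_none(self):
        genome = self._genome_with("", 0)
        assert classify_origin(self.MCS, [], [], genome) is None

    def test_match_outside_any_repeat_returns_none(self):
        genome = self._genome_with(self.MCS, 850)
        assert classify_origin(self.MCS, [], [_toy_locus()], genome) is None


class TestOrientationDecision:
    @pytest.mark.parametrize(
        "region,vs_gene,vs_ere,n_loci,kept",
        [
            ("CDS", "sense", "sense", 1, False),
            ("CDS", "antisense", "sense", 1, True),
            ("intergenic", "n/a", "sense", 1, True),
            ("intergenic", "n/a", "antisense", 1, True),
            ("intronic", "sense", "antisense", 1, False),
            ("intronic", "sense", "antisense", 3, True),
            ("intronic", "sense", "sense", 1, True),
            ("intronic", "antisense", "antisense", 1, True),
        ],
    )
    def test_decision_tree(self, region, vs_gene, vs_ere, n_loci, kept):
        keep, _ = orientation_decision(region, vs_gene, vs_ere, n_loci)
        assert keep is kept


class TestAggregateNonredundant:
    CHARS_A = ("FAM1", "LTR", "intronic", "sense", "sense")
    CHARS_B = ("FAM1", "LTR", "intergenic", "sense", "n/a")

    def test_identical_characteristics_merge(self):
        per_sample = [("PEPTIDEA1"[:9], s, self.CHARS_A) for s in ("s1", "s2", "s3")]
        per_sample = [("ADHKNPQRT", s, self.CHARS_A) for s in ("s1", "s2", "s3")]
        (rec,) = aggregate_nonredundant(per_sample)
        assert rec.samples == ("s1", "s2", "s3")
        assert rec.characteristics == (self.CHARS_A,)

    def test_conflicting_characteristics_kept_as_alternatives(self):
        per_sample = [
            ("ADHKNPQRT", "s1", self.CHARS_A),
            ("ADHKNPQRT", "s2", self.CHARS_B),
        ]
        (rec,) = aggregate_nonredundant(per_sample)
        assert set(rec.characteristics) == {self.CHARS_A, self.CHARS_B}

    def test_disjoint_peptides_preserved(self):
        per_sample = [
            ("ADHKNPQRT", "s1", self.CHARS_A),
            ("TRQPNKHDA", "s1", self.CHARS_A),
        ]
        assert len(aggregate_nonredundant(per_sample)) == 2


class TestCharacterizeCohort:
    def test_single_group_cohort(self, pipeline_run):
        bundle = pipeline_run["bundle"]
        records = pipeline_run["records"]
        summary = characterize_cohort(
            records, bundle.genome.repeats, bundle.genome.genes
        )
        imm = summary["immunopeptidome_proportions"]
        assert sum(imm.values()) == pytest.approx(1.0)
        gen = summary["genome_proportions"]
        assert sum(gen.values()) == pytest.approx(1.0)
        regions = summary["eremap_region_proportions"]
        assert sum(regions.values()) == pytest.approx(1.0)
        # the generator plants mostly intronic origins
        assert regions["intronic"] > 0.5
        assert "copy_number_kendall" in summary

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            characterize_cohort([], [], [])


class TestEndToEndVerdicts:
    def test_every_planted_case_gets_its_intended_verdict(self, pipeline_run):
        truth = pipeline_run["bundle"].truth
        called = {r.peptide for r in pipeline_run["records"]}
        for p in truth.planted:
            should_call = p.intended_verdict in ("eremap", "ambiguous-keep")
            assert (p.peptide in called) == should_call, (
                p.intended_verdict, p.reason,
            )

    def test_no_decoy_or_unplanted_peptides_called(self, pipeline_run):
        truth = pipeline_run["bundle"].truth
        planted = {p.peptide for p in truth.planted}
        called = {r.peptide for r in pipeline_run["records"]}
        assert called <= planted
        decoys = {c.peptide for c in pipeline_run["bundle"].candidates if c.is_decoy}
        assert not called & decoys

    def test_called_annotations_match_truth(self, pipeline_run):
        truth = {p.peptide: p for p in pipeline_run["bundle"].truth.planted}
        for rec in pipeline_run["records"]:
            p = truth[rec.peptide]
            assert rec.region_class == p.region_class
            assert rec.orientation_vs_ere == p.orientation_vs_ere
            assert rec.family == p.family

    def test_discards_carry_one_terminal_reason(self, pipeline_run):
        truth = {p.peptide: p for p in pipeline_run["bundle"].truth.planted}
        called = {r.peptide for r in pipeline_run["records"]}
        for cand in pipeline_run["audited"]:
            if cand.is_decoy or cand.peptide in called:
                continue
            assert cand.verdict_trail, cand.peptide
            last_rule, last_outcome = cand.verdict_trail[-1]
            assert "discard" in last_outcome or last_rule in ("fdr", "binder")
            # exactly one terminal discard in the trail
            discards = [o for _, o in cand.verdict_trail if o.startswith("discard")]
            assert len(discards) <= 1
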