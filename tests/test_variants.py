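"""Variant calling, gene-model classification, coding effects, and
TFBS / miRNA regulatory deltas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabolinker import datasets
from metabolinker.variants import (
    GeneModel,
    Variant,
    call_variants,
    classify_region,
    coding_effect,
    mirna_site_scan,
    pwm_from_counts,
    pwm_relative_score,
    scan_mirna_delta,
    scan_tfbs_delta,
    summarize_variants,
)

TOY_MODEL = GeneModel(
    chrom="1", strand="+", exons=((421, 720),), cds=(481, 660),
    promoter_length=420,
)


class TestCallVariants:
    def test_identical_sequences_empty(self):
        assert call_variants("ACGTACGT", "ACGTACGT", offset=1) == []

    def test_single_snp_by_inspection(self):
        called = call_variants("ACGTA", "ACTTA", offset=1)
        assert len(called) == 1
        v = called[0]
        assert (v.pos, v.ref, v.alt, v.type) == (3, "G", "T", "SNP")

    def test_adjacent_mismatches_split_into_snps(self):
        called = call_variants("AAACCCAAA", "AAAGGCAAA", offset=1)
        assert [(v.pos, v.ref, v.alt) for v in called] == [
            (4, "C", "G"), (5, "C", "G")
        ]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            call_variants("", "ACGT", offset=1)

    def test_minus_strand_coordinates(self):
        # local position 3 maps to genomic offset - 3 + 1
        called = call_variants("ACGTA", "ACTTA", offset=100, strand="-")
        assert called[0].pos == 98

    def test_table_fixture_counts(self, ccna2_fixture, ccna2_variants):
        """The packaged variant set round-trips: 29 variants, 24 SNPs,
        5 InDels."""
        ref, alt, model = ccna2_fixture
        called = call_variants(ref, alt, offset=model.span[1],
                              strand=model.strand)
        summary = summarize_variants(called)
        assert summary["total"] == 29
        assert summary["by_type"]["SNP"] == 24
        assert summary["by_type"].get("INS", 0) + summary["by_type"].get(
            "DEL", 0
        ) == 5
        planted = {(v.pos, v.ref, v.alt) for v in ccna2_variants}
        assert {(v.pos, v.ref, v.alt) for v in called} == planted


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (36471433, "promoter"),   # published promoter SNP
            (36470691, "coding"),     # published exon-1 coding SNP
            (36471074, "promoter"),   # first base upstream of exon 1
            (36471073, "5'UTR"),      # first base of exon 1
            (36465032, "3'UTR"),
            (36468000, "other"),      # intronic
        ],
    )
    def test_published_and_boundary_positions(self, pos, expected):
        model = datasets.ccna2_gene_model()
        v = Variant(pos=pos, ref="A", alt="G")
        assert classify_region(v, model) == expected

    def test_plus_strand_orientation(self):
        assert classify_region(Variant(pos=100, ref="A", alt="G"),
                               TOY_MODEL) == "promoter"
        assert classify_region(Variant(pos=470, ref="A", alt="G"),
                               TOY_MODEL) == "5'UTR"
        assert classify_region(Variant(pos=500, ref="A", alt="G"),
                               TOY_MODEL) == "coding"
        assert classify_region(Variant(pos=700, ref="A", alt="G"),
                               TOY_MODEL) == "3'UTR"


class TestCodingEffect:
    def _region_seq(self, cds_codons):
        # toy model: promoter 420 + 60 bp 5'UTR + 180 bp CDS + 60 bp 3'UTR
        np.random.seed(0)
        flank = lambda n: "".join(np.random.choice(list("ACGT"), n))
        return flank(420) + flank(60) + cds_codons + flank(60)

    def test_leucine_wobble_synonymous(self):
        cds = "CTG" * 60
        seq = self._region_seq(cds)
        # CTG codon position 1: C->T gives TTG, still Leu
        v = Variant(pos=481, ref="C", alt="T")
        assert coding_effect(v, TOY_MODEL, seq, offset=1) == "synonymous"

    def test_lysine_third_position(self):
        seq = self._region_seq("AAA" * 60)
        syn = Variant(pos=483, ref="A", alt="G")   # AAA->AAG, Lys
        mis = Variant(pos=483, ref="A", alt="C")   # AAA->AAC, Asn
        assert coding_effect(syn, TOY_MODEL, seq, offset=1) == "synonymous"
        assert coding_effect(mis, TOY_MODEL, seq, offset=1) == "missense"

    def test_published_coding_snps_synonymous(self, ccna2_fixture):
        ref, _, model = ccna2_fixture
        offset = model.span[1]
        for pos, r, a in [(36470691, "C", "T"), (36467695, "G", "A")]:
            v = Variant(pos=pos, ref=r, alt=a)
            assert coding_effect(v, model, ref, offset) == "synonymous"

    def test_indel_rejected(self):
        seq = self._region_seq("AAA" * 60)
        v = Variant(pos=483, ref="A", alt="-")
        with pytest.raises(ValueError, match="frameshift"):
            coding_effect(v, TOY_MODEL, seq, offset=1)


TOY_PWM = pwm_from_counts(
    "TOY", {"A": [8, 0, 0, 1], "C": [0, 8, 0, 1],
            "G": [0, 0, 8, 1], "T": [0, 0, 0, 5]}
)


class TestPwmScore:
    def test_consensus_scores_one(self):
        assert pwm_relative_score("ACGT", TOY_PWM) == pytest.approx(1.0)

    def test_anti_consensus_scores_zero(self):
        # minimum-weight base at each position
        w = np.asarray(TOY_PWM.weights)
        bases = "ACGT"
        anti = "".join(bases[j] for j in w.argmin(axis=1))
        assert pwm_relative_score(anti, TOY_PWM) == pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pwm_relative_score("ACGTA", TOY_PWM)

    def test_exhaustive_window_oracle(self):
        """Relative scores over every window of a 7-mer equal direct
        per-position weight sums normalized by hand."""
        seq = "ACGTACG"
        w = np.asarray(TOY_PWM.weights)
        lo, hi = w.min(axis=1).sum(), w.max(axis=1).sum()
        idx = {b: i for i, b in enumerate("ACGT")}
        for i in range(len(seq) - 3):
            window = seq[i : i + 4]
            raw = sum(w[j, idx[b]] for j, b in enumerate(window))
            assert pwm_relative_score(window, TOY_PWM) == pytest.approx(
                (raw - lo) / (hi - lo)
            )

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounds_on_random_windows(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            window = "".join(rng.choice(list("ACGT"), size=4))
            s = pwm_relative_score(window, TOY_PWM)
            assert 0.0 <= s <= 1.0


class TestScanTfbsDelta:
    def _seqs(self):
        # motif consensus ACGT broken by one base in the reference
        ref = "TTTTTTACTTTTTTTT"
        alt = "TTTTTTACGTTTTTTT"  # position 9 T->G completes ACGT
        return ref, alt, Variant(pos=9, ref="T", alt="G")

    def test_identical_sequences_no_deltas(self):
        ref = "TTTTTTACGTTTTTTT"
        v = Variant(pos=9, ref="G", alt="G") if False else Variant(
            pos=9, ref="G", alt="A"
        )
        out = scan_tfbs_delta(ref, ref, v, [TOY_PWM], offset=1)
        assert out == {"gain": [], "loss": [], "modification": []}

    def test_snp_completing_consensus_is_gain(self):
        ref, alt, v = self._seqs()
        out = scan_tfbs_delta(ref, alt, v, [TOY_PWM], offset=1)
        assert out["gain"] == ["TOY"]
        assert out["loss"] == []

    def test_symmetry_swapping_alleles(self):
        ref, alt, v = self._seqs()
        swapped = Variant(pos=v.pos, ref=v.alt, alt=v.ref)
        fwd = scan_tfbs_delta(ref, alt, v, [TOY_PWM], offset=1)
        rev = scan_tfbs_delta(alt, ref, swapped, [TOY_PWM], offset=1)
        assert fwd["gain"] == rev["loss"]
        assert fwd["loss"] == rev["gain"]

    def test_hit_boundary_inclusive(self):
        ref, alt, v = self._seqs()
        score = 1.0  # consensus present in alt
        out = scan_tfbs_delta(ref, alt, v, [TOY_PWM], offset=1,
                              threshold=score)
        assert out["gain"] == ["TOY"]

    def test_reverse_strand_hits_detected(self):
        # reverse complement of consensus ACGT is ACGT itself; use an
        # asymmetric motif
        pwm = pwm_from_counts(
            "ASYM", {"A": [9, 0, 0, 0], "C": [0, 9, 0, 0],
                     "G": [0, 0, 9, 0], "T": [0, 0, 0, 9]}
        )
        # plant revcomp(ACGT)=ACGT; use AAGT motif instead
        pwm = pwm_from_counts(
            "ASYM", {"A": [9, 9, 0, 0], "C": [0, 0, 0, 0],
                     "G": [0, 0, 9, 0], "T": [0, 0, 0, 9]}
        )
        # revcomp(AAGT) = ACTT; create it in alt only
        ref = "GGGGGGACGTGGGGGG"
        alt = "GGGGGGACTTGGGGGG"
        v = Variant(pos=9, ref="G", alt="T")
        out = scan_tfbs_delta(ref, alt, v, [pwm], offset=1)
        assert "ASYM" in out["gain"]


class TestMirnaScan:
    # miRNA 5'->3'; seed = positions 2-8
    MIRNA = {"mir-x": "UGGCGCGAAUU"}

    def _site_for(self, mirna_seq):
        from metabolinker.variants import reverse_complement

        m = mirna_seq.replace("U", "T")
        return reverse_complement(m)  # full-length perfect complement

    def test_no_seed_match_empty(self):
        assert mirna_site_scan("A" * 40, self.MIRNA) == []

    def test_full_complement_energy_sum(self):
        """A 10-bp perfect duplex of 6 GC + 4 AU pairs scores -26
        (per-pair sum oracle: 6 * -3 + 4 * -2)."""
        # miRNA AGCGCGCAAU: 6 G/C positions, 4 A/U positions
        site = self._site_for("AGCGCGCAAU")
        utr = "TTTT" + site + "TTTT"
        sites = mirna_site_scan(utr, {"mir-t": "AGCGCGCAAU"})
        assert len(sites) == 1
        assert sites[0].score == pytest.approx(-26.0)

    def test_energy_threshold_boundary(self):
        """Score exactly -10 is reported; -9 is not (7 AU-only seed
        scores -14; use a pluggable energy model to hit the boundary)."""
        mirna = {"m": "UAAAAAAA"}  # seed AAAAAAA -> site TTTTTTT
        # seed match (7 A:U) plus the 3'-flank A:U opposite miRNA
        # position 1 gives 8 pairs total
        utr = "GGG" + "TTTTTTT" + "A" + "GGG"
        at_minus_10 = mirna_site_scan(
            utr, mirna, energy_threshold=-10.0,
            pair_energies={"GC": -3.0, "AT": -1.25, "GT": -1.0},
        )
        # 8 AU pairs at -1.25 each = -10.0 exactly
        assert len(at_minus_10) == 1
        assert at_minus_10[0].score == pytest.approx(-10.0)
        below = mirna_site_scan(
            utr, mirna, energy_threshold=-10.0,
            pair_energies={"GC": -3.0, "AT": -1.2, "GT": -1.0},
        )  # 8 * -1.2 = -9.6 -> not reported
        assert below == []

    def test_threshold_monotonicity(self):
        site = self._site_for("AGCGCGCAAU")
        utr = "TTTT" + site + "TTTT"
        mirna = {"m": "AGCGCGCAAU"}
        loose = mirna_site_scan(utr, mirna, energy_threshold=-5.0)
        tight = mirna_site_scan(utr, mirna, energy_threshold=-30.0)
        assert len(tight) <= len(loose)

    def test_gu_disallowed_in_seed(self):
        # seed complement with one G:U wobble is not a candidate site
        mirna = {"m": "AACCCCCCAA"}
        seed = "ACCCCCC"  # positions 2-8
        from metabolinker.variants import reverse_complement

        target = reverse_complement(seed.replace("U", "T"))  # GGGGGGT
        wobble = "T" + target[1:]  # G->T creates G:U against seed pos 8
        utr = "AAAA" + wobble + "AAAA"
        assert mirna_site_scan(utr, mirna, energy_threshold=0.0) == []

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="8"):
            mirna_site_scan("ACGT" * 5, {"m": "ACGU"})


class TestScanMirnaDelta:
    MIRNA = {"m": "AGCGCGCAAU"}

    def _utr_with_site(self):
        from metabolinker.variants import reverse_complement

        site = reverse_complement("AGCGCGCAAT")
        return "TTTT" + site + "TTTT", site

    def test_identical_utrs_no_deltas(self):
        utr, _ = self._utr_with_site()
        assert scan_mirna_delta(utr, utr, self.MIRNA) == {
            "gain": [], "loss": []
        }

    def test_insertion_creating_site_is_gain(self):
        utr, site = self._utr_with_site()
        ref = "TTTTTTTT"
        alt = "TTTT" + site + "TTTT"
        out = scan_mirna_delta(ref, alt, self.MIRNA)
        assert out == {"gain": ["m"], "loss": []}

    def test_deletion_destroying_site_is_loss(self):
        utr, site = self._utr_with_site()
        out = scan_mirna_delta(utr, "TTTTTTTT", self.MIRNA)
        assert out == {"gain": [], "loss": ["m"]}


class TestSummarizeVariants:
    def test_published_record_bookkeeping(self, ccna2_variants):
        summary = summarize_variants(ccna2_variants)
        assert summary["total"] == 29
        assert summary["by_type"] == {"SNP": 24, "DEL": 2, "INS": 3}
        assert summary["novel"] == 8
        promoter_tf_snps = [
            v
            for v in ccna2_variants
            if v.type == "SNP" and v.region == "promoter"
            and v.function == "TF-regulation"
        ]
        assert len(promoter_tf_snps) == 7

    def test_region_annotations_consistent_with_model(self, ccna2_variants):
        model = datasets.ccna2_gene_model()
        for v in ccna2_variants:
            assert classify_region(v, model) == v.region

    def test_round_trip_preserves_annotation_free_fields(self, ccna2_fixture,
                                                         ccna2_variants):
        ref, alt, model = ccna2_fixture
        called = call_variants(ref, alt, offset=model.span[1],
                               strand=model.strand)
        regions = [classify_region(v, model) for v in called]
        planted_regions = {
            (v.pos): v.region for v in ccna2_variants
        }
        for v, r in zip(called, regions):
            assert planted_regions[v.pos] == r
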