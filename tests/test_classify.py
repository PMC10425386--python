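"""Microhomology, donor detection and the outcome cascade."""

from dataclasses import replace

import pytest

from editcall import (
    Category,
    ClassifierConfig,
    DonorKind,
    DonorSpec,
    MixtureSpec,
    Orientation,
    ReadRecord,
    build_allele_model,
    classify_read,
    classify_reads,
    detect_donor_insertion,
    mh_length,
    revcomp,
    simulate_reads,
)
from editcall.simulate import build_templates, _mh_del_template

from _oracles import mh_by_placement_count
from conftest import random_dna


class TestMhLength:
    @pytest.mark.parametrize(
        "reference,interval,expected",
        [
            # deleting one ACG of the ACGACG repeat: placements [2,5)..[5,8)
            ("TTACGACGTT", (2, 5), 3),
            # two-base deletion inside an A-run: placements [2,4),[3,5),[4,6)
            ("GGAAAAGG", (2, 4), 2),
            ("AACGTTGCAA", (2, 5), 0),  # no shared junction bases
        ],
    )
    def test_spec_examples_match_placement_count(self, reference, interval, expected):
        s, e = interval
        assert mh_by_placement_count(reference, s, e) == expected
        assert mh_length(reference, s, e) == expected

    def test_homopolymer_run_longer_than_deletion(self):
        # a 1-bp deletion inside AAAAAA slides over the whole run
        ref = "GCAAAAAAGC"
        assert mh_length(ref, 4, 5) == mh_by_placement_count(ref, 4, 5) == 5

    def test_matches_placement_oracle_on_random_references(self, rng):
        for _ in range(60):
            ref = random_dna(rng, 120)
            for _ in range(10):
                dl = int(rng.integers(2, 11))
                s = int(rng.integers(1, len(ref) - dl - 1))
                assert mh_length(ref, s, s + dl) == mh_by_placement_count(ref, s, s + dl)

    def test_placement_invariance(self, rng):
        """Equivalent deletion placements report the same microhomology."""
        ref = "TTACGACGTT"
        edited = ref[:2] + ref[5:]
        placements = [t for t in range(8) if ref[:t] + ref[t + 3:] == edited]
        values = {mh_length(ref, t, t + 3) for t in placements}
        assert len(placements) == 4 and values == {3}


class TestDetectDonorInsertion:
    DONOR = DonorSpec(kind=DonorKind.DSDNA_BLUNT, insert="TGCATTCGAAGGCCTATATCGGATCCACTAGTAA")

    def test_exact_payload_forward(self):
        hit = detect_donor_insertion(self.DONOR.insert, self.DONOR)
        assert hit == (Orientation.FORWARD, 1.0)

    def test_reverse_complement_payload(self):
        hit = detect_donor_insertion(revcomp(self.DONOR.insert), self.DONOR)
        assert hit == (Orientation.REVERSE, 1.0)

    def test_two_mismatches_identity(self):
        payload = self.DONOR.insert
        mutated = "AA" + payload[2:]  # brute-force: positions 0,1 differ
        n_match = sum(1 for a, b in zip(mutated, payload) if a == b)
        assert n_match == 32
        hit = detect_donor_insertion(mutated, self.DONOR)
        assert hit is not None
        orient, identity = hit
        assert orient is Orientation.FORWARD
        assert identity == pytest.approx(32 / 34)

    def test_unrelated_insertion_rejected(self, rng):
        hit = detect_donor_insertion(random_dna(rng, 34), self.DONOR)
        assert hit is None

    def test_palindromic_tie_is_ambiguous(self):
        donor = DonorSpec(kind=DonorKind.DSDNA_BLUNT, insert="ACGCGT")  # own rc
        assert detect_donor_insertion("ACGCGT", donor) is None


def _classify_seq(seq, design, alleles=None, cfg=None):
    return classify_read(ReadRecord(read_id="r", sequence=seq), alleles, design, cfg=cfg)


class TestCascade:
    def test_reference_read_is_unmodified(self, ssodn_fixture):
        d = ssodn_fixture.design
        rec = _classify_seq(d.reference, d, build_allele_model(d))
        assert rec.category is Category.UNMODIFIED
        assert rec.variant_key == "="

    def test_plus_one_duplication_is_nhej(self, ssodn_fixture):
        d = ssodn_fixture.design
        c = d.cut.window_center
        read = d.reference[:c] + d.reference[c - 1] + d.reference[c:]
        rec = _classify_seq(read, d, build_allele_model(d))
        assert rec.category is Category.NHEJ

    def test_hdr_allele_read_is_hdr_ki(self, ssodn_fixture):
        d = ssodn_fixture.design
        alleles = build_allele_model(d)
        rec = _classify_seq(alleles.hdr_allele, d, alleles)
        assert rec.category is Category.HDR_KI

    def test_reverse_payload_capture_is_nhej_ki_reverse(self, dsdna_fixture):
        d = dsdna_fixture.design
        alleles = build_allele_model(d)
        rec = _classify_seq(alleles.nhej_ki_rev, d, alleles)
        assert rec.category is Category.NHEJ_KI
        assert rec.orientation is Orientation.REVERSE

    def test_microhomology_deletion_is_mh_del(self, ssodn_fixture):
        d = ssodn_fixture.design
        read = _mh_del_template(ssodn_fixture)
        rec = _classify_seq(read, d, build_allele_model(d))
        assert rec.category is Category.MH_DEL

    def test_two_in_window_indels_are_other(self, ssodn_fixture):
        d = ssodn_fixture.design
        read = build_templates(d, build_allele_model(d))["OTHER_multi_indel"]
        rec = _classify_seq(read, d, build_allele_model(d))
        assert rec.category is Category.OTHER

    def test_one_bp_deletion_is_never_mh_del(self, ssodn_fixture):
        """A 1-bp deletion stays NHEJ even when it slides in a repeat."""
        d = ssodn_fixture.design
        c = d.cut.window_center
        read = d.reference[: c - 1] + d.reference[c:]
        rec = _classify_seq(read, d, build_allele_model(d))
        assert rec.category is Category.NHEJ

    def test_long_deletion_without_mh_is_other(self, rng):
        from editcall import make_fixture

        fx = make_fixture(seed=23, mh_len=0, del_len=4)
        d = fx.design
        read = _mh_del_template(fx)
        rec = _classify_seq(read, d, build_allele_model(d))
        assert rec.category is Category.OTHER

    def test_imperfect_hdr_junction_is_other(self, ssodn_fixture):
        """Payload present but an extra in-window indel: not HDR_KI."""
        d = ssodn_fixture.design
        alleles = build_allele_model(d)
        j, _ = alleles.insert_coords["hdr"]
        hdr = alleles.hdr_allele
        read = hdr[: j - 6] + hdr[j - 5 :]  # extra in-window 1-bp deletion
        rec = _classify_seq(read, d, alleles)
        assert rec.category is Category.OTHER

    def test_low_quality_read_discarded(self, ssodn_fixture):
        d = ssodn_fixture.design
        read = ReadRecord(
            read_id="r", sequence=d.reference, qualities=[5] * len(d.reference)
        )
        rec = classify_read(read, None, d)
        assert rec.category is Category.DISCARDED

    def test_garbage_read_discarded_by_score_floor(self, ssodn_fixture, rng):
        d = ssodn_fixture.design
        rec = _classify_seq(random_dna(rng, len(d.reference)), d)
        assert rec.category is Category.DISCARDED


class TestProperties:
    MIX = {
        "UNMODIFIED": 0.2, "NHEJ_plus1": 0.15, "NHEJ_minus1": 0.1,
        "MH_DEL": 0.2, "HDR_KI": 0.15, "NHEJ_KI_fwd": 0.1,
        "NHEJ_KI_rev": 0.05, "OTHER_multi_indel": 0.05,
    }

    def test_partition_over_categories(self, ssodn_fixture):
        mix = MixtureSpec(proportions=self.MIX, n_reads=500, error_rate=0.002, seed=9)
        reads, _ = simulate_reads(ssodn_fixture, mix)
        run = classify_reads(reads, ssodn_fixture.design)
        by_cat = {}
        for rec in run.records:
            by_cat[rec.category] = by_cat.get(rec.category, 0) + rec.count
        assert sum(by_cat.values()) == len(reads)

    def test_raising_mh_min_only_moves_mh_del_to_other(self, ssodn_fixture):
        mix = MixtureSpec(proportions=self.MIX, n_reads=400, error_rate=0.001, seed=4)
        reads, _ = simulate_reads(ssodn_fixture, mix)
        lax = classify_reads(reads, ssodn_fixture.design, cfg=ClassifierConfig(mh_min=2))
        strict = classify_reads(
            reads, ssodn_fixture.design, cfg=ClassifierConfig(mh_min=ssodn_fixture.mh_len + 1)
        )
        for a, b in zip(lax.records, strict.records):
            if a.category is Category.MH_DEL:
                assert b.category in (Category.MH_DEL, Category.OTHER)
            else:
                assert b.category is a.category

    def test_orientation_flip_symmetry(self, dsdna_fixture):
        """rc of every inserted payload flips forward<->reverse only."""
        d = dsdna_fixture.design
        alleles = build_allele_model(d)
        mix = MixtureSpec(
            proportions={"UNMODIFIED": 0.3, "NHEJ_plus1": 0.2,
                         "NHEJ_KI_fwd": 0.3, "NHEJ_KI_rev": 0.2},
            n_reads=300, error_rate=0.0, seed=2,
        )
        reads, _ = simulate_reads(dsdna_fixture, mix)
        swap = {alleles.nhej_ki_fwd: alleles.nhej_ki_rev,
                alleles.nhej_ki_rev: alleles.nhej_ki_fwd}
        flipped = [
            replace(r, sequence=swap.get(r.sequence, r.sequence)) for r in reads
        ]
        run_a = classify_reads(reads, d, alleles=alleles)
        run_b = classify_reads(flipped, d, alleles=alleles)
        for a, b in zip(run_a.records, run_b.records):
            assert a.category is b.category
            if a.category is Category.NHEJ_KI:
                assert a.orientation is not b.orientation
            else:
                assert a.orientation is b.orientation
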