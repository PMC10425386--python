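"""Alignment, variant extraction, normalization and readers."""

import numpy as np
import pytest

from editcall import (
    EventType,
    MixtureSpec,
    ReadRecord,
    align_read,
    apply_variants,
    extract_variants,
    read_allele_table,
    read_fastq,
    simulate_reads,
)
from editcall.align import events_from_alignment, normalize_events, VariantEvent
from editcall.errors import LowQualityError
from editcall.simulate import write_fastq

from _oracles import affine_optimal, canonical_events
from conftest import random_dna


def _events(read_seq: str, allele: str, window=None):
    aln = align_read(ReadRecord(read_id="r", sequence=read_seq), allele)
    return events_from_alignment(aln, allele, window or (0, len(allele)))


class TestAlignRead:
    def test_identity_read_has_single_match_op(self, simple_design):
        ref = simple_design.reference
        aln = align_read(ReadRecord(read_id="r", sequence=ref), ref)
        assert aln.ops == [("match", len(ref), "")]
        assert aln.score == 2.0 * len(ref)

    def test_single_base_deletion_recovered(self, simple_design):
        ref = simple_design.reference
        read = ref[:87] + ref[88:]
        evs = [e for e in _events(read, ref) if e.is_indel]
        assert len(evs) == 1
        assert evs[0].etype is EventType.DELETION and evs[0].length == 1

    def test_block_insertion_at_cut_recovered(self, simple_design, rng):
        ref = simple_design.reference
        block = random_dna(rng, 34)
        read = ref[:87] + block + ref[87:]
        evs = [e for e in _events(read, ref) if e.is_indel]
        assert len(evs) == 1
        ev = evs[0]
        assert ev.etype is EventType.INSERTION and ev.length == 34
        # left-normalization may rotate the block within flanking homology,
        # but re-applying the event must reproduce the read exactly
        assert apply_variants(ref, evs) == read

    def test_low_quality_read_rejected(self, simple_design):
        read = ReadRecord(
            read_id="r", sequence=simple_design.reference,
            qualities=[10] * len(simple_design.reference),
        )
        with pytest.raises(LowQualityError):
            align_read(read, simple_design.reference)

    def test_agrees_with_exhaustive_affine_oracle(self, rng):
        """Score equality and event membership on 200 short random pairs."""
        checked = 0
        while checked < 200:
            target = random_dna(rng, int(rng.integers(15, 31)))
            query = _mutate(target, rng, n_edits=int(rng.integers(0, 4)))
            if not query:
                continue
            score, event_sets = affine_optimal(target, query)
            aln = align_read(ReadRecord(read_id="r", sequence=query), target)
            assert aln.score == pytest.approx(score)
            assert canonical_events(aln, target) in event_sets
            checked += 1


def _mutate(seq: str, rng: np.random.Generator, n_edits: int) -> str:
    out = seq
    for _ in range(n_edits):
        if not out:
            break
        kind = rng.integers(0, 3)
        pos = int(rng.integers(0, len(out)))
        if kind == 0:  # substitution
            out = out[:pos] + random_dna(rng, 1) + out[pos + 1:]
        elif kind == 1:  # deletion of 1-3 bases
            out = out[:pos] + out[pos + int(rng.integers(1, 4)):]
        else:  # insertion of 1-3 bases
            out = out[:pos] + random_dna(rng, int(rng.integers(1, 4))) + out[pos:]
    return out


class TestNormalization:
    def test_homopolymer_deletion_reported_leftmost(self):
        #        0123456789
        ref = "GGCAAAATGG"
        read = ref[:5] + ref[6:]  # delete one A from the run [3,7)
        evs = [e for e in _events(read, ref) if e.is_indel]
        assert len(evs) == 1
        ev = evs[0]
        # enumerate equivalent placements: deleting any one A of the run
        # yields the same string; the leftmost is position 3
        equivalents = [t for t in range(len(ref)) if ref[:t] + ref[t + 1:] == read]
        assert ev.ref_start == min(equivalents) == 3

    def test_normalization_is_idempotent(self, rng):
        for _ in range(50):
            ref = random_dna(rng, 60)
            read = _mutate(ref, rng, n_edits=int(rng.integers(1, 4)))
            if not read:
                continue
            aln = align_read(ReadRecord(read_id="r", sequence=read), ref)
            evs = events_from_alignment(aln, ref, (0, len(ref)))
            once = normalize_events(list(evs), ref)
            twice = normalize_events(list(once), ref)
            assert once == twice

    def test_substitution_only_read_has_no_indels(self, simple_design):
        ref = simple_design.reference
        read = ref[:50] + ("A" if ref[50] != "A" else "C") + ref[51:]
        evs = _events(read, ref)
        assert [e.etype for e in evs] == [EventType.SUBSTITUTION]

    def test_window_flag_interval_arithmetic(self, simple_design):
        ref = simple_design.reference
        lo, hi = simple_design.window
        # deletion entirely before the window
        read = ref[: lo - 10] + ref[lo - 7 :]
        aln = align_read(ReadRecord(read_id="r", sequence=read), ref)
        evs = [e for e in extract_variants(aln, simple_design) if e.is_indel]
        assert len(evs) == 1 and not evs[0].in_window
        # deletion overlapping the window boundary
        read2 = ref[: lo - 1] + ref[lo + 2 :]
        aln2 = align_read(ReadRecord(read_id="r", sequence=read2), ref)
        evs2 = [e for e in extract_variants(aln2, simple_design) if e.is_indel]
        assert len(evs2) == 1 and evs2[0].in_window


class TestRoundTrip:
    def test_simulated_reads_reconstruct_exactly(self, ssodn_fixture):
        """Applying extracted events to the reference rebuilds every read."""
        mix = MixtureSpec(
            proportions={
                "UNMODIFIED": 0.2, "NHEJ_plus1": 0.1, "NHEJ_minus1": 0.1,
                "MH_DEL": 0.2, "HDR_KI": 0.2, "NHEJ_KI_fwd": 0.1,
                "NHEJ_KI_rev": 0.05, "OTHER_multi_indel": 0.05,
            },
            n_reads=300, error_rate=0.002, seed=3,
        )
        reads, _ = simulate_reads(ssodn_fixture, mix)
        ref = ssodn_fixture.design.reference
        for read in reads:
            aln = align_read(read, ref)
            evs = events_from_alignment(aln, ref, ssodn_fixture.design.window)
            assert apply_variants(ref, evs) == read.sequence


class TestReaders:
    def test_fastq_round_trip(self, tmp_path, ssodn_fixture):
        mix = MixtureSpec(
            proportions={"UNMODIFIED": 0.5, "NHEJ_plus1": 0.5},
            n_reads=20, error_rate=0.0, seed=1,
        )
        reads, _ = simulate_reads(ssodn_fixture, mix)
        path = tmp_path / "reads.fastq"
        write_fastq(reads, path)
        back = list(read_fastq(path))
        assert [r.sequence for r in back] == [r.sequence for r in reads]
        assert all(r.mean_quality == 40 for r in back)

    def test_allele_table_reader_strips_gaps_and_counts(self, tmp_path):
        path = tmp_path / "table.tsv"
        path.write_text(
            "Aligned_Sequence\tRead_Count\nACGT--ACGT\t12\nTTTTTTTT\t3\n"
        )
        records = read_allele_table(path)
        assert [(r.sequence, r.count) for r in records] == [
            ("ACGTACGT", 12), ("TTTTTTTT", 3),
        ]

    def test_allele_table_requires_columns(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("foo\tbar\nACGT\t3\n")
        with pytest.raises(ValueError):
            read_allele_table(path)


class TestVariantEventInvariants:
    def test_insertion_length_must_match_sequence(self):
        with pytest.raises(ValueError):
            VariantEvent(EventType.INSERTION, 0, 3, inserted_seq="AC")

    def test_deletion_carries_no_sequence(self):
        with pytest.raises(ValueError):
            VariantEvent(EventType.DELETION, 0, 2, inserted_seq="AC")
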