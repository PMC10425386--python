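"""Read-to-allele alignment and variant extraction.

Reads are aligned globally against the reference amplicon (and, when
present, against the expected knock-in alleles) with affine gap
penalties. The scoring defaults — match +2, mismatch -2, gap open -10,
gap extend -1 — strongly favour one contiguous indel at the cut over
scattered gaps, which is the behaviour expected of amplicon variant
callers. A gap of length ``k`` costs ``open + (k - 1) * extend``.

Indels are reported left-normalized (shifted to their smallest reference
start among textually equivalent placements) so that identical edited
sequences always yield identical variant keys; normalization never
crosses a neighbouring event.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
from Bio import Align, SeqIO

from .errors import LowQualityError
from .model import ExperimentDesign


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring; all four parameters are config-exposed."""

    match: float = 2.0
    mismatch: float = -2.0
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def self_score(self, seq_len: int) -> float:
        return self.match * seq_len


@dataclass
class ReadRecord:
    """One sequencing read, or one collapsed allele-table row (count > 1)."""

    read_id: str
    sequence: str
    qualities: Optional[Sequence[int]] = None
    count: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("read sequence must be non-empty")
        if self.count < 1:
            raise ValueError("read count must be >= 1")

    @property
    def mean_quality(self) -> Optional[float]:
        if not self.qualities:
            return None
        return sum(self.qualities) / len(self.qualities)


class EventType(str, Enum):
    INSERTION = "insertion"
    DELETION = "deletion"
    SUBSTITUTION = "substitution"


@dataclass(frozen=True)
class VariantEvent:
    """One normalized difference between a read and an allele.

    ``ref_start`` is the event's 0-based position on the allele; for
    insertions it is the inter-base coordinate where ``inserted_seq`` is
    placed. ``mh_len`` is the junction-microhomology length, filled for
    deletions by the classifier. ``in_window`` flags intersection with the
    quantification window.
    """

    etype: EventType
    ref_start: int
    length: int
    inserted_seq: str = ""
    mh_len: int = 0
    in_window: bool = False

    def __post_init__(self) -> None:
        if self.etype is EventType.INSERTION and self.length != len(self.inserted_seq):
            raise ValueError("insertion length must equal len(inserted_seq)")
        if self.etype is EventType.DELETION and self.inserted_seq:
            raise ValueError("deletion carries no inserted sequence")

    @property
    def ref_end(self) -> int:
        """Exclusive end on the allele (== ref_start for insertions)."""
        if self.etype is EventType.INSERTION:
            return self.ref_start
        return self.ref_start + self.length

    @property
    def is_indel(self) -> bool:
        return self.etype is not EventType.SUBSTITUTION


@dataclass
class AlignmentResult:
    """Pairwise global alignment of a read against one allele.

    ``ops`` is an ordered run-length list of ``(op, length, query_seq)``
    with op in {match, mismatch, ins, del}; ``query_seq`` is non-empty for
    ins and mismatch runs (the read-side bases).
    """

    allele_name: str
    score: float
    ops: list[tuple[str, int, str]]
    ref_span: tuple[int, int]


def make_aligner(scoring: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _ops_from_gapped(target: str, query: str) -> list[tuple[str, int, str]]:
    """Run-length ops from the two gapped rows of an alignment."""
    ops: list[tuple[str, int, str]] = []
    cur_op: Optional[str] = None
    cur_len = 0
    cur_seq: list[str] = []

    def flush() -> None:
        nonlocal cur_op, cur_len, cur_seq
        if cur_op is not None:
            ops.append((cur_op, cur_len, "".join(cur_seq)))
        cur_op, cur_len, cur_seq = None, 0, []

    for t, q in zip(target, query):
        if t == "-" and q == "-":
            continue
        if t == "-":
            op, seq = "ins", q
        elif q == "-":
            op, seq = "del", ""
        elif t == q:
            op, seq = "match", ""
        else:
            op, seq = "mismatch", q
        if op != cur_op:
            flush()
            cur_op = op
        cur_len += 1
        if seq:
            cur_seq.append(seq)
    flush()
    return ops


def align_read(
    read: ReadRecord,
    allele: str,
    scoring: Optional[ScoringParams] = None,
    allele_name: str = "reference",
    min_mean_quality: float = 20.0,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> AlignmentResult:
    """Optimal global alignment of a read against one allele.

    Deterministic for fixed inputs and scoring (the first co-optimal
    traceback is taken; indel placement is canonicalized later by
    left-normalization). Raises :class:`LowQualityError` when the read
    carries qualities and their mean is below ``min_mean_quality``.
    """
    mq = read.mean_quality
    if mq is not None and mq < min_mean_quality:
        raise LowQualityError(
            f"read {read.read_id}: mean quality {mq:.1f} < {min_mean_quality}"
        )
    if aligner is None:
        aligner = make_aligner(scoring or ScoringParams())
    aln = aligner.align(allele, read.sequence)[0]
    ops = _ops_from_gapped(str(aln[0]), str(aln[1]))
    return AlignmentResult(
        allele_name=allele_name,
        score=float(aln.score),
        ops=ops,
        ref_span=(0, len(allele)),
    )


def _normalize_indel(event: VariantEvent, allele: str, floor: int) -> VariantEvent:
    """Shift one indel to its leftmost equivalent placement, not below floor."""
    if event.etype is EventType.DELETION:
        start, length = event.ref_start, event.length
        while start > floor and allele[start - 1] == allele[start + length - 1]:
            start -= 1
        return replace(event, ref_start=start)
    if event.etype is EventType.INSERTION:
        pos, seq = event.ref_start, event.inserted_seq
        while pos > floor and allele[pos - 1] == seq[-1]:
            seq = allele[pos - 1] + seq[:-1]
            pos -= 1
        return replace(event, ref_start=pos, inserted_seq=seq)
    return event


def normalize_events(events: list[VariantEvent], allele: str) -> list[VariantEvent]:
    """Left-normalize indels and merge adjacent same-type events.

    Events are processed left to right; an indel never shifts across the
    end of the preceding event, so normalized events stay sorted and
    non-overlapping. The operation is idempotent.
    """
    out: list[VariantEvent] = []
    floor = 0
    for ev in sorted(events, key=lambda e: (e.ref_start, e.etype.value)):
        ev = _normalize_indel(ev, allele, floor)
        if out:
            prev = out[-1]
            if (
                prev.etype is ev.etype is EventType.DELETION
                and prev.ref_end == ev.ref_start
            ):
                out[-1] = replace(prev, length=prev.length + ev.length)
                floor = out[-1].ref_end
                continue
            if (
                prev.etype is ev.etype is EventType.INSERTION
                and prev.ref_start == ev.ref_start
            ):
                merged = prev.inserted_seq + ev.inserted_seq
                out[-1] = replace(prev, length=len(merged), inserted_seq=merged)
                floor = out[-1].ref_end
                continue
        out.append(ev)
        floor = max(floor, ev.ref_end) if ev.etype is not EventType.INSERTION else max(floor, ev.ref_start)
    return out


def _window_flag(ev: VariantEvent, window: tuple[int, int]) -> bool:
    lo, hi = window
    if ev.etype is EventType.INSERTION:
        # an insertion occupies no reference bases; treat it as touching
        # the base to its right for window-intersection purposes
        return lo <= ev.ref_start < hi
    return ev.ref_start < hi and ev.ref_end > lo


def events_from_alignment(
    aln: AlignmentResult, allele: str, window: tuple[int, int]
) -> list[VariantEvent]:
    """Convert alignment ops into normalized, window-flagged events."""
    events: list[VariantEvent] = []
    pos = 0
    for op, length, seq in aln.ops:
        if op == "match":
            pos += length
        elif op == "mismatch":
            events.append(
                VariantEvent(EventType.SUBSTITUTION, pos, length, inserted_seq=seq)
            )
            pos += length
        elif op == "del":
            events.append(VariantEvent(EventType.DELETION, pos, length))
            pos += length
        elif op == "ins":
            events.append(VariantEvent(EventType.INSERTION, pos, length, inserted_seq=seq))
        else:  # pragma: no cover
            raise ValueError(f"unknown op {op}")
    events = normalize_events(events, allele)
    return [replace(ev, in_window=_window_flag(ev, window)) for ev in events]


def extract_variants(aln: AlignmentResult, design: ExperimentDesign) -> list[VariantEvent]:
    """Events of a reference alignment, in reference coordinates."""
    return events_from_alignment(aln, design.reference, design.window)


def apply_variants(allele: str, events: Iterable[VariantEvent]) -> str:
    """Reconstruct the read sequence implied by a set of events.

    Inverse of variant extraction: applying a read's events to the allele
    it was aligned against returns the read exactly.
    """
    out: list[str] = []
    pos = 0
    for ev in sorted(events, key=lambda e: (e.ref_start, 0 if e.etype is EventType.INSERTION else 1)):
        out.append(allele[pos:ev.ref_start])
        if ev.etype is EventType.INSERTION:
            out.append(ev.inserted_seq)
            pos = ev.ref_start
        elif ev.etype is EventType.DELETION:
            pos = ev.ref_end
        else:
            out.append(ev.inserted_seq)
            pos = ev.ref_end
    out.append(allele[pos:])
    return "".join(out)


# ---------------------------------------------------------------------------
# readers


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate reads from a (optionally gzipped) Sanger-Phred+33 FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=rec.letter_annotations.get("phred_quality"),
            )


_SEQ_ALIASES = ("aligned_sequence", "sequence", "read_sequence")
_COUNT_ALIASES = ("read_count", "reads", "#reads", "count", "n_reads")


def read_allele_table(path: str | Path) -> list[ReadRecord]:
    """Read a tab-delimited allele-frequency table.

    Expects columns (case-insensitive) ``aligned_sequence`` and
    ``read_count`` (common aliases accepted). Gap characters in the
    sequence column are stripped and every sequence is re-aligned
    internally, so only {sequence, count} are trusted from the table.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower().strip(): c for c in df.columns}
    seq_col = next((cols[a] for a in _SEQ_ALIASES if a in cols), None)
    count_col = next((cols[a] for a in _COUNT_ALIASES if a in cols), None)
    if seq_col is None or count_col is None:
        raise ValueError(
            f"allele table must have sequence and count columns; found {list(df.columns)}"
        )
    out: list[ReadRecord] = []
    for i, (seq, count) in enumerate(zip(df[seq_col], df[count_col])):
        seq = str(seq).upper().replace("-", "")
        out.append(ReadRecord(read_id=f"variant_{i:05d}", sequence=seq, count=int(count)))
    return out
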