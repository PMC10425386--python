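"""Repair-outcome classification of aligned amplicon reads.

Every mapped read is assigned to exactly one category:

* ``HDR_KI``     — matches the seamless homology-arm-templated allele
                   (zero in-window indels against the HDR allele, intended
                   donor substitutions present);
* ``NHEJ_KI``    — end-capture of an armless donor payload at the cut, in
                   forward or reverse orientation;
* ``UNMODIFIED`` — no in-window indels against the reference
                   (substitution-only reads count here: sequencing errors
                   dominate substitutions and there is no substitution
                   outcome class);
* ``NHEJ``       — a single in-window +/-1 bp indel;
* ``MH_DEL``     — a single in-window deletion of >= 2 bp whose junction
                   microhomology is >= 2 bp, the signature of
                   microhomology-mediated (alt-EJ/TMEJ) repair;
* ``OTHER``      — everything else (multi-indel reads, long insertions
                   not matching the donor, long deletions without
                   microhomology, imperfect HDR junctions);
* ``DISCARDED``  — reads failing the quality or mapping filters; never
                   part of "mapped reads".

The cascade order gives HDR precedence over donor-payload detection: a
read identical to the seamless HDR allele necessarily contains the
payload, but it is the templated, precise edit and is reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .align import (
    EventType,
    ReadRecord,
    ScoringParams,
    VariantEvent,
    align_read,
    events_from_alignment,
    make_aligner,
)
from .model import AlleleModel, DonorSpec, ExperimentDesign, build_allele_model, revcomp


class Category(str, Enum):
    UNMODIFIED = "UNMODIFIED"
    NHEJ = "NHEJ"
    MH_DEL = "MH_DEL"
    NHEJ_KI = "NHEJ_KI"
    HDR_KI = "HDR_KI"
    OTHER = "OTHER"
    DISCARDED = "DISCARDED"


MAPPED_CATEGORIES = (
    Category.UNMODIFIED,
    Category.NHEJ,
    Category.MH_DEL,
    Category.NHEJ_KI,
    Category.HDR_KI,
    Category.OTHER,
)


class Orientation(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the outcome cascade.

    ``mh_min`` and the deletion-length floor of 2 bp are both applied for
    MH_DEL (a deletion must be >= 2 bp long *and* show >= ``mh_min`` bp of
    junction microhomology); ``nhej_indel_max`` bounds the +/-1 bp NHEJ
    class. ``donor_min_identity`` is the fraction of donor-payload bases
    that must be recovered inside an insertion for NHEJ_KI, with
    full-payload coverage implied by the ratio's denominator.
    """

    mh_min: int = 2
    mh_del_min_len: int = 2
    nhej_indel_max: int = 1
    donor_min_identity: float = 0.90
    hdr_requires_perfect_window: bool = True
    min_mean_quality: float = 20.0
    mapped_score_frac: float = 0.60

    def __post_init__(self) -> None:
        if not (0.0 < self.donor_min_identity <= 1.0):
            raise ValueError("donor_min_identity must be in (0, 1]")
        if self.mh_min < 1 or self.nhej_indel_max < 1:
            raise ValueError("mh_min and nhej_indel_max must be >= 1")


@dataclass
class ReadClassification:
    """Per-read (or per-collapsed-variant) outcome call."""

    read_id: str
    category: Category
    count: int = 1
    orientation: Optional[Orientation] = None
    variant_key: str = ""

    def __post_init__(self) -> None:
        if (self.orientation is not None) != (self.category is Category.NHEJ_KI):
            raise ValueError("orientation is set iff category is NHEJ_KI")


def mh_length(reference: str, del_start: int, del_end: int) -> int:
    """Junction-microhomology length of a deletion.

    Counts how far the deletion can slide left plus how far it can slide
    right while producing the identical edited sequence; this equals the
    number of distinct equal-length placements yielding the same product,
    minus one. Sliding one step left is valid iff
    ``reference[del_start - i] == reference[del_end - i]`` for every step
    taken, and symmetrically to the right, so the count is
    placement-invariant: any equivalent placement gives the same value.
    """
    if not (0 <= del_start < del_end <= len(reference)):
        raise ValueError("deletion interval out of bounds")
    left = 0
    while del_start - left - 1 >= 0 and reference[del_start - left - 1] == reference[del_end - left - 1]:
        left += 1
    right = 0
    while del_end + right < len(reference) and reference[del_end + right] == reference[del_start + right]:
        right += 1
    return left + right


def detect_donor_insertion(
    inserted_seq: str,
    donor: DonorSpec,
    cfg: Optional[ClassifierConfig] = None,
    scoring: Optional[ScoringParams] = None,
) -> Optional[tuple[Orientation, float]]:
    """Match an inserted segment against the donor payload.

    The payload and its reverse complement are each aligned locally
    against the insertion; identity = identical aligned bases / payload
    length. Returns the better orientation when its identity reaches
    ``donor_min_identity``; an exact tie between orientations is treated
    as ambiguous and returns None.
    """
    if not inserted_seq:
        raise ValueError("inserted_seq must be non-empty")
    cfg = cfg or ClassifierConfig()
    aligner = make_aligner(scoring or ScoringParams())
    aligner.mode = "local"

    def identities(payload: str) -> int:
        alns = aligner.align(inserted_seq, payload)
        if len(alns) == 0:
            return 0
        aln = alns[0]
        t, q = str(aln[0]), str(aln[1])
        return sum(1 for a, b in zip(t, q) if a == b and a != "-")

    payload = donor.insert
    fwd = identities(payload)
    rev = identities(revcomp(payload))
    if fwd == rev:
        return None
    best, orient = (fwd, Orientation.FORWARD) if fwd > rev else (rev, Orientation.REVERSE)
    identity = best / len(payload)
    if identity < cfg.donor_min_identity:
        return None
    return orient, identity


def variant_key(events: Sequence[VariantEvent]) -> str:
    """Canonical text key of a read's in-window events.

    Out-of-window variation (sequencing noise away from the cut) never
    splits variants; in-window substitutions are part of the key so that,
    e.g., an HDR allele with a PAM-blocking edit is distinct from an
    armless capture of the same payload.
    """
    parts = []
    for ev in events:
        if not ev.in_window:
            continue
        if ev.etype is EventType.INSERTION:
            parts.append(f"ins@{ev.ref_start}:{ev.inserted_seq}")
        elif ev.etype is EventType.DELETION:
            parts.append(f"del@{ev.ref_start}-{ev.ref_end}")
        else:
            parts.append(f"sub@{ev.ref_start}:{ev.inserted_seq}")
    return ";".join(parts) if parts else "="


def _hdr_window(design: ExperimentDesign, alleles: AlleleModel) -> tuple[int, int]:
    lo, hi = design.window
    delta = len(alleles.hdr_allele) - len(design.reference)
    return lo, hi + delta


def _hdr_sub_positions(design: ExperimentDesign, alleles: AlleleModel) -> list[int]:
    """Intended-substitution positions mapped into HDR-allele coordinates."""
    j, j_end = alleles.insert_coords["hdr"]
    ins_len = j_end - j
    out = []
    for pos, _base in design.donor.intended_substitutions:
        out.append(pos if pos < j else pos + ins_len)
    return out


def _is_hdr(
    hdr_events: Sequence[VariantEvent],
    sub_positions: Sequence[int],
    cfg: ClassifierConfig,
) -> bool:
    if any(ev.is_indel and ev.in_window for ev in hdr_events):
        return False
    if not cfg.hdr_requires_perfect_window:
        return True
    # intended substitutions present <=> the read does not revert them:
    # no mismatch or deletion of the HDR allele covers those positions
    for p in sub_positions:
        for ev in hdr_events:
            if ev.etype is EventType.INSERTION:
                continue
            if ev.ref_start <= p < ev.ref_end:
                return False
    return True


@dataclass
class _Caller:
    """Reusable classification context for one experiment."""

    design: ExperimentDesign
    cfg: ClassifierConfig
    scoring: ScoringParams
    alleles: Optional[AlleleModel]

    def __post_init__(self) -> None:
        self.aligner = make_aligner(self.scoring)
        self.hdr_window = (
            _hdr_window(self.design, self.alleles)
            if self.alleles is not None and self.alleles.hdr_allele is not None
            else None
        )
        self.hdr_subs = (
            _hdr_sub_positions(self.design, self.alleles)
            if self.hdr_window is not None
            else []
        )

    def call_sequence(self, sequence: str) -> tuple[Category, Optional[Orientation], str, list[VariantEvent]]:
        """Classify one read sequence; returns (category, orientation,
        variant_key, reference-alignment events)."""
        design, cfg = self.design, self.cfg
        rec = ReadRecord(read_id="_", sequence=sequence)
        aln_ref = align_read(rec, design.reference, aligner=self.aligner)
        ref_events = events_from_alignment(aln_ref, design.reference, design.window)
        key = variant_key(ref_events)

        hdr_aln = None
        if self.hdr_window is not None:
            hdr_aln = align_read(rec, self.alleles.hdr_allele, aligner=self.aligner)

        # mapping filter: best score must reach a fraction of the
        # best-matching allele's self-alignment score
        best_score = aln_ref.score
        best_len = len(design.reference)
        if hdr_aln is not None and hdr_aln.score > best_score:
            best_score = hdr_aln.score
            best_len = len(self.alleles.hdr_allele)
        if best_score < cfg.mapped_score_frac * self.scoring.self_score(best_len):
            return Category.DISCARDED, None, key, ref_events

        # (1) HDR knock-in
        if hdr_aln is not None:
            hdr_events = events_from_alignment(
                hdr_aln, self.alleles.hdr_allele, self.hdr_window
            )
            if _is_hdr(hdr_events, self.hdr_subs, cfg):
                return Category.HDR_KI, None, key, ref_events

        in_window = [ev for ev in ref_events if ev.in_window and ev.is_indel]
        insertions = [ev for ev in in_window if ev.etype is EventType.INSERTION]
        deletions = [ev for ev in in_window if ev.etype is EventType.DELETION]

        # (2) NHEJ knock-in: one in-window insertion matching the donor payload.
        # Left-normalization can rotate the inserted segment when the payload
        # ends happen to match the reference flank, so the insertion is
        # matched together with a little reference context on either side.
        if design.donor is not None and len(insertions) == 1 and not deletions:
            ins = insertions[0]
            pad = 16
            seg = (
                design.reference[max(0, ins.ref_start - pad) : ins.ref_start]
                + ins.inserted_seq
                + design.reference[ins.ref_start : ins.ref_start + pad]
            )
            hit = detect_donor_insertion(seg, design.donor, cfg, self.scoring)
            if hit is not None:
                return Category.NHEJ_KI, hit[0], key, ref_events

        # (3) unmodified (substitution-only reads land here)
        if not in_window:
            return Category.UNMODIFIED, None, key, ref_events

        # (4) single small indel: NHEJ
        if len(in_window) == 1 and in_window[0].length <= cfg.nhej_indel_max:
            return Category.NHEJ, None, key, ref_events

        # (5) single deletion with junction microhomology: alt-EJ
        if len(in_window) == 1 and in_window[0].etype is EventType.DELETION:
            ev = in_window[0]
            if ev.length >= cfg.mh_del_min_len:
                mh = mh_length(design.reference, ev.ref_start, ev.ref_end)
                if mh >= cfg.mh_min:
                    return Category.MH_DEL, None, key, ref_events

        # (6) everything else
        return Category.OTHER, None, key, ref_events


@dataclass
class ClassificationRun:
    """Result of classifying one read set against one design."""

    design: ExperimentDesign
    cfg: ClassifierConfig
    records: list[ReadClassification]
    key_events: dict[str, list[VariantEvent]] = field(default_factory=dict)
    key_category: dict[str, tuple[Category, Optional[Orientation]]] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(r.count for r in self.records)


def classify_read(
    read: ReadRecord,
    alleles: Optional[AlleleModel],
    design: ExperimentDesign,
    cfg: Optional[ClassifierConfig] = None,
    scoring: Optional[ScoringParams] = None,
) -> ReadClassification:
    """Classify a single read (convenience wrapper around the cascade)."""
    cfg = cfg or ClassifierConfig()
    scoring = scoring or ScoringParams()
    mq = read.mean_quality
    if mq is not None and mq < cfg.min_mean_quality:
        return ReadClassification(read.read_id, Category.DISCARDED, count=read.count)
    caller = _Caller(design, cfg, scoring, alleles)
    cat, orient, key, _ = caller.call_sequence(read.sequence)
    return ReadClassification(read.read_id, cat, count=read.count, orientation=orient, variant_key=key)


def classify_reads(
    reads: Sequence[ReadRecord] | list[ReadRecord],
    design: ExperimentDesign,
    cfg: Optional[ClassifierConfig] = None,
    scoring: Optional[ScoringParams] = None,
    alleles: Optional[AlleleModel] = None,
) -> ClassificationRun:
    """Classify a read set; identical sequences are aligned only once."""
    cfg = cfg or ClassifierConfig()
    scoring = scoring or ScoringParams()
    if alleles is None and design.donor is not None:
        alleles = build_allele_model(design)
    caller = _Caller(design, cfg, scoring, alleles)

    cache: dict[str, tuple[Category, Optional[Orientation], str, list[VariantEvent]]] = {}
    records: list[ReadClassification] = []
    key_events: dict[str, list[VariantEvent]] = {}
    key_category: dict[str, tuple[Category, Optional[Orientation]]] = {}
    for read in reads:
        mq = read.mean_quality
        if mq is not None and mq < cfg.min_mean_quality:
            records.append(
                ReadClassification(read.read_id, Category.DISCARDED, count=read.count)
            )
            continue
        hit = cache.get(read.sequence)
        if hit is None:
            hit = caller.call_sequence(read.sequence)
            cache[read.sequence] = hit
        cat, orient, key, events = hit
        records.append(
            ReadClassification(
                read.read_id, cat, count=read.count, orientation=orient, variant_key=key
            )
        )
        if cat is not Category.DISCARDED and key not in key_events:
            key_events[key] = [ev for ev in events if ev.in_window]
            key_category[key] = (cat, orient)
    return ClassificationRun(
        design=design, cfg=cfg, records=records,
        key_events=key_events, key_category=key_category,
    )


def write_classifications(records: Sequence[ReadClassification], path) -> None:
    """Write the per-read classification stream as TSV."""
    with open(path, "w") as fh:
        fh.write("read_id\tcount\tcategory\torientation\tvariant_key\n")
        for r in records:
            orient = r.orientation.value if r.orientation else ""
            fh.write(f"{r.read_id}\t{r.count}\t{r.category.value}\t{orient}\t{r.variant_key}\n")
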