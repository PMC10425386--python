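"""Experiment geometry for SpCas9 amplicon editing.

This module represents one editing experiment — a reference amplicon, a
20-nt guide with its NGG PAM, the predicted cut geometry (blunt, or a
staggered cut with a 1-nt 5' overhang) and an optional DNA donor — and
derives the expected knock-in alleles used downstream for read
classification.

Coordinate conventions
----------------------
All coordinates are 0-based, half-open on the amplicon top strand. Cut
sites are inter-base integers: a cut at ``c`` separates ``reference[c-1]``
and ``reference[c]``.

Cut model
---------
SpCas9 nicks the strand base-paired to the guide (the strand *not*
carrying the protospacer) exactly 3 nt 5' of the PAM; this is the classic
blunt cut position and the centre of the quantification window. In
staggered mode the protospacer-carrying strand is instead cut one base
further PAM-distal, which leaves a 1-nt 5' overhang on both fragments. The
overhang base is ``reference[min(top_cut, bottom_cut)]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .errors import AmbiguousGuideError, ArmMismatchError, GuideNotFoundError, PamError

_DNA_RE = re.compile(r"[ACGT]+\Z")
_PAM_RE = re.compile(r"[ACGT]GG\Z")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def _check_dna(seq: str, what: str) -> None:
    if not _DNA_RE.match(seq):
        raise ValueError(f"{what} must be a non-empty A/C/G/T string, got {seq!r}")


class CutMode(str, Enum):
    BLUNT = "blunt"
    STAGGERED_1NT = "staggered_1nt"


class DonorKind(str, Enum):
    SSODN_HDR = "ssodn_hdr"
    DSDNA_BLUNT = "dsdna_blunt"
    DSDNA_OVERHANG = "dsdna_overhang"


@dataclass(frozen=True)
class GuideSpec:
    """A 20-nt SpCas9 protospacer with its NGG PAM.

    Only SpCas9 guides are accepted: the protospacer must be exactly 20 nt
    of unambiguous DNA and the PAM must match NGG. Other nucleases are
    rejected with :class:`PamError` rather than silently mis-modelled.
    """

    name: str
    protospacer: str
    pam: str

    def __post_init__(self) -> None:
        _check_dna(self.protospacer, "protospacer")
        if len(self.protospacer) != 20:
            raise ValueError(
                f"protospacer must be exactly 20 nt, got {len(self.protospacer)}"
            )
        if not _PAM_RE.match(self.pam):
            raise PamError(
                f"PAM {self.pam!r} does not match NGG; only SpCas9 is supported"
            )

    @property
    def target23(self) -> str:
        """The 23-mer protospacer+PAM searched for in the amplicon."""
        return self.protospacer + self.pam


@dataclass(frozen=True)
class CutGeometry:
    """Predicted SpCas9 cut positions as inter-base coordinates.

    ``top_cut`` is the cut on the strand carrying the protospacer,
    ``bottom_cut`` on the opposite strand. Blunt cuts coincide; the
    staggered model separates them by exactly one base, producing a 1-nt
    5' overhang whose identity is ``overhang_base``.
    """

    top_cut: int
    bottom_cut: int
    mode: CutMode
    overhang_base: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode is CutMode.BLUNT and self.top_cut != self.bottom_cut:
            raise ValueError("blunt cut requires top_cut == bottom_cut")
        if self.mode is CutMode.STAGGERED_1NT and abs(self.top_cut - self.bottom_cut) != 1:
            raise ValueError("staggered_1nt cut requires |top_cut - bottom_cut| == 1")

    @property
    def window_center(self) -> int:
        """Centre of the quantification window.

        This is the scissile position 3 nt 5' of the PAM on the
        non-protospacer strand (``bottom_cut``), which coincides with both
        cuts in blunt mode, so the window does not move when switching cut
        models.
        """
        return self.bottom_cut

    @property
    def insertion_site(self) -> int:
        """Inter-base position where donor sequence is modelled to insert."""
        if self.mode is CutMode.BLUNT:
            return self.top_cut
        return min(self.top_cut, self.bottom_cut)


@dataclass(frozen=True)
class DonorSpec:
    """A DNA donor: HDR ssODN with homology arms, or armless dsDNA.

    ``insert`` is the payload to be integrated. For ``ssodn_hdr`` both
    homology arms must be given and must match the reference exactly on
    either side of the integration junction; ``intended_substitutions``
    lists (amplicon position, base) edits carried by the arms, e.g. a
    PAM-blocking mutation. For ``dsdna_overhang``, ``overhang`` is the 1-nt
    5' extension on the payload top strand (forward orientation); when
    omitted it defaults to the base complementary to the staggered-cut
    overhang of the target site.
    """

    kind: DonorKind
    insert: str
    left_arm: str = ""
    right_arm: str = ""
    intended_substitutions: tuple[tuple[int, str], ...] = ()
    overhang: Optional[str] = None

    def __post_init__(self) -> None:
        _check_dna(self.insert, "donor insert")
        if self.kind is DonorKind.SSODN_HDR:
            if not self.left_arm or not self.right_arm:
                raise ValueError("ssODN HDR donor requires both homology arms")
            _check_dna(self.left_arm, "left_arm")
            _check_dna(self.right_arm, "right_arm")
        else:
            if self.left_arm or self.right_arm:
                raise ValueError("dsDNA donors carry no homology arms")
        if self.overhang is not None:
            if self.kind is not DonorKind.DSDNA_OVERHANG:
                raise ValueError("overhang only applies to dsdna_overhang donors")
            _check_dna(self.overhang, "overhang")
            if len(self.overhang) != 1:
                raise ValueError("overhang must be a single base")


@dataclass(frozen=True)
class ExperimentDesign:
    """The coordinate frame for one editing experiment.

    Ties the amplicon to a unique guide placement, the predicted cut
    geometry, the optional donor, and the half-width of the quantification
    window within which variants are attributed to editing (default 8 bp,
    the convention used for short amplicon analyses).
    """

    amplicon_name: str
    reference: str
    guide: GuideSpec
    guide_strand: str
    protospacer_start: int
    cut: CutGeometry
    donor: Optional[DonorSpec] = None
    quant_window: int = 8

    def __post_init__(self) -> None:
        _check_dna(self.reference, "reference")
        if self.guide_strand not in "+-":
            raise ValueError("guide_strand must be '+' or '-'")
        if self.quant_window < 1:
            raise ValueError("quant_window must be >= 1")
        strand, start = locate_protospacer(self.reference, self.guide)
        if (strand, start) != (self.guide_strand, self.protospacer_start):
            raise ValueError(
                "guide placement inconsistent with reference "
                f"(expected {(strand, start)}, got {(self.guide_strand, self.protospacer_start)})"
            )
        lo, hi = self.window
        if lo < 0 or hi > len(self.reference):
            raise ValueError("quantification window extends outside the reference")

    @property
    def window(self) -> tuple[int, int]:
        """Half-open interval [center - w, center + w) on the amplicon."""
        c = self.cut.window_center
        return (c - self.quant_window, c + self.quant_window)

    @classmethod
    def from_components(
        cls,
        reference: str,
        guide: GuideSpec,
        donor: Optional[DonorSpec] = None,
        cut_mode: CutMode = CutMode.BLUNT,
        quant_window: int = 8,
        amplicon_name: str = "amplicon",
    ) -> "ExperimentDesign":
        """Locate the guide, predict the cut and assemble a design."""
        strand, start = locate_protospacer(reference, guide)
        cut = predict_cut(strand, start, cut_mode, reference)
        return cls(
            amplicon_name=amplicon_name,
            reference=reference,
            guide=guide,
            guide_strand=strand,
            protospacer_start=start,
            cut=cut,
            donor=donor,
            quant_window=quant_window,
        )


@dataclass(frozen=True)
class AlleleModel:
    """Expected edited sequences derived from reference + donor.

    ``hdr_allele`` is defined only for ssODN donors; ``nhej_ki_fwd`` /
    ``nhej_ki_rev`` only for dsDNA donors. ``insert_coords`` maps allele
    name to the half-open interval occupied by the inserted segment in
    that allele's own coordinates.
    """

    reference: str
    hdr_allele: Optional[str] = None
    nhej_ki_fwd: Optional[str] = None
    nhej_ki_rev: Optional[str] = None
    insert_coords: dict[str, tuple[int, int]] = field(default_factory=dict)


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def locate_protospacer(reference: str, guide: GuideSpec) -> tuple[str, int]:
    """Find the unique placement of protospacer+PAM in the amplicon.

    Returns ``(strand, protospacer_start)`` where ``protospacer_start`` is
    the 0-based start of the protospacer (or of its reverse complement for
    '-' placements) on the amplicon top strand. The match must be exact
    and unique; mismatched guides are an error because the entire
    classification frame depends on the placement.
    """
    if len(reference) < 23:
        raise ValueError("reference must be at least 23 nt")
    fwd = _find_all(reference, guide.target23)
    rev = _find_all(reference, revcomp(guide.target23))
    n = len(fwd) + len(rev)
    if n == 0:
        raise GuideNotFoundError(
            f"protospacer+PAM for guide {guide.name!r} not found in reference"
        )
    if n > 1:
        raise AmbiguousGuideError(
            f"protospacer+PAM for guide {guide.name!r} occurs {n} times in reference"
        )
    if fwd:
        return "+", fwd[0]
    # rc(protospacer+PAM) = rc(PAM) + rc(protospacer): the protospacer's own
    # reverse complement starts 3 nt into the matched 23-mer.
    return "-", rev[0] + 3


def predict_cut(
    strand: str,
    protospacer_start: int,
    mode: CutMode = CutMode.BLUNT,
    reference: Optional[str] = None,
) -> CutGeometry:
    """Predict SpCas9 cut coordinates for a located guide.

    Blunt: both strands cut 3 nt 5' of the PAM (between protospacer
    positions 17 and 18). Staggered: the protospacer-carrying strand is
    cut one base PAM-distal, yielding a 1-nt 5' overhang. Passing the
    reference fills in the overhang base.
    """
    mode = CutMode(mode)
    ps = protospacer_start
    if strand == "+":
        blunt = ps + 17
        top, bottom = (blunt, blunt) if mode is CutMode.BLUNT else (ps + 16, blunt)
    elif strand == "-":
        blunt = ps + 3
        top, bottom = (blunt, blunt) if mode is CutMode.BLUNT else (ps + 4, blunt)
    else:
        raise ValueError("strand must be '+' or '-'")
    base = None
    if mode is CutMode.STAGGERED_1NT and reference is not None:
        base = reference[min(top, bottom)]
    return CutGeometry(top_cut=top, bottom_cut=bottom, mode=mode, overhang_base=base)


def _apply_substitutions(reference: str, subs: tuple[tuple[int, str], ...]) -> str:
    seq = list(reference)
    for pos, base in subs:
        if not (0 <= pos < len(seq)):
            raise ValueError(f"intended substitution position {pos} outside reference")
        _check_dna(base, "substitution base")
        seq[pos] = base
    return "".join(seq)


def build_allele_model(design: ExperimentDesign, arm_search_radius: int = 20) -> AlleleModel:
    """Derive the expected knock-in alleles for a design with a donor.

    ssODN donors yield one seamless HDR allele: the payload spliced in at
    the junction defined by the homology arms, with the intended
    substitutions applied to the flanks. Armless dsDNA donors yield two
    end-capture alleles, one per payload orientation, inserted at the cut.

    For a staggered cut with an overhang donor, ligation of the donor's
    1-nt 5' overhang into the matching genomic overhang is modelled
    explicitly: each 5' end anneals flush with its complementary partner,
    so the compatible (forward) orientation produces seamless junctions in
    which the donor contributes its overhang base alongside the payload.
    The flipped orientation presents non-complementary overhangs and
    carries a 1-nt junction anomaly (a non-reference base at the left
    junction).
    """
    donor = design.donor
    if donor is None:
        raise ValueError("design has no donor; no knock-in alleles to build")
    ref = design.reference

    if donor.kind is DonorKind.SSODN_HDR:
        center = design.cut.window_center
        la, ra = donor.left_arm, donor.right_arm
        junction = None
        for j in range(max(len(la), center - arm_search_radius),
                       min(len(ref) - len(ra), center + arm_search_radius) + 1):
            if ref[j - len(la):j] == la and ref[j:j + len(ra)] == ra:
                junction = j
                break
        if junction is None:
            raise ArmMismatchError(
                "homology arms not found flanking the cut within "
                f"{arm_search_radius} bp of position {center}"
            )
        subbed = _apply_substitutions(ref, donor.intended_substitutions)
        hdr = subbed[:junction] + donor.insert + subbed[junction:]
        return AlleleModel(
            reference=ref,
            hdr_allele=hdr,
            insert_coords={"hdr": (junction, junction + len(donor.insert))},
        )

    site = design.cut.insertion_site
    if donor.kind is DonorKind.DSDNA_BLUNT:
        fwd_seg = donor.insert
        rev_seg = revcomp(donor.insert)
    else:  # DSDNA_OVERHANG
        if design.cut.mode is not CutMode.STAGGERED_1NT:
            raise ValueError("dsdna_overhang donor requires a staggered_1nt cut")
        b = donor.overhang if donor.overhang is not None else ref[site]
        fwd_seg = b + donor.insert
        rev_seg = complement_base(b) + revcomp(donor.insert)
    fwd = ref[:site] + fwd_seg + ref[site:]
    rev = ref[:site] + rev_seg + ref[site:]
    return AlleleModel(
        reference=ref,
        nhej_ki_fwd=fwd,
        nhej_ki_rev=rev,
        insert_coords={
            "nhej_ki_fwd": (site, site + len(fwd_seg)),
            "nhej_ki_rev": (site, site + len(rev_seg)),
        },
    )
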