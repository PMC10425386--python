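"""Synthetic fixtures and reads with ground-truth repair outcomes.

The generator builds random amplicons carrying a unique SpCas9 target
site and an engineered repeat so that a designed deletion at the cut has
a junction microhomology of exactly the requested length, then emits
reads drawn i.i.d. from a stated mixture of repair outcomes:

* ``UNMODIFIED``         — the reference sequence;
* ``NHEJ_plus1``         — duplication of the base 5' of the cut, the
                           canonical template-independent +1 insertion;
* ``NHEJ_minus1``        — deletion of the base 5' of the cut;
* ``MH_DEL``             — the engineered microhomology-flanked deletion;
* ``NHEJ_KI_fwd/rev``    — donor payload captured at the cut in either
                           orientation;
* ``HDR_KI``             — the seamless homology-templated allele
                           (requires an ssODN donor);
* ``OTHER_multi_indel``  — a -1 deletion at the cut plus a +1 insertion
                           5 bp away, guaranteeing the multi-indel
                           fall-through class.

Sequencing noise is a uniform per-base substitution process
(amplicon short-read error profiles are substitution-dominated); indel
errors default to off so category ground truth stays well defined. Read
length equals the template length, emulating merged paired-end reads.
Identical (design, mixture, seed) inputs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .align import ReadRecord
from .classify import (
    Category,
    ClassifierConfig,
    Orientation,
    classify_reads,
    mh_length,
)
from .errors import ConstructionFailureError, InconsistentSpecError
from .longread import LongReadAlignment
from .model import (
    AlleleModel,
    CutMode,
    DonorKind,
    DonorSpec,
    ExperimentDesign,
    GuideSpec,
    build_allele_model,
    revcomp,
)

MIXTURE_CLASSES = (
    "UNMODIFIED",
    "NHEJ_plus1",
    "NHEJ_minus1",
    "MH_DEL",
    "NHEJ_KI_fwd",
    "NHEJ_KI_rev",
    "HDR_KI",
    "OTHER_multi_indel",
)

_TRUE_CATEGORY = {
    "UNMODIFIED": Category.UNMODIFIED,
    "NHEJ_plus1": Category.NHEJ,
    "NHEJ_minus1": Category.NHEJ,
    "MH_DEL": Category.MH_DEL,
    "NHEJ_KI_fwd": Category.NHEJ_KI,
    "NHEJ_KI_rev": Category.NHEJ_KI,
    "HDR_KI": Category.HDR_KI,
    "OTHER_multi_indel": Category.OTHER,
}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class MixtureSpec:
    """A mixture of repair outcomes to draw reads from."""

    proportions: dict[str, float]
    n_reads: int
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.proportions) - set(MIXTURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown mixture classes: {sorted(unknown)}")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("mixture proportions must be non-negative")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions sum to {total}, expected 1")
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


@dataclass(frozen=True)
class TruthLabel:
    read_id: str
    true_class: str
    true_category: Category
    true_orientation: Optional[Orientation]
    true_variant_key: str


@dataclass(frozen=True)
class FixtureTruth:
    """Ground truth attached to a generated fixture design."""

    design: ExperimentDesign
    mh_del_interval: tuple[int, int]
    mh_len: int


def _random_dna(rng: np.random.Generator, n: int) -> list[str]:
    return [b.decode() for b in rng.choice(_BASES, size=n)]


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(3))]


def build_templates(
    design: ExperimentDesign, alleles: Optional[AlleleModel]
) -> dict[str, str]:
    """Ground-truth template sequence for each available mixture class."""
    ref = design.reference
    c = design.cut.window_center
    templates = {
        "UNMODIFIED": ref,
        "NHEJ_plus1": ref[:c] + ref[c - 1] + ref[c:],
        "NHEJ_minus1": ref[: c - 1] + ref[c:],
        "OTHER_multi_indel": (
            ref[: c - 1] + ref[c : c + 5] + "T" + ref[c + 5 :]
            if ref[c + 4] != "T"
            else ref[: c - 1] + ref[c : c + 5] + "A" + ref[c + 5 :]
        ),
    }
    if alleles is not None:
        if alleles.hdr_allele is not None:
            templates["HDR_KI"] = alleles.hdr_allele
            # armless end-capture of the same payload (blunt ligation at
            # the cut) remains possible in an ssODN experiment
            ins = design.donor.insert
            templates["NHEJ_KI_fwd"] = ref[:c] + ins + ref[c:]
            templates["NHEJ_KI_rev"] = ref[:c] + revcomp(ins) + ref[c:]
        else:
            templates["NHEJ_KI_fwd"] = alleles.nhej_ki_fwd
            templates["NHEJ_KI_rev"] = alleles.nhej_ki_rev
    return templates


def _mh_del_template(fixture: FixtureTruth) -> str:
    s, e = fixture.mh_del_interval
    ref = fixture.design.reference
    return ref[:s] + ref[e:]


def _mh_del_category(fixture: FixtureTruth, cfg: Optional[ClassifierConfig] = None) -> Category:
    """True category of the engineered deletion under the classifier
    thresholds: MH_DEL only when it is long enough and has enough junction
    homology; a 1-bp deletion is NHEJ; anything else is OTHER."""
    cfg = cfg or ClassifierConfig()
    s, e = fixture.mh_del_interval
    del_len = e - s
    if del_len <= cfg.nhej_indel_max:
        return Category.NHEJ
    if del_len >= cfg.mh_del_min_len and fixture.mh_len >= cfg.mh_min:
        return Category.MH_DEL
    return Category.OTHER


def make_fixture(
    seed: int,
    mh_len: int = 3,
    del_len: int = 3,
    length: int = 200,
    donor_kind: DonorKind | str = DonorKind.SSODN_HDR,
    cut_mode: CutMode | str = CutMode.BLUNT,
    insert_len: int = 34,
    arm_len: int = 20,
    max_attempts: int = 200,
) -> FixtureTruth:
    """Construct a random experiment design with engineered microhomology.

    The amplicon carries a unique protospacer+NGG placement with the cut
    near the middle, and a repeat such that deleting ``del_len`` bases at
    the cut leaves exactly ``mh_len`` bases of junction microhomology
    (verified against :func:`mh_length` at construction). The donor is an
    ssODN with homology arms and a PAM-blocking intended substitution, or
    an armless dsDNA payload. Every candidate fixture is self-checked:
    all available outcome templates must classify correctly at zero
    noise, otherwise construction retries with fresh draws.
    """
    donor_kind = DonorKind(donor_kind)
    cut_mode = CutMode(cut_mode)
    if mh_len < 0 or del_len < 1 or mh_len > del_len:
        raise ValueError("require 0 <= mh_len <= del_len and del_len >= 1")
    if mh_len > 4:
        raise ValueError("engineered microhomology is limited to 4 bp (PAM would be overwritten)")
    if del_len > 8:
        raise ValueError("engineered deletion must stay inside the quantification window (<= 8 bp)")
    if length < 150:
        raise ValueError("fixture length must be >= 150")
    if donor_kind is DonorKind.DSDNA_OVERHANG and cut_mode is not CutMode.STAGGERED_1NT:
        raise ValueError("dsdna_overhang fixtures require staggered_1nt cut mode")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        fixture = _try_fixture(
            rng, mh_len, del_len, length, donor_kind, cut_mode, insert_len, arm_len
        )
        if fixture is not None:
            return fixture
    raise ConstructionFailureError(
        f"could not build a valid fixture in {max_attempts} attempts (seed={seed})"
    )


def _try_fixture(
    rng: np.random.Generator,
    mh_len: int,
    del_len: int,
    length: int,
    donor_kind: DonorKind,
    cut_mode: CutMode,
    insert_len: int,
    arm_len: int,
) -> Optional[FixtureTruth]:
    seq = _random_dna(rng, length)
    ps = length // 2 - 17  # protospacer start; blunt cut lands mid-amplicon
    seq[ps + 21] = "G"
    seq[ps + 22] = "G"
    c = ps + 17
    # engineered deletion sits PAM-distal of the cut so the repeat copy
    # cannot clobber the PAM GG
    s, e = c - del_len, c
    # engineer the junction: exactly mh_len bases of homology to the right,
    # none to the left
    for k in range(mh_len):
        seq[e + k] = seq[s + k]
    if seq[e + mh_len] == seq[s + mh_len]:
        seq[e + mh_len] = _other_base(rng, seq[s + mh_len])
    if seq[s - 1] == seq[e - 1]:
        seq[s - 1] = _other_base(rng, seq[e - 1])
    seq[ps + 21] = "G"
    seq[ps + 22] = "G"
    reference = "".join(seq)
    if mh_length(reference, s, e) != mh_len:
        return None

    guide = GuideSpec(
        name="sim_guide", protospacer=reference[ps : ps + 20], pam=reference[ps + 20 : ps + 23]
    )
    insert = "".join(_random_dna(rng, insert_len))
    if donor_kind is DonorKind.SSODN_HDR:
        donor = DonorSpec(
            kind=donor_kind,
            insert=insert,
            left_arm=reference[c - arm_len : c],
            right_arm=reference[c : c + arm_len],
            intended_substitutions=((ps + 21, "C"),),  # PAM-blocking edit
        )
    else:
        donor = DonorSpec(kind=donor_kind, insert=insert)

    try:
        design = ExperimentDesign.from_components(
            reference, guide, donor=donor, cut_mode=cut_mode, amplicon_name="sim_amplicon"
        )
    except Exception:
        return None
    fixture = FixtureTruth(design=design, mh_del_interval=(s, e), mh_len=mh_len)
    if not _self_check(fixture):
        return None
    return fixture


def _self_check(fixture: FixtureTruth) -> bool:
    """Zero-noise identifiability: every template classifies correctly."""
    design = fixture.design
    alleles = build_allele_model(design) if design.donor else None
    templates = build_templates(design, alleles)
    templates["MH_DEL"] = _mh_del_template(fixture)
    expected = dict(_TRUE_CATEGORY)
    expected["MH_DEL"] = _mh_del_category(fixture)
    reads = [ReadRecord(read_id=name, sequence=seq) for name, seq in templates.items()]
    run = classify_reads(reads, design, alleles=alleles)
    for rec in run.records:
        if rec.category is not expected[rec.read_id]:
            return False
        if rec.category is Category.NHEJ_KI:
            want = Orientation.FORWARD if rec.read_id.endswith("fwd") else Orientation.REVERSE
            if rec.orientation is not want:
                return False
    return True


def simulate_reads(
    fixture: FixtureTruth, mix: MixtureSpec
) -> tuple[list[ReadRecord], list[TruthLabel]]:
    """Draw reads i.i.d. from the mixture with substitution errors.

    Deterministic given (fixture, mixture): the RNG is seeded solely from
    ``mix.seed``. Raises :class:`InconsistentSpecError` when a knock-in
    class has positive mass but the design lacks the required donor.
    """
    design = fixture.design
    alleles = build_allele_model(design) if design.donor else None
    templates = build_templates(design, alleles)
    templates["MH_DEL"] = _mh_del_template(fixture)

    active = [(name, p) for name, p in sorted(mix.proportions.items()) if p > 0]
    for name, _ in active:
        if name not in templates:
            raise InconsistentSpecError(
                f"mixture class {name} has positive mass but the design "
                "provides no template for it (missing or wrong donor kind)"
            )

    truth_keys = _truth_variant_keys(fixture, templates, [n for n, _ in active])
    true_cats = dict(_TRUE_CATEGORY)
    true_cats["MH_DEL"] = _mh_del_category(fixture)

    rng = np.random.default_rng(mix.seed)
    names = [n for n, _ in active]
    probs = np.array([p for _, p in active], dtype=float)
    probs = probs / probs.sum()
    draws = rng.choice(len(names), size=mix.n_reads, p=probs)

    reads: list[ReadRecord] = []
    labels: list[TruthLabel] = []
    for i, k in enumerate(draws):
        name = names[int(k)]
        seq = templates[name]
        if mix.error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            hits = np.nonzero(rng.random(arr.size) < mix.error_rate)[0]
            for pos in hits:
                cur = arr[pos].decode()
                arr[pos] = _other_base(rng, cur).encode()
            seq = arr.tobytes().decode()
        else:
            # burn no RNG draws at zero noise: category sequence stays
            # aligned with the error-free limit of the same seed
            pass
        read_id = f"sim_{i:06d}"
        reads.append(ReadRecord(read_id=read_id, sequence=seq))
        orientation = (
            Orientation.FORWARD
            if name == "NHEJ_KI_fwd"
            else Orientation.REVERSE if name == "NHEJ_KI_rev" else None
        )
        labels.append(
            TruthLabel(
                read_id=read_id,
                true_class=name,
                true_category=true_cats[name],
                true_orientation=orientation,
                true_variant_key=truth_keys[name],
            )
        )
    return reads, labels


def _truth_variant_keys(
    fixture: FixtureTruth, templates: dict[str, str], active: Sequence[str]
) -> dict[str, str]:
    """Canonical variant key of each noise-free template."""
    design = fixture.design
    alleles = build_allele_model(design) if design.donor else None
    reads = [ReadRecord(read_id=name, sequence=templates[name]) for name in active]
    run = classify_reads(reads, design, alleles=alleles)
    return {rec.read_id: rec.variant_key for rec in run.records}


def simulate_long_reads(
    amplicon_length: int,
    large_del_fraction: float,
    del_interval: tuple[int, int],
    n_reads: int,
    seed: int,
) -> list[LongReadAlignment]:
    """Aligned long reads over the amplicon, a fraction carrying one
    large deletion; the rest span the amplicon fully. Deterministic."""
    if not (0.0 <= large_del_fraction <= 1.0):
        raise ValueError("large_del_fraction must be in [0, 1]")
    ds, de = del_interval
    if not (0 <= ds < de <= amplicon_length):
        raise ValueError("del_interval must lie within the amplicon")
    rng = np.random.default_rng(seed)
    carry = rng.random(n_reads) < large_del_fraction
    out: list[LongReadAlignment] = []
    for i in range(n_reads):
        dels = ((ds, de),) if carry[i] else ()
        out.append(
            LongReadAlignment(
                read_id=f"lr_{i:06d}", start=0, end=amplicon_length, deletions=dels
            )
        )
    return out


# ---------------------------------------------------------------------------
# writers


def write_fastq(reads: Sequence[ReadRecord], path: str | Path, quality: int = 40) -> None:
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qchar * len(r.sequence)}\n")


def write_truth(labels: Sequence[TruthLabel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttrue_class\ttrue_category\ttrue_orientation\ttrue_variant_key\n")
        for t in labels:
            orient = t.true_orientation.value if t.true_orientation else ""
            fh.write(
                f"{t.read_id}\t{t.true_class}\t{t.true_category.value}\t{orient}\t{t.true_variant_key}\n"
            )
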