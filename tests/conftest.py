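"""Shared fixtures: a small hand-built design and simulator fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from editcall import (
    CutMode,
    DonorKind,
    DonorSpec,
    ExperimentDesign,
    GuideSpec,
    make_fixture,
)

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def simple_design() -> ExperimentDesign:
    """Deterministic 160-bp amplicon with a '+' strand guide.

    Protospacer at [70, 90), PAM AGG at [90, 93), blunt cut at 87.
    """
    rng = np.random.default_rng(7)
    seq = list(random_dna(rng, 160))
    proto = "GACTTGCACGTATCGGTCAA"
    seq[70:90] = list(proto)
    seq[90:93] = list("AGG")
    reference = "".join(seq)
    guide = GuideSpec(name="g1", protospacer=proto, pam="AGG")
    design = ExperimentDesign.from_components(reference, guide, amplicon_name="amp1")
    assert design.cut.top_cut == 87
    return design


@pytest.fixture(scope="session")
def ssodn_fixture():
    """Simulator fixture with ssODN donor (all 8 mixture classes available)."""
    return make_fixture(seed=11)


@pytest.fixture(scope="session")
def dsdna_fixture():
    """Simulator fixture with a blunt armless dsDNA donor."""
    return make_fixture(seed=13, donor_kind=DonorKind.DSDNA_BLUNT)


@pytest.fixture(scope="session")
def overhang_fixture():
    """Staggered-cut fixture with a 1-nt 5' overhang dsDNA donor."""
    return make_fixture(
        seed=17, donor_kind=DonorKind.DSDNA_OVERHANG, cut_mode=CutMode.STAGGERED_1NT
    )


def make_ssodn_donor(design: ExperimentDesign, insert: str, arm: int = 20,
                     subs=()) -> DonorSpec:
    c = design.cut.window_center
    return DonorSpec(
        kind=DonorKind.SSODN_HDR,
        insert=insert,
        left_arm=design.reference[c - arm : c],
        right_arm=design.reference[c : c + arm],
        intended_substitutions=tuple(subs),
    )
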