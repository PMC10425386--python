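"""Flat key=value configuration files tying the pipeline together.

One config file describes an experiment (amplicon FASTA or inline
reference, guide, donor, cut model, quantification window) plus optional
classifier and alignment-scoring overrides. Lines are ``key = value``;
``#`` starts a comment. FASTA files are read with Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio import SeqIO

from .align import ScoringParams
from .classify import ClassifierConfig
from .model import (
    CutMode,
    DonorKind,
    DonorSpec,
    ExperimentDesign,
    GuideSpec,
)

_DESIGN_KEYS = {
    "amplicon_fasta", "amplicon_name", "reference",
    "guide_name", "protospacer", "pam",
    "donor_kind", "donor_fasta", "donor_insert", "donor_left_arm",
    "donor_right_arm", "donor_overhang", "intended_substitutions",
    "cut_mode", "quant_window",
}
_CLASSIFIER_KEYS = {
    "mh_min", "mh_del_min_len", "nhej_indel_max", "donor_min_identity",
    "hdr_requires_perfect_window", "min_mean_quality", "mapped_score_frac",
}
_SCORING_KEYS = {"match", "mismatch", "gap_open", "gap_extend"}


def parse_flat_config(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip().lower()] = value.strip()
    return out


def _read_single_fasta(path: str | Path) -> tuple[str, str]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    return records[0].id, str(records[0].seq).upper()


def _parse_substitutions(text: str) -> tuple[tuple[int, str], ...]:
    """'pos:base' pairs, comma separated, e.g. '104:C,110:T'."""
    out = []
    for item in text.split(","):
        item = item.strip()
        if not item:
            continue
        pos_s, base = item.split(":")
        out.append((int(pos_s), base.strip().upper()))
    return tuple(out)


def _parse_bool(text: str) -> bool:
    val = text.strip().lower()
    if val in ("true", "yes", "1"):
        return True
    if val in ("false", "no", "0"):
        return False
    raise ValueError(f"expected a boolean, got {text!r}")


@dataclass
class RunConfig:
    design: ExperimentDesign
    classifier: ClassifierConfig
    scoring: ScoringParams


def load_run_config(path: str | Path) -> RunConfig:
    """Build the experiment design and thresholds from one config file."""
    cfg = parse_flat_config(path)
    unknown = set(cfg) - _DESIGN_KEYS - _CLASSIFIER_KEYS - _SCORING_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    base = Path(path).parent

    if "reference" in cfg:
        reference = cfg["reference"].upper()
        name = cfg.get("amplicon_name", "amplicon")
    elif "amplicon_fasta" in cfg:
        fasta = base / cfg["amplicon_fasta"]
        name, reference = _read_single_fasta(fasta)
        name = cfg.get("amplicon_name", name)
    else:
        raise ValueError(f"{path}: need 'reference' or 'amplicon_fasta'")

    guide = GuideSpec(
        name=cfg.get("guide_name", "guide"),
        protospacer=cfg["protospacer"].upper(),
        pam=cfg["pam"].upper(),
    )

    donor: Optional[DonorSpec] = None
    if "donor_kind" in cfg:
        kind = DonorKind(cfg["donor_kind"])
        if "donor_fasta" in cfg:
            _, insert = _read_single_fasta(base / cfg["donor_fasta"])
        else:
            insert = cfg["donor_insert"].upper()
        donor = DonorSpec(
            kind=kind,
            insert=insert,
            left_arm=cfg.get("donor_left_arm", "").upper(),
            right_arm=cfg.get("donor_right_arm", "").upper(),
            intended_substitutions=_parse_substitutions(
                cfg.get("intended_substitutions", "")
            ),
            overhang=cfg.get("donor_overhang", "").upper() or None,
        )

    design = ExperimentDesign.from_components(
        reference=reference,
        guide=guide,
        donor=donor,
        cut_mode=CutMode(cfg.get("cut_mode", "blunt")),
        quant_window=int(cfg.get("quant_window", 8)),
        amplicon_name=name,
    )

    classifier = ClassifierConfig(
        mh_min=int(cfg.get("mh_min", 2)),
        mh_del_min_len=int(cfg.get("mh_del_min_len", 2)),
        nhej_indel_max=int(cfg.get("nhej_indel_max", 1)),
        donor_min_identity=float(cfg.get("donor_min_identity", 0.90)),
        hdr_requires_perfect_window=_parse_bool(
            cfg.get("hdr_requires_perfect_window", "true")
        ),
        min_mean_quality=float(cfg.get("min_mean_quality", 20.0)),
        mapped_score_frac=float(cfg.get("mapped_score_frac", 0.60)),
    )
    scoring = ScoringParams(
        match=float(cfg.get("match", 2.0)),
        mismatch=float(cfg.get("mismatch", -2.0)),
        gap_open=float(cfg.get("gap_open", -10.0)),
        gap_extend=float(cfg.get("gap_extend", -1.0)),
    )
    return RunConfig(design=design, classifier=classifier, scoring=scoring)


def save_design_config(design: ExperimentDesign, path: str | Path) -> None:
    """Serialize a design to the same flat format :func:`load_run_config` reads."""
    lines = [
        f"amplicon_name = {design.amplicon_name}",
        f"reference = {design.reference}",
        f"guide_name = {design.guide.name}",
        f"protospacer = {design.guide.protospacer}",
        f"pam = {design.guide.pam}",
        f"cut_mode = {design.cut.mode.value}",
        f"quant_window = {design.quant_window}",
    ]
    donor = design.donor
    if donor is not None:
        lines.append(f"donor_kind = {donor.kind.value}")
        lines.append(f"donor_insert = {donor.insert}")
        if donor.left_arm:
            lines.append(f"donor_left_arm = {donor.left_arm}")
        if donor.right_arm:
            lines.append(f"donor_right_arm = {donor.right_arm}")
        if donor.intended_substitutions:
            subs = ",".join(f"{p}:{b}" for p, b in donor.intended_substitutions)
            lines.append(f"intended_substitutions = {subs}")
        if donor.overhang:
            lines.append(f"donor_overhang = {donor.overhang}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_mixture_config(path: str | Path):
    """Read a mixture file: class proportions plus n_reads / error_rate / seed."""
    from .simulate import MIXTURE_CLASSES, MixtureSpec

    cfg = parse_flat_config(path)
    props = {}
    for name in MIXTURE_CLASSES:
        key = name.lower()
        if key in cfg:
            props[name] = float(cfg.pop(key))
    unknown = set(cfg) - {"n_reads", "error_rate", "seed"}
    if unknown:
        raise ValueError(f"{path}: unknown mixture keys: {sorted(unknown)}")
    return MixtureSpec(
        proportions=props,
        n_reads=int(cfg.get("n_reads", 1000)),
        error_rate=float(cfg.get("error_rate", 0.0)),
        seed=int(cfg.get("seed", 0)),
    )
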