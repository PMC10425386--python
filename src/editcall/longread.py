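"""Large-deletion statistics for long-read amplicons.

Kilobase-scale deletions around a cut site deplete per-base coverage
relative to the number of reads. With ``Ct`` unique reads aligned within
the amplicon and ``Cm`` the mean per-base coverage, the deletion
proportion is ``(Ct - Cm) / Ct`` — 0 when every read spans every base,
approaching 1 as deletions remove more of the aligned footprint. The
deletion index is the difference in deletion proportion between a
treated and a control sample.

Inputs are either pre-aligned long reads (reference span plus deletion
segments, e.g. from the simulator) or a per-base coverage TSV with a
``#Ct=`` manifest line; alignment of real long reads is delegated
upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np


@dataclass(frozen=True)
class LongReadAlignment:
    """One aligned long read: reference span and deletion segments."""

    read_id: str
    start: int
    end: int
    deletions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid read span")
        for s, e in self.deletions:
            if not (self.start <= s < e <= self.end):
                raise ValueError("deletion segment outside read span")


@dataclass
class CoverageProfile:
    """Per-base depth over the amplicon plus the unique-read count Ct."""

    depth: np.ndarray
    unique_reads: int

    @property
    def amplicon_length(self) -> int:
        return int(self.depth.size)

    @property
    def mean_depth(self) -> float:
        """Cm: mean per-base read coverage of the amplicon."""
        return float(self.depth.mean())


@dataclass(frozen=True)
class DeletionStats:
    deletion_proportion: float
    deletion_index: Optional[float] = None


def coverage_from_alignments(
    alignments: Iterable[LongReadAlignment],
    amplicon_length: int,
    min_span_fraction: float = 0.0,
) -> CoverageProfile:
    """Per-base depth and unique-read count from aligned long reads.

    ``depth[i]`` counts reads whose alignment covers base ``i`` outside
    any deletion segment. Every read whose span intersects the amplicon
    counts toward Ct unless it covers less than ``min_span_fraction`` of
    the amplicon (default 0: any overlapping read counts).
    """
    diff = np.zeros(amplicon_length + 1, dtype=np.int64)
    seen: set[str] = set()
    for aln in alignments:
        s, e = max(aln.start, 0), min(aln.end, amplicon_length)
        if e <= s:
            continue
        if (e - s) / amplicon_length < min_span_fraction:
            continue
        seen.add(aln.read_id)
        diff[s] += 1
        diff[e] -= 1
        for ds, de in aln.deletions:
            ds, de = max(ds, 0), min(de, amplicon_length)
            if de > ds:
                diff[ds] -= 1
                diff[de] += 1
    depth = np.cumsum(diff[:-1])
    return CoverageProfile(depth=depth, unique_reads=len(seen))


def deletion_proportion(profile: CoverageProfile) -> float:
    """(Ct - Cm) / Ct for one sample."""
    ct = profile.unique_reads
    if ct == 0:
        raise ZeroDivisionError("no reads aligned within the amplicon (Ct == 0)")
    return (ct - profile.mean_depth) / ct


def deletion_index(treated: DeletionStats, control: DeletionStats) -> float:
    """Difference in deletion proportion, treated minus control."""
    return treated.deletion_proportion - control.deletion_proportion


def stats_from_profile(
    profile: CoverageProfile, control: Optional[CoverageProfile] = None
) -> DeletionStats:
    dp = deletion_proportion(profile)
    if control is None:
        return DeletionStats(deletion_proportion=dp)
    dc = deletion_proportion(control)
    return DeletionStats(deletion_proportion=dp, deletion_index=dp - dc)


# ---------------------------------------------------------------------------
# coverage TSV interchange: "#Ct=<int>" manifest line, then pos<TAB>depth


def write_coverage_tsv(profile: CoverageProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#Ct={profile.unique_reads}\n")
        fh.write("pos\tdepth\n")
        for pos, d in enumerate(profile.depth):
            fh.write(f"{pos}\t{int(d)}\n")


def read_coverage_tsv(path: str | Path) -> CoverageProfile:
    ct: Optional[int] = None
    positions: list[int] = []
    depths: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.lower().startswith("#ct="):
                    ct = int(line.split("=", 1)[1])
                continue
            if line.lower().startswith("pos"):
                continue
            pos_s, depth_s = line.split("\t")
            positions.append(int(pos_s))
            depths.append(int(depth_s))
    if ct is None:
        raise ValueError(f"{path}: missing '#Ct=' manifest line")
    if positions != list(range(len(positions))):
        raise ValueError(f"{path}: positions must be 0-based and contiguous")
    return CoverageProfile(depth=np.asarray(depths, dtype=np.int64), unique_reads=ct)
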