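"""Aggregation of read classifications into reported quantities.

Produces the per-category outcome table (counts, fractions of mapped and
of mutated reads), the HDR:InDel ratio, and the top-variant profile that
renders the most frequent alleles across a +/-30 bp window around the
cut site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .align import EventType, VariantEvent
from .classify import (
    MAPPED_CATEGORIES,
    Category,
    ClassificationRun,
    Orientation,
    ReadClassification,
)
from .errors import EmptyInputError
from .model import ExperimentDesign


@dataclass
class OutcomeTable:
    """Per-category counts and fractions for one sample.

    ``fraction_of_mapped`` sums to 1 over the six mapped categories
    (UNMODIFIED included); ``fraction_of_mutated`` is defined over the
    non-UNMODIFIED categories and is all zeros, with
    ``mutated_fractions_defined`` False, when every read is unmodified.
    """

    counts: dict[Category, int]
    mapped_reads: int
    mutated_reads: int
    fraction_of_mapped: dict[Category, float]
    fraction_of_mutated: dict[Category, float]
    mutated_fractions_defined: bool = True

    @property
    def discarded(self) -> int:
        return self.counts.get(Category.DISCARDED, 0)

    @property
    def total_reads(self) -> int:
        return self.mapped_reads + self.discarded


def tabulate(classifications: Iterable[ReadClassification]) -> OutcomeTable:
    """Aggregate a stream of classifications into an outcome table.

    Exact integer counting; invariant to input order and to splitting the
    stream (tabulating a concatenation equals merging partial tables).
    """
    counts: dict[Category, int] = {cat: 0 for cat in Category}
    for rec in classifications:
        counts[rec.category] += rec.count
    return table_from_counts(counts)


def table_from_counts(category_counts: dict[Category, int]) -> OutcomeTable:
    """Build an outcome table directly from per-category counts."""
    counts = {cat: int(category_counts.get(cat, 0)) for cat in Category}
    mapped = sum(counts[c] for c in MAPPED_CATEGORIES)
    if mapped == 0:
        raise EmptyInputError("no mapped reads to tabulate")
    mutated = mapped - counts[Category.UNMODIFIED]
    frac_mapped = {c: counts[c] / mapped for c in MAPPED_CATEGORIES}
    defined = mutated > 0
    frac_mutated = {
        c: (counts[c] / mutated if defined else 0.0)
        for c in MAPPED_CATEGORIES
        if c is not Category.UNMODIFIED
    }
    return OutcomeTable(
        counts=counts,
        mapped_reads=mapped,
        mutated_reads=mutated,
        fraction_of_mapped=frac_mapped,
        fraction_of_mutated=frac_mutated,
        mutated_fractions_defined=defined,
    )


def hdr_indel_ratio(table: OutcomeTable, include_nhej_ki: bool = False) -> float:
    """HDR_KI fraction divided by the mutagenic-InDel fraction.

    The denominator pools NHEJ, MH_DEL and OTHER — the mutagenic non-KI
    outcomes an experimenter wants to minimise; NHEJ_KI is excluded by
    default (it is a templated insertion, not a scar) but can be pooled
    in via ``include_nhej_ki``. Zero HDR gives 0.0; a zero denominator
    with non-zero HDR is reported as infinity.
    """
    num = table.fraction_of_mapped[Category.HDR_KI]
    denom_cats = [Category.NHEJ, Category.MH_DEL, Category.OTHER]
    if include_nhej_ki:
        denom_cats.append(Category.NHEJ_KI)
    den = sum(table.fraction_of_mapped[c] for c in denom_cats)
    if num == 0.0:
        return 0.0
    if den == 0.0:
        return math.inf
    return num / den


@dataclass
class VariantProfileRow:
    """One row of the top-variant profile (rank 1 = most frequent)."""

    rank: int
    variant_key: str
    window_sequence: str
    category: Category
    orientation: Optional[Orientation]
    count: int
    abs_freq: float  # fraction of mapped reads
    rel_freq: float  # fraction of mutated reads; NaN for unmodified rows


def render_window(
    design: ExperimentDesign,
    events: Sequence[VariantEvent],
    flank: int = 30,
) -> str:
    """Render a variant across +/-flank bp around the cut.

    Deleted reference bases become ``-``; inserted bases are shown in
    lowercase at their insertion point; substituted bases appear as the
    read base. Positions outside the reference are left blank.
    """
    ref = design.reference
    center = design.cut.window_center
    lo, hi = center - flank, center + flank
    dels: set[int] = set()
    subs: dict[int, str] = {}
    ins_at: dict[int, str] = {}
    for ev in events:
        if ev.etype is EventType.DELETION:
            dels.update(range(ev.ref_start, ev.ref_end))
        elif ev.etype is EventType.SUBSTITUTION:
            for k, base in enumerate(ev.inserted_seq):
                subs[ev.ref_start + k] = base
        else:
            ins_at[ev.ref_start] = ev.inserted_seq.lower()
    out: list[str] = []
    for pos in range(lo, hi):
        if pos in ins_at:
            out.append(ins_at[pos])
        if pos < 0 or pos >= len(ref):
            out.append(" ")
        elif pos in dels:
            out.append("-")
        elif pos in subs:
            out.append(subs[pos])
        else:
            out.append(ref[pos])
    if hi in ins_at:
        out.append(ins_at[hi])
    return "".join(out)


def top_variants(run: ClassificationRun, n: int = 10, flank: int = 30) -> list[VariantProfileRow]:
    """The n most frequent variants, ranked by fraction of mapped reads.

    Reads are grouped by canonical in-window variant key; ties are broken
    by lexicographic key order. Frequencies are fractions of mapped
    (absolute) and of mutated (relative) reads.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    table = tabulate(run.records)
    key_counts: dict[str, int] = {}
    for rec in run.records:
        if rec.category is Category.DISCARDED:
            continue
        key_counts[rec.variant_key] = key_counts.get(rec.variant_key, 0) + rec.count
    ranked = sorted(key_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    rows: list[VariantProfileRow] = []
    for rank, (key, count) in enumerate(ranked, start=1):
        cat, orient = run.key_category[key]
        events = run.key_events[key]
        if cat is Category.UNMODIFIED:
            rel = math.nan
        else:
            rel = count / table.mutated_reads if table.mutated_reads else math.nan
        rows.append(
            VariantProfileRow(
                rank=rank,
                variant_key=key,
                window_sequence=render_window(run.design, events, flank=flank),
                category=cat,
                orientation=orient,
                count=count,
                abs_freq=count / table.mapped_reads,
                rel_freq=rel,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# writers and plotting


def write_outcome_table(table: OutcomeTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tcount\tpct_of_mapped\tpct_of_mutated\n")
        for cat in MAPPED_CATEGORIES:
            pm = 100.0 * table.fraction_of_mapped[cat]
            if cat is Category.UNMODIFIED:
                pmu = ""
            else:
                pmu = f"{100.0 * table.fraction_of_mutated[cat]:.4f}"
            fh.write(f"{cat.value}\t{table.counts[cat]}\t{pm:.4f}\t{pmu}\n")
        fh.write(f"DISCARDED\t{table.discarded}\t\t\n")


def write_variant_profile(rows: Sequence[VariantProfileRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tcategory\torientation\tcount\tabs_freq\trel_freq\twindow_sequence\tvariant_key\n")
        for r in rows:
            orient = r.orientation.value if r.orientation else ""
            rel = "" if math.isnan(r.rel_freq) else f"{r.rel_freq:.6f}"
            fh.write(
                f"{r.rank}\t{r.category.value}\t{orient}\t{r.count}\t"
                f"{r.abs_freq:.6f}\t{rel}\t{r.window_sequence}\t{r.variant_key}\n"
            )


_CATEGORY_COLORS = {
    Category.UNMODIFIED: "#bdbdbd",
    Category.NHEJ: "#1f77b4",
    Category.MH_DEL: "#d62728",
    Category.NHEJ_KI: "#ff7f0e",
    Category.HDR_KI: "#2ca02c",
    Category.OTHER: "#9467bd",
}


def plot_report(
    tables: dict[str, OutcomeTable],
    path,
    profile: Optional[Sequence[VariantProfileRow]] = None,
) -> None:
    """Stacked-bar outcome summary (one bar per sample) with an optional
    top-variant panel; written as SVG or PNG depending on the suffix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ncols = 2 if profile else 1
    fig, axes = plt.subplots(1, ncols, figsize=(5 * ncols, 4.5))
    ax0 = axes[0] if ncols == 2 else axes
    samples = list(tables)
    bottoms = [0.0] * len(samples)
    for cat in MAPPED_CATEGORIES:
        vals = [100.0 * tables[s].fraction_of_mapped[cat] for s in samples]
        ax0.bar(samples, vals, bottom=bottoms, label=cat.value,
                color=_CATEGORY_COLORS[cat])
        bottoms = [b + v for b, v in zip(bottoms, vals)]
    ax0.set_ylabel("% of mapped reads")
    ax0.set_ylim(0, 100)
    ax0.legend(fontsize=7)
    ax0.tick_params(axis="x", rotation=30)
    if profile:
        ax1 = axes[1]
        ypos = range(len(profile), 0, -1)
        ax1.barh(
            list(ypos),
            [100.0 * r.abs_freq for r in profile],
            color=[_CATEGORY_COLORS[r.category] for r in profile],
        )
        ax1.set_yticks(list(ypos))
        ax1.set_yticklabels(
            [f"#{r.rank} {r.category.value}" for r in profile], fontsize=7
        )
        ax1.set_xlabel("% of mapped reads")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
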