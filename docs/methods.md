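# Methods

## Coordinate frame and cut model

All coordinates are 0-based, half-open, on the amplicon top strand; cut
sites are inter-base integers (a cut at `c` separates `reference[c-1]`
and `reference[c]`). The guide's 20-nt protospacer plus its NGG PAM must
match the reference exactly and uniquely — a mismatched or multiply
matching guide is an error, not a warning, because every downstream
coordinate (window, alleles, variant keys) hangs off this placement.
Only SpCas9 (NGG) is modelled; other nucleases are rejected.

SpCas9's HNH domain cuts the strand base-paired to the guide 3 nt 5′ of
the PAM; in blunt mode both strands are cut there (between protospacer
positions 17 and 18). In staggered mode the protospacer-carrying strand
(RuvC substrate) is cut one base further PAM-distal, leaving a 1-nt 5′
overhang on each fragment whose base is
`reference[min(top_cut, bottom_cut)]`. Which physical strand carries
which nick follows the standard HNH/RuvC assignment; this is the only
assignment that yields 5′ (rather than 3′) overhangs. Longer overhangs
are out of scope. The quantification window is centred on the HNH
scissile position (`bottom_cut`), which coincides with both cuts in
blunt mode, so switching cut models never moves the window.

## Quantification window

Variants are attributed to editing only if they intersect the window
`[center − w, center + w)` with half-width `w = 8` bp by default, the
convention commonly used for short-amplicon editing analysis. Events
outside the window are treated as sequencing noise: they neither change
a read's category nor split variant keys.

## Alignment and variant extraction

Reads are aligned globally (Needleman–Wunsch with affine gaps, via
Biopython's `PairwiseAligner`) against the reference and, when an ssODN
donor is present, against the expected HDR allele. Scoring defaults —
match +2, mismatch −2, gap open −10, gap extend −1, a gap of length *k*
costing `open + (k−1)·extend` — make one contiguous indel at the cut
cheaper than scattered gaps, which is the desired behaviour for
amplicon data; all four parameters are config-exposed. Ties between
co-optimal alignments are resolved deterministically by the aligner's
traceback order and then canonicalized: every indel is left-normalized
to its smallest reference start among textually equivalent placements,
without crossing a neighbouring event, so identical edited sequences
always produce identical variant keys. Normalization is idempotent and
round-trips: applying a read's extracted events to the reference
reconstructs the read exactly.

Two filters define "mapped reads", which the upstream experimental
literature reports against without defining: reads with mean Phred
quality < 20 are discarded, as are reads whose best alignment score is
below 60% of the best-matching allele's self-alignment score. Both
thresholds are declared defaults, not reconstructions of any published
pipeline. Reads are assumed single-end or pre-merged; paired-end
merging, adapter trimming and BAM ingestion are out of scope. A
tab-delimited allele-frequency table ({aligned_sequence, read_count})
can substitute for FASTQ; gap characters are stripped and every
sequence is re-aligned internally, so only the sequence and count
columns are trusted.

## Microhomology

For a deletion `[s, e)` the junction-microhomology length is the number
of distinct equal-length deletion placements producing the identical
edited sequence, minus one. It is computed by sliding: one step left is
valid iff `ref[s−i] == ref[e−i]` for every step taken, and
symmetrically to the right; the count is therefore placement-invariant,
so upstream left-alignment can never change it. Note this deliberately
extends past the deleted segment's own length in homopolymer runs
(deleting one A of AAAAAA has microhomology 5), which the
"shared junction bases" intuition caps; the placement-count definition
is the one the package uses throughout because it is exactly testable
by enumeration.

## Classification cascade

First match wins, per read:

1. **HDR_KI** — an HDR allele exists, the read's alignment to it has
   zero in-window indels, and all intended donor substitutions (e.g. a
   PAM-blocking edit) are present. In-window substitutions elsewhere
   are tolerated (sequencing errors must not demote genuine HDR reads);
   reverting an intended substitution disqualifies.
2. **NHEJ_KI** — the reference alignment has exactly one in-window
   insertion and no in-window deletion, and the insertion matches the
   donor payload (either orientation) with identity ≥ 0.90, where
   identity = identical aligned bases / payload length, so full-payload
   coverage is required and partial or concatemeric integrations fall
   through to OTHER. The insertion is matched together with ±16 bp of
   reference context because left-normalization can rotate an inserted
   segment whose ends coincide with the flanking reference. An exact
   identity tie between orientations (palindromic payload) is
   ambiguous and does not call NHEJ_KI.
3. **UNMODIFIED** — zero in-window indels. Substitution-only reads land
   here: there is no substitution outcome class and sequencing errors
   dominate substitutions.
4. **NHEJ** — exactly one in-window indel of length ≤ 1.
5. **MH_DEL** — exactly one in-window indel, a deletion of length ≥ 2
   with junction microhomology ≥ 2 bp. Both thresholds
   (`mh_del_min_len`, `mh_min`) are config-exposed because the length
   condition is genuinely a modelling choice; the defaults require
   both.
6. **OTHER** — everything else, including reads with several in-window
   indels (their treatment is another open choice; a dedicated
   multi-indel class was not warranted).

HDR takes precedence over donor-payload detection: a read equal to the
seamless HDR allele necessarily contains the payload but is the
templated, precise edit. Imperfect HDR junctions (payload present plus
a separate in-window indel) are OTHER, keeping HDR_KI equal to the
precise edit; when the extra indel is directly adjacent to the payload
the alignment legitimately merges them into a single insertion and the
read is called NHEJ_KI, which matches the end-joining appearance of
such junctions.

## Expected knock-in alleles

HDR (ssODN): the payload is spliced at the junction defined by the
homology arms (searched within ±20 bp of the cut; arms must match the
reference exactly), with intended substitutions applied to the flanks.
Armless dsDNA: the payload (or its reverse complement) is inserted at
the cut. For 1-nt 5′-overhang dsDNA in a staggered cut, ligation is
modelled base by base: each 5′ overhang anneals with its complementary
partner, so the compatible (forward) orientation yields seamless
junctions in which the donor contributes its overhang base alongside
the payload (the inserted segment is `overhang + payload`), while the
flipped orientation presents non-complementary ends and carries a 1-nt
non-reference base at the junction. When the donor overhang is not
specified it defaults to the base complementary to the target-site
overhang.

## Aggregation

The outcome table reports exact integer counts, fractions of mapped
reads (summing to 1 including UNMODIFIED) and fractions of mutated
reads (mapped − unmodified; reported as 0 with a flag when no read is
mutated). The HDR:InDel ratio divides the HDR_KI fraction by the pooled
NHEJ + MH_DEL + OTHER fraction — the mutagenic non-knock-in outcomes —
with NHEJ_KI excluded by default (config switch to include it); zero
HDR gives 0, a zero denominator with positive HDR is reported as
infinity. The top-variant profile groups reads by canonical in-window
variant key (indels and substitutions; out-of-window noise never splits
a variant), ranks by count with lexicographic tie-break, and renders
each variant across ±30 bp of the cut with `-` for deleted bases and
lowercase for insertions.

## Long-read deletion statistics

`depth[i]` counts reads covering base `i` outside any deletion segment;
`Ct` counts unique reads whose span intersects the amplicon (an
optional minimum-span-fraction filter, default 0, excludes fragmentary
alignments); `Cm` is the mean of `depth`. The deletion proportion is
`(Ct − Cm) / Ct` — the only reading of that expression that yields a
proportion in [0, 1] — and the deletion index is treated minus control.
Inputs are pre-aligned read spans or a coverage TSV (`#Ct=` manifest
line, then pos/depth); aligning real long reads, consensus calling and
CPM normalization are delegated upstream, since raw depth suffices for
the statistic.

## Simulator

`make_fixture` draws a random amplicon (default 200 nt; cut centred),
plants a unique protospacer+NGG, and engineers a repeat so that the
designed deletion ending at the cut has junction microhomology of
exactly the requested length (verified against `mh_length` at
construction; the engineered microhomology is limited to 4 bp so the
repeat cannot overwrite the PAM). ssODN fixtures carry 20-bp homology
arms, a 34-nt payload, and a PAM-blocking intended substitution — as a
real ssODN design would — which also makes the HDR allele
distinguishable from an armless capture of the same payload. Each
candidate fixture must classify all of its own outcome templates
correctly at zero noise or construction retries.

`simulate_reads` draws categories i.i.d. from the mixture and applies
uniform per-base substitution errors (rate ≤ 0.05; indel errors are
deliberately absent so category ground truth stays well defined — a
limitation relative to real data, where indel sequencing errors and
PCR chimeras exist). Read length equals template length, emulating
merged paired-end reads; PCR bias and quality profiles are not
modelled. Passing tests therefore demonstrate correctness of the
classification logic under substitution noise, not robustness to every
artefact of real libraries. The NHEJ +1 template duplicates the base 5′
of the cut (the canonical template-independent insertion); the
multi-indel template combines a −1 deletion at the cut with a +1
insertion 5 bp away, guaranteeing the fall-through class. The
engineered deletion's true category follows the classifier thresholds
(a 1-bp engineered deletion is NHEJ; microhomology below 2 is OTHER).
Identical (design, mixture, seed) inputs give byte-identical FASTQ and
labels; all randomness flows from explicit integer seeds.

## Problem sizes and numerical choices

The validation suite uses 1,000 random references for the
microhomology/placement-enumeration equivalence (180,000 deletions),
ten fixtures × 5,000 reads for zero-noise identifiability, one 20,000
read mixture at 0.1% error for fraction recovery (tolerance ±0.01, the
3σ binomial bound), 10,000 long reads for the deletion statistics
(tolerance ±0.02), and 200 random pairs ≤ 30 nt against an exhaustive
affine-gap dynamic program that enumerates all optimal paths (the
implementation's event list must be a member of the optimal set, since
distinct co-optimal placements can exist). Fractions of mapped reads
are checked to sum to 1 within 1e-12. The acceptance script scales the
zero-noise and microhomology checks down (five fixtures × 2,000 reads;
300 references) to keep a single run light while the test suite
retains the full sizes.

## Known limitations

- Substitution-only reads are counted UNMODIFIED; an experiment whose
  intended edit is itself a substitution needs the HDR route (intended
  substitutions on an ssODN), not the category table.
- Donor payloads sharing long identity with the target locus can
  inflate insertion/payload identity via the ±16 bp context padding.
- Translocations, concatemers, vector-backbone integration and
  synthesis-dependent alt-EJ are not typed; they surface as OTHER.
- Multi-guide designs within one amplicon and non-NGG nucleases are
  rejected by construction.
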