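# Methods

This note documents the models behind each module, the defaults and why they
were chosen, what the simulator does and does not emulate, and the numerical
conventions used throughout.

## Bead-primer and whitelist model

The bead primer is modelled 5′→3′ as: a 27-nt PCR handle carrying an
enzymatic (uracil) cleavage site, then three ligation rounds — segment 1
(10 nt) + 7-nt linker, segment 2 (10 nt) + 4-nt linker, segment 3 (10 nt) —
then the 8-nt UMI and a 20-nt poly(T) capture tail. The stage lengths after
initial synthesis and each ligation round are therefore 27, 44, 58 and
96 nt, and the three segments concatenate to the 30-nt cell barcode. Only
the total lengths are constrained by the assay; the split between segment
and linker lengths is a design choice of this toolkit (10+10+10 segments
with linkers sized to meet the stage totals), and the handle/linker
sequences shipped as defaults are placeholders — real bead manifests can be
loaded from a `(round, index, sequence)` TSV and override everything.

Segment sets are drawn by seeded rejection sampling under a minimum
intra-round pairwise Hamming distance of 3. Because per-round segment
lengths are fixed and segments are unique within a round, two distinct
whitelist barcodes always differ in at least one whole segment, so the
whitelist-wide minimum distance equals the intra-round minimum (3). The
default 96 × 96 × 48 design yields exactly 442,368 barcodes.

In sequenced Read1 the barcode appears as a contiguous 30-mer after the
8-nt UMI; the linkers belong to the physical primer, not to the read layout
consumed by demultiplexing.

## Barcode correction

An observed 30-mer is assigned to a whitelist member iff exactly one member
lies within Hamming distance 2; zero or multiple candidates discard the
read ("uniquely assigned" is read literally, and nothing is repaired by
frequency priors). Two equivalent strategies are used:

- whitelists ≤ 2·10⁵ members: a vectorised distance scan over the encoded
  whitelist matrix;
- larger whitelists: exact-hash lookups of the ≤2-substitution
  neighbourhood of the query (1 + 90 + 35,235 variants).

An exact hit short-circuits only when the whitelist carries a verified
minimum pairwise distance ≥ 3 — by the triangle inequality no second member
can then sit within distance 2 of the query. Note that a minimum distance
of 3 does *not* guarantee unique correction of every ≤2-error read
(guaranteed unique 2-error correction needs distance 5); ambiguous cases
are discarded, and for randomly generated segments (typical intra-round
distances ≈ 7) they are rare (<1% at 1% per-base error in simulation).

## Simulator

The generator emulates, per molecule: biotype choice (rRNA with probability
0.83 by default — the pre-depletion regime; the non-rRNA mass split
80/15/5 across mRNA/tRNA/ncRNA, roughly a bacterial total-RNA library),
gene choice by log-normal within-class abundances, a capture start position
that is geometric from the 5′ end (rate `coverage_decay`, default 0.003 per
nt — cDNA synthesis runs 5′→3′, so coverage decays toward 3′), an insert
length uniform on 100–400 bp (clamped so the insert fits the transcript —
fragments below the library's size selection are not captured), and a PCR
copy number 1 + Poisson(reads_per_umi_mean − 1). Per cell, UMI budgets are
log-normal (default median 300, σ_log 0.5, i.e. the 10²–10³ UMIs/cell
regime of real bacterial droplet libraries). Droplet occupancy is
zero-truncated Poisson(λ) with k ≥ 3 collapsed to 2 (negligible at realistic
loading, λ ≈ 0.1 by default); each occupied droplet draws a distinct
whitelist barcode. Barcode sequencing errors are uniform substitutions at a
configurable per-base rate; quality strings are constant, since correction
logic operates in sequence space. `inject_ambient` re-draws a fraction of
each barcode's reads from the pooled cross-cell molecule pool, emulating
free cDNA captured by the wrong droplet (this is what pushes per-species
specificity below 100%).

Every read carries ground truth (cell, species, gene, biotype, UMI, capture
position) and a "perfect aligner" record (contig, 1-based inclusive
interval, strand, unique flag), so downstream stages are testable exactly.

What the simulator does **not** model: sequencing errors beyond uniform
substitution on the barcode, chimeras or realistic PCR family-size
distributions, primer-sequence thermodynamics of random priming (capture is
positional only), droplet/bead size variation, and cross-species
differences in lysis efficiency or RNA content. Tests passing on simulated
data therefore validate the pipeline's logic and statistics, not its
robustness to artefacts absent from the model.

## Counting

Reads are assigned to genes by interval overlap (≥ 1 nt) against the
annotation; reads overlapping zero or ≥ 2 genes are dropped and counted by
reason, matching the default behaviour of standard feature-counting tools.
Assignment is unstranded by default: bacterial operons plus random priming
make the strand of a cDNA read uninformative; a stranded mode exists.
UMI deduplication is exact by default (identical (barcode, gene, UMI)
triples count once) — the conservative reading when only the tool family,
not the collapse method, is specified. The optional directional mode builds
the standard directed UMI network (edge u→v when d_H = 1 and
count(u) ≥ 2·count(v) − 1) and counts clusters from the highest-count nodes
down.

## Cell calling

Barcodes are ranked descending by detected genes (the published ranking;
total UMIs available by flag — the parameter names reference UMIs and at
small gene universes the genes metric saturates, so the UMI metric is used
in the toolkit's own desk-scale experiments). The knee threshold is
`quantile(maxPercentile)` of the top `nExpectedCells` metrics divided by
`maxMinRatio`. The "EmptyDrops-like" rescue is this toolkit's concrete
definition of the published parameterisation: ambient profile = pooled
counts of barcodes ranked in `(indMin, indMax]`, smoothed with a 1e-8
pseudocount per gene; candidates = sub-knee barcodes with
UMIs ≥ max(umiMin, umiMinFracMedian × median knee-cell UMIs), capped at
`candMaxN` by rank; per candidate a Monte-Carlo p-value
(1 + #{LL_sim ≤ LL_obs})/(simN + 1) under the ambient multinomial (full
log-likelihood including the multinomial coefficient), draws cached per
distinct total; Benjamini–Hochberg across candidates, q ≤ FDR ⇒ rescued.
The +1 correction means p-values are never 0, and the whole procedure is
deterministic given (matrix, params, seed). With fewer than 100 barcodes in
the ambient window the rescue degrades to knee-only calling with a warning.

## QC metrics

*Barnyard*: a barcode is "mixed" iff its minor-species UMI fraction ≥ 0.2
and both top species have ≥ 10 UMIs (both thresholds exposed — the
published analysis reports counts, not a rule, so this is a toolkit
convention); doublet rate = mixed / all labelled barcodes; specificity per
species = median own-species UMI fraction over that species' singlets.
*Saturation*: reads (not UMIs) are subsampled without replacement to
depth × n_cells, so duplication structure shapes the curve realistically;
depths beyond the library are marked unattainable rather than erroring.
*Gene-body coverage*: per-base coverage per transcript (length ≥ 100 nt),
averaged into 100 percentile bins oriented 5′→3′ by strand, summed over
transcripts and normalised to a maximum of 1. Under 5′-biased capture the
profile ramps over roughly one fragment length (fragments accumulate from
the 5′ end) and then decays monotonically — the shape asserted in tests.
*Pseudo-bulk correlation*: Pearson r on per-gene log10(count + 1) over the
outer-joined gene universe.

## DASH guide design

Cut sites are fixed at the canonical blunt position 3 bp 5′ of the PAM.
Filters: GC in [0.30, 0.70]; no homopolymer run > 4 and no TTTT anywhere
(T7 terminator); off-targets defined conservatively as an exact 12-nt
PAM-proximal seed adjacent to NGG in the non-rRNA sequence set. Tiling is
greedy left-to-right (always the rightmost candidate within `max_gap` of the
last covered position — minimal among feasible covers); PAM deserts are
reported as uncovered intervals, not errors. Digestion is binary — any full
protospacer+PAM between the adapters kills re-amplification — with an
optional global cutting-efficiency multiplier (default 1.0; the wet
protocol's molar ratios are metadata, not a kinetic model). The composition
identity r(1−d)/(r(1−d)+(1−r)) conserves non-rRNA molecules exactly. The
observed ~90% depletion of an 83%-rRNA library to ~32% corresponds to
d ≈ 0.904; in the toolkit's experiments that incompleteness is reproduced
structurally by a PAM-free (A/T-only) stretch of the target that no guide
can reach. Templates for in-vitro transcription are promoter + spacer +
scaffold with a G prepended when the spacer does not start with one; the
shipped scaffold constant is a synthetic stand-in and should be replaced
with the validated scaffold for real pools.

## Numerical conventions and problem sizes

All user-facing coordinates are 1-based inclusive (GTF convention);
internal arithmetic is 0-based half-open. Gzip is detected by magic bytes.
Rank ties break by the secondary metric then lexicographic barcode, so
orderings are deterministic. All randomness flows from explicit integer
seeds through numpy Generators.

The test-suite experiments run at desk scale by design: end-to-end counting
uses 500 cells / ~10⁵ reads; the rescue experiments use 1,000 large +
300 small planted cells over 20,000 ambient barcodes with simN = 1000 and
rank windows rescaled to that barcode count; coverage checks use 3 × 10⁵
fragments on 1-kb transcripts. Dataset-scale figures that depend on real
sequencing depth (median UMIs/genes per cell, total called cells) are
covered qualitatively by these simulations, not asserted numerically.

## Known limitations

Alignment itself is out of scope — alignments are consumed from a TSV (or
SAM via a thin adapter mapping MAPQ to the unique flag), never produced.
Genes are single intervals (no splicing); multi-overlap reads are dropped
rather than fractionally assigned; ambient-RNA decontamination and doublet
*removal* are not attempted (the toolkit measures them); sgRNA on-target
activity and secondary structure are not scored.
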